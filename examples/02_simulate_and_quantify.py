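"""Closed-loop binding quantification on simulated gel bands.

Simulates a supershift experiment in which KLF4 binds its canonical site
4-fold over background whenever the site sits in the linkers (|offset|
>= 55 bp from the dyad), processes the error-free reads through the full
trim/merge/filter/map pipeline, and recovers the relative supershift.
"""

import numpy as np

import pioneerseq as ps

motifs = ps.default_motifs()
manifest = ps.simulate_demo_library(n_tfbs=4, seed=0, n_itn=10, motifs=motifs)

# ground truth: 4-fold enrichment at linker/edge positions of Klf4-1 on 601
enriched = [
    e.id for e in manifest
    if e.nps_id == "601" and e.tfbs_id == "Klf4-1"
    and e.dyad_offset is not None and abs(e.dyad_offset) >= 55
]
cfg = ps.SimulationConfig(seed=1, reads_per_band=40_000, error_rate=0.0,
                          enrichment={i: 4.0 for i in enriched})
reads, truth = ps.simulate_emsa(manifest, cfg)

tables = {}
for band in ("supershift", "nucleosome_null"):
    tables[band], _ = ps.process_pairs(reads[band], manifest, band=band)
    exact = tables[band].counts == truth.band_counts[band]
    print(f"{band:<16}: {tables[band].total_mapped} reads mapped, "
          f"matches ground truth: {exact}")

controls = ps.select_controls(manifest, "KLF4", motifs, nps_id="601")
vals = ps.relative_supershift(
    tables["supershift"], tables["nucleosome_null"], controls, tf="KLF4",
    library_ids=[e.id for e in manifest if e.nps_id == "601"],
)
edge = [v.value for i, v in vals.items() if i in enriched and v.status == "ok"]
core = [
    v.value for i, v in vals.items()
    if v.status == "ok" and manifest.by_id(i).tfbs_id == "Klf4-1" and i not in enriched
]
print(f"mean supershift, enriched linker sites : {np.mean(edge):+.3f} log2 "
      f"(simulated truth: +2.000)")
print(f"mean supershift, unenriched core sites : {np.mean(core):+.3f} log2 "
      f"(simulated truth:  0.000)")
# The statistic reads out log2 fold enrichment over the nonspecific
# controls; values near 2 and 0 mean the pipeline recovered the simulated
# binding pattern.
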