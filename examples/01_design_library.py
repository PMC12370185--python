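"""Design a tiled binding-site nucleosome library.

Scrubs three synthetic positioning inserts of resident binding sites,
tiles the full TFBS variant catalogue across each at 1-bp resolution
(dyad offsets -74..+74), and assembles the primer-flanked 230-nt oligo
manifest that downstream mapping uses as its reference.
"""

import pioneerseq as ps

motifs = ps.default_motifs()
nps = ps.make_demo_nps(seed=0, motifs=motifs)

tiled = [t for rec in nps for m in motifs for t in ps.tile_tfbs(rec, m)]
manifest = ps.assemble_library(tiled)

print(f"NPS backbones      : {[r.id for r in nps]}")
print(f"TFBS variants      : {len(motifs)}")
print(f"entries per variant: 149 (dyad offsets -74..+74)")
print(f"library size       : {len(manifest)} oligos, all "
      f"{len(manifest.entries[0].oligo_seq)} nt")
for tf in ("KLF4", "OCT4", "SOX2", "MYC"):
    cs = ps.select_controls(manifest, tf, motifs, nps_id="601")
    print(f"601 controls for {tf:<5}: {len(cs)} sequences")
# Each count is the number of same-backbone sequences carrying another
# factor's site — the nonspecific baseline the supershift statistic
# normalizes against.
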