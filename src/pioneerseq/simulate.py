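"""Synthetic Pioneer-seq experiments with known ground truth.

Everything upstream — library design, gel-band sequencing, MNase
digestion — can be emulated here so the full analysis stack has a closed
loop: band read pools are multinomial draws over the library with known
per-sequence enrichment, MNase fragment pools draw centers from a known
dyad-position mixture, and reads carry configurable substitution errors.
All randomness flows from a single seeded generator, so a (config, seed)
pair reproduces a run exactly.

The demonstration NPS inserts generated here are synthetic stand-ins for
the classic positioning sequences (random seeded 191-mers, scrubbed of
the study motifs); they carry the familiar labels only so that demo
output reads naturally.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .coords import DYAD_INDEX, INSERT_LEN
from .design import (
    DEFAULT_FWD_PRIMER,
    DEFAULT_REV_PRIMER,
    ITNCandidate,
    LibraryManifest,
    NPSRecord,
    assemble_library,
    scrub_nps,
    select_itns,
    tile_tfbs,
)
from .mnase import FragmentRecord
from .motifs import TFBSMotif, default_motifs, revcomp
from .reads import CountTable, SequencedRead, write_fastq

BANDS = ("input", "naked_dna", "nucleosome_null", "supershift")


@dataclass
class SimulationConfig:
    """Study conditions for a synthetic experiment.

    `enrichment` maps library id -> fold enrichment e in the supershift
    band (e = 1 is the nonspecific baseline); `formation` maps library id
    -> relative abundance in the nucleosome bands (capturing unequal
    nucleosome formation); ids absent from either map default to 1.
    Fragment lengths follow a truncated normal (mean 140, sd 10, clipped
    to [80, 191]) whose mean shrinks by `trim_per_minute` per digestion
    minute past the 15-minute reference.
    """

    seed: int = 0
    reads_per_band: int = 50_000
    error_rate: float = 0.0
    read_length: int = 150
    enrichment: dict[str, float] = field(default_factory=dict)
    formation: dict[str, float] = field(default_factory=dict)
    naked_abundance: dict[str, float] = field(default_factory=dict)
    dyad_mixture: dict[str, list[tuple[float, float, float]]] = field(default_factory=dict)
    fragment_mean: float = 140.0
    fragment_sd: float = 10.0
    fragment_bounds: tuple[int, int] = (80, INSERT_LEN)
    trim_per_minute: float = 0.6

    def quality(self) -> int:
        """Constant Phred score consistent with the substitution rate."""
        if self.error_rate <= 0:
            return 41
        return int(min(41, max(2, round(-10.0 * math.log10(self.error_rate)))))


@dataclass
class GroundTruth:
    """What the simulator actually drew, for closed-loop assertions."""

    seed: int
    band_counts: dict[str, dict[str, int]] = field(default_factory=dict)
    log2_enrichment: dict[str, float] = field(default_factory=dict)
    fragments: list[FragmentRecord] = field(default_factory=list)

    def write(self, path: str | Path) -> None:
        payload = {
            "seed": self.seed,
            "band_counts": self.band_counts,
            "log2_enrichment": self.log2_enrichment,
            "fragments": [
                [f.library_id, f.insert_start, f.insert_end, f.timepoint]
                for f in self.fragments
            ],
        }
        Path(path).write_text(json.dumps(payload))


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


def make_demo_nps(
    seed: int = 0,
    names: Sequence[str] = ("601", "5S", "MMTV"),
    motifs: Sequence[TFBSMotif] | None = None,
) -> list[NPSRecord]:
    """Seeded synthetic 191-nt positioning inserts, scrubbed of study motifs."""
    motifs = list(motifs) if motifs is not None else default_motifs()
    rng = np.random.default_rng(seed)
    records = []
    for name in names:
        raw = NPSRecord(name, random_dna(rng, INSERT_LEN))
        records.append(scrub_nps(raw, motifs).record)
    return records


def simulate_demo_library(
    n_tfbs: int = 4,
    nps: Sequence[NPSRecord] | None = None,
    seed: int = 0,
    n_itn: int = 20,
    motifs: Sequence[TFBSMotif] | None = None,
    capacity: int = 7500,
) -> LibraryManifest:
    """Deterministic reduced-scale library built through the design module.

    Tiles the first `n_tfbs` motifs of the catalogue over each NPS (149
    entries per NPS x TFBS) and adds `n_itn` ITN-like entries: random
    genomic-looking windows with one motif planted at a random position,
    passed through the ITN filter.
    """
    motifs = list(motifs) if motifs is not None else default_motifs()
    # prefer one motif per factor so control sets exist for every focal TF
    use, rest, seen = [], [], set()
    for m in motifs:
        (use if set(m.owners) - seen else rest).append(m)
        seen |= set(m.owners)
    use = (use + rest)[:n_tfbs]
    nps = list(nps) if nps is not None else make_demo_nps(seed, motifs=motifs)
    tiled = []
    for rec in nps:
        for m in use:
            tiled.extend(tile_tfbs(rec, m))
    rng = np.random.default_rng(seed + 1)
    candidates = []
    for k in range(n_itn):
        window = list(random_dna(rng, INSERT_LEN))
        m = motifs[int(rng.integers(len(motifs)))]
        pos = int(rng.integers(0, INSERT_LEN - len(m)))
        window[pos : pos + len(m)] = m.site_seq
        start = int(rng.integers(1_000_000, 2_000_000))
        candidates.append(
            ITNCandidate(f"chr{1 + k % 5}", start, start + INSERT_LEN,
                         "".join(window), score=0.9)
        )
    itns, _log = select_itns(candidates, motifs)
    return assemble_library(tiled, itns, capacity=capacity)


# ---------------------------------------------------------------------------
# EMSA band simulation
# ---------------------------------------------------------------------------

def _band_probabilities(
    manifest: LibraryManifest, config: SimulationConfig
) -> dict[str, np.ndarray]:
    ids = manifest.ids
    unknown = (set(config.enrichment) | set(config.formation)) - set(ids)
    if unknown:
        raise ValueError(f"enrichment/formation map references unknown ids: {sorted(unknown)[:5]}")
    a = np.array([config.formation.get(i, 1.0) for i in ids], dtype=float)
    e = np.array([config.enrichment.get(i, 1.0) for i in ids], dtype=float)
    naked = np.array([config.naked_abundance.get(i, 1.0) for i in ids], dtype=float)
    if (a <= 0).any() or (e < 0).any():
        raise ValueError("abundances must be > 0 and enrichments >= 0")
    probs = {
        "input": a / a.sum(),
        "naked_dna": naked / naked.sum(),
        "nucleosome_null": a / a.sum(),
        "supershift": (a * e) / (a * e).sum(),
    }
    return probs


def simulate_band_counts(
    manifest: LibraryManifest,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[dict[str, CountTable], GroundTruth]:
    """Multinomial band counts — the read pools without the sequencing step.

    This is exactly the allocation :func:`simulate_emsa` turns into reads;
    at error rate 0 the read pipeline reproduces these tables verbatim.
    """
    rng = rng or np.random.default_rng(config.seed)
    probs = _band_probabilities(manifest, config)
    ids = manifest.ids
    truth = GroundTruth(seed=config.seed)
    tables: dict[str, CountTable] = {}
    for band in BANDS:
        draw = rng.multinomial(config.reads_per_band, probs[band])
        counts = {i: int(c) for i, c in zip(ids, draw) if c > 0}
        truth.band_counts[band] = counts
        tables[band] = CountTable("sim", band, dict(counts))
    truth.log2_enrichment = {
        i: math.log2(config.enrichment.get(i, 1.0)) if config.enrichment.get(i, 1.0) > 0
        else float("-inf")
        for i in ids
    }
    return tables, truth


def _mutate(seq: str, rng: np.random.Generator, error_rate: float) -> str:
    if error_rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hits = np.nonzero(rng.random(len(arr)) < error_rate)[0]
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    for i in hits:
        choices = bases[bases != arr[i]]
        arr[i] = rng.choice(choices)
    return arr.tobytes().decode()


def _pair_from_molecule(
    molecule: str, read_id: str, read_length: int, qual: int
) -> tuple[SequencedRead, SequencedRead]:
    """Exact prefix/suffix read views of a molecule (guaranteed overlap)."""
    L = min(read_length, len(molecule))
    r1 = molecule[:L]
    r2 = revcomp(molecule[-L:])
    quals = (qual,) * L
    return (
        SequencedRead(read_id + "/1", r1, quals),
        SequencedRead(read_id + "/2", r2, quals),
    )


def simulate_emsa(
    manifest: LibraryManifest,
    config: SimulationConfig,
) -> tuple[dict[str, list[tuple[SequencedRead, SequencedRead]]], GroundTruth]:
    """Paired reads for the four gel bands plus the ground-truth allocation.

    Each band's molecules are drawn once (multinomial over the library),
    then each molecule is the full 230-nt oligo with independent per-base
    substitution errors, split into a 150-nt forward/reverse read pair
    with constant qualities consistent with the error rate.
    """
    rng = np.random.default_rng(config.seed)
    tables, truth = simulate_band_counts(manifest, config, rng)
    qual = config.quality()
    reads: dict[str, list[tuple[SequencedRead, SequencedRead]]] = {}
    for band in BANDS:
        pairs = []
        k = 0
        for lid, count in tables[band].counts.items():
            oligo = manifest.by_id(lid).oligo_seq
            for _ in range(count):
                molecule = _mutate(oligo, rng, config.error_rate)
                pairs.append(
                    _pair_from_molecule(molecule, f"{band}:{lid}:{k}",
                                        config.read_length, qual)
                )
                k += 1
        reads[band] = pairs
    return reads, truth


# ---------------------------------------------------------------------------
# MNase simulation
# ---------------------------------------------------------------------------

def simulate_mnase(
    manifest: LibraryManifest,
    config: SimulationConfig,
    timepoints: Sequence[int] = (15,),
    fragments_per_id: int = 200,
) -> tuple[list[FragmentRecord], GroundTruth]:
    """MNase fragments with centers from each NPS's dyad-position mixture.

    Per library sequence and timepoint, `fragments_per_id` fragments are
    drawn: the center from the configured (center, sd, weight) mixture of
    its NPS (default: single population at the dyad, sd 3), the length
    from the truncated normal model with the timepoint's shortened mean,
    the span clipped to the insert.
    """
    rng = np.random.default_rng(config.seed + 1)
    lo, hi = config.fragment_bounds
    fragments: list[FragmentRecord] = []
    for entry in manifest:
        mixture = config.dyad_mixture.get(
            entry.nps_id, [(float(DYAD_INDEX), 3.0, 1.0)]
        )
        weights = np.array([w for _, _, w in mixture], dtype=float)
        if not math.isclose(weights.sum(), 1.0, abs_tol=1e-6):
            raise ValueError(f"dyad mixture weights for {entry.nps_id} must sum to 1")
        for t in timepoints:
            mean_len = config.fragment_mean - config.trim_per_minute * (t - 15)
            comp = rng.choice(len(mixture), size=fragments_per_id, p=weights)
            for ci in comp:
                center_mu, center_sd, _ = mixture[ci]
                center = int(round(rng.normal(center_mu, center_sd)))
                length = int(round(rng.normal(mean_len, config.fragment_sd)))
                length = int(np.clip(length, lo, hi))
                start = center - (length - 1) // 2
                end = start + length - 1
                start, end = max(1, start), min(INSERT_LEN, end)
                if end < start:
                    continue
                fragments.append(FragmentRecord(entry.id, start, end, t))
    truth = GroundTruth(seed=config.seed, fragments=list(fragments))
    return fragments, truth


def fragment_reads(
    fragments: Sequence[FragmentRecord],
    manifest: LibraryManifest,
    config: SimulationConfig,
) -> list[tuple[SequencedRead, SequencedRead]]:
    """Paired reads covering each MNase fragment (for mapping tests)."""
    rng = np.random.default_rng(config.seed + 2)
    qual = config.quality()
    pairs = []
    for k, f in enumerate(fragments):
        insert = manifest.by_id(f.library_id).insert_seq
        molecule = _mutate(insert[f.insert_start - 1 : f.insert_end], rng,
                           config.error_rate)
        pairs.append(
            _pair_from_molecule(molecule, f"mnase:{f.library_id}:{k}",
                                config.read_length, qual)
        )
    return pairs


# ---------------------------------------------------------------------------
# on-disk experiment bundle
# ---------------------------------------------------------------------------

def write_experiment(
    outdir: str | Path,
    manifest: LibraryManifest,
    config: SimulationConfig,
) -> dict:
    """Write FASTQ pairs per band, ground truth, and a samplesheet TSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    reads, truth = simulate_emsa(manifest, config)
    rows = []
    for band, pairs in reads.items():
        fq1 = outdir / f"sim_{band}_R1.fastq"
        fq2 = outdir / f"sim_{band}_R2.fastq"
        write_fastq([p[0] for p in pairs], fq1)
        write_fastq([p[1] for p in pairs], fq2)
        rows.append(
            {"sample": "sim", "band": band, "fastq1": str(fq1), "fastq2": str(fq2)}
        )
    truth.write(outdir / "ground_truth.json")
    manifest.write(outdir / "manifest.tsv", outdir / "library.fasta")
    import pandas as pd

    pd.DataFrame(rows).to_csv(outdir / "samplesheet.tsv", sep="\t", index=False)
    return {"outdir": str(outdir), "bands": list(reads), "n_entries": len(manifest)}
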