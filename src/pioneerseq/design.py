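"""Nucleosome oligo library design.

Builds the tiled binding-site library: each nucleosome positioning sequence
(NPS) is first *scrubbed* of pre-existing binding sites for the factors
under study, then a site is substituted in at every dyad offset of a
1-bp-resolution grid covering the 147-bp core and both linkers (149
positions by default). Genomic in vivo-targeted nucleosome (ITN) windows
pass a motif-presence and nucleosome-formation-score filter. Every insert
is flanked by PCR primers to a 230-nt synthesis oligo, and the full design
is written as a manifest (TSV) plus reference FASTA that downstream read
mapping treats as its genome.

Design is fully deterministic: no randomness anywhere in this module.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .coords import (
    CORE_LEN,
    CORE_SPAN,
    DEFAULT_GRID,
    DYAD_INDEX,
    INSERT_LEN,
    OLIGO_LEN,
    offset_to_window,
)
from .motifs import MotifHit, TFBSMotif, _column_scores, revcomp, scan_motifs, validate_dna

# default primers: generic 19/20-nt amplification handles, configurable
DEFAULT_FWD_PRIMER = "ACACTCTTTCCCTACACGA"      # 19 nt
DEFAULT_REV_PRIMER = "GTGACTGGAGTTCAGACGTG"     # 20 nt
DEFAULT_CAPACITY = 7500


@dataclass(frozen=True)
class NPSRecord:
    """A 191-nt nucleosome positioning insert with its dyad coordinate."""

    id: str
    insert_seq: str
    dyad_index: int = DYAD_INDEX
    core_span: tuple[int, int] = CORE_SPAN

    def __post_init__(self):
        seq = validate_dna(self.insert_seq, what=f"NPS {self.id}")
        object.__setattr__(self, "insert_seq", seq)
        if len(seq) != INSERT_LEN:
            raise ValueError(f"NPS {self.id}: insert must be {INSERT_LEN} nt, got {len(seq)}")
        lo, hi = self.core_span
        if hi - lo + 1 != CORE_LEN:
            raise ValueError(f"NPS {self.id}: core span must cover {CORE_LEN} bp")
        if self.dyad_index != (lo + hi) // 2:
            raise ValueError(f"NPS {self.id}: dyad index must be the core midpoint")


@dataclass(frozen=True)
class TiledSequence:
    """One designed library entry: an insert plus its primer-flanked oligo."""

    id: str
    nps_id: str
    tfbs_id: str
    dyad_offset: int | None
    insert_seq: str
    oligo_seq: str
    category: str  # 'tiled' | 'itn' | 'control'
    region: str = ""
    score: float = float("nan")

    def __post_init__(self):
        if self.category not in ("tiled", "itn", "control"):
            raise ValueError(f"unknown category {self.category!r}")
        if len(self.insert_seq) != INSERT_LEN:
            raise ValueError(f"{self.id}: insert must be {INSERT_LEN} nt")
        if len(self.oligo_seq) != OLIGO_LEN:
            raise ValueError(f"{self.id}: oligo must be {OLIGO_LEN} nt")


@dataclass(frozen=True)
class ITNCandidate:
    """A called genomic nucleosome window proposed for the library.

    `region` follows BED conventions (chrom, 0-based half-open interval);
    `window_seq` is the 191-nt sequence centered on the called nucleosome
    center; `score` is a nucleosome-formation probability in [0, 1].
    """

    chrom: str
    start: int
    end: int
    window_seq: str
    score: float = float("nan")
    tfbs_hits: tuple = ()

    @property
    def region(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


@dataclass
class ScrubResult:
    record: NPSRecord
    n_substitutions: int
    edits: list[tuple[int, str, str]]  # (1-based position, old base, new base)


@dataclass
class LibraryManifest:
    """The designed library: ordered entries plus the primer pair."""

    entries: list[TiledSequence]
    primers: tuple[str, str] = (DEFAULT_FWD_PRIMER, DEFAULT_REV_PRIMER)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        ids = [e.id for e in self.entries]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate manifest ids: {dup[:5]}")

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def by_id(self, entry_id: str) -> TiledSequence:
        return self._index()[entry_id]

    def _index(self) -> dict[str, TiledSequence]:
        if not hasattr(self, "_idx") or len(self._idx) != len(self.entries):
            self._idx = {e.id: e for e in self.entries}
        return self._idx

    @property
    def ids(self) -> list[str]:
        return [e.id for e in self.entries]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": [e.id for e in self.entries],
                "category": [e.category for e in self.entries],
                "nps_id": [e.nps_id for e in self.entries],
                "tfbs_id": [e.tfbs_id for e in self.entries],
                "dyad_offset": [e.dyad_offset for e in self.entries],
                "region": [e.region for e in self.entries],
                "score": [e.score for e in self.entries],
                "insert_seq": [e.insert_seq for e in self.entries],
                "oligo_seq": [e.oligo_seq for e in self.entries],
            }
        )

    def write(self, tsv_path: str | Path, fasta_path: str | Path | None = None) -> None:
        df = self.to_frame()
        header = json.dumps({"fwd_primer": self.primers[0], "rev_primer": self.primers[1],
                             "provenance": self.provenance})
        with open(tsv_path, "w") as fh:
            fh.write(f"#pioneerseq-manifest {header}\n")
            df.to_csv(fh, sep="\t", index=False)
        if fasta_path is not None:
            records = [
                SeqRecord(Seq(e.oligo_seq), id=e.id, description="")
                for e in self.entries
            ]
            SeqIO.write(records, str(fasta_path), "fasta")

    @classmethod
    def read(cls, tsv_path: str | Path) -> "LibraryManifest":
        with open(tsv_path) as fh:
            first = fh.readline()
            meta = {}
            if first.startswith("#pioneerseq-manifest"):
                meta = json.loads(first.split(" ", 1)[1])
                df = pd.read_csv(fh, sep="\t", dtype={"region": str})
            else:
                fh.seek(0)
                df = pd.read_csv(fh, sep="\t", dtype={"region": str})
        entries = []
        for row in df.itertuples(index=False):
            offset = None if pd.isna(row.dyad_offset) else int(row.dyad_offset)
            region = "" if pd.isna(row.region) else str(row.region)
            entries.append(
                TiledSequence(
                    id=row.id, nps_id=row.nps_id, tfbs_id=row.tfbs_id,
                    dyad_offset=offset, insert_seq=row.insert_seq,
                    oligo_seq=row.oligo_seq, category=row.category,
                    region=region, score=float(row.score),
                )
            )
        primers = (
            meta.get("fwd_primer", DEFAULT_FWD_PRIMER),
            meta.get("rev_primer", DEFAULT_REV_PRIMER),
        )
        return cls(entries, primers, meta.get("provenance", {}))


# ---------------------------------------------------------------------------
# scrubbing
# ---------------------------------------------------------------------------

def _best_edit(seq: str, hit: MotifHit, motif: TFBSMotif) -> tuple[int, str]:
    """Pick (0-based position, replacement base) that best disrupts `hit`.

    The edited position is the one with the largest per-position score
    contribution (leftmost on ties); the replacement is the base minimizing
    that contribution, alphabetical on ties, never the current base.
    """
    m = len(motif)
    window = seq[hit.start0 : hit.start0 + m]
    rc = hit.strand == "-"
    contrib = _column_scores(motif, window, rc)
    j = int(np.argmax(contrib))
    pos = hit.start0 + j
    current = seq[pos]
    target = revcomp(motif.site_seq) if rc else motif.site_seq
    if motif.pwm is None:
        # any base other than the consensus base removes the exact match
        candidates = [b for b in "ACGT" if b != target[j] and b != current]
        if not candidates:  # current already differs from consensus (PWM-free: impossible)
            candidates = [b for b in "ACGT" if b != current]
        return pos, candidates[0]
    pwm = motif.pwm_array
    col = pwm[::-1, ::-1][j] if rc else pwm[j]
    order = np.argsort(col, kind="stable")  # ascending contribution, ties alphabetical
    for k in order:
        base = "ACGT"[int(k)]
        if base != current:
            return pos, base
    return pos, "A"


def scrub_nps(
    nps: NPSRecord,
    motifs: Sequence[TFBSMotif],
    max_rounds: int = 10,
    min_score: float | None = None,
) -> ScrubResult:
    """Remove all binding-site occurrences from an NPS insert.

    Each round rescans the insert and applies one substitution per hit at
    the position contributing most to that hit's score. Raises RuntimeError
    when hits survive `max_rounds` rounds.
    """
    by_id = {m.id: m for m in motifs}
    seq = list(nps.insert_seq)
    edits: list[tuple[int, str, str]] = []
    for _ in range(max_rounds):
        hits = scan_motifs("".join(seq), motifs, min_score=min_score)
        if not hits:
            return ScrubResult(replace(nps, insert_seq="".join(seq)), len(edits), edits)
        edited_this_round: set[int] = set()
        for hit in hits:
            window = range(hit.start0, hit.start0 + len(by_id[hit.motif_id]))
            if edited_this_round.intersection(window):
                continue  # an earlier edit this round already falls in this window
            pos, base = _best_edit("".join(seq), hit, by_id[hit.motif_id])
            edits.append((pos + 1, seq[pos], base))
            seq[pos] = base
            edited_this_round.add(pos)
    residual = scan_motifs("".join(seq), motifs, min_score=min_score)
    if residual:
        raise RuntimeError(
            f"scrubbing {nps.id} failed after {max_rounds} rounds; "
            f"residual hits: {[(h.motif_id, h.start, h.strand) for h in residual]}"
        )
    return ScrubResult(replace(nps, insert_seq="".join(seq)), len(edits), edits)


# ---------------------------------------------------------------------------
# tiling and assembly
# ---------------------------------------------------------------------------

def flank_primers(
    insert: str,
    fwd: str = DEFAULT_FWD_PRIMER,
    rev: str = DEFAULT_REV_PRIMER,
) -> str:
    """Concatenate fwd(19) + insert(191) + rev(20) into the 230-nt oligo."""
    if len(fwd) != 19:
        raise ValueError(f"forward primer must be 19 nt, got {len(fwd)}")
    if len(rev) != 20:
        raise ValueError(f"reverse primer must be 20 nt, got {len(rev)}")
    if len(insert) != INSERT_LEN:
        raise ValueError(f"insert must be {INSERT_LEN} nt, got {len(insert)}")
    oligo = fwd + insert + rev
    assert len(oligo) == OLIGO_LEN
    return oligo


def tile_tfbs(
    nps: NPSRecord,
    motif: TFBSMotif,
    grid: Sequence[int] = DEFAULT_GRID,
    primers: tuple[str, str] = (DEFAULT_FWD_PRIMER, DEFAULT_REV_PRIMER),
) -> list[TiledSequence]:
    """Substitute `motif` into a scrubbed NPS at every grid dyad offset.

    The motif replaces the resident bases (insert length stays 191), its
    center landing at dyad_index + offset. Offsets where the motif would
    overrun the insert raise rather than being dropped silently.
    """
    out = []
    for offset in grid:
        start, end = offset_to_window(offset, len(motif), nps.dyad_index)
        insert = nps.insert_seq[: start - 1] + motif.site_seq + nps.insert_seq[end:]
        assert len(insert) == INSERT_LEN
        out.append(
            TiledSequence(
                id=f"{nps.id}_{motif.id}_{offset:+d}",
                nps_id=nps.id,
                tfbs_id=motif.id,
                dyad_offset=offset,
                insert_seq=insert,
                oligo_seq=flank_primers(insert, *primers),
                category="tiled",
            )
        )
    return out


# ---------------------------------------------------------------------------
# ITN selection
# ---------------------------------------------------------------------------

def periodicity_scorer(seq: str, dyad_index: int = DYAD_INDEX) -> float:
    """Surrogate nucleosome-formation score in [0, 1].

    Scores the 10-bp phasing of AA/TT/TA dinucleotides relative to the
    dyad — a coarse sequence signal of rotational positioning. This is a
    stand-in scoring function with the same [0, 1] contract as published
    nucleosome-formation models, not a reimplementation of any of them;
    inject a different callable wherever a calibrated score is needed.
    """
    seq = validate_dna(seq)
    phases = [
        math.cos(2 * math.pi * (i + 1 - dyad_index) / 10.0)
        for i in range(len(seq) - 1)
        if seq[i : i + 2] in ("AA", "TT", "TA")
    ]
    if not phases:
        return 0.5
    return (1.0 + float(np.mean(phases))) / 2.0


def select_itns(
    candidates: Iterable[ITNCandidate],
    motifs: Sequence[TFBSMotif],
    scorer: Callable[[str], float] | None = None,
    min_score: float = 0.7,
    primers: tuple[str, str] = (DEFAULT_FWD_PRIMER, DEFAULT_REV_PRIMER),
) -> tuple[list[TiledSequence], list[dict]]:
    """Filter ITN candidates and convert survivors into library entries.

    A candidate is retained iff its window contains at least one binding
    site for a studied factor AND its nucleosome-formation score is
    >= `min_score` (candidates scoring strictly below the threshold are
    removed). Returns (retained entries, per-candidate log with rejection
    reasons).
    """
    scorer = scorer or periodicity_scorer
    retained: list[TiledSequence] = []
    log: list[dict] = []
    for cand in candidates:
        rec: dict = {"region": cand.region, "retained": False, "reasons": []}
        if len(cand.window_seq) != INSERT_LEN:
            rec["reasons"].append(f"window length {len(cand.window_seq)} != {INSERT_LEN}")
            log.append(rec)
            continue
        hits = scan_motifs(cand.window_seq, motifs)
        score = cand.score if not math.isnan(cand.score) else float(scorer(cand.window_seq))
        rec["score"] = score
        rec["n_tfbs_hits"] = len(hits)
        if not hits:
            rec["reasons"].append("no identifiable TFBS")
        if score < min_score:
            rec["reasons"].append(f"formation score {score:.3f} < {min_score}")
        if not rec["reasons"]:
            rec["retained"] = True
            tfbs_id = hits[0].motif_id
            retained.append(
                TiledSequence(
                    id=f"ITN_{cand.region}",
                    nps_id="ITN",
                    tfbs_id=tfbs_id,
                    dyad_offset=None,
                    insert_seq=cand.window_seq,
                    oligo_seq=flank_primers(cand.window_seq, *primers),
                    category="itn",
                    region=cand.region,
                    score=score,
                )
            )
        log.append(rec)
    return retained, log


def assemble_library(
    tiled: Iterable[TiledSequence],
    itns: Iterable[TiledSequence] = (),
    capacity: int = DEFAULT_CAPACITY,
    primers: tuple[str, str] = (DEFAULT_FWD_PRIMER, DEFAULT_REV_PRIMER),
    provenance: dict | None = None,
) -> LibraryManifest:
    """Combine tiled and ITN entries into a validated manifest.

    Raises on duplicate ids, duplicate oligo sequences, and when the entry
    count exceeds the synthesis capacity (default 7,500 oligos).
    """
    entries = list(tiled) + list(itns)
    if len(entries) > capacity:
        raise ValueError(
            f"library has {len(entries)} entries, {len(entries) - capacity} over "
            f"the capacity of {capacity}"
        )
    seen: dict[str, str] = {}
    for e in entries:
        if e.oligo_seq in seen:
            raise ValueError(f"duplicate oligo sequence in entries {seen[e.oligo_seq]!r} and {e.id!r}")
        seen[e.oligo_seq] = e.id
    prov = dict(provenance or {})
    prov.setdefault(
        "config_hash",
        hashlib.sha256(
            ("|".join(e.id for e in entries) + primers[0] + primers[1]).encode()
        ).hexdigest()[:16],
    )
    prov.setdefault("n_entries", len(entries))
    return LibraryManifest(entries, primers, prov)
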