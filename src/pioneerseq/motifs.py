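"""Transcription-factor binding-site motifs and motif scanning.

A :class:`TFBSMotif` is either a plain consensus string (matched exactly on
both strands) or a consensus with an attached position weight matrix, scored
as the sum of per-position log-odds against a uniform 0.25 background. The
scanner reports every hit on both strands, overlapping hits included, which
is what the library-design scrubbing step needs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def validate_dna(seq: str, *, what: str = "sequence") -> str:
    """Upper-case and validate a DNA string; ambiguity codes are rejected."""
    seq = seq.upper()
    bad = set(seq) - set(_BASES)
    if bad:
        raise ValueError(
            f"{what} contains non-ACGT characters {sorted(bad)}; "
            "ambiguous bases are not supported"
        )
    return seq


@dataclass(frozen=True)
class TFBSMotif:
    """A binding-site variant placed into nucleosome sequences.

    Parameters
    ----------
    id:
        Variant label, e.g. ``Klf4-1``.
    site_seq:
        The DNA string inserted during tiling (4-40 nt).
    owners:
        Transcription factors this site belongs to. Composite sites
        (e.g. an Oct4-Sox2 joint site) list every owner; control-set
        selection excludes a sequence when the focal TF appears here.
    pwm:
        Optional per-position log-odds matrix, shape (len(site_seq), 4)
        with columns A, C, G, T. When absent, scanning is exact-string.
    is_rc_of:
        Id of the motif this one is the reverse complement of, if any.
    """

    id: str
    site_seq: str
    owners: tuple[str, ...] = ()
    pwm: tuple[tuple[float, float, float, float], ...] | None = None
    is_rc_of: str | None = None

    def __post_init__(self):
        seq = validate_dna(self.site_seq, what=f"motif {self.id}")
        object.__setattr__(self, "site_seq", seq)
        if not 4 <= len(seq) <= 40:
            raise ValueError(f"motif {self.id}: length must be in [4, 40]")
        if self.pwm is not None and len(self.pwm) != len(seq):
            raise ValueError(f"motif {self.id}: PWM length != site length")

    def __len__(self) -> int:
        return len(self.site_seq)

    @property
    def pwm_array(self) -> np.ndarray | None:
        return None if self.pwm is None else np.asarray(self.pwm, dtype=float)

    def max_score(self) -> float:
        """Best attainable scan score (consensus motifs score 1 per column)."""
        if self.pwm is None:
            return float(len(self))
        return float(self.pwm_array.max(axis=1).sum())


@dataclass(frozen=True)
class MotifHit:
    motif_id: str
    start: int  # 1-based position on the forward strand of the scanned seq
    strand: str  # '+' or '-'
    score: float

    @property
    def start0(self) -> int:
        return self.start - 1


def _column_scores(motif: TFBSMotif, window: str, rc: bool) -> np.ndarray:
    """Per-position score contributions of `window` against the motif.

    For consensus motifs a matching base contributes 1 and a mismatch 0.
    `rc` scores the window against the motif's reverse complement (a
    '-' strand hit), with contributions reported in window coordinates.
    """
    target = revcomp(motif.site_seq) if rc else motif.site_seq
    if motif.pwm is None:
        return np.array([1.0 if w == t else 0.0 for w, t in zip(window, target)])
    pwm = motif.pwm_array
    if rc:
        # complement base lookup on the reversed matrix
        pwm = pwm[::-1, ::-1]
    idx = [_BASE_INDEX[b] for b in window]
    return pwm[np.arange(len(window)), idx]


def scan_motifs(
    seq: str,
    motifs: Iterable[TFBSMotif],
    min_score: float | None = None,
) -> list[MotifHit]:
    """Report every motif occurrence on both strands of `seq`.

    Consensus motifs match exactly (score = motif length). PWM motifs are
    accepted when the summed log-odds reaches ``min_score`` (default: 80%
    of the motif's maximum score). Hits are sorted by start position, then
    strand, then motif id; overlapping hits are all reported.
    """
    seq = validate_dna(seq)
    hits: list[MotifHit] = []
    for motif in motifs:
        m = len(motif)
        if m > len(seq):
            continue
        if motif.pwm is None:
            targets = {"+": motif.site_seq, "-": revcomp(motif.site_seq)}
            for strand, target in targets.items():
                pos = seq.find(target)
                while pos != -1:
                    hits.append(MotifHit(motif.id, pos + 1, strand, float(m)))
                    pos = seq.find(target, pos + 1)
        else:
            thr = min_score if min_score is not None else 0.8 * motif.max_score()
            for i in range(len(seq) - m + 1):
                window = seq[i : i + m]
                for strand, rc in (("+", False), ("-", True)):
                    score = float(_column_scores(motif, window, rc).sum())
                    if score >= thr:
                        hits.append(MotifHit(motif.id, i + 1, strand, score))
    hits.sort(key=lambda h: (h.start, h.strand, h.motif_id))
    return hits


# ---------------------------------------------------------------------------
# default motif catalogue: the KLF4/OCT4/SOX2/MYC/p53 variant set
# ---------------------------------------------------------------------------

def default_motifs() -> list[TFBSMotif]:
    """The demonstration TFBS variant set for the four Yamanaka factors.

    Klf4-1 is the canonical short KLF4 motif with Klf4-2 the long ES-cell
    motif (both with reverse-complement variants), OCT4 and SOX2 have
    monomer motifs plus a composite Oct4-Sox2 site owned by both factors,
    MYC is the palindromic E-box, p53-1 a TP53 response element (with RC),
    and NS-1 a nonspecific control site owned by no studied factor.
    """
    return [
        TFBSMotif("Klf4-1", "CCCCACCC", ("KLF4",)),
        TFBSMotif("Klf4-1RC", "GGGTGGGG", ("KLF4",), is_rc_of="Klf4-1"),
        TFBSMotif("Klf4-2", "GCCCCGCCCCGCCCC", ("KLF4",)),
        TFBSMotif("Klf4-2RC", "GGGGCGGGGCGGGGC", ("KLF4",), is_rc_of="Klf4-2"),
        TFBSMotif("Oct4-1", "TATGCAAAT", ("OCT4",)),
        TFBSMotif("Oct4-Sox2", "CTTTGTTATGCAAAT", ("OCT4", "SOX2")),
        TFBSMotif("Sox2-1", "ACAATGG", ("SOX2",)),
        TFBSMotif("Myc-1", "ACCACGTGGT", ("MYC",)),
        TFBSMotif("p53-1", "GGGCATGTCCGGGCATGTCC", ("P53",)),
        TFBSMotif("p53-1RC", "GGACATGCCCGGACATGCCC", ("P53",), is_rc_of="p53-1"),
        TFBSMotif("NS-1", "TGTTTACTTTG", ("NS",)),
    ]


def read_motif_table(path: str | Path) -> list[TFBSMotif]:
    """Read motifs from a TSV with columns id, site_seq, owners, [rc_of].

    `owners` is comma-separated; `rc_of` may be empty.
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    motifs = []
    for row in df.itertuples(index=False):
        owners = tuple(o for o in str(row.owners).split(",") if o)
        rc_of = getattr(row, "rc_of", "") or None
        motifs.append(TFBSMotif(row.id, row.site_seq, owners, is_rc_of=rc_of))
    return motifs


def write_motif_table(motifs: Sequence[TFBSMotif], path: str | Path) -> None:
    pd.DataFrame(
        {
            "id": [m.id for m in motifs],
            "site_seq": [m.site_seq for m in motifs],
            "owners": [",".join(m.owners) for m in motifs],
            "rc_of": [m.is_rc_of or "" for m in motifs],
        }
    ).to_csv(path, sep="\t", index=False)
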