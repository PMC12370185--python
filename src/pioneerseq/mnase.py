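"""MNase-seq analytics on the designed nucleosome library.

Micrococcal nuclease preferentially digests DNA not wrapped around the
histone octamer, so mapped fragment spans report where each library
sequence actually positions its nucleosome. This module computes, in the
191-nt insert coordinate system:

* per-base protection (fraction of mapped fragments covering each base),
* fragment-center histograms after a 107-150 bp core-size filter,
* nucleosome population summaries (fraction of centers within a tolerance
  of a reference position, plus smoothed modes for multi-population NPSs),
* the protection center used by the ITN distance analysis, and
* nucleosome formation efficiency from nucleosome-input vs naked-DNA
  band counts (median-centered log2 ratio).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .coords import INSERT_LEN
from .reads import CountTable

SIZE_MIN = 107
SIZE_MAX = 150
DEFAULT_TIMEPOINT = 15  # minutes of digestion used for center histograms


@dataclass(frozen=True)
class FragmentRecord:
    """One MNase fragment mapped to a library insert (1-based inclusive)."""

    library_id: str
    insert_start: int
    insert_end: int
    timepoint: int = DEFAULT_TIMEPOINT

    def __post_init__(self):
        if not (1 <= self.insert_start <= self.insert_end <= INSERT_LEN):
            raise ValueError(
                f"fragment [{self.insert_start},{self.insert_end}] outside [1,{INSERT_LEN}]"
            )

    @property
    def length(self) -> int:
        return self.insert_end - self.insert_start + 1

    @property
    def center(self) -> int:
        """Fragment midpoint; even-length fragments take the left-of-center base."""
        return (self.insert_start + self.insert_end) // 2


@dataclass
class ProtectionMatrix:
    library_id: str
    timepoint: int
    protection: np.ndarray  # length 191, values in [0, 1]
    total_reads: int


@dataclass
class CenterHistogram:
    library_id: str
    counts: dict[int, int]
    size_bounds: tuple[int, int]
    n_pass: int
    n_fail: int

    def total(self) -> int:
        return sum(self.counts.values())


@dataclass(frozen=True)
class FormationRecord:
    library_id: str
    reads_nucleosome_input: int
    reads_naked_band: int
    efficiency: float  # median-centered log2 ratio
    low_formation: bool = False


def protection_matrix(
    fragments: Iterable[FragmentRecord],
    library_id: str,
    timepoint: int = DEFAULT_TIMEPOINT,
) -> ProtectionMatrix:
    """Per-base protection: fragments covering base i over total fragments."""
    cov = np.zeros(INSERT_LEN, dtype=float)
    n = 0
    for f in fragments:
        if f.library_id != library_id or f.timepoint != timepoint:
            continue
        cov[f.insert_start - 1 : f.insert_end] += 1.0
        n += 1
    if n == 0:
        raise ValueError(f"no fragments for {library_id} at t={timepoint}")
    return ProtectionMatrix(library_id, timepoint, cov / n, n)


def center_histogram(
    fragments: Iterable[FragmentRecord],
    library_id: str | None = None,
    min_len: int = SIZE_MIN,
    max_len: int = SIZE_MAX,
    timepoint: int | None = DEFAULT_TIMEPOINT,
) -> CenterHistogram:
    """Histogram of fragment centers after the core-size filter.

    Only fragments with min_len <= length <= max_len (bounds inclusive)
    contribute; the rest are tallied in n_fail. `library_id=None` pools
    every fragment (e.g. all entries sharing one NPS backbone).
    """
    counts: dict[int, int] = {}
    n_pass = n_fail = 0
    for f in fragments:
        if library_id is not None and f.library_id != library_id:
            continue
        if timepoint is not None and f.timepoint != timepoint:
            continue
        if min_len <= f.length <= max_len:
            counts[f.center] = counts.get(f.center, 0) + 1
            n_pass += 1
        else:
            n_fail += 1
    return CenterHistogram(library_id or "pooled", counts, (min_len, max_len),
                           n_pass, n_fail)


def _smoothed(hist: CenterHistogram, width: int = 3) -> np.ndarray:
    dense = np.zeros(INSERT_LEN)
    for pos, c in hist.counts.items():
        dense[pos - 1] = c
    kernel = np.ones(width) / width
    return np.convolve(dense, kernel, mode="same")


def population_summary(
    hist: CenterHistogram,
    ref_center: int,
    tol: int = 10,
) -> dict:
    """Fraction of fragment centers within +/- tol of a reference position.

    Also reports population modes: local maxima of the center histogram
    after 3-bp moving-average smoothing, to describe sequences that place
    nucleosomes in several alternative positions.
    """
    total = hist.total()
    if total == 0:
        raise ValueError("empty center histogram")
    within = sum(
        c for pos, c in hist.counts.items() if ref_center - tol <= pos <= ref_center + tol
    )
    sm = _smoothed(hist)
    modes = [
        i + 1
        for i in range(1, INSERT_LEN - 1)
        if sm[i] > 0 and sm[i] >= sm[i - 1] and sm[i] > sm[i + 1]
    ]
    return {
        "ref_center": ref_center,
        "tol": tol,
        "fraction_within": within / total,
        "n_within": within,
        "n_total": total,
        "modes": modes,
    }


def protection_center(matrix: ProtectionMatrix, method: str = "centroid") -> int:
    """Center of MNase protection for one library sequence.

    ``centroid`` (default) is the protection-weighted mean position,
    rounded half-up; ``mode`` is the position of maximum protection
    (leftmost on ties).
    """
    p = matrix.protection
    if p.sum() <= 0:
        raise ValueError(f"no protection signal for {matrix.library_id}")
    positions = np.arange(1, INSERT_LEN + 1)
    if method == "centroid":
        centroid = float((positions * p).sum() / p.sum())
        return int(math.floor(centroid + 0.5))
    if method == "mode":
        return int(positions[np.argmax(p)])
    raise ValueError(f"unknown method {method!r}")


def protection_centers(
    fragments: Iterable[FragmentRecord],
    timepoint: int = DEFAULT_TIMEPOINT,
    method: str = "centroid",
) -> dict[str, int]:
    """Protection center per library id present in the fragment stream."""
    frags = [f for f in fragments if f.timepoint == timepoint]
    ids = sorted({f.library_id for f in frags})
    return {
        lid: protection_center(protection_matrix(frags, lid, timepoint), method)
        for lid in ids
    }


def formation_efficiency(
    input_counts: CountTable | Mapping[str, int],
    naked_counts: CountTable | Mapping[str, int],
    pseudocount: float = 0.5,
    flag_percentile: float = 5.0,
) -> dict[str, FormationRecord]:
    """Median-centered log2 nucleosome/naked-DNA read ratio per sequence.

    Sequences below `flag_percentile` of the centered efficiency are
    flagged low-formation; those ids feed the supershift gap logic.
    """
    nuc = input_counts.counts if isinstance(input_counts, CountTable) else dict(input_counts)
    naked = naked_counts.counts if isinstance(naked_counts, CountTable) else dict(naked_counts)
    ids = sorted(set(nuc) | set(naked))
    if not ids:
        raise ValueError("no counts supplied")
    raw = {
        i: math.log2((nuc.get(i, 0) + pseudocount) / (naked.get(i, 0) + pseudocount))
        for i in ids
    }
    med = float(np.median(list(raw.values())))
    centered = {i: v - med for i, v in raw.items()}
    cutoff = float(np.percentile(list(centered.values()), flag_percentile))
    return {
        i: FormationRecord(
            i, nuc.get(i, 0), naked.get(i, 0), centered[i],
            low_formation=centered[i] < cutoff,
        )
        for i in ids
    }


# ---------------------------------------------------------------------------
# tabular I/O
# ---------------------------------------------------------------------------

def fragments_to_frame(fragments: Sequence[FragmentRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "library_id": [f.library_id for f in fragments],
            "insert_start": [f.insert_start for f in fragments],
            "insert_end": [f.insert_end for f in fragments],
            "timepoint": [f.timepoint for f in fragments],
        }
    )


def fragments_from_frame(df: pd.DataFrame) -> list[FragmentRecord]:
    return [
        FragmentRecord(r.library_id, int(r.insert_start), int(r.insert_end),
                       int(r.timepoint))
        for r in df.itertuples(index=False)
    ]


def protection_to_frame(matrices: Sequence[ProtectionMatrix]) -> pd.DataFrame:
    rows = []
    for m in matrices:
        for pos in range(INSERT_LEN):
            rows.append(
                {"library_id": m.library_id, "timepoint": m.timepoint,
                 "pos": pos + 1, "protection": m.protection[pos]}
            )
    return pd.DataFrame(rows)
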