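"""Paired-end read processing: trim, merge, filter, and map to the library.

Reproduces the assay's sequencing pipeline: 3' quality trimming at Q30
(partial-sum rule), overlap merging of read pairs (>=20-nt overlap, <=2
mismatches, higher-quality consensus base), anchored primer removal,
length filtering to 174-220 nt, and assignment to the designed library by
semi-global alignment with >=150 aligned columns, >=98.5% identity, and a
single unambiguous best hit. Every input pair ends in exactly one bucket:
a per-library-sequence count or a named discard reason.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import edlib
import numpy as np
from Bio import SeqIO

from .coords import INSERT_LEN
from .design import LibraryManifest
from .motifs import revcomp

# discard reason codes, in pipeline order
REASONS = (
    "empty_after_trim",
    "merge_no_overlap",
    "merge_too_many_diffs",
    "length_out_of_range",
    "map_below_threshold",
    "map_ambiguous",
)


@dataclass
class SequencedRead:
    """One read with per-base Phred scores (Phred+33 on disk)."""

    id: str
    seq: str
    quals: tuple[int, ...]

    def __post_init__(self):
        if len(self.seq) != len(self.quals):
            raise ValueError(f"{self.id}: sequence/quality length mismatch")
        if self.quals and not (0 <= min(self.quals) and max(self.quals) <= 60):
            raise ValueError(f"{self.id}: Phred scores must be in [0, 60]")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class MergedRead:
    id: str
    seq: str
    quals: tuple[int, ...]
    overlap_len: int
    n_diffs: int
    flags: tuple[str, ...] = ()

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class MappedRead:
    read_id: str
    library_id: str
    aln_cols: int
    identity: float
    insert_start: int  # 1-based inclusive on the library insert
    insert_end: int


@dataclass
class CountTable:
    """Per-library-sequence read counts for one band of one sample."""

    sample: str
    band: str
    counts: dict[str, int] = field(default_factory=dict)
    discards: Counter = field(default_factory=Counter)

    @property
    def total_mapped(self) -> int:
        return sum(self.counts.values())

    @property
    def total_processed(self) -> int:
        return self.total_mapped + sum(self.discards.values())

    def get(self, library_id: str) -> int:
        return self.counts.get(library_id, 0)

    def scaled(self, k: float) -> "CountTable":
        """Counts multiplied by k (for scale-invariance checks)."""
        return CountTable(
            self.sample, self.band,
            {i: int(round(c * k)) for i, c in self.counts.items()},
            Counter(self.discards),
        )


# ---------------------------------------------------------------------------
# quality trimming (cutadapt/BWA partial-sum rule)
# ---------------------------------------------------------------------------

def trim_quality(read: SequencedRead, cutoff: int = 30) -> SequencedRead:
    """Trim the 3' end at the position maximizing the sum of (cutoff - q).

    Walking in from the 3' end, the running sum of (cutoff - q) is tracked
    and the read is cut where that sum is largest and positive; the 5' end
    is never touched. An all-low-quality read trims to empty.
    """
    best, best_pos, running = 0, len(read), 0
    for i in range(len(read) - 1, -1, -1):
        running += cutoff - read.quals[i]
        if running > best:
            best, best_pos = running, i
    return SequencedRead(read.id, read.seq[:best_pos], read.quals[:best_pos])


# ---------------------------------------------------------------------------
# pair merging
# ---------------------------------------------------------------------------

def _seq_to_array(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode(), dtype=np.uint8)


def merge_pairs(
    r1: SequencedRead,
    r2: SequencedRead,
    min_overlap: int = 20,
    max_diffs: int = 2,
) -> MergedRead | str:
    """Merge a read pair by their best 3' overlap, or return a reason code.

    The reverse read is reverse-complemented, every overlap offset of the
    forward read's suffix against its prefix is scored as matches minus
    mismatches, and the best-scoring overlap (largest overlap on ties) is
    accepted iff it spans >= `min_overlap` bases with <= `max_diffs`
    mismatches. Consensus: higher-quality base (forward read on ties),
    quality = max of the pair.
    """
    if len(r1) == 0 or len(r2) == 0:
        return "merge_no_overlap"
    s2 = revcomp(r2.seq)
    q2 = r2.quals[::-1]
    a1, a2 = _seq_to_array(r1.seq), _seq_to_array(s2)
    n1, n2 = len(a1), len(a2)
    best_score, best_L, best_mm = None, 0, 0
    for L in range(1, min(n1, n2) + 1):
        mm = int(np.count_nonzero(a1[n1 - L :] != a2[:L]))
        score = L - 2 * mm
        if best_score is None or score > best_score or (score == best_score and L > best_L):
            best_score, best_L, best_mm = score, L, mm
    if best_L < min_overlap:
        return "merge_no_overlap"
    if best_mm > max_diffs:
        return "merge_too_many_diffs"
    L = best_L
    head = r1.seq[: n1 - L]
    head_q = r1.quals[: n1 - L]
    tail = s2[L:]
    tail_q = q2[L:]
    mid, mid_q = [], []
    for k in range(L):
        b1, b2 = r1.seq[n1 - L + k], s2[k]
        p1, p2 = r1.quals[n1 - L + k], q2[k]
        mid.append(b1 if p1 >= p2 else b2)
        mid_q.append(max(p1, p2))
    return MergedRead(
        id=r1.id,
        seq=head + "".join(mid) + tail,
        quals=tuple(head_q) + tuple(mid_q) + tuple(tail_q),
        overlap_len=L,
        n_diffs=best_mm,
    )


# ---------------------------------------------------------------------------
# primer trimming and length filter
# ---------------------------------------------------------------------------

def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def trim_primers(
    merged: MergedRead,
    fwd: str,
    rev: str,
    max_mismatch: int = 2,
) -> MergedRead:
    """Remove anchored primer prefix/suffix within `max_mismatch` each.

    A missing primer (partial molecule) is allowed and recorded in flags
    as ``no_fwd`` / ``no_rev``.
    """
    seq, quals, flags = merged.seq, merged.quals, list(merged.flags)
    if len(seq) >= len(fwd) and _hamming(seq[: len(fwd)], fwd) <= max_mismatch:
        seq, quals = seq[len(fwd):], quals[len(fwd):]
    else:
        flags.append("no_fwd")
    if len(seq) >= len(rev) and _hamming(seq[-len(rev):], rev) <= max_mismatch:
        seq, quals = seq[: -len(rev)], quals[: -len(rev)]
    else:
        flags.append("no_rev")
    return MergedRead(merged.id, seq, quals, merged.overlap_len, merged.n_diffs, tuple(flags))


def length_filter(merged: MergedRead, min_len: int = 174, max_len: int = 220) -> bool:
    """Pass iff min_len <= length <= max_len (bounds inclusive)."""
    return min_len <= len(merged) <= max_len


# ---------------------------------------------------------------------------
# mapping
# ---------------------------------------------------------------------------

def _cigar_stats(cigar: str) -> tuple[int, int]:
    """(matches, alignment columns) from an edlib extended cigar."""
    matches = cols = 0
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            n = int(num)
            num = ""
            cols += n
            if ch == "=":
                matches += n
    return matches, cols


def _align_identity(query: str, ref: str) -> tuple[float, int, int, int]:
    """Semi-global identity of `query` vs `ref` (free end gaps on `ref`).

    Returns (identity, alignment columns, ref start, ref end), identity
    being matches over alignment columns. When the query is longer than
    the reference the roles are swapped so end gaps stay free on the
    longer sequence.
    """
    if len(query) <= len(ref):
        res = edlib.align(query, ref, mode="HW", task="path")
        matches, cols = _cigar_stats(res["cigar"])
        start, end = res["locations"][0]
        return matches / cols, cols, start + 1, end + 1
    res = edlib.align(ref, query, mode="HW", task="path")
    matches, cols = _cigar_stats(res["cigar"])
    return matches / cols, cols, 1, len(ref)


class LibraryIndex:
    """Reference index over manifest inserts with an exact-match fast path.

    The decision rule is always the alignment; exact full-insert matches
    are just the trivial case (identity 1.0 over the full insert) resolved
    by dictionary lookup. Non-exact reads are ranked by edit distance
    (both strands) and identity is computed from the optimal alignment of
    the top candidates.
    """

    def __init__(self, manifest: LibraryManifest):
        self.ids: list[str] = []
        self.refs: list[str] = []
        for e in manifest:
            self.ids.append(e.id)
            self.refs.append(e.insert_seq)
        self._exact: dict[str, int] = {}
        ambiguous: set[str] = set()
        for i, ref in enumerate(self.refs):
            if ref in self._exact:
                ambiguous.add(ref)
            self._exact[ref] = i
        for ref in ambiguous:
            del self._exact[ref]

    def map_read(
        self,
        read: MergedRead,
        min_cols: int = 150,
        min_identity: float = 0.985,
    ) -> MappedRead | str:
        for seq in (read.seq, revcomp(read.seq)):
            i = self._exact.get(seq)
            if i is not None and len(seq) >= min_cols:
                return MappedRead(read.id, self.ids[i], len(seq), 1.0, 1, len(seq))
        best: list[tuple[float, int, int, int, int]] = []  # (id, cols, start, end, ref_idx)
        best_identity = -1.0
        for seq in (read.seq, revcomp(read.seq)):
            dists = [
                edlib.align(seq, ref, mode="HW", task="distance")["editDistance"]
                if len(seq) <= len(ref)
                else edlib.align(ref, seq, mode="HW", task="distance")["editDistance"]
                for ref in self.refs
            ]
            dmin = min(dists)
            for i, d in enumerate(dists):
                if d > dmin + 2:  # identity is monotone-ish in distance; keep near-best
                    continue
                ident, cols, start, end = _align_identity(seq, self.refs[i])
                if cols < min_cols or ident < min_identity:
                    continue
                if ident > best_identity + 1e-12:
                    best_identity = ident
                    best = [(ident, cols, start, end, i)]
                elif abs(ident - best_identity) <= 1e-12 and all(b[4] != i for b in best):
                    best.append((ident, cols, start, end, i))
        if not best:
            return "map_below_threshold"
        if len({b[4] for b in best}) > 1:
            return "map_ambiguous"
        ident, cols, start, end, i = best[0]
        return MappedRead(read.id, self.ids[i], cols, ident, start, end)


def map_to_library(
    read: MergedRead,
    manifest: LibraryManifest | LibraryIndex,
    min_cols: int = 150,
    min_identity: float = 0.985,
) -> MappedRead | str:
    """Assign a merged read to its best library sequence, or a reason code."""
    index = manifest if isinstance(manifest, LibraryIndex) else LibraryIndex(manifest)
    return index.map_read(read, min_cols=min_cols, min_identity=min_identity)


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

def build_count_table(
    mapped: Iterable[MappedRead | str],
    sample: str,
    band: str,
) -> CountTable:
    """Aggregate mapping outcomes into a count table (order-independent)."""
    table = CountTable(sample, band)
    for item in mapped:
        if isinstance(item, MappedRead):
            table.counts[item.library_id] = table.counts.get(item.library_id, 0) + 1
        else:
            table.discards[item] += 1
    return table


def process_pairs(
    pairs: Iterable[tuple[SequencedRead, SequencedRead]],
    manifest: LibraryManifest,
    sample: str = "sample",
    band: str = "input",
    quality_cutoff: int = 30,
    min_overlap: int = 20,
    max_diffs: int = 2,
    primer_mismatch: int = 2,
    min_len: int = 174,
    max_len: int = 220,
    min_cols: int = 150,
    min_identity: float = 0.985,
    collect_fragments: bool = False,
) -> tuple[CountTable, list[MappedRead]]:
    """Run the full pipeline: trim -> merge -> primer-trim -> filter -> map.

    Returns the count table and (optionally) the mapped records with their
    insert spans, which the MNase analytics consume.
    """
    index = LibraryIndex(manifest)
    fwd, rev = manifest.primers
    table = CountTable(sample, band)
    fragments: list[MappedRead] = []
    for r1, r2 in pairs:
        t1, t2 = trim_quality(r1, quality_cutoff), trim_quality(r2, quality_cutoff)
        if len(t1) == 0 or len(t2) == 0:
            table.discards["empty_after_trim"] += 1
            continue
        merged = merge_pairs(t1, t2, min_overlap=min_overlap, max_diffs=max_diffs)
        if isinstance(merged, str):
            table.discards[merged] += 1
            continue
        merged = trim_primers(merged, fwd, rev, max_mismatch=primer_mismatch)
        if not length_filter(merged, min_len=min_len, max_len=max_len):
            table.discards["length_out_of_range"] += 1
            continue
        result = index.map_read(merged, min_cols=min_cols, min_identity=min_identity)
        if isinstance(result, str):
            table.discards[result] += 1
            continue
        table.counts[result.library_id] = table.counts.get(result.library_id, 0) + 1
        if collect_fragments:
            fragments.append(result)
    return table, fragments


# ---------------------------------------------------------------------------
# FASTQ I/O
# ---------------------------------------------------------------------------

def read_fastq_pairs(
    fq1: str | Path, fq2: str | Path
) -> Iterator[tuple[SequencedRead, SequencedRead]]:
    """Iterate paired reads from two FASTQ files (Phred+33), matched by order."""
    it1 = SeqIO.parse(str(fq1), "fastq")
    it2 = SeqIO.parse(str(fq2), "fastq")
    for rec1, rec2 in zip(it1, it2):
        yield (
            SequencedRead(rec1.id, str(rec1.seq),
                          tuple(rec1.letter_annotations["phred_quality"])),
            SequencedRead(rec2.id, str(rec2.seq),
                          tuple(rec2.letter_annotations["phred_quality"])),
        )


def write_fastq(reads: Sequence[SequencedRead], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.id}\n{r.seq}\n+\n")
            fh.write("".join(chr(q + 33) for q in r.quals) + "\n")
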