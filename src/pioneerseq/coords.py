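"""Coordinate conventions used throughout the package.

Library inserts are 191 nt and addressed with 1-based inclusive positions.
The nucleosome dyad sits at insert position 96 by default, with the 147-bp
core spanning positions 23..169. Positions of tiled binding sites are
expressed as signed *dyad offsets*: motif-center position minus the dyad
index, so negative offsets lie 5' (left) of the dyad and offsets with
absolute value >= 74 fall in the linkers. BED-style interval inputs are
0-based half-open and converted here, in one place.
"""

from __future__ import annotations

INSERT_LEN = 191
DYAD_INDEX = 96
CORE_SPAN = (23, 169)  # 1-based inclusive, 147 bp
CORE_LEN = 147
OLIGO_LEN = 230

#: default tiling grid: motif-center dyad offsets, inclusive
DEFAULT_GRID = tuple(range(-74, 75))


def motif_center_index(length: int) -> int:
    """0-based index of the motif's center base.

    For even-length motifs the left-of-center base is the center, so that
    dyad offsets are reproducible for any motif length.
    """
    if length < 1:
        raise ValueError("motif length must be positive")
    return (length - 1) // 2


def offset_to_window(offset: int, motif_len: int, dyad_index: int = DYAD_INDEX):
    """Map a dyad offset to the 1-based inclusive insert window it occupies.

    Returns (start, end). Raises ValueError when the motif would overrun
    the insert at this offset.
    """
    center = dyad_index + offset
    start = center - motif_center_index(motif_len)
    end = start + motif_len - 1
    if start < 1 or end > INSERT_LEN:
        raise ValueError(
            f"motif of length {motif_len} at dyad offset {offset:+d} spans "
            f"[{start},{end}], outside the 191-nt insert"
        )
    return start, end


def bed_to_insert(start0: int, end0: int) -> tuple[int, int]:
    """Convert a 0-based half-open interval to 1-based inclusive."""
    if end0 <= start0:
        raise ValueError("empty or inverted interval")
    return start0 + 1, end0


def insert_to_bed(start1: int, end1: int) -> tuple[int, int]:
    """Convert a 1-based inclusive interval to 0-based half-open."""
    if end1 < start1:
        raise ValueError("inverted interval")
    return start1 - 1, end1
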