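# Methods

## Coordinate system

Library inserts are 191 nt, 1-based, with the dyad at position 96 and the
147-bp core spanning 23–169. TFBS positions are signed dyad offsets
(motif center − 96); negative is 5′ of the dyad, |offset| ≥ 74 lies in a
linker. Even-length motifs take the left-of-center base as their center
so offsets are reproducible for any motif length. BED inputs are 0-based
half-open and converted in `coords.py` only.

## Library design

The tiling grid defaults to dyad offsets −74…+74 (149 positions), the
span for which all catalogue motifs (≤ 20 nt) fit inside the insert at
every offset. The grid is configurable; an offset where a motif would
overrun the insert raises rather than being dropped, so a requested grid
is always produced exactly or not at all. Motifs are placed by
substitution into a fixed-length insert — never insertion — so dyad
coordinates stay comparable across offsets.

Scrubbing removes resident binding sites iteratively: each round rescans,
then makes one substitution per hit at the position contributing most to
the hit's score (for exact-string motifs all positions tie and the
leftmost is edited), replacing it with the base minimizing that
contribution, alphabetical on ties. The loop caps at 10 rounds and fails
loudly with the residual hits. Scrubbing is idempotent by construction
(a scrubbed insert rescans clean).

ITN selection is a pure predicate: a 191-nt window is kept iff it
contains ≥ 1 catalogue motif and its nucleosome-formation score is
≥ 0.7 (strictly smaller scores are removed). The published scoring
functions in this space are not reimplemented; the scorer is an injected
callable `seq -> [0,1]`, with a default surrogate that scores the 10-bp
phasing of AA/TT/TA dinucleotides about the dyad and maps the mean phase
cosine to [0,1]. The surrogate shares only the output contract with
calibrated models — scores are comparable within a run, not across
methods — which is why it is pluggable.

Primers default to generic 19/20-nt handles (configurable); the 230-nt
oligo total is enforced. Library capacity defaults to 7,500 entries.

## Read pipeline

Order of operations: quality trim → merge → primer trim → length filter
→ map. Choices the underlying tools leave open:

* **Quality trimming** uses the partial-sum rule (trim where the running
  sum of `cutoff − q` from the 3′ end is maximal); ties — a base exactly
  at the cutoff — keep the longer read.
* **Merging** scores every overlap offset as matches − mismatches and
  keeps the best (largest overlap on ties); accepted iff overlap ≥ 20 nt
  and mismatches ≤ 2. Consensus takes the higher-quality base (forward
  read on ties) and the max quality.
* **Primer trimming** is anchored with ≤ 2 mismatches per primer; a
  missing primer is allowed and flagged, since partial molecules still
  map.
* **Mapping** identity is matches / alignment columns (gap columns count
  against identity) over a semi-global alignment with free end gaps on
  the longer sequence. Thresholds: ≥ 150 columns, ≥ 98.5% identity, both
  strands tried. Ambiguous best-identity ties are discarded and counted —
  conservative for a counting assay. Alignment runs on edlib with an
  exact-match dictionary fast path (the trivial identity-1.0 case) and an
  edit-distance prefilter; the decision rule is always the alignment.
  Candidates within edit distance `best + 2` get a full traceback, a
  margin that cannot exclude the identity optimum at these thresholds
  (98.5% over ≥ 150 columns bounds the distance at 3).
* Every input pair lands in exactly one bucket: a count or one named
  discard reason; tables are order-independent.

MNase fragments are shorter than the EMSA mapping minimum of 150
columns, so fragment mapping uses a configurable `min_cols` (100 in the
tests). Short fragments of tiled entries are intrinsically ambiguous —
same-NPS entries share their backbone — so fragment-level mapping is
only meaningful for sequence-distinct entries (e.g. ITNs); analytics
otherwise consume fragment records keyed by library id.

## Supershift statistic

`RS(N) = log2(((SS_N + c)/mean_NS(SS + c)) / ((Null_N + c)/mean_NS(Null + c)))`
with pseudocount `c = 0.5` on every count (the ratio is undefined at
zero); the control aggregate is the arithmetic mean (median available).
The statistic is scale-invariant per band up to the pseudocount
perturbation (< 0.02 at realistic depths). A TF-null count below the
input floor (default 10 reads) marks the sequence
`missing_low_input` — the deterministic proxy for failed nucleosome
formation, producing the gaps in position profiles.

Controls for a focal TF are same-NPS tiled sequences whose TFBS belongs
to other factors; composite sites exclude every owner, reverse-complement
variants inherit owners, and each candidate insert is rescanned for focal
sites (junction artefacts are excluded and logged). An optional linker
screen drops a control TFBS whose linker-position variants show mean
focal-TF supershift above a threshold (default 0.5 log2) — observed
cross-binding. A minimum of 25 controls is enforced.

Replicates aggregate as mean ± SEM (sd/√n, ddof 1), SEM reported only
for n ≥ 2; no depth weighting. Concentration selection standardizes
(mean specific linker − mean nonspecific linker) by the pooled SEM and
takes the argmax, lower concentration on ties. The ITN bound/unbound
flag defaults to mean RS ≥ 1.0 log2 — one doubling over background — and
is exposed as configuration and reported alongside raw values. The
distance analysis uses Spearman correlation (robust to the unknown shape
of the supershift–distance relation) and reports the bound fraction
within 40 bp of the protection center, with an empty denominator
reported as n = 0, never 0%.

## MNase analytics

Protection is per-base coverage over fragments mapped to the sequence;
the protection center is the protection-weighted centroid, rounded
half-up (mode available via config); the centroid is shift-equivariant.
Fragment centers use the floor midpoint (left-of-center for even
lengths); the size filter is 107–150 bp inclusive, and histograms default
to the 15-minute digestion timepoint. Population modes are local maxima
after 3-bp moving-average smoothing; the population fraction uses a
±10 bp tolerance. Formation efficiency is the median-centered log2
nucleosome/naked ratio (median 0 by construction); ids below the 5th
percentile are flagged for the gap logic.

## Simulator

The generator emulates: multinomial sampling of band read pools
(supershift probabilities ∝ abundance × enrichment; TF-null ∝
abundance), substitution-only sequencing errors with constant Phred
scores consistent with the error rate (no indels — the identity rule is
substitution-dominated at these read lengths), exact 150-nt
prefix/suffix read pairs (≥ 70-nt overlaps on full oligos), and MNase
fragments with mixture-drawn centers and truncated-normal lengths
(mean 140, sd 10, clipped to [80, 191]; the mean shrinks by 0.6
bp/minute of digestion past the 15-minute reference). One seeded
generator drives all draws.

It does not emulate PCR bias, gel-extraction losses, position-dependent
quality decay, chimeric pairs, or indels; passing closed-loop tests
therefore demonstrates correctness of the computations, not robustness
to those real-data artefacts. Note that because fragment centers closer
than ~54 bp to an insert edge cannot pass the 107-bp size floor,
simulated alternative populations must sit ≥ ~54 bp from the edges to be
recoverable — the mixture-recovery tests use 60/132 bp.

## Problem sizes in the test suite

The suite runs on a reduced-scale demo library (3 NPS × 4 TFBS × 149 +
10 ITNs = 1,798 entries) with read depths of 10³–4×10⁴ pairs for
pipeline loops and 2×10⁵ multinomial reads per band × 20 seeds for
enrichment-recovery checks; MNase recovery uses 10⁴ fragments. These
sizes put multinomial sampling error well inside the asserted
tolerances (recovery of log2 e within ±0.1; mixture weights within
±0.05).
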