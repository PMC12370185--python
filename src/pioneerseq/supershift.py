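"""Relative-supershift quantification and downstream binding analyses.

The core statistic compares, for each library sequence N, its read share
in the TF-bound (supershifted) gel band against the mean share of
nonspecific control sequences NS, normalized by the same ratio in the
TF-null nucleosome band::

    relative supershift = log2( ((SS_N + c) / mean_NS(SS + c))
                              / ((Null_N + c) / mean_NS(Null + c)) )

with pseudocount c (default 0.5). Controls share the test sequence's
nucleosome positioning sequence but carry binding sites of other factors,
so the statistic cancels gel-loading, PCR, and sequencing variability.
Sequences whose TF-null nucleosome-band count falls below an input floor
are reported as missing (inefficient nucleosome formation), producing the
characteristic breaks in position profiles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .design import LibraryManifest, TiledSequence
from .motifs import TFBSMotif, scan_motifs
from .reads import CountTable

LINKER_MIN_ABS_OFFSET = 74  # |dyad offset| >= 74 lies outside the 147-bp core


@dataclass
class ControlSet:
    """Nonspecific control sequences for one focal TF on one NPS."""

    tf: str
    nps_id: str
    library_ids: list[str]
    excluded: dict[str, str] = field(default_factory=dict)  # id -> reason

    def __len__(self) -> int:
        return len(self.library_ids)


@dataclass(frozen=True)
class SupershiftValue:
    library_id: str
    tf: str
    concentration: float
    replicate: int
    value: float
    status: str  # 'ok' | 'missing_low_input'


@dataclass
class SupershiftProfile:
    """Mean +/- SEM relative supershift by dyad offset for one TFBS track."""

    tf: str
    tfbs_id: str
    nps_id: str
    table: pd.DataFrame  # columns: dyad_offset, mean, sem, n


@dataclass(frozen=True)
class ITNResult:
    itn_id: str
    tf: str
    supershift: float
    n_replicates: int
    bound: bool
    status: str = "ok"
    distance_from_center: float = float("nan")


def _owners_by_tfbs(motifs: Sequence[TFBSMotif]) -> dict[str, set[str]]:
    owners = {m.id: set(m.owners) for m in motifs}
    # reverse-complement variants inherit each other's owners
    by_id = {m.id: m for m in motifs}
    for m in motifs:
        if m.is_rc_of and m.is_rc_of in by_id:
            owners[m.id] |= set(by_id[m.is_rc_of].owners)
            owners[m.is_rc_of] |= set(m.owners)
    return owners


def select_controls(
    manifest: LibraryManifest,
    tf: str,
    motifs: Sequence[TFBSMotif],
    nps_id: str | None = None,
    linker_screen: Mapping[str, float] | None = None,
    screen_threshold: float = 0.5,
    min_controls: int = 25,
) -> ControlSet | dict[str, ControlSet]:
    """Select same-NPS tiled sequences whose TFBS belongs to other TFs.

    A candidate control is excluded when (a) its TFBS lists the focal TF
    as an owner (reverse-complement variants included), (b) a rescan of
    its insert still finds a focal-TF site, or (c) `linker_screen` — mean
    observed supershift of the focal TF over that TFBS's linker-position
    variants — exceeds `screen_threshold`, evidence of cross-binding.
    Returns one ControlSet per NPS (or a single set when `nps_id` given).
    """
    owners = _owners_by_tfbs(motifs)
    focal_motifs = [m for m in motifs if tf in owners.get(m.id, set())]
    out: dict[str, ControlSet] = {}
    nps_ids = {e.nps_id for e in manifest if e.category == "tiled"}
    if nps_id is not None:
        nps_ids &= {nps_id}
    for nid in sorted(nps_ids):
        cs = ControlSet(tf, nid, [])
        for e in manifest:
            if e.category != "tiled" or e.nps_id != nid:
                continue
            if tf in owners.get(e.tfbs_id, set()):
                continue
            if linker_screen is not None and e.tfbs_id in linker_screen:
                if linker_screen[e.tfbs_id] > screen_threshold:
                    cs.excluded[e.id] = (
                        f"linker cross-binding: mean supershift "
                        f"{linker_screen[e.tfbs_id]:.2f} > {screen_threshold}"
                    )
                    continue
            if focal_motifs and scan_motifs(e.insert_seq, focal_motifs):
                cs.excluded[e.id] = "focal-TF site present after rescan"
                continue
            cs.library_ids.append(e.id)
        if len(cs) < min_controls:
            raise ValueError(
                f"only {len(cs)} controls for TF {tf} on NPS {nid} "
                f"(minimum {min_controls}); review manifest or screening threshold"
            )
        out[nid] = cs
    if not out:
        raise ValueError(f"no tiled sequences available to build controls for TF {tf}")
    return out[nps_id] if nps_id is not None else out


def linker_screen_means(
    values: Iterable[SupershiftValue],
    manifest: LibraryManifest,
) -> dict[str, float]:
    """Mean supershift per TFBS over linker-position variants.

    Feed the focal TF's own measured values here, then pass the result to
    :func:`select_controls` to drop cross-bound nonspecific TFBSs.
    """
    offsets = {e.id: e.dyad_offset for e in manifest}
    tfbs = {e.id: e.tfbs_id for e in manifest}
    acc: dict[str, list[float]] = {}
    for v in values:
        off = offsets.get(v.library_id)
        if v.status != "ok" or off is None or abs(off) < LINKER_MIN_ABS_OFFSET:
            continue
        acc.setdefault(tfbs[v.library_id], []).append(v.value)
    return {k: float(np.mean(vs)) for k, vs in acc.items()}


def relative_supershift(
    ss: CountTable,
    null: CountTable,
    controls: ControlSet,
    tf: str = "",
    concentration: float = float("nan"),
    replicate: int = 1,
    library_ids: Sequence[str] | None = None,
    pseudocount: float = 0.5,
    input_floor: int = 10,
    control_stat: str = "mean",
) -> dict[str, SupershiftValue]:
    """Relative supershift per library sequence from one replicate gel.

    `ss` and `null` are the supershift-band and TF-null nucleosome-band
    count tables; `controls` supplies the nonspecific set. Sequences with
    a raw TF-null count below `input_floor` get status
    ``missing_low_input`` and no value (failed nucleosome formation).
    """
    if ss.total_mapped == 0 or null.total_mapped == 0:
        raise ValueError("zero mapped reads in a band; cannot normalize")
    if not controls.library_ids:
        raise ValueError("empty control set")
    agg = np.mean if control_stat == "mean" else np.median
    c = pseudocount
    ss_ns = float(agg([ss.get(i) + c for i in controls.library_ids]))
    null_ns = float(agg([null.get(i) + c for i in controls.library_ids]))
    ids = list(library_ids) if library_ids is not None else sorted(
        set(ss.counts) | set(null.counts)
    )
    out: dict[str, SupershiftValue] = {}
    for lid in ids:
        if null.get(lid) < input_floor:
            out[lid] = SupershiftValue(lid, tf, concentration, replicate,
                                       float("nan"), "missing_low_input")
            continue
        val = math.log2(((ss.get(lid) + c) / ss_ns) / ((null.get(lid) + c) / null_ns))
        out[lid] = SupershiftValue(lid, tf, concentration, replicate, val, "ok")
    return out


def build_profile(
    values: Iterable[SupershiftValue],
    manifest: LibraryManifest,
) -> list[SupershiftProfile]:
    """Aggregate replicate values into per-offset mean +/- SEM profiles.

    SEM is sd/sqrt(n) over replicates and reported only for n >= 2. An
    offset where every replicate is missing appears as a gap (absent row).
    """
    meta = {e.id: e for e in manifest}
    rows = []
    for v in values:
        e = meta.get(v.library_id)
        if e is None or e.dyad_offset is None:
            continue
        rows.append(
            {
                "tf": v.tf, "tfbs_id": e.tfbs_id, "nps_id": e.nps_id,
                "dyad_offset": e.dyad_offset, "value": v.value,
                "ok": v.status == "ok",
            }
        )
    if not rows:
        return []
    df = pd.DataFrame(rows)
    df = df[df["ok"]]
    profiles = []
    for (tf, tfbs, nps), grp in df.groupby(["tf", "tfbs_id", "nps_id"], sort=True):
        agg = (
            grp.groupby("dyad_offset")["value"]
            .agg(mean="mean", sd=lambda x: x.std(ddof=1), n="count")
            .reset_index()
        )
        agg["sem"] = np.where(agg["n"] >= 2, agg["sd"] / np.sqrt(agg["n"]), np.nan)
        profiles.append(
            SupershiftProfile(tf, tfbs, nps, agg[["dyad_offset", "mean", "sem", "n"]])
        )
    return profiles


def select_concentration(
    values_by_conc: Mapping[float, Iterable[SupershiftValue]],
    manifest: LibraryManifest,
    specific_tfbs: Sequence[str],
    nonspecific_tfbs: Sequence[str],
) -> tuple[float, pd.DataFrame]:
    """Pick the TF concentration with the strongest specific linker signal.

    For each concentration the score is the mean supershift over
    linker-position variants of the specific TFBSs minus the mean over
    linker-position variants of nonspecific TFBSs, standardized by the
    pooled SEM of the two groups. Returns (chosen concentration, score
    table); ties resolve to the lower concentration.
    """
    offsets = {e.id: e.dyad_offset for e in manifest}
    tfbs = {e.id: e.tfbs_id for e in manifest}
    records = []
    for conc in sorted(values_by_conc):
        spec, nonspec = [], []
        for v in values_by_conc[conc]:
            off = offsets.get(v.library_id)
            if v.status != "ok" or off is None or abs(off) < LINKER_MIN_ABS_OFFSET:
                continue
            if tfbs[v.library_id] in specific_tfbs:
                spec.append(v.value)
            elif tfbs[v.library_id] in nonspecific_tfbs:
                nonspec.append(v.value)
        if not spec or not nonspec:
            raise ValueError(f"no linker-position values at concentration {conc}")
        sem_s = np.std(spec, ddof=1) / math.sqrt(len(spec)) if len(spec) > 1 else 0.0
        sem_n = np.std(nonspec, ddof=1) / math.sqrt(len(nonspec)) if len(nonspec) > 1 else 0.0
        pooled = math.sqrt(sem_s**2 + sem_n**2)
        diff = float(np.mean(spec) - np.mean(nonspec))
        score = diff / pooled if pooled > 0 else diff
        records.append({"concentration": conc, "diff": diff, "pooled_sem": pooled,
                        "score": score})
    df = pd.DataFrame(records)
    best = df.loc[df["score"].idxmax()]  # idxmax takes the first (lowest conc) on ties
    return float(best["concentration"]), df


def itn_supershift(
    values_by_replicate: Iterable[Mapping[str, SupershiftValue]],
    manifest: LibraryManifest,
    tf: str,
    bound_threshold: float = 1.0,
) -> dict[str, ITNResult]:
    """One replicate-averaged supershift value per ITN for one TF.

    The bound flag is mean supershift >= `bound_threshold` (log2 units).
    ITNs missing in every replicate (failed formation) carry status
    ``missing`` and no flag; replicate disagreement about the flag is
    noted in the status.
    """
    itn_ids = [e.id for e in manifest if e.category == "itn"]
    values_by_replicate = list(values_by_replicate)
    out: dict[str, ITNResult] = {}
    for iid in itn_ids:
        vals = []
        for rep in values_by_replicate:
            v = rep.get(iid)
            if v is not None and v.status == "ok":
                vals.append(v.value)
        if not vals:
            out[iid] = ITNResult(iid, tf, float("nan"), 0, False, status="missing")
            continue
        mean = float(np.mean(vals))
        flags = [v >= bound_threshold for v in vals]
        status = "ok" if len(set(flags)) == 1 else "replicates_disagree"
        out[iid] = ITNResult(iid, tf, mean, len(vals), mean >= bound_threshold, status)
    return out


def distance_analysis(
    itn_results: Mapping[str, ITNResult],
    protection_centers: Mapping[str, int],
    tfbs_centers: Mapping[str, int],
    window: int = 40,
) -> dict:
    """Relate ITN binding to TFBS distance from the MNase-protection center.

    Computes the Spearman correlation between supershift and
    |TFBS center - protection center| across ITNs with data, and the
    bound fraction among ITNs whose distance is <= `window` bp. With no
    near-center ITNs the fraction is reported as None with n=0, never 0%.
    """
    dists, shifts, flags = [], [], []
    for iid, res in itn_results.items():
        if res.status == "missing" or iid not in protection_centers or iid not in tfbs_centers:
            continue
        d = abs(tfbs_centers[iid] - protection_centers[iid])
        dists.append(d)
        shifts.append(res.supershift)
        flags.append(res.bound)
    report: dict = {"n": len(dists), "window": window}
    if len(dists) >= 3:
        rho, p = stats.spearmanr(dists, shifts)
        report["spearman_rho"] = float(rho)
        report["spearman_p"] = float(p)
    near = [(d, b) for d, b in zip(dists, flags) if d <= window]
    report["n_within_window"] = len(near)
    if near:
        bound = sum(1 for _, b in near if b)
        report["n_bound_within_window"] = bound
        report["bound_fraction"] = bound / len(near)
        report["bound_percent"] = 100.0 * bound / len(near)
    else:
        report["n_bound_within_window"] = 0
        report["bound_fraction"] = None
        report["bound_percent"] = None
    return report


def values_to_frame(values: Iterable[SupershiftValue]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "library_id": [v.library_id for v in values],
            "tf": [v.tf for v in values],
            "concentration": [v.concentration for v in values],
            "replicate": [v.replicate for v in values],
            "value": [v.value for v in values],
            "status": [v.status for v in values],
        }
    )
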