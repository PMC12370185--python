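"""Relative-supershift statistic, control selection, profiles, ITN analyses."""

from __future__ import annotations

import math

import numpy as np
import pytest

import pioneerseq as ps
from pioneerseq.reads import CountTable


def make_counts(band, counts):
    return CountTable("s", band, dict(counts))


@pytest.fixture(scope="module")
def controls_601(demo_manifest, motifs):
    return ps.select_controls(demo_manifest, "KLF4", motifs, nps_id="601")


class TestSelectControls:
    def test_same_nps_other_tf_arithmetic(self, demo_manifest, motifs, controls_601):
        # demo library tiles 4 factor-diverse TFBSs per NPS; 3 are non-KLF4
        non_klf4 = {
            e.id for e in demo_manifest
            if e.nps_id == "601" and e.category == "tiled" and e.tfbs_id != "Klf4-1"
        }
        assert set(controls_601.library_ids) <= non_klf4
        # nearly all 3 x 149 candidates survive the purity rescan
        assert len(controls_601) > 0.9 * 3 * 149

    def test_composite_site_excluded_for_both_owners(self, demo_manifest, motifs):
        cs = ps.select_controls(demo_manifest, "SOX2", motifs, nps_id="601")
        tfbs = {demo_manifest.by_id(i).tfbs_id for i in cs.library_ids}
        assert "Oct4-Sox2" not in tfbs

    def test_all_focal_manifest_errors(self, nps601, motifs):
        klf4_only = [m for m in motifs if "KLF4" in m.owners][:2]
        tiled = [t for m in klf4_only for t in ps.tile_tfbs(nps601, m)]
        man = ps.assemble_library(tiled)
        with pytest.raises(ValueError):
            ps.select_controls(man, "KLF4", motifs, nps_id="601")

    def test_linker_screen_only_removes_members(self, demo_manifest, motifs, controls_601):
        screened = ps.select_controls(
            demo_manifest, "KLF4", motifs, nps_id="601",
            linker_screen={"Myc-1": 0.9}, screen_threshold=0.5,
        )
        assert set(screened.library_ids) < set(controls_601.library_ids)
        assert all("Myc-1" != demo_manifest.by_id(i).tfbs_id for i in screened.library_ids)


class TestRelativeSupershift:
    def test_balanced_ratios_give_zero(self, controls_601):
        ss = make_counts("supershift", {i: 100 for i in controls_601.library_ids})
        null = make_counts("nucleosome_null", {i: 50 for i in controls_601.library_ids})
        target = controls_601.library_ids[0]
        vals = ps.relative_supershift(ss, null, controls_601, library_ids=[target])
        assert vals[target].value == pytest.approx(0.0, abs=1e-12)

    def test_fourfold_enrichment_gives_two(self, controls_601):
        target = controls_601.library_ids[0]
        others = controls_601.library_ids[1:]
        cs = ps.ControlSet("KLF4", "601", others)
        ss = make_counts("supershift", {**{i: 100 for i in others}, target: 400})
        null = make_counts("nucleosome_null", {i: 50 for i in controls_601.library_ids})
        vals = ps.relative_supershift(ss, null, cs, library_ids=[target])
        assert vals[target].value == pytest.approx(2.0, abs=0.02)

    def test_scale_invariance_per_band(self, controls_601):
        target = controls_601.library_ids[0]
        others = controls_601.library_ids[1:]
        cs = ps.ControlSet("KLF4", "601", others)
        ss = make_counts("supershift", {**{i: 80 for i in others}, target: 320})
        null = make_counts("nucleosome_null", {i: 40 for i in controls_601.library_ids})
        base = ps.relative_supershift(ss, null, cs, library_ids=[target])[target].value
        for scaled_ss, scaled_null in ((ss.scaled(10), null), (ss, null.scaled(10))):
            v = ps.relative_supershift(scaled_ss, scaled_null, cs,
                                       library_ids=[target])[target].value
            assert abs(v - base) < 0.02

    def test_low_input_floor_marks_missing(self, controls_601):
        target = controls_601.library_ids[0]
        others = controls_601.library_ids[1:]
        cs = ps.ControlSet("KLF4", "601", others)
        ss = make_counts("supershift", {i: 100 for i in controls_601.library_ids})
        null = make_counts("nucleosome_null", {**{i: 50 for i in others}, target: 9})
        vals = ps.relative_supershift(ss, null, cs, library_ids=[target])
        assert vals[target].status == "missing_low_input"
        assert math.isnan(vals[target].value)

    def test_zero_band_errors(self, controls_601):
        empty = make_counts("supershift", {})
        null = make_counts("nucleosome_null", {controls_601.library_ids[0]: 5})
        with pytest.raises(ValueError, match="zero mapped"):
            ps.relative_supershift(empty, null, controls_601)

    def test_recovers_log2_enrichment(self, demo_manifest, motifs, controls_601):
        """Simulated enrichment e is recovered within 0.1 log2 units."""
        target = [
            e.id for e in demo_manifest if e.nps_id == "601" and e.tfbs_id == "Klf4-1"
        ]
        for e in (1, 2, 4, 8):
            recovered = []
            for seed in range(20):
                cfg = ps.SimulationConfig(
                    seed=seed, reads_per_band=200_000,
                    enrichment={t: float(e) for t in target},
                )
                tables, _ = ps.simulate_band_counts(demo_manifest, cfg)
                vals = ps.relative_supershift(
                    tables["supershift"], tables["nucleosome_null"],
                    controls_601, library_ids=target,
                )
                recovered.append(
                    np.mean([v.value for v in vals.values() if v.status == "ok"])
                )
            assert np.mean(recovered) == pytest.approx(math.log2(e), abs=0.1)

    def test_null_simulation_centers_on_zero(self, demo_manifest, controls_601):
        """With uniform enrichment the specific mean sits within 3 SEM of 0."""
        target = [
            e.id for e in demo_manifest if e.nps_id == "601" and e.tfbs_id == "Klf4-1"
        ]
        means = []
        for seed in range(10):
            cfg = ps.SimulationConfig(seed=seed, reads_per_band=200_000)
            tables, _ = ps.simulate_band_counts(demo_manifest, cfg)
            vals = ps.relative_supershift(
                tables["supershift"], tables["nucleosome_null"],
                controls_601, library_ids=target,
            )
            means.append(np.mean([v.value for v in vals.values() if v.status == "ok"]))
        sem = np.std(means, ddof=1) / math.sqrt(len(means))
        assert abs(np.mean(means)) < 3 * sem + 1e-3


class TestProfiles:
    def _values(self, demo_manifest, triples):
        out = []
        for lid, rep, val in triples:
            out.append(ps.SupershiftValue(lid, "KLF4", 57.0, rep, val,
                                          "ok" if not math.isnan(val) else "missing_low_input"))
        return out

    def test_mean_and_sem(self, demo_manifest):
        lid = "601_Klf4-1_+0"
        vals = self._values(demo_manifest, [(lid, 1, 0.9), (lid, 2, 1.0), (lid, 3, 1.1)])
        prof = ps.build_profile(vals, demo_manifest)[0]
        row = prof.table[prof.table["dyad_offset"] == 0].iloc[0]
        assert row["mean"] == pytest.approx(1.0)
        assert row["sem"] == pytest.approx(0.1 / math.sqrt(3), abs=1e-4)
        assert row["n"] == 3

    def test_single_replicate_has_no_sem(self, demo_manifest):
        vals = self._values(demo_manifest, [("601_Klf4-1_+3", 1, 0.5)])
        prof = ps.build_profile(vals, demo_manifest)[0]
        row = prof.table.iloc[0]
        assert row["mean"] == 0.5 and np.isnan(row["sem"])

    def test_all_missing_offset_is_a_gap(self, demo_manifest):
        vals = self._values(
            demo_manifest,
            [("601_Klf4-1_+0", 1, 1.0), ("601_Klf4-1_+1", 1, float("nan"))],
        )
        prof = ps.build_profile(vals, demo_manifest)[0]
        assert set(prof.table["dyad_offset"]) == {0}


class TestConcentrationSelection:
    def _values_at(self, demo_manifest, conc, spec_linker, nonspec_linker, noise=0.0, seed=0):
        rng = np.random.default_rng(seed)
        out = []
        for e in demo_manifest:
            if e.category != "tiled" or e.nps_id != "601" or e.dyad_offset is None:
                continue
            if abs(e.dyad_offset) < 74:
                continue
            base = spec_linker if e.tfbs_id == "Klf4-1" else nonspec_linker
            out.append(
                ps.SupershiftValue(e.id, "KLF4", conc, 1,
                                   base + noise * rng.normal(), "ok")
            )
        return out

    def test_monotone_signal_picks_highest(self, demo_manifest):
        by_conc = {
            c: self._values_at(demo_manifest, c, spec, 0.0, noise=0.05, seed=int(c))
            for c, spec in [(14.0, 0.5), (28.0, 1.0), (57.0, 2.0)]
        }
        best, _ = ps.select_concentration(
            by_conc, demo_manifest, ["Klf4-1"], ["Myc-1", "Oct4-1", "Oct4-Sox2"]
        )
        assert best == 57.0

    def test_identical_profiles_pick_lowest(self, demo_manifest):
        by_conc = {
            c: self._values_at(demo_manifest, c, 1.0, 0.0, noise=0.05, seed=1)
            for c in (14.0, 28.0, 57.0)
        }
        best, _ = ps.select_concentration(
            by_conc, demo_manifest, ["Klf4-1"], ["Myc-1", "Oct4-1", "Oct4-Sox2"]
        )
        assert best == 14.0

    def test_interior_optimum_recovered(self, demo_manifest):
        # saturation of the specific signal with nonspecific rise at high TF
        spec = {14.0: 0.8, 28.0: 1.8, 57.0: 2.0, 114.0: 2.05}
        nonspec = {14.0: 0.0, 28.0: 0.05, 57.0: 0.1, 114.0: 1.5}
        by_conc = {
            c: self._values_at(demo_manifest, c, spec[c], nonspec[c], noise=0.05,
                               seed=int(c))
            for c in spec
        }
        best, _ = ps.select_concentration(
            by_conc, demo_manifest, ["Klf4-1"], ["Myc-1", "Oct4-1", "Oct4-Sox2"]
        )
        assert best in (28.0, 57.0)


class TestITNAnalyses:
    def _itn_values(self, demo_manifest, mapping, replicate=1):
        return {
            iid: ps.SupershiftValue(iid, "KLF4", 57.0, replicate, v, "ok")
            for iid, v in mapping.items()
        }

    def test_bound_flag_from_replicate_mean(self, demo_manifest):
        itns = [e.id for e in demo_manifest if e.category == "itn"]
        reps = [
            self._itn_values(demo_manifest, {itns[0]: 3.0, itns[1]: 0.0}, 1),
            self._itn_values(demo_manifest, {itns[0]: 3.2, itns[1]: 0.1}, 2),
        ]
        res = ps.itn_supershift(reps, demo_manifest, "KLF4")
        assert res[itns[0]].bound and not res[itns[1]].bound
        assert res[itns[0]].supershift == pytest.approx(3.1)

    def test_replicate_disagreement_logged_flag_from_mean(self, demo_manifest):
        itns = [e.id for e in demo_manifest if e.category == "itn"]
        reps = [
            self._itn_values(demo_manifest, {itns[0]: 0.8}, 1),
            self._itn_values(demo_manifest, {itns[0]: 1.4}, 2),
        ]
        res = ps.itn_supershift(reps, demo_manifest, "KLF4")
        assert res[itns[0]].status == "replicates_disagree"
        assert res[itns[0]].bound  # mean 1.1 >= 1.0

    def test_missing_everywhere_gives_no_flag(self, demo_manifest):
        res = ps.itn_supershift([{}], demo_manifest, "KLF4")
        assert all(r.status == "missing" and not r.bound for r in res.values())


class TestDistanceAnalysis:
    def _results(self, pairs):
        return {
            f"itn{k}": ps.ITNResult(f"itn{k}", "KLF4", s, 2, s >= 1.0)
            for k, (d, s) in enumerate(pairs)
        }

    def test_monotone_decreasing_gives_rho_minus_one(self):
        pairs = [(d, 3.0 - 0.03 * d) for d in (5, 20, 40, 60, 80)]
        res = self._results(pairs)
        centers = {k: 0 for k in res}
        tfbs = {k: d for k, (d, _) in zip(res, pairs)}
        rep = ps.distance_analysis(res, centers, tfbs)
        assert rep["spearman_rho"] == pytest.approx(-1.0)

    def test_no_near_center_itns_reports_n_zero(self):
        pairs = [(60, 2.0), (80, 1.5)]
        res = self._results(pairs)
        rep = ps.distance_analysis(res, {k: 0 for k in res},
                                   {k: d for k, (d, _) in zip(res, pairs)})
        assert rep["n_within_window"] == 0 and rep["bound_fraction"] is None

    def test_bound_fraction_direct_count(self):
        # 9 near-center ITNs, 6 bound, plus 3 distal ones that must not count
        near = [(10 + i, 2.0 if i < 6 else 0.0) for i in range(9)]
        far = [(90, 2.0), (100, 0.0), (120, 2.0)]
        res = self._results(near + far)
        pairs = near + far
        rep = ps.distance_analysis(res, {k: 0 for k in res},
                                   {k: d for k, (d, _) in zip(res, pairs)})
        assert rep["n_within_window"] == 9
        assert rep["bound_percent"] == pytest.approx(66.7, abs=0.1)
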