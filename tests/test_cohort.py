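"""Donor aggregation, endotype/risk rules and cohort statistics."""

import numpy as np
import pandas as pd
import pytest

import eoquant as eq
from eoquant.cohort import anova2_posthoc, group_mean_ci, kruskal_tukey
from eoquant.pipeline import build_section_profile


def section_with_density(density, region, tissue_mm2=2.0, donor="d0"):
    """Section whose total EO density equals ``density`` per mm²."""
    n = int(round(density * tissue_mm2))
    objs = eq.objects_from_table(pd.DataFrame([{
        "object_id": f"{region}{i}", "area_um2": 500.0,
        "ins_area_um2": 460.0, "gluc_area_um2": 0.0} for i in range(n)]))
    return build_section_profile(objs, tissue_mm2, donor_id=donor,
                                 region=region)


class TestAggregateDonor:
    def test_single_section_is_identity(self):
        s = section_with_density(4.0, "PH")
        agg = eq.aggregate_donor([s])
        pd.testing.assert_series_equal(agg, s.metrics, check_names=False)

    def test_two_stage_mean_weights_regions_equally(self):
        sections = [section_with_density(4.0, "PH"),
                    section_with_density(6.0, "PH"),
                    section_with_density(10.0, "PT")]
        agg = eq.aggregate_donor(sections)
        # region means are (5, 10); donor value is their mean, not the
        # flat mean of (4, 6, 10)
        assert agg["eo_density_per_mm2"] == pytest.approx(7.5)

    def test_aggregation_idempotent_for_single_region(self):
        sections = [section_with_density(4.0, "PH"),
                    section_with_density(6.0, "PH")]
        once = eq.aggregate_donor(sections)
        prof = build_section_profile([], 1.0, region="PH")
        prof.metrics[:] = once
        twice = eq.aggregate_donor([prof])
        assert np.allclose(once.to_numpy(), twice.to_numpy())

    def test_no_sections_is_an_error(self):
        with pytest.raises(ValueError):
            eq.aggregate_donor([])


class TestEndotypeAndRisk:
    def donor(self, **kw):
        base = dict(donor_id="d", age_years=30.0, group="T1D")
        base.update(kw)
        return eq.DonorRecord(**base)

    @pytest.mark.parametrize("dx_age, expected", [
        (6.0, "T1DE1"), (12.9, "T1DE1"), (13.0, "T1DE2"), (40.0, "T1DE2"),
    ])
    def test_endotype_by_diagnosis_age(self, dx_age, expected):
        assert eq.assign_endotype(
            self.donor(age_at_diagnosis_years=dx_age)) == expected

    def test_non_t1d_donor_is_na(self):
        assert eq.assign_endotype(self.donor(group="ND")) == "NA"
        assert eq.assign_endotype(self.donor()) == "NA"  # no dx age

    @pytest.mark.parametrize("flags, aabs, expected", [
        (dict(grs_ge_50th=True, insulitis_reported=True), {"IA2A"}, "high"),
        (dict(grs_ge_50th=True, insulitis_reported=True), set(), "low"),
        (dict(grs_ge_50th=True, insulitis_reported=True,
              hlaI_hyperexpression=True), {"IA2A"}, "high"),  # all four
        (dict(), set(), "low"),
    ])
    def test_risk_needs_three_of_four_criteria(self, flags, aabs, expected):
        d = self.donor(group="AAb_multi", aab_flags=frozenset(aabs), **flags)
        assert eq.assign_aab_risk(d) == expected

    def test_risk_na_outside_aab_groups(self):
        assert eq.assign_aab_risk(self.donor(group="T1D")) == "NA"

    def test_missing_flags_count_as_false(self, caplog):
        d = self.donor(group="AAb_multi", grs_ge_50th=True,
                       insulitis_reported=None, hlaI_hyperexpression=True,
                       aab_flags=frozenset({"IA2A"}))
        with caplog.at_level("WARNING", logger="eoquant"):
            assert eq.assign_aab_risk(d) == "high"
        assert "missing flag" in caplog.text


class TestStatistics:
    def test_bh_step_up_matches_hand_computation(self):
        from eoquant.cohort import bh_adjust
        # step-up by hand for raw (0.01, 0.02, 0.03), m = 3:
        # p(3)=0.03·3/3=0.03; p(2)=min(0.03, 0.02·3/2)=0.03;
        # p(1)=min(0.03, 0.01·3)=0.03
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03]),
                           [0.03, 0.03, 0.03])
        assert np.allclose(bh_adjust([0.005, 0.5, 0.04]),
                           [0.015, 0.5, 0.06])

    def test_bh_monotone_and_applied_across_family(self):
        metrics = pd.DataFrame({
            "m1": [1, 2, 3, 10, 11, 12.5],
            "m2": [1, 2, 3, 9, 10, 11],
            "m3": [3, 2, 1, 2.5, 1.5, 3.5],
        }, dtype=float)
        groups = pd.Series(["A"] * 3 + ["B"] * 3)
        out = eq.mann_whitney_bh(metrics, groups)
        assert (out["p_adj"] >= out["p_raw"] - 1e-12).all()
        assert (out["p_adj"] <= 1.0).all()
        ranked = out.sort_values("p_raw")
        assert ranked["p_adj"].is_monotonic_increasing

    def test_identical_groups_give_p_one(self):
        metrics = pd.DataFrame({"m": [5.0, 5.0, 5.0, 5.0, 5.0, 5.0]})
        groups = pd.Series(["A"] * 3 + ["B"] * 3)
        out = eq.mann_whitney_bh(metrics, groups)
        assert out["p_adj"].iloc[0] == pytest.approx(1.0)

    def test_small_groups_skipped_and_flagged(self):
        metrics = pd.DataFrame({"m": [1.0, 2.0, 3.0, 4.0]})
        groups = pd.Series(["A", "A", "B", "B"])
        out = eq.mann_whitney_bh(metrics, groups)
        assert (out["note"] == "skipped: n < 3").all()
        assert out["p_adj"].isna().all()

    def test_kruskal_tukey_three_groups(self):
        rng = np.random.default_rng(1)
        vals = pd.Series(np.concatenate([
            rng.normal(0, 1, 8), rng.normal(0, 1, 8), rng.normal(5, 1, 8)]))
        groups = pd.Series(["A"] * 8 + ["B"] * 8 + ["C"] * 8)
        out = kruskal_tukey(vals, groups, metric="x")
        omnibus = out[out["comparison"] == "omnibus"]
        assert omnibus["p_raw"].iloc[0] < 0.01
        ac = out[out["comparison"] == "A vs C"]
        assert ac["p_adj"].iloc[0] < 0.05
        ab = out[out["comparison"] == "A vs B"]
        assert ab["p_adj"].iloc[0] > 0.05

    def test_anova2_typeII_with_dunnett_control(self):
        rng = np.random.default_rng(1)
        rows = []
        for g, shift in (("ND", 0.0), ("T1D", 3.0), ("AAb", 0.2)):
            for b in (0, 1):
                for _ in range(6):
                    rows.append({"group": g, "eo_bin": b,
                                 "value": rng.normal(shift + b, 0.5)})
        long = pd.DataFrame(rows)
        out = anova2_posthoc(long, posthoc="dunnett", control="ND")
        assert {"anova2-typeII", "dunnett"} <= set(out["procedure"])
        t1d = out[out["comparison"].str.startswith("T1D vs ND")]
        assert (t1d["p_adj"] < 0.01).all()
        aab = out[out["comparison"].str.startswith("AAb vs ND")]
        assert (aab["p_adj"] > 0.05).all()

    def test_dunnett_requires_control(self):
        with pytest.raises(ValueError, match="control"):
            anova2_posthoc(pd.DataFrame({"value": [1.0], "group": ["A"],
                                         "eo_bin": [0]}), posthoc="dunnett")

    def test_group_mean_ci_contains_mean(self):
        metrics = pd.DataFrame({"m": [1.0, 2.0, 3.0, 4.0]})
        groups = pd.Series(["A", "A", "A", "A"])
        out = group_mean_ci(metrics, groups)
        r = out.iloc[0]
        assert r["ci_lo"] <= r["mean"] <= r["ci_hi"]
        assert r["mean"] == pytest.approx(2.5)


class TestPancreasWeight:
    def test_fold_changes_from_medians(self):
        out = eq.pancreas_weight_foldchange(
            {"0-1": [10.0], "2-6": [20.0], "7-12": [30.0]})
        assert np.isnan(out.loc[0, "fold_change"])
        assert out.loc[1, "fold_change"] == pytest.approx(2.0)
        assert out.loc[2, "fold_change"] == pytest.approx(1.5)

    def test_constant_medians_give_unit_folds(self):
        out = eq.pancreas_weight_foldchange(
            {"a": [7.0, 9.0], "b": [8.0], "c": [6.0, 10.0]})
        assert np.allclose(out["fold_change"].iloc[1:], 1.0)

    def test_empty_bracket_leaves_gap_and_flags_next(self):
        out = eq.pancreas_weight_foldchange(
            {"a": [10.0], "b": [], "c": [30.0]})
        assert np.isnan(out.loc[1, "fold_change"])
        assert out.loc[2, "fold_change"] == pytest.approx(3.0)
        assert "previous bracket empty" in out.loc[2, "note"]


class TestSpatialPlot:
    def test_point_count_and_sizes(self, tmp_path):
        objs = eq.objects_from_table(pd.DataFrame([
            {"object_id": "a", "area_um2": 200.0, "ins_area_um2": 180.0,
             "gluc_area_um2": 0.0, "centroid_x_px": 10.0,
             "centroid_y_px": 10.0},
            {"object_id": "b", "area_um2": 170 * 2**5, "ins_area_um2": 3000.0,
             "gluc_area_um2": 2000.0, "centroid_x_px": 50.0,
             "centroid_y_px": 50.0},
            {"object_id": "c", "area_um2": 170 * 2**9, "ins_area_um2": 0.0,
             "gluc_area_um2": 80000.0, "centroid_x_px": 90.0,
             "centroid_y_px": 90.0},
        ]))
        prof = build_section_profile(objs, 1.0, donor_id="d1", region="PH")
        path = tmp_path / "plot.png"
        fig = eq.spatial_plot(prof, path=path,
                              header={"age": 9, "group": "ND"})
        assert path.exists()
        sizes = fig.axes[0].collections[0].get_sizes()
        assert len(sizes) == 3
        assert list(sizes) == sorted(sizes) and sizes[0] < sizes[1] < sizes[2]

    def test_empty_section_plots_background_only(self, tmp_path):
        prof = build_section_profile([], 1.0)
        path = tmp_path / "empty.svg"
        fig = eq.spatial_plot(prof, path=path)
        assert path.exists()
        assert len(fig.axes[0].collections[0].get_offsets()) == 0
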