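"""Layer aggregation and histology ANOVA."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm

import vesselmech as vm
from vesselmech.errors import ValidationError
from vesselmech.histology import aggregate_histology, histo_anova


class TestMeanOfFrames:
    def test_mean(self):
        assert vm.mean_of_frames([10, 12, 14, 16, 18]) == pytest.approx(14.0)
        assert vm.mean_of_frames([7, 7, 7, 7, 7]) == 7.0

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            vm.mean_of_frames([])


class TestOverallAreaPercent:
    def test_weighted_example(self):
        assert vm.overall_area_percent(40, 600, 10, 400) == pytest.approx(28.0)

    def test_equal_layers_passthrough(self):
        for t1, t2 in [(100, 900), (500, 500), (1, 2)]:
            assert vm.overall_area_percent(33.0, t1, 33.0, t2) == pytest.approx(33.0)

    def test_single_layer_degenerate(self):
        assert vm.overall_area_percent(35.0, 1200.0) == 35.0
        assert vm.overall_area_percent(35.0, 1200.0, None, 0.0) == 35.0

    def test_convex_combination_bounds(self, rng):
        for _ in range(50):
            p1, p2 = rng.uniform(0, 100, 2)
            t1, t2 = rng.uniform(1, 2000, 2)
            v = vm.overall_area_percent(p1, t1, p2, t2)
            assert min(p1, p2) - 1e-12 <= v <= max(p1, p2) + 1e-12

    def test_zero_total_thickness_rejected(self):
        with pytest.raises(ValidationError):
            vm.overall_area_percent(40, 0, 10, 0)

    def test_out_of_range_pct_rejected(self):
        with pytest.raises(ValidationError):
            vm.overall_area_percent(120, 100, 10, 100)


def _frame_rows(horse, age, loc, layer, stain, pcts=None, thicknesses=None):
    rows = []
    vals = pcts if pcts is not None else thicknesses
    for k, v in enumerate(vals):
        rows.append({
            "horse_id": horse, "age_group": age, "location": loc,
            "layer": layer, "stain": stain, "frame_index": k + 1,
            "area_pct": v if pcts is not None else np.nan,
            "thickness_um": v if thicknesses is not None else np.nan,
        })
    return rows


class TestAggregateHistology:
    def test_two_layer_weighting(self):
        rows = (
            _frame_rows("h1", "young", "common_carotid", "1", "elastin",
                        pcts=[40] * 5)
            + _frame_rows("h1", "young", "common_carotid", "2", "elastin",
                          pcts=[10] * 5)
            + _frame_rows("h1", "young", "common_carotid", "1", "thickness",
                          thicknesses=[600] * 5)
            + _frame_rows("h1", "young", "common_carotid", "2", "thickness",
                          thicknesses=[400] * 5)
        )
        out = aggregate_histology(pd.DataFrame(rows))
        assert out.loc[0, "elastin"] == pytest.approx(28.0)
        assert out.loc[0, "thickness_um"] == pytest.approx(1000.0)

    def test_single_layer_passthrough(self):
        rows = _frame_rows("h1", "young", "proximal_aorta", "single", "elastin",
                           pcts=[30, 32, 34, 36, 38])
        out = aggregate_histology(pd.DataFrame(rows))
        assert out.loc[0, "elastin"] == pytest.approx(34.0)
        assert np.isnan(out.loc[0, "thickness_um"])

    def test_aggregation_order_matters(self):
        """Means-first then weighting differs from weighting frame-by-frame
        when thickness weights vary by frame; the implementation follows the
        means-first protocol. Counterexample documents the non-equivalence."""
        pct1 = [10, 50, 10, 50, 10]
        pct2 = [50, 10, 50, 10, 50]
        th1 = [100, 900, 100, 900, 100]
        th2 = [900, 100, 900, 100, 900]
        rows = (
            _frame_rows("h1", "young", "common_carotid", "1", "elastin", pcts=pct1)
            + _frame_rows("h1", "young", "common_carotid", "2", "elastin", pcts=pct2)
            + _frame_rows("h1", "young", "common_carotid", "1", "thickness",
                          thicknesses=th1)
            + _frame_rows("h1", "young", "common_carotid", "2", "thickness",
                          thicknesses=th2)
        )
        out = aggregate_histology(pd.DataFrame(rows))
        means_first = vm.overall_area_percent(
            np.mean(pct1), np.mean(th1), np.mean(pct2), np.mean(th2)
        )
        framewise = np.mean([
            vm.overall_area_percent(p1, t1, p2, t2)
            for p1, t1, p2, t2 in zip(pct1, th1, pct2, th2)
        ])
        assert out.loc[0, "elastin"] == pytest.approx(means_first)
        assert abs(means_first - framewise) > 1.0

    def test_out_of_range_pct_rejected(self):
        rows = _frame_rows("h1", "young", "femoral", "1", "elastin",
                           pcts=[10, 10, 10, 10, 150])
        with pytest.raises(ValidationError):
            aggregate_histology(pd.DataFrame(rows))


class TestHistoAnova:
    def test_recovers_generator_means(self, histo_table):
        overall = aggregate_histology(histo_table)
        prox = overall[(overall["location"] == "proximal_aorta")]
        assert prox["elastin"].between(10, 60).all()
        assert prox["thickness_um"].isna().all()

    def test_age_effect_power_on_thickness(self):
        """A simulated old-group thickness shift at the generator's scale is
        detected in >= 80% of seeded replicates."""
        hits, n_rep = 0, 60
        profs = vm.default_histo_profiles()
        # equalize ages first so the shift is the only age difference
        young = {p.location: p for p in profs if p.age_group == "young"}
        eq = [p if p.age_group == "young" else
              vm.HistoProfile(p.location, "old",
                              young[p.location].stain_means,
                              young[p.location].stain_sds,
                              young[p.location].thickness_um,
                              young[p.location].thickness_sd,
                              single_layer=p.single_layer)
              for p in profs]
        for i in range(n_rep):
            tab = vm.gen_histology_dataset(
                eq, 6, 14, seed=3000 + i, age_effects={"thickness_um": 350.0}
            )
            res = histo_anova(aggregate_histology(tab), outcomes=("thickness_um",))
            hits += res["thickness_um"].effects.loc["age", "p_value"] <= 0.05
        assert hits >= 0.80 * n_rep

    def test_null_type_i_within_binomial_tolerance(self):
        """With no simulated effects the age test rejects at ~nominal rate."""
        profs = vm.default_histo_profiles()
        young = {p.location: p for p in profs if p.age_group == "young"}
        eq = [p if p.age_group == "young" else
              vm.HistoProfile(p.location, "old",
                              young[p.location].stain_means,
                              young[p.location].stain_sds,
                              young[p.location].thickness_um,
                              young[p.location].thickness_sd,
                              single_layer=p.single_layer)
              for p in profs]
        hits, n_rep = 0, 150
        for i in range(n_rep):
            tab = vm.gen_histology_dataset(eq, 6, 14, seed=5000 + i)
            res = histo_anova(aggregate_histology(tab), outcomes=("elastin",))
            hits += res["elastin"].effects.loc["age", "p_value"] <= 0.05
        lo, hi = 0.05 - 1.96 * np.sqrt(0.05 * 0.95 / n_rep), \
            0.05 + 1.96 * np.sqrt(0.05 * 0.95 / n_rep)
        assert lo <= hits / n_rep <= hi + 1e-9

    def test_fallback_matches_fixed_two_way_anova(self, rng):
        """One row per horse: horse is confounded with residual, and the
        fallback agrees with a direct two-way fixed ANOVA to 1e-8."""
        rows = []
        h = 0
        for age in ("young", "old"):
            for loc in ("A", "B"):
                for _ in range(5):
                    rows.append({
                        "horse_id": f"h{h}", "age_group": age, "location": loc,
                        "elastin": float(rng.normal(20 if loc == "A" else 25, 3)),
                    })
                    h += 1
        df = pd.DataFrame(rows)
        res = histo_anova(df, outcomes=("elastin",))["elastin"]
        assert "fixed-effects fallback" in res.note
        direct = anova_lm(
            smf.ols("elastin ~ C(age_group) * C(location)", data=df).fit(), typ=2
        )
        assert res.effects.loc["age", "F"] == pytest.approx(
            float(direct.loc["C(age_group)", "F"]), abs=1e-8
        )
        assert res.effects.loc["location", "F"] == pytest.approx(
            float(direct.loc["C(location)", "F"]), abs=1e-8
        )

    def test_identical_values_degenerate(self):
        df = pd.DataFrame({
            "horse_id": [f"h{i}" for i in range(8)] * 2,
            "age_group": (["young"] * 4 + ["old"] * 4) * 2,
            "location": ["A"] * 8 + ["B"] * 8,
            "elastin": 5.0,
        })
        res = histo_anova(df, outcomes=("elastin",))["elastin"]
        assert res.degenerate

    def test_single_horse_group_not_estimable(self):
        df = pd.DataFrame({
            "horse_id": ["h1", "h1", "h2", "h2"],
            "age_group": ["young", "young", "old", "old"],
            "location": ["A", "B", "A", "B"],
            "elastin": [10.0, 12.0, 14.0, 16.0],
        })
        res = histo_anova(df, outcomes=("elastin",))["elastin"]
        assert res.degenerate
        assert "single-horse" in res.note
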