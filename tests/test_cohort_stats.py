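"""Nutrition arithmetic, GEE equivalences, Mann-Whitney oracles."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from neomaturity.cohort_stats import (
    days_to_weeks,
    energy_kcal,
    fit_gee,
    gee_grid,
    mann_whitney,
    outcome_group_report,
    percent_of,
    summarize_nutrition,
)


def _daily(infants):
    rows = []
    for iid, (p, l, c) in infants.items():
        for dol in range(1, 8):
            rows.append({"infant_id": iid, "dol": dol,
                         "proteins": p, "lipids": l, "carbohydrates": c})
    return pd.DataFrame(rows)


class TestNutrition:
    def test_constant_week_mean(self):
        out = summarize_nutrition(_daily({"a": (2.5, 2.0, 10.0)}))
        assert out.loc[0, "proteins"] == pytest.approx(2.5)

    def test_energy_from_four_nine_rule(self):
        # carbs 10.31, lipids 2.03, proteins 2.54 -> 4*(10.31+2.54)+9*2.03
        assert energy_kcal(2.54, 2.03, 10.31) == pytest.approx(69.67)
        out = summarize_nutrition(_daily({"a": (2.54, 2.03, 10.31)}))
        assert out.loc[0, "energy"] == pytest.approx(69.67)

    def test_zero_intake_zero_energy(self):
        assert energy_kcal(0, 0, 0) == 0.0

    def test_energy_identity_holds_for_every_summary(self, rng):
        daily = _daily({f"i{k}": tuple(rng.uniform(0, 12, 3)) for k in range(10)})
        out = summarize_nutrition(daily)
        np.testing.assert_allclose(
            out["energy"],
            4 * (out["proteins"] + out["carbohydrates"]) + 9 * out["lipids"],
        )

    def test_negative_intake_rejected(self):
        daily = _daily({"a": (2.5, -1.0, 10.0)})
        with pytest.raises(ValueError, match="negative"):
            summarize_nutrition(daily)

    def test_window_restriction(self):
        daily = _daily({"a": (2.0, 2.0, 10.0)})
        daily.loc[daily.dol > 3, "proteins"] = 99.0
        out = summarize_nutrition(daily, window=(1, 3))
        assert out.loc[0, "proteins"] == pytest.approx(2.0)


def _gee_table(rng, n=30, b_nut=1.0, b_age=0.5, cluster_sd=0.5, obs_sd=0.5,
               one_obs=False):
    rows = []
    for i in range(n):
        nut = rng.normal(2.5, 0.4)
        u = rng.normal(0, cluster_sd)
        sessions = [("T1", rng.normal(32.4, 0.7))] if one_obs else [
            ("T1", rng.normal(32.4, 0.7)), ("T2", rng.normal(36.7, 0.9))]
        for ses, pma in sessions:
            rows.append({
                "infant_id": f"i{i}", "session": ses, "pma_weeks": pma,
                "metric": 1.0 + b_nut * nut + b_age * pma + u + rng.normal(0, obs_sd),
                "proteins": nut,
            })
    return pd.DataFrame(rows)


class TestGee:
    def test_recovers_known_effect(self, rng):
        fit = fit_gee(_gee_table(rng, n=150), "metric", "proteins")
        assert fit.params["proteins"] == pytest.approx(1.0, abs=0.2)
        assert fit.params["pma_weeks"] == pytest.approx(0.5, abs=0.1)
        assert 0 <= fit.pvalues["proteins"] <= 1
        assert fit.robust_se["proteins"] > 0

    def test_single_observation_clusters_match_ols_hc3(self, rng):
        # bias-reduced sandwich collapses to the HC3 leverage correction
        # when every cluster holds a single observation
        table = _gee_table(rng, n=60, one_obs=True)
        fit = fit_gee(table, "metric", "proteins")
        exog = sm.add_constant(table[["proteins", "pma_weeks"]])
        ols = sm.OLS(table["metric"], exog).fit(cov_type="HC3")
        assert fit.params["proteins"] == pytest.approx(ols.params["proteins"], rel=1e-6)
        assert fit.robust_se["proteins"] == pytest.approx(ols.bse["proteins"], rel=1e-6)

    def test_singular_design_raises(self, rng):
        table = _gee_table(rng, n=20)
        table["proteins"] = 2.0 * table["pma_weeks"]
        with pytest.raises(ValueError, match="collinear|singular"):
            fit_gee(table, "metric", "proteins")

    def test_grid_emits_bh_extension_column(self, rng):
        table = _gee_table(rng, n=25)
        table["lipids"] = table["proteins"] * 0.5 + 1.0  # a second nutrient
        out = gee_grid(table, ["metric"], nutrients=["proteins", "lipids"])
        assert {"B", "p", "p_bh", "robust_se"} <= set(out.columns)
        assert ((out["p"] >= 0) & (out["p"] <= 1)).all()

    def test_missing_rows_dropped_per_model(self, rng):
        table = _gee_table(rng, n=30)
        table.loc[table.index[:5], "metric"] = np.nan
        fit = fit_gee(table, "metric", "proteins")
        assert fit.n_obs == len(table) - 5


class TestMannWhitney:
    def test_exact_enumeration_small_groups(self):
        u, p = mann_whitney([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1)  # 2/C(6,3) * 2-sided

    def test_identical_groups(self):
        _, p = mann_whitney([1, 2, 3, 4], [1, 2, 3, 4])
        assert p == pytest.approx(1.0)

    def test_monotone_transform_invariance(self, rng):
        a, b = rng.normal(size=12), rng.normal(loc=1, size=10)
        _, p1 = mann_whitney(a, b)
        _, p2 = mann_whitney(np.exp(a), np.exp(b))
        assert p1 == pytest.approx(p2)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])


class TestOutcomeReport:
    def _features(self, rng, shift=0.0):
        rows = []
        for i in range(24):
            grp = "normal" if i < 14 else "mild_moderate"
            for ses in ("T1", "T2"):
                rows.append({
                    "infant_id": f"i{i}", "session": ses, "outcome": grp,
                    "asi_C-O": rng.normal(shift if grp == "normal" else 0.0, 1.0),
                })
        return pd.DataFrame(rows)

    def test_groups_compared_per_session(self, rng):
        rep = outcome_group_report(self._features(rng), ["asi_C-O"])
        assert set(rep["session"]) == {"T1", "T2"}
        assert ((rep["p"] >= 0) & (rep["p"] <= 1)).all()

    def test_small_group_skipped_with_note(self, rng):
        feats = self._features(rng)
        feats = feats[(feats.outcome == "normal") | (feats.infant_id == "i20")]
        rep = outcome_group_report(feats, ["asi_C-O"], min_group=2)
        assert (rep["note"] == "group too small").all()

    def test_missing_session_excluded_only_there(self, rng):
        feats = self._features(rng)
        feats = feats[~((feats.infant_id == "i0") & (feats.session == "T2"))]
        rep = outcome_group_report(feats, ["asi_C-O"])
        t1 = rep[rep.session == "T1"].iloc[0]
        t2 = rep[rep.session == "T2"].iloc[0]
        assert t1["n_normal"] == t2["n_normal"] + 1


class TestCohortArithmetic:
    @pytest.mark.parametrize("count,total,expected", [
        (16, 28, 57), (12, 28, 43), (36, 60, 60), (25, 28, 89),
    ])
    def test_percentages(self, count, total, expected):
        assert percent_of(count, total) == expected

    @pytest.mark.parametrize("days,weeks", [(30, 4.3), (21, 3.0), (49, 7.0)])
    def test_interval_conversion(self, days, weeks):
        assert days_to_weeks(days) == weeks
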