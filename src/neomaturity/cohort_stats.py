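"""Nutrition summaries and cohort inference.

The inference stage relates first-week parenteral nutrition to the change
in each quantitative EEG metric over serial recordings: one GEE model per
(metric, macronutrient) with infants as clusters, a working-independence
correlation, robust (sandwich) standard errors and adjustment for PMA at
the recording; outcome groups are compared with the Mann-Whitney U test.
No multiplicity correction enters the primary p-values; Benjamini-Hochberg
adjusted columns are emitted alongside as a clearly labelled extension.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import mannwhitneyu
from statsmodels.stats.multitest import multipletests

__all__ = [
    "NutritionSummary",
    "GEEFit",
    "summarize_nutrition",
    "energy_kcal",
    "fit_gee",
    "gee_grid",
    "mann_whitney",
    "outcome_group_report",
    "percent_of",
    "days_to_weeks",
]

KCAL_PER_G = {"proteins": 4.0, "carbohydrates": 4.0, "lipids": 9.0}


@dataclass
class NutritionSummary:
    """Mean daily first-week intakes for one infant, g/kg/day and kcal/kg/day."""

    infant_id: str
    proteins: float
    lipids: float
    carbohydrates: float
    energy: float


@dataclass
class GEEFit:
    """One GEE model: coefficient, robust SE and p per predictor.

    Standard errors come from the bias-reduced (Mancl-DeRouen) sandwich and
    inference uses a t reference with (clusters - parameters) degrees of
    freedom — the standard small-sample treatment for GEE with a few dozen
    clusters, where the plain sandwich/normal combination is anticonservative.
    """

    metric: str
    nutrient: str
    params: dict[str, float]
    robust_se: dict[str, float]
    pvalues: dict[str, float]
    n_infants: int
    n_obs: int
    df: int = 0

    def conf_int(self, name: str, level: float = 0.95) -> tuple[float, float]:
        """Robust t-based confidence interval for one predictor."""
        from scipy.stats import t as t_dist

        half = t_dist.ppf(0.5 + level / 2, self.df) * self.robust_se[name]
        return self.params[name] - half, self.params[name] + half


def energy_kcal(proteins: float, lipids: float, carbohydrates: float) -> float:
    """Energy from macronutrients: 4 kcal/g for protein and carbohydrate,
    9 kcal/g for lipid."""
    return (
        KCAL_PER_G["proteins"] * proteins
        + KCAL_PER_G["carbohydrates"] * carbohydrates
        + KCAL_PER_G["lipids"] * lipids
    )


def summarize_nutrition(
    daily: pd.DataFrame, window: tuple[int, int] = (1, 7)
) -> pd.DataFrame:
    """Per-infant mean daily intakes over days of life ``window`` (inclusive).

    ``daily`` needs columns ``infant_id, dol, proteins, lipids,
    carbohydrates``; days outside the window are ignored and the mean runs
    over the available days within it.  Negative intakes are rejected.
    """
    required = {"infant_id", "dol", "proteins", "lipids", "carbohydrates"}
    if not required.issubset(daily.columns):
        raise ValueError(f"daily table needs columns {sorted(required)}")
    if (daily[["proteins", "lipids", "carbohydrates"]] < 0).any().any():
        raise ValueError("negative nutrient intake")
    sub = daily[(daily["dol"] >= window[0]) & (daily["dol"] <= window[1])]
    if sub.empty:
        raise ValueError("no days within the summary window")
    out = (
        sub.groupby("infant_id")[["proteins", "lipids", "carbohydrates"]]
        .mean()
        .reset_index()
    )
    out["energy"] = energy_kcal(
        out["proteins"], out["lipids"], out["carbohydrates"]
    )
    return out


def fit_gee(table: pd.DataFrame, metric: str, nutrient: str) -> GEEFit:
    """GEE of one EEG metric on one nutrient, age-adjusted.

    Mean model ``metric ~ intercept + nutrient + pma_weeks`` with infants
    as clusters, working independence and sandwich covariance.  Rows with a
    missing response or predictor are dropped (complete-case per model).
    """
    cols = ["infant_id", "pma_weeks", metric, nutrient]
    sub = table[cols].dropna()
    if sub["infant_id"].nunique() < 3:
        raise ValueError("too few infants for a cluster-robust fit")
    exog = sm.add_constant(sub[[nutrient, "pma_weeks"]].astype(float))
    if np.linalg.matrix_rank(exog.to_numpy()) < exog.shape[1]:
        raise ValueError(
            f"singular design: columns {list(exog.columns)} are collinear"
        )
    model = sm.GEE(
        sub[metric].astype(float),
        exog,
        groups=sub["infant_id"],
        family=sm.families.Gaussian(),
        cov_struct=sm.cov_struct.Independence(),
    )
    n_clusters = int(sub["infant_id"].nunique())
    df = max(n_clusters - exog.shape[1], 1)
    res = model.fit(cov_type="bias_reduced")
    from scipy.stats import t as t_dist

    pvals = {
        k: float(2 * t_dist.sf(abs(res.params[k] / res.bse[k]), df))
        for k in res.params.index
    }
    return GEEFit(
        metric=metric,
        nutrient=nutrient,
        params={k: float(v) for k, v in res.params.items()},
        robust_se={k: float(v) for k, v in res.bse.items()},
        pvalues=pvals,
        n_infants=n_clusters,
        n_obs=int(len(sub)),
        df=df,
    )


def gee_grid(
    table: pd.DataFrame,
    metrics: list[str],
    nutrients: list[str] = ("energy", "carbohydrates", "lipids", "proteins"),
) -> pd.DataFrame:
    """Separate GEE models for every (metric, nutrient) pair.

    Returns a tidy frame with B, robust SE and p for the nutrient and the
    age covariate, plus Benjamini-Hochberg adjusted nutrient p-values
    (``p_bh``, an extension next to the unadjusted primary column).
    """
    rows = []
    for metric in metrics:
        for nutrient in nutrients:
            try:
                fit = fit_gee(table, metric, nutrient)
            except ValueError as err:
                rows.append({"metric": metric, "nutrient": nutrient,
                             "error": str(err)})
                continue
            rows.append({
                "metric": metric, "nutrient": nutrient,
                "B": fit.params[nutrient],
                "robust_se": fit.robust_se[nutrient],
                "p": fit.pvalues[nutrient],
                "B_age": fit.params["pma_weeks"],
                "p_age": fit.pvalues["pma_weeks"],
                "n_infants": fit.n_infants,
                "n_obs": fit.n_obs,
            })
    out = pd.DataFrame(rows)
    if "p" in out.columns:
        ok = out["p"].notna()
        out.loc[ok, "p_bh"] = multipletests(out.loc[ok, "p"], method="fdr_bh")[1]
    return out


def mann_whitney(group_a, group_b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U.

    Exact p for combined n <= 20 without ties; otherwise the normal
    approximation with tie correction.  Returns ``(U, p)`` with U counted
    for the first group.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (pooled.size <= 20 and not has_ties) else "asymptotic"
    res = mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def outcome_group_report(
    features: pd.DataFrame,
    metrics: list[str],
    group_col: str = "outcome",
    groups: tuple[str, str] = ("normal", "mild_moderate"),
    min_group: int = 2,
) -> pd.DataFrame:
    """Outcome-group comparison per metric and session.

    ``features`` is the long table with one row per (infant, session) and
    metric columns.  For each metric and session the two groups are
    compared with Mann-Whitney U; groups smaller than ``min_group`` skip
    the metric with a note.  Infants missing one session drop out of that
    session's comparison only.
    """
    rows = []
    for metric in metrics:
        for session, sub in features.groupby("session"):
            sub = sub.dropna(subset=[metric])
            a = sub.loc[sub[group_col] == groups[0], metric].to_numpy()
            b = sub.loc[sub[group_col] == groups[1], metric].to_numpy()
            if len(a) < min_group or len(b) < min_group:
                rows.append({"metric": metric, "session": session,
                             "note": "group too small"})
                continue
            u, p = mann_whitney(a, b)
            rows.append({
                "metric": metric, "session": session,
                f"median_{groups[0]}": float(np.median(a)),
                f"median_{groups[1]}": float(np.median(b)),
                f"n_{groups[0]}": len(a), f"n_{groups[1]}": len(b),
                "U": u, "p": p,
            })
    return pd.DataFrame(rows)


# --- small cohort arithmetic helpers ---------------------------------------

def percent_of(count: int, total: int, decimals: int = 0) -> float:
    """Share of a cohort as a percentage, rounded to ``decimals`` places."""
    if total <= 0:
        raise ValueError("total must be positive")
    return round(100.0 * count / total, decimals)


def days_to_weeks(days: float, decimals: int = 1) -> float:
    """Convert a between-recording interval from days to weeks."""
    return round(days / 7.0, decimals)
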