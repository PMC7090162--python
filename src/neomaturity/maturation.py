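"""EEG maturational age (EMA): feature assembly, training, estimation.

EMA is a regression prediction of postmenstrual age from quantitative EEG
features; its deviation from the true age (the EMA gap, weeks) and the
change in that gap between serial recordings (delta gap) are the
maturation readouts.  The regressor here is ridge regression on
standardized features — transparent and deterministic; the model class is
pluggable behind the JSON-serialized :class:`EMAModel` contract.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

from .spectral import BANDS

__all__ = [
    "FEATURE_NAMES",
    "FeatureVector",
    "EMAModel",
    "EMAResult",
    "assemble_features",
    "train_ema",
    "loso_validate",
    "estimate_ema",
]

#: Fixed, documented feature order of the EMA regressor.
FEATURE_NAMES: tuple[str, ...] = tuple(
    [f"abs_{b}" for b in BANDS]
    + [f"rel_{b}" for b in BANDS]
    + ["msc", "ibi95", "ibi_mean_CO", "ibi_mean_FC", "global_asi"]
    + [f"asi_{p}" for p in ("Fp-C", "Fp-T", "Fp-O", "C-O", "T-O", "C-T")]
    + ["amplitude_iqr"]
)


@dataclass
class FeatureVector:
    """One recording's qEEG feature vector in :data:`FEATURE_NAMES` order.

    Missing metrics are carried as NaN and flagged, never silently zeroed.
    """

    values: np.ndarray
    missing: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(FEATURE_NAMES),):
            raise ValueError(
                f"feature vector must have length {len(FEATURE_NAMES)}"
            )


def assemble_features(metrics: dict[str, float]) -> FeatureVector:
    """Assemble a :class:`FeatureVector` from a metric-name dictionary.

    Absent or non-finite entries become NaN and are listed in ``missing``;
    an all-missing vector is an error.
    """
    values = np.full(len(FEATURE_NAMES), np.nan)
    missing = []
    for i, name in enumerate(FEATURE_NAMES):
        v = metrics.get(name, float("nan"))
        if v is None or not np.isfinite(v):
            missing.append(name)
        else:
            values[i] = float(v)
    if len(missing) == len(FEATURE_NAMES):
        raise ValueError("all features missing")
    return FeatureVector(values=values, missing=tuple(missing))


@dataclass
class EMAModel:
    """Standardized-feature ridge regressor mapping qEEG features to weeks."""

    feature_names: tuple[str, ...]
    mean: np.ndarray
    scale: np.ndarray
    coef: np.ndarray
    intercept: float
    alpha: float
    dropped: tuple[str, ...] = ()        # constant features excluded from the fit
    training_cohort: str = ""

    def predict(self, fv: FeatureVector) -> tuple[float, tuple[str, ...]]:
        """Predict EMA (weeks); missing features are imputed with their
        training mean and reported back."""
        x = fv.values.copy()
        imputed = tuple(
            name for name, v in zip(self.feature_names, x) if not np.isfinite(v)
        )
        bad = ~np.isfinite(x)
        x[bad] = self.mean[bad]
        z = (x - self.mean) / self.scale
        return float(z @ self.coef + self.intercept), imputed

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {
            "feature_names": list(self.feature_names),
            "mean": self.mean.tolist(),
            "scale": self.scale.tolist(),
            "coef": self.coef.tolist(),
            "intercept": self.intercept,
            "alpha": self.alpha,
            "dropped": list(self.dropped),
            "training_cohort": self.training_cohort,
        }
        path.write_text(json.dumps(payload, indent=1))
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "EMAModel":
        d = json.loads(Path(path).read_text())
        return cls(
            feature_names=tuple(d["feature_names"]),
            mean=np.array(d["mean"]),
            scale=np.array(d["scale"]),
            coef=np.array(d["coef"]),
            intercept=float(d["intercept"]),
            alpha=float(d["alpha"]),
            dropped=tuple(d["dropped"]),
            training_cohort=d["training_cohort"],
        )


@dataclass
class EMAResult:
    ema: float
    gap: float                  # ema - pma, weeks
    imputed: tuple[str, ...] = ()


def _ridge_fit(z: np.ndarray, y: np.ndarray, alpha: float) -> tuple[np.ndarray, float]:
    """Closed-form ridge on standardized, centered features (intercept free)."""
    yc = y - y.mean()
    k = z.shape[1]
    coef = np.linalg.solve(z.T @ z + alpha * np.eye(k), z.T @ yc)
    return coef, float(y.mean())


def train_ema(
    features: np.ndarray,
    ages: np.ndarray,
    alpha: float = 1.0,
    feature_names: tuple[str, ...] = FEATURE_NAMES,
    training_cohort: str = "synthetic-reference",
) -> EMAModel:
    """Fit the EMA ridge regressor.

    ``features`` is ``(n_recordings, n_features)``; missing entries (NaN)
    are imputed with the column mean before standardization.  Requires at
    least 10 recordings spanning at least 4 weeks of age.  Constant
    features are dropped with a warning (their coefficient is pinned to 0).
    """
    X = np.asarray(features, dtype=float).copy()
    y = np.asarray(ages, dtype=float)
    if X.shape[0] < 10:
        raise ValueError("need at least 10 training recordings")
    if np.ptp(y) < 4.0:
        raise ValueError("training ages must span at least 4 weeks")
    col_mean = np.nanmean(X, axis=0)
    nan_mask = ~np.isfinite(X)
    X[nan_mask] = np.take(col_mean, np.where(nan_mask)[1])
    scale = X.std(axis=0, ddof=0)
    dropped = tuple(
        name for name, s in zip(feature_names, scale) if s < 1e-12
    )
    if dropped:
        warnings.warn(f"dropping constant features: {dropped}", stacklevel=2)
    safe_scale = np.where(scale < 1e-12, 1.0, scale)
    z = (X - X.mean(axis=0)) / safe_scale
    z[:, scale < 1e-12] = 0.0
    coef, intercept = _ridge_fit(z, y, alpha)
    coef[scale < 1e-12] = 0.0
    return EMAModel(
        feature_names=tuple(feature_names),
        mean=X.mean(axis=0),
        scale=safe_scale,
        coef=coef,
        intercept=intercept,
        alpha=alpha,
        dropped=dropped,
        training_cohort=training_cohort,
    )


def loso_validate(
    features: np.ndarray,
    ages: np.ndarray,
    subjects: np.ndarray,
    alpha: float = 1.0,
) -> pd.DataFrame:
    """Leave-one-subject-out validation of the EMA regressor.

    Folds leave out all recordings of one infant (not one recording), so
    the report is free of within-subject leakage.  Returns one row per
    recording with the held-out prediction; ``attrs`` carries the MAE and
    the Pearson correlation with true age.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(ages, dtype=float)
    subjects = np.asarray(subjects)
    preds = np.full(y.shape, np.nan)
    for s in np.unique(subjects):
        hold = subjects == s
        model = train_ema(X[~hold], y[~hold], alpha=alpha)
        for i in np.where(hold)[0]:
            preds[i], _ = model.predict(FeatureVector(X[i]))
    report = pd.DataFrame({
        "subject": subjects, "age_weeks": y, "ema_pred": preds,
        "gap": preds - y,
    })
    report.attrs["mae"] = float(np.mean(np.abs(preds - y)))
    report.attrs["pearson_r"] = float(pearsonr(preds, y)[0])
    return report


def estimate_ema(model: EMAModel, fv: FeatureVector, pma_weeks: float) -> EMAResult:
    """Predict EMA and the EMA gap for one recording.

    The gap (EMA minus PMA) is reported unclamped — its sign carries the
    delayed/advanced information.
    """
    ema, imputed = model.predict(fv)
    return EMAResult(ema=ema, gap=ema - pma_weeks, imputed=imputed)
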