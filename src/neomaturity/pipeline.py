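"""End-to-end orchestration: simulate -> features -> EMA -> statistics.

Each recording is reduced to a quantitative-EEG feature row (band powers,
MSC, IBI95, derivation IBIs, ASI set, amplitude IQR), computed twice —
on quiet sleep only (the substrate of the discontinuity/synchrony metrics)
and on the whole recording (the EMA substrate).  EMA is obtained by
leave-one-subject-out prediction within the cohort, the GEE grid relates
nutrition to the four headline metric families, and outcome groups are
compared nonparametrically.  Outputs are tidy CSVs plus a JSON run log;
failures are isolated per recording.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
import traceback
from dataclasses import dataclass, field
from pathlib import Path

import click
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .continuity import (
    DetectionParams,
    derivation_ibi,
    detect_bursts,
    interburst_intervals,
    suppression_curve,
)
from .eeg_io import (
    ANALYSIS_CHANNELS,
    Recording,
    Segment,
    SegmentSet,
    SleepAnnotation,
    extract_state_segments,
    make_bipolar,
    preprocess,
    read_annotations,
    read_edf,
)
from .maturation import FEATURE_NAMES, FeatureVector, loso_validate
from .cohort_stats import gee_grid, outcome_group_report, summarize_nutrition
from .spectral import BANDS, band_power_table, regional_band_powers
from .synchrony import AsiParams, asi_all_pairs
from .synthetic_data import SimulationConfig, write_dataset

log = logging.getLogger("neomaturity")

__all__ = [
    "RunConfig",
    "compute_recording_metrics",
    "run_study",
    "cli",
]

#: Metric families entering the GEE grid (mirroring the headline analyses).
GEE_METRICS = ["abs_Delta1", "rel_Delta1", "msc", "ibi95", "asi_C-O", "ema_gap"]

OUTCOME_METRICS = GEE_METRICS + ["global_asi", "ibi_mean_FC", "asi_Fp-T", "asi_C-T"]


@dataclass
class RunConfig:
    """Everything a study run depends on; defaults mirror the method."""

    out_dir: str = "neomaturity_out"
    data_dir: str | None = None          # existing dataset; None -> simulate
    seed: int = 0
    min_qs_s: float = 300.0
    ema_alpha: float = 1.0
    ema_on_whole_recording: bool = True
    sim: SimulationConfig = field(default_factory=SimulationConfig)
    detection: DetectionParams = field(default_factory=DetectionParams)
    asi: AsiParams = field(default_factory=AsiParams)

    def __post_init__(self) -> None:
        self.sim.seed = self.seed

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = dict(raw)
        for key, typ in (("sim", SimulationConfig),
                         ("detection", DetectionParams),
                         ("asi", AsiParams)):
            if key in kwargs:
                kwargs[key] = typ(**{
                    k: tuple(v) if isinstance(v, list) else v
                    for k, v in kwargs[key].items()
                })
        return cls(**kwargs)

    def parameter_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return f"{abs(hash(blob)) % 16**8:08x}"


def _continuity_metrics(
    segments: SegmentSet, params: DetectionParams
) -> dict[str, float]:
    """MSC, IBI95 and derivation IBIs pooled over segments (duration-weighted
    MSC; IBIs never span segment joins)."""
    msc_num, total, ibis = 0.0, 0.0, []
    fs = segments.fs
    idx = [segments.channels.index(c) for c in ANALYSIS_CHANNELS]
    for seg in segments:
        bm = detect_bursts(seg.data[idx], fs, params)
        _, msc = suppression_curve(bm)
        msc_num += msc * seg.duration
        total += seg.duration
        seg_ibis, _ = interburst_intervals(bm.consensus, bm.frame_s)
        ibis.extend(seg_ibis)
    out = {
        "msc": msc_num / total if total else float("nan"),
        "ibi95": float(np.percentile(ibis, 95, method="linear")) if ibis else float("nan"),
        "n_ibi": len(ibis),
    }
    # derivation-specific mean IBIs, pooled across segments per derivation
    group_vals: dict[str, list[float]] = {}
    for seg in segments:
        rec_like = Recording(
            "x", "T1", float("nan"), fs, list(segments.channels), seg.data
        )
        derivs = make_bipolar(rec_like, (("C3", "O1"), ("C4", "O2"),
                                         ("Fp1", "C3"), ("Fp2", "C4")))
        vals = derivation_ibi(derivs, fs, params)
        for k, v in vals.items():
            group_vals.setdefault(k, []).append(v)
    for k, vs in group_vals.items():
        vs = [v for v in vs if np.isfinite(v)]
        out[k] = float(np.mean(vs)) if vs else float("nan")
    return out


def compute_recording_metrics(
    rec: Recording,
    annotations: list[SleepAnnotation],
    cfg: RunConfig | None = None,
    variants: tuple[str, ...] = ("qs", "whole"),
) -> dict[str, dict[str, float]]:
    """All qEEG metrics of one recording.

    Returns ``{"qs": ..., "whole": ...}`` (restrictable via ``variants``):
    the quiet-sleep metrics feeding the nutrition models and the
    whole-recording variant feeding EMA.  An empty quiet-sleep set yields
    NaN metrics (reported, not raised).
    """
    cfg = cfg or RunConfig()
    rec = preprocess(rec)

    def metrics_for(segments: SegmentSet) -> dict[str, float]:
        if len(segments) == 0:
            return {name: float("nan") for name in FEATURE_NAMES}
        out: dict[str, float] = {}
        per_chan = band_power_table(rec, segments)
        regional = regional_band_powers(per_chan)
        tot = regional[regional["region"] == "total"].set_index("band")
        for band in BANDS:
            out[f"abs_{band}"] = float(tot.loc[band, "abs_uV2"])
            out[f"rel_{band}"] = float(tot.loc[band, "rel_pct"])
        out["abs_total"] = float(tot.loc["total", "abs_uV2"])
        out.update(_continuity_metrics(segments, cfg.detection))
        asi = asi_all_pairs(rec, segments, cfg.asi, seed=cfg.seed)
        out["global_asi"] = asi.global_asi
        for name, v in asi.symmetric_pairs.items():
            out[f"asi_{name}"] = v
        pooled = np.concatenate(
            [seg.data[[segments.channels.index(c) for c in ANALYSIS_CHANNELS]].ravel()
             for seg in segments]
        )
        q75, q25 = np.percentile(pooled, [75, 25])
        out["amplitude_iqr"] = float(q75 - q25)
        return out

    out: dict[str, dict[str, float]] = {}
    if "qs" in variants:
        qs = extract_state_segments(rec, annotations, "QS", cfg.min_qs_s)
        out["qs"] = metrics_for(qs)
    if "whole" in variants:
        whole = SegmentSet(
            [Segment(rec.data, 0.0, rec.duration_s)], "all", rec.fs,
            channels=list(rec.channels),
        )
        out["whole"] = metrics_for(whole)
    return out


def _feature_matrix(df: pd.DataFrame) -> np.ndarray:
    return df[list(FEATURE_NAMES)].to_numpy(dtype=float)


def run_study(cfg: RunConfig) -> dict:
    """Run the full study; returns the output bundle paths and key frames.

    Writes per-recording features, the LOSO EMA report, ``gee_results.csv``,
    ``group_comparisons.csv`` and a run log under ``cfg.out_dir``.
    """
    t0 = time.time()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if cfg.data_dir is None:
        log.info("simulating dataset seed=%s n=%d", cfg.seed, cfg.sim.n_infants)
        paths = write_dataset(cfg.sim, out / "data")
        data_dir = out / "data"
    else:
        data_dir = Path(cfg.data_dir)
    cohort = pd.read_csv(data_dir / "cohort.csv")
    nutrition = pd.read_csv(data_dir / "nutrition_daily.csv")
    nut_summary = summarize_nutrition(nutrition)

    rows, failures = [], []
    for _, infant in cohort.iterrows():
        for session in ("T1", "T2"):
            iid = infant["infant_id"]
            pma = float(infant[f"pma_{session.lower()}"])
            try:
                rec = read_edf(
                    data_dir / "edf" / f"{iid}_{session}.edf",
                    infant_id=iid, session=session, pma_weeks=pma,
                )
                ann = read_annotations(
                    data_dir / "edf" / f"{iid}_{session}_annotations.csv"
                )
                metrics = compute_recording_metrics(rec, ann, cfg)
            except Exception as err:   # noqa: BLE001 - isolate per recording
                failures.append({"infant_id": iid, "session": session,
                                 "error": repr(err),
                                 "trace": traceback.format_exc(limit=3)})
                log.warning("recording %s %s failed: %r", iid, session, err)
                continue
            row = {"infant_id": iid, "session": session, "pma_weeks": pma,
                   "outcome": infant["outcome"]}
            row.update(metrics["qs"])
            row.update({f"whole_{k}": v for k, v in metrics["whole"].items()})
            rows.append(row)
            log.info("features %s %s ok (%.1fs)", iid, session, time.time() - t0)

    features = pd.DataFrame(rows).merge(nut_summary, on="infant_id", how="left")

    # EMA via leave-one-subject-out prediction within the cohort
    source_prefix = "whole_" if cfg.ema_on_whole_recording else ""
    ema_cols = {name: f"{source_prefix}{name}" for name in FEATURE_NAMES}
    X = features[list(ema_cols.values())].to_numpy(dtype=float)
    usable = ~np.all(~np.isfinite(X), axis=1)
    features["ema"] = np.nan
    try:
        report = loso_validate(
            X[usable],
            features.loc[usable, "pma_weeks"].to_numpy(),
            features.loc[usable, "infant_id"].to_numpy(),
            alpha=cfg.ema_alpha,
        )
        features.loc[usable, "ema"] = report["ema_pred"].to_numpy()
    except ValueError as err:
        log.warning("EMA validation skipped: %s", err)
        report = pd.DataFrame()
        report.attrs.update({"mae": float("nan"), "pearson_r": float("nan")})
    features["ema_gap"] = features["ema"] - features["pma_weeks"]
    gaps = features.pivot_table(index="infant_id", columns="session",
                                values="ema_gap")
    if {"T1", "T2"}.issubset(gaps.columns):
        delta_gap = (gaps["T2"] - gaps["T1"]).rename("delta_gap")
        features = features.merge(delta_gap, on="infant_id", how="left")

    gee = gee_grid(features, GEE_METRICS)
    groups = outcome_group_report(features, OUTCOME_METRICS)

    features_path = out / "features.csv"
    gee_path = out / "gee_results.csv"
    groups_path = out / "group_comparisons.csv"
    features.to_csv(features_path, index=False, float_format="%.6g")
    gee.to_csv(gee_path, index=False, float_format="%.6g")
    groups.to_csv(groups_path, index=False, float_format="%.6g")
    run_log = {
        "version": __version__,
        "seed": cfg.seed,
        "parameter_hash": cfg.parameter_hash(),
        "n_recordings": int(len(rows)),
        "failures": failures,
        "ema_loso_mae": report.attrs["mae"],
        "ema_pearson_r": report.attrs["pearson_r"],
        "elapsed_s": round(time.time() - t0, 1),
    }
    (out / "run_log.json").write_text(json.dumps(run_log, indent=1))
    return {
        "features": features, "gee": gee, "groups": groups,
        "ema_report": report, "failures": failures, "run_log": run_log,
        "paths": {"features": features_path, "gee": gee_path,
                  "groups": groups_path},
    }


def ema_validation_study(
    sim_cfg: SimulationConfig, run_cfg: RunConfig | None = None
) -> pd.DataFrame:
    """Leave-one-subject-out EMA validation on a freshly simulated cohort.

    Simulates every recording, computes whole-recording features in memory
    and returns the LOSO report (``attrs['mae']``, ``attrs['pearson_r']``).
    """
    from .synthetic_data import simulate_cohort, simulate_eeg

    run_cfg = run_cfg or RunConfig()
    _, _, truth = simulate_cohort(sim_cfg)
    X, ages, subjects = [], [], []
    for iid, info in truth["infants"].items():
        for session in ("T1", "T2"):
            rec, ann, _ = simulate_eeg({**info, "infant_id": iid}, session, sim_cfg)
            m = compute_recording_metrics(rec, ann, run_cfg, variants=("whole",))["whole"]
            X.append([m.get(name, float("nan")) for name in FEATURE_NAMES])
            ages.append(rec.pma_weeks)
            subjects.append(iid)
    return loso_validate(
        np.array(X), np.array(ages), np.array(subjects), alpha=run_cfg.ema_alpha
    )


# --- CLI --------------------------------------------------------------------

@click.group()
@click.version_option(__version__)
def cli() -> None:
    """Quantitative EEG maturation pipeline for serial preterm recordings."""
    logging.basicConfig(level=logging.INFO,
                        format="%(asctime)s %(name)s %(message)s")


def _load_cfg(config: str | None, seed: int, out: str) -> RunConfig:
    cfg = RunConfig.from_yaml(config) if config else RunConfig()
    cfg.seed = seed
    cfg.sim.seed = seed
    cfg.out_dir = out
    return cfg


@cli.command()
@click.option("--config", type=click.Path(exists=True), default=None)
@click.option("--seed", type=int, default=0)
@click.option("--out", type=click.Path(), default="neomaturity_out")
def simulate(config, seed, out):
    """Generate a synthetic cohort dataset (EDF + CSV + ground truth)."""
    cfg = _load_cfg(config, seed, out)
    paths = write_dataset(cfg.sim, Path(out) / "data")
    click.echo(json.dumps({k: str(v) for k, v in paths.items()}, indent=1))


@cli.command()
@click.option("--config", type=click.Path(exists=True), default=None)
@click.option("--seed", type=int, default=0)
@click.option("--data", "data_dir", type=click.Path(exists=True), required=True)
@click.option("--out", type=click.Path(), default="neomaturity_out")
def features(config, seed, data_dir, out):
    """Compute per-recording qEEG features from an existing dataset."""
    cfg = _load_cfg(config, seed, out)
    cfg.data_dir = data_dir
    bundle = run_study(cfg)
    click.echo(f"wrote {bundle['paths']['features']}")


@cli.command()
@click.option("--config", type=click.Path(exists=True), default=None)
@click.option("--seed", type=int, default=0)
@click.option("--out", type=click.Path(), default="neomaturity_out")
@click.option("--data", "data_dir", type=click.Path(exists=True), default=None)
def run(config, seed, data_dir, out):
    """Full study: simulate (unless --data), features, EMA, statistics."""
    cfg = _load_cfg(config, seed, out)
    cfg.data_dir = data_dir
    bundle = run_study(cfg)
    click.echo(json.dumps(bundle["run_log"], indent=1))


@cli.command()
@click.option("--seed", type=int, default=0)
@click.option("--out", type=click.Path(), default="neomaturity_out")
@click.option("--data", "data_dir", type=click.Path(exists=True), required=True)
def stats(seed, data_dir, out):
    """Statistics stage only, from a directory containing features.csv."""
    feats = pd.read_csv(Path(data_dir) / "features.csv")
    gee = gee_grid(feats, [m for m in GEE_METRICS if m in feats.columns])
    outp = Path(out)
    outp.mkdir(parents=True, exist_ok=True)
    gee.to_csv(outp / "gee_results.csv", index=False, float_format="%.6g")
    click.echo(f"wrote {outp / 'gee_results.csv'}")
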