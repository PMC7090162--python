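"""Synthetic preterm EEG cohort with programmable ground truth.

Emulates the data layout of a serial-recording nutrition study: ~28 very
preterm infants, each with a first-week parenteral nutrition record and two
EEG sessions near 32 (T1) and 36 (T2) weeks postmenstrual age.  Each
recording is 40 min of 9-channel, 256-Hz EEG whose quiet-sleep stretch
shows burst-suppression (trace discontinu) with:

* suppression durations decreasing with effective maturational age
  (so IBI95 and MSC fall from T1 to T2);
* burst amplitude (hence delta-band power) decreasing with age;
* homologous left/right channels sharing an amplitude-modulation driver
  whose weight rho increases with age (so interhemispheric ASI rises).

Effective maturational age at a session is PMA plus an infant-level shift
``delta_i`` driven by first-week protein and lipid intake — the causal
structure the downstream GEE models are meant to recover.  Every stochastic
choice derives from one master seed via counter-based seed sequences, and
all synthesized events are logged so detector output can be scored against
ground truth.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .eeg_io import (
    ANALYSIS_CHANNELS,
    Recording,
    SleepAnnotation,
    write_annotations,
    write_edf,
)

__all__ = [
    "SimulationConfig",
    "simulate_cohort",
    "simulate_eeg",
    "simulate_coupled_envelopes",
    "simulate_feature_table",
    "write_dataset",
    "colored_noise",
    "events_to_mask",
]

#: Homologous channel pairs sharing an activation driver.
HOMOLOGOUS_PAIRS: tuple[tuple[str, str], ...] = (
    ("Fp1", "Fp2"), ("C3", "C4"), ("O1", "O2"), ("T3", "T4"),
)


@dataclass
class SimulationConfig:
    """Cohort and EEG generation parameters.

    Demographics and nutrition match a very-low-birth-weight NICU cohort
    (GA 28.4 +/- 2.1 weeks in [24.3, 32.0]; sessions at 32.4 +/- 0.7 and
    36.7 +/- 0.9 weeks PMA; first-week protein 2.54 +/- 0.36, lipids
    2.03 +/- 0.42, carbohydrates 10.31 +/- 0.72 g/kg/day).  Nutrition
    shifts the maturation clock: ``delta_i = beta_protein * (protein_i -
    mean) + beta_lipid * (lipid_i - mean) + N(0, delta_sd)`` weeks.
    """

    n_infants: int = 28
    seed: int = 0

    ga_mean: float = 28.4
    ga_sd: float = 2.1
    ga_range: tuple[float, float] = (24.3, 32.0)
    pma_t1_mean: float = 32.4
    pma_t1_sd: float = 0.7
    pma_t1_range: tuple[float, float] = (30.4, 33.6)
    pma_t2_mean: float = 36.7
    pma_t2_sd: float = 0.9
    pma_t2_range: tuple[float, float] = (35.3, 39.1)

    protein_mean: float = 2.54
    protein_sd: float = 0.36
    lipid_mean: float = 2.03
    lipid_sd: float = 0.42
    carb_mean: float = 10.31
    carb_sd: float = 0.72
    daily_noise_frac: float = 0.05     # day-to-day wobble, fraction of the mean

    # nutrition effect on the maturation clock, sized so the programmed
    # protein effect is reliably detectable in a 28-infant serial design
    beta_protein: float = 1.0          # weeks of maturation per g/kg/day
    beta_lipid: float = 0.6
    delta_sd: float = 0.4              # unexplained maturational spread, weeks
    outcome_quantile: float = 12 / 28  # fraction labelled mild_moderate
    label_flip_prob: float = 0.1

    # --- EEG synthesis ---
    fs: float = 256.0
    duration_s: float = 2400.0         # 40 min
    qs_onset_s: float = 600.0
    qs_duration_s: float = 720.0       # 12 min annotated quiet sleep
    spectral_exponent: float = 1.5     # burst noise ~ 1/f^alpha above 0.5 Hz
    alpha_age_slope: float = -0.06     # spectral exponent change per week
    burst_rms: float = 45.0            # uV at 32 w effective age
    burst_rms_age_slope: float = -0.06  # fractional change per week
    suppression_rms: float = 3.0       # uV
    as_rms: float = 25.0               # continuous active-sleep filler, uV
    ref_rms: float = 0.5               # token noise on the reference channel

    sup_median_32: float = 6.0         # suppression duration median at 32 w, s
    sup_log_slope: float = -0.18       # d log(median) / d week
    burst_median_32: float = 3.0
    burst_log_slope: float = 0.10
    duration_log_sd: float = 0.3       # lognormal spread; 0 = deterministic
    min_event_s: float = 1.0
    # anterior channels (Fp1, Fp2, C3, C4) start each burst late, so
    # fronto-central derivations carry longer interburst intervals
    frontal_burst_delay_s: float = 0.5

    rho_32: float = 0.30               # homologous coupling at 32 w
    rho_age_slope: float = 0.06        # per week
    rho_max: float = 0.90
    mod_sigma: float = 0.5             # log-amplitude modulation depth
    mod_rate: float = 4.0              # driver sample rate before interpolation, Hz

    ema_measurement_sd: float = 0.3    # metric noise in the feature-level table

    def __post_init__(self) -> None:
        if self.n_infants < 1:
            raise ValueError("need at least one infant")
        for name in ("ga_sd", "pma_t1_sd", "pma_t2_sd", "protein_sd",
                     "lipid_sd", "carb_sd", "delta_sd", "duration_log_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.pma_t2_mean <= self.pma_t1_mean:
            raise ValueError("T2 target must exceed T1 target")
        if self.qs_onset_s + self.qs_duration_s > self.duration_s:
            raise ValueError("quiet-sleep block exceeds the recording")

    def alpha_at(self, age_weeks: float) -> float:
        return max(0.5, self.spectral_exponent + self.alpha_age_slope * (age_weeks - 32.0))

    def rho_at(self, age_weeks: float) -> float:
        return float(np.clip(
            self.rho_32 + self.rho_age_slope * (age_weeks - 32.0), 0.0, self.rho_max
        ))

    def burst_rms_at(self, age_weeks: float) -> float:
        return self.burst_rms * max(
            0.1, 1.0 + self.burst_rms_age_slope * (age_weeks - 32.0)
        )


def _rng(cfg: SimulationConfig, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((cfg.seed, *key)))


def _truncnorm(rng, mean, sd, lo, hi, size=None):
    """Normal draw re-sampled into [lo, hi] (simple rejection)."""
    x = rng.normal(mean, sd, size=size)
    bad = (x < lo) | (x > hi)
    while np.any(bad):
        x = np.where(bad, rng.normal(mean, sd, size=size), x)
        bad = (x < lo) | (x > hi)
    return x


# --- cohort-level simulation ------------------------------------------------

def simulate_cohort(
    cfg: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Draw demographics, nutrition and maturation shifts for the cohort.

    Returns ``(cohort, nutrition_daily, ground_truth)``: the cohort table
    (infant_id, ga_weeks, outcome, pma_t1, pma_t2), seven daily nutrition
    rows per infant, and the ground-truth dictionary holding each infant's
    ``delta`` and effective ages.
    """
    rows, nut_rows = [], []
    truth: dict = {"config": asdict(cfg), "infants": {}}
    for i in range(cfg.n_infants):
        rng = _rng(cfg, i, 0)
        iid = f"sim{i + 1:03d}"
        ga = float(_truncnorm(rng, cfg.ga_mean, cfg.ga_sd, *cfg.ga_range))
        pma_t1 = float(_truncnorm(rng, cfg.pma_t1_mean, cfg.pma_t1_sd, *cfg.pma_t1_range))
        pma_t2 = float(_truncnorm(rng, cfg.pma_t2_mean, cfg.pma_t2_sd, *cfg.pma_t2_range))
        protein = max(0.0, rng.normal(cfg.protein_mean, cfg.protein_sd))
        lipid = max(0.0, rng.normal(cfg.lipid_mean, cfg.lipid_sd))
        carb = max(0.0, rng.normal(cfg.carb_mean, cfg.carb_sd))
        delta = (
            cfg.beta_protein * (protein - cfg.protein_mean)
            + cfg.beta_lipid * (lipid - cfg.lipid_mean)
            + rng.normal(0.0, cfg.delta_sd)
        )
        for dol in range(1, 8):
            nut_rows.append({
                "infant_id": iid,
                "dol": dol,
                "proteins": max(0.0, protein * (1 + cfg.daily_noise_frac * rng.normal())),
                "lipids": max(0.0, lipid * (1 + cfg.daily_noise_frac * rng.normal())),
                "carbohydrates": max(0.0, carb * (1 + cfg.daily_noise_frac * rng.normal())),
            })
        rows.append({
            "infant_id": iid, "ga_weeks": ga,
            "pma_t1": pma_t1, "pma_t2": pma_t2,
        })
        truth["infants"][iid] = {
            "index": i, "ga_weeks": ga, "pma_t1": pma_t1, "pma_t2": pma_t2,
            "proteins": protein, "lipids": lipid, "carbohydrates": carb,
            "delta": float(delta),
            "effective_age_t1": pma_t1 + float(delta),
            "effective_age_t2": pma_t2 + float(delta),
        }

    # outcome: infants in the lower delta quantile get the adverse label
    deltas = np.array([truth["infants"][r["infant_id"]]["delta"] for r in rows])
    thresh = np.quantile(deltas, cfg.outcome_quantile)
    label_rng = _rng(cfg, 10**6)
    for r, d in zip(rows, deltas):
        label = "mild_moderate" if d <= thresh else "normal"
        if label_rng.random() < cfg.label_flip_prob:
            label = "normal" if label == "mild_moderate" else "mild_moderate"
        r["outcome"] = label
        truth["infants"][r["infant_id"]]["outcome"] = label

    cohort = pd.DataFrame(rows)[["infant_id", "ga_weeks", "outcome", "pma_t1", "pma_t2"]]
    return cohort, pd.DataFrame(nut_rows), truth


# --- EEG synthesis ----------------------------------------------------------

def colored_noise(
    n: int, alpha: float, fs: float, rng: np.random.Generator, f_min: float = 0.5
) -> np.ndarray:
    """Unit-variance 1/f^alpha noise, spectrally flat below ``f_min`` Hz."""
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    amp = np.ones_like(freqs)
    above = freqs > f_min
    amp[above] = (freqs[above] / f_min) ** (-alpha / 2.0)
    amp[0] = 0.0
    spec = amp * (rng.normal(size=freqs.size) + 1j * rng.normal(size=freqs.size))
    x = np.fft.irfft(spec, n=n)
    return x / x.std()


def _draw_events(
    cfg: SimulationConfig, eff_age: float, duration: float, rng
) -> list[dict]:
    """Alternating burst/suppression events (lognormal durations) filling
    ``duration`` seconds, starting and ending with a burst."""
    sup_med = cfg.sup_median_32 * np.exp(cfg.sup_log_slope * (eff_age - 32.0))
    bur_med = cfg.burst_median_32 * np.exp(cfg.burst_log_slope * (eff_age - 32.0))
    events, t, kind = [], 0.0, "burst"
    while t < duration:
        med = bur_med if kind == "burst" else sup_med
        d = float(med * np.exp(cfg.duration_log_sd * rng.normal()))
        d = max(cfg.min_event_s, min(d, duration - t))
        events.append({"kind": kind, "onset": t, "duration": d})
        t += d
        kind = "suppression" if kind == "burst" else "burst"
    if events and events[-1]["kind"] == "suppression":
        events[-1]["kind"] = "burst"        # never end mid-suppression
    return events


def events_to_mask(events: list[dict], frame_s: float, duration: float) -> np.ndarray:
    """Frame-rate boolean burst mask (True = burst) from an event list."""
    n = int(round(duration / frame_s))
    mask = np.ones(n, dtype=bool)
    for ev in events:
        if ev["kind"] != "suppression":
            continue
        i0 = int(round(ev["onset"] / frame_s))
        i1 = int(round((ev["onset"] + ev["duration"]) / frame_s))
        mask[i0:min(i1, n)] = False
    return mask


def _smooth_driver(n_out: int, fs: float, cfg: SimulationConfig, rng) -> np.ndarray:
    """Slow unit-variance modulation signal, generated at ``mod_rate`` and
    linearly interpolated to the sampling rate."""
    n_slow = max(8, int(np.ceil(n_out / fs * cfg.mod_rate)) + 2)
    w = rng.normal(size=n_slow)
    kernel = np.hanning(9)
    w = np.convolve(w, kernel / kernel.sum(), mode="same")
    w = (w - w.mean()) / max(w.std(), 1e-12)
    t_slow = np.arange(n_slow) / cfg.mod_rate
    t_out = np.arange(n_out) / fs
    return np.interp(t_out, t_slow, w)


def simulate_eeg(
    infant: dict,
    session: str,
    cfg: SimulationConfig,
) -> tuple[Recording, list[SleepAnnotation], dict]:
    """Synthesize one 9-channel recording plus annotations and ground truth.

    Quiet sleep carries the burst-suppression regime; the surrounding time
    is continuous lower-amplitude activity annotated as active sleep.
    Frontal channels start each burst ``frontal_burst_delay_s`` late,
    making fronto-central interburst intervals longer than centro-occipital
    ones.  Returns ``(recording, annotations, truth)`` where ``truth``
    logs per-channel suppression events, rho and the effective age.
    """
    s_idx = {"T1": 1, "T2": 2}[session]
    i = infant["index"]
    eff_age = infant[f"effective_age_t{s_idx}"]
    pma = infant[f"pma_t{s_idx}"]
    rng = _rng(cfg, i, s_idx)

    fs = cfg.fs
    n = int(round(cfg.duration_s * fs))
    qs0, qs1 = cfg.qs_onset_s, cfg.qs_onset_s + cfg.qs_duration_s
    events = _draw_events(cfg, eff_age, cfg.qs_duration_s, rng)
    rho = cfg.rho_at(eff_age)
    burst_rms = cfg.burst_rms_at(eff_age)

    pair_of = {}
    for a, b in HOMOLOGOUS_PAIRS:
        pair_of[a] = pair_of[b] = (a, b)
    pair_driver = {
        pair: _smooth_driver(n, fs, cfg, _rng(cfg, i, s_idx, 100 + k))
        for k, pair in enumerate(HOMOLOGOUS_PAIRS)
    }

    t = np.arange(n) / fs
    in_qs = (t >= qs0) & (t < qs1)
    channel_events: dict[str, list[dict]] = {}
    data = np.empty((9, n))
    taper = np.hanning(int(0.25 * fs))
    taper = taper / taper.sum()

    for ci, ch in enumerate(ANALYSIS_CHANNELS):
        ch_rng = _rng(cfg, i, s_idx, 200 + ci)
        base = colored_noise(n, cfg.alpha_at(eff_age), fs, ch_rng)
        delay = (
            cfg.frontal_burst_delay_s if ch in ("Fp1", "Fp2", "C3", "C4") else 0.0
        )
        ch_events = []
        for ev in events:
            onset, dur = ev["onset"], ev["duration"]
            if ev["kind"] == "burst" and delay > 0:
                onset = min(onset + delay, onset + dur)
                dur = dur - (onset - ev["onset"])
            elif ev["kind"] == "suppression" and delay > 0:
                dur = min(dur + delay, cfg.qs_duration_s - onset)
            ch_events.append({"kind": ev["kind"], "onset": onset + qs0, "duration": dur})
        # per-sample rms target
        gain = np.full(n, cfg.as_rms)
        gain[in_qs] = cfg.suppression_rms
        for ev in ch_events:
            if ev["kind"] == "burst":
                i0 = int(round(ev["onset"] * fs))
                i1 = int(round((ev["onset"] + ev["duration"]) * fs))
                gain[i0:i1] = burst_rms
        # homologous amplitude modulation during bursts
        w_pair = pair_driver[pair_of[ch]]
        w_own = _smooth_driver(n, fs, cfg, _rng(cfg, i, s_idx, 300 + ci))
        mod = np.exp(
            cfg.mod_sigma * (rho * w_pair + np.sqrt(1 - rho**2) * w_own)
            - cfg.mod_sigma**2 / 2.0
        )
        burst_zone = in_qs & (gain == burst_rms)
        gain[burst_zone] *= mod[burst_zone]
        gain = np.convolve(gain, taper, mode="same")
        data[ci] = base * gain
        channel_events[ch] = [
            {k: round(v, 4) if isinstance(v, float) else v for k, v in ev.items()}
            for ev in ch_events
            if ev["kind"] == "suppression"
        ]

    data[8] = cfg.ref_rms * _rng(cfg, i, s_idx, 999).normal(size=n)
    rec = Recording(
        infant_id=infant.get("infant_id", f"sim{i + 1:03d}"),
        session=session,
        pma_weeks=pma,
        fs=fs,
        channels=list(ANALYSIS_CHANNELS) + ["Ref"],
        data=data,
    )
    annotations = [
        SleepAnnotation(0.0, qs0, "AS"),
        SleepAnnotation(qs0, cfg.qs_duration_s, "QS"),
    ]
    if cfg.duration_s > qs1:
        annotations.append(SleepAnnotation(qs1, cfg.duration_s - qs1, "AS"))
    truth = {
        "effective_age": eff_age,
        "pma": pma,
        "rho": rho,
        "burst_rms": burst_rms,
        "qs_interval": [qs0, qs1],
        "global_suppressions": [
            {"kind": "suppression", "onset": ev["onset"] + qs0, "duration": ev["duration"]}
            for ev in events if ev["kind"] == "suppression"
        ],
        "channel_suppressions": channel_events,
    }
    return rec, annotations, truth


# --- lightweight generators for calibration studies -------------------------

def simulate_coupled_envelopes(
    rho: float,
    duration_s: float,
    rate: float = 4.0,
    sigma: float = 0.5,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Two stationary lognormal envelopes sharing a common driver of weight rho.

    ``rho = 0`` gives independent envelopes (the surrogate-null reference);
    increasing rho increases their zero-lag dependence.  Used for ASI
    calibration without synthesizing full EEG.
    """
    if not 0 <= rho <= 1:
        raise ValueError("rho must lie in [0, 1]")
    rng = np.random.default_rng() if rng is None else rng
    n = int(round(duration_s * rate))

    def smooth(z):
        kernel = np.hanning(9)
        z = np.convolve(z, kernel / kernel.sum(), mode="same")
        return (z - z.mean()) / max(z.std(), 1e-12)

    w_c = smooth(rng.normal(size=n))
    x = np.exp(sigma * (rho * w_c + np.sqrt(1 - rho**2) * smooth(rng.normal(size=n))))
    y = np.exp(sigma * (rho * w_c + np.sqrt(1 - rho**2) * smooth(rng.normal(size=n))))
    return x, y


def simulate_feature_table(
    cfg: SimulationConfig, measurement_sd: float | None = None
) -> pd.DataFrame:
    """Cohort-level table of a maturation readout without EEG synthesis.

    Draws the cohort (nutrition, ``delta_i``) and emits one row per
    recording with the maturation readout ``ema_gap = delta_i + noise``
    (the quantity the full pipeline estimates from EEG) plus nutrition
    summaries — the input the inference stage expects.  Used for
    statistical calibration at scale, where synthesizing EEG for hundreds
    of replicate cohorts would add nothing but runtime.
    """
    sd = cfg.ema_measurement_sd if measurement_sd is None else measurement_sd
    cohort, nutrition, truth = simulate_cohort(cfg)
    noise_rng = _rng(cfg, 2 * 10**6)
    nut_means = nutrition.groupby("infant_id")[
        ["proteins", "lipids", "carbohydrates"]
    ].mean()
    rows = []
    for _, r in cohort.iterrows():
        info = truth["infants"][r["infant_id"]]
        nm = nut_means.loc[r["infant_id"]]
        for session in ("T1", "T2"):
            pma = info[f"pma_{session.lower()}"]
            rows.append({
                "infant_id": r["infant_id"],
                "session": session,
                "pma_weeks": pma,
                "outcome": r["outcome"],
                "proteins": nm["proteins"],
                "lipids": nm["lipids"],
                "carbohydrates": nm["carbohydrates"],
                "energy": 4.0 * (nm["proteins"] + nm["carbohydrates"]) + 9.0 * nm["lipids"],
                "ema_gap": info["delta"] + noise_rng.normal(0.0, sd),
            })
    return pd.DataFrame(rows)


# --- dataset writer ---------------------------------------------------------

def write_dataset(cfg: SimulationConfig, outdir: str | Path) -> dict[str, Path]:
    """Generate and write a full dataset: EDFs, annotation CSVs, cohort and
    nutrition tables, and ground_truth.json.  Deterministic in ``cfg.seed``."""
    outdir = Path(outdir)
    (outdir / "edf").mkdir(parents=True, exist_ok=True)
    cohort, nutrition, truth = simulate_cohort(cfg)
    for iid, info in truth["infants"].items():
        info["recordings"] = {}
        for session in ("T1", "T2"):
            rec, ann, rec_truth = simulate_eeg({**info, "infant_id": iid}, session, cfg)
            write_edf(outdir / "edf" / f"{iid}_{session}.edf", rec)
            write_annotations(outdir / "edf" / f"{iid}_{session}_annotations.csv", ann)
            info["recordings"][session] = rec_truth
    cohort_path = outdir / "cohort.csv"
    nutrition_path = outdir / "nutrition_daily.csv"
    truth_path = outdir / "ground_truth.json"
    cohort.to_csv(cohort_path, index=False, float_format="%.6f")
    nutrition.to_csv(nutrition_path, index=False, float_format="%.6f")
    with open(truth_path, "w") as fh:
        json.dump(truth, fh, indent=1)
    return {"cohort": cohort_path, "nutrition": nutrition_path,
            "ground_truth": truth_path, "edf_dir": outdir / "edf"}
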