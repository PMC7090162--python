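"""Welch band powers of quiet-sleep EEG.

Power spectral densities are estimated per referential channel with Welch's
method (2-s epochs, 50% overlap, Hamming taper), integrated over the
neonatal band scheme (Delta1 0.5-1 Hz, Delta2 1-4 Hz, Theta 4-8 Hz,
Alpha 8-13 Hz, Beta 13-30 Hz), and expressed both absolutely (uV^2) and
relative to the 0.5-30 Hz total.  Regional summaries average channels over
frontal, central, occipital and centrotemporal groups.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import welch

from .eeg_io import ANALYSIS_CHANNELS, Recording, SegmentSet

__all__ = [
    "BANDS",
    "TOTAL_BAND",
    "REGIONS",
    "PSD",
    "welch_psd",
    "pooled_psd",
    "band_powers",
    "band_power_table",
    "regional_band_powers",
]

#: Neonatal band scheme, half-open [low, high) Hz; contiguous partition of total.
BANDS: dict[str, tuple[float, float]] = {
    "Delta1": (0.5, 1.0),
    "Delta2": (1.0, 4.0),
    "Theta": (4.0, 8.0),
    "Alpha": (8.0, 13.0),
    "Beta": (13.0, 30.0),
}

TOTAL_BAND: tuple[float, float] = (0.5, 30.0)

#: Channel groups for regional averages.
REGIONS: dict[str, tuple[str, ...]] = {
    "frontal": ("Fp1", "Fp2"),
    "central": ("C3", "C4"),
    "occipital": ("O1", "O2"),
    "centrotemporal_right": ("C4", "T4"),
    "centrotemporal_left": ("C3", "T3"),
    "total": ANALYSIS_CHANNELS,
}


@dataclass
class PSD:
    """One-sided power spectral density, uV^2/Hz on a uniform grid."""

    freqs: np.ndarray
    density: np.ndarray     # (..., n_freqs), uV^2/Hz

    def __post_init__(self) -> None:
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("frequency grid must be strictly increasing")
        if np.any(self.density < 0):
            raise ValueError("spectral density must be non-negative")


def welch_psd(
    x: np.ndarray,
    fs: float,
    win: float = 2.0,
    overlap: float = 0.5,
    window: str = "hamming",
) -> PSD:
    """Welch PSD of one signal (or a channel stack along the first axis).

    Uses constant detrending per window.  The one-sided density integrates
    to the signal variance (Parseval, within taper bias).
    """
    x = np.asarray(x, dtype=float)
    nperseg = int(round(win * fs))
    if x.shape[-1] < nperseg:
        raise ValueError(
            f"segment of {x.shape[-1]} samples shorter than one {win}-s window"
        )
    freqs, density = welch(
        x,
        fs=fs,
        window=window,
        nperseg=nperseg,
        noverlap=int(round(nperseg * overlap)),
        detrend="constant",
        axis=-1,
    )
    return PSD(freqs=freqs, density=density)


def pooled_psd(segments: SegmentSet, **welch_kwargs) -> PSD:
    """Duration-weighted mean PSD over the segments of one recording.

    Weighting each segment's Welch estimate by its duration is equivalent
    (up to edge windows) to running Welch over all windows pooled, so the
    result is invariant to how a contiguous stretch was split.
    """
    if len(segments) == 0:
        raise ValueError("no segments to pool")
    num = None
    total = 0.0
    freqs = None
    for seg in segments:
        p = welch_psd(seg.data, segments.fs, **welch_kwargs)
        if freqs is None:
            freqs = p.freqs
            num = p.density * seg.duration
        else:
            num = num + p.density * seg.duration
        total += seg.duration
    return PSD(freqs=freqs, density=num / total)


def _band_integral(psd: PSD, low: float, high: float) -> np.ndarray:
    """Trapezoidal integral of the density over [low, high] on the grid.

    Band edges sit on the Welch grid (0.5 Hz spacing at 2-s windows);
    sharing edge points between adjacent bands makes the band integrals
    telescope exactly to the total-band integral.
    """
    mask = (psd.freqs >= low - 1e-9) & (psd.freqs <= high + 1e-9)
    if mask.sum() < 2:
        raise ValueError(f"PSD grid does not cover band [{low}, {high}] Hz")
    return np.trapezoid(psd.density[..., mask], psd.freqs[mask], axis=-1)


def band_powers(
    psd: PSD, bands: dict[str, tuple[float, float]] | None = None
) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray]]:
    """Absolute (uV^2) and relative (%) band powers from a PSD.

    Relative power divides each band by the total-band (0.5-30 Hz) power,
    so the five bands sum to 100% per channel.  A zero total yields NaN
    relative powers.
    """
    bands = BANDS if bands is None else bands
    abs_p = {name: _band_integral(psd, lo, hi) for name, (lo, hi) in bands.items()}
    total = _band_integral(psd, *TOTAL_BAND)
    with np.errstate(divide="ignore", invalid="ignore"):
        rel_p = {
            name: np.where(total > 0, 100.0 * p / total, np.nan)
            for name, p in abs_p.items()
        }
    abs_p["total"] = total
    return abs_p, rel_p


def band_power_table(rec: Recording, segments: SegmentSet, **welch_kwargs) -> pd.DataFrame:
    """Per-channel band powers of one recording's quiet-sleep data.

    Returns a tidy frame with columns ``channel, band, abs_uV2, rel_pct``
    over the eight analysis channels.
    """
    chan_segments = SegmentSet(
        [
            type(seg)(
                data=np.stack(
                    [seg.data[segments.channels.index(c)] for c in ANALYSIS_CHANNELS]
                ),
                onset=seg.onset,
                duration=seg.duration,
            )
            for seg in segments
        ],
        state=segments.state,
        fs=segments.fs,
        channels=list(ANALYSIS_CHANNELS),
    )
    psd = pooled_psd(chan_segments, **welch_kwargs)
    abs_p, rel_p = band_powers(psd)
    rows = []
    for i, ch in enumerate(ANALYSIS_CHANNELS):
        for band in BANDS:
            rows.append(
                {
                    "channel": ch,
                    "band": band,
                    "abs_uV2": float(abs_p[band][i]),
                    "rel_pct": float(rel_p[band][i]),
                }
            )
        rows.append(
            {
                "channel": ch,
                "band": "total",
                "abs_uV2": float(abs_p["total"][i]),
                "rel_pct": 100.0,
            }
        )
    return pd.DataFrame(rows)


def regional_band_powers(per_channel: pd.DataFrame) -> pd.DataFrame:
    """Regional arithmetic means of per-channel band powers.

    A region's value is the mean of its member channels, separately for
    absolute and relative power; if any member is missing (NaN) the region
    is NaN.
    """
    rows = []
    for region, members in REGIONS.items():
        sub = per_channel[per_channel["channel"].isin(members)]
        for band, grp in sub.groupby("band", sort=False):
            missing = grp["abs_uV2"].isna().any() or len(grp) < len(members)
            rows.append(
                {
                    "region": region,
                    "band": band,
                    "abs_uV2": np.nan if missing else float(grp["abs_uV2"].mean()),
                    "rel_pct": np.nan if missing else float(grp["rel_pct"].mean()),
                }
            )
    return pd.DataFrame(rows)
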