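"""Burst/suppression detection and discontinuity metrics.

Preterm quiet-sleep EEG alternates high-amplitude bursts with low-amplitude
suppression (trace discontinu).  Bursts are detected per channel from a
smoothed line-length feature; a cross-channel consensus mask yields the
global discontinuity summaries:

* MSC — mean suppression curve: the time-averaged fraction of channels in
  suppression, in [0, 1];
* IBI95 — the empirical 95th percentile of interburst-interval durations;
* mean IBI on centro-occipital (C3-O1, C4-O2) and fronto-central
  (Fp1-C3, Fp2-C4) bipolar derivations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import median_filter

from .eeg_io import Derivation

__all__ = [
    "DetectionParams",
    "BurstMask",
    "ContinuityResult",
    "line_length_feature",
    "detect_bursts",
    "suppression_curve",
    "interburst_intervals",
    "derivation_ibi",
    "runs_of",
    "DERIVATION_GROUPS",
]

#: Derivation groups for the regional mean-IBI summaries.
DERIVATION_GROUPS: dict[str, tuple[str, ...]] = {
    "CO": ("C3-O1", "C4-O2"),
    "FC": ("Fp1-C3", "Fp2-C4"),
}


@dataclass
class DetectionParams:
    """Tunables of the line-length burst detector.

    The feature is the mean absolute first difference (uV per sample) in
    ``frame_s`` windows at ``hop_s`` hop, median-smoothed over
    ``smooth_frames``.  A frame is a burst when the feature exceeds an
    adaptive threshold: ``theta_rel`` times the segment median feature,
    clipped into ``[theta_floor, theta_ceil]``.  The clip keeps fully
    continuous EEG (median at burst level) from being called suppressed and
    fully suppressed EEG from being called burst.  Runs shorter than the
    minimum burst/suppression durations are merged into their neighbours.
    """

    frame_s: float = 1.0
    hop_s: float = 0.5
    smooth_frames: int = 3
    theta_rel: float = 1.5
    theta_floor: float = 3.5      # uV/sample-diff; midway between suppression
    theta_ceil: float = 6.5       # and burst feature levels of neonatal EEG
    min_burst_s: float = 1.0
    min_suppression_s: float = 2.0
    consensus_fraction: float = 0.5   # suppressed consensus iff > this fraction


@dataclass
class BurstMask:
    """Frame-rate burst masks: True = burst, one row per channel."""

    masks: np.ndarray            # (n_channels, n_frames) bool
    consensus: np.ndarray        # (n_frames,) bool, True = burst
    frame_s: float               # seconds per frame (the hop)

    @property
    def n_frames(self) -> int:
        return self.masks.shape[1]


@dataclass
class ContinuityResult:
    msc: float
    ibi95: float                          # s; NaN if no complete IBI
    ibi_list: list[float] = field(default_factory=list)
    ibi_mean_CO: float = float("nan")
    ibi_mean_FC: float = float("nan")


def runs_of(mask: np.ndarray, value: bool) -> list[tuple[int, int]]:
    """Maximal runs of ``value`` in a boolean vector, as [start, stop) pairs."""
    mask = np.asarray(mask, dtype=bool)
    if mask.size == 0:
        return []
    ids = np.flatnonzero(np.diff(mask.astype(np.int8))) + 1
    bounds = np.concatenate(([0], ids, [mask.size]))
    return [
        (int(bounds[i]), int(bounds[i + 1]))
        for i in range(len(bounds) - 1)
        if mask[bounds[i]] == value
    ]


def line_length_feature(x: np.ndarray, fs: float, params: DetectionParams) -> np.ndarray:
    """Mean absolute first difference per frame (frame ``frame_s``, hop ``hop_s``)."""
    x = np.asarray(x, dtype=float)
    frame = int(round(params.frame_s * fs))
    hop = int(round(params.hop_s * fs))
    n = x.shape[-1]
    if n < frame:
        raise ValueError("signal shorter than one analysis frame")
    diffs = np.abs(np.diff(x, axis=-1))
    # cumulative-sum trick: frame sums at hop spacing
    cs = np.concatenate(
        [np.zeros(x.shape[:-1] + (1,)), np.cumsum(diffs, axis=-1)], axis=-1
    )
    starts = np.arange(0, n - frame + 1, hop)
    return (cs[..., starts + frame - 1] - cs[..., starts]) / (frame - 1)


def _enforce_min_durations(mask: np.ndarray, params: DetectionParams) -> np.ndarray:
    """Absorb too-short runs into their neighbours (suppressions first)."""
    mask = mask.copy()
    min_sup = int(round(params.min_suppression_s / params.hop_s))
    min_burst = int(round(params.min_burst_s / params.hop_s))
    changed = True
    while changed:
        changed = False
        for value, min_len in ((False, min_sup), (True, min_burst)):
            for start, stop in runs_of(mask, value):
                if stop - start < min_len and not (start == 0 and stop == mask.size):
                    mask[start:stop] = not value
                    changed = True
    return mask


def detect_bursts(
    data: np.ndarray, fs: float, params: DetectionParams | None = None
) -> BurstMask:
    """Detect bursts per channel and form the cross-channel consensus.

    ``data`` is ``(n_channels, n_samples)`` in uV (a single channel may be
    passed as a 1-D array).  A consensus frame is suppressed when more than
    ``consensus_fraction`` of channels are suppressed there.
    """
    params = params or DetectionParams()
    data = np.atleast_2d(np.asarray(data, dtype=float))
    feat = line_length_feature(data, fs, params)
    if params.smooth_frames > 1:
        feat = median_filter(feat, size=(1, params.smooth_frames), mode="nearest")
    masks = np.empty(feat.shape, dtype=bool)
    for i in range(feat.shape[0]):
        med = float(np.median(feat[i]))
        if med <= 0:
            warnings.warn("flat channel: treated as fully suppressed", stacklevel=2)
            masks[i] = False
            continue
        thr = float(np.clip(params.theta_rel * med, params.theta_floor, params.theta_ceil))
        masks[i] = _enforce_min_durations(feat[i] > thr, params)
    suppressed_frac = 1.0 - masks.mean(axis=0)
    consensus = _enforce_min_durations(
        ~(suppressed_frac > params.consensus_fraction), params
    )
    return BurstMask(masks=masks, consensus=consensus, frame_s=params.hop_s)


def suppression_curve(mask: BurstMask) -> tuple[np.ndarray, float]:
    """Fraction of channels suppressed per frame, and its time average (MSC)."""
    if mask.n_frames == 0:
        raise ValueError("empty burst mask")
    curve = 1.0 - mask.masks.mean(axis=0)
    return curve, float(curve.mean())


def interburst_intervals(
    consensus: np.ndarray, frame_s: float
) -> tuple[list[float], float]:
    """IBI durations from a consensus burst mask, and their 95th percentile.

    IBIs are maximal suppression runs; runs touching either end of the
    segment are discarded as truncated.  The percentile interpolates
    linearly between order statistics (p(k) = (k-1)/(n-1)); with no
    complete IBI the percentile is NaN.
    """
    consensus = np.asarray(consensus, dtype=bool)
    n = consensus.size
    ibis = [
        (stop - start) * frame_s
        for start, stop in runs_of(consensus, False)
        if start > 0 and stop < n
    ]
    if not ibis:
        return [], float("nan")
    return ibis, float(np.percentile(ibis, 95, method="linear"))


def derivation_ibi(
    derivs: list[Derivation],
    fs: float,
    params: DetectionParams | None = None,
    groups: dict[str, tuple[str, ...]] | None = None,
) -> dict[str, float]:
    """Mean IBI per derivation group (burst detection run per derivation).

    Each group's value is the mean over its derivations of that
    derivation's mean IBI; derivations with no complete IBI are dropped
    from the group mean, and a group with no usable derivation is NaN.
    """
    groups = DERIVATION_GROUPS if groups is None else groups
    by_label = {d.label: d for d in derivs}
    out: dict[str, float] = {}
    for group, labels in groups.items():
        per_deriv = []
        for label in labels:
            if label not in by_label:
                per_deriv = []
                break
            bm = detect_bursts(by_label[label].signal, fs, params)
            ibis, _ = interburst_intervals(bm.masks[0], bm.frame_s)
            if ibis:
                per_deriv.append(float(np.mean(ibis)))
        out[f"ibi_mean_{group}"] = float(np.mean(per_deriv)) if per_deriv else float("nan")
    return out
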