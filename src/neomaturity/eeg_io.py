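"""Reading, writing and conditioning of neonatal multichannel EEG.

Recordings follow the restricted neonatal 10-20 montage used for preterm
monitoring: eight referential scalp channels (Fp1, Fp2, C3, C4, O1, O2,
T3, T4) plus a reference, sampled at 256 Hz and stored as EDF.  Sleep-state
annotations arrive as CSV (``onset_s,duration_s,state``), replacing visual
sleep staging.  This module also applies the acquisition band-pass
(0.3-70 Hz) and derives the standard neonatal bipolar montage.
"""

from __future__ import annotations

import csv
import datetime as _dt
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.signal import butter, sosfiltfilt

__all__ = [
    "ANALYSIS_CHANNELS",
    "BIPOLAR_PAIRS",
    "Recording",
    "Derivation",
    "SleepAnnotation",
    "Segment",
    "SegmentSet",
    "normalize_label",
    "read_edf",
    "write_edf",
    "read_annotations",
    "write_annotations",
    "preprocess",
    "make_bipolar",
    "extract_state_segments",
]

#: Referential channels entering every analysis, in canonical order.
ANALYSIS_CHANNELS: tuple[str, ...] = (
    "Fp1", "Fp2", "C3", "C4", "O1", "O2", "T3", "T4",
)

#: Standard neonatal bipolar montage (anode, cathode), in conventional order.
BIPOLAR_PAIRS: tuple[tuple[str, str], ...] = (
    ("Fp1", "C3"), ("C3", "O1"), ("Fp1", "T3"), ("T3", "O1"),
    ("Fp2", "C4"), ("C4", "O2"), ("Fp2", "T4"), ("T4", "O2"),
)

SLEEP_STATES = ("QS", "AS", "wake", "indeterminate")


class ChannelMissingError(KeyError):
    """A required electrode label is absent from the recording."""


@dataclass
class Recording:
    """A referential multichannel EEG recording.

    ``data`` is a ``(n_channels, n_samples)`` float array in microvolts;
    ``channels`` gives the label of each row.
    """

    infant_id: str
    session: str                # "T1" or "T2"
    pma_weeks: float
    fs: float
    channels: list[str]
    data: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.data.ndim != 2 or self.data.shape[0] != len(self.channels):
            raise ValueError("data must be (n_channels, n_samples)")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("EEG data contains non-finite samples")

    @property
    def duration_s(self) -> float:
        return self.data.shape[1] / self.fs

    def channel(self, label: str) -> np.ndarray:
        """Return the samples of one channel; raises if the label is absent."""
        try:
            return self.data[self.channels.index(label)]
        except ValueError:
            raise ChannelMissingError(
                f"channel {label!r} not present (have {self.channels})"
            ) from None

    def analysis_matrix(self) -> np.ndarray:
        """Data of the eight analysis channels in canonical order."""
        return np.stack([self.channel(c) for c in ANALYSIS_CHANNELS])


@dataclass
class Derivation:
    """A bipolar derivation: anode minus cathode, samplewise, in uV."""

    anode: str
    cathode: str
    signal: np.ndarray

    @property
    def label(self) -> str:
        return f"{self.anode}-{self.cathode}"


@dataclass
class SleepAnnotation:
    """One sleep-state interval, half-open [onset, onset + duration) seconds."""

    onset: float
    duration: float
    state: str

    def __post_init__(self) -> None:
        if self.onset < 0:
            raise ValueError("annotation onset must be >= 0")
        if self.duration <= 0:
            raise ValueError("annotation duration must be > 0")
        if self.state not in SLEEP_STATES:
            raise ValueError(f"unknown sleep state {self.state!r}")


@dataclass
class Segment:
    """A contiguous slice of a recording attributed to one sleep state."""

    data: np.ndarray            # (n_channels, n_samples), uV
    onset: float                # s from recording start
    duration: float             # s

    def __len__(self) -> int:
        return self.data.shape[1]


@dataclass
class SegmentSet:
    """Extracted same-state segments of one recording."""

    segments: list[Segment]
    state: str
    fs: float
    channels: list[str] = field(default_factory=list)

    @property
    def total_duration(self) -> float:
        return float(sum(s.duration for s in self.segments))

    def __iter__(self):
        return iter(self.segments)

    def __len__(self) -> int:
        return len(self.segments)


# --- channel label normalization -------------------------------------------

_CANONICAL = {c.lower(): c for c in ANALYSIS_CHANNELS}
_CANONICAL["ref"] = "Ref"

_REF_SUFFIX = re.compile(r"[-_ ](ref|a1|a2|avg|le|re)$", re.IGNORECASE)


def normalize_label(raw: str) -> str:
    """Map a stored channel label onto the canonical montage label.

    Strips an ``"EEG "`` prefix and reference suffixes such as ``-Ref`` or
    ``-A1``, case-insensitively.  Labels that do not match an analysis
    channel are returned stripped but otherwise untouched.
    """
    label = raw.strip()
    if label.lower().startswith("eeg "):
        label = label[4:].strip()
    label = _REF_SUFFIX.sub("", label).strip()
    return _CANONICAL.get(label.lower(), label)


# --- EDF I/O ----------------------------------------------------------------

def write_edf(path: str | Path, rec: Recording) -> Path:
    """Write a recording as 16-bit EDF with 1-second data records.

    Physical dimension is uV, with per-channel physical ranges spanning the
    data, so the quantization step is ``(max - min) / 65535``.  The signal
    is truncated to a whole number of records.
    """
    path = Path(path)
    fs = rec.fs
    spr = int(round(fs))            # samples per 1 s record
    if abs(spr - fs) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    n_records = rec.data.shape[1] // spr
    if n_records < 1:
        raise ValueError("recording shorter than one data record")
    data = rec.data[:, : n_records * spr]
    ns = len(rec.channels)

    phys_min, phys_max = [], []
    digital = np.empty_like(data, dtype="<i2")
    for i in range(ns):
        lo = float(np.min(data[i]))
        hi = float(np.max(data[i]))
        if hi - lo < 1e-6:          # flat channel: open a token range
            lo, hi = lo - 1.0, hi + 1.0
        phys_min.append(lo)
        phys_max.append(hi)
        scaled = (data[i] - lo) / (hi - lo) * 65535.0 - 32768.0
        digital[i] = np.round(scaled).astype("<i2")

    def pad(text: str, width: int) -> bytes:
        b = text.encode("ascii")[:width]
        return b + b" " * (width - len(b))

    start = _dt.datetime(2000, 1, 1, 0, 0, 0)
    header = b"".join([
        pad("0", 8),
        pad(f"X X X {rec.infant_id}", 80),
        pad(f"Startdate X X X X {rec.session}", 80),
        pad(start.strftime("%d.%m.%y"), 8),
        pad(start.strftime("%H.%M.%S"), 8),
        pad(str(256 + ns * 256), 8),
        pad("", 44),
        pad(str(n_records), 8),
        pad("1", 8),                # record duration, s
        pad(str(ns), 4),
    ])
    fields = [
        b"".join(pad(lbl, 16) for lbl in rec.channels),
        b"".join(pad("AgAgCl electrode", 80) for _ in range(ns)),
        b"".join(pad("uV", 8) for _ in range(ns)),
        b"".join(pad(f"{phys_min[i]:.2f}"[:8], 8) for i in range(ns)),
        b"".join(pad(f"{phys_max[i]:.2f}"[:8], 8) for i in range(ns)),
        b"".join(pad("-32768", 8) for _ in range(ns)),
        b"".join(pad("32767", 8) for _ in range(ns)),
        b"".join(pad("", 80) for _ in range(ns)),
        b"".join(pad(str(spr), 8) for _ in range(ns)),
        b"".join(pad("", 32) for _ in range(ns)),
    ]
    with open(path, "wb") as fh:
        fh.write(header)
        for f in fields:
            fh.write(f)
        # records are channel-blocked: all of ch0's samples, then ch1's, ...
        for r in range(n_records):
            block = digital[:, r * spr : (r + 1) * spr]
            fh.write(np.ascontiguousarray(block).tobytes())
    return path


def read_edf(
    path: str | Path,
    infant_id: str | None = None,
    session: str = "T1",
    pma_weeks: float = float("nan"),
) -> Recording:
    """Read an EDF file into a :class:`Recording` (signals in uV).

    Channel labels are normalized (``"EEG Fp1-Ref"`` maps to ``Fp1``); all
    eight analysis channels must be present.  Metadata not carried by EDF
    (PMA, session) can be supplied by the caller, typically from the cohort
    table.
    """
    import mne

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    labels = [normalize_label(ch) for ch in raw.ch_names]
    data_uv = raw.get_data() * 1e6          # mne loads Volts
    present = set(labels)
    for ch in ANALYSIS_CHANNELS:
        if ch not in present:
            raise ChannelMissingError(
                f"EDF file {path.name} lacks required channel {ch!r}"
            )
    if infant_id is None:
        infant_id = path.stem
    return Recording(
        infant_id=infant_id,
        session=session,
        pma_weeks=pma_weeks,
        fs=float(raw.info["sfreq"]),
        channels=labels,
        data=data_uv,
    )


# --- annotations ------------------------------------------------------------

def write_annotations(path: str | Path, annotations: list[SleepAnnotation]) -> Path:
    path = Path(path)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["onset_s", "duration_s", "state"])
        for a in annotations:
            w.writerow([f"{a.onset:.3f}", f"{a.duration:.3f}", a.state])
    return path


def read_annotations(path: str | Path) -> list[SleepAnnotation]:
    """Read a sleep-annotation CSV (``onset_s,duration_s,state``)."""
    out: list[SleepAnnotation] = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            out.append(
                SleepAnnotation(
                    onset=float(row["onset_s"]),
                    duration=float(row["duration_s"]),
                    state=row["state"].strip(),
                )
            )
    _check_non_overlapping(out)
    return out


def _check_non_overlapping(annotations: list[SleepAnnotation]) -> None:
    intervals = sorted((a.onset, a.onset + a.duration) for a in annotations)
    for (s0, e0), (s1, _) in zip(intervals, intervals[1:]):
        if s1 < e0 - 1e-9:
            raise ValueError("sleep annotations overlap")


# --- preprocessing ----------------------------------------------------------

def preprocess(rec: Recording, hp: float = 0.3, lp: float = 70.0) -> Recording:
    """Zero-phase 4th-order Butterworth band-pass, per channel.

    Mirrors the acquisition filters (0.3 Hz high-pass, 70 Hz low-pass);
    forward-backward application avoids group-delay distortion that would
    bias zero-lag synchrony estimates.
    """
    nyq = rec.fs / 2.0
    if not (0 < hp < lp):
        raise ValueError("need 0 < hp < lp")
    if lp >= nyq:
        raise ValueError(f"low-pass cutoff {lp} Hz must be below Nyquist {nyq} Hz")
    sos = butter(4, [hp, lp], btype="bandpass", fs=rec.fs, output="sos")
    filtered = sosfiltfilt(sos, rec.data, axis=1)
    return Recording(
        infant_id=rec.infant_id,
        session=rec.session,
        pma_weeks=rec.pma_weeks,
        fs=rec.fs,
        channels=list(rec.channels),
        data=filtered,
    )


def make_bipolar(
    rec: Recording, pairs: tuple[tuple[str, str], ...] = BIPOLAR_PAIRS
) -> list[Derivation]:
    """Build bipolar derivations (anode - cathode) from a referential recording."""
    out = []
    for anode, cathode in pairs:
        if anode == cathode:
            raise ValueError(f"degenerate derivation {anode}-{cathode}")
        out.append(
            Derivation(anode, cathode, rec.channel(anode) - rec.channel(cathode))
        )
    return out


def extract_state_segments(
    rec: Recording,
    annotations: list[SleepAnnotation],
    state: str = "QS",
    min_dur: float = 300.0,
) -> SegmentSet:
    """Extract contiguous segments of one sleep state.

    Intervals are clipped to the recording and kept only if the clipped
    length still reaches ``min_dur`` (default 5 min, the minimum for the
    discontinuity and synchrony metrics).  An empty result is legal.
    """
    _check_non_overlapping(annotations)
    segs: list[Segment] = []
    n = rec.data.shape[1]
    for a in annotations:
        if a.state != state:
            continue
        i0 = int(round(a.onset * rec.fs))
        i1 = int(round((a.onset + a.duration) * rec.fs))
        i0, i1 = max(i0, 0), min(i1, n)
        if i1 <= i0:
            continue
        dur = (i1 - i0) / rec.fs
        if dur + 1e-9 < min_dur:
            continue
        segs.append(Segment(rec.data[:, i0:i1], onset=i0 / rec.fs, duration=dur))
    return SegmentSet(segs, state=state, fs=rec.fs, channels=list(rec.channels))
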