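"""Actigraphic sleep/wake scoring from 125 Hz accelerometry.

Acceleration is reduced to one activity count per 60 s epoch: the
gravity-removed magnitude is band-pass filtered to the 0.25-3 Hz body
movement band, samples inside a small noise deadband are zeroed, and the
zero crossings of the remainder are counted (the activity metric wrist
actigraphy scoring equations were fit to).  Epochs are then scored
sleep/wake with the Cole et al. weighted 7-epoch moving sum

    D_t = scale * sum_j w_j A_{t+j},   j = -4..+2,

scoring SLEEP when ``D_t`` falls below threshold 1.  Sleep onset is the
first epoch beginning a sustained run of SLEEP epochs; total sleep time
counts SLEEP epochs at or after onset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import butter, sosfiltfilt

from .series import AccelSeries

__all__ = [
    "ActivityCounts",
    "SleepWakeSeries",
    "COLE_WEIGHTS",
    "COLE_SCALE",
    "epoch_activity_counts",
    "cole_score",
    "detect_onset",
    "total_sleep_time",
    "score_sleep",
]

# Published 1-min Cole et al. scoring equation: weights for epochs t-4..t+2
# and overall scale; sleep iff scale * weighted sum < 1.
COLE_WEIGHTS = np.array([106.0, 54.0, 58.0, 76.0, 230.0, 74.0, 67.0])
COLE_SCALE = 0.001


@dataclass
class ActivityCounts:
    """Non-negative integer activity count per epoch."""

    counts: np.ndarray
    epoch_s: float = 60.0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if np.any(self.counts < 0):
            raise ValueError("activity counts must be >= 0")
        self.counts = self.counts.astype(float)

    def __len__(self) -> int:
        return self.counts.size


@dataclass
class SleepWakeSeries:
    """Per-epoch sleep/wake labels with the Cole scores that produced them."""

    is_sleep: np.ndarray  # bool per epoch
    scores: np.ndarray  # D_t per epoch
    epoch_s: float = 60.0
    onset_epoch: int | None = None

    def __len__(self) -> int:
        return self.is_sleep.size

    @property
    def labels(self) -> np.ndarray:
        return np.where(self.is_sleep, "SLEEP", "WAKE").astype(object)

    def to_frame(self, counts: ActivityCounts | None = None) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "epoch_index": np.arange(len(self)),
                "D": self.scores,
                "label": self.labels,
            }
        )
        if counts is not None:
            df.insert(1, "counts", counts.counts.astype(int))
        return df


def epoch_activity_counts(
    accel: AccelSeries,
    epoch_s: float = 60.0,
    band_hz: tuple[float, float] = (0.25, 3.0),
    deadband_g: float = 0.01,
    mode: str = "zero_crossing",
) -> ActivityCounts:
    """Per-epoch activity counts from the dynamic acceleration magnitude.

    ``zero_crossing`` (default): count sign changes of the band-passed
    magnitude after zeroing samples within ``deadband_g``.  ``max_mag``:
    peak dynamic magnitude per epoch in milli-g.  ``integration``: sum of
    above-deadband magnitude per epoch in g-samples.
    """
    if epoch_s <= 0:
        raise ValueError("epoch_s must be positive")
    dyn = accel.dynamic_magnitude()
    n_epoch = int(np.ceil(len(dyn) / (epoch_s * accel.fs)))
    per = int(round(epoch_s * accel.fs))

    if mode == "max_mag":
        sig = dyn
    else:
        lo, hi = band_hz
        sos = butter(2, [lo, hi], btype="bandpass", fs=accel.fs, output="sos")
        sig = sosfiltfilt(sos, dyn)
        sig = np.where(np.abs(sig) < deadband_g, 0.0, sig)

    counts = np.zeros(n_epoch)
    for e in range(n_epoch):
        seg = sig[e * per : (e + 1) * per]
        if mode == "zero_crossing":
            nz = seg[seg != 0.0]
            counts[e] = int(np.count_nonzero(np.diff(np.sign(nz)) != 0)) if nz.size > 1 else 0
        elif mode == "max_mag":
            counts[e] = int(round(seg.max() * 1000)) if seg.size else 0
        elif mode == "integration":
            counts[e] = int(round(np.abs(seg).sum()))
        else:
            raise ValueError(f"unknown activity mode: {mode}")
    return ActivityCounts(counts, epoch_s)


def cole_score(
    counts: ActivityCounts,
    weights: np.ndarray | None = None,
    scale: float = COLE_SCALE,
    threshold: float = 1.0,
) -> SleepWakeSeries:
    """Score each epoch sleep/wake by the Cole weighted moving sum.

    ``weights`` is the 7-term kernel for epochs ``t-4 .. t+2``.  Epochs near
    the boundaries use zero padding for the missing terms.  Epoch ``t`` is
    SLEEP iff ``scale * (w . A) < threshold``.
    """
    w = COLE_WEIGHTS if weights is None else np.asarray(weights, float)
    if w.shape != (7,):
        raise ValueError("Cole kernel must have exactly 7 terms (t-4 .. t+2)")
    a = counts.counts
    if a.size < 7:
        raise ValueError("need at least 7 epochs to score")
    padded = np.concatenate([np.zeros(4), a, np.zeros(2)])
    d = scale * np.convolve(padded, w[::-1], mode="valid")
    return SleepWakeSeries(is_sleep=d < threshold, scores=d, epoch_s=counts.epoch_s)


def detect_onset(sw: SleepWakeSeries, run_len: int = 10) -> int | None:
    """First epoch starting a run of >= ``run_len`` consecutive SLEEP epochs.

    Returns None (and leaves ``sw.onset_epoch`` unset) when no such run
    exists.  The persistence requirement suppresses transient false sleep
    during quiet wakefulness.
    """
    if run_len < 1:
        raise ValueError("run_len must be >= 1")
    s = sw.is_sleep
    run = 0
    for i, val in enumerate(s):
        run = run + 1 if val else 0
        if run >= run_len:
            sw.onset_epoch = i - run_len + 1
            return sw.onset_epoch
    sw.onset_epoch = None
    return None


def total_sleep_time(sw: SleepWakeSeries) -> float:
    """Total sleep time in minutes: SLEEP epochs at/after onset.

    Returns 0 when no onset was detected.
    """
    if sw.onset_epoch is None:
        return 0.0
    return float(np.sum(sw.is_sleep[sw.onset_epoch :]) * sw.epoch_s / 60.0)


def score_sleep(
    accel: AccelSeries,
    epoch_s: float = 60.0,
    run_len: int = 10,
    **kw,
) -> tuple[ActivityCounts, SleepWakeSeries]:
    """Counts -> Cole scoring -> onset detection, with defaults."""
    counts = epoch_activity_counts(accel, epoch_s=epoch_s, **kw)
    sw = cole_score(counts)
    detect_onset(sw, run_len=run_len)
    return counts, sw
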