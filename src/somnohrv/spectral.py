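"""Per-minute LF/HF spectral indices of the R-R tachogram.

Each non-overlapping 60 s window of the 4 Hz tachogram is mean-removed,
Hann-tapered and Fourier transformed; the one-sided periodogram is
power-normalized (density scaling) so that band integrals estimate the
windowed signal's variance in ms^2.  Band powers are discrete integrals of
the PSD over half-open frequency intervals — LF 0.05-0.15 Hz, HF
0.15-0.40 Hz — so the 0.15 Hz bin belongs to HF and the two bands never
double count.  The reported LF and HF *values* are the square roots of the
integrated band powers (ms), which damps the variance of the per-minute
estimates; the LF/HF ratio is the ratio of band powers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import get_window

from .preprocess import Tachogram

__all__ = [
    "BandDefinition",
    "SpectralFrame",
    "NightSummary",
    "window_psd",
    "band_power",
    "lf_hf_ratio",
    "frame_series",
    "frames_to_frame",
    "night_summary",
]

EPS_POWER = 1e-12  # ms^2; below this an HF power cannot anchor a ratio


@dataclass(frozen=True)
class BandDefinition:
    """LF/HF band edges in Hz (half-open bins: the 0.15 Hz edge is HF)."""

    lf_lo: float = 0.05
    lf_hi: float = 0.15
    hf_lo: float = 0.15
    hf_hi: float = 0.40

    def __post_init__(self) -> None:
        if not (0.0 < self.lf_lo < self.lf_hi <= self.hf_lo < self.hf_hi):
            raise ValueError("band edges must satisfy 0 < lf_lo < lf_hi <= hf_lo < hf_hi")

    @property
    def lf(self) -> tuple[float, float]:
        return (self.lf_lo, self.lf_hi)

    @property
    def hf(self) -> tuple[float, float]:
        return (self.hf_lo, self.hf_hi)


@dataclass
class SpectralFrame:
    """One minute of spectral HRV indices."""

    window_start_min: int
    lf_power: float  # ms^2
    hf_power: float  # ms^2
    lf_amp: float  # ms, sqrt of integrated LF PSD
    hf_amp: float  # ms
    lf_hf: float  # band-power ratio; nan when invalid
    valid: bool


def window_psd(
    tach: Tachogram,
    window_s: float = 60.0,
    step_s: float = 60.0,
    window: str = "hann",
    min_valid_frac: float = 0.8,
) -> list[tuple[np.ndarray, np.ndarray, bool]]:
    """Periodograms of consecutive tachogram windows.

    Returns one ``(frequencies, psd, valid)`` triple per window.  A window
    is valid when at least ``min_valid_frac`` of its grid points are valid;
    within a valid window, masked samples are replaced by the window's
    valid-sample mean (zero after mean removal) so they contribute no power.
    Windows extending past the recording are not produced.
    """
    fs = tach.grid_rate
    nwin = int(round(window_s * fs))
    nstep = int(round(step_s * fs))
    if nwin < 16:
        raise ValueError("window must contain at least 16 samples")
    if nstep < 1:
        raise ValueError("step must be positive")
    n = len(tach)
    starts = np.arange(0, n - nwin + 1, nstep)
    f = np.fft.rfftfreq(nwin, d=1.0 / fs)
    if starts.size == 0:
        return []

    idx = starts[:, None] + np.arange(nwin)[None, :]
    segs = tach.values[idx]
    masks = tach.valid_mask[idx]
    n_valid = masks.sum(axis=1)
    good = (n_valid >= min_valid_frac * nwin) & (n_valid > 0)

    # masked samples take the window's valid-sample mean -> zero power
    mu = np.where(n_valid > 0, (segs * masks).sum(axis=1) / np.maximum(n_valid, 1), 0.0)
    x = np.where(masks, segs, mu[:, None])
    x = x - x.mean(axis=1, keepdims=True)  # detrend='constant'

    w = get_window(window, nwin)
    spec = np.fft.rfft(x * w[None, :], axis=1)
    # one-sided density scaling, identical to scipy.signal.periodogram
    pxx = (spec.real**2 + spec.imag**2) / (fs * float(np.sum(w * w)))
    if nwin % 2 == 0:
        pxx[:, 1:-1] *= 2.0
    else:
        pxx[:, 1:] *= 2.0
    pxx[~good] = 0.0
    return [(f, pxx[i], bool(good[i])) for i in range(starts.size)]


def band_power(frequencies: np.ndarray, psd: np.ndarray, band: tuple[float, float]) -> float:
    """Integrated PSD over the half-open band ``[lo, hi)`` in ms^2.

    Discrete integral: sum of PSD bins with ``lo <= f < hi`` times the bin
    width, so adjacent bands partition the spectrum without double counting
    the shared edge.
    """
    lo, hi = band
    if lo > hi:
        raise ValueError("inverted band")
    f = np.asarray(frequencies, float)
    p = np.asarray(psd, float)
    if f.size < 2:
        return 0.0
    nyq = f[-1]
    if lo < 0 or hi > nyq + 1e-12:
        raise ValueError("band must lie inside [0, Nyquist]")
    df = f[1] - f[0]
    sel = (f >= lo - 1e-12) & (f < hi - 1e-12)
    if hi >= nyq - 1e-12:  # a band closed at Nyquist keeps the last bin
        sel |= np.abs(f - nyq) < 1e-12
    return float(p[sel].sum() * df)


def lf_hf_ratio(lf_power: float, hf_power: float) -> tuple[float, bool]:
    """Band-power ratio with an explicit invalid signal for vanishing HF.

    Returns ``(ratio, valid)``; when ``hf_power`` is below 1e-12 ms^2 the
    frame is invalid (``(nan, False)``) rather than an infinite ratio.
    """
    if lf_power < 0 or hf_power < 0:
        raise ValueError("band powers must be >= 0")
    if hf_power < EPS_POWER:
        return (math.nan, False)
    return (lf_power / hf_power, True)


def frame_series(
    tach: Tachogram,
    bands: BandDefinition | None = None,
    window_s: float = 60.0,
    window: str = "hann",
    min_valid_frac: float = 0.8,
) -> list[SpectralFrame]:
    """One :class:`SpectralFrame` per minute of the tachogram."""
    bands = bands if bands is not None else BandDefinition()
    frames: list[SpectralFrame] = []
    for i, (f, pxx, ok) in enumerate(
        window_psd(tach, window_s, window_s, window, min_valid_frac)
    ):
        minute = int(round(i * window_s / 60.0))
        if not ok:
            frames.append(SpectralFrame(minute, 0.0, 0.0, 0.0, 0.0, math.nan, False))
            continue
        lf = band_power(f, pxx, bands.lf)
        hf = band_power(f, pxx, bands.hf)
        ratio, ratio_ok = lf_hf_ratio(lf, hf)
        frames.append(
            SpectralFrame(minute, lf, hf, math.sqrt(lf), math.sqrt(hf), ratio, ratio_ok)
        )
    return frames


def frames_to_frame(frames: list[SpectralFrame]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "minute": [fr.window_start_min for fr in frames],
            "lf_power": [fr.lf_power for fr in frames],
            "hf_power": [fr.hf_power for fr in frames],
            "lf_amp": [fr.lf_amp for fr in frames],
            "hf_amp": [fr.hf_amp for fr in frames],
            "lf_hf": [fr.lf_hf for fr in frames],
            "valid": [int(fr.valid) for fr in frames],
        }
    )


@dataclass
class NightSummary:
    """Per-night means of the spectral indices, overall and per stage."""

    lf_amp: float
    hf_amp: float
    lf_hf: float
    n_frames: int
    per_stage: dict = field(default_factory=dict)

    def as_row(self) -> dict:
        row = {
            "lf_amp": self.lf_amp,
            "hf_amp": self.hf_amp,
            "lf_hf": self.lf_hf,
            "n_frames": self.n_frames,
        }
        for st, vals in self.per_stage.items():
            for k, v in vals.items():
                row[f"{st}_{k}"] = v
        return row


def night_summary(
    frames: list[SpectralFrame],
    hypnogram_labels: np.ndarray,
    sleep_stages: tuple = ("S", "PS_SHALLOW", "PS_DEEP"),
    ratio_mode: str = "mean_of_ratios",
) -> NightSummary:
    """Night means of lf_amp, hf_amp and LF/HF over valid sleep frames.

    ``hypnogram_labels`` must be aligned with ``frames`` on the same 1-min
    epoch grid (frames beyond the hypnogram are ignored).  Per-stage means
    are computed over the frames carrying that label.  ``ratio_mode``
    selects the night LF/HF as the mean of per-minute ratios (default) or
    the ratio of mean band powers (``"ratio_of_means"``).
    """
    labels = np.asarray(hypnogram_labels, dtype=object)
    usable = [
        (fr, labels[fr.window_start_min])
        for fr in frames
        if fr.valid and fr.window_start_min < labels.size
        and labels[fr.window_start_min] in sleep_stages
    ]
    if not usable:
        raise ValueError("no valid sleep frames to summarize")

    def _means(sel) -> dict:
        lf_a = float(np.mean([fr.lf_amp for fr in sel]))
        hf_a = float(np.mean([fr.hf_amp for fr in sel]))
        if ratio_mode == "ratio_of_means":
            lp = float(np.mean([fr.lf_power for fr in sel]))
            hp = float(np.mean([fr.hf_power for fr in sel]))
            ratio = lp / hp if hp > EPS_POWER else math.nan
        else:
            ratio = float(np.mean([fr.lf_hf for fr in sel]))
        return {"lf_amp": lf_a, "hf_amp": hf_a, "lf_hf": ratio}

    overall = _means([fr for fr, _ in usable])
    per_stage = {}
    for st in sleep_stages:
        sel = [fr for fr, lab in usable if lab == st]
        if sel:
            per_stage[st] = {**_means(sel), "n_frames": len(sel)}
    return NightSummary(
        overall["lf_amp"],
        overall["hf_amp"],
        overall["lf_hf"],
        len(usable),
        per_stage,
    )
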