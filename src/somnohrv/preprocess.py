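"""R-R interval cleaning: movement gating, ectopic removal, even resampling.

Movement artifacts are flagged by the 0.5 g dynamic-acceleration threshold:
an interval is flagged iff any gravity-removed acceleration sample inside
its ``[t_{i-1}, t_i)`` span reaches the threshold.  Physiological outliers
(ectopic beats, missed/extra detections) are flagged by absolute bounds and
a relative-jump rule against the running median of recently accepted
intervals — standard HRV practice, stated explicitly here because the
recording device documents only the movement gate.

Flagging never alters interval values.  Flagged intervals are excluded from
the interpolation support when the series is resampled onto the uniform
tachogram grid used for the FFT; grid points far from any clean beat are
masked rather than bridged, so long movement bouts produce invalid spectral
windows instead of fabricated data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline

from .series import AccelSeries, RRISeries

__all__ = [
    "Tachogram",
    "flag_movement_artifacts",
    "filter_ectopic",
    "resample_evenly",
    "preprocess_night",
]


@dataclass
class Tachogram:
    """R-R intervals resampled to a uniform grid (for Fourier analysis).

    ``values[k]`` is the interpolated RR (ms) at time ``t0_s + k/grid_rate``;
    ``valid_mask[k]`` is False where the grid point is unsupported by clean
    beats (nearest clean beat further than the masking gap).
    """

    values: np.ndarray
    valid_mask: np.ndarray
    grid_rate: float = 4.0
    t0_s: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if self.values.shape != self.valid_mask.shape:
            raise ValueError("values and valid_mask must have the same shape")
        if self.grid_rate <= 0:
            raise ValueError("grid_rate must be positive")

    def __len__(self) -> int:
        return self.values.size

    @property
    def t_s(self) -> np.ndarray:
        return self.t0_s + np.arange(self.values.size) / self.grid_rate

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"t_s": self.t_s, "rr_ms": self.values, "valid": self.valid_mask.astype(int)}
        )


def flag_movement_artifacts(
    rri: RRISeries,
    accel: AccelSeries,
    threshold_g: float = 0.5,
) -> RRISeries:
    """Flag intervals whose time span contains body movement >= ``threshold_g``.

    Interval ``i`` spans ``[t_{i-1}, t_i)`` ms with ``t_{-1} = 0``.  The
    comparison uses the gravity-removed acceleration magnitude.  Raises if
    the two recordings do not overlap in time.
    """
    if threshold_g <= 0:
        raise ValueError("threshold_g must be positive")
    if len(rri) == 0:
        return rri.copy()
    if accel.duration_s <= 0 or rri.duration_ms <= 0:
        raise ValueError("empty recording")
    if accel.duration_s * 1000.0 < float(rri.rri_ms[0]):
        raise ValueError("acceleration and RRI recordings do not overlap in time")

    out = rri.copy()
    dyn = accel.dynamic_magnitude()
    hit_ms = np.flatnonzero(dyn >= threshold_g) * (1000.0 / accel.fs)
    if hit_ms.size:
        ends = out.t_ms
        idx = np.searchsorted(ends, hit_ms, side="right")
        idx = idx[idx < len(out)]  # samples past the last beat are ignored
        out.movement_flag[np.unique(idx)] = True
    return out


def filter_ectopic(
    rri: RRISeries,
    min_ms: float = 300.0,
    max_ms: float = 2000.0,
    max_rel_jump: float = 0.2,
) -> RRISeries:
    """Flag physiologically implausible intervals.

    An interval is flagged if it falls outside ``[min_ms, max_ms]`` or
    differs from the median of the 5 previous accepted (non-ectopic)
    intervals by more than ``max_rel_jump`` (relative).  The jump rule only
    engages once 5 accepted intervals exist, so it cannot be poisoned by a
    bad start.  Movement flags are ignored here, which keeps the two
    flagging passes order-independent.
    """
    if min_ms <= 0 or max_ms <= 0 or min_ms >= max_ms:
        raise ValueError("need 0 < min_ms < max_ms")
    if max_rel_jump <= 0:
        raise ValueError("max_rel_jump must be positive")
    out = rri.copy()
    recent: list[float] = []
    flags = out.ectopic_flag
    for i, rr in enumerate(out.rri_ms.tolist()):
        bad = not (min_ms <= rr <= max_ms)
        if not bad and len(recent) == 5:
            med = sorted(recent)[2]
            bad = abs(rr - med) > max_rel_jump * med
        if bad:
            flags[i] = True
        else:
            recent.append(rr)
            if len(recent) > 5:
                recent.pop(0)
    return out


def resample_evenly(
    rri: RRISeries,
    grid_rate: float = 4.0,
    max_gap_s: float = 5.0,
    method: str = "cubic",
) -> Tachogram:
    """Interpolate clean beats onto a uniform grid starting at t = 0.

    Cubic-spline interpolation of the unflagged ``(t_i, rri_i)`` pairs.
    Grid points whose nearest clean beat is more than ``max_gap_s`` away
    (including points before the first or after the last clean beat by more
    than the gap) are masked invalid; values there are held at the nearest
    clean beat's RR rather than extrapolated.
    """
    if grid_rate <= 0:
        raise ValueError("grid_rate must be positive")
    mask = rri.clean_mask
    if int(mask.sum()) < 4:
        raise ValueError("fewer than 4 usable intervals; cannot resample")
    t_beat = rri.t_ms[mask] / 1000.0
    v_beat = rri.rri_ms[mask]

    n_grid = int(np.floor(rri.duration_ms / 1000.0 * grid_rate)) + 1
    t_grid = np.arange(n_grid) / grid_rate

    if method == "cubic":
        f = CubicSpline(t_beat, v_beat, extrapolate=True)
        values = f(t_grid)
    elif method == "linear":
        values = np.interp(t_grid, t_beat, v_beat)
    else:
        raise ValueError(f"unknown interpolation method: {method}")

    # distance from each grid point to the nearest clean beat
    pos = np.searchsorted(t_beat, t_grid)
    left = np.clip(pos - 1, 0, t_beat.size - 1)
    right = np.clip(pos, 0, t_beat.size - 1)
    dist = np.minimum(np.abs(t_grid - t_beat[left]), np.abs(t_beat[right] - t_grid))
    valid = dist <= max_gap_s

    # outside the clean support, hold the boundary value (masked anyway
    # unless within the gap, where the hold is the safest estimate)
    values = np.where(t_grid < t_beat[0], v_beat[0], values)
    values = np.where(t_grid > t_beat[-1], v_beat[-1], values)
    return Tachogram(values, valid, grid_rate=grid_rate)


def preprocess_night(
    rri: RRISeries,
    accel: AccelSeries,
    threshold_g: float = 0.5,
    min_ms: float = 300.0,
    max_ms: float = 2000.0,
    max_rel_jump: float = 0.2,
    grid_rate: float = 4.0,
    max_gap_s: float = 5.0,
) -> tuple[RRISeries, Tachogram]:
    """Movement gating, ectopic filtering, then even resampling (the default order)."""
    flagged = filter_ectopic(
        flag_movement_artifacts(rri, accel, threshold_g),
        min_ms=min_ms,
        max_ms=max_ms,
        max_rel_jump=max_rel_jump,
    )
    return flagged, resample_evenly(flagged, grid_rate=grid_rate, max_gap_s=max_gap_s)
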