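"""Core recording containers: beat-to-beat R-R intervals and 3-axis acceleration.

An :class:`RRISeries` holds millisecond R-R intervals (RRI) together with
per-interval artifact flags.  Interval ``i`` spans ``[t_{i-1}, t_i)`` with
``t_{-1} = 0`` and ``t_i`` the cumulative sum of the intervals, so for a
contiguous recording ``t_i - t_{i-1} == rri_i`` holds by construction.

An :class:`AccelSeries` holds a uniformly sampled 3-axis acceleration signal
in g units.  Gravity is treated as a constant offset per axis; the
"dynamic" acceleration used for movement detection and activity counting is
the vector magnitude after removing the per-axis median (a robust estimate
of the gravity component for a recording dominated by lying still).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["RRISeries", "AccelSeries"]


@dataclass
class RRISeries:
    """Timestamped R-R intervals with movement and ectopic artifact flags.

    Parameters
    ----------
    rri_ms
        R-R intervals in milliseconds; all strictly positive.
    movement_flag, ectopic_flag
        Per-interval boolean artifact flags.  Flagging never alters the
        interval values, only these flags.
    """

    rri_ms: np.ndarray
    movement_flag: np.ndarray = field(default=None)  # type: ignore[assignment]
    ectopic_flag: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.rri_ms = np.asarray(self.rri_ms, dtype=float)
        if self.rri_ms.ndim != 1:
            raise ValueError("rri_ms must be 1-D")
        if self.rri_ms.size and not np.all(self.rri_ms > 0):
            raise ValueError("all R-R intervals must be > 0 ms")
        n = self.rri_ms.size
        if self.movement_flag is None:
            self.movement_flag = np.zeros(n, dtype=bool)
        if self.ectopic_flag is None:
            self.ectopic_flag = np.zeros(n, dtype=bool)
        self.movement_flag = np.asarray(self.movement_flag, dtype=bool)
        self.ectopic_flag = np.asarray(self.ectopic_flag, dtype=bool)
        if self.movement_flag.shape != (n,) or self.ectopic_flag.shape != (n,):
            raise ValueError("flag arrays must match rri_ms length")

    def __len__(self) -> int:
        return self.rri_ms.size

    @property
    def t_ms(self) -> np.ndarray:
        """Interval end times (ms since record start); strictly increasing."""
        return np.cumsum(self.rri_ms)

    @property
    def duration_ms(self) -> float:
        return float(self.rri_ms.sum())

    @property
    def clean_mask(self) -> np.ndarray:
        """True where an interval carries no artifact flag."""
        return ~(self.movement_flag | self.ectopic_flag)

    def copy(self) -> "RRISeries":
        return RRISeries(
            self.rri_ms.copy(), self.movement_flag.copy(), self.ectopic_flag.copy()
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t_ms": np.rint(self.t_ms).astype(np.int64),
                "rri_ms": np.rint(self.rri_ms).astype(np.int64),
                "movement_flag": self.movement_flag.astype(int),
                "ectopic_flag": self.ectopic_flag.astype(int),
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path) -> "RRISeries":
        df = pd.read_csv(path)
        mov = df["movement_flag"].to_numpy(bool) if "movement_flag" in df else None
        ect = df["ectopic_flag"].to_numpy(bool) if "ectopic_flag" in df else None
        return cls(df["rri_ms"].to_numpy(float), mov, ect)


@dataclass
class AccelSeries:
    """Uniformly sampled 3-axis acceleration in g units.

    ``xyz`` has shape ``(n_samples, 3)``; sample ``k`` is taken at
    ``k / fs`` seconds from record start (the same origin as the RRI clock).
    """

    xyz: np.ndarray
    fs: float = 125.0

    def __post_init__(self) -> None:
        self.xyz = np.asarray(self.xyz)
        if self.xyz.dtype not in (np.float32, np.float64):
            self.xyz = self.xyz.astype(np.float64)
        if self.xyz.ndim != 2 or self.xyz.shape[1] != 3:
            raise ValueError("xyz must have shape (n, 3)")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")

    def __len__(self) -> int:
        return self.xyz.shape[0]

    @property
    def t_s(self) -> np.ndarray:
        return np.arange(self.xyz.shape[0]) / self.fs

    @property
    def duration_s(self) -> float:
        return self.xyz.shape[0] / self.fs

    def dynamic_magnitude(self) -> np.ndarray:
        """Gravity-removed acceleration magnitude (g).

        The per-axis median over the whole record estimates the static
        gravity vector; the result is the Euclidean norm of the residual.
        Cached: the array is computed once per series.
        """
        cached = getattr(self, "_dyn_cache", None)
        if cached is not None:
            return cached
        r = self.xyz - np.median(self.xyz, axis=0)
        dyn = np.sqrt(np.einsum("ij,ij->i", r, r))
        self._dyn_cache = dyn
        return dyn

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t_s": self.t_s,
                "ax_g": self.xyz[:, 0],
                "ay_g": self.xyz[:, 1],
                "az_g": self.xyz[:, 2],
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.6f")

    @classmethod
    def read_csv(cls, path) -> "AccelSeries":
        df = pd.read_csv(path)
        xyz = df[["ax_g", "ay_g", "az_g"]].to_numpy(float)
        t = df["t_s"].to_numpy(float)
        if len(t) > 1:
            dt = np.diff(t)
            if not np.allclose(dt, dt[0], rtol=0, atol=1e-6):
                raise ValueError("acceleration CSV is not uniformly sampled")
            fs = 1.0 / dt[0]
        else:
            fs = 125.0
        return cls(xyz, fs=float(round(fs, 6)))
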