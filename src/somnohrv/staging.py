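"""Three-class autonomic sleep staging from per-minute LF/HF indices.

Each minute scored as sleep by actigraphy is assigned one of three
autonomic stages:

* **S sleep** — sympathetic dominance: LF/HF at or above a threshold;
* **PS sleep (deep)** — strong parasympathetic drive: below the LF/HF
  threshold and HF amplitude at or above a high per-night quantile;
* **PS sleep (shallow)** — the remaining sleep minutes.

Thresholds are adaptive per night by default (the LF/HF cut is 1.5x the
night's median sleep LF/HF; the depth cut is the 0.60 quantile of sleep HF
amplitude), which makes the rule robust to inter-subject differences in
overall HRV scale.  Both can be overridden with absolute values.  Minutes
with an invalid spectral frame inherit the previous minute's label.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .actigraphy import SleepWakeSeries
from .spectral import SpectralFrame

__all__ = ["Hypnogram", "classify_stages", "stage_durations", "plot_night"]

SLEEP_STAGES = ("S", "PS_SHALLOW", "PS_DEEP")


@dataclass
class Hypnogram:
    """Per-epoch stage labels plus the index values each decision used."""

    labels: np.ndarray  # WAKE / S / PS_SHALLOW / PS_DEEP per epoch
    epoch_s: float = 60.0
    onset_epoch: int | None = None
    provenance: pd.DataFrame | None = field(default=None, repr=False)

    def __len__(self) -> int:
        return self.labels.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"epoch_index": np.arange(len(self)), "label": self.labels}
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def classify_stages(
    frames: list[SpectralFrame],
    sw: SleepWakeSeries,
    theta_s: float | None = None,
    theta_s_scale: float = 1.5,
    theta_d: float = 0.60,
) -> Hypnogram:
    """Assign an autonomic stage to every actigraphic sleep minute.

    Parameters
    ----------
    frames
        Per-minute spectral frames aligned with ``sw`` on the epoch grid.
    sw
        Actigraphic sleep/wake series; ``onset_epoch`` must be set.
    theta_s
        Absolute LF/HF threshold for S sleep.  Default (None): 1.5x the
        per-night median LF/HF over valid sleep frames.
    theta_d
        Quantile (0-1) of the night's sleep HF amplitude above which a
        non-S minute is PS deep.
    """
    if sw.onset_epoch is None:
        raise ValueError("sleep onset must be detected before staging")
    if not 0.0 <= theta_d <= 1.0:
        raise ValueError("theta_d must be a quantile in [0, 1]")
    n = len(sw)
    frame_by_min = {fr.window_start_min: fr for fr in frames}

    def _is_sleep_epoch(e: int) -> bool:
        return e >= sw.onset_epoch and bool(sw.is_sleep[e])

    sleep_frames = [
        frame_by_min[e]
        for e in range(n)
        if _is_sleep_epoch(e) and e in frame_by_min and frame_by_min[e].valid
    ]
    if not sleep_frames:
        raise ValueError("no valid sleep frames; cannot stage")

    if theta_s is None:
        theta_s = theta_s_scale * float(np.median([fr.lf_hf for fr in sleep_frames]))
    hf_cut = float(np.quantile([fr.hf_amp for fr in sleep_frames], theta_d))

    labels = np.full(n, "WAKE", dtype=object)
    prov = {"epoch_index": [], "lf_hf": [], "hf_amp": []}
    prev_sleep_label = None
    for e in range(n):
        if not _is_sleep_epoch(e):
            continue
        fr = frame_by_min.get(e)
        if fr is not None and fr.valid:
            if fr.lf_hf >= theta_s:
                lab = "S"
            elif fr.hf_amp >= hf_cut:
                lab = "PS_DEEP"
            else:
                lab = "PS_SHALLOW"
            prov["epoch_index"].append(e)
            prov["lf_hf"].append(fr.lf_hf)
            prov["hf_amp"].append(fr.hf_amp)
        else:
            lab = prev_sleep_label if prev_sleep_label is not None else "PS_SHALLOW"
        labels[e] = lab
        prev_sleep_label = lab
    return Hypnogram(
        labels,
        epoch_s=sw.epoch_s,
        onset_epoch=sw.onset_epoch,
        provenance=pd.DataFrame(prov),
    )


def stage_durations(h: Hypnogram) -> dict:
    """Minutes per stage plus the total (equals total sleep time exactly)."""
    per_epoch_min = h.epoch_s / 60.0
    out = {st: float(np.sum(h.labels == st) * per_epoch_min) for st in SLEEP_STAGES}
    out["total"] = float(sum(out[st] for st in SLEEP_STAGES))
    return out


def plot_night(
    frames: list[SpectralFrame],
    hypnogram: Hypnogram,
    path=None,
):
    """Time-course plot: LF and HF amplitudes with the stage band below."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    minutes = [fr.window_start_min for fr in frames if fr.valid]
    lf = [fr.lf_amp for fr in frames if fr.valid]
    hf = [fr.hf_amp for fr in frames if fr.valid]
    order = {"WAKE": 3, "S": 2, "PS_SHALLOW": 1, "PS_DEEP": 0}
    stage_y = [order[l] for l in hypnogram.labels]

    fig, (ax1, ax2) = plt.subplots(
        2, 1, sharex=True, figsize=(10, 5), height_ratios=[2, 1]
    )
    ax1.plot(minutes, lf, label="LF amplitude (ms)", lw=0.8)
    ax1.plot(minutes, hf, label="HF amplitude (ms)", lw=0.8)
    ax1.set_ylabel("amplitude (ms)")
    ax1.legend(loc="upper right")
    ax2.step(range(len(hypnogram)), stage_y, where="post", lw=1.0)
    ax2.set_yticks(list(order.values()), list(order.keys()))
    ax2.set_xlabel("minutes from record start")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
        return None
    return fig
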