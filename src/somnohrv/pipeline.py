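"""End-to-end orchestration: recordings -> cleaned RRI -> spectral frames ->
sleep scoring -> staging -> per-night summaries -> trial tables.

A :class:`RunConfig` carries every tunable of the pipeline with the standard
defaults: the 0.5 g movement threshold, the 0.05-0.15 / 0.15-0.40 Hz bands,
60 s windows and epochs, 125 Hz accelerometry, alpha = 0.05 and k = 3
Bonferroni comparisons.  Runs are reproducible: the same config + seed give
identical outputs, and each run writes a manifest (config hash, seed,
package version, outputs).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .actigraphy import score_sleep, total_sleep_time
from .preprocess import preprocess_night
from .series import AccelSeries, RRISeries
from .spectral import BandDefinition, frame_series, frames_to_frame, night_summary
from .staging import classify_stages, stage_durations
from .synth import CohortDesign, SyntheticNight, generate_cohort
from .trialstats import build_tables

__all__ = ["RunConfig", "NightResult", "process_night", "run_pipeline"]


@dataclass
class RunConfig:
    """Full pipeline configuration with the standard defaults."""

    input_mode: str = "synthetic"  # or "csv"
    input_dir: str | None = None  # csv mode: directory of per-night CSVs
    out_dir: str = "somnohrv_out"
    master_seed: int = 0

    # preprocessing
    movement_threshold_g: float = 0.5
    ectopic_min_ms: float = 300.0
    ectopic_max_ms: float = 2000.0
    ectopic_max_rel_jump: float = 0.2
    grid_rate_hz: float = 4.0
    max_gap_s: float = 5.0

    # spectral
    lf_lo_hz: float = 0.05
    lf_hi_hz: float = 0.15
    hf_lo_hz: float = 0.15
    hf_hi_hz: float = 0.40
    window_s: float = 60.0
    ratio_mode: str = "mean_of_ratios"

    # actigraphy / staging
    epoch_s: float = 60.0
    onset_run_len: int = 10
    theta_s_scale: float = 1.5
    theta_d: float = 0.60

    # statistics
    t_variant: str = "welch"
    bonferroni_cap: bool = False
    alpha: float = 0.05

    # synthetic cohort (synthetic mode only)
    design: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(raw) - known
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        return cls(**raw)

    def bands(self) -> BandDefinition:
        return BandDefinition(self.lf_lo_hz, self.lf_hi_hz, self.hf_lo_hz, self.hf_hi_hz)

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class NightResult:
    """All per-night pipeline outputs."""

    frames: list
    sw: object
    hypnogram: object
    summary: object
    durations: dict
    tst_min: float
    n_flagged: int

    def measures(self) -> dict:
        """The seven trial measures for this night."""
        return {
            "total": self.durations["total"],
            "S": self.durations["S"],
            "PS_shallow": self.durations["PS_SHALLOW"],
            "PS_deep": self.durations["PS_DEEP"],
            "LF": self.summary.lf_amp,
            "HF": self.summary.hf_amp,
            "LF_HF": self.summary.lf_hf,
        }


def process_night(
    rri: RRISeries, accel: AccelSeries, config: RunConfig | None = None
) -> NightResult:
    """Run the full single-night pipeline on one recording pair."""
    cfg = config if config is not None else RunConfig()
    flagged, tach = preprocess_night(
        rri,
        accel,
        threshold_g=cfg.movement_threshold_g,
        min_ms=cfg.ectopic_min_ms,
        max_ms=cfg.ectopic_max_ms,
        max_rel_jump=cfg.ectopic_max_rel_jump,
        grid_rate=cfg.grid_rate_hz,
        max_gap_s=cfg.max_gap_s,
    )
    frames = frame_series(tach, cfg.bands(), window_s=cfg.window_s)
    _, sw = score_sleep(accel, epoch_s=cfg.epoch_s, run_len=cfg.onset_run_len)
    hyp = classify_stages(
        frames, sw, theta_s_scale=cfg.theta_s_scale, theta_d=cfg.theta_d
    )
    summary = night_summary(frames, hyp.labels, ratio_mode=cfg.ratio_mode)
    return NightResult(
        frames=frames,
        sw=sw,
        hypnogram=hyp,
        summary=summary,
        durations=stage_durations(hyp),
        tst_min=total_sleep_time(sw),
        n_flagged=int((~flagged.clean_mask).sum()),
    )


def _load_csv_nights(input_dir: str) -> dict:
    """csv mode: nights are ``<night>_rri.csv`` / ``<night>_accel.csv`` pairs.

    The night id must be ``<group>_s<subject>_d<day>``.
    """
    d = Path(input_dir)
    rri_files = sorted(d.glob("*_rri.csv"))
    if not rri_files:
        raise FileNotFoundError(f"no *_rri.csv files under {d}")
    missing = [
        f.name.replace("_rri.csv", "")
        for f in rri_files
        if not (d / f.name.replace("_rri.csv", "_accel.csv")).exists()
    ]
    if missing:
        raise FileNotFoundError(f"nights missing acceleration files: {missing}")
    nights = {}
    for f in rri_files:
        night = f.name.replace("_rri.csv", "")
        try:
            group, subj, day = night.split("_")
            key = (group, int(subj.lstrip("s")), int(day.lstrip("d")))
        except ValueError as err:
            raise ValueError(
                f"night file {f.name}: expected <group>_s<subject>_d<day>_rri.csv"
            ) from err
        nights[key] = (
            RRISeries.read_csv(f),
            AccelSeries.read_csv(d / f"{night}_accel.csv"),
        )
    return nights


def run_pipeline(config: RunConfig) -> dict:
    """Run the whole pipeline and write all outputs under ``config.out_dir``.

    Returns ``{"summaries": DataFrame, "tables": dict, "manifest": dict,
    "errors": list}``.  Per-night failures are recorded with the stage and
    night id; completed outputs are retained.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if config.input_mode == "synthetic":
        design = CohortDesign(master_seed=config.master_seed, **config.design)
        cohort = generate_cohort(design)
        pairs = {}
        for key, night in cohort.items():
            pairs[key] = (night.rri, night.accel)
            g, s, d = key
            night.stages.to_csv(out / f"{g}_s{s}_d{d}_truth_hypnogram.csv")
    elif config.input_mode == "csv":
        if not config.input_dir:
            raise ValueError("csv mode requires input_dir")
        pairs = _load_csv_nights(config.input_dir)
    else:
        raise ValueError(f"unknown input_mode: {config.input_mode}")

    rows, errors, outputs = [], [], []
    for (g, s, d), (rri, accel) in sorted(pairs.items()):
        night_id = f"{g}_s{s}_d{d}"
        try:
            res = process_night(rri, accel, config)
        except Exception as err:  # noqa: BLE001 - reported per night
            errors.append({"night": night_id, "error": str(err)})
            continue
        frames_to_frame(res.frames).to_csv(out / f"{night_id}_frames.csv", index=False)
        res.hypnogram.to_csv(out / f"{night_id}_hypnogram.csv")
        outputs.extend([f"{night_id}_frames.csv", f"{night_id}_hypnogram.csv"])
        rows.append(
            {
                "group": g,
                "subject": s,
                "day": d,
                "n_flagged": res.n_flagged,
                "tst_min": res.tst_min,
                **res.measures(),
            }
        )
    summaries = pd.DataFrame(rows)
    summaries.to_csv(out / "summaries.csv", index=False)
    outputs.append("summaries.csv")

    tables = {}
    if not summaries.empty:
        groups = tuple(dict.fromkeys(summaries["group"]))
        days = tuple(sorted(summaries["day"].unique()))
        if len(groups) == 2 and summaries.groupby(["group", "day"]).size().min() >= 2:
            tables = build_tables(
                summaries,
                groups=groups,
                days=days,
                t_variant=config.t_variant,
                bonferroni_cap=config.bonferroni_cap,
                alpha=config.alpha,
            )
            for name, df in tables.items():
                df.to_csv(out / f"table_{name}.csv", index=False)
                outputs.append(f"table_{name}.csv")

    manifest = {
        "somnohrv_version": __version__,
        "config_hash": config.config_hash(),
        "master_seed": config.master_seed,
        "n_nights": len(pairs),
        "n_failed": len(errors),
        "errors": errors,
        "outputs": sorted(outputs),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return {"summaries": summaries, "tables": tables, "manifest": manifest, "errors": errors}
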