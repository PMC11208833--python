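"""Ground-truth recovery and calibration studies on synthetic recordings.

The trial's group-level numbers come from unreleased participant
recordings, so the pipeline is validated by simulation instead: each
function here generates synthetic data with known truth, runs the relevant
pipeline stage(s) from scratch, and measures how well the truth is
recovered (or how well a test's error rate is calibrated).  They are used
by both the test suite and the reproduction script.

All functions accept a ``seed`` and are deterministic given it; derived
per-night streams are spawned via ``numpy.random.SeedSequence``.
"""

from __future__ import annotations

import math

import numpy as np

from .actigraphy import score_sleep
from .pipeline import process_night
from .preprocess import flag_movement_artifacts, resample_evenly
from .spectral import BandDefinition, band_power, window_psd
from .synth import (
    STAGES,
    AutonomicProfile,
    Burst,
    BurstSpec,
    CohortDesign,
    NightSpec,
    StageSequence,
    generate_accel,
    generate_cohort,
    generate_night,
    generate_rri,
)
from .trialstats import games_howell, one_way_anova, t_test_two_tailed

__all__ = [
    "two_tone_ratio",
    "single_tone_parseval_error",
    "artifact_gating_mismatch",
    "onset_recovery_rate",
    "staging_agreement",
    "test_calibration",
    "lf_decline_detection_power",
]

QUIET = BurstSpec(rate_per_min={s: 0.0 for s in STAGES}, noise_sd_g=0.0)


def two_tone_ratio(seed: int = 0, minutes: int = 10) -> dict:
    """LF/HF band-power ratio of a noise-free equal-amplitude two-tone night.

    Generates a beat series with 20 ms tones at the default LF and HF
    carriers, resamples it, and returns the pooled and per-minute ratios
    (truth: exactly 1).
    """
    stages = StageSequence(np.array(["S"] * minutes, dtype=object))
    prof = AutonomicProfile(noise_sd_ms=0.0, lf_amp_ms=20.0, hf_amp_ms=20.0)
    tach = resample_evenly(generate_rri(stages, prof, seed=seed))
    b = BandDefinition()
    lf = hf = 0.0
    per_min = []
    for f, pxx, ok in window_psd(tach):
        wlf, whf = band_power(f, pxx, b.lf), band_power(f, pxx, b.hf)
        lf += wlf
        hf += whf
        if whf > 0:
            per_min.append(wlf / whf)
    return {
        "pooled_ratio": lf / hf,
        "per_minute_ratios": per_min,
        "n_minutes": len(per_min),
    }


def single_tone_parseval_error(amp_ms: float = 30.0) -> float:
    """Relative error of the integrated 60 s periodogram vs the a^2/2 truth."""
    from .preprocess import Tachogram

    t = np.arange(0.0, 60.0, 0.25)
    tach = Tachogram(
        900.0 + amp_ms * np.sin(2 * np.pi * 0.10 * t), np.ones(t.size, bool), 4.0
    )
    f, pxx, _ = window_psd(tach)[0]
    total = band_power(f, pxx, (0.0, 2.0))
    truth = amp_ms * amp_ms / 2.0
    return abs(total - truth) / truth


def artifact_gating_mismatch(seed: int = 0, n_bursts: int = 5) -> dict:
    """Exactness of 0.5 g movement gating against scripted ground truth.

    Scripts ``n_bursts`` rectangular bursts at and above the threshold into
    an otherwise quiet night, flags movement artifacts, and compares the
    flagged-interval set against a brute-force overlap scan of the bursts.
    Returns the mismatch count (truth: 0).
    """
    rng = np.random.default_rng(seed)
    minutes = 30
    stages = StageSequence(np.array(["S"] * minutes, dtype=object))
    starts = np.sort(rng.uniform(30.0, minutes * 60.0 - 30.0, n_bursts))
    bursts = [
        Burst(float(t0), float(rng.uniform(0.5, 3.0)), float(rng.uniform(0.5, 1.2)), "rect")
        for t0 in starts
    ]
    accel, truth = generate_accel(stages, QUIET, seed=seed, scripted_bursts=bursts)
    rri = generate_rri(
        stages, AutonomicProfile(lf_amp_ms=20.0, hf_amp_ms=20.0), seed=seed + 1
    )
    out = flag_movement_artifacts(rri, accel)

    ends = rri.t_ms
    lo = np.concatenate([[0.0], ends[:-1]])
    expect = np.zeros(len(rri), dtype=bool)
    fs = accel.fs
    for b in truth:
        if b.amplitude_g < 0.5:
            continue
        ks = np.arange(int(np.ceil(b.t_start_s * fs)), int(round(b.t_end_s * fs)))
        ts = ks / fs * 1000.0
        for i in range(len(rri)):  # brute-force overlap scan
            if np.any((ts >= lo[i]) & (ts < ends[i])):
                expect[i] = True
    return {
        "mismatch_count": int(np.sum(out.movement_flag != expect)),
        "n_flagged": int(out.movement_flag.sum()),
        "n_intervals": len(rri),
    }


def onset_recovery_rate(
    seed: int = 0,
    n_nights: int = 50,
    latencies_min: tuple = (10, 30, 60),
    tolerance_min: int = 5,
) -> dict:
    """Fraction of synthetic nights whose detected onset is within tolerance.

    Nights cycle through the given true latencies; each night is scored with
    the default actigraphy pipeline.
    """
    ss = np.random.SeedSequence(seed, spawn_key=(101,))
    seeds = ss.spawn(n_nights)
    hits, errors = 0, []
    for i in range(n_nights):
        latency = latencies_min[i % len(latencies_min)]
        night = generate_night(
            NightSpec(duration_min=latency + 90, onset_latency_min=latency), seeds[i]
        )
        _, sw = score_sleep(night.accel)
        err = abs(sw.onset_epoch - latency) if sw.onset_epoch is not None else math.inf
        errors.append(err)
        hits += err <= tolerance_min
    return {"rate": hits / n_nights, "n_nights": n_nights, "errors_min": errors}


def staging_agreement(seed: int = 0, n_nights: int = 20, duration_min: int = 360) -> dict:
    """Per-epoch agreement between staged and ground-truth hypnograms.

    Runs the full pipeline (preprocess, spectra, sleep scoring, staging) on
    default-profile nights and scores agreement on all epochs at/after the
    detected onset.  Also verifies stage-minute conservation against total
    sleep time on every night.
    """
    ss = np.random.SeedSequence(seed, spawn_key=(102,))
    seeds = ss.spawn(n_nights)
    agree = total = 0
    conserved = True
    for i in range(n_nights):
        night = generate_night(
            NightSpec(duration_min=duration_min, onset_latency_min=15), seeds[i]
        )
        res = process_night(night.rri, night.accel)
        truth = night.stages.labels
        pred = res.hypnogram.labels
        n = min(truth.size, pred.size)
        sel = np.arange(res.sw.onset_epoch, n)
        agree += int(np.sum(truth[sel] == pred[sel]))
        total += sel.size
        d = res.durations
        conserved &= (
            abs(d["S"] + d["PS_SHALLOW"] + d["PS_DEEP"] - res.tst_min) < 1e-9
        )
    return {"agreement": agree / total, "n_epochs": total, "n_nights": n_nights,
            "minutes_conserved": conserved}


def test_calibration(seed: int = 0, n_reps: int = 200, n: int = 9, alpha: float = 0.05) -> dict:
    """Null-simulation type-I error of the t test, ANOVA and Games-Howell.

    All groups are drawn from the same normal distribution; the Games-Howell
    rate is familywise over the three pairwise comparisons.  Also returns
    the two algebraic identities: |p_GH - p_Welch| at k = 2 and |F - t^2|
    at k = 2 on a fixed draw.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(103,)))
    hits = {"t": 0, "anova": 0, "games_howell": 0}
    for _ in range(n_reps):
        g = [rng.normal(10.0, 2.0, n) for _ in range(3)]
        hits["t"] += t_test_two_tailed(g[0], g[1]).p < alpha
        hits["anova"] += one_way_anova(g).p < alpha
        hits["games_howell"] += any(r.p < alpha for r in games_howell(g))
    x, y = rng.normal(0.0, 1.0, 9), rng.normal(0.4, 2.0, 7)
    gh2 = games_howell([x, y])[0]
    tt_w = t_test_two_tailed(x, y)
    tt_s = t_test_two_tailed(x, y, variant="student")
    f2 = one_way_anova([x, y])
    return {
        "type1": {k: v / n_reps for k, v in hits.items()},
        "n_reps": n_reps,
        "gh_vs_welch_abs_diff": abs(gh2.p - tt_w.p),
        "anova_f_vs_t2_abs_diff": abs(f2.statistic - tt_s.statistic**2),
    }


def lf_decline_detection_power(
    seed: int = 0,
    n_reps: int = 50,
    duration_min: int = 120,
    alpha: float = 0.05,
) -> dict:
    """Power to detect the declining-LF day pattern in a two-arm cohort.

    Each replicate simulates the default cohort design (n = 9 per group,
    days 1/5/9, the active arm's LF base amplitude falling 30 -> 20 -> 15 ms
    while the control arm stays at 30 ms), runs the full pipeline on all 54
    nights, and tests the within-group day contrasts of the night LF value
    with Games-Howell.  A replicate reproduces the pattern when both of the
    active arm's day-1 contrasts (vs day 5 and vs day 9) are significant.
    Nights are shortened to ``duration_min`` to keep the study tractable;
    the day effect acts on per-minute spectral means, so night length only
    changes within-night averaging noise.
    """
    base = np.random.SeedSequence(seed, spawn_key=(104,))
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in base.spawn(n_reps)]
    pattern_hits = 0
    control_false = 0
    for rep_seed in child_seeds:
        design = CohortDesign(
            duration_min=duration_min, onset_latency_min=10, master_seed=rep_seed
        )
        cohort = generate_cohort(design)
        lf: dict = {g: {d: [] for d in design.days} for g in design.groups}
        for (g, _subj, d), night in cohort.items():
            res = process_night(night.rri, night.accel)
            lf[g][d].append(res.summary.lf_amp)
        gh_mi = {
            r.label: r.p
            for r in games_howell(
                [lf["Mi"][d] for d in design.days],
                labels=[f"day {d}" for d in design.days],
            )
        }
        pattern_hits += (
            gh_mi["day 1 vs day 5"] < alpha and gh_mi["day 1 vs day 9"] < alpha
        )
        gh_nmi = games_howell([lf["nMi"][d] for d in design.days])
        control_false += any(r.p < alpha for r in gh_nmi)
    return {
        "power": pattern_hits / n_reps,
        "control_familywise_rate": control_false / n_reps,
        "n_reps": n_reps,
        "n_per_group": 9,
    }
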