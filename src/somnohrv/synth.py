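"""Synthetic overnight recordings with known ground truth.

Real overnight wearable recordings (millisecond R-R intervals plus 125 Hz
3-axis accelerometry) are emulated so that every downstream stage —
artifact gating, spectral LF/HF estimation, actigraphic sleep-onset
detection, autonomic staging and the trial statistics — can be tested
against a known truth.

Model
-----
* Stage dynamics: a first-order Markov chain over
  ``{WAKE, S, PS_SHALLOW, PS_DEEP}`` on 60 s epochs, preceded by a scripted
  sleep-onset latency of pure WAKE.
* Tachogram: additive sinusoidal modulation of the R-R interval,

  ``RR_i = meanRR + A_LF(stage) sin(2 pi f_LF t_i) + A_HF(stage) sin(2 pi f_HF t_i) + eps_i``

  with ``t_i`` the cumulative beat time, ``f_LF`` inside 0.05-0.15 Hz and
  ``f_HF`` inside 0.15-0.40 Hz.  A tone of amplitude ``A`` contributes
  band power ``A^2 / 2`` (ms^2), so per-stage LF/HF power ratios are known
  in closed form.
* Acceleration: Gaussian sensor noise around a constant 1 g gravity offset
  on the z axis, plus movement bursts — short oscillatory packets (or
  rectangular pulses when scripted) whose rate per minute depends on the
  stage.  Every burst is returned as ground truth.

All randomness flows from a single seed through
``numpy.random.SeedSequence``; per-(group, subject, day) streams are spawned
with ``spawn_key=(group_index, subject, day)`` so any night is reproducible
in isolation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .series import AccelSeries, RRISeries

__all__ = [
    "STAGES",
    "WAKE",
    "S",
    "PS_SHALLOW",
    "PS_DEEP",
    "LF_BAND",
    "HF_BAND",
    "StageSequence",
    "AutonomicProfile",
    "Burst",
    "BurstSpec",
    "NightSpec",
    "SyntheticNight",
    "CohortDesign",
    "default_transitions",
    "stationary_distribution",
    "generate_hypnogram",
    "generate_rri",
    "generate_accel",
    "generate_night",
    "generate_cohort",
]

WAKE, S, PS_SHALLOW, PS_DEEP = "WAKE", "S", "PS_SHALLOW", "PS_DEEP"
STAGES = (WAKE, S, PS_SHALLOW, PS_DEEP)
SLEEP_STAGES = (S, PS_SHALLOW, PS_DEEP)

LF_BAND = (0.05, 0.15)
HF_BAND = (0.15, 0.40)


# ---------------------------------------------------------------------------
# Stage sequences


@dataclass
class StageSequence:
    """Ground-truth per-epoch stage labels on a fixed epoch grid."""

    labels: np.ndarray  # array of strings from STAGES
    epoch_length_s: float = 60.0
    onset_latency_min: int = 0

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=object)
        bad = set(self.labels) - set(STAGES)
        if bad:
            raise ValueError(f"unknown stage labels: {sorted(bad)}")
        if self.epoch_length_s <= 0:
            raise ValueError("epoch_length_s must be positive")
        if self.onset_latency_min > 0:
            lead = self.labels[: min(self.onset_latency_min, len(self.labels))]
            if not np.all(lead == WAKE):
                raise ValueError("leading latency epochs must be WAKE")

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def duration_s(self) -> float:
        return len(self.labels) * self.epoch_length_s

    def stage_at(self, t_s: np.ndarray) -> np.ndarray:
        """Stage label at each time (s); times past the end get the last epoch."""
        idx = np.clip(
            (np.asarray(t_s, float) // self.epoch_length_s).astype(int),
            0,
            len(self.labels) - 1,
        )
        return self.labels[idx]

    def fractions(self) -> dict:
        n = max(len(self.labels), 1)
        return {s: float(np.mean(self.labels == s)) for s in STAGES}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"epoch_index": np.arange(len(self.labels)), "label": self.labels}
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def default_transitions() -> pd.DataFrame:
    """Default per-epoch stage transition matrix (rows sum to 1).

    Dwell times are geometric (mean 1/(1 - stay) epochs).  The chain mixes
    within a few epochs (second eigenvalue ~0.68), so a single night of a
    few hundred epochs visits all four states and its empirical stage
    fractions track the stationary distribution, which is approximately
    3% WAKE, 42% S, 14% shallow and 41% deep parasympathetic sleep — an
    operating point at which the staging rule's default per-night quantile
    threshold (deep = top 40% of sleep HF amplitude) is self-consistent.
    """
    m = pd.DataFrame(
        [
            # WAKE    S     SHALLOW  DEEP
            [0.600, 0.200, 0.120, 0.080],  # from WAKE
            [0.015, 0.785, 0.080, 0.120],  # from S
            [0.020, 0.270, 0.510, 0.200],  # from PS_SHALLOW
            [0.010, 0.110, 0.080, 0.800],  # from PS_DEEP
        ],
        index=list(STAGES),
        columns=list(STAGES),
    )
    return m


def _validate_transitions(transitions: pd.DataFrame) -> np.ndarray:
    t = transitions.loc[list(STAGES), list(STAGES)].to_numpy(float)
    if np.any(t < 0):
        raise ValueError("transition probabilities must be non-negative")
    if not np.allclose(t.sum(axis=1), 1.0, atol=1e-9):
        raise ValueError("transition rows must sum to 1")
    return t


def stationary_distribution(transitions: pd.DataFrame) -> dict:
    """Stationary distribution of the stage chain via eigen-decomposition."""
    t = _validate_transitions(transitions)
    vals, vecs = np.linalg.eig(t.T)
    k = int(np.argmin(np.abs(vals - 1.0)))
    v = np.real(vecs[:, k])
    v = np.abs(v) / np.abs(v).sum()
    return dict(zip(STAGES, (float(x) for x in v)))


def generate_hypnogram(
    duration_min: int,
    transitions: pd.DataFrame | None = None,
    onset_latency_min: int = 15,
    seed: int | np.random.Generator = 0,
    consolidation_min: int = 10,
) -> StageSequence:
    """Simulate a ground-truth stage sequence on 1-min epochs.

    The first ``onset_latency_min`` epochs are WAKE; from sleep onset the
    chain starts in PS_SHALLOW (light sleep first) and evolves by the
    first-order transition matrix.  Sleep onset is consolidated: during the
    first ``consolidation_min`` epochs after onset, transitions back to WAKE
    are suppressed (redistributed over the sleep states), so the scripted
    latency is the night's true sustained sleep onset.
    """
    if duration_min < 0 or onset_latency_min < 0:
        raise ValueError("durations must be non-negative")
    if duration_min < onset_latency_min:
        raise ValueError("duration_min must be >= onset_latency_min")
    t = _validate_transitions(
        default_transitions() if transitions is None else transitions
    )
    # transition rows with the WAKE column removed and renormalized, used
    # inside the post-onset consolidation window (undefined for a row that
    # can only go to WAKE, where the original row is kept)
    wake_idx = STAGES.index(WAKE)
    t_nowake = t.copy()
    t_nowake[:, wake_idx] = 0.0
    sums = t_nowake.sum(axis=1, keepdims=True)
    ok_rows = sums[:, 0] > 0
    t_nowake[ok_rows] /= sums[ok_rows]
    t_nowake[~ok_rows] = t[~ok_rows]

    rng = np.random.default_rng(seed)
    labels = [WAKE] * onset_latency_min
    n_rest = duration_min - onset_latency_min
    if n_rest > 0:
        state = STAGES.index(PS_SHALLOW) if onset_latency_min > 0 else STAGES.index(WAKE)
        labels.append(STAGES[state])
        for step in range(1, n_rest):
            consolidating = onset_latency_min > 0 and step < consolidation_min
            rows = t_nowake if consolidating else t
            state = rng.choice(4, p=rows[state])
            labels.append(STAGES[state])
    return StageSequence(
        np.array(labels, dtype=object), 60.0, onset_latency_min
    )


# ---------------------------------------------------------------------------
# R-R interval generation


def _stage_map(values, default: float) -> dict:
    out = {s: float(default) for s in STAGES}
    if values is not None:
        if np.isscalar(values):
            out = {s: float(values) for s in STAGES}
        else:
            out.update({k: float(v) for k, v in dict(values).items()})
    return out


@dataclass
class AutonomicProfile:
    """Stage-dependent tachogram model parameters.

    ``lf_amp_ms`` / ``hf_amp_ms`` map each stage to a sinusoidal modulation
    amplitude in ms.  Carrier frequencies must lie strictly inside the LF
    (0.05-0.15 Hz) and HF (0.15-0.40 Hz) bands.  The noise term is white
    Gaussian, truncated at +/- 5 SD so the positivity guarantee checked at
    construction holds for every realized beat.
    """

    mean_rr_ms: float = 900.0
    noise_sd_ms: float = 20.0
    lf_freq_hz: float = 0.10
    hf_freq_hz: float = 0.25
    lf_amp_ms: dict = field(default_factory=dict)
    hf_amp_ms: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.lf_amp_ms = _stage_map(self.lf_amp_ms or 0.0, 0.0)
        self.hf_amp_ms = _stage_map(self.hf_amp_ms or 0.0, 0.0)
        if not 400.0 <= self.mean_rr_ms <= 1500.0:
            raise ValueError("mean_rr_ms must lie in [400, 1500] ms")
        if not LF_BAND[0] < self.lf_freq_hz < LF_BAND[1]:
            raise ValueError("lf_freq_hz must lie strictly inside 0.05-0.15 Hz")
        if not HF_BAND[0] < self.hf_freq_hz < HF_BAND[1]:
            raise ValueError("hf_freq_hz must lie strictly inside 0.15-0.40 Hz")
        if self.noise_sd_ms < 0:
            raise ValueError("noise_sd_ms must be >= 0")
        amps = list(self.lf_amp_ms.values()) + list(self.hf_amp_ms.values())
        if any(a < 0 for a in amps):
            raise ValueError("modulation amplitudes must be >= 0")
        worst = max(
            self.lf_amp_ms[s] + self.hf_amp_ms[s] for s in STAGES
        )
        if self.mean_rr_ms - worst - 5.0 * self.noise_sd_ms <= 0:
            raise ValueError(
                "modulation amplitude too large: R-R intervals could reach zero"
            )

    def scaled(self, lf_factor: float = 1.0, hf_factor: float = 1.0) -> "AutonomicProfile":
        return replace(
            self,
            lf_amp_ms={s: a * lf_factor for s, a in self.lf_amp_ms.items()},
            hf_amp_ms={s: a * hf_factor for s, a in self.hf_amp_ms.items()},
        )


def default_profile(base_lf_ms: float = 40.0, base_hf_ms: float = 40.0, **kw) -> AutonomicProfile:
    """Profile with the default stage contrast in autonomic balance.

    Relative to the (base_lf, base_hf) amplitudes: S sleep is sympathetic
    dominant (full LF, quarter HF), shallow parasympathetic sleep is
    balanced at just under half amplitude, deep parasympathetic sleep
    mirrors S, and WAKE resembles S with slightly reduced LF.  With the
    default 20 ms beat noise, these amplitudes put the per-stage LF/HF
    band-power ratios near 4 (S), 0.7 (shallow) and 0.13 (deep) after
    resampling — clearly separated sympathetic-dominant, balanced, and
    vagal-dominant regimes.
    """
    lf = {WAKE: 0.80 * base_lf_ms, S: 1.00 * base_lf_ms,
          PS_SHALLOW: 0.45 * base_lf_ms, PS_DEEP: 0.25 * base_lf_ms}
    hf = {WAKE: 0.30 * base_hf_ms, S: 0.25 * base_hf_ms,
          PS_SHALLOW: 0.45 * base_hf_ms, PS_DEEP: 1.00 * base_hf_ms}
    return AutonomicProfile(lf_amp_ms=lf, hf_amp_ms=hf, **kw)


def generate_rri(
    stages: StageSequence,
    profile: AutonomicProfile,
    seed: int | np.random.Generator = 0,
) -> RRISeries:
    """Simulate a beat-to-beat R-R interval series over the stage sequence.

    Intervals are rounded to integer milliseconds, matching the 1 ms timing
    resolution of the recording device.
    """
    rng = np.random.default_rng(seed)
    duration_ms = stages.duration_s * 1000.0
    epoch_ms = stages.epoch_length_s * 1000.0
    lf_w = 2.0 * math.pi * profile.lf_freq_hz
    hf_w = 2.0 * math.pi * profile.hf_freq_hz
    lf_amp = profile.lf_amp_ms
    hf_amp = profile.hf_amp_ms
    labels = stages.labels
    n_epochs = len(labels)
    mean_rr = profile.mean_rr_ms
    sd = profile.noise_sd_ms

    # pre-draw noise in blocks; beats per night ~ duration / mean_rr
    est = int(duration_ms / mean_rr * 1.3) + 16
    noise = np.clip(rng.standard_normal(est) * sd, -5.0 * sd, 5.0 * sd) if sd > 0 else np.zeros(est)

    rri = []
    t = 0.0  # ms, cumulative
    k = 0
    while t < duration_ms:
        ep = min(int(t / epoch_ms), n_epochs - 1)
        st = labels[ep]
        ts = t / 1000.0
        if k >= noise.size:  # rare: extend the noise block
            extra = np.clip(rng.standard_normal(1024) * sd, -5 * sd, 5 * sd) if sd > 0 else np.zeros(1024)
            noise = np.concatenate([noise, extra])
        rr = (
            mean_rr
            + lf_amp[st] * math.sin(lf_w * ts)
            + hf_amp[st] * math.sin(hf_w * ts)
            + noise[k]
        )
        k += 1
        rr = max(round(rr), 1.0)
        rri.append(rr)
        t += rr
    return RRISeries(np.asarray(rri, dtype=float))


# ---------------------------------------------------------------------------
# Acceleration generation


@dataclass(frozen=True)
class Burst:
    """Ground-truth movement burst (times in s, amplitude = peak dynamic g)."""

    t_start_s: float
    duration_s: float
    amplitude_g: float
    shape: str = "packet"  # "packet" (Hann-enveloped cosine) or "rect"

    @property
    def t_end_s(self) -> float:
        return self.t_start_s + self.duration_s


@dataclass
class BurstSpec:
    """Stage-dependent movement-burst statistics for the accelerometer model.

    Rates are bursts per minute.  Waking movement is modeled as ~1 s
    oscillatory packets every ~30 s; movements during sleep are rarer and
    shorter (posture shifts).  Amplitudes are log-normal around the stage
    median; waking movements occasionally exceed the 0.5 g artifact
    threshold.
    """

    rate_per_min: dict = field(
        default_factory=lambda: {WAKE: 2.0, S: 0.08, PS_SHALLOW: 0.05, PS_DEEP: 0.01}
    )
    duration_s: dict = field(
        default_factory=lambda: {WAKE: 1.0, S: 0.5, PS_SHALLOW: 0.5, PS_DEEP: 0.5}
    )
    median_amplitude_g: dict = field(
        default_factory=lambda: {WAKE: 0.30, S: 0.12, PS_SHALLOW: 0.12, PS_DEEP: 0.10}
    )
    amplitude_log_sd: float = 0.4
    carrier_hz: float = 1.0
    noise_sd_g: float = 0.003

    def __post_init__(self) -> None:
        self.rate_per_min = _stage_map(self.rate_per_min, 0.0)
        self.duration_s = _stage_map(self.duration_s, 0.5)
        self.median_amplitude_g = _stage_map(self.median_amplitude_g, 0.1)
        if any(r < 0 for r in self.rate_per_min.values()):
            raise ValueError("burst rates must be >= 0")
        if any(d <= 0 for d in self.duration_s.values()):
            raise ValueError("burst durations must be positive")
        if any(a < 0 for a in self.median_amplitude_g.values()):
            raise ValueError("burst amplitudes must be >= 0 g")


def _packet_wave(burst: Burst, fs: float, carrier_hz: float = 1.0) -> np.ndarray:
    """Sampled burst waveform; a packet peaks at exactly ``amplitude_g``."""
    n = max(int(round(burst.duration_s * fs)), 1)
    tt = np.arange(n) / fs
    if burst.shape == "rect":
        return np.full(n, burst.amplitude_g)
    env = 0.5 * (1.0 - np.cos(2.0 * math.pi * tt / burst.duration_s))
    return burst.amplitude_g * env * np.cos(
        2.0 * math.pi * carrier_hz * (tt - burst.duration_s / 2.0)
    )


def generate_accel(
    stages: StageSequence,
    burst_spec: BurstSpec | None = None,
    seed: int | np.random.Generator = 0,
    scripted_bursts: list[Burst] | None = None,
    fs: float = 125.0,
) -> tuple[AccelSeries, list[Burst]]:
    """Simulate 125 Hz 3-axis acceleration with ground-truth bursts.

    Returns the series and the full list of bursts (random per-stage bursts
    plus any ``scripted_bursts``), sorted by start time.  A packet burst of
    amplitude ``A`` reaches peak dynamic magnitude ``A`` at its center.
    """
    spec = burst_spec if burst_spec is not None else BurstSpec()
    rng = np.random.default_rng(seed)
    n = int(round(stages.duration_s * fs))
    # float32 throughout: ample precision for g-scale signals, half the memory
    if spec.noise_sd_g > 0:
        xyz = rng.standard_normal((n, 3), dtype=np.float32) * np.float32(spec.noise_sd_g)
    else:
        xyz = np.zeros((n, 3), dtype=np.float32)
    xyz[:, 2] += np.float32(1.0)  # gravity on z

    bursts: list[Burst] = []
    epoch_s = stages.epoch_length_s
    for e, st in enumerate(stages.labels):
        rate = spec.rate_per_min[st] * (epoch_s / 60.0)
        for _ in range(rng.poisson(rate)):
            dur = spec.duration_s[st]
            t0 = e * epoch_s + rng.uniform(0.0, max(epoch_s - dur, 0.0))
            amp = spec.median_amplitude_g[st] * math.exp(
                rng.normal(0.0, spec.amplitude_log_sd)
            )
            bursts.append(Burst(t0, dur, amp, "packet"))
    if scripted_bursts:
        bursts.extend(scripted_bursts)
    bursts.sort(key=lambda b: b.t_start_s)

    for b in bursts:
        i0 = int(round(b.t_start_s * fs))
        wave = _packet_wave(b, fs, spec.carrier_hz)
        i1 = min(i0 + wave.size, n)
        if i0 >= n or i1 <= max(i0, 0):
            continue
        xyz[max(i0, 0):i1, 0] += wave[max(i0, 0) - i0 : i1 - i0]
    return AccelSeries(xyz, fs=fs), bursts


# ---------------------------------------------------------------------------
# Whole nights and cohorts


@dataclass
class NightSpec:
    """Everything needed to simulate one subject-night."""

    duration_min: int = 360
    onset_latency_min: int = 15
    base_lf_ms: float = 40.0
    base_hf_ms: float = 40.0
    mean_rr_ms: float = 900.0
    noise_sd_ms: float = 20.0
    transitions: pd.DataFrame | None = None
    burst_spec: BurstSpec | None = None


@dataclass
class SyntheticNight:
    """One simulated night plus its complete ground truth."""

    rri: RRISeries
    accel: AccelSeries
    stages: StageSequence
    bursts: list
    profile: AutonomicProfile
    spec: NightSpec

    @property
    def true_sleep_min(self) -> int:
        return int(np.sum(np.isin(self.stages.labels, SLEEP_STAGES)))


def generate_night(
    spec: NightSpec | None = None,
    seed: int | np.random.SeedSequence = 0,
    scripted_bursts: list[Burst] | None = None,
) -> SyntheticNight:
    """Simulate a complete night (hypnogram, RRI, acceleration) from one seed."""
    spec = spec if spec is not None else NightSpec()
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    seeds = ss.spawn(3)
    stages = generate_hypnogram(
        spec.duration_min,
        spec.transitions,
        spec.onset_latency_min,
        np.random.default_rng(seeds[0]),
    )
    profile = default_profile(
        spec.base_lf_ms,
        spec.base_hf_ms,
        mean_rr_ms=spec.mean_rr_ms,
        noise_sd_ms=spec.noise_sd_ms,
    )
    rri = generate_rri(stages, profile, np.random.default_rng(seeds[1]))
    accel, bursts = generate_accel(
        stages, spec.burst_spec, np.random.default_rng(seeds[2]), scripted_bursts
    )
    return SyntheticNight(rri, accel, stages, bursts, profile, spec)


@dataclass
class CohortDesign:
    """Two-arm, three-day measurement design with per-cell night parameters.

    ``base_lf_ms[group]`` maps each measurement day to the LF modulation
    base amplitude for that (group, day) cell; analogously for HF.  The
    default design mirrors the study conditions: n = 9 per group, days
    1/5/9, the mindfulness (Mi) arm's LF amplitude declining 30 -> 20 -> 15
    ms across days while the control (nMi) arm stays flat.
    """

    n_per_group: int = 9
    groups: tuple = ("Mi", "nMi")
    days: tuple = (1, 5, 9)
    base_lf_ms: dict = field(
        default_factory=lambda: {
            "Mi": {1: 30.0, 5: 20.0, 9: 15.0},
            "nMi": {1: 30.0, 5: 30.0, 9: 30.0},
        }
    )
    base_hf_ms: dict = field(
        default_factory=lambda: {
            "Mi": {1: 30.0, 5: 30.0, 9: 30.0},
            "nMi": {1: 30.0, 5: 30.0, 9: 30.0},
        }
    )
    duration_min: int = 360
    onset_latency_min: int = 15
    subject_sd_frac: float = 0.10  # between-subject log-scale amplitude spread
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        for g in self.groups:
            for d in self.days:
                if d not in self.base_lf_ms.get(g, {}) or d not in self.base_hf_ms.get(g, {}):
                    raise ValueError(f"missing amplitude for cell ({g}, day {d})")

    def cell_truth(self) -> pd.DataFrame:
        rows = [
            {
                "group": g,
                "day": d,
                "base_lf_ms": self.base_lf_ms[g][d],
                "base_hf_ms": self.base_hf_ms[g][d],
            }
            for g in self.groups
            for d in self.days
        ]
        return pd.DataFrame(rows)


def generate_cohort(design: CohortDesign) -> dict:
    """Simulate every (group, subject, day) night of a cohort design.

    Returns ``{(group, subject_index, day): SyntheticNight}``.  Each night's
    random stream is spawned from the master seed with
    ``spawn_key=(group_index, subject_index, day)``, so identical designs
    yield byte-identical cohorts and any single night can be regenerated.
    A per-subject log-normal factor (SD ``subject_sd_frac``) scales both
    amplitudes, constant across that subject's days.
    """
    nights: dict = {}
    for gi, g in enumerate(design.groups):
        for subj in range(design.n_per_group):
            subj_ss = np.random.SeedSequence(
                design.master_seed, spawn_key=(gi, subj)
            )
            factor = math.exp(
                np.random.default_rng(subj_ss).normal(0.0, design.subject_sd_frac)
            )
            for d in design.days:
                night_ss = np.random.SeedSequence(
                    design.master_seed, spawn_key=(gi, subj, d)
                )
                spec = NightSpec(
                    duration_min=design.duration_min,
                    onset_latency_min=design.onset_latency_min,
                    base_lf_ms=design.base_lf_ms[g][d] * factor,
                    base_hf_ms=design.base_hf_ms[g][d] * factor,
                )
                nights[(g, subj, d)] = generate_night(spec, night_ss)
    return nights
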