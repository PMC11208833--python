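# Methods

`somnohrv` implements a complete overnight autonomic sleep analysis for
wearable recordings: beat-to-beat R-R intervals (RRI, ms, 1 ms timing
resolution) plus 125 Hz 3-axis accelerometry per night, analyzed to
per-minute LF/HF spectral indices, an actigraphic sleep onset, a
three-class autonomic hypnogram, and two-arm/three-day trial statistics.
Because no participant recordings are public, the package also contains a
synthetic-night generator with complete ground truth; every downstream
stage is validated by recovery studies against that truth.

## Signal model and preprocessing

**Movement gating.** "Dynamic" acceleration is the vector magnitude after
subtracting the per-axis median (a robust estimate of the constant 1 g
gravity component for a night spent lying down). An RR interval, spanning
`[t_{i-1}, t_i)` with `t_{-1} = 0`, is flagged as a movement artifact iff
any dynamic-acceleration sample in that span reaches **0.5 g**. Flagging
never alters values, only flags.

**Ectopic/outlier filtering.** Intervals outside **[300, 2000] ms**, or
deviating more than **20%** from the median of the 5 previous accepted
intervals, are flagged. The jump rule engages only after 5 accepted
intervals exist, and ignores movement flags so the two passes commute.
Standard HRV practice; thresholds are config-exposed.

**Even resampling.** Clean beats `(t_i, RR_i)` are cubic-spline
interpolated onto a uniform **4 Hz** grid starting at t = 0. Grid points
whose nearest clean beat is more than **5 s** away are masked invalid
rather than bridged: long movement bouts must yield invalid spectral
windows, not fabricated data. Flagged intervals can alternatively be kept
(`method`/flag switches) but exclusion is the default.

## Spectral indices (per minute)

Non-overlapping **60 s** windows of the tachogram (240 samples) are
mean-removed, **Hann**-tapered and Fourier transformed; the one-sided
periodogram uses density scaling so band integrals estimate variance in
ms². A window needs ≥ **80%** valid grid points, else its frame is
invalid; masked samples inside a valid window are set to the window mean
(zero power). A rectangular-window mode exists for oracle checks.

Band powers are discrete integrals over half-open bands — LF
**[0.05, 0.15) Hz**, HF **[0.15, 0.40) Hz** — so the 0.15 Hz bin belongs
to HF and the bands partition the spectrum exactly (additivity holds to
machine precision; a band closed at Nyquist keeps the last bin). The
frequency resolution at 60 s is 1/60 Hz; no zero padding by default.

The per-minute **LF value** and **HF value** are the square roots of the
integrated band powers (ms), which damps the variance of the per-minute
estimate; the **LF/HF ratio** uses band powers. A frame whose HF power is
below 1e-12 ms² is invalid (no infinite ratios). The per-night LF/HF is
the mean of per-minute ratios by default; the ratio-of-mean-powers
alternative is config-exposed (`ratio_mode`).

## Actigraphy

Activity per 60 s epoch is the zero-crossing count of the band-passed
(0.25–3 Hz, 2nd-order Butterworth, forward-backward) dynamic acceleration
after zeroing a 0.01 g deadband — the activity metric wrist-actigraphy
scoring equations were fit to; max-magnitude and integration modes are
available. Epochs are scored with the published 1-minute Cole et al.
weighted sum over epochs t−4..t+2 (weights 106, 54, 58, 76, 230, 74, 67,
scale 0.001; SLEEP iff the sum < 1; boundary epochs zero-padded). The
kernel, scale and threshold are injectable. Webster rescoring rules are
off by default.

Sleep onset is the first epoch starting a run of ≥ **10** consecutive
SLEEP epochs (persistence suppresses transient false sleep); total sleep
time counts SLEEP epochs at/after onset. The kernel's forward terms smear
waking activity ~3 epochs into sleep, so detected onset is biased about
+3 min — well inside the ±5 min recovery target.

## Autonomic staging

Each actigraphic sleep minute with a valid frame is staged:

* **S sleep** (sympathetic dominance) if LF/HF ≥ θ_s,
* else **PS deep** if the HF amplitude ≥ the θ_d quantile of that night's
  valid sleep-epoch HF amplitudes,
* else **PS shallow**.

Defaults: θ_s = 1.5 × the night's median sleep LF/HF; θ_d = 0.60. The
thresholds are per-night adaptive (robust to inter-subject HRV scale) and
both are overridable with absolute values. Minutes with invalid frames
inherit the previous minute's label (first such minute: PS shallow).
Stage minutes sum to total sleep time by construction. The staging rule is
this package's explicit operationalization of autonomic-balance staging;
it is validated purely by ground-truth recovery on synthetic nights, never
against clinical polysomnography.

## Synthetic-night generator

**Stages** follow a first-order Markov chain on 1-min epochs over
{WAKE, S, PS shallow, PS deep}, preceded by a scripted all-WAKE onset
latency (default 15 min). The default transition matrix mixes within a few
epochs (|λ₂| ≈ 0.68) and has stationary fractions ≈ 3/42/14/41% — chosen
so the staging rule's default quantile (deep = top 40% of sleep HF) is
self-consistent with the generated stage mix, i.e. the generator emulates
the three-stage alternation the classifier assumes rather than any
empirical stage-time distribution. The first 10 min after onset are
wake-free (consolidated onset), making the scripted latency the night's
true sustained sleep onset.

**Tachogram.** `RR_i = meanRR + A_LF(stage)·sin(2π f_LF t_i) +
A_HF(stage)·sin(2π f_HF t_i) + ε_i` with cumulative beat time `t_i`,
carriers 0.10 / 0.25 Hz strictly inside the bands, mean RR 900 ms and
white noise SD 20 ms (plausibility defaults, config-exposed), intervals
rounded to integer ms. A tone of amplitude A contributes A²/2 ms² of band
power, so per-stage ratios are analytic. Construction rejects profiles
that could produce RR ≤ 0 (noise is truncated at ±5 SD to keep the
guarantee). Note one non-obvious consequence of beat-domain noise: after
resampling, the 400 ms² of white beat noise concentrates below the ~0.55
Hz beat-rate Nyquist, leaving in-band noise floors of roughly 75 (LF) and
180 (HF) ms² that damp realized LF/HF contrasts relative to the pure-tone
ratios.

**Default stage contrast** (base amplitudes 40/40 ms): LF multipliers
1.0 / 0.45 / 0.25 and HF multipliers 0.25 / 0.45 / 1.0 for S / shallow /
deep (WAKE: 0.8 / 0.3). With the noise floors above this puts realized
LF/HF near 4 / 0.7 / 0.13 — separated sympathetic-dominant, balanced and
vagal-dominant regimes.

**Acceleration.** Gaussian sensor noise (SD 0.003 g, float32) around 1 g
gravity on z, plus movement bursts: Hann-enveloped 1 Hz packets (peak =
the drawn amplitude) at stage-dependent Poisson rates — defaults 2/min in
WAKE (~1 s, median 0.3 g, log-normal spread so some exceed 0.5 g) and
0.01–0.08/min during sleep (~0.5 s, ~0.1 g). Rectangular bursts can be
scripted for exact artifact-gating oracles. Every burst is returned as
ground truth.

**Cohorts.** The default design mirrors the study conditions: two arms ×
9 subjects × measurement days 1/5/9, the active arm's LF base amplitude
declining 30 → 20 → 15 ms across days with a flat 30 ms control arm and
constant 30 ms HF. A per-subject log-normal factor (SD 10%) scales both
amplitudes, constant across that subject's days. All streams spawn from
one master seed with `spawn_key = (group_index, subject, day)`;
regeneration is byte-identical.

What the generator does **not** emulate: respiration and its coupling to
RSA, circadian trends within the night, apnea/arousal microstructure,
non-sinusoidal HRV, sensor drift and posture changes. Passing recovery
tests therefore demonstrates internal consistency of the pipeline under
the stated signal model, not clinical validity on real recordings.

## Trial statistics

Two-tailed two-sample t tests (Welch by default; Student available since
standard trial software reports both), Pearson r with the t-based p value,
one-way ANOVA, and Games-Howell post-hoc comparisons
(SE = √(s²ᵢ/nᵢ + s²ⱼ/nⱼ), q = |Δ|√2/SE, Welch–Satterthwaite df,
p from the studentized-range distribution computed by numerical
integration via `scipy.stats.studentized_range` — no table lookup; at
k = 2 it reduces exactly to the Welch t test). Bonferroni rechecking
multiplies raw p by k **uncapped** by default, so adjusted values can
exceed 1 (the α/k convention); capping is available. Degenerate inputs
follow explicit conventions: both-samples-zero-variance pairs give p = 1
(equal means) or the p = 0 limit (unequal means); all-identical ANOVA
input is an error.

The table builders emit the trial's three shapes from per-subject-night
summaries: group means/SD with between-group t and Pearson r per
(day, measure); within-group Games-Howell contrasts among the four
duration measures per day; and within-group day contrasts of LF, HF and
LF/HF with raw and Bonferroni-adjusted p (k = 3 day pairs). The Pearson
column pairs the two independent arms' subject vectors by within-group
subject order — a reporting convention only, exposed generically, since
no principled pairing of independent groups exists. Normality screening
is assumed upstream and out of scope. Day labels standardize on day 9.

## Validation studies and problem sizes

`somnohrv.validation` regenerates every study from scratch (all sizes are
the package's own choices):

* **Spectral fidelity** — noise-free two-tone nights: pooled and
  per-minute LF/HF = 1 within 10%; single-tone Parseval within 5%
  (observed: machine precision on exact-bin tones).
* **Artifact gating** — scripted ≥ 0.5 g rectangular bursts: the flagged
  set equals a brute-force burst-overlap scan exactly.
* **Onset recovery** — 50 nights cycling latencies 10/30/60 min
  (duration latency + 90 min): onset within ±5 min in ≥ 90% of nights.
* **Staging recovery** — 20 default nights of 360 min: pooled per-epoch
  agreement ≥ 80% (typically ~88%), with stage-minute conservation
  checked on every night.
* **Calibration** — 200 null replicates (three N(10, 2²) groups of 9):
  type-I error of t, ANOVA and familywise Games-Howell within
  [0.025, 0.10] at α = 0.05; the k = 2 identities hold to 1e-9.
* **Power** — 50 replicates of the default cohort with 120-min nights:
  both active-arm day-1 LF contrasts significant (Games-Howell,
  α = 0.05) in ≥ 90% of replicates (observed 100%), with the flat control
  arm's familywise rate near 0.05. Nights are shortened from the 360-min
  default because the day effect acts on per-minute spectral means; night
  length only changes within-night averaging noise.

## Known limitations

* The staging thresholds and the generator's stage mix are co-designed;
  real recordings with very different stage proportions would need the
  θ thresholds re-tuned (they are per-night adaptive but the quantile is
  fixed).
* Sleep-onset detection inherits the scoring kernel's ~3-min forward
  smear; latency estimates are biased slightly late.
* The between-arm Pearson column depends on an arbitrary subject pairing.
* No repeated-measures modeling: days are compared as independent groups,
  mirroring the trial's own scheme, even though subjects repeat across
  days.
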