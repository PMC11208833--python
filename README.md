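# somnohrv

Overnight autonomic sleep analysis from wearable recordings: beat-to-beat
R-R intervals (RRI) and 125 Hz 3-axis accelerometry in, per-minute LF/HF
heart-rate-variability indices, actigraphic sleep onset, a three-class
autonomic hypnogram, and two-arm trial statistics out.

It is written for sleep/HRV researchers who record cardiac potentials with
chest-worn sensors and want an open, testable version of the vendor-style
processing chain — plus a synthetic-night generator with complete ground
truth, so every stage can be validated without access to participant data.

## What it computes

1. **Preprocessing** — RR intervals overlapping body movement
   (gravity-removed acceleration ≥ 0.5 g) are flagged, ectopic/outlier
   beats removed ([300, 2000] ms bounds, 20% jump rule), and the clean
   beats cubic-spline resampled to a uniform 4 Hz tachogram with gap
   masking.
2. **Spectra** — per non-overlapping 60 s window, a Hann-tapered
   periodogram with density scaling; band powers
   `LF = ∫_{0.05}^{0.15} S(f) df`, `HF = ∫_{0.15}^{0.40} S(f) df` (ms²),
   the amplitudes `√LF`, `√HF` (ms), and the ratio LF/HF.
3. **Actigraphy** — zero-crossing activity counts per 60 s epoch and the
   Cole et al. weighted 7-epoch scoring
   `D_t = 0.001·(106 A_{t-4} + 54 A_{t-3} + 58 A_{t-2} + 76 A_{t-1} +
   230 A_t + 74 A_{t+1} + 67 A_{t+2})`, SLEEP iff `D_t < 1`; sleep onset =
   first run of ≥ 10 SLEEP epochs; total sleep time.
4. **Staging** — each sleep minute becomes S sleep (sympathetic dominant,
   LF/HF ≥ θ_s), PS deep (HF amplitude above the θ_d night quantile) or
   PS shallow; θ_s defaults to 1.5× the night median LF/HF, θ_d to 0.60.
5. **Trial statistics** — Welch t tests, Pearson r, one-way ANOVA,
   Games-Howell post-hoc comparisons (studentized-range p values), and
   uncapped Bonferroni adjustment (`p·k`, values > 1 reported as-is), with
   builders for the three standard trial table shapes.
6. **Synthetic data** — Markov-chain hypnograms, sinusoidally modulated
   RRI (`RR_i = meanRR + A_LF sin 2πf_LF t_i + A_HF sin 2πf_HF t_i + ε`),
   bursty accelerometry, and whole two-arm cohorts, all deterministic from
   one master seed.

See `docs/methods.md` for the model details, defaults and limitations.

## Worked example

```python
from somnohrv import NightSpec, generate_night, process_night

night = generate_night(NightSpec(duration_min=360, onset_latency_min=30), seed=7)
res = process_night(night.rri, night.accel)
print("onset epoch:", res.sw.onset_epoch)
print("total sleep (min):", res.tst_min)
print("stage minutes:", res.durations)
print("LF %.2f ms  HF %.2f ms  LF/HF %.2f" %
      (res.summary.lf_amp, res.summary.hf_amp, res.summary.lf_hf))
```

prints

```
onset epoch: 30
total sleep (min): 329.0
stage minutes: {'S': 145.0, 'PS_SHALLOW': 52.0, 'PS_DEEP': 132.0, 'total': 329.0}
LF 19.36 ms  HF 21.74 ms  LF/HF 1.95
```

The scripted 30-min latency is recovered exactly; stage minutes sum to the
total sleep time; and the night means are the averages of the valid
per-minute sleep frames (ms for the amplitudes, dimensionless for LF/HF).

The same pipeline runs from the shell:

```bash
somnohrv synth --out nights/ --seed 7          # write a synthetic cohort as CSV
somnohrv hrv   --rri nights/Mi_s0_d1_rri.csv --accel nights/Mi_s0_d1_accel.csv --out frames.csv
somnohrv sleep --accel nights/Mi_s0_d1_accel.csv --out sleep.csv
somnohrv stage --rri nights/Mi_s0_d1_rri.csv --accel nights/Mi_s0_d1_accel.csv --out hypnogram.csv
somnohrv run   --config run.yaml               # end-to-end with manifest + tables
```

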