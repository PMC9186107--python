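# adkit

Arousal-linked slow-drift analysis for multimodal neurophysiology sessions.

## The problem

Over the course of a ~2-hour recording session, an animal's arousal level
wanders slowly.  That wandering leaves fingerprints in every signal that can
be recorded at once: a low-dimensional **slow drift** in the spiking of a
cortical population, the power of spontaneous **prestimulus α (8–12 Hz)
oscillations** in scalp EEG, **pupil diameter**, and the rate of
**microsaccades** during fixation.  `adkit` is a tested, reusable pipeline
for quantifying these signals and their covariation in sessions from an
orientation-change detection task, plus a synthetic-session generator that
produces ground truth for validating every stage.

The core quantities, in the field's standard notation:

* **Slow drift** — per-neuron residual counts
  `r_i(t) = c_i(t) − mean_{t': θ(t')=θ(t)} c_i(t')` are binned with a 30-min
  sliding window (6-min step) and projected onto their first principal
  component, with weights sign-aligned to be majority-positive.
* **Residual α power** — 300-ms prestimulus EEG segments are
  average-rereferenced, screened, Hanning-windowed and zero-padded to a 1-Hz
  grid; the aperiodic background `log₁₀P(f) = c − χ·log₁₀f` is fit
  (3–50 Hz, excluding 7–14 Hz) and subtracted per electrode before
  averaging; α power is the mean residual over [8, 12) Hz.
* **Microsaccades** — velocity-threshold detection at 6× the median-based SD
  `σ = sqrt(median(v²) − median(v)²)` per component, elliptic criterion,
  ≥ 6 ms duration, < 100 ms separations merged, amplitude ≤ 1° and peak
  velocity ≤ 100 °/s.
* **Timescale** — the Gaussian-smoothing SD at which 10-fold cross-validated
  R² drops to 75% of its maximum, on a 1–90 min grid.
* **Cohort statistics** — per-session Pearson r between any two binned
  metrics, a Wilcoxon signed-rank test (exact up to n = 25) of the median r
  across sessions, cross-session null distributions, and per-subject
  z-scored variance-magnitude correlations.

See `docs/methods.md` for assumptions, parameter defaults, and limitations.

## Worked example

```python
import numpy as np
from adkit import SynthConfig, generate_session, analyze_session, pearson_r

cfg = SynthConfig(session_duration=120.0, eeg_rate=200.0, eye_rate=250.0, seed=7)
rec, truth = generate_session(cfg)          # spikes + EEG + eye + events
sm = analyze_session(rec)                   # all binned metrics, shared bins

for name in ("alpha", "pupil", "msrate", "drift"):
    s = sm.series[name]
    r, p = pearson_r(s.values, truth.latent.at(s.bin_centers * 60.0))
    print(f"corr({name:6s}, latent) = {r:+.3f}")
```

Output:

```
corr(alpha , latent) = -0.969
corr(pupil , latent) = +1.000
corr(msrate, latent) = -0.992
corr(drift , latent) = +0.997
```

The session's shared arousal latent is recovered with the expected signs:
α power falls while pupil dilates, microsaccades become rarer, and the
population drift rises.  A cohort-level run with statistics and CSV exports:

```python
from adkit import PipelineConfig, run_cohort

result = run_cohort(PipelineConfig(
    n_sessions=20, seed=11, out_dir="results/cohort",
    synth=dict(session_duration=120.0, eeg_rate=200.0, eye_rate=250.0)))
summ = result.correlations["alpha~drift"]
print(summ.median_r, summ.p)   # negative median r, signed-rank p << 0.05
```

A CLI mirrors the library for shell use:
`adkit simulate | detect-microsaccades | spectra | drift | timescale |
correlate | run | convert` (see `adkit --help`).

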