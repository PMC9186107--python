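# Methods

`adkit` links three simultaneously recorded views of a slowly varying
internal brain state over a ~2-hour recording session: residual prestimulus
alpha power from scalp EEG, a low-dimensional "slow drift" in the spiking of
a visual-cortex population, and arousal-linked eye metrics (pupil diameter,
microsaccade rate, reaction time, saccade velocity, behavioral outcome
rates).  This note documents the model assumptions, the estimation
procedures, the synthetic-data generator used for validation, and the
numerical choices that were genuinely open.

## Task and data model

A session consists of trials on an orientation-change detection task: a
sequence of 400-ms stimulus periods (a Gabor pair at 45° or 135°) separated
by prestimulus fixation periods drawn uniformly from 300–500 ms.  A trial
ends when the subject saccades to a changed stimulus within 400 ms (hit),
saccades to an unchanged stimulus (false alarm), or fixates past a change
(miss).  Recorded signals: per-neuron spike counts in a 400-ms window
starting 50 ms after each stimulus onset; 8-electrode scalp EEG at 1 kHz;
monocular eye position and pupil diameter at 1 kHz.

All analyses reduce signals to a common sliding-window time series: 30-min
windows stepped by 6 min from session start, value = window mean, bin center
at the window midpoint.  Half-open intervals `[t, t+30)` prevent double
counting; a 120-min session yields 16 bins.  One binning implementation is
shared by every metric so bin centers align exactly across modalities;
correlations between two metrics use only their common bins.

## Microsaccade detection

Velocity is computed per component with the five-point central difference
`v_t = rate * (x_{t+2} + x_{t+1} - x_{t-1} - x_{t-2}) / 6`, which implicitly
smooths over ±2 samples; raw first differences would inflate the threshold
estimate.  The per-component threshold is six times the median-based SD
`sqrt(median(v^2) - median(v)^2)` (robust to the saccades themselves), and a
sample is a candidate under the elliptic criterion
`(vx/6sx)^2 + (vy/6sy)^2 > 1`.  Candidate runs of at least 6 ms become
events; events separated by less than 100 ms are merged into one event
spanning both (merging rather than deletion preserves total displacement —
the literature's minimum-separation rule does not specify which).  Amplitude
is the Euclidean displacement between onset and offset positions.  After
merging, events with amplitude > 1° or peak velocity > 100 °/s are discarded
as ordinary saccades.  Detection quality is validated per session by the
main sequence: the Pearson correlation between amplitude and peak velocity
(≈ 0.98 on synthetic sessions; real recordings of this kind report ~0.84).

## Prestimulus EEG power

EEG is rereferenced to the session-wide electrode average.  A 300-ms segment
is cut from the start of every prestimulus period except each trial's first
(fixation has just been re-established there and eye variability is high).
Three screening rules, all computed from session-level statistics *before*
any rejection so each segment's fate is independent of the others':

1. any electrode's within-segment SD exceeds 10× that electrode's
   session-mean segment SD (amplitude artifact);
2. any electrode's within-segment SD is below 300 nV (flat channel);
3. the within-period SD of 1-D eye speed exceeds 2× the session-mean eye
   speed over all prestimulus periods (eye-movement contamination).

Rule 3 compares an SD to a mean; the units are heterogeneous but the rule is
implemented literally on eye speed, as stated in its source.  Note that by
design it removes most segments containing a microsaccade larger than
~0.15°: at the default 1.5 events/s rate, roughly a third of segments are
rejected.  That is the rule doing its job (keeping oculomotor transients out
of the EEG measure); a session generated without microsaccades loses < 5% of
segments to distribution tails.

Each kept segment is Hanning-windowed per electrode and zero-padded to 1 s
before the FFT, giving a 1-Hz analysis grid (the raw 300-ms grid has 3.33-Hz
spacing, too coarse for 4-Hz sliding windows); power at 1–50 Hz is retained,
scaled so the full-grid sum equals the windowed-signal energy.  Spectra are
averaged per electrode within each 30-min bin (bins with fewer than 10
segments are dropped).  The aperiodic background is then removed per bin and
electrode by a least-squares fit of `log10 P = c - chi * log10 f` over
3–50 Hz excluding 5–19 Hz.  The guard is that wide because a 300-ms Hanning
window smears an 8–12 Hz peak over roughly 5–19 Hz (mainlobe half-width
2/T ≈ 6.7 Hz); with a narrower guard the leaked peak tilts the fit and
imprints an inverted copy of the alpha modulation on every other band's
residual.  The fitted
power law is subtracted on the full grid and the residuals are averaged
across electrodes — removal strictly precedes electrode averaging.  Band
power is the mean residual over half-open bands theta [4,8), alpha [8,12),
beta [12,30), gamma [30,50); the frequency-resolved variant uses 4-Hz
windows stepped by 2 Hz (left edges 2–46).

## Slow drift

Stimulus tuning is removed by subtracting each neuron's session-mean
response per orientation from its counts; the residuals are binned with the
shared geometry and the bins × neurons matrix is centered per neuron and
decomposed by SVD.  The drift is the projection onto the first principal
component; `variance_explained` is the first squared singular value over the
total.  Neurons are not z-scored before the PCA (the procedure is defined on
residual counts; normalization is a separate modeling choice we do not
make).  Because a principal component's sign is arbitrary, the weights are
flipped to be majority-positive — larger drift then means higher firing in
most of the population, a common reference frame across sessions.  Exact
even ties flip toward a nonnegative weight sum.  Consequence worth stating:
negating the residuals leaves the weights unchanged and exactly negates the
drift; the output is a deterministic function of the data with no solver
ambiguity.

## Timescale estimation

The timescale of any binned series (computed from the 1-min-step binning
variant for temporal resolution) is estimated by cross-validated Gaussian
kernel smoothing: points are split into 10 random folds; each held-out point
is predicted by the Gaussian-weighted average of the retained points,
`sum w_j y_j / sum w_j` with `w_j = exp(-(t-t_j)^2 / (2 SD^2))`, for SDs of
1–90 min; R² is pooled over all held-out predictions about the global mean
(pooling is more stable than per-fold averaging at ~100 points).  The
timescale is the smallest SD *above* the R² argmax at which R² has dropped
to 75% of its maximum — scanning upward because stronger smoothing is what
destroys fast structure; if the curve never drops that far the estimate is
censored at 90 min.

Two estimator properties that users should know, both verified by the test
suite against a brute-force oracle: (1) for a noiseless trend the R² curve
peaks near SD = 1 min and *decays* with SD (wide kernels shrink predictions
toward the global mean), so "trend-like" series get moderate, not maximal,
timescales; (2) the 75% point saturates when the session is short relative
to the true timescale — recovering a 60-min timescale within a factor of two
requires roughly 4× that much data.  Estimator validation therefore uses
240-min synthetic latents for generator SDs {5, 15, 30, 60} min (median
estimates ≈ 8/23/39/47 min, strictly increasing, each within a factor of 2).

## Cohort statistics

A single within-session correlation between two slow, autocorrelated series
is unreliable ("nonsense correlation"), so inference is across sessions:
per-session Pearson r between the aligned binned series (sessions with fewer
than 3 common bins are excluded), then a two-sided Wilcoxon signed-rank test
of whether the median r is zero.  The signed-rank null is enumerated exactly
(by convolution over mid-ranks) up to n = 25 nonzero values and approximated
normally with tie and continuity corrections above; exact zeros are dropped.
Medians are reported pooled and per subject, with seeded percentile-bootstrap
95% CIs (10,000 resamples).  A cross-session null — correlating metric A
from one session with metric B from another, over the first min(len) bins of
every ordered pair — verifies the r distribution is centered on zero under
independence.  The variance-magnitude analysis asks whether fluctuation
*sizes* covary: per-session variances of both metrics are z-scored within
subject (so a between-subject variance difference cannot masquerade as an
association) and pooled into one Pearson correlation.  Sliding-frequency
p-values are reported uncorrected for the 23 windows, mirroring band-wise
reporting conventions; callers needing family-wise control should apply it
downstream.

## Synthetic sessions

The generator inverts the analysis: a single latent arousal process drives
all modalities, so every stage is a recovery problem with known truth.

* **Latent**: white noise convolved with a Gaussian kernel of SD
  `latent_timescale_sd` (default 30 min) on a 1-s grid, standardized;
  autocorrelation `exp(-dt^2/(4 SD^2))`.  Interpolated linearly wherever the
  session needs it (downstream binning is ≥ minutes, so a 1-s grid is ample).
* **Spikes**: `count ~ Poisson(exp(b_i + tuning_i(theta)/2 +
  drift_coupling * w_i * latent))`, baseline ~10 spikes/400 ms, loadings
  `w_i = ±|N(1, 0.4)|` with 85% positive signs.  Default
  `drift_coupling = 0.5` per latent SD.
* **EEG**: per electrode, an independent `1/f^chi` background (chi = 1,
  20 µV RMS) with slow multiplicative broadband drift (log-SD 0.2, ~10-min
  timescale, independent of the latent — real EEG is not
  amplitude-stationary), plus an alpha oscillation with a Gaussian spectral
  peak (center 10 Hz, spectral SD 1 Hz — a bump, not a rectangular band, as
  real alpha peaks are) whose amplitude is
  `10 µV * exp(alpha_coupling * latent)`, `alpha_coupling = -0.5`, plus
  theta (6 Hz) and low-beta (16 Hz) distractor rhythms (8 µV RMS) with their
  own slow amplitude fluctuations uncoupled to arousal.  The distractors
  matter: without band-specific variability, every frequency's residual
  would be a pure spectral-leakage proxy of the alpha envelope and the
  frequency scan would lose all selectivity.  Electrode independence also
  matters: a fully common oscillation would be annihilated by average
  rereferencing.
* **Eye**: slow fixational drift (Gaussian-low-passed noise, SD 0.05°,
  200-ms kernel) plus 0.001° tracker jitter; microsaccades arrive as a
  Poisson process at `1.5/s * exp(msrate_coupling * latent)`
  (`msrate_coupling = -0.3`) with a 150-ms refractory gap, amplitudes
  uniform on [0.05°, 1°], raised-cosine velocity pulses on the main sequence
  `v_peak ≈ 80 (°/s)/° * amplitude` with 10% lognormal scatter (durations
  `2a/v_peak` clipped to 6–30 ms), directions biased back toward fixation so
  gaze stays bounded.  No microsaccades are injected within (−0.15 s,
  +0.5 s) of a response saccade: fixational movements pause around large
  saccades, and the ground-truth event list stays unambiguous for detector
  scoring.  Hit/false-alarm trials get a 6°, 300 °/s response saccade at the
  drawn reaction time (150–350 ms) and a return saccade 300 ms later.
  Pupil = 1000 + 100 * pupil_coupling * latent + slow noise
  (`pupil_coupling = +1`).
* **Behavior**: each stimulus period changes with probability 0.35; hit
  probability `0.6 * exp(0.2 * latent)`, false-alarm probability
  `0.05 * exp(0.3 * latent)` — arousal makes responding more likely, giving
  the false-alarm-rate coupling its sign.

With the default signs (alpha down, pupil up, microsaccade rate down,
population rate up, false alarms up when arousal rises), the full pipeline
recovers the expected sign pattern of median within-session correlations:
alpha–pupil < 0, alpha–msrate > 0, alpha–drift < 0, drift–pupil > 0,
drift–msrate < 0.

What the generator does **not** emulate — and hence what passing tests do
not certify about real recordings: no EEG artifacts beyond what screening
rules are unit-tested on (no blinks, line noise, electrode pops), no
binocular disparity or blink gaps in the eye trace, no spike-sorting errors
or non-Poisson count dispersion, no attention/cueing structure, no
nonstationarity beyond the shared latent and the uncoupled slow EEG
amplitude drifts, and a strictly linear main sequence.  Real-data effect sizes will be smaller and messier; the
synthetic couplings are chosen to be physiologically plausible, not fitted
to any dataset.

## Problem sizes and numerical choices

Cohort-scale validation runs sample EEG at 200 Hz and eye at 250 Hz
(detector validation keeps the 1-kHz default; 300 ms must contain an integer
number of samples, which both satisfy); the type-I control (50 replicate
20-session cohorts with all couplings zero) uses 42-min sessions at
100/125 Hz with 4 electrodes and 20 neurons.  These sizes keep the full
validation suite and the reproduction script desk-sized while exercising
every code path; all defaults remain at the full study scale.

Degenerate inputs are errors, not silent results: zero-variance series
(correlation, PCA, cross-validation), all-rejected segment sets, nonpositive
power in the aperiodic fit range (named by bin and electrode), orientations
with no periods.  A flat eye trace yields zero detected events with a
warning.  Kernel weights that underflow entirely fall back to the nearest
retained point.  All randomness flows from explicit seeds through
`numpy.random.SeedSequence` spawning (cohort → session → stage), so cohort
runs are bit-reproducible.

## Known limitations

* The eye-speed screening rule rejects microsaccade-containing segments by
  construction (see above); studies needing those segments must relax it.
* Timescales are censored at 90 min and compress toward ~23 min when the
  session is shorter than ~4× the true timescale.
* The false-alarm-rate denominator (all completed trials per bin) is a
  convention; `fa_denominator="fa_miss"` is provided.
* Real-data ingestion is CSV-based (`adkit convert`); native tracker/array
  formats are out of scope.
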