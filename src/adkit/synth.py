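"""Synthetic multimodal recording sessions driven by a shared arousal latent.

A single slowly varying latent process stands in for the animal's arousal
level over a ~2-hour session.  It simultaneously

* scales per-neuron firing rates through majority-positive loadings
  (the population "slow drift"),
* inversely modulates the amplitude of a narrow-band 8-12 Hz EEG
  oscillation riding on a 1/f^chi aperiodic background,
* positively drives pupil diameter, and
* inversely drives the Poisson occurrence rate of microsaccades, whose
  amplitude and peak velocity obey a linear main-sequence law.

Every generated session carries its ground truth (latent trajectory, true
microsaccade list, neuron loadings) so each downstream analysis stage can be
validated as a recovery problem.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.fft import irfft, rfft, rfftfreq
from scipy import fft as sfft

from .session_io import SessionRecording

__all__ = [
    "LatentArousal",
    "SynthConfig",
    "GroundTruth",
    "generate_arousal_latent",
    "generate_events",
    "generate_spikes",
    "generate_eeg_and_eye",
    "generate_session",
]

# hard cap on the Poisson log-rate; beyond this the generator refuses
_LOG_RATE_CAP = math.log(1e6)


@dataclass
class LatentArousal:
    """Standardized slow arousal process on a regular time grid (seconds)."""

    time_grid: np.ndarray  # seconds from session start, strictly increasing
    value: np.ndarray      # zero mean, unit variance over the session
    timescale_sd: float    # minutes; SD of the generating Gaussian kernel

    def at(self, times_s) -> np.ndarray:
        """Linear interpolation of the latent at arbitrary session times."""
        return np.interp(np.asarray(times_s, float), self.time_grid, self.value)


@dataclass
class SynthConfig:
    """Parameters of one synthetic session.

    Couplings are signed effect sizes per SD of the latent: the defaults
    reproduce the arousal sign pattern (alpha down, pupil up, microsaccade
    rate down, population rate up when arousal rises).
    """

    session_duration: float = 120.0        # minutes
    n_neurons: int = 40
    n_electrodes: int = 8
    eeg_rate: float = 1000.0               # Hz
    eye_rate: float = 1000.0               # Hz
    prestimulus_range: tuple = (300.0, 500.0)   # ms, uniform
    stimulus_duration: float = 400.0       # ms
    latent_timescale_sd: float = 30.0      # minutes
    aperiodic_exponent: float = 1.0        # chi of the 1/f^chi background
    alpha_center: float = 10.0             # Hz
    alpha_coupling: float = -0.5           # log-amplitude per latent SD
    pupil_coupling: float = 1.0            # x100 a.u. per latent SD
    msrate_coupling: float = -0.3          # log-rate per latent SD
    drift_coupling: float = 0.5            # log firing rate per latent SD
    base_msaccade_rate: float = 1.5        # events/s
    main_sequence_slope: float = 80.0      # (deg/s) per deg amplitude
    seed: int = 0
    # secondary knobs ------------------------------------------------------
    base_count: float = 10.0               # mean spikes per stimulus period
    positive_loading_fraction: float = 0.85
    ms_amplitude_range: tuple = (0.05, 1.0)   # deg
    ms_velocity_noise: float = 0.1         # fractional main-sequence scatter
    p_change: float = 0.35
    base_hit_rate: float = 0.6
    base_fa_rate: float = 0.05
    hit_coupling: float = 0.2
    fa_coupling: float = 0.3
    aperiodic_rms: float = 20e-6           # volts
    alpha_rms: float = 10e-6               # volts, baseline (latent = 0)
    background_variability: float = 0.2    # log-amplitude SD of slow broadband drift
    distractor_rms: float = 8e-6           # volts; theta/beta rhythms uncoupled to arousal
    pupil_baseline: float = 1000.0         # a.u.
    session_id: str = "synth-000"
    subject_id: str = "subjA"

    def __post_init__(self):
        if self.session_duration <= 0:
            raise ValueError("session_duration must be positive")
        if self.stimulus_duration <= 0:
            raise ValueError("stimulus_duration must be positive")
        lo, hi = self.prestimulus_range
        if not (0 < lo < hi):
            raise ValueError("prestimulus_range must satisfy 0 < lo < hi")
        if self.n_electrodes < 2:
            raise ValueError("need at least 2 electrodes")
        if self.n_neurons < 1:
            raise ValueError("need at least 1 neuron")
        if min(self.eeg_rate, self.eye_rate) < 100:
            raise ValueError("sampling rates must be at least 100 Hz")
        if self.main_sequence_slope <= 0:
            raise ValueError("main_sequence_slope must be positive")
        for name in ("alpha_coupling", "pupil_coupling", "msrate_coupling",
                     "drift_coupling"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if self.session_duration < 2 * self.latent_timescale_sd:
            raise ValueError("session must span at least 2x the latent timescale SD")

    def replace(self, **kw) -> "SynthConfig":
        return dataclasses.replace(self, **kw)


@dataclass
class GroundTruth:
    """What the generator knows and the analysis must recover."""

    latent: LatentArousal
    true_microsaccades: pd.DataFrame   # onset_s, offset_s, amplitude_deg, peak_velocity_dps
    neuron_loadings: np.ndarray        # signed weight of each neuron on the latent
    config: SynthConfig = field(default=None, repr=False)


def _smoothed_standard_noise(n: int, sigma_samples: float, rng) -> np.ndarray:
    """White noise convolved with a Gaussian kernel (FFT), then standardized."""
    white = rng.standard_normal(n)
    if sigma_samples <= 0:
        out = white
    else:
        # multiply the spectrum by the kernel transfer function exp(-2 pi^2 f^2 s^2)
        f = rfftfreq(n)  # cycles per sample
        out = irfft(rfft(white) * np.exp(-2 * np.pi**2 * f**2 * sigma_samples**2), n)
    out = out - out.mean()
    sd = out.std()
    if sd == 0:
        raise ValueError("degenerate latent: zero variance after smoothing")
    return out / sd


def generate_arousal_latent(duration: float, timescale_sd: float,
                            step: float = 1.0, seed=None) -> LatentArousal:
    """Standardized Gaussian-smoothed white noise.

    Parameters
    ----------
    duration : minutes.  Must be at least twice ``timescale_sd``.
    timescale_sd : minutes.  SD of the Gaussian smoothing kernel; the
        autocorrelation of the result is exp(-dt^2 / (4 SD^2)).
    step : seconds between grid points.
    """
    if duration <= 0 or timescale_sd <= 0:
        raise ValueError("duration and timescale_sd must be positive")
    if step <= 0:
        raise ValueError("step must be positive")
    if duration < 2 * timescale_sd:
        raise ValueError("duration must be at least 2x timescale_sd")
    rng = np.random.default_rng(seed)
    n = int(round(duration * 60.0 / step))
    grid = np.arange(n) * step
    value = _smoothed_standard_noise(n, timescale_sd * 60.0 / step, rng)
    return LatentArousal(time_grid=grid, value=value, timescale_sd=timescale_sd)


def generate_events(config: SynthConfig, seed=None,
                    latent: LatentArousal | None = None) -> pd.DataFrame:
    """Alternating prestimulus/stimulus periods tiling the session.

    Each trial is a run of periods ending at the first "terminal" stimulus
    period: an orientation change (resolved as hit or miss) or a false alarm.
    Hit and false-alarm probabilities are weakly modulated by the latent when
    one is supplied (arousal up -> more impulsive responding).

    Returns a table with one row per period: period_type, onset (s),
    duration (s), trial_index, is_first_prestim, orientation, outcome,
    change_time, saccade_time.
    """
    rng = np.random.default_rng(seed)
    duration_s = config.session_duration * 60.0
    lo, hi = (config.prestimulus_range[0] / 1000.0,
              config.prestimulus_range[1] / 1000.0)
    stim_d = config.stimulus_duration / 1000.0
    n_est = int(duration_s / (0.5 * (lo + hi) + stim_d)) + 64

    pre_d = rng.uniform(lo, hi, n_est)
    pair_d = pre_d + stim_d
    pair_end = np.cumsum(pair_d)
    n_pairs = int(np.searchsorted(pair_end, duration_s, side="right"))
    if n_pairs == 0:
        raise ValueError("session too short for a single prestimulus+stimulus pair")
    pre_d = pre_d[:n_pairs]
    pre_on = np.concatenate([[0.0], pair_end[:n_pairs - 1]])
    stim_on = pre_on + pre_d

    orientation = rng.choice([45.0, 135.0], n_pairs)
    lat = latent.at(stim_on) if latent is not None else np.zeros(n_pairs)
    changed = rng.random(n_pairs) < config.p_change
    p_hit = np.clip(config.base_hit_rate * np.exp(config.hit_coupling * lat), 0, 1)
    p_fa = np.clip(config.base_fa_rate * np.exp(config.fa_coupling * lat), 0, 1)
    hit = changed & (rng.random(n_pairs) < p_hit)
    fa = ~changed & (rng.random(n_pairs) < p_fa)
    terminal = changed | fa

    # trial index: number of terminal stimulus periods strictly before this pair
    trial_index = np.concatenate([[0], np.cumsum(terminal[:-1])]).astype(int)
    first_pre = np.concatenate([[True], terminal[:-1]])

    outcome = np.full(n_pairs, "", dtype=object)
    outcome[changed & hit] = "hit"
    outcome[changed & ~hit] = "miss"
    outcome[fa] = "false_alarm"

    change_time = np.where(changed, stim_on, np.nan)
    rt_true = rng.uniform(0.15, 0.35, n_pairs)
    saccade_time = np.full(n_pairs, np.nan)
    saccade_time[hit] = stim_on[hit] + rt_true[hit]
    saccade_time[fa] = stim_on[fa] + rt_true[fa]

    def rows(ptype, onsets, durs, ori, outc, ct, st, fp):
        return pd.DataFrame({
            "period_type": ptype, "onset": onsets, "duration": durs,
            "trial_index": trial_index, "is_first_prestim": fp,
            "orientation": ori, "outcome": outc,
            "change_time": ct, "saccade_time": st,
        })

    nanp = np.full(n_pairs, np.nan)
    pre = rows("prestimulus", pre_on, pre_d, nanp,
               np.full(n_pairs, "", dtype=object), nanp, nanp, first_pre)
    stim = rows("stimulus", stim_on, np.full(n_pairs, stim_d), orientation,
                outcome, change_time, saccade_time, np.zeros(n_pairs, bool))
    events = pd.concat([pre, stim]).sort_values("onset", kind="stable")
    return events.reset_index(drop=True)


def generate_spikes(latent: LatentArousal, events: pd.DataFrame,
                    config: SynthConfig, seed=None):
    """Per-neuron spike counts for every stimulus period.

    Counts are Poisson with log-rate b_i + tuning_i(theta) +
    drift_coupling * w_i * latent(t); the loadings w_i are majority-positive.
    Returns (counts [n_neurons x n_periods], loadings).
    """
    rng = np.random.default_rng(seed)
    stim = events[events.period_type == "stimulus"]
    t = stim.onset.to_numpy() + 0.05 + 0.4 / 2.0  # center of the count window
    if latent.time_grid[-1] + 1.0 < t[-1] - 1.0:
        raise ValueError("latent does not cover all event times")
    theta = stim.orientation.to_numpy()

    n = config.n_neurons
    baseline = math.log(config.base_count) + rng.normal(0.0, 0.3, n)
    tuning = rng.normal(0.0, 0.4, n)  # half-difference of log rates, 45 vs 135
    sign = np.where(rng.random(n) < config.positive_loading_fraction, 1.0, -1.0)
    loadings = sign * np.abs(rng.normal(1.0, 0.4, n))

    ori_sign = np.where(theta == 45.0, 1.0, -1.0)
    lat = latent.at(t)
    log_rate = (baseline[:, None] + 0.5 * tuning[:, None] * ori_sign[None, :]
                + config.drift_coupling * loadings[:, None] * lat[None, :])
    if np.any(log_rate > _LOG_RATE_CAP):
        raise ValueError("firing-rate overflow: log rate exceeds cap")
    counts = rng.poisson(np.exp(log_rate))
    return counts, loadings


def _spectral_noise(n, amplitude, rng):
    """Unit-RMS Gaussian noise synthesized from a one-sided amplitude profile.

    Drawing the complex spectrum directly (instead of FFT-filtering white
    noise) costs a single inverse FFT; float32 is ample for simulated noise.
    """
    m = n // 2 + 1
    z = rng.standard_normal(2 * m, dtype=np.float32)
    spec = (z[:m] + 1j * z[m:]) * amplitude.astype(np.float32)
    spec[0] = 0.0
    if n % 2 == 0:
        spec[-1] = spec[-1].real
    out = sfft.irfft(spec, n)
    out /= out.std()
    return out


def _colored_noise(n, rate, exponent, rng):
    """Unit-RMS noise with power spectrum proportional to f^-exponent."""
    f = rfftfreq(n, 1.0 / rate)
    amp = np.zeros_like(f)
    amp[1:] = f[1:] ** (-exponent / 2.0)
    return _spectral_noise(n, amp, rng)


def _gaussian_peak_noise(n, rate, center, sd, rng):
    """Unit-RMS oscillatory noise with a Gaussian spectral peak.

    Real alpha rhythms show a bump-shaped spectrum around ~10 Hz, not a
    rectangular band; a 1-Hz spectral SD keeps ~86% of the energy inside
    [center-2, center+2)."""
    f = rfftfreq(n, 1.0 / rate)
    amp = np.exp(-(f - center) ** 2 / (2.0 * sd * sd))
    amp[0] = 0.0
    return _spectral_noise(n, amp, rng)


def _slow_noise(n, rate, sigma_s, rng, grid_rate=50.0):
    """Standardized Gaussian-smoothed noise, built on a coarse grid and
    linearly interpolated to the full rate (the kernel SD is >> one sample).

    The kernel is capped at a quarter of the series duration so short
    sessions still get a non-degenerate (if slower-varying) process.
    """
    sigma_s = min(sigma_s, n / rate / 4.0)
    if rate <= grid_rate:
        return _smoothed_standard_noise(n, sigma_s * rate, rng)
    m = int(np.ceil(n * grid_rate / rate)) + 2
    coarse = _smoothed_standard_noise(m, sigma_s * grid_rate, rng)
    t = np.arange(n) * (grid_rate / rate)
    out = np.interp(t, np.arange(m), coarse)
    return (out - out.mean()) / out.std()


def _raised_cosine_pulse(n_samp):
    """Velocity profile of unit peak: 0.5 (1 - cos(2 pi t / D))."""
    ph = np.arange(1, n_samp + 1) / (n_samp + 1)
    return 0.5 * (1.0 - np.cos(2.0 * np.pi * ph))


def generate_eeg_and_eye(latent: LatentArousal, events: pd.DataFrame,
                         config: SynthConfig, seed=None):
    """Continuous EEG, eye trace, and ground-truth microsaccade list.

    EEG per electrode = 1/f^chi background (with slow broadband amplitude
    drift independent of the latent) + an independent Gaussian-peaked alpha
    oscillation whose amplitude is exp(alpha_coupling * latent).  Eye = slow
    fixational drift + tracker jitter + injected microsaccades (raised-cosine
    velocity pulses on the main sequence) + large response saccades on hit and
    false-alarm trials.  Pupil = baseline + 100 * pupil_coupling * latent +
    slow noise.

    Returns (eeg [n_electrodes x n], eye [n x 3: x deg, y deg, pupil],
    true_microsaccades DataFrame).
    """
    ss = np.random.SeedSequence(seed) if not isinstance(seed, np.random.SeedSequence) else seed
    r_eeg, r_eye, r_ms = [np.random.default_rng(s) for s in ss.spawn(3)]
    duration_s = config.session_duration * 60.0

    # ---------------- EEG ----------------
    n_eeg = int(round(duration_s * config.eeg_rate))
    t_eeg = np.arange(n_eeg) / config.eeg_rate
    alpha_gain = (config.alpha_rms
                  * np.exp(config.alpha_coupling * latent.at(t_eeg))
                  ).astype(np.float32)
    eeg = np.empty((config.n_electrodes, n_eeg))
    for e in range(config.n_electrodes):
        row = _colored_noise(n_eeg, config.eeg_rate,
                             config.aperiodic_exponent, r_eeg)
        row *= np.float32(config.aperiodic_rms)
        if config.background_variability > 0:
            # slow broadband amplitude drift, independent of the arousal
            # latent: real EEG is not amplitude-stationary, and without this
            # every band would inherit the alpha modulation through spectral
            # leakage alone
            row *= np.exp(config.background_variability * _slow_noise(
                n_eeg, config.eeg_rate, 600.0, r_eeg)).astype(np.float32)
        row += alpha_gain * _gaussian_peak_noise(n_eeg, config.eeg_rate,
                                                 config.alpha_center, 1.0, r_eeg)
        if config.distractor_rms > 0:
            # theta and beta rhythms with their own slow amplitude
            # fluctuations, uncoupled to arousal: without band-specific
            # variability every frequency would be a pure leakage proxy of
            # the alpha envelope and the spectrum would lose all selectivity
            for center, sd in ((6.0, 1.0), (16.0, 2.5)):
                gain = np.exp(0.5 * _slow_noise(n_eeg, config.eeg_rate,
                                                600.0, r_eeg)
                              ).astype(np.float32)
                row += (np.float32(config.distractor_rms) * gain
                        * _gaussian_peak_noise(n_eeg, config.eeg_rate,
                                               center, sd, r_eeg))
        eeg[e] = row
    del alpha_gain, t_eeg

    # ---------------- eye position ----------------
    rate = config.eye_rate
    n_eye = int(round(duration_s * rate))
    eye = np.empty((n_eye, 3))
    # slow fixational drift: Gaussian-low-passed noise, SD 0.05 deg per axis
    # (200-ms kernel keeps baseline velocity far below detection threshold)
    eye[:, 0] = 0.05 * _slow_noise(n_eye, rate, 0.2, r_eye)
    eye[:, 1] = 0.05 * _slow_noise(n_eye, rate, 0.2, r_eye)
    pos = eye[:, :2]
    pos += r_eye.normal(0.0, 1e-3, (n_eye, 2))  # tracker jitter

    vel_impulse = np.zeros((n_eye, 2))  # injected velocity, integrated below

    # response saccades happen here; no microsaccades are injected nearby
    # (fixational movements pause around large saccades, and ground truth
    # stays unambiguous for detector matching)
    sacc_times = events.saccade_time.to_numpy()
    sacc_times = np.sort(sacc_times[np.isfinite(sacc_times)])

    # ---------------- microsaccades ----------------
    lam_max = config.base_msaccade_rate * math.exp(
        abs(config.msrate_coupling) * (np.abs(latent.value).max() + 0.1))
    n_cand = r_ms.poisson(lam_max * duration_s)
    cand = np.sort(r_ms.uniform(0.0, duration_s, n_cand))
    lam = config.base_msaccade_rate * np.exp(config.msrate_coupling * latent.at(cand))
    cand = cand[r_ms.random(n_cand) < lam / lam_max]
    if sacc_times.size:
        k = np.searchsorted(sacc_times, cand)
        d_next = np.where(k < sacc_times.size, sacc_times[np.minimum(k, sacc_times.size - 1)] - cand, np.inf)
        d_prev = np.where(k > 0, cand - sacc_times[np.maximum(k - 1, 0)], np.inf)
        cand = cand[(d_next > 0.15) & (d_prev > 0.50)]

    # keep a refractory gap so ground truth is unambiguous for matching
    min_gap = 0.15
    kept, last = [], -np.inf
    for t0 in cand:
        if t0 - last >= min_gap and t0 > 0.05 and t0 < duration_s - 0.1:
            kept.append(t0)
            last = t0
    kept = np.asarray(kept)

    a_lo, a_hi = config.ms_amplitude_range
    amps = r_ms.uniform(a_lo, a_hi, kept.size)
    vpeaks = config.main_sequence_slope * amps * np.exp(
        r_ms.normal(0.0, config.ms_velocity_noise, kept.size))
    durs = np.clip(2.0 * amps / vpeaks, 0.006, 0.030)
    vpeaks = 2.0 * amps / durs  # re-derive after clipping so area = amplitude

    gaze = np.zeros(2)  # cumulative offset from fixation due to saccades
    records = []
    for t0, a, vp, d in zip(kept, amps, vpeaks, durs):
        # bias direction back toward fixation so gaze stays in a small box
        if np.hypot(*gaze) > 0.3:
            phi = math.atan2(-gaze[1], -gaze[0]) + r_ms.normal(0.0, 0.5)
        else:
            phi = r_ms.uniform(0.0, 2.0 * np.pi)
        i0 = int(round(t0 * rate))
        m = max(int(round(d * rate)), 2)
        if i0 + m >= n_eye:
            continue
        pulse = vp * _raised_cosine_pulse(m)
        step = a * np.array([math.cos(phi), math.sin(phi)])
        vel_impulse[i0:i0 + m, 0] += pulse * math.cos(phi)
        vel_impulse[i0:i0 + m, 1] += pulse * math.sin(phi)
        gaze += step
        records.append((t0, t0 + d, a, vp))

    true_ms = pd.DataFrame(records, columns=[
        "onset_s", "offset_s", "amplitude_deg", "peak_velocity_dps"])

    # ---------------- response saccades on hit / false-alarm trials --------
    stim = events[events.period_type == "stimulus"]
    for st in stim.saccade_time.to_numpy():
        if not np.isfinite(st):
            continue
        i0 = int(round(st * rate))
        m = int(round(0.040 * rate))
        amp, phi = 6.0, r_eye.uniform(0.0, 2.0 * np.pi)
        vp = 2.0 * amp / 0.040
        if i0 + m >= n_eye:
            continue
        pulse = vp * _raised_cosine_pulse(m)
        vel_impulse[i0:i0 + m, 0] += pulse * math.cos(phi)
        vel_impulse[i0:i0 + m, 1] += pulse * math.sin(phi)
        # return saccade 300 ms later
        j0 = i0 + int(round(0.3 * rate))
        if j0 + m < n_eye:
            vel_impulse[j0:j0 + m, 0] -= pulse * math.cos(phi)
            vel_impulse[j0:j0 + m, 1] -= pulse * math.sin(phi)

    pos += np.cumsum(vel_impulse, axis=0) / rate
    del vel_impulse

    # ---------------- pupil ----------------
    t_eye = np.arange(n_eye) / rate
    eye[:, 2] = (config.pupil_baseline
                 + 100.0 * config.pupil_coupling * latent.at(t_eye)
                 + 20.0 * _slow_noise(n_eye, rate, 1.0, r_eye))
    np.maximum(eye[:, 2], 1.0, out=eye[:, 2])
    return eeg, eye, true_ms


def generate_session(config: SynthConfig, include_eeg: bool = True,
                     include_eye: bool = True, include_spikes: bool = True):
    """Generate one full session.  Returns (SessionRecording, GroundTruth).

    Modalities can be switched off to generate cheap partial sessions (the
    omitted arrays are empty); events and latent are always produced so the
    remaining modalities stay mutually consistent.
    """
    ss = np.random.SeedSequence(config.seed)
    s_lat, s_ev, s_spk, s_cont = ss.spawn(4)
    latent = generate_arousal_latent(
        config.session_duration, config.latent_timescale_sd, step=1.0, seed=s_lat)
    events = generate_events(config, seed=s_ev, latent=latent)

    if include_spikes:
        counts, loadings = generate_spikes(latent, events, config, seed=s_spk)
    else:
        n_stim = int((events.period_type == "stimulus").sum())
        counts = np.zeros((0, n_stim), dtype=int)
        loadings = np.zeros(0)

    if include_eeg or include_eye:
        eeg, eye, true_ms = generate_eeg_and_eye(latent, events, config, seed=s_cont)
        if not include_eeg:
            eeg = np.zeros((config.n_electrodes, 0))
        if not include_eye:
            eye = np.zeros((0, 3))
            true_ms = true_ms.iloc[:0]
    else:
        eeg = np.zeros((config.n_electrodes, 0))
        eye = np.zeros((0, 3))
        true_ms = pd.DataFrame(columns=[
            "onset_s", "offset_s", "amplitude_deg", "peak_velocity_dps"])

    rec = SessionRecording(
        session_id=config.session_id, subject_id=config.subject_id,
        spike_counts=counts,
        orientations=events.loc[events.period_type == "stimulus",
                                "orientation"].to_numpy(),
        eeg=eeg, eeg_rate=config.eeg_rate,
        eye=eye, eye_rate=config.eye_rate,
        events=events, duration_s=config.session_duration * 60.0)
    truth = GroundTruth(latent=latent, true_microsaccades=true_ms,
                        neuron_loadings=loadings, config=config)
    return rec, truth


def write_ground_truth(truth: GroundTruth, out_dir):
    """Sidecar CSVs: one row per true microsaccade; one row per neuron loading."""
    from pathlib import Path
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    truth.true_microsaccades.to_csv(out / "true_microsaccades.csv", index=False)
    pd.DataFrame({"neuron": np.arange(truth.neuron_loadings.size),
                  "loading": truth.neuron_loadings}
                 ).to_csv(out / "neuron_loadings.csv", index=False)
    pd.DataFrame({"time_s": truth.latent.time_grid,
                  "latent": truth.latent.value}
                 ).to_csv(out / "latent.csv", index=False)
    return [out / "true_microsaccades.csv", out / "neuron_loadings.csv",
            out / "latent.csv"]
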