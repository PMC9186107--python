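"""Generator contracts: latent statistics, event timing, coupling structure."""

import numpy as np
import pytest
from scipy import signal as ssig

from adkit.binning import bin_matrix
from adkit.synth import (SynthConfig, generate_arousal_latent, generate_events,
                         generate_session, generate_spikes)

from conftest import FAST_RATES


# ---------------------------------------------------------------- latent ----

def test_latent_is_standardized_and_smooth():
    lat = generate_arousal_latent(120.0, 30.0, seed=1)
    assert abs(lat.value.mean()) < 1e-9
    assert abs(lat.value.std() - 1.0) < 1e-9
    assert np.all(np.diff(lat.time_grid) > 0)
    # Gaussian-smoothed white noise: autocorr at lag d is exp(-d^2/(4 SD^2));
    # at a 1-min lag with SD=30 min that is ~0.9997
    v = lat.value
    lag = 60  # samples = 1 min on the 1-s grid
    r = np.corrcoef(v[:-lag], v[lag:])[0, 1]
    assert r > 0.9


def test_latent_no_smoothing_limit_is_white():
    lat = generate_arousal_latent(2.0, 0.01, step=0.1, seed=2)
    v = lat.value
    r = np.corrcoef(v[:-600], v[600:])[0, 1]  # 1-min lag
    assert abs(r) < 0.2


def test_latent_determinism():
    a = generate_arousal_latent(120.0, 20.0, seed=42)
    b = generate_arousal_latent(120.0, 20.0, seed=42)
    np.testing.assert_array_equal(a.value, b.value)


@pytest.mark.parametrize("duration,sd", [(-1, 10), (120, 0), (10, 30)])
def test_latent_invalid_parameters(duration, sd):
    with pytest.raises(ValueError):
        generate_arousal_latent(duration, sd, seed=0)


# ---------------------------------------------------------------- events ----

def test_event_timing_contract():
    cfg = SynthConfig(session_duration=120.0, seed=3, **FAST_RATES)
    ev = generate_events(cfg, seed=3)
    pre = ev[ev.period_type == "prestimulus"]
    stim = ev[ev.period_type == "stimulus"]
    assert np.all((pre.duration >= 0.300) & (pre.duration <= 0.500))
    np.testing.assert_allclose(stim.duration, 0.400)
    assert set(stim.orientation) <= {45.0, 135.0}
    # strict alternation tiling the session
    assert list(ev.period_type[:4]) == ["prestimulus", "stimulus"] * 2
    ends = (ev.onset + ev.duration).to_numpy()
    np.testing.assert_allclose(ev.onset.to_numpy()[1:], ends[:-1])
    assert ends[-1] <= 120.0 * 60.0


def test_first_prestimulus_flags_follow_trial_structure():
    cfg = SynthConfig(session_duration=40.0, latent_timescale_sd=10.0, seed=4,
                      **FAST_RATES)
    ev = generate_events(cfg, seed=4)
    pre = ev[ev.period_type == "prestimulus"].reset_index(drop=True)
    # exactly one initial fixation period per trial
    per_trial = pre.groupby("trial_index").is_first_prestim.sum()
    complete = per_trial.index[:-1]  # last trial may be truncated
    assert (per_trial.loc[complete] == 1).all()
    assert pre.is_first_prestim.iloc[0]


# ---------------------------------------------------------------- spikes ----

def _pc1_share(counts, ori, times, duration_min):
    from adkit.slow_drift import bin_residuals, compute_drift, residual_counts
    res = residual_counts(counts, ori)
    centers, binned = bin_residuals(res, times, duration_min)
    return compute_drift(centers, binned).variance_explained


def test_spike_counts_shape_and_conservation():
    cfg = SynthConfig(session_duration=36.0, latent_timescale_sd=10.0,
                      n_neurons=1, seed=5, **FAST_RATES)
    rec, truth = generate_session(cfg, include_eeg=False, include_eye=False)
    n_stim = int((rec.events.period_type == "stimulus").sum())
    assert rec.spike_counts.shape == (1, n_stim)
    assert rec.orientations.size == n_stim
    assert truth.neuron_loadings.size == 1
    assert rec.spike_counts.min() >= 0


def test_zero_coupling_leaves_no_shared_slow_structure():
    """With drift_coupling=0 the PC1 variance share stays at the level set by
    window-overlap autocorrelation alone (oracle: repeated null generation);
    with coupling on, the share is far above every null draw."""
    shares = {0.0: [], 0.5: []}
    for coupling, n_rep in ((0.0, 8), (0.5, 3)):
        for seed in range(n_rep):
            cfg = SynthConfig(session_duration=120.0, n_neurons=30,
                              drift_coupling=coupling, seed=700 + seed,
                              **FAST_RATES)
            rec, _ = generate_session(cfg, include_eeg=False, include_eye=False)
            stim_t = rec.stimulus_periods().onset.to_numpy()
            shares[coupling].append(_pc1_share(
                rec.spike_counts, rec.orientations, stim_t, 120.0))
    assert max(shares[0.0]) < 0.7          # no dominant shared direction
    assert min(shares[0.5]) > max(shares[0.0])


def test_coupled_neurons_track_latent():
    cfg = SynthConfig(session_duration=120.0, n_neurons=20, drift_coupling=0.5,
                      positive_loading_fraction=1.0, seed=12, **FAST_RATES)
    rec, truth = generate_session(cfg, include_eeg=False, include_eye=False)
    from adkit.slow_drift import residual_counts
    res = residual_counts(rec.spike_counts, rec.orientations)
    stim_t = rec.stimulus_periods().onset.to_numpy()
    centers, binned, _ = bin_matrix(stim_t / 60.0, res, 120.0)
    lat = truth.latent.at(centers * 60.0)
    rs = [np.corrcoef(binned[:, i], lat)[0, 1] for i in range(20)]
    assert np.median(rs) > 0.8


def test_rate_overflow_raises():
    cfg = SynthConfig(session_duration=36.0, latent_timescale_sd=10.0,
                      drift_coupling=30.0, seed=6, **FAST_RATES)
    lat = generate_arousal_latent(36.0, 10.0, seed=6)
    ev = generate_events(cfg, seed=6)
    with pytest.raises(ValueError, match="overflow"):
        generate_spikes(lat, ev, cfg, seed=6)


# ------------------------------------------------------------- EEG / eye ----

def test_eeg_spectrum_has_configured_aperiodic_slope():
    cfg = SynthConfig(session_duration=10.0, latent_timescale_sd=2.0,
                      alpha_coupling=0.0, aperiodic_exponent=1.0, seed=8,
                      distractor_rms=0.0, **FAST_RATES)
    rec, _ = generate_session(cfg, include_spikes=False)
    f, p = ssig.welch(rec.eeg[0], fs=cfg.eeg_rate, nperseg=4096)
    sel = (f >= 3) & (f <= 50) & ~((f >= 7) & (f <= 14))
    slope = np.polyfit(np.log10(f[sel]), np.log10(p[sel]), 1)[0]
    assert abs(slope - (-1.0)) < 0.1


def test_microsaccade_count_matches_thinned_poisson_rate():
    # no behavior saccades, no rate modulation: the injected count follows a
    # Poisson process thinned by the 150-ms refractory gap
    cfg = SynthConfig(session_duration=10.0, latent_timescale_sd=2.0,
                      msrate_coupling=0.0, p_change=0.0, base_fa_rate=0.0,
                      seed=9, **FAST_RATES)
    rec, truth = generate_session(cfg, include_eeg=False, include_spikes=False)
    lam, gap, T = cfg.base_msaccade_rate, 0.15, 10.0 * 60.0
    expected = lam / (1.0 + lam * gap) * T
    assert abs(len(truth.true_microsaccades) - expected) <= 3 * np.sqrt(expected)


def test_ground_truth_main_sequence_slope_recovered():
    cfg = SynthConfig(session_duration=10.0, latent_timescale_sd=2.0, seed=10,
                      **FAST_RATES)
    _, truth = generate_session(cfg, include_eeg=False, include_spikes=False)
    tm = truth.true_microsaccades
    slope = np.polyfit(tm.amplitude_deg, tm.peak_velocity_dps, 1)[0]
    assert abs(slope - cfg.main_sequence_slope) / cfg.main_sequence_slope < 0.05


def test_ground_truth_events_inside_session_with_positive_amplitude(small_session):
    rec, truth = small_session
    tm = truth.true_microsaccades
    assert (tm.amplitude_deg > 0).all()
    assert (tm.onset_s >= 0).all()
    assert (tm.offset_s <= rec.duration_s).all()
    assert (rec.eye[:, 2] > 0).all()  # pupil positive


def test_session_determinism():
    cfg = SynthConfig(session_duration=36.0, latent_timescale_sd=10.0,
                      n_neurons=5, seed=13, **FAST_RATES)
    a, _ = generate_session(cfg)
    b, _ = generate_session(cfg)
    np.testing.assert_array_equal(a.eeg, b.eeg)
    np.testing.assert_array_equal(a.eye, b.eye)
    np.testing.assert_array_equal(a.spike_counts, b.spike_counts)


def test_config_validation():
    with pytest.raises(ValueError, match="main_sequence_slope"):
        SynthConfig(main_sequence_slope=-1.0)
    with pytest.raises(ValueError, match="electrodes"):
        SynthConfig(n_electrodes=1)
    with pytest.raises(ValueError, match="prestimulus_range"):
        SynthConfig(prestimulus_range=(500.0, 300.0))
    with pytest.raises(ValueError, match="finite"):
        SynthConfig(alpha_coupling=np.nan)
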