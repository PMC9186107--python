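"""EEG segmentation, screening, spectra, aperiodic removal, band power."""

import numpy as np
import pytest

from adkit.eeg_spectral import (BANDS, EegSegments, ResidualSpectrumSet,
                                SpectrumBins, band_power, bin_spectra,
                                extract_segments, remove_aperiodic,
                                screen_segments, segment_spectrum,
                                sliding_band_power)


# ------------------------------------------------------------ segments ------

def test_segment_extraction_skips_initial_fixation(small_session):
    rec, _ = small_session
    segs = extract_segments(rec)
    pre = rec.prestimulus_periods()
    assert len(segs) == (~pre.is_first_prestim).sum()
    # 300 ms at the session's EEG rate
    assert segs.data.shape[2] == int(0.3 * rec.eeg_rate)
    assert segs.data.shape[1] == 8


def test_rereferencing_zeroes_the_electrode_mean(small_session):
    rec, _ = small_session
    segs = extract_segments(rec)
    np.testing.assert_allclose(segs.data.mean(axis=1), 0.0, atol=1e-18)


def test_segment_count_at_1khz():
    from adkit.synth import SynthConfig, generate_session
    cfg = SynthConfig(session_duration=31.0, latent_timescale_sd=10.0,
                      n_neurons=2, seed=2)  # default 1 kHz rates
    rec, _ = generate_session(cfg, include_spikes=False)
    segs = extract_segments(rec)
    assert segs.data.shape[2] == 300


# ------------------------------------------------------------ screening -----

def test_artifact_and_flat_segments_rejected(small_session):
    rec, _ = small_session
    segs = extract_segments(rec)
    data = segs.data.copy()
    data[3] *= 20.0    # amplitude artifact on every electrode
    data[7, 2] = 0.0   # one flat electrode
    dirty = EegSegments(data=data, onsets=segs.onsets, rate=segs.rate,
                        period_index=segs.period_index)
    kept, log = screen_segments(dirty, rec)
    assert bool(log.rule_noisy[3]) and bool(log.rejected[3])
    assert bool(log.rule_flat[7]) and bool(log.rejected[7])


def test_clean_session_rejection_fraction_below_5_percent():
    # "clean" = no microsaccades and no artifacts; only distribution tails
    # can fire the rules
    from adkit.synth import SynthConfig, generate_session
    cfg = SynthConfig(session_duration=36.0, latent_timescale_sd=10.0,
                      base_msaccade_rate=1e-9, p_change=0.0, base_fa_rate=0.0,
                      seed=3, eeg_rate=200.0, eye_rate=250.0)
    rec, _ = generate_session(cfg, include_spikes=False)
    segs = extract_segments(rec)
    kept, log = screen_segments(segs, rec)
    assert log.rejected.mean() < 0.05


def test_screening_is_independent_of_other_segments(small_session):
    """Session-level reference statistics are computed before rejection, so
    a segment's fate does not change when another segment is corrupted."""
    rec, _ = small_session
    segs = extract_segments(rec)
    _, log0 = screen_segments(segs, rec)
    data = segs.data.copy()
    data[0] *= 20.0
    _, log1 = screen_segments(
        EegSegments(data, segs.onsets, segs.rate, segs.period_index), rec)
    # all other segments keep their fate (the corrupted segment only nudges
    # the session mean SD by ~2/n, far from any decision boundary here)
    np.testing.assert_array_equal(log0.rejected[1:], log1.rejected[1:])
    assert bool(log1.rejected[0])


def test_all_rejected_errors(small_session):
    rec, _ = small_session
    segs = extract_segments(rec)
    flat = EegSegments(np.zeros_like(segs.data), segs.onsets, segs.rate,
                       segs.period_index)
    with pytest.raises(ValueError, match="rejected"):
        screen_segments(flat, rec)


# ------------------------------------------------------------- spectra ------

def _segments_from_array(x, rate):
    n_seg, n_el, n_samp = x.shape
    return EegSegments(data=x, onsets=np.arange(n_seg, dtype=float), rate=rate,
                       period_index=np.arange(n_seg))


def test_sinusoid_spectrum_peaks_at_its_frequency():
    rate = 1000.0
    t = np.arange(300) / rate
    x = (2e-5 * np.sin(2 * np.pi * 10.0 * t))[None, None, :]
    freqs, power = segment_spectrum(_segments_from_array(x, rate))
    assert freqs[np.argmax(power[0, 0])] == 10.0
    assert power[0, 0, freqs == 10.0] >= 100.0 * power[0, 0, freqs == 30.0]


def test_zero_segment_gives_zero_spectrum():
    x = np.zeros((1, 2, 300))
    _, power = segment_spectrum(_segments_from_array(x, 1000.0))
    np.testing.assert_array_equal(power, 0.0)


def test_parseval_identity_on_full_grid():
    from adkit.eeg_spectral import _power_spectrum
    rng = np.random.default_rng(0)
    x = rng.normal(size=300)
    win = np.hanning(300)
    p = _power_spectrum(x * win, 1000.0, 1000)
    energy = np.sum((x * win) ** 2)
    assert abs(p.sum() - energy) / energy < 1e-9


def test_nan_segment_rejected():
    x = np.zeros((1, 2, 300))
    x[0, 0, 5] = np.nan
    with pytest.raises(ValueError, match="finite"):
        segment_spectrum(_segments_from_array(x, 1000.0))


# ------------------------------------------------------------- binning ------

def test_bin_counts_for_session_lengths():
    freqs = np.arange(1.0, 51.0)
    n_seg = 2000
    rng = np.random.default_rng(1)
    onsets = np.sort(rng.uniform(0, 120 * 60, n_seg))
    power = np.ones((n_seg, 2, freqs.size))
    bins = bin_spectra(freqs, power, onsets, 120.0)
    assert len(bins.bin_centers) == 16
    fine = bin_spectra(freqs, power, onsets, 120.0, step_min=1.0)
    assert len(fine.bin_centers) == 91
    np.testing.assert_allclose(bins.power, 1.0)  # identical spectra everywhere


# ---------------------------------------------------- aperiodic removal -----

def _power_law_bins(chi, k=1e-10, bump_height=0.0, bump_center=10.0,
                    bump_sd=1.0, n_el=3, n_bins=2):
    freqs = np.arange(1.0, 51.0)
    base = k * freqs ** (-chi)
    bump = bump_height * np.exp(-(freqs - bump_center) ** 2 / (2 * bump_sd ** 2))
    power = np.tile(base + bump, (n_bins, n_el, 1))
    return SpectrumBins(bin_centers=np.arange(n_bins, dtype=float),
                        freqs=freqs, power=power)


@pytest.mark.parametrize("chi", [0.5, 1.0, 1.5])
def test_pure_power_law_leaves_no_residual(chi):
    res = remove_aperiodic(_power_law_bins(chi))
    assert np.abs(res.residual).max() < 1e-6 * 1e-10
    np.testing.assert_allclose(res.aperiodic[..., 1], chi, atol=1e-9)


@pytest.mark.parametrize("chi", [0.5, 1.0, 1.5])
def test_power_law_plus_bump_recovered(chi):
    k, h = 1e-10, 5e-11
    res = remove_aperiodic(_power_law_bins(chi, k=k, bump_height=h))
    fitted_chi = res.aperiodic[..., 1]
    assert np.abs(fitted_chi - chi).max() < 0.05
    peak = res.residual[0, res.freqs == 10.0][0]
    assert abs(peak - h) / h < 0.10


def test_residuals_averaged_after_per_electrode_removal():
    """Electrodes with different exponents: the result equals the mean of the
    per-electrode residuals, not the residual of the mean spectrum."""
    freqs = np.arange(1.0, 51.0)
    k = 1e-10
    p0 = k * freqs ** -0.5
    p1 = k * freqs ** -1.5
    power = np.stack([p0, p1])[None, :, :]
    bins = SpectrumBins(np.array([15.0]), freqs, power)
    res = remove_aperiodic(bins)
    # each electrode is exactly power-law, so per-electrode residuals vanish
    assert np.abs(res.residual).max() < 1e-6 * k
    # whereas a single fit to the electrode-average cannot vanish
    avg_bins = SpectrumBins(np.array([15.0]), freqs,
                            power.mean(axis=1, keepdims=True))
    res_avg = remove_aperiodic(avg_bins)
    assert np.abs(res_avg.residual).max() > 100 * np.abs(res.residual).max()


def test_nonpositive_power_names_bin_and_electrode():
    bins = _power_law_bins(1.0)
    bins.power[1, 2, 19] = 0.0  # 20 Hz, inside the 3-50 Hz fit range
    with pytest.raises(ValueError, match="bin 1, electrode 2"):
        remove_aperiodic(bins)


# ----------------------------------------------------------- band power -----

def _residual_set(values):
    freqs = np.arange(1.0, 51.0)
    return ResidualSpectrumSet(bin_centers=np.array([15.0]), freqs=freqs,
                               residual=np.asarray(values)[None, :])


def test_band_power_isolates_a_10hz_bump():
    freqs = np.arange(1.0, 51.0)
    res = _residual_set(np.where(freqs == 10.0, 1.0, 0.0))
    assert band_power(res, BANDS["alpha"]).values[0] > 0
    for name in ("theta", "beta", "gamma"):
        assert band_power(res, BANDS[name]).values[0] == 0.0


def test_constant_residual_gives_constant_band_power():
    res = _residual_set(np.full(50, 0.7))
    for band in BANDS.values():
        assert band_power(res, band).values[0] == pytest.approx(0.7)


def test_alpha_band_is_half_open():
    freqs = np.arange(1.0, 51.0)
    res = _residual_set((freqs >= 8) & (freqs < 12))
    # [8,12) on the 1-Hz grid covers exactly {8,9,10,11}
    assert band_power(res, (8.0, 12.0)).values[0] == pytest.approx(1.0)
    res12 = _residual_set(freqs == 12.0)
    assert band_power(res12, (8.0, 12.0)).values[0] == 0.0


def test_empty_band_errors():
    with pytest.raises(ValueError, match="no grid frequencies"):
        band_power(_residual_set(np.zeros(50)), (8.2, 8.4))


def test_sliding_windows_match_band_power_and_count():
    freqs = np.arange(1.0, 51.0)
    bump = np.exp(-(freqs - 10.0) ** 2 / 2.0)
    res = _residual_set(bump)
    windows = sliding_band_power(res)
    assert len(windows) == 23  # left edges 2..46 step 2
    np.testing.assert_array_equal(windows[8.0].values,
                                  band_power(res, (8.0, 12.0)).values)
    strongest = max(windows, key=lambda lo: windows[lo].values[0])
    assert strongest == 8.0  # symmetric bump at 10 Hz peaks in [8,12)
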