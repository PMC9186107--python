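"""Prestimulus EEG power: segmentation, screening, spectra, aperiodic removal.

The chain is: average-rereference the session EEG, cut a fixed 300-ms segment
from every qualifying prestimulus period, reject artifactual segments,
compute Hanning-windowed power spectra (zero-padded to 1 s for a 1-Hz grid),
average spectra within sliding 30-min bins, fit and subtract the 1/f^chi
aperiodic background per electrode, average the residuals across electrodes,
and finally reduce each bin's residual spectrum to band power.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .binning import BinnedSeries, bin_matrix
from .eye_metrics import compute_velocity

__all__ = ["EegSegments", "ResidualSpectrumSet", "extract_segments",
           "screen_segments", "segment_spectrum", "bin_spectra",
           "remove_aperiodic", "band_power", "sliding_band_power", "BANDS"]

SEGMENT_MS = 300.0
#: canonical frequency bands, half-open [lo, hi) Hz
BANDS = {"theta": (4.0, 8.0), "alpha": (8.0, 12.0),
         "beta": (12.0, 30.0), "gamma": (30.0, 50.0)}


@dataclass
class EegSegments:
    """Fixed-duration EEG segments cut from prestimulus periods."""

    data: np.ndarray       # (n_segments, n_electrodes, n_samples), volts
    onsets: np.ndarray     # s, prestimulus onset of each segment
    rate: float            # Hz
    period_index: np.ndarray = None  # row index into the session event table

    def __len__(self):
        return self.data.shape[0]


@dataclass
class SpectrumBins:
    """Per-bin, per-electrode mean power spectra."""

    bin_centers: np.ndarray   # minutes
    freqs: np.ndarray         # Hz
    power: np.ndarray         # (n_bins, n_electrodes, n_freqs)
    counts: np.ndarray = None


@dataclass
class ResidualSpectrumSet:
    """Aperiodic-subtracted power, averaged over electrodes, per time bin."""

    bin_centers: np.ndarray    # minutes
    freqs: np.ndarray          # Hz
    residual: np.ndarray       # (n_bins, n_freqs)
    aperiodic: np.ndarray = field(default=None, repr=False)  # (n_bins, n_el, 2): offset, exponent


def extract_segments(rec) -> EegSegments:
    """300-ms segments from every prestimulus period except each trial's first.

    The EEG is rereferenced to the session-wide average across electrodes
    before segmentation.  Periods not fully covered by the EEG trace are
    skipped with a warning.
    """
    eeg = rec.eeg - rec.eeg.mean(axis=0, keepdims=True)
    rate = rec.eeg_rate
    n_samp = int(round(SEGMENT_MS / 1000.0 * rate))
    pre = rec.prestimulus_periods()
    pre = pre[~pre.is_first_prestim]
    onsets = pre.onset.to_numpy()
    idx = pre.index.to_numpy()
    i0 = (onsets * rate).round().astype(int)
    ok = i0 + n_samp <= eeg.shape[1]
    if not ok.all():
        warnings.warn(f"{(~ok).sum()} prestimulus period(s) not covered by EEG; skipped")
    i0, onsets, idx = i0[ok], onsets[ok], idx[ok]
    data = eeg[:, i0[:, None] + np.arange(n_samp)[None, :]]  # (el, seg, samp)
    return EegSegments(data=np.ascontiguousarray(data.transpose(1, 0, 2)),
                       onsets=onsets, rate=rate, period_index=idx)


def screen_segments(segments: EegSegments, rec,
                    sd_ratio: float = 10.0, flat_sd_volts: float = 300e-9,
                    eye_ratio: float = 2.0, eye_velocity: np.ndarray = None):
    """Artifact screening.  Returns (kept EegSegments, rejection-log DataFrame).

    A segment is rejected if any electrode's within-segment SD exceeds
    ``sd_ratio`` times that electrode's session-mean segment SD, or falls
    below ``flat_sd_volts`` (flat channel), or if the within-period SD of 1-D
    eye speed exceeds ``eye_ratio`` times the session-mean eye speed over all
    prestimulus periods.  Session-level reference statistics are computed over
    all segments before any rejection, so each segment's fate is independent
    of the others'.
    """
    if len(segments) == 0:
        raise ValueError("no segments to screen")
    seg_sd = segments.data.std(axis=2)            # (n_seg, n_el)
    mean_sd = seg_sd.mean(axis=0)                 # per electrode, pre-rejection
    noisy = (seg_sd > sd_ratio * mean_sd).any(axis=1)
    flat = (seg_sd < flat_sd_volts).any(axis=1)

    # eye-speed rule over the segment's source prestimulus period
    v = (compute_velocity(rec.eye[:, :2], rec.eye_rate)
         if eye_velocity is None else eye_velocity)
    speed = np.hypot(v[:, 0], v[:, 1])
    pre = rec.prestimulus_periods()
    t0 = pre.onset.to_numpy()
    t1 = t0 + pre.duration.to_numpy()
    i0 = (t0 * rec.eye_rate).round().astype(int)
    i1 = np.minimum((t1 * rec.eye_rate).round().astype(int), speed.size)
    csum = np.concatenate([[0.0], np.cumsum(speed)])
    csum2 = np.concatenate([[0.0], np.cumsum(speed ** 2)])
    n = np.maximum(i1 - i0, 1)
    mean_all = (csum[i1] - csum[i0]).sum() / n.sum()   # session mean eye speed
    m1 = (csum[i1] - csum[i0]) / n
    m2 = (csum2[i1] - csum2[i0]) / n
    sd_speed_all = np.sqrt(np.maximum(m2 - m1 ** 2, 0.0))
    by_period = dict(zip(pre.index.to_numpy(), sd_speed_all))
    eye_sd = np.array([by_period[i] for i in segments.period_index])
    eye_bad = eye_sd > eye_ratio * mean_all

    rejected = noisy | flat | eye_bad
    log = pd.DataFrame({
        "onset_s": segments.onsets, "rejected": rejected,
        "rule_noisy": noisy, "rule_flat": flat, "rule_eye": eye_bad})
    if rejected.all():
        raise ValueError("all EEG segments rejected by screening")
    keep = ~rejected
    kept = EegSegments(data=segments.data[keep], onsets=segments.onsets[keep],
                       rate=segments.rate,
                       period_index=segments.period_index[keep])
    return kept, log


def _power_spectrum(x: np.ndarray, rate: float, n_fft: int) -> np.ndarray:
    """One-sided power of the last axis, scaled so the sum over the full grid
    equals the signal energy sum(x^2) (discrete Parseval)."""
    X = np.fft.rfft(x, n=n_fft, axis=-1)
    p = np.abs(X) ** 2 / n_fft
    p[..., 1:] *= 2.0
    if n_fft % 2 == 0:
        p[..., -1] /= 2.0
    return p


def segment_spectrum(segments: EegSegments, f_lo: float = 1.0, f_hi: float = 50.0):
    """Hanning-windowed per-electrode power spectra on a 1-Hz grid.

    Each 300-ms segment is windowed and zero-padded to 1 s before the FFT,
    giving 1-Hz frequency spacing; the 1-50 Hz range is retained.
    Returns (freqs, power (n_seg, n_el, n_freq)).
    """
    data = segments.data
    if not np.all(np.isfinite(data)):
        raise ValueError("segments contain non-finite samples")
    n = data.shape[-1]
    win = np.hanning(n)
    n_fft = int(round(segments.rate))  # zero-pad to 1 s -> 1-Hz grid
    power = _power_spectrum(data * win, segments.rate, n_fft)
    freqs = np.fft.rfftfreq(n_fft, 1.0 / segments.rate)
    keep = (freqs >= f_lo) & (freqs <= f_hi)
    return freqs[keep], power[..., keep]


def bin_spectra(freqs, power, onsets_s, duration_min,
                window_min: float = 30.0, step_min: float = 6.0,
                min_segments: int = 10) -> SpectrumBins:
    """Mean spectrum per electrode in each sliding time window.

    Bins holding fewer than ``min_segments`` segments are dropped.
    """
    n_seg, n_el, n_f = power.shape
    flat = power.reshape(n_seg, n_el * n_f).T
    centers, binned, counts = bin_matrix(
        np.asarray(onsets_s) / 60.0, flat, duration_min,
        window_min, step_min, min_count=min_segments)
    return SpectrumBins(bin_centers=centers, freqs=np.asarray(freqs),
                        power=binned.reshape(len(centers), n_el, n_f),
                        counts=counts)


def remove_aperiodic(bins: SpectrumBins, fit_lo: float = 3.0, fit_hi: float = 50.0,
                     guard=(5.0, 19.0)) -> ResidualSpectrumSet:
    """Fit and subtract the 1/f^chi background per bin and electrode.

    log10 P(f) = c - chi log10 f is fit by least squares over
    [fit_lo, fit_hi] excluding the ``guard`` interval around the alpha peak;
    the fitted power law is subtracted on the full grid and the residuals are
    then averaged across electrodes (removal happens before averaging).

    The default guard is wide because a 300-ms Hanning window smears an
    8-12 Hz peak over roughly 5-19 Hz (mainlobe half-width 2/T = 6.7 Hz);
    a narrow guard lets the leaked peak tilt the fit and imprint the alpha
    modulation, with inverted sign, on every other band's residual.
    """
    f = bins.freqs
    in_fit = (f >= fit_lo) & (f <= fit_hi) & ~((f >= guard[0]) & (f <= guard[1]))
    logf_fit = np.log10(f[in_fit])
    A = np.column_stack([np.ones_like(logf_fit), -logf_fit])
    n_bins, n_el, _ = bins.power.shape

    pw_fit = bins.power[:, :, in_fit]
    if np.any(pw_fit <= 0):
        b, e, _ = np.unravel_index(int(np.argmin(pw_fit)), pw_fit.shape)
        raise ValueError(
            f"nonpositive power in aperiodic fit range (bin {b}, electrode {e})")
    # one lstsq over all (bin, electrode) columns at once
    Y = np.log10(pw_fit).reshape(n_bins * n_el, -1).T
    coef, *_ = np.linalg.lstsq(A, Y, rcond=None)
    c = coef[0].reshape(n_bins, n_el)
    chi = coef[1].reshape(n_bins, n_el)
    model = 10.0 ** (c[:, :, None] - chi[:, :, None] * np.log10(f)[None, None, :])
    residual = (bins.power - model).mean(axis=1)
    return ResidualSpectrumSet(bin_centers=bins.bin_centers, freqs=f,
                               residual=residual,
                               aperiodic=np.stack([c, chi], axis=-1))


def band_power(resset: ResidualSpectrumSet, band, name: str = "") -> BinnedSeries:
    """Mean residual power over grid frequencies in the half-open band [lo, hi)."""
    lo, hi = band
    sel = (resset.freqs >= lo) & (resset.freqs < hi)
    if not sel.any():
        raise ValueError(f"band [{lo}, {hi}) contains no grid frequencies")
    return BinnedSeries(resset.bin_centers, resset.residual[:, sel].mean(axis=1),
                        name=name or f"band:{lo:g}-{hi:g}")


def sliding_band_power(resset: ResidualSpectrumSet, width: float = 4.0,
                       step: float = 2.0, f_start: float = 2.0,
                       f_stop: float = 46.0) -> dict:
    """Band power in a sliding frequency window; keys are window left edges."""
    edges = np.arange(f_start, f_stop + 1e-9, step)
    return {float(lo): band_power(resset, (lo, lo + width)) for lo in edges}
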