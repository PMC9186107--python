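"""Microsaccade detection and per-period eye/behavioral metrics.

Detection follows the median-based velocity-threshold scheme standard in the
fixational-eye-movement literature: velocities from a five-point central
difference, per-component thresholds at six times a median-based SD, an
elliptic two-dimensional criterion, a 6-ms minimum duration, and a 100-ms
minimum separation (closer events are merged).  Detected events with an
amplitude above 1 degree or a peak velocity above 100 deg/s are discarded as
ordinary saccades.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["MicrosaccadeEvent", "EyeMetricSeries", "compute_velocity",
           "detect_microsaccades", "main_sequence_correlation",
           "per_period_metrics", "events_to_frame"]


@dataclass
class MicrosaccadeEvent:
    onset: float           # s
    offset: float          # s
    amplitude: float       # degrees
    peak_velocity: float   # deg/s


@dataclass
class EyeMetricSeries:
    """Raw (un-binned) per-period metrics; times are period onsets in seconds."""

    msrate_times: np.ndarray   # qualifying prestimulus periods
    msrate: np.ndarray         # events / s
    pupil_times: np.ndarray    # stimulus periods
    pupil: np.ndarray          # mean pupil diameter, a.u.
    rt_times: np.ndarray       # hit trials
    reaction_time: np.ndarray  # s, 150 deg/s threshold crossing
    saccade_velocity: np.ndarray  # deg/s, peak of the response saccade


def compute_velocity(position: np.ndarray, rate: float) -> np.ndarray:
    """Eye velocity (deg/s) by the five-point central difference.

    v_t = rate * (x_{t+2} + x_{t+1} - x_{t-1} - x_{t-2}) / 6 per component;
    the two samples at each edge take the nearest interior value.
    """
    pos = np.atleast_2d(np.asarray(position, float).T).T  # (n, k)
    n = pos.shape[0]
    if n < 5:
        raise ValueError("need at least 5 samples to compute velocity")
    v = np.empty_like(pos)
    v[2:-2] = rate * (pos[4:] + pos[3:-1] - pos[1:-3] - pos[:-4]) / 6.0
    v[:2] = v[2]
    v[-2:] = v[-3]
    return v if np.asarray(position).ndim > 1 else v[:, 0]


def _median_sd(v: np.ndarray) -> float:
    """Median-based SD estimator: sqrt(median(v^2) - median(v)^2)."""
    return float(np.sqrt(np.median(v ** 2) - np.median(v) ** 2))


def detect_microsaccades(position: np.ndarray, rate: float,
                         velocity: np.ndarray | None = None,
                         threshold_multiplier: float = 6.0,
                         min_duration_s: float = 0.006,
                         min_separation_s: float = 0.100,
                         max_amplitude_deg: float = 1.0,
                         max_velocity_dps: float = 100.0):
    """Detect microsaccades in a 2-D gaze trace.

    Returns a list of :class:`MicrosaccadeEvent`.  Samples are candidates when
    (vx / (6 sx))^2 + (vy / (6 sy))^2 > 1 with s the per-component median-based
    SD; candidate runs of at least 6 ms are events; events separated by less
    than 100 ms are merged into one spanning both; amplitude is the Euclidean
    displacement between onset and offset positions; finally events exceeding
    the amplitude or velocity bound are removed.
    """
    pos = np.asarray(position, float)
    if velocity is None:
        velocity = compute_velocity(pos[:, :2], rate)
    v = np.asarray(velocity, float)
    if not np.all(np.isfinite(v)):
        raise ValueError("velocity contains non-finite samples")

    sx, sy = _median_sd(v[:, 0]), _median_sd(v[:, 1])
    if sx <= 0 or sy <= 0:
        warnings.warn("degenerate flat trace: zero velocity spread, no events")
        return []
    tx, ty = threshold_multiplier * sx, threshold_multiplier * sy
    crit = (v[:, 0] / tx) ** 2 + (v[:, 1] / ty) ** 2 > 1.0

    # candidate runs
    d = np.diff(crit.astype(np.int8))
    starts = np.flatnonzero(d == 1) + 1
    ends = np.flatnonzero(d == -1) + 1   # exclusive
    if crit[0]:
        starts = np.concatenate([[0], starts])
    if crit[-1]:
        ends = np.concatenate([ends, [crit.size]])
    min_len = max(int(round(min_duration_s * rate)), 1)
    keep = (ends - starts) >= min_len
    starts, ends = starts[keep], ends[keep]

    # merge events separated by < min_separation
    merged = []
    gap = int(round(min_separation_s * rate))
    for s, e in zip(starts, ends):
        if merged and s - merged[-1][1] < gap:
            merged[-1][1] = e
        else:
            merged.append([s, e])

    speed = np.hypot(v[:, 0], v[:, 1])
    out = []
    for s, e in merged:
        amp = float(np.hypot(pos[e - 1, 0] - pos[s, 0], pos[e - 1, 1] - pos[s, 1]))
        pv = float(speed[s:e].max())
        if amp > max_amplitude_deg or pv > max_velocity_dps:
            continue
        out.append(MicrosaccadeEvent(onset=s / rate, offset=(e - 1) / rate,
                                     amplitude=amp, peak_velocity=pv))
    return out


def events_to_frame(events) -> pd.DataFrame:
    return pd.DataFrame(
        [(m.onset, m.offset, m.amplitude, m.peak_velocity) for m in events],
        columns=["onset_s", "offset_s", "amplitude_deg", "peak_velocity_dps"])


def main_sequence_correlation(events) -> float:
    """Pearson r between amplitude and peak velocity (detector sanity check)."""
    if len(events) < 3:
        raise ValueError("need at least 3 events for the main sequence")
    amp = np.array([m.amplitude for m in events])
    pv = np.array([m.peak_velocity for m in events])
    return float(sps.pearsonr(amp, pv)[0])


def per_period_metrics(rec, events, rt_threshold_dps: float = 150.0,
                       velocity: np.ndarray | None = None) -> EyeMetricSeries:
    """Per-period eye metrics from a session and its detected microsaccades.

    Microsaccade rate is measured during prestimulus periods (excluding each
    trial's initial fixation period); pupil diameter is averaged over each
    stimulus period; reaction time and peak saccade velocity are computed on
    hit trials from the first crossing of the 150 deg/s velocity threshold
    after the orientation change.
    """
    rate = rec.eye_rate
    v = compute_velocity(rec.eye[:, :2], rate) if velocity is None else velocity
    speed = np.hypot(v[:, 0], v[:, 1])
    onsets = np.array([m.onset for m in events])

    pre = rec.prestimulus_periods()
    pre = pre[~pre.is_first_prestim]
    t0 = pre.onset.to_numpy()
    dur = pre.duration.to_numpy()
    counts = (np.searchsorted(np.sort(onsets), t0 + dur)
              - np.searchsorted(np.sort(onsets), t0)) if onsets.size else np.zeros(len(pre))
    msrate = counts / dur

    stim = rec.stimulus_periods()
    s0 = (stim.onset.to_numpy() * rate).round().astype(int)
    s1 = ((stim.onset + stim.duration).to_numpy() * rate).round().astype(int)
    s1 = np.minimum(s1, rec.eye.shape[0])
    csum = np.concatenate([[0.0], np.cumsum(rec.eye[:, 2])])
    pupil = (csum[s1] - csum[s0]) / np.maximum(s1 - s0, 1)

    hits = stim[stim.outcome == "hit"]
    rt_times, rts, svels = [], [], []
    for ct in hits.change_time.to_numpy():
        i0 = int(round(ct * rate))
        i1 = min(i0 + int(round(0.6 * rate)), speed.size)
        seg = speed[i0:i1]
        above = np.flatnonzero(seg > rt_threshold_dps)
        if above.size == 0:
            continue
        k = above[0]
        run_end = k
        while run_end < seg.size and seg[run_end] > rt_threshold_dps:
            run_end += 1
        rt_times.append(ct)
        rts.append(k / rate)
        svels.append(float(seg[k:run_end].max()))

    return EyeMetricSeries(
        msrate_times=t0, msrate=msrate,
        pupil_times=stim.onset.to_numpy(), pupil=pupil,
        rt_times=np.asarray(rt_times), reaction_time=np.asarray(rts),
        saccade_velocity=np.asarray(svels))
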