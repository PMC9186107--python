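"""End-to-end orchestration over a cohort of sessions.

``analyze_session`` turns one recording into aligned binned metric series
(residual band powers, pupil, microsaccade rate, drift, behavioral rates);
``run_cohort`` maps it over a synthetic or on-disk cohort and assembles the
cohort-level statistics: within-session correlation summaries per metric
pair, variance-magnitude associations, a cross-session null distribution,
the sliding-frequency correlation scan, and (optionally) per-session
timescale estimates from the 1-min-step binning variant.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import behavior_metrics, eeg_spectral, eye_metrics, slow_drift, stats
from .binning import align_series, bin_values
from .session_io import export_results, read_session
from .synth import SynthConfig, generate_session
from .timescale import cv_r2_curve, estimate_timescale

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "SessionMetrics", "CohortResult",
           "analyze_session", "run_cohort", "HEADLINE_PAIRS"]

#: the five headline metric pairs and the arousal-consistent sign of each
HEADLINE_PAIRS = [("alpha", "pupil"), ("alpha", "msrate"), ("alpha", "drift"),
                  ("drift", "pupil"), ("drift", "msrate")]


@dataclass
class PipelineConfig:
    """Cohort specification: synthetic (n_sessions) or on-disk (paths)."""

    n_sessions: int = 20
    paths: list = None                  # session bundle files; overrides synth
    synth: dict = field(default_factory=dict)   # SynthConfig overrides
    seed: int = 0
    window_min: float = 30.0
    step_min: float = 6.0
    min_segments: int = 10
    bands: dict = field(default_factory=lambda: dict(eeg_spectral.BANDS))
    pairs: list = field(default_factory=lambda: list(HEADLINE_PAIRS))
    sliding_scan: bool = True
    compute_timescales: bool = False
    out_dir: str = None

    def __post_init__(self):
        if self.paths is None and self.n_sessions < 1:
            raise ValueError("need at least 1 session")
        if self.window_min <= 0 or self.step_min <= 0:
            raise ValueError("window and step must be positive")


@dataclass
class SessionMetrics:
    session_id: str
    subject_id: str
    series: dict                     # name -> BinnedSeries
    sliding: dict = None             # left edge Hz -> BinnedSeries
    drift_estimate: object = None
    timescales: dict = None          # name -> TimescaleEstimate
    counts: dict = field(default_factory=dict)
    truth: object = None             # GroundTruth for synthetic sessions


@dataclass
class CohortResult:
    sessions: list                   # SessionMetrics
    correlations: dict               # "a~b" -> CorrelationSummary
    variance_magnitude: dict         # "a~b" -> VarianceMagnitudeResult
    null_r: np.ndarray
    frequency_scan: pd.DataFrame = None   # left edge, median r, p per window
    timescales: pd.DataFrame = None
    manifest: dict = None


def analyze_session(rec, window_min: float = 30.0, step_min: float = 6.0,
                    min_segments: int = 10, bands: dict = None,
                    sliding_scan: bool = False, compute_timescales: bool = False,
                    timescale_seed=None) -> SessionMetrics:
    """All binned metric series for one session, on a shared bin geometry."""
    bands = dict(eeg_spectral.BANDS) if bands is None else bands
    dur = rec.duration_min
    series, counts = {}, {}

    # ---- eye metrics -------------------------------------------------------
    velocity = eye_metrics.compute_velocity(rec.eye[:, :2], rec.eye_rate)
    ms_events = eye_metrics.detect_microsaccades(rec.eye[:, :2], rec.eye_rate,
                                                 velocity=velocity)
    counts["microsaccades_detected"] = len(ms_events)
    em = eye_metrics.per_period_metrics(rec, ms_events, velocity=velocity)
    series["msrate"] = bin_values(em.msrate_times / 60.0, em.msrate, dur,
                                  window_min, step_min, name="msrate")
    series["pupil"] = bin_values(em.pupil_times / 60.0, em.pupil, dur,
                                 window_min, step_min, name="pupil")
    if em.rt_times.size:
        series["rt"] = bin_values(em.rt_times / 60.0, em.reaction_time, dur,
                                  window_min, step_min, name="rt")
        series["sacc_vel"] = bin_values(em.rt_times / 60.0, em.saccade_velocity,
                                        dur, window_min, step_min, name="sacc_vel")

    # ---- EEG band power ----------------------------------------------------
    segs = eeg_spectral.extract_segments(rec)
    kept, log = eeg_spectral.screen_segments(segs, rec, eye_velocity=velocity)
    counts["segments_total"] = len(segs)
    counts["segments_kept"] = len(kept)
    freqs, power = eeg_spectral.segment_spectrum(kept)
    sbins = eeg_spectral.bin_spectra(freqs, power, kept.onsets, dur,
                                     window_min, step_min, min_segments)
    resset = eeg_spectral.remove_aperiodic(sbins)
    counts["bins"] = len(resset.bin_centers)
    for name, band in bands.items():
        series[name] = eeg_spectral.band_power(resset, band, name=name)
    sliding = eeg_spectral.sliding_band_power(resset) if sliding_scan else None

    # ---- slow drift --------------------------------------------------------
    drift_est = None
    if rec.n_neurons:
        res = slow_drift.residual_counts(rec.spike_counts, rec.orientations)
        stim_t = rec.stimulus_periods().onset.to_numpy()
        centers, binned = slow_drift.bin_residuals(res, stim_t, dur,
                                                   window_min, step_min)
        drift_est = slow_drift.compute_drift(centers, binned)
        series["drift"] = drift_est.series()

    # ---- behavior ----------------------------------------------------------
    beh = behavior_metrics.binned_outcome_rates(rec.events, dur,
                                                window_min, step_min)
    series["hit_rate"] = beh.hit_rate
    series["fa_rate"] = beh.false_alarm_rate

    # ---- timescales (1-min-step binning variant) ---------------------------
    timescales = None
    if compute_timescales:
        timescales = {}
        fine = {}
        if rec.n_neurons:
            c1, b1 = slow_drift.bin_residuals(res, stim_t, dur, window_min, 1.0)
            fine["drift"] = slow_drift.compute_drift(c1, b1).series()
        sb1 = eeg_spectral.bin_spectra(freqs, power, kept.onsets, dur,
                                       window_min, 1.0, min_segments)
        rs1 = eeg_spectral.remove_aperiodic(sb1)
        fine["alpha"] = eeg_spectral.band_power(rs1, bands.get("alpha", (8, 12)))
        for name, s in fine.items():
            r2 = cv_r2_curve(s.bin_centers, s.values, seed=timescale_seed)
            timescales[name] = estimate_timescale(np.arange(1.0, 91.0), r2)

    return SessionMetrics(session_id=rec.session_id, subject_id=rec.subject_id,
                          series=series, sliding=sliding,
                          drift_estimate=drift_est, timescales=timescales,
                          counts=counts)


def _build_sessions(cfg: PipelineConfig):
    """Yield (label, factory) pairs; each factory returns
    (SessionRecording, GroundTruth-or-None) when called."""
    if cfg.paths is not None:
        for p in cfg.paths:
            yield str(p), (lambda p=p: (read_session(p), None))
        return
    children = np.random.SeedSequence(cfg.seed).spawn(cfg.n_sessions)
    for i, child in enumerate(children):
        subj = "subjA" if i < (cfg.n_sessions + 1) // 2 else "subjB"
        sc = SynthConfig(**{"session_id": f"synth-{i:03d}", "subject_id": subj,
                            "seed": child.generate_state(1)[0] % (2 ** 31),
                            **cfg.synth})
        yield sc.session_id, (lambda sc=sc: generate_session(sc))


def run_cohort(cfg: PipelineConfig) -> CohortResult:
    """Run the full analysis over a cohort and assemble summary statistics."""
    sessions = []
    failures = []
    for label, factory in _build_sessions(cfg):
        try:  # one corrupt or failing session must not abort the cohort
            rec, truth = factory()
            sm = analyze_session(rec, cfg.window_min, cfg.step_min,
                                 cfg.min_segments, cfg.bands,
                                 sliding_scan=cfg.sliding_scan,
                                 compute_timescales=cfg.compute_timescales,
                                 timescale_seed=cfg.seed)
            sm.truth = truth
            sessions.append(sm)
        except Exception as exc:
            failures.append((label, repr(exc)))
            logger.warning("session %s failed: %r", label, exc)
    if not sessions:
        raise ValueError(f"every session failed: {failures}")

    def tuples(pair):
        a, b = pair
        return [(s.session_id, s.subject_id, s.series[a], s.series[b])
                for s in sessions if a in s.series and b in s.series]

    correlations, varmag = {}, {}
    enough = len(sessions) >= 5
    for pair in cfg.pairs:
        key = "~".join(pair)
        tups = tuples(pair)
        if not tups:
            continue
        if enough:
            correlations[key] = stats.within_session_correlations(
                tups, ci=True, seed=cfg.seed)
        else:
            rows = []
            for sid, subj, a, b in tups:
                va, vb, _ = align_series(a, b)
                if va.size < 3:
                    warnings.warn(f"session {sid}: only {va.size} common bins;"
                                  " excluded")
                    continue
                rows.append((sid, subj, stats.pearson_r(va, vb)[0], va.size))
            if not rows:
                continue
            per = pd.DataFrame(rows, columns=["session_id", "subject_id",
                                              "r", "n_bins"])
            correlations[key] = stats.CorrelationSummary(
                per_session=per, median_r=float(per.r.median()),
                median_r_by_subject={s: float(g.r.median())
                                     for s, g in per.groupby("subject_id")},
                p=None)
            warnings.warn("cohort too small for a signed-rank test; p omitted")
        subj_sizes = pd.Series([t[1] for t in tups]).value_counts()
        if len(tups) >= 3 and subj_sizes.min() >= 3:
            varmag[key] = stats.variance_magnitude(tups)

    # cross-session null on the first pair with full coverage
    null_r = np.array([])
    if enough and cfg.pairs:
        a, b = cfg.pairs[0]
        sa = [s.series[a] for s in sessions if a in s.series and b in s.series]
        sb = [s.series[b] for s in sessions if a in s.series and b in s.series]
        if len(sa) >= 2:
            null_r = stats.cross_session_null(sa, sb)

    scan = None
    if cfg.sliding_scan and enough:
        rows = []
        for edge in sorted(sessions[0].sliding or []):
            tups = [(s.session_id, s.subject_id, s.series["drift"],
                     s.sliding[edge]) for s in sessions
                    if s.sliding and "drift" in s.series]
            if len(tups) < 5:
                break
            summ = stats.within_session_correlations(tups)
            rows.append((edge, summ.median_r, summ.p))
        if rows:
            scan = pd.DataFrame(rows, columns=["left_edge_hz", "median_r", "p"])

    ts_frame = None
    if cfg.compute_timescales:
        rows = [(s.session_id, s.subject_id, name, est.timescale, est.sd_max,
                 est.censored)
                for s in sessions for name, est in (s.timescales or {}).items()]
        ts_frame = pd.DataFrame(rows, columns=["session_id", "subject_id",
                                               "metric", "timescale_min",
                                               "sd_max_min", "censored"])

    manifest = {
        "seed": cfg.seed, "n_sessions_requested": (len(cfg.paths) if cfg.paths
                                                   else cfg.n_sessions),
        "n_sessions_analyzed": len(sessions), "failures": failures,
        "window_min": cfg.window_min, "step_min": cfg.step_min,
        "min_segments": cfg.min_segments,
        "per_session_counts": {s.session_id: s.counts for s in sessions},
    }
    result = CohortResult(sessions=sessions, correlations=correlations,
                          variance_magnitude=varmag, null_r=null_r,
                          frequency_scan=scan, timescales=ts_frame,
                          manifest=manifest)
    if cfg.out_dir:
        _export(result, cfg.out_dir)
    return result


def _export(result: CohortResult, out_dir):
    import json
    from pathlib import Path

    tables = {}
    for key, summ in result.correlations.items():
        tables[f"correlations_{key.replace('~', '_vs_')}"] = summ.per_session
    for key, vm in result.variance_magnitude.items():
        tables[f"varmag_{key.replace('~', '_vs_')}"] = vm.per_session
    if result.null_r.size:
        tables["null_distribution"] = pd.DataFrame({"r": result.null_r})
    if result.frequency_scan is not None:
        tables["frequency_scan"] = result.frequency_scan
    if result.timescales is not None:
        tables["timescales"] = result.timescales
    for s in result.sessions:
        for name, series in s.series.items():
            tables[f"series_{s.session_id}_{name}"] = series
    export_results(tables, out_dir)
    Path(out_dir, "manifest.json").write_text(
        json.dumps(result.manifest, indent=2, default=str))
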