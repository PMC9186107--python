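"""Session-level statistics relating binned metrics across a cohort.

The central design: within each session a Pearson correlation between two
binned series; across sessions a Wilcoxon signed-rank test of whether the
median correlation is zero.  Because both series in a session are slow and
autocorrelated, a single within-session r is unreliable ("nonsense
correlation"); the cohort-level test and the variance-magnitude analysis are
the meaningful statistics, and a cross-session null (pairing series from
different sessions) verifies that the r distribution is centered on zero
under independence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .binning import align_series

__all__ = ["CorrelationSummary", "VarianceMagnitudeResult", "pearson_r",
           "wilcoxon_signed_rank", "within_session_correlations",
           "cross_session_null", "variance_magnitude", "bootstrap_median_ci"]


@dataclass
class CorrelationSummary:
    per_session: pd.DataFrame          # session_id, subject_id, r, n_bins
    median_r: float
    median_r_by_subject: dict
    p: float                           # Wilcoxon signed-rank, two-sided
    ci95: tuple = None                 # bootstrap CI on the median r
    null_distribution: np.ndarray = field(default=None, repr=False)


@dataclass
class VarianceMagnitudeResult:
    per_session: pd.DataFrame          # session_id, subject_id, var_a, var_b, za, zb
    r: float                           # pooled Pearson on z-scored variances
    p: float


def pearson_r(x, y):
    """Pearson product-moment correlation and two-sided p (t transformation)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length inputs with at least 3 points")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    if np.var(x) == 0 or np.var(y) == 0:
        raise ValueError("undefined correlation: an input has zero variance")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


def _signed_rank_statistic(values):
    """(W+, scaled integer ranks) after dropping zeros; ties mid-ranked."""
    v = np.asarray(values, float)
    v = v[v != 0]
    ranks = sps.rankdata(np.abs(v))        # mid-ranks: multiples of 0.5
    w_plus = ranks[v > 0].sum()
    scaled = np.rint(2 * ranks).astype(np.int64)
    return w_plus, scaled, v.size


def _exact_sf_cdf(scaled_ranks, w_scaled):
    """P(W <= w) and P(W >= w) by dynamic-programming convolution over ranks."""
    total = int(scaled_ranks.sum())
    dist = np.zeros(total + 1)
    dist[0] = 1.0
    for r in scaled_ranks:
        dist[r:] += dist[:-r] if r > 0 else dist
    dist /= dist.sum()
    w = int(round(w_scaled))
    return float(dist[:w + 1].sum()), float(dist[w:].sum())


def wilcoxon_signed_rank(values, exact_max_n: int = 25) -> float:
    """Two-sided signed-rank p for H0: symmetric about zero.

    Exact zeros are dropped.  The null distribution of W+ is enumerated
    exactly (by convolution over the mid-ranks) up to ``exact_max_n`` nonzero
    values; above that a normal approximation with tie correction and
    continuity correction is used.
    """
    v = np.asarray(values, float)
    if np.all(v == 0):
        warnings.warn("all values are zero; signed-rank p = 1")
        return 1.0
    w_plus, scaled, n = _signed_rank_statistic(v)
    if n < 5:
        raise ValueError("need at least 5 nonzero values for the signed-rank test")
    if n <= exact_max_n:
        lo, hi = _exact_sf_cdf(scaled, 2 * w_plus)
        return min(1.0, 2.0 * min(lo, hi))
    mean = n * (n + 1) / 4.0
    _, tie_counts = np.unique(scaled, return_counts=True)
    var = (n * (n + 1) * (2 * n + 1) / 24.0
           - (tie_counts ** 3 - tie_counts).sum() / 48.0)
    d = w_plus - mean
    z = (d - 0.5 * np.sign(d)) / np.sqrt(var)
    return float(2.0 * sps.norm.sf(abs(z)))


def within_session_correlations(sessions, min_bins: int = 3,
                                ci: bool = False, n_boot: int = 10000,
                                seed=None) -> CorrelationSummary:
    """Per-session Pearson r between two binned metrics, pooled across a cohort.

    ``sessions`` is an iterable of (session_id, subject_id, BinnedSeries a,
    BinnedSeries b).  Series are restricted to their common bins; sessions
    with fewer than ``min_bins`` common bins are excluded with a warning.
    The Wilcoxon signed-rank p tests whether the median r across sessions is
    zero (None when fewer than 5 sessions survive).
    """
    rows = []
    for sid, subj, a, b in sessions:
        va, vb, _ = align_series(a, b)
        if va.size < min_bins:
            warnings.warn(f"session {sid}: only {va.size} common bins; excluded")
            continue
        r, _ = pearson_r(va, vb)
        rows.append((sid, subj, r, va.size))
    per = pd.DataFrame(rows, columns=["session_id", "subject_id", "r", "n_bins"])
    if per.empty:
        raise ValueError("no session had enough common bins")
    med = float(per.r.median())
    by_subj = {s: float(g.r.median()) for s, g in per.groupby("subject_id")}
    rvals = per.r.to_numpy()
    p = wilcoxon_signed_rank(rvals) if np.count_nonzero(rvals) >= 5 else None
    ci95 = bootstrap_median_ci(rvals, n_boot=n_boot, seed=seed) if ci else None
    return CorrelationSummary(per_session=per, median_r=med,
                              median_r_by_subject=by_subj, p=p, ci95=ci95)


def cross_session_null(series_a, series_b, min_bins: int = 3) -> np.ndarray:
    """Null r distribution from mismatched sessions.

    For every ordered pair of distinct sessions, metric A from one is
    correlated with metric B from the other over the first
    min(len(a), len(b)) bins.  Sessions too short to overlap raise an error.
    """
    series_a, series_b = list(series_a), list(series_b)
    if len(series_a) < 2 or len(series_a) != len(series_b):
        raise ValueError("need at least 2 sessions with both metrics")
    out = []
    for i, a in enumerate(series_a):
        for j, b in enumerate(series_b):
            if i == j:
                continue
            m = min(len(a), len(b))
            if m < min_bins:
                raise ValueError(
                    f"sessions {i},{j}: incompatible bin geometry ({m} common bins)")
            r, _ = pearson_r(a.values[:m], b.values[:m])
            out.append(r)
    return np.asarray(out)


def _zscore_within(values, groups):
    values = np.asarray(values, float)
    z = np.empty_like(values)
    for g in np.unique(groups):
        sel = np.asarray(groups) == g
        sd = values[sel].std(ddof=1)
        if sd == 0:
            raise ValueError(f"zero variance within subject {g}")
        z[sel] = (values[sel] - values[sel].mean()) / sd
    return z


def variance_magnitude(sessions) -> VarianceMagnitudeResult:
    """Do the fluctuation magnitudes of two metrics covary across sessions?

    ``sessions`` is an iterable of (session_id, subject_id, BinnedSeries a,
    BinnedSeries b).  The within-session variance of each metric is z-scored
    separately per subject (to keep a between-subject variance difference from
    masquerading as an association) and the z-scores are pooled into one
    Pearson correlation.
    """
    rows = [(sid, subj, float(np.var(a.values, ddof=1)),
             float(np.var(b.values, ddof=1)))
            for sid, subj, a, b in sessions]
    per = pd.DataFrame(rows, columns=["session_id", "subject_id", "var_a", "var_b"])
    subjects = per.subject_id.to_numpy()
    if len(np.unique(subjects)) < 2:
        warnings.warn("single-subject cohort: z-scoring degenerates to global")
    for s, g in per.groupby("subject_id"):
        if len(g) < 3:
            raise ValueError(f"subject {s}: need at least 3 sessions")
    per["za"] = _zscore_within(per.var_a.to_numpy(), subjects)
    per["zb"] = _zscore_within(per.var_b.to_numpy(), subjects)
    r, p = pearson_r(per.za.to_numpy(), per.zb.to_numpy())
    return VarianceMagnitudeResult(per_session=per, r=r, p=p)


def bootstrap_median_ci(values, n_boot: int = 10000, seed=None,
                        level: float = 0.95):
    """Percentile bootstrap CI on the median (resampling sessions)."""
    v = np.asarray(values, float)
    rng = np.random.default_rng(seed)
    meds = np.median(rng.choice(v, size=(n_boot, v.size), replace=True), axis=1)
    alpha = (1.0 - level) / 2.0
    return (float(np.quantile(meds, alpha)), float(np.quantile(meds, 1 - alpha)))
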