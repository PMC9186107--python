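"""Slow drift: the first principal component of binned residual spike counts.

Orientation tuning is removed by subtracting each neuron's session-mean
response per orientation; the residuals are binned with the shared sliding
window and projected onto their first principal component.  The projection's
sign is aligned so that the majority of neuron weights are nonnegative,
giving every session a common reference frame in which larger drift values
mean higher firing in most of the population.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .binning import BinnedSeries, bin_matrix

__all__ = ["DriftEstimate", "residual_counts", "bin_residuals", "compute_drift"]


@dataclass
class DriftEstimate:
    bin_centers: np.ndarray        # minutes
    drift: np.ndarray              # PC1 projection, spike-count units
    weights: np.ndarray            # per-neuron loading on PC1, unit norm
    variance_explained: float      # fraction in [0, 1]

    def series(self) -> BinnedSeries:
        return BinnedSeries(self.bin_centers, self.drift, name="drift")


def residual_counts(spike_counts: np.ndarray, orientations: np.ndarray) -> np.ndarray:
    """Counts minus each neuron's session-mean response for that orientation.

    After subtraction every neuron's mean over each orientation's periods
    is zero, so stimulus tuning cannot leak into the drift axis.
    """
    counts = np.asarray(spike_counts, float)
    ori = np.asarray(orientations)
    if counts.ndim != 2 or counts.shape[1] != ori.size:
        raise ValueError("need one orientation label per stimulus period")
    res = counts.copy()
    for label in (45.0, 135.0):
        sel = ori == label
        if not sel.any():
            raise ValueError(f"no periods with orientation {label:g}")
        res[:, sel] -= counts[:, sel].mean(axis=1, keepdims=True)
    return res


def bin_residuals(residuals: np.ndarray, period_times_s, duration_min: float,
                  window_min: float = 30.0, step_min: float = 6.0,
                  min_count: int = 10):
    """Sliding-window means of residual counts per neuron.

    Shares the binning geometry of the EEG/eye metrics, so bin centers line
    up exactly across modalities within a session.
    Returns (bin_centers_min, binned (n_bins x n_neurons)).
    """
    centers, binned, _ = bin_matrix(
        np.asarray(period_times_s) / 60.0, residuals, duration_min,
        window_min, step_min, min_count=min_count)
    return centers, binned


def compute_drift(bin_centers, binned_residuals) -> DriftEstimate:
    """PC1 of the bins-by-neurons matrix, sign-aligned to majority-positive weights.

    Neuron-wise means across bins are removed, the first right singular vector
    gives the weights, and the projection of the centered matrix onto it gives
    the drift.  If strictly more weights are negative than nonnegative the
    sign is flipped; on an exact tie the sign making the weight sum
    nonnegative is chosen (left as computed when the sum is zero).
    """
    X = np.atleast_2d(np.asarray(binned_residuals, float))
    if X.shape[0] < 2:
        raise ValueError("need at least 2 bins for a drift estimate")
    Xc = X - X.mean(axis=0, keepdims=True)
    if not Xc.any():
        raise ValueError("degenerate input: binned residuals have zero variance")
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    w = Vt[0]
    drift = Xc @ w
    n_neg = int((w < 0).sum())
    n_nonneg = w.size - n_neg
    flip = n_neg > n_nonneg or (n_neg == n_nonneg and w.sum() < 0)
    if flip:
        w, drift = -w, -drift
    var_expl = float(s[0] ** 2 / (s ** 2).sum())
    return DriftEstimate(bin_centers=np.asarray(bin_centers, float),
                         drift=drift, weights=w, variance_explained=var_expl)
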