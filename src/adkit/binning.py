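"""Sliding-window binning shared by every metric in the pipeline.

All slow time series in this package are produced by the same geometry: a
30-min window slid in 6-min steps from session start (a 1-min step variant is
used for timescale estimation).  Sharing one implementation guarantees that
bin centers are identical across metrics within a session, so series can be
correlated bin-by-bin without interpolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["BinnedSeries", "window_edges", "bin_values", "bin_matrix"]


@dataclass
class BinnedSeries:
    """A metric reduced to a sliding-window time series.

    bin_centers are minutes from session start; values are the window means.
    """

    bin_centers: np.ndarray  # minutes
    values: np.ndarray
    name: str = ""
    counts: np.ndarray = field(default=None, repr=False)

    def __post_init__(self):
        self.bin_centers = np.asarray(self.bin_centers, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.bin_centers.shape != self.values.shape:
            raise ValueError("bin_centers and values must have equal length")

    def __len__(self) -> int:
        return self.bin_centers.size


def window_edges(duration_min: float, window_min: float = 30.0,
                 step_min: float = 6.0) -> np.ndarray:
    """Left edges (minutes) of half-open windows [t, t+window) tiling a session.

    Windows start at 0 and advance by ``step_min`` as long as the full window
    fits inside the session, so a 120-min session yields
    floor((120-30)/6)+1 = 16 windows at the defaults.
    """
    if duration_min < window_min:
        raise ValueError(
            f"session ({duration_min:g} min) shorter than window ({window_min:g} min)")
    if step_min <= 0 or window_min <= 0:
        raise ValueError("window and step must be positive")
    n = int(np.floor((duration_min - window_min) / step_min + 1e-9)) + 1
    return np.arange(n) * step_min


def _window_sums(times_min, values, edges, window_min):
    """Sum and count of values per half-open window, via sorted searchsorted."""
    order = np.argsort(times_min, kind="stable")
    t = np.asarray(times_min, float)[order]
    v = np.asarray(values, float)[..., order]
    lo = np.searchsorted(t, edges, side="left")
    hi = np.searchsorted(t, edges + window_min, side="left")
    csum = np.concatenate(
        [np.zeros(v.shape[:-1] + (1,)), np.cumsum(v, axis=-1)], axis=-1)
    sums = csum[..., hi] - csum[..., lo]
    counts = hi - lo
    return sums, counts


def bin_values(times_min, values, duration_min, window_min=30.0, step_min=6.0,
               min_count: int = 1, name: str = "") -> BinnedSeries:
    """Mean of ``values`` (sampled at ``times_min``) in each sliding window.

    Windows with fewer than ``min_count`` samples are dropped.
    """
    edges = window_edges(duration_min, window_min, step_min)
    sums, counts = _window_sums(times_min, values, edges, window_min)
    keep = counts >= max(min_count, 1)
    centers = edges[keep] + window_min / 2.0
    with np.errstate(invalid="ignore"):
        means = sums[keep] / counts[keep]
    return BinnedSeries(centers, means, name=name, counts=counts[keep])


def bin_matrix(times_min, matrix, duration_min, window_min=30.0, step_min=6.0,
               min_count: int = 1):
    """Window means of a (features x samples) matrix.

    Returns (bin_centers_min, binned (n_bins x features), counts); the bin
    geometry is identical to :func:`bin_values` on the same session.
    """
    matrix = np.atleast_2d(np.asarray(matrix, float))
    edges = window_edges(duration_min, window_min, step_min)
    sums, counts = _window_sums(times_min, matrix, edges, window_min)
    keep = counts >= max(min_count, 1)
    centers = edges[keep] + window_min / 2.0
    binned = (sums[:, keep] / counts[keep]).T
    return centers, binned, counts[keep]


def align_series(a: BinnedSeries, b: BinnedSeries, decimals: int = 6):
    """Restrict two binned series to their common bin centers."""
    ca = np.round(a.bin_centers, decimals)
    cb = np.round(b.bin_centers, decimals)
    common, ia, ib = np.intersect1d(ca, cb, return_indices=True)
    return a.values[ia], b.values[ib], common
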