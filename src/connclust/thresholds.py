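"""Cluster-forming threshold selection via isocontour significance curves.

The cluster-forming threshold t0 is a free parameter of any cluster test: a
low t0 favours large diffuse clusters, a high t0 favours focal ones, and at
the extremes the test either loses spatial specificity or degenerates into a
single-connection test.  The isocontour procedure maps this trade-off
without double dipping: for a grid of t0 values, a (possibly reduced)
permutation distribution of maximum CSS extents is built and the critical
cluster size — the smallest extent significant at the chosen FWE level — is
recorded.  Plotting critical size against t0 and fitting a cubic spline
gives a curve of constant significance from which the t0 associated with a
desired critical extent can be interpolated.  Only permutation maxima are
used; the identity labelling's clusters are never evaluated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline, PchipInterpolator
from sklearn.isotonic import IsotonicRegression

from .grid import MaskedGrid
from .permutation import (
    MaxStatDistribution,
    PermutationScheme,
    _counts_from_links,
    _t_blocks,
    _upper_diffs,
    enumerate_flips,
)
from .cluster import _max_css_cms_from_counts

__all__ = [
    "IsocontourCurve",
    "critical_cluster_size",
    "isocontour",
    "threshold_for_size",
]


def critical_cluster_size(dist: MaxStatDistribution, alpha: float) -> int:
    """Smallest integer cluster size significant at FWE level ``alpha``.

    Returns the smallest integer s such that the fraction of permutation
    maxima >= s is at most ``alpha``; clusters of size >= s are significant.
    With a degenerate all-zero distribution this is 1 (any non-empty cluster
    is significant).
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    values = np.sort(np.asarray(dist.values))
    P = values.size
    if alpha < 1.0 / P:
        raise ValueError(
            f"alpha={alpha} unattainable with {P} permutations "
            f"(minimum achievable level is {1.0 / P:.6g})"
        )
    budget = alpha * P

    def exceed(s: int) -> int:  # count of maxima >= s
        return P - int(np.searchsorted(values, s, side="left"))

    lo, hi = 0, int(values[-1]) + 1
    while lo < hi:  # binary search: exceed(s) is non-increasing in s
        mid = (lo + hi) // 2
        if exceed(mid) <= budget:
            hi = mid
        else:
            lo = mid + 1
    return max(lo, 1)


@dataclass
class IsocontourCurve:
    """Critical CSS extent as a function of the cluster-forming threshold."""

    threshold_grid: np.ndarray
    raw_sizes: np.ndarray          # critical sizes as measured
    critical_sizes: np.ndarray     # after non-increasing (isotonic) adjustment
    alpha: float
    n_permutations: int
    seed: int | None = None
    _spline: CubicSpline = field(init=False, repr=False)

    def __post_init__(self) -> None:
        tg = np.asarray(self.threshold_grid, dtype=float)
        if tg.size < 3 or np.any(np.diff(tg) <= 0):
            raise ValueError("threshold grid must be >= 3 strictly "
                             "increasing values")
        self._spline = CubicSpline(tg, np.asarray(self.critical_sizes, float))

    def interpolate(self, t0) -> np.ndarray:
        """Spline-interpolated critical size at threshold(s) t0."""
        return self._spline(t0)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "t0": self.threshold_grid,
                "critical_size_raw": self.raw_sizes,
                "critical_size": self.critical_sizes,
            }
        )


def default_threshold_grid(dof: int, n_points: int = 9) -> np.ndarray:
    """t-values whose nominal two-sided p spans 1e-2 .. 1e-8 at given dof."""
    from scipy import stats

    p = np.logspace(-2, -8, n_points)
    return stats.t.isf(p / 2, dof)


def isocontour(
    mats_A,
    mats_B,
    grid: MaskedGrid,
    threshold_grid=None,
    alpha: float = 0.05,
    n_permutations: int = 1000,
    seed: int | None = 0,
    scheme: PermutationScheme | None = None,
    block: int = 256,
) -> IsocontourCurve:
    """Critical cluster size across a grid of cluster-forming thresholds.

    One shared permutation scheme is used for every threshold (shared flips
    remove between-grid-point Monte Carlo jitter), and the per-permutation
    t-matrix is computed once and thresholded at each grid value.  Raw
    critical sizes are isotonically adjusted to be non-increasing in t0
    before the cubic spline fit; subset-permutation noise can otherwise
    break the monotonicity that holds in expectation.
    """
    D, iu, ju, N = _upper_diffs(mats_A, mats_B)
    n = D.shape[0]
    if threshold_grid is None:
        threshold_grid = default_threshold_grid(n - 1)
    tg = np.asarray(threshold_grid, dtype=float)
    if tg.size < 3:
        raise ValueError("need at least 3 thresholds")
    if scheme is None:
        total = 1 << n
        if n_permutations >= total:
            scheme = enumerate_flips(n, mode="full")
        else:
            scheme = enumerate_flips(n, mode="subset",
                                     n_permutations=n_permutations, seed=seed)
    P = scheme.n_permutations
    max_css = np.zeros((tg.size, P), dtype=np.int64)
    for start, t in _t_blocks(D, scheme.flips, block):
        for k, t0 in enumerate(tg):
            links = t > t0
            for b in range(t.shape[0]):
                counts = _counts_from_links(links[b], iu, ju, N)
                css, _ = _max_css_cms_from_counts(counts, grid)
                max_css[k, start + b] = css
    raw = np.array(
        [
            critical_cluster_size(
                MaxStatDistribution("css", max_css[k], t0=tg[k]), alpha
            )
            for k in range(tg.size)
        ],
        dtype=float,
    )
    iso = IsotonicRegression(increasing=False)
    adjusted = iso.fit_transform(tg, raw)
    return IsocontourCurve(
        threshold_grid=tg,
        raw_sizes=raw,
        critical_sizes=adjusted,
        alpha=alpha,
        n_permutations=P,
        seed=scheme.seed,
    )


def threshold_for_size(curve: IsocontourCurve, target_size: float,
                       n_dense: int = 4001) -> float:
    """Interpolate the t0 associated with a target critical cluster extent.

    The fitted spline is evaluated on a dense grid and the largest t0 at
    which it still reaches the target size is returned — for a
    non-increasing curve this is the crossing point, and it is well defined
    on plateaus.  No extrapolation: the target must lie within the observed
    critical-size range.
    """
    lo, hi = float(np.min(curve.critical_sizes)), float(np.max(curve.critical_sizes))
    if not lo <= target_size <= hi:
        raise ValueError(
            f"target size {target_size} outside the curve's observed range "
            f"[{lo}, {hi}]; refusing to extrapolate"
        )
    tg = curve.threshold_grid
    dense = np.linspace(tg[0], tg[-1], n_dense)
    sizes = curve.interpolate(dense)
    reach = np.flatnonzero(sizes >= target_size)
    if reach.size == 0:
        # spline overshoot below the target everywhere: fall back to a
        # monotone interpolant through the adjusted points
        mono = PchipInterpolator(tg, curve.critical_sizes)
        sizes = mono(dense)
        reach = np.flatnonzero(sizes >= target_size)
    return float(dense[reach[-1]])


def plot_isocontour(curve: IsocontourCurve, path=None, ax=None):
    """Plot critical cluster extent against the cluster-forming threshold.

    Requires matplotlib (optional dependency).  Returns the axes.
    """
    import matplotlib
    if path is not None:
        matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    dense = np.linspace(curve.threshold_grid[0], curve.threshold_grid[-1],
                        400)
    ax.plot(dense, curve.interpolate(dense), "-", lw=1.2,
            label="cubic spline")
    ax.plot(curve.threshold_grid, curve.critical_sizes, "ko", ms=4,
            label="computed")
    ax.set_xlabel("cluster-forming t-threshold")
    ax.set_ylabel(f"critical cluster extent (p<{curve.alpha:g} FWE)")
    ax.legend(frameon=False)
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
    return ax
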