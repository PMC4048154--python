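"""Sign-flip permutation inference with maximum-statistic FWE control.

For a repeated-measures design the exchangeability unit is the per-subject
condition difference: under the null, flipping the sign of any subject's
difference leaves the data distribution unchanged.  Each permutation
recomputes the element-wise paired-t matrix, and the maximum of the chosen
statistic (CSS extent, CMS mass, or the element-wise max/min t) is recorded,
giving a null distribution whose percentiles control the family-wise error
rate across the whole connectome.

The engine works on the vector of upper-triangle condition differences: sign
flips leave squared differences unchanged, so per permutation only the
flipped column means need recomputing — one matrix product for a whole block
of permutations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cluster import _max_css_cms_from_counts
from .grid import MaskedGrid

__all__ = [
    "PermutationScheme",
    "MaxStatDistribution",
    "enumerate_flips",
    "null_distribution_cluster",
    "cluster_null_distributions",
    "fwe_pvalue",
    "elementwise_maxt_test",
]


@dataclass
class PermutationScheme:
    """A set of per-subject sign-flip vectors, identity labelling included."""

    n_subjects: int
    mode: str                     # "full" | "subset"
    flips: np.ndarray             # (n_permutations, n_subjects) of +/-1
    seed: int | None = None

    @property
    def n_permutations(self) -> int:
        return self.flips.shape[0]


@dataclass
class MaxStatDistribution:
    """Per-permutation maxima of one statistic, identity value included."""

    statistic_kind: str           # "css" | "cms" | "max_t" | "min_t"
    values: np.ndarray            # one scalar per permutation; index 0 = identity
    t0: float | None = None
    sign: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.size == 0:
            raise ValueError("empty permutation distribution")

    @property
    def n_permutations(self) -> int:
        return self.values.size

    def percentile(self, q: float) -> float:
        return float(np.percentile(self.values, q))


def enumerate_flips(
    n: int,
    mode: str = "full",
    n_permutations: int | None = None,
    seed: int | None = None,
) -> PermutationScheme:
    """Enumerate or sample per-subject sign-flip vectors.

    Full mode returns all 2**n labellings (row 0 is the identity, all +1).
    Subset mode returns the identity plus ``n_permutations - 1`` distinct
    non-identity labellings sampled without replacement, deterministically
    for a given seed.
    """
    if n < 2:
        raise ValueError(f"need at least 2 subjects, got {n}")
    total = 1 << n
    if mode == "full":
        codes = np.arange(total, dtype=np.int64)
    elif mode == "subset":
        if n_permutations is None:
            raise ValueError("subset mode requires n_permutations")
        if n_permutations > total:
            raise ValueError(
                f"requested {n_permutations} permutations but only "
                f"{total} labellings exist for n={n}"
            )
        rng = np.random.default_rng(seed)
        if n <= 24:
            others = rng.choice(total - 1, size=n_permutations - 1,
                                replace=False) + 1
        else:  # rejection sampling when 2**n is too large to materialise
            chosen: set[int] = set()
            while len(chosen) < n_permutations - 1:
                for c in rng.integers(1, total, size=n_permutations):
                    if len(chosen) >= n_permutations - 1:
                        break
                    chosen.add(int(c))
            others = np.fromiter(chosen, dtype=np.int64)
        codes = np.concatenate([[0], others])
    else:
        raise ValueError(f"mode must be 'full' or 'subset', got {mode!r}")
    bits = (codes[:, None] >> np.arange(n)) & 1
    flips = (1 - 2 * bits).astype(np.int8)  # bit 0 -> +1, bit 1 -> -1
    return PermutationScheme(n_subjects=n, mode=mode, flips=flips, seed=seed)


# ---------------------------------------------------------------------------
# internal: upper-triangle difference engine


def _as_values(mats) -> np.ndarray:
    return np.stack([m.values if hasattr(m, "values") else np.asarray(m, float)
                     for m in mats])


def _upper_diffs(mats_A, mats_B):
    """Per-subject upper-triangle differences D (n, M) plus pair indices."""
    A = _as_values(mats_A)
    B = _as_values(mats_B)
    if A.shape != B.shape:
        raise ValueError(f"condition shapes differ: {A.shape} vs {B.shape}")
    n, N, _ = A.shape
    iu, ju = np.triu_indices(N, k=1)
    D = (A - B)[:, iu, ju]
    return D, iu, ju, N


def _t_blocks(D: np.ndarray, flips: np.ndarray, block: int = 256):
    """Yield (start, t) blocks of permuted paired-t vectors, shape (b, M).

    Sign flips do not change sum(d^2), so the per-element sum of squares is
    computed once; each block needs only one (b, n) @ (n, M) product, and
    the paired t reduces to ``t = s1 * sqrt((n-1) / (n*ssq - s1^2))`` where
    s1 is the flipped per-element sum of differences.
    """
    n, M = D.shape
    nssq = n * np.einsum("ij,ij->j", D, D)      # constant across flips
    tiny = nssq * 1e-12
    for start in range(0, flips.shape[0], block):
        F = flips[start:start + block].astype(np.float64)
        s1 = F @ D                               # (b, M) flipped sums
        denom = np.square(s1)
        np.subtract(nssq[None, :], denom, out=denom)
        # zero-variance elements have denom == 0 up to rounding; they never
        # form links, so force t = 0 there
        bad = denom <= tiny[None, :]
        np.maximum(denom, 1e-300, out=denom)
        np.divide(n - 1.0, denom, out=denom)
        np.sqrt(denom, out=denom)
        s1 *= denom                              # t, in place
        s1[bad] = 0.0
        yield start, s1


def _counts_from_links(sup: np.ndarray, iu, ju, N: int) -> np.ndarray:
    """Per-voxel link counts from a boolean upper-triangle link vector."""
    idx = np.flatnonzero(sup)
    counts = np.bincount(iu[idx], minlength=N)
    counts += np.bincount(ju[idx], minlength=N)
    return counts


def cluster_null_distributions(
    mats_A,
    mats_B,
    t0: float,
    scheme: PermutationScheme,
    grid: MaskedGrid,
    sign: str = "positive",
    block: int = 256,
    include_elementwise: bool = False,
) -> dict[str, MaxStatDistribution]:
    """Null distributions of max CSS and max CMS in one permutation pass.

    For every sign-flip labelling the paired-t matrix is recomputed,
    thresholded at +t0 (or -t0 for ``sign="negative"``), turned into a
    link-count map, and the largest cluster's extent and mass recorded.  By
    the sign symmetry of the flip set the distribution is identical for
    positive and negative thresholds under full enumeration, so one
    distribution serves clusters of both signs.
    """
    if t0 <= 0:
        raise ValueError(f"cluster-forming threshold must be > 0, got {t0}")
    D, iu, ju, N = _upper_diffs(mats_A, mats_B)
    if N != grid.n_voxels:
        raise ValueError(f"matrix N={N} does not match grid N={grid.n_voxels}")
    P = scheme.n_permutations
    max_css = np.zeros(P, dtype=np.int64)
    max_cms = np.zeros(P, dtype=np.int64)
    max_t = np.empty(P) if include_elementwise else None
    min_t = np.empty(P) if include_elementwise else None
    for start, t in _t_blocks(D, scheme.flips, block):
        links = (t > t0) if sign == "positive" else (t < -t0)
        if include_elementwise:
            max_t[start:start + t.shape[0]] = t.max(axis=1)
            min_t[start:start + t.shape[0]] = t.min(axis=1)
        for b in range(t.shape[0]):
            counts = _counts_from_links(links[b], iu, ju, N)
            css, cms = _max_css_cms_from_counts(counts, grid)
            max_css[start + b] = css
            max_cms[start + b] = cms
    dists = {
        "css": MaxStatDistribution("css", max_css, t0=t0, sign=sign),
        "cms": MaxStatDistribution("cms", max_cms, t0=t0, sign=sign),
    }
    if include_elementwise:
        dists["max_t"] = MaxStatDistribution("max_t", max_t)
        dists["min_t"] = MaxStatDistribution("min_t", min_t)
    return dists


def null_distribution_cluster(
    mats_A,
    mats_B,
    t0: float,
    statistic_kind: str,
    scheme: PermutationScheme,
    grid: MaskedGrid,
    sign: str = "positive",
) -> MaxStatDistribution:
    """Null distribution of the maximum CSS extent or CMS mass."""
    if statistic_kind not in ("css", "cms"):
        raise ValueError("statistic_kind must be 'css' or 'cms'")
    dists = cluster_null_distributions(mats_A, mats_B, t0, scheme, grid, sign)
    return dists[statistic_kind]


def fwe_pvalue(
    observed: float, dist: MaxStatDistribution, sidedness: str = "one"
) -> float:
    """FWE-corrected permutation p-value of an observed cluster statistic.

    One-sided p is the fraction of permutation maxima >= the observed value
    (ties count as extreme; the identity labelling is a member of the
    distribution, so p >= 1/n_permutations).  Two-sided reporting doubles the
    one-sided p, capped at 1 — a cluster is significant at level p when it
    exceeds the 100(1 - p/2)th percentile of the maximum distribution.
    """
    p = float(np.count_nonzero(dist.values >= observed)) / dist.n_permutations
    if sidedness == "two":
        p = min(1.0, 2.0 * p)
    elif sidedness != "one":
        raise ValueError("sidedness must be 'one' or 'two'")
    return p


def elementwise_maxt_test(
    mats_A,
    mats_B,
    scheme: PermutationScheme,
    alpha: float = 0.05,
    block: int = 256,
):
    """Element-wise max/min-t permutation test (the single-connection baseline).

    Per permutation the maximum and minimum paired-t value over all unique
    off-diagonal elements are recorded.  An observed element is declared
    significant (two-sided, FWE-corrected at ``alpha``) when its t lies in
    the top alpha/2 tail of the max-t distribution or the bottom alpha/2 tail
    of the min-t distribution, using the same counting convention as
    :func:`fwe_pvalue`.

    Returns
    -------
    (max_t_dist, min_t_dist, sig_elements) where ``sig_elements`` is a
    symmetric boolean N x N matrix.
    """
    D, iu, ju, N = _upper_diffs(mats_A, mats_B)
    P = scheme.n_permutations
    max_t = np.empty(P)
    min_t = np.empty(P)
    t_obs: np.ndarray | None = None
    identity_row = None
    for start, t in _t_blocks(D, scheme.flips, block):
        max_t[start:start + t.shape[0]] = t.max(axis=1)
        min_t[start:start + t.shape[0]] = t.min(axis=1)
        for b in range(t.shape[0]):
            if np.all(scheme.flips[start + b] == 1):
                t_obs = t[b].copy()
                identity_row = start + b
    if t_obs is None:
        raise ValueError("permutation scheme does not include the identity")
    # count(max_t >= t_e) and count(min_t <= t_e) via sorted search
    p_hi = (P - np.searchsorted(np.sort(max_t), t_obs, side="left")) / P
    p_lo = np.searchsorted(np.sort(min_t), t_obs, side="right") / P
    sig_vec = (p_hi <= alpha / 2) | (p_lo <= alpha / 2)
    sig = np.zeros((N, N), dtype=bool)
    sig[iu, ju] = sig_vec
    sig |= sig.T
    max_dist = MaxStatDistribution("max_t", max_t)
    min_dist = MaxStatDistribution("min_t", min_t)
    return max_dist, min_dist, sig
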