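"""Cluster size (CSS) and cluster mass (CMS) statistics.

The workflow: an element-wise paired t-statistic is computed for every
voxel-pair connectivity value, a cluster-forming threshold t0 binarizes the
matrix into an adjacency matrix of "cluster links", row sums of that matrix
give each voxel's link count, the counts are mapped back into image space,
and spatially contiguous groups of voxels with at least one link each are
extracted as clusters.  A cluster's CSS is its voxel extent; its CMS is the
total link count over its member voxels (row-sum semantics, so a link whose
two endpoints fall in the same cluster contributes twice — an optional
once-per-link mode is available).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .grid import MaskedGrid, connectivity_structure

__all__ = [
    "TestStatMatrix",
    "AdjacencyMatrix",
    "LinkCountMap",
    "ClusterResult",
    "paired_t_matrix",
    "threshold_to_adjacency",
    "link_count_map",
    "extract_clusters",
    "max_statistics",
]

logger = logging.getLogger(__name__)


@dataclass
class TestStatMatrix:
    """Symmetric N x N matrix of element-wise test statistics.

    Diagonal entries are undefined (a voxel's correlation with itself never
    changes) and are set to NaN so no threshold can pick them up.
    """

    values: np.ndarray
    dof: int
    statistic_kind: str = "paired-t"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        np.fill_diagonal(self.values, np.nan)

    @property
    def n_voxels(self) -> int:
        return self.values.shape[0]


@dataclass
class AdjacencyMatrix:
    """Binary matrix of suprathreshold connectivity changes (cluster links)."""

    values: np.ndarray
    threshold_value: float
    sign: str

    @property
    def n_voxels(self) -> int:
        return self.values.shape[0]


@dataclass
class LinkCountMap:
    """Per-voxel count of cluster links, in the grid's flat-index order."""

    counts: np.ndarray
    grid: MaskedGrid
    sign: str = "positive"

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (self.grid.n_voxels,):
            raise ValueError(
                f"counts length {self.counts.shape} does not match grid "
                f"N={self.grid.n_voxels}"
            )

    def to_volume(self) -> np.ndarray:
        return self.grid.embed(self.counts.astype(np.int64))


@dataclass
class ClusterResult:
    """One spatially contiguous cluster with its CSS extent and CMS mass."""

    member_coords: np.ndarray          # (k, ndim) grid coordinates
    member_indices: np.ndarray         # (k,) flat voxel indices
    css_extent: int
    cms_mass: int
    sign: str
    peak_voxel: tuple[int, ...]        # member with maximal link count
    peak_world_mm: np.ndarray
    fwe_p: float | None = None
    fwe_p_css: float | None = None
    fwe_p_cms: float | None = None


def paired_t_matrix(mats_A, mats_B, flips=None) -> TestStatMatrix:
    """Element-wise paired t-statistics between two conditions.

    For each voxel pair, per-subject connectivity differences d_i = A_i - B_i
    (optionally sign-flipped per subject, the permutation primitive of the
    repeated-measures design) are summarised as
    ``t = mean(d) / (sd(d) / sqrt(n))`` with ``dof = n - 1``.

    Elements whose differences have zero variance (e.g. A identical to B for
    every subject) get t = 0 — they can never form links — and their count is
    logged rather than failing the whole run.
    """
    A = np.stack([m.values if hasattr(m, "values") else np.asarray(m, float)
                  for m in mats_A])
    B = np.stack([m.values if hasattr(m, "values") else np.asarray(m, float)
                  for m in mats_B])
    if A.shape != B.shape:
        raise ValueError(f"condition shapes differ: {A.shape} vs {B.shape}")
    n = A.shape[0]
    if n < 2:
        raise ValueError(f"paired t needs at least 2 subjects, got {n}")
    d = A - B
    if flips is not None:
        flips = np.asarray(flips, dtype=float)
        if flips.shape != (n,) or not np.all(np.abs(flips) == 1):
            raise ValueError("flips must be a length-n vector of +/-1")
        d = d * flips[:, None, None]
    # t = s1 * sqrt((n-1) / (n*ssq - s1^2)) — algebraically mean/(sd/sqrt(n))
    s1 = d.sum(axis=0)
    nssq = n * np.einsum("ijk,ijk->jk", d, d)
    denom = nssq - s1**2
    zero = denom <= nssq * 1e-12  # zero difference variance
    n_zero = int(zero.sum()) - A.shape[1]  # diagonal is always zero-variance
    if n_zero > 0:
        logger.info("%d off-diagonal zero-variance elements set to t=0", n_zero)
    t = s1 * np.sqrt((n - 1.0) / np.maximum(denom, 1e-300))
    t[zero] = 0.0
    return TestStatMatrix(t, dof=n - 1, statistic_kind="paired-t")


def threshold_to_adjacency(T: TestStatMatrix, t0: float,
                           sign: str = "positive") -> AdjacencyMatrix:
    """Binarize the test-statistic matrix at the cluster-forming threshold.

    Strict inequality: for ``sign="positive"`` an element links iff t > t0,
    for ``sign="negative"`` iff t < -t0.  The diagonal is forced to zero.
    """
    if t0 <= 0:
        raise ValueError(f"cluster-forming threshold must be > 0, got {t0}")
    if sign == "positive":
        adj = T.values > t0
    elif sign == "negative":
        adj = T.values < -t0
    else:
        raise ValueError(f"sign must be 'positive' or 'negative', got {sign!r}")
    adj = adj.astype(np.uint8)
    np.fill_diagonal(adj, 0)
    return AdjacencyMatrix(adj, threshold_value=t0, sign=sign)


def link_count_map(adj: AdjacencyMatrix, grid: MaskedGrid) -> LinkCountMap:
    """Row sums of the adjacency matrix, mapped back onto the mask."""
    if adj.n_voxels != grid.n_voxels:
        raise ValueError(
            f"adjacency N={adj.n_voxels} does not match grid N={grid.n_voxels}"
        )
    counts = adj.values.sum(axis=1).astype(np.int64)
    return LinkCountMap(counts, grid, sign=adj.sign)


def _label_counts(counts: np.ndarray, grid: MaskedGrid):
    """Label connected components of {counts >= 1} in image space."""
    vol = grid.embed((counts > 0).astype(np.uint8))
    labels, n_labels = ndimage.label(vol, structure=grid.structure)
    return labels[grid.mask], n_labels  # per-voxel label in flat order


def extract_clusters(
    lcm: LinkCountMap,
    adjacency: AdjacencyMatrix | None = None,
    mass_mode: str = "endpoint",
) -> list[ClusterResult]:
    """Connected components of linked voxels with CSS extent and CMS mass.

    Components are found over voxels with at least one link, using
    face-or-edge adjacency (18-connectivity in 3-D, 8-connectivity in 2-D).
    Clusters are sorted by extent descending, ties broken by the
    lexicographically smallest peak coordinate, so output order is
    deterministic and independent of voxel enumeration.

    Parameters
    ----------
    mass_mode : {"endpoint", "link"}
        "endpoint" (default): CMS = sum of member link counts, i.e. the
        row-sum semantics of the workflow — an intra-cluster link counts at
        both endpoints.  "link": each link with at least one endpoint in the
        cluster counts once; requires ``adjacency``.
    """
    grid = lcm.grid
    counts = np.asarray(lcm.counts)
    flat_labels, n_labels = _label_counts(counts, grid)
    if n_labels == 0:
        return []
    if mass_mode == "link" and adjacency is None:
        raise ValueError("mass_mode='link' requires the adjacency matrix")

    clusters: list[ClusterResult] = []
    for lab in range(1, n_labels + 1):
        members = np.flatnonzero(flat_labels == lab)
        member_counts = counts[members]
        if mass_mode == "endpoint":
            mass = int(member_counts.sum())
        else:
            sub = np.asarray(adjacency.values)[members, :]
            total = int(sub.sum())                     # endpoint-counted
            internal = int(sub[:, members].sum())      # both endpoints inside
            mass = total - internal // 2               # each link once
        coords = grid.coords[members]
        # peak = member with maximal count, lexicographic coordinate tie-break
        best = np.max(member_counts)
        cand = coords[member_counts == best]
        order = np.lexsort(cand.T[::-1])
        peak = tuple(int(c) for c in cand[order[0]])
        clusters.append(
            ClusterResult(
                member_coords=coords,
                member_indices=members,
                css_extent=int(len(members)),
                cms_mass=mass,
                sign=lcm.sign,
                peak_voxel=peak,
                peak_world_mm=grid.world_coords(np.asarray(peak))[0],
            )
        )
    clusters.sort(key=lambda c: (-c.css_extent, c.peak_voxel))
    return clusters


def max_statistics(lcm: LinkCountMap) -> tuple[int, int]:
    """Maximum CSS extent and maximum CMS mass over all clusters.

    Returns (0, 0) for a map with no linked voxels.  Note the maxima may be
    attained by different clusters.
    """
    counts = np.asarray(lcm.counts)
    return _max_css_cms_from_counts(counts, lcm.grid)


def _max_css_cms_from_counts(counts: np.ndarray,
                             grid: MaskedGrid) -> tuple[int, int]:
    """Fast path used by the permutation engine: maxima without full results."""
    if not (counts > 0).any():
        return 0, 0
    flat_labels, n_labels = _label_counts(counts, grid)
    linked = flat_labels > 0
    extents = np.bincount(flat_labels[linked], minlength=n_labels + 1)[1:]
    masses = np.bincount(
        flat_labels[linked], weights=counts[linked].astype(float),
        minlength=n_labels + 1,
    )[1:]
    return int(extents.max()), int(masses.max())
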