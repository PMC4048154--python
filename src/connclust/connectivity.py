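"""From masked voxel timecourses to subject-level connectivity matrices.

This module covers the in-scope preprocessing (group mask construction from
probabilistic grey-matter maps, low-pass filtering, cosine baseline
correction, nuisance regression) and the Pearson-correlation connectivity
matrix computed for every subject and condition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .grid import MaskedGrid

__all__ = [
    "TimecourseSet",
    "ConnectivityMatrix",
    "build_group_mask",
    "preprocess_timecourses",
    "pearson_connectivity",
    "cosine_basis",
    "fisher_z",
    "save_connectivity",
    "load_connectivity",
]

logger = logging.getLogger(__name__)


@dataclass
class TimecourseSet:
    """Per-subject, per-condition masked voxel timecourses.

    data has shape ``(n_subjects, n_conditions, N, T)`` where N is the number
    of mask voxels (in the grid's flat-index order) and T the number of
    timepoints, all finite, with the same T for every scan.
    """

    data: np.ndarray
    tr_seconds: float
    grid: MaskedGrid
    condition_labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError(
                "data must be (n_subjects, n_conditions, N, T), "
                f"got shape {self.data.shape}"
            )
        if self.data.shape[2] != self.grid.n_voxels:
            raise ValueError(
                f"voxel axis {self.data.shape[2]} does not match grid "
                f"N={self.grid.n_voxels}"
            )
        if self.data.shape[3] < 3:
            raise ValueError("need at least 3 timepoints")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("timecourses contain non-finite values")
        if self.condition_labels is None:
            # default labels A, B, C, ... matching the condition axis
            self.condition_labels = tuple(
                chr(ord("A") + i) for i in range(self.data.shape[1])
            )
        if len(self.condition_labels) != self.data.shape[1]:
            raise ValueError("condition_labels must match the condition axis")

    @property
    def n_subjects(self) -> int:
        return self.data.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[3]

    @property
    def nyquist_hz(self) -> float:
        return 1.0 / (2.0 * self.tr_seconds)


@dataclass
class ConnectivityMatrix:
    """N x N Pearson correlation matrix for one subject and condition."""

    values: np.ndarray
    subject: str | int = ""
    condition: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError(f"connectivity matrix must be square, got {v.shape}")

    def validate(self, atol: float = 1e-10) -> None:
        """Check symmetry, unit diagonal and the [-1, 1] range."""
        v = self.values
        if not np.allclose(v, v.T, atol=atol):
            raise ValueError("connectivity matrix is not symmetric")
        if not np.allclose(np.diag(v), 1.0, atol=atol):
            raise ValueError("connectivity matrix diagonal is not 1")
        if np.nanmax(np.abs(v)) > 1.0 + atol:
            raise ValueError("connectivity values outside [-1, 1]")


def build_group_mask(
    prob_maps, threshold: float, voxel_size_mm=(1.0,), affine=None
) -> MaskedGrid:
    """Build a binary group mask from per-subject probabilistic maps.

    The across-subject mean probability is computed per grid cell and cells
    with mean >= ``threshold`` are included (inclusive convention).

    Parameters
    ----------
    prob_maps : sequence of numpy.ndarray
        Per-subject probability volumes on one shared grid, values in [0, 1].
    threshold : float
        Inclusion probability, in (0, 1).  The reference analysis used 0.8.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"threshold must be in (0, 1), got {threshold}")
    maps = [np.asarray(m, dtype=float) for m in prob_maps]
    if not maps:
        raise ValueError("no probability maps given")
    shape = maps[0].shape
    for i, m in enumerate(maps):
        if m.shape != shape:
            raise ValueError(
                f"probability map {i} has shape {m.shape}, expected {shape}"
            )
    mean_prob = np.mean(maps, axis=0)
    mask = mean_prob >= threshold
    if not mask.any():
        raise ValueError(
            f"group mask is empty at probability threshold {threshold}"
        )
    return MaskedGrid(mask, voxel_size_mm=voxel_size_mm, affine=affine)


def cosine_basis(n_timepoints: int, order: int) -> np.ndarray:
    """Discrete cosine baseline regressors plus an intercept.

    Columns: a constant, then ``cos(pi * k * (t + 1/2) / T)`` for
    k = 1..order — the DCT-II drift basis conventionally used for fMRI
    baseline correction.
    """
    t = np.arange(n_timepoints)
    cols = [np.ones(n_timepoints)]
    for k in range(1, order + 1):
        cols.append(np.cos(np.pi * k * (t + 0.5) / n_timepoints))
    return np.column_stack(cols)


def _residualize(data: np.ndarray, design: np.ndarray, what: str) -> np.ndarray:
    """Least-squares residuals of each row of ``data`` against ``design``."""
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        raise ValueError(
            f"rank-deficient design for {what}: rank {rank} < "
            f"{design.shape[1]} columns"
        )
    coef, *_ = np.linalg.lstsq(design, data.T, rcond=None)
    return data - (design @ coef).T


def lowpass_filter(
    data: np.ndarray, cutoff_hz: float, tr_seconds: float, order: int = 4
) -> np.ndarray:
    """Zero-phase Butterworth low-pass along the last axis."""
    nyquist = 1.0 / (2.0 * tr_seconds)
    if cutoff_hz >= nyquist:
        raise ValueError(
            f"cutoff {cutoff_hz} Hz is not below the Nyquist frequency "
            f"{nyquist} Hz (TR = {tr_seconds} s)"
        )
    sos = signal.butter(order, cutoff_hz, btype="low", fs=1.0 / tr_seconds,
                        output="sos")
    return signal.sosfiltfilt(sos, data, axis=-1)


def preprocess_timecourses(
    ts: TimecourseSet,
    cutoff_hz: float = 0.1,
    cosine_order: int = 2,
    nuisance=None,
    filter_order: int = 4,
) -> TimecourseSet:
    """Low-pass filter, cosine baseline correction and nuisance regression.

    Each voxel timecourse is (i) low-pass filtered at ``cutoff_hz`` with a
    zero-phase Butterworth filter, then (ii) residualized against a discrete
    cosine basis of order ``cosine_order`` plus an intercept and, when given,
    (iii) the per-scan nuisance covariates (e.g. realignment parameters),
    demeaned and included in the same regression.  The residual timecourses
    have mean ~0.

    Parameters
    ----------
    ts : TimecourseSet
    cutoff_hz : float
        Low-pass cutoff frequency in Hz (default 0.1, the BOLD band edge).
    cosine_order : int
        Highest cosine harmonic in the drift basis (default 2).
    nuisance : array or nested sequence, optional
        Either a single ``(T, k)`` covariate matrix applied to every scan or
        an ``(n_subjects, n_conditions)`` nested sequence of per-scan
        matrices.
    filter_order : int
        Butterworth filter order (recorded in the run log by the pipeline).
    """
    T = ts.n_timepoints
    filtered = lowpass_filter(ts.data, cutoff_hz, ts.tr_seconds, filter_order)

    base = cosine_basis(T, cosine_order)
    out = np.empty_like(filtered)
    for s in range(ts.n_subjects):
        for c in range(ts.data.shape[1]):
            design = base
            if nuisance is not None:
                shared = isinstance(nuisance, np.ndarray) and nuisance.ndim == 2
                nui = np.asarray(nuisance if shared else nuisance[s][c],
                                 dtype=float)
                if nui.shape[0] != T:
                    raise ValueError(
                        f"nuisance matrix for scan ({s},{c}) has "
                        f"{nui.shape[0]} rows, expected {T}"
                    )
                if nui.shape[1] >= T:
                    raise ValueError("more nuisance covariates than timepoints")
                design = np.column_stack([base, nui - nui.mean(axis=0)])
            out[s, c] = _residualize(filtered[s, c], design, f"scan ({s},{c})")
    return TimecourseSet(out, ts.tr_seconds, ts.grid, ts.condition_labels)


def pearson_connectivity(
    ts_one_scan: np.ndarray,
    subject="",
    condition: str = "",
    on_zero_variance: str = "raise",
) -> ConnectivityMatrix:
    """Pearson correlation matrix of one scan's voxel timecourses.

    Parameters
    ----------
    ts_one_scan : numpy.ndarray
        ``(N, T)`` voxel timecourses.
    on_zero_variance : {"raise", "zero"}
        A constant timecourse has no defined correlation.  "raise" (default)
        fails listing the offending voxel indices; "zero" sets the affected
        correlations to 0 with a warning, which keeps degenerate synthetic
        inputs usable.
    """
    x = np.asarray(ts_one_scan, dtype=float)
    if x.ndim != 2:
        raise ValueError(f"expected (N, T) timecourses, got shape {x.shape}")
    sd = x.std(axis=1)
    dead = np.flatnonzero(sd == 0.0)
    if dead.size:
        if on_zero_variance == "raise":
            raise ValueError(
                f"zero-variance timecourses at voxel indices {dead.tolist()}"
            )
        logger.warning(
            "%d zero-variance voxels; their correlations set to 0", dead.size
        )
    centered = x - x.mean(axis=1, keepdims=True)
    norm = np.where(sd == 0.0, 1.0, sd * np.sqrt(x.shape[1]))
    z = centered / norm[:, None]
    corr = z @ z.T
    if dead.size:
        corr[dead, :] = 0.0
        corr[:, dead] = 0.0
    np.clip(corr, -1.0, 1.0, out=corr)
    corr = (corr + corr.T) / 2.0
    np.fill_diagonal(corr, 1.0)
    return ConnectivityMatrix(corr, subject=subject, condition=condition)


def fisher_z(values: np.ndarray, eps: float = 1e-7) -> np.ndarray:
    """Fisher z-transform of correlation values (variance-stabilising).

    Off by default throughout the package — the cluster statistics test
    connectivity values directly — but available for designs that prefer
    approximately normal inputs.  Values are clipped away from +/-1.
    """
    return np.arctanh(np.clip(values, -1.0 + eps, 1.0 - eps))


def save_connectivity(mat: ConnectivityMatrix, path, grid=None) -> None:
    """Persist a connectivity matrix as a dense array plus a JSON sidecar.

    The sidecar (``<path>.json``) records the subject and condition labels,
    the matrix size and, when a grid is given, its shape and mask hash so a
    matrix can be matched to the voxel universe it was computed on.
    """
    import json
    from pathlib import Path

    path = Path(path)
    np.save(path, mat.values)
    meta = {
        "subject": str(mat.subject),
        "condition": mat.condition,
        "n_voxels": int(mat.values.shape[0]),
    }
    if grid is not None:
        meta["grid_shape"] = list(grid.shape)
        meta["mask_hash"] = grid.mask_hash()
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(meta, indent=2, sort_keys=True)
    )


def load_connectivity(path) -> ConnectivityMatrix:
    """Load a matrix saved by :func:`save_connectivity`."""
    import json
    from pathlib import Path

    path = Path(path)
    if not path.suffix:
        path = path.with_suffix(".npy")
    values = np.load(path)
    meta_path = path.with_suffix(path.suffix + ".json")
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    return ConnectivityMatrix(values, subject=meta.get("subject", ""),
                              condition=meta.get("condition", ""))
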