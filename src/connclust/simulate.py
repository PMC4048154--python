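"""Synthetic connectome data and AFROC evaluation of CSS/CMS.

The generator emulates a single-slice study: groups of scans whose voxel
timecourses are unit-variance Gaussian noise, with a shared 0.1 Hz sinusoid
added to a compact "primary cluster" of voxels and to voxels scattered over
the rest of the slice in the contrast group.  All groups then receive the
same order-1 autoregressive temporal structure, spatial Gaussian smoothing
and low-pass filtering, so the only group difference is the contrast.

Detection performance is scored AFROC-style: the true-positive rate is the
fraction of primary-cluster voxels recovered by clusters whose statistic
(CSS extent or CMS mass) meets a discrimination threshold, comparing the
contrast group against a noise group; the false-positive rate is the
probability of *any* cluster meeting the threshold when two noise-only
groups are compared — the family-wise notion of a false positive that CSS
and CMS are built to control.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import ndimage, signal

from .cluster import extract_clusters, link_count_map, paired_t_matrix, \
    threshold_to_adjacency
from .connectivity import lowpass_filter, pearson_connectivity
from .grid import MaskedGrid

__all__ = [
    "SimulationConfig",
    "TrialOutcome",
    "ROCCurve",
    "generate_groups",
    "run_trial",
    "run_simulation",
    "SimulationResult",
    "partial_auc",
]

_FWHM_TO_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))


@dataclass
class SimulationConfig:
    """Study conditions for one simulated comparison.

    Defaults are the reference conditions: twelve scans per group, a 0.1 Hz
    contrast sinusoid, contrast-to-noise CN = A/sigma_N of 0.4, a primary
    cluster of radius 2 voxels, scattered contrast voxels numbering CV = 2
    times the primary-cluster size, cluster-forming threshold t0 = 5, 8 mm
    FWHM smoothing on 4 mm voxels, AR(1) coefficient 0.3 and a 0.1 Hz
    low-pass.  The grid is a 20 x 20 fully-true 2-D slice and T = 120
    timepoints at TR = 2 s (a scaled slice; see the methods note).
    """

    shape: tuple[int, ...] = (20, 20)
    voxel_size_mm: tuple[float, ...] = (4.0, 4.0)
    n_subjects: int = 12
    n_timepoints: int = 120
    tr_seconds: float = 2.0
    contrast_freq_hz: float = 0.1
    cn: float = 0.4               # contrast-to-noise A / sigma_N
    radius: float = 2.0           # primary cluster radius, in voxels
    cv: float = 2.0               # scattered voxels as multiple of primary size
    t0: float = 5.0               # cluster-forming threshold
    ar_coefficient: float = 0.3
    smooth_fwhm_mm: float = 8.0
    lowpass_hz: float = 0.1
    lowpass_order: int = 4
    n_trials: int = 1000
    seed: int = 0
    center: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if self.cn < 0:
            raise ValueError("contrast-to-noise must be >= 0")
        if self.radius < 1:
            raise ValueError("primary cluster radius must be >= 1")
        if self.cv < 0:
            raise ValueError("scattered-voxel multiple must be >= 0")

    def grid(self) -> MaskedGrid:
        return MaskedGrid(np.ones(self.shape, dtype=bool),
                          voxel_size_mm=self.voxel_size_mm)

    def to_dict(self) -> dict:
        return asdict(self)


def primary_cluster_indices(config: SimulationConfig,
                            grid: MaskedGrid) -> np.ndarray:
    """Flat indices of the primary cluster: a Euclidean disc of radius R."""
    center = config.center
    if center is None:
        center = tuple(s // 2 for s in grid.shape)
    d2 = ((grid.coords - np.asarray(center)) ** 2).sum(axis=1)
    members = np.flatnonzero(d2 <= config.radius**2)
    if members.size == 0:
        raise ValueError("primary cluster is empty — center outside the mask?")
    return members


def _temporal_structure(x: np.ndarray, config: SimulationConfig) -> np.ndarray:
    """AR(1) recursion along time: y[t] = x[t] + phi * y[t-1]."""
    if config.ar_coefficient == 0.0:
        return x
    return signal.lfilter([1.0], [1.0, -config.ar_coefficient], x, axis=-1)


def _smooth_spatial(scans: np.ndarray, config: SimulationConfig,
                    grid: MaskedGrid) -> np.ndarray:
    """Gaussian smoothing of each timepoint's image, per scan.

    The masked values are embedded into the full grid (zeros outside), the
    volume is smoothed, and masked values are read back.
    """
    if config.smooth_fwhm_mm == 0.0:
        return scans
    sigma_vox = [
        config.smooth_fwhm_mm / _FWHM_TO_SIGMA / vs
        for vs in grid.voxel_size_mm
    ]
    n_scans, N, T = scans.shape
    out = np.empty_like(scans)
    for s in range(n_scans):
        vol = np.zeros(grid.shape + (T,))
        vol[grid.mask] = scans[s]
        vol = ndimage.gaussian_filter(vol, sigma=tuple(sigma_vox) + (0.0,))
        out[s] = vol[grid.mask]
    return out


def _postprocess(scans: np.ndarray, config: SimulationConfig,
                 grid: MaskedGrid) -> np.ndarray:
    scans = _temporal_structure(scans, config)
    scans = _smooth_spatial(scans, config, grid)
    return lowpass_filter(scans, config.lowpass_hz, config.tr_seconds,
                          config.lowpass_order)


def generate_groups(config: SimulationConfig, trial_seed: int):
    """Generate one trial's noise groups A, B and contrast group C.

    A and B are independent groups of ``n_subjects`` scans of unit-variance
    Gaussian noise.  C equals A plus a zero-phase sinusoid of amplitude
    CN * sigma_N (sigma_N = 1, measured before smoothing) at the contrast
    frequency, added to the primary-cluster voxels and to
    ``round(CV * |primary|)`` voxels sampled uniformly without replacement
    from the rest of the mask (re-drawn per trial).  All three groups then
    receive identical AR temporal structure, spatial smoothing and low-pass
    filtering.  With CN = 0, C is bit-identical to A.

    Returns
    -------
    (A, B, C, primary, scattered) where the group arrays have shape
    ``(n_subjects, N, T)`` and primary/scattered are flat voxel indices.
    """
    grid = config.grid()
    rng = np.random.default_rng(trial_seed)
    N, T = grid.n_voxels, config.n_timepoints
    shape = (config.n_subjects, N, T)
    noise_A = rng.standard_normal(shape)
    noise_B = rng.standard_normal(shape)

    primary = primary_cluster_indices(config, grid)
    outside = np.setdiff1d(np.arange(N), primary)
    n_scatter = int(round(config.cv * primary.size))
    if n_scatter > outside.size:
        raise ValueError(
            f"{n_scatter} scattered contrast voxels requested but only "
            f"{outside.size} mask voxels lie outside the primary cluster"
        )
    scattered = rng.choice(outside, size=n_scatter, replace=False)

    contrast_voxels = np.concatenate([primary, scattered])
    t = np.arange(T) * config.tr_seconds
    sine = config.cn * np.sin(2.0 * np.pi * config.contrast_freq_hz * t)
    noise_C = noise_A.copy()
    noise_C[:, contrast_voxels, :] += sine

    A = _postprocess(noise_A, config, grid)
    B = _postprocess(noise_B, config, grid)
    C = _postprocess(noise_C, config, grid)
    return A, B, C, primary, scattered


def _group_matrices(group: np.ndarray) -> list[np.ndarray]:
    return [pearson_connectivity(s, on_zero_variance="zero").values
            for s in group]


def _clusters_both_signs(mats_x, mats_y, config, grid):
    """Paired-t at t0, clusters of both signs, pooled into one list."""
    tmat = paired_t_matrix(mats_x, mats_y)
    clusters = []
    for sign in ("positive", "negative"):
        adj = threshold_to_adjacency(tmat, config.t0, sign)
        lcm = link_count_map(adj, grid)
        clusters.extend(extract_clusters(lcm))
    return clusters


@dataclass
class TrialOutcome:
    """Per-trial detection record, evaluable at any discrimination threshold.

    For each method the contrast-side clusters are kept as statistics sorted
    descending with the cumulative count of primary-cluster voxels recovered,
    so TPR(theta) is a table lookup; the noise-side comparison contributes a
    single maximum statistic whose comparison with theta is the FPR
    indicator.
    """

    trial_id: int
    n_primary: int
    tpr_stats: dict[str, np.ndarray]       # per method, sorted descending
    tpr_cum_hits: dict[str, np.ndarray]    # |C ∩ union of first k clusters|
    fpr_max: dict[str, int]                # max statistic, noise vs noise

    def tpr(self, method: str, thresholds) -> np.ndarray:
        """Fraction of primary-cluster voxels detected at each threshold."""
        stats = self.tpr_stats[method]
        cum = self.tpr_cum_hits[method]
        thresholds = np.asarray(thresholds, dtype=float)
        if stats.size == 0:
            return np.zeros(thresholds.shape)
        # number of clusters with statistic >= theta
        k = stats.size - np.searchsorted(stats[::-1], thresholds, side="left")
        hits = np.where(k > 0, cum[np.maximum(k - 1, 0)], 0)
        return hits / self.n_primary

    def fpr(self, method: str, thresholds) -> np.ndarray:
        """1 when any noise-vs-noise cluster reaches the threshold."""
        return (np.asarray(thresholds, dtype=float)
                <= self.fpr_max[method]).astype(float)


def run_trial(config: SimulationConfig, trial_seed: int,
              methods=("css", "cms")) -> TrialOutcome:
    """One simulation trial: generate groups, cluster both comparisons.

    TPR side compares the contrast group C against noise group B; FPR side
    compares the two noise-only groups A and B.  Detection is two-sided:
    clusters of either sign enter the detected set.
    """
    grid = config.grid()
    A, B, C, primary, _ = generate_groups(config, trial_seed)
    mats_B = _group_matrices(B)
    tpr_clusters = _clusters_both_signs(_group_matrices(C), mats_B, config,
                                        grid)
    fpr_clusters = _clusters_both_signs(_group_matrices(A), mats_B, config,
                                        grid)

    primary_set = set(primary.tolist())
    tpr_stats: dict[str, np.ndarray] = {}
    tpr_cum: dict[str, np.ndarray] = {}
    fpr_max: dict[str, int] = {}
    for method in methods:
        key = "css_extent" if method == "css" else "cms_mass"
        stats = np.array([getattr(c, key) for c in tpr_clusters], dtype=float)
        order = np.argsort(-stats)
        seen: set[int] = set()
        cum = np.zeros(order.size, dtype=np.int64)
        running = 0
        for rank, ci in enumerate(order):
            for v in tpr_clusters[ci].member_indices:
                if v not in seen:
                    seen.add(int(v))
                    if int(v) in primary_set:
                        running += 1
            cum[rank] = running
        tpr_stats[method] = stats[order]
        tpr_cum[method] = cum
        fpr_max[method] = int(
            max((getattr(c, key) for c in fpr_clusters), default=0)
        )
    return TrialOutcome(
        trial_id=trial_seed,
        n_primary=primary.size,
        tpr_stats=tpr_stats,
        tpr_cum_hits=tpr_cum,
        fpr_max=fpr_max,
    )


@dataclass
class ROCCurve:
    """Mean AFROC operating points across trials for one method."""

    method: str
    thresholds: np.ndarray
    mean_tpr: np.ndarray
    mean_fpr: np.ndarray
    n_trials: int
    config: SimulationConfig | None = None

    def restricted(self, fpr_max: float = 0.05) -> "ROCCurve":
        """Operating points with mean FPR inside [0, fpr_max]."""
        keep = self.mean_fpr <= fpr_max
        return ROCCurve(self.method, self.thresholds[keep],
                        self.mean_tpr[keep], self.mean_fpr[keep],
                        self.n_trials, self.config)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "threshold": self.thresholds,
                "mean_tpr": self.mean_tpr,
                "mean_fpr": self.mean_fpr,
                "method": self.method,
            }
        )


def partial_auc(mean_fpr: np.ndarray, mean_tpr: np.ndarray,
                fpr_max: float = 0.05) -> float:
    """Trapezoidal area under the (FPR, TPR) curve for FPR in [0, fpr_max].

    The curve is anchored at (0, 0) and linearly interpolated at the
    ``fpr_max`` boundary when an operating point straddles it.
    """
    order = np.argsort(mean_fpr, kind="stable")
    f = np.concatenate([[0.0], np.asarray(mean_fpr)[order]])
    t = np.concatenate([[0.0], np.asarray(mean_tpr)[order]])
    if f[-1] > fpr_max:
        hi = np.searchsorted(f, fpr_max, side="right")
        t_at = np.interp(fpr_max, f, t)
        f = np.concatenate([f[:hi], [fpr_max]])
        t = np.concatenate([t[:hi], [t_at]])
    return float(np.trapezoid(t, f))


@dataclass
class SimulationResult:
    """Trial collection with ROC curve and partial-AUC summaries."""

    config: SimulationConfig
    methods: tuple[str, ...]
    trials: list[TrialOutcome]

    def _threshold_grid(self, method: str) -> np.ndarray:
        vals = {t.fpr_max[method] for t in self.trials}
        for t in self.trials:
            vals.update(t.tpr_stats[method].tolist())
        vals.add(0.0)
        return np.sort(np.array(sorted(vals), dtype=float))[::-1]

    def roc_curve(self, method: str, thresholds=None) -> ROCCurve:
        if thresholds is None:
            thresholds = self._threshold_grid(method)
        thresholds = np.asarray(thresholds, dtype=float)
        tpr = np.mean([t.tpr(method, thresholds) for t in self.trials], axis=0)
        fpr = np.mean([t.fpr(method, thresholds) for t in self.trials], axis=0)
        return ROCCurve(method, thresholds, tpr, fpr, len(self.trials),
                        self.config)

    def _fpr_threshold_grid(self, method: str) -> np.ndarray:
        """Thresholds where the mean FPR changes — sufficient for the pAUC.

        Between consecutive noise-side maxima the FPR is constant, so extra
        thresholds only add zero-width segments to the FPR integral.
        """
        vals = sorted({t.fpr_max[method] for t in self.trials} | {0.0})
        return np.asarray(vals, dtype=float)[::-1]

    def partial_auc(self, method: str, fpr_max: float = 0.05) -> float:
        curve = self.roc_curve(method, self._fpr_threshold_grid(method))
        return partial_auc(curve.mean_fpr, curve.mean_tpr, fpr_max)

    def partial_auc_se(self, method: str, fpr_max: float = 0.05,
                       n_boot: int = 200, seed: int = 0) -> float:
        """Bootstrap (over trials) standard error of the partial AUC."""
        return self._bootstrap(lambda r: r.partial_auc(method, fpr_max),
                               n_boot, seed)

    def partial_auc_diff_se(self, method_a: str, method_b: str,
                            fpr_max: float = 0.05, n_boot: int = 200,
                            seed: int = 0) -> float:
        """Paired bootstrap SE of pAUC(method_a) - pAUC(method_b)."""
        return self._bootstrap(
            lambda r: r.partial_auc(method_a, fpr_max)
            - r.partial_auc(method_b, fpr_max),
            n_boot, seed,
        )

    def _bootstrap(self, stat, n_boot: int, seed: int) -> float:
        rng = np.random.default_rng(seed)
        n = len(self.trials)
        reps = np.empty(n_boot)
        for i in range(n_boot):
            idx = rng.integers(0, n, size=n)
            sub = SimulationResult(self.config, self.methods,
                                   [self.trials[j] for j in idx])
            reps[i] = stat(sub)
        return float(reps.std(ddof=1))


def run_simulation(config: SimulationConfig, methods=("css", "cms"),
                   n_trials: int | None = None) -> SimulationResult:
    """Run repeated trials, independently and reproducibly seeded.

    Trial seeds are spawned from the master seed with
    :class:`numpy.random.SeedSequence`, so two runs with the same master
    seed produce identical results and individual trials are independent.
    """
    if n_trials is None:
        n_trials = config.n_trials
    if n_trials < 1:
        raise ValueError("need at least one trial")
    seeds = np.random.SeedSequence(config.seed).generate_state(n_trials)
    trials = [
        run_trial(config, int(s) % (2**31), methods) for s in seeds
    ]
    return SimulationResult(config=config, methods=tuple(methods),
                            trials=trials)


def save_config(config: SimulationConfig, path) -> None:
    """Write a simulation configuration as a YAML text file."""
    import yaml

    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)


def load_config(path) -> SimulationConfig:
    """Read a simulation configuration written by :func:`save_config`."""
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh)
    for key in ("shape", "voxel_size_mm"):
        if key in raw and raw[key] is not None:
            raw[key] = tuple(raw[key])
    if raw.get("center") is not None:
        raw["center"] = tuple(raw["center"])
    return SimulationConfig(**raw)


def plot_roc(curves, path=None, ax=None, fpr_max: float = 0.05):
    """Plot AFROC curves (mean TPR vs mean FPR), restricted to low FPR."""
    import matplotlib
    if path is not None:
        matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    for curve in curves:
        r = curve.restricted(fpr_max)
        order = np.argsort(r.mean_fpr)
        ax.plot(r.mean_fpr[order], r.mean_tpr[order], "-o", ms=3,
                label=curve.method.upper())
    ax.set_xlabel("false positive rate (any false cluster)")
    ax.set_ylabel("true positive rate (primary cluster coverage)")
    ax.set_xlim(0, fpr_max)
    ax.legend(frameon=False)
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
    return ax
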