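"""End-to-end analysis: volumes in, cluster tables and maps out.

Ties the stages together for a repeated-measures comparison: load and
preprocess masked timecourses, compute per-scan connectivity matrices, the
element-wise paired-t matrix, optionally fix the cluster-forming threshold
from an isocontour curve, run CSS and CMS permutation inference at both
signs, and write the cluster table (TSV), link-count and cluster-label maps
(NIfTI), null distributions and a provenance log.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cluster import (
    extract_clusters,
    link_count_map,
    paired_t_matrix,
    threshold_to_adjacency,
)
from .connectivity import pearson_connectivity, preprocess_timecourses, \
    TimecourseSet
from .grid import MaskedGrid
from .nifti import extract_timecourses, load_mask, save_voxel_map
from .permutation import cluster_null_distributions, enumerate_flips, \
    fwe_pvalue
from .thresholds import isocontour, threshold_for_size

__all__ = ["RunConfig", "AnalysisResult", "run_full_analysis", "read_manifest"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of one full analysis run.

    Exactly one of ``t0`` and ``target_size`` must be given: either the
    cluster-forming threshold directly, or the critical CSS extent whose
    associated threshold is interpolated from an isocontour curve first.
    """

    manifest: dict                      # subject -> {condition: volume path}
    mask_path: str
    output_dir: str
    alpha: float = 0.05
    t0: float | None = None
    target_size: int | None = None
    permutation_mode: str = "full"
    n_permutations: int | None = None
    seed: int = 0
    lowpass_hz: float = 0.1
    cosine_order: int = 2
    mass_mode: str = "endpoint"
    fisher_z: bool = False
    paranoid_sign_check: bool = False
    isocontour_permutations: int = 1000

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if (self.t0 is None) == (self.target_size is None):
            raise ValueError("supply exactly one of t0 and target_size")

    def config_hash(self) -> str:
        # output_dir does not influence the analysis, so it is excluded:
        # equal hashes mean reproducible numbers
        payload = {k: v for k, v in asdict(self).items()
                   if k != "output_dir"}
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def read_manifest(path) -> dict:
    """Read a subject/condition/path TSV manifest into nested dicts."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"subject", "condition", "path"}
    if not required.issubset(df.columns):
        raise ValueError(f"manifest must have columns {sorted(required)}")
    manifest: dict = {}
    for row in df.itertuples():
        manifest.setdefault(row.subject, {})[row.condition] = row.path
    return manifest


@dataclass
class AnalysisResult:
    cluster_table: pd.DataFrame
    t0: float
    grid: MaskedGrid
    distributions: dict
    clusters: dict
    output_dir: Path


def _validate_manifest(manifest: dict) -> tuple[list, list[str]]:
    subjects = sorted(manifest)
    conditions: set = set()
    for s in subjects:
        conditions.update(manifest[s])
    conditions = sorted(conditions)
    if len(conditions) != 2:
        raise ValueError(
            f"expected exactly two conditions, found {conditions}"
        )
    for s in subjects:
        for c in conditions:
            if c not in manifest[s]:
                raise ValueError(f"subject {s} is missing condition {c!r}")
            if not Path(manifest[s][c]).exists():
                raise ValueError(
                    f"volume for subject {s}, condition {c} not found: "
                    f"{manifest[s][c]}"
                )
    return subjects, conditions


def run_full_analysis(config: RunConfig) -> AnalysisResult:
    """Execute the whole workflow and write all outputs.

    Outputs in ``output_dir``: ``clusters.tsv`` (method, cluster id, sign,
    statistic size, FWE p, peak world mm), per-sign link-count and
    cluster-label NIfTI volumes, one null-distribution text file per
    statistic, and ``run_log.json`` with the config hash, seed and package
    version.  Reruns with an identical config and seed are byte-identical.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    subjects, conditions = _validate_manifest(config.manifest)
    grid = load_mask(config.mask_path)
    logger.info("mask: %d voxels, shape %s", grid.n_voxels, grid.shape)

    # --- timecourses and connectivity
    import nibabel as nib

    first = nib.load(config.manifest[subjects[0]][conditions[0]])
    T = first.shape[3]
    tr = float(first.header.get_zooms()[3]) or 2.0
    data = np.empty((len(subjects), 2, grid.n_voxels, T))
    for i, s in enumerate(subjects):
        for j, c in enumerate(conditions):
            data[i, j] = extract_timecourses(config.manifest[s][c], grid)
    ts = TimecourseSet(data, tr_seconds=tr, grid=grid,
                       condition_labels=tuple(conditions))
    ts = preprocess_timecourses(ts, cutoff_hz=config.lowpass_hz,
                                cosine_order=config.cosine_order)
    mats = {
        c: [
            pearson_connectivity(ts.data[i, j], subject=s, condition=c).values
            for i, s in enumerate(subjects)
        ]
        for j, c in enumerate(conditions)
    }
    mats_A, mats_B = mats[conditions[0]], mats[conditions[1]]
    if config.fisher_z:
        from .connectivity import fisher_z as _fz

        mats_A = [_fz(m) for m in mats_A]
        mats_B = [_fz(m) for m in mats_B]

    # --- permutation scheme
    n = len(subjects)
    if config.permutation_mode == "full":
        scheme = enumerate_flips(n, mode="full")
    else:
        scheme = enumerate_flips(n, mode="subset",
                                 n_permutations=config.n_permutations,
                                 seed=config.seed)

    # --- threshold
    if config.t0 is not None:
        t0 = float(config.t0)
    else:
        curve = isocontour(
            mats_A, mats_B, grid, alpha=config.alpha,
            n_permutations=config.isocontour_permutations, seed=config.seed,
        )
        curve.to_frame().to_csv(out / "isocontour.tsv", sep="\t", index=False)
        t0 = threshold_for_size(curve, config.target_size)
        logger.info("interpolated t0=%.3f for target size %d", t0,
                    config.target_size)

    # --- null distributions (positive threshold; sign symmetry reused)
    dists = cluster_null_distributions(mats_A, mats_B, t0, scheme, grid,
                                       sign="positive")
    if config.paranoid_sign_check:
        neg = cluster_null_distributions(mats_A, mats_B, t0, scheme, grid,
                                         sign="negative")
        for k in dists:
            if not np.array_equal(np.sort(dists[k].values),
                                  np.sort(neg[k].values)):
                raise AssertionError(
                    f"positive/negative null distributions differ for {k}"
                )

    # --- observed clusters at both signs
    tmat = paired_t_matrix(mats_A, mats_B)
    rows = []
    clusters_by_sign = {}
    for sign in ("positive", "negative"):
        adj = threshold_to_adjacency(tmat, t0, sign)
        lcm = link_count_map(adj, grid)
        clusters = extract_clusters(lcm, adjacency=adj,
                                    mass_mode=config.mass_mode)
        clusters_by_sign[sign] = clusters
        save_voxel_map(lcm.counts, grid, out / f"linkcount_{sign}.nii.gz")
        label_map = np.zeros(grid.n_voxels, dtype=np.int32)
        for ci, cl in enumerate(clusters, start=1):
            label_map[cl.member_indices] = ci
        save_voxel_map(label_map, grid, out / f"clusters_{sign}.nii.gz")
        for ci, cl in enumerate(clusters, start=1):
            cl.fwe_p_css = fwe_pvalue(cl.css_extent, dists["css"], "two")
            cl.fwe_p_cms = fwe_pvalue(cl.cms_mass, dists["cms"], "two")
            for method, stat, p in (
                ("CSS", cl.css_extent, cl.fwe_p_css),
                ("CMS", cl.cms_mass, cl.fwe_p_cms),
            ):
                rows.append(
                    {
                        "method": method,
                        "cluster_id": f"{method}{ci}_{sign[:3]}",
                        "sign": sign,
                        "statistic_size": stat,
                        "fwe_p": round(p, 6),
                        "peak_mm": " ".join(
                            f"{x:.1f}" for x in cl.peak_world_mm
                        ),
                        "significant": p <= config.alpha,
                    }
                )
    table = pd.DataFrame(
        rows,
        columns=["method", "cluster_id", "sign", "statistic_size", "fwe_p",
                 "peak_mm", "significant"],
    )
    cfg_hash = config.config_hash()
    with open(out / "clusters.tsv", "w") as fh:
        fh.write(f"# config_hash={cfg_hash}\n")
        table.to_csv(fh, sep="\t", index=False)

    # --- distributions and provenance
    for kind, dist in dists.items():
        header = (f"statistic={kind} t0={t0:.6g} "
                  f"n_permutations={dist.n_permutations} seed={config.seed} "
                  f"config_hash={cfg_hash}")
        np.savetxt(out / f"null_{kind}.txt", dist.values, fmt="%d",
                   header=header)
    log = {
        "config_hash": config.config_hash(),
        "version": __version__,
        "seed": config.seed,
        "t0": t0,
        "alpha": config.alpha,
        "n_permutations": scheme.n_permutations,
        "n_subjects": n,
        "n_voxels": grid.n_voxels,
        "mask_hash": grid.mask_hash(),
        "mass_mode": config.mass_mode,
        "conditions": conditions,
    }
    (out / "run_log.json").write_text(json.dumps(log, indent=2, sort_keys=True))
    return AnalysisResult(
        cluster_table=table, t0=t0, grid=grid, distributions=dists,
        clusters=clusters_by_sign, output_dir=out,
    )
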