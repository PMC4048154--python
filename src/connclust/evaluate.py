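"""Study-condition evaluation runs: null calibration and ROC parameter sweeps.

These are the two expensive, end-to-end evaluations of the method: the
family-wise error calibration of CSS, CMS and the element-wise max-t test on
noise-only data, and the AFROC parameter sweeps over contrast-to-noise,
scattered-contrast count and primary-cluster radius.  Both run on the scaled
2-D study conditions described in the methods note.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .connectivity import pearson_connectivity
from .permutation import cluster_null_distributions, enumerate_flips, \
    fwe_pvalue
from .simulate import SimulationConfig, generate_groups, run_simulation

__all__ = [
    "null_rejection_rates",
    "roc_parameter_sweep",
    "SWEEPS",
]

# Sweep parameterizations: one parameter varied per sweep, everything
# else held at the base condition (CN=0.4, R=2, CV=2, t0=5)
SWEEPS: dict[str, list[float]] = {
    "cn": [0.25, 0.4, 0.5],
    "cv": [1.0, 2.0, 3.0],
    "radius": [1.0, 2.0, 3.0],
}


def null_calibration_config(n_subjects: int = 8,
                            seed: int = 0) -> SimulationConfig:
    """Noise-only study conditions for the FWE calibration run."""
    return SimulationConfig(shape=(20, 20), n_subjects=n_subjects,
                            n_timepoints=120, cn=0.0, seed=seed)


def null_rejection_rates(
    n_replicates: int = 200,
    n_subjects: int = 8,
    t0: float = 3.0,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict[str, float]:
    """Family-wise rejection rates of CSS, CMS and max-t on pure noise.

    Each replicate draws two independent noise groups, runs full sign-flip
    enumeration (2**n_subjects permutations), and rejects when the observed
    maximum statistic is significant at ``alpha`` (two-sided for the
    element-wise test: either tail at alpha/2).  Under the null every rate
    should sit at alpha up to discreteness.
    """
    config = null_calibration_config(n_subjects)
    grid = config.grid()
    scheme = enumerate_flips(n_subjects, "full")
    P = scheme.n_permutations
    rejections = {"css": 0, "cms": 0, "max_t": 0}
    rep_seeds = np.random.SeedSequence(seed).generate_state(n_replicates)
    for r in range(n_replicates):
        A, B, *_ = generate_groups(config, int(rep_seeds[r]) % (2**31))
        mats_a = [pearson_connectivity(s).values for s in A]
        mats_b = [pearson_connectivity(s).values for s in B]
        dists = cluster_null_distributions(
            mats_a, mats_b, t0, scheme, grid, include_elementwise=True
        )
        for kind in ("css", "cms"):
            p = fwe_pvalue(dists[kind].values[0], dists[kind])
            if p <= alpha:
                rejections[kind] += 1
        p_hi = np.count_nonzero(
            dists["max_t"].values >= dists["max_t"].values[0]) / P
        p_lo = np.count_nonzero(
            dists["min_t"].values <= dists["min_t"].values[0]) / P
        if min(p_hi, p_lo) <= alpha / 2:
            rejections["max_t"] += 1
    return {k: v / n_replicates for k, v in rejections.items()}


def roc_parameter_sweep(
    n_trials: int = 300,
    seed: int = 0,
    n_boot: int = 500,
    sweeps: dict[str, list[float]] | None = None,
) -> dict:
    """Partial AUCs (FPR <= 0.05) across the standard parameter sweeps.

    Returns ``{sweep_name: [(value, summary), ...]}`` where each summary has
    the CSS and CMS partial AUCs, their bootstrap standard errors, and the
    paired SE of the CMS - CSS difference.  Identical (parameter, value)
    conditions across sweeps share one simulation run.
    """
    if sweeps is None:
        sweeps = SWEEPS
    base = SimulationConfig()  # reference conditions
    cache: dict[tuple, dict] = {}
    config_seeds = {}
    # deterministic per-condition seeds from the master seed
    all_conditions = sorted(
        {(param, value) for param, values in sweeps.items()
         for value in values}
    )
    state = np.random.SeedSequence(seed).generate_state(len(all_conditions))
    for (param, value), s in zip(all_conditions, state):
        config_seeds[(param, value)] = int(s) % (2**31)

    def summarise(param: str, value: float) -> dict:
        key = (param, value) if value != getattr(base, param) else ("base", 0)
        if key in cache:
            return cache[key]
        run_seed = config_seeds[(param, value)] if key != ("base", 0) else \
            int(np.random.SeedSequence(seed).generate_state(1)[0]) % (2**31)
        config = replace(base, **{param: value}, seed=run_seed) \
            if key != ("base", 0) else replace(base, seed=run_seed)
        result = run_simulation(config, n_trials=n_trials)
        summary = {
            "css": result.partial_auc("css"),
            "cms": result.partial_auc("cms"),
            "css_se": result.partial_auc_se("css", n_boot=n_boot,
                                            seed=run_seed),
            "cms_se": result.partial_auc_se("cms", n_boot=n_boot,
                                            seed=run_seed),
            "diff_se": result.partial_auc_diff_se("cms", "css",
                                                  n_boot=n_boot,
                                                  seed=run_seed),
        }
        cache[key] = summary
        return summary

    out: dict = {}
    for param, values in sweeps.items():
        out[param] = [(value, summarise(param, value)) for value in values]
    return out
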