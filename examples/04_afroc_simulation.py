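"""AFROC evaluation of CSS vs CMS on synthetic contrast data.

Runs repeated simulation trials at the reference conditions (CN=0.4, R=2,
CV=2, t0=5) and prints the partial area under the AFROC curve restricted to
family-wise false-positive rates below 0.05 — the operating region that
matters for neuroimaging.
"""

from connclust.simulate import SimulationConfig, run_simulation

config = SimulationConfig(cn=0.4, radius=2.0, cv=2.0, t0=5.0, seed=11)
result = run_simulation(config, n_trials=50)

for method in ("css", "cms"):
    curve = result.roc_curve(method).restricted(0.05)
    pauc = result.partial_auc(method)
    se = result.partial_auc_se(method, n_boot=50)
    print(f"{method.upper()}: partial AUC (FPR<=0.05) = {pauc:.4f} "
          f"± {se:.4f} over {len(result.trials)} trials, "
          f"{len(curve.thresholds)} operating points")
# The maximum attainable partial AUC is 0.05 (perfect detection at every
# admissible false-positive rate).  CMS typically edges out CSS because a
# focal cluster's mass grows with every extra link while its extent
# saturates at the cluster's voxel count.
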