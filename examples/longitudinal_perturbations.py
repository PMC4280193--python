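"""Two-scan longitudinal lesion analysis with small perturbations.

Simulates weighted lesions (R = 0.8) to three shared random nodes on the
second scan of each subject, runs per-node paired t-tests with FDR against
the baseline scan at every lesion step, and prints the sensitivity summary
and the change-versus-distance correlations.
"""

import numpy as np

import commlesion as cl

cohort = cl.generate_cohort(cl.CohortSpec(n_subjects=12, n_nodes=40), seed=11)
spec = cl.LesionSpec(
    kind="node_weighted", target_mode="random_shared",
    n_targets=3, rate=0.8, hemisphere="R", seed=11,
)
res = cl.run_longitudinal_experiment(cohort, spec)
ids = cohort.subject_ids
targets = res.targets[ids[0]]
print("lesioned nodes (shared):", targets)

metric = "Sw"
base = np.vstack(
    [cl.node_metric_table(res.baseline[s], metrics=(metric,))[metric] for s in ids]
)
reports = []
for step, snap in enumerate(res.steps, start=1):
    les = np.vstack(
        [cl.node_metric_table(snap[s], metrics=(metric,))[metric] for s in ids]
    )
    reports.append(cl.make_change_report(metric, step, base, les))

counts, earliest = cl.sensitivity_summary(reports)
print(f"significant {metric} changes per step: {counts.tolist()}, "
      f"earliest change at step {earliest:g}")

dists = [cl.distance_from_lesion(res.baseline[s], targets, "binary") for s in ids]
keep = np.ones(40, dtype=bool)
keep[targets] = False
changes = base - np.vstack(
    [cl.node_metric_table(res.steps[-1][s], metrics=(metric,))[metric] for s in ids]
)
r = cl.correlate_change_distance(
    changes.mean(axis=0)[keep], np.mean(dists, axis=0)[keep], "spearman"
)
print(f"Spearman(change in {metric}, hop distance from lesion) = {r:.3f}")
print()
print("a negative coefficient means the metric drops most near the lesion")
print("focus — the spatial signature used to map damage from metric change.")
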