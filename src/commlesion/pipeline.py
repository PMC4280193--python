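"""End-to-end experiment drivers with config, logging and TSV/JSON reports.

Three experiments are orchestrated, each taking an :class:`ExperimentConfig`
and writing diff-able TSV tables plus a JSON summary that embeds the fully
resolved configuration and root seed — re-running a bundle's config
reproduces every output byte for byte.

* ``run_targeted_attacks``: per-subject efficiency-decay traces for every
  (criterion x method) pair, mean decay curves, pairwise permutation tests
  between strategies, and paired t-tests of efficiency at checkpoint steps.
* ``run_small_perturbations``: the two-scan longitudinal protocol for node
  and edge lesions — per-step significant-change counts for each metric,
  earliest-change summaries, change-versus-distance correlation tables and
  a change-location ranking, averaged over repetitions.
* ``run_stroke_preset``: the fixed left-thalamus/left-caudate lesion with
  random per-subject rates, averaged over repetitions, with global,
  hemispheric and local comparisons.
"""

from __future__ import annotations

import json
import math
import time
from dataclasses import asdict, dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import lesions as ls
from . import metrics as nm
from . import stats as gs
from ._rng import stream
from .io import Cohort, load_cohort
from .synth import CohortSpec, generate_cohort

__all__ = [
    "ExperimentConfig",
    "run_targeted_attacks",
    "run_small_perturbations",
    "run_stroke_preset",
    "run_experiment",
]

_FLOAT_FMT = "%.12g"  # stable text formatting => byte-identical reruns


@dataclass
class ExperimentConfig:
    """Resolved configuration of one experiment.

    ``cohort`` is either ``{"manifest": path}`` or ``{"spec": {...}}`` with
    :class:`~commlesion.synth.CohortSpec` fields.  ``options`` carries the
    experiment-specific knobs (criteria, methods, scenario list, ...).
    """

    experiment: str
    cohort: dict[str, Any]
    seed: int = 0
    alpha: float = gs.ALPHA
    n_perm: int = 5000
    options: dict[str, Any] = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def resolve_cohort(self) -> Cohort:
        if "manifest" in self.cohort:
            return load_cohort(self.cohort["manifest"])
        if "spec" in self.cohort:
            spec = CohortSpec(**self.cohort["spec"])
            return generate_cohort(spec, seed=self.seed)
        raise ValueError("cohort must give either 'manifest' or 'spec'")


def _write_summary(out_dir: Path, config: ExperimentConfig, extra: dict) -> None:
    """summary.json is fully determined by (config, seed); timings go to a
    separate run_log.json so reruns stay byte-identical."""
    extra = dict(extra)
    wall = extra.pop("wall_time_s", None)
    payload = {"config": asdict(config), **extra}
    with open(out_dir / "summary.json", "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
    if wall is not None:
        with open(out_dir / "run_log.json", "w") as fh:
            json.dump({"wall_time_s": wall}, fh, indent=2)
            fh.write("\n")


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


# ---------------------------------------------------------------------------
# targeted attacks


def run_targeted_attacks(
    config: ExperimentConfig, out_dir: str | Path
) -> dict[str, Any]:
    """Compare node-removal strategies by their efficiency decay.

    Options: ``criteria`` (default all eight), ``methods``
    (single_choice / hubs_order), ``n_attacks`` (default 80, capped at
    n_nodes - 1), ``checkpoints`` (steps for the paired efficiency t-tests,
    default 10/20/40/80), ``scan`` (which scan to attack, default "a").
    """
    t0 = time.perf_counter()
    out_dir = Path(out_dir)
    (out_dir / "traces").mkdir(parents=True, exist_ok=True)
    opts = config.options
    cohort = config.resolve_cohort()
    criteria = list(opts.get("criteria", nm.NODE_METRICS))
    methods = list(opts.get("methods", ["single_choice", "hubs_order"]))
    n_nodes = cohort.subjects[0][1].n_nodes
    n_attacks = int(min(opts.get("n_attacks", 80), n_nodes - 1))
    checkpoints = [
        int(k) for k in opts.get("checkpoints", [10, 20, 40, 80]) if k <= n_attacks
    ]
    scans = {
        sid: scan
        for (sid, a, b), scan in zip(
            cohort.subjects,
            cohort.scans(opts.get("scan", "a")),
        )
    }

    curves: dict[tuple[str, str], dict[str, np.ndarray]] = {}
    for criterion in criteria:
        for method in methods:
            eb, ew = [], []
            for sid, net in scans.items():
                trace = ls.targeted_attack(net, criterion, method, n_attacks)
                _write_tsv(
                    trace.to_frame(),
                    out_dir / "traces" / f"{sid}_{criterion}_{method}.tsv",
                )
                eb.append(trace.eff_binary)
                ew.append(trace.eff_weighted)
            curves[(criterion, method)] = {
                "eff": np.stack(eb),
                "eff_w": np.stack(ew),
            }

    # mean decay curves
    mean_rows: dict[str, Any] = {"step": np.arange(n_attacks + 1)}
    for (criterion, method), c in curves.items():
        mean_rows[f"{criterion}_{method}_eff"] = c["eff"].mean(axis=0)
        mean_rows[f"{criterion}_{method}_eff_w"] = c["eff_w"].mean(axis=0)
    _write_tsv(pd.DataFrame(mean_rows), out_dir / "mean_curves.tsv")

    # pairwise permutation tests between strategies
    perm_rows = []
    keys = sorted(curves.keys())
    for (k1, k2) in combinations(keys, 2):
        for eff_kind in ("eff", "eff_w"):
            rng = stream(
                config.seed, "perm", eff_kind, *k1, *k2
            )
            t_obs, p = gs.permutation_test_curves(
                curves[k1][eff_kind], curves[k2][eff_kind],
                n_perm=config.n_perm, rng=rng,
            )
            perm_rows.append(
                {
                    "efficiency": eff_kind,
                    "criterion_1": k1[0], "method_1": k1[1],
                    "criterion_2": k2[0], "method_2": k2[1],
                    "T": t_obs, "p": p,
                }
            )
    _write_tsv(pd.DataFrame(perm_rows), out_dir / "permutation_tests.tsv")

    # paired t-tests of efficiency at checkpoint steps
    tt_rows = []
    for (k1, k2) in combinations(keys, 2):
        for eff_kind in ("eff", "eff_w"):
            for step in checkpoints:
                t, p, _ = gs.paired_ttest_per_node(
                    curves[k1][eff_kind][:, [step]],
                    curves[k2][eff_kind][:, [step]],
                )
                tt_rows.append(
                    {
                        "efficiency": eff_kind, "step": step,
                        "criterion_1": k1[0], "method_1": k1[1],
                        "criterion_2": k2[0], "method_2": k2[1],
                        "t": t[0], "p": p[0],
                    }
                )
    _write_tsv(pd.DataFrame(tt_rows), out_dir / "ttest_checkpoints.tsv")

    _write_summary(
        out_dir,
        config,
        {
            "n_attacks": n_attacks,
            "criteria": criteria,
            "methods": methods,
            "n_subjects": cohort.n_subjects,
            "wall_time_s": round(time.perf_counter() - t0, 3),
        },
    )
    return {"curves": curves, "out_dir": out_dir}


# ---------------------------------------------------------------------------
# small perturbations


def _metric_arrays(
    nets: dict[str, Connectome_like], ids: list[str], metric_names: tuple[str, ...]
) -> np.ndarray:
    tables = [nm.node_metric_table(nets[sid], metrics=metric_names) for sid in ids]
    return np.stack([t.to_numpy() for t in tables])  # subjects x nodes x metrics


Connectome_like = Any  # keep the helper signature readable without an import cycle


def run_small_perturbations(
    config: ExperimentConfig, out_dir: str | Path
) -> dict[str, Any]:
    """Two-scan longitudinal sensitivity analysis for small lesions.

    Options: ``scenarios`` — list of dicts with
    :class:`~commlesion.lesions.LesionSpec` fields; ``metrics`` (default all
    eight); ``distance_steps`` — lesion steps at which change-vs-distance
    tables are produced (default: the final step); ``top_k`` for the
    change-location ranking.  Significance counts are averaged over
    repetitions after testing (test-then-average).
    """
    t0 = time.perf_counter()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    opts = config.options
    cohort = config.resolve_cohort()
    ids = cohort.subject_ids
    labels = cohort.subjects[0][1].labels
    metric_names = tuple(opts.get("metrics", nm.NODE_METRICS))
    scenarios = opts.get("scenarios")
    if not scenarios:
        raise ValueError("small_perturbations needs options['scenarios']")
    top_k = int(opts.get("top_k", 5))

    sens_rows, dist_frames, loc_frames = [], [], []
    for sc_idx, sc in enumerate(scenarios):
        sc_name = sc.get("name", f"scenario{sc_idx}")
        spec_fields = {k: v for k, v in sc.items() if k != "name"}
        spec = ls.LesionSpec(**{**spec_fields, "seed": config.seed})
        per_rep_counts = []
        earliest = []
        all_reports: list[gs.ChangeReport] = []
        damaged: set[int] = set()
        dist_steps = opts.get("distance_steps")
        for rep in range(spec.repetitions):
            res = ls.run_longitudinal_experiment(cohort, spec, repetition=rep)
            base_arr = _metric_arrays(res.baseline, ids, metric_names)
            for sid, t in res.targets.items():
                damaged |= set(t)
            steps_here = dist_steps or [res.n_steps]
            rep_counts = np.zeros((len(metric_names), res.n_steps), dtype=float)
            rep_reports: dict[int, list[gs.ChangeReport]] = {}
            for step_idx, snapshot in enumerate(res.steps):
                les_arr = _metric_arrays(snapshot, ids, metric_names)
                for m, name in enumerate(metric_names):
                    report = gs.make_change_report(
                        name, step_idx + 1,
                        base_arr[:, :, m], les_arr[:, :, m],
                        alpha=config.alpha,
                    )
                    rep_counts[m, step_idx] = report.n_significant
                    rep_reports.setdefault(m, []).append(report)
                if step_idx + 1 in steps_here:
                    # change-vs-distance table at this step
                    lesioned_sets = {
                        sid: set(res.targets[sid][: step_idx + 1])
                        for sid in ids
                    }
                    changes = {
                        name: base_arr[:, :, m] - les_arr[:, :, m]
                        for m, name in enumerate(metric_names)
                    }
                    excl = set().union(*lesioned_sets.values())
                    dist_b = [
                        gs.distance_from_lesion(
                            res.baseline[sid], lesioned_sets[sid] or excl, "binary"
                        )
                        for sid in ids
                    ] if excl else None
                    if dist_b is not None:
                        dist_w = [
                            gs.distance_from_lesion(
                                res.baseline[sid], lesioned_sets[sid] or excl,
                                "weighted",
                            )
                            for sid in ids
                        ]
                        tbl = gs.distance_correlation_table(
                            changes, {"DistB": dist_b, "DistW": dist_w},
                            exclude=excl,
                        )
                        tbl.insert(0, "scenario", sc_name)
                        tbl.insert(1, "repetition", rep)
                        tbl.insert(2, "step", step_idx + 1)
                        dist_frames.append(tbl)
            per_rep_counts.append(rep_counts)
            for m, name in enumerate(metric_names):
                counts, first = gs.sensitivity_summary(rep_reports[m])
                earliest.append(
                    {
                        "scenario": sc_name, "repetition": rep, "metric": name,
                        "earliest_step": first if math.isfinite(first) else "",
                        "total_significant": int(counts.sum()),
                    }
                )
                all_reports.extend(rep_reports[m])
        mean_counts = np.mean(per_rep_counts, axis=0)
        for m, name in enumerate(metric_names):
            for step_idx in range(mean_counts.shape[1]):
                sens_rows.append(
                    {
                        "scenario": sc_name, "metric": name,
                        "step": step_idx + 1,
                        "mean_n_significant": mean_counts[m, step_idx],
                    }
                )
        loc = gs.report_change_locations(
            all_reports, damaged_nodes=damaged, k=top_k, labels=labels
        )
        loc.insert(0, "scenario", sc_name)
        loc_frames.append(loc)
        earliest_df = pd.DataFrame(earliest)
        _write_tsv(earliest_df, out_dir / f"earliest_{sc_name}.tsv")

    _write_tsv(pd.DataFrame(sens_rows), out_dir / "sensitivity.tsv")
    if dist_frames:
        _write_tsv(
            pd.concat(dist_frames, ignore_index=True),
            out_dir / "distance_correlations.tsv",
        )
    _write_tsv(
        pd.concat(loc_frames, ignore_index=True), out_dir / "change_locations.tsv"
    )
    _write_summary(
        out_dir,
        config,
        {
            "n_subjects": cohort.n_subjects,
            "metrics": list(metric_names),
            "wall_time_s": round(time.perf_counter() - t0, 3),
        },
    )
    return {"out_dir": out_dir}


# ---------------------------------------------------------------------------
# stroke preset


def run_stroke_preset(config: ExperimentConfig, out_dir: str | Path) -> dict[str, Any]:
    """Fixed-site subcortical lesion experiment with averaged repetitions.

    Options: ``site_labels`` (default left thalamus + caudate),
    ``repetitions`` (default 10), ``kinds`` (default both node lesion
    kinds), ``metrics``.
    """
    t0 = time.perf_counter()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    opts = config.options
    cohort = config.resolve_cohort()
    labels = cohort.subjects[0][1].labels
    kinds = list(opts.get("kinds", ["node_weighted", "node_binary"]))
    metric_names = tuple(opts.get("metrics", nm.NODE_METRICS))
    results = {}
    for kind in kinds:
        res = ls.stroke_preset(
            cohort,
            seed=config.seed,
            site_labels=tuple(opts.get("site_labels", ("Left-Thalamus", "Left-Caudate"))),
            repetitions=int(opts.get("repetitions", 10)),
            kind=kind,
            metrics=metric_names,
            alpha=config.alpha,
        )
        results[kind] = res
        _write_tsv(res["global"], out_dir / f"global_{kind}.tsv")
        _write_tsv(res["hemispheric"], out_dir / f"hemispheric_{kind}.tsv")
        local = pd.concat(
            [
                rep.to_frame(labels).assign(metric=name)
                for name, rep in res["local"].items()
            ],
            ignore_index=True,
        )
        _write_tsv(local, out_dir / f"local_{kind}.tsv")
    _write_summary(
        out_dir,
        config,
        {
            "kinds": kinds,
            "n_subjects": cohort.n_subjects,
            "wall_time_s": round(time.perf_counter() - t0, 3),
        },
    )
    return results


_RUNNERS = {
    "targeted_attacks": run_targeted_attacks,
    "small_perturbations": run_small_perturbations,
    "stroke_preset": run_stroke_preset,
}


def run_experiment(config: ExperimentConfig, out_dir: str | Path) -> dict[str, Any]:
    """Dispatch on ``config.experiment``."""
    try:
        runner = _RUNNERS[config.experiment]
    except KeyError:
        raise ValueError(f"unknown experiment {config.experiment!r}")
    return runner(config, out_dir)
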