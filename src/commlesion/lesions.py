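"""Simulated lesions: targeted attacks, small perturbations, stroke preset.

Three families of simulated damage are provided:

* **Targeted attacks** delete whole nodes in order of a centrality
  criterion, either recomputing the criterion after every removal
  (*single-choice*) or freezing the removal order on the intact network
  (*hubs* order), and record the binary and weighted global efficiency
  after each removal.
* **Small perturbations** damage the network without removing nodes:
  binary node lesions delete a random fraction R of a node's connections,
  weighted node lesions scale all its edge weights by (1 - R), and edge
  lesions remove single randomly chosen edges one at a time.  The
  longitudinal driver pairs these with the two-scan design: per subject one
  scan (seeded coin flip) is the baseline and the other receives the
  cumulative lesion sequence.
* The **stroke preset** applies node lesions to the left thalamus and left
  caudate with a per-subject uniform random rate in [0.2, 0.8], repeated 10
  times and averaged, and reports global, hemispheric and local
  baseline-versus-lesion comparisons.

All operations preserve the connectome invariants and are monotone
destructive (no weight ever increases); every random draw comes from a
labelled stream derived from the experiment seed, so logs suffice to replay
any intermediate network.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import metrics as nm
from . import stats as gs
from ._rng import stream
from .io import Cohort, Connectome, build_average_network

__all__ = [
    "LesionSpec",
    "AttackTrace",
    "LongitudinalResult",
    "targeted_attack",
    "perturb_node_binary",
    "perturb_node_weighted",
    "perturb_edges",
    "select_targets",
    "run_longitudinal_experiment",
    "stroke_preset",
    "remove_nodes",
]

ATTACK_CRITERIA = nm.NODE_METRICS  # Deg, Sw, BC, BCw, Cm, Cmw, CBC, CBCw


@dataclass
class LesionSpec:
    """Full description of a perturbation experiment.

    ``kind``: ``node_binary`` (delete a fraction R of a node's edges),
    ``node_weighted`` (scale a node's weights by 1 - R), ``node_removal``
    (drop the node entirely) or ``edge_removal`` (single random edges).
    ``target_mode``: ``hubs_shared`` (hubs of the cohort average network,
    same list for every subject), ``random_shared``, ``random_individual``
    or ``fixed_list``.
    """

    kind: str
    target_mode: str = "hubs_shared"
    criterion: str | None = None
    n_targets: int | None = None
    rate: float | None = None
    n_edges: int | None = None
    repetitions: int = 1
    hemisphere: str | None = "R"
    fixed_targets: list[int] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in (
            "node_binary",
            "node_weighted",
            "node_removal",
            "edge_removal",
        ):
            raise ValueError(f"unknown lesion kind {self.kind!r}")
        if self.rate is not None and not 0 < self.rate <= 1:
            raise ValueError("rate must lie in (0, 1]")
        if self.repetitions < 1:
            raise ValueError("repetitions must be positive")


@dataclass
class AttackTrace:
    """Efficiency decay under one targeted-attack run.

    ``eff_binary``/``eff_weighted`` have one entry per state, index 0 being
    the intact network.  ``removal_order`` holds (original index, label)
    pairs in removal order.  ``status`` is "ok" or "truncated" (criterion
    became undefined mid-run).
    """

    criterion: str
    method: str
    removal_order: list[tuple[int, str]]
    eff_binary: np.ndarray
    eff_weighted: np.ndarray
    status: str = "ok"

    def to_frame(self) -> pd.DataFrame:
        steps = len(self.removal_order)
        return pd.DataFrame(
            {
                "step": np.arange(steps + 1),
                "removed_node": [0] + [i + 1 for i, _ in self.removal_order],
                "removed_label": [""] + [lab for _, lab in self.removal_order],
                "eff": self.eff_binary,
                "eff_w": self.eff_weighted,
            }
        )


def remove_nodes(c: Connectome, nodes: Iterable[int]) -> Connectome:
    """Delete nodes (rows/columns and metadata); the network shrinks."""
    drop = sorted(set(int(i) for i in nodes))
    keep = [i for i in range(c.n_nodes) if i not in set(drop)]
    return Connectome(
        labels=[c.labels[i] for i in keep],
        hemisphere=[c.hemisphere[i] for i in keep],
        W=c.W[np.ix_(keep, keep)],
        coords=None if c.coords is None else c.coords[keep],
        node_size=None if c.node_size is None else c.node_size[keep],
    )


def _criterion_values(c: Connectome, criterion: str) -> np.ndarray:
    if criterion not in ATTACK_CRITERIA:
        raise ValueError(f"unknown criterion {criterion!r}")
    return nm.node_metric_table(c, metrics=(criterion,))[criterion].to_numpy()


def _safe_efficiency(c: Connectome, weighted: bool) -> float:
    return 0.0 if c.n_nodes < 2 else nm.global_efficiency(c, weighted=weighted)


def targeted_attack(
    c: Connectome, criterion: str, method: str, n_attacks: int
) -> AttackTrace:
    """Sequentially delete the maximal-criterion node, tracking efficiency.

    ``method='single_choice'`` recomputes the criterion on the lesioned
    network before every removal; ``method='hubs_order'`` ranks the nodes
    once on the intact network and removes them in that frozen order.  Ties
    break toward the lower node index.  If the criterion becomes undefined
    mid-run (e.g. too few nodes left), the trace is truncated and flagged.
    """
    if method not in ("single_choice", "hubs_order"):
        raise ValueError(f"unknown attack method {method!r}")
    if not 0 <= n_attacks < c.n_nodes:
        raise ValueError("n_attacks must satisfy 0 <= N < n_nodes")
    cur = c.copy()
    alive = list(range(c.n_nodes))
    eff_b = [_safe_efficiency(cur, False)]
    eff_w = [_safe_efficiency(cur, True)]
    order: list[tuple[int, str]] = []
    status = "ok"

    frozen: list[int] = []
    if method == "hubs_order":
        vals = _criterion_values(c, criterion)
        frozen = np.lexsort((np.arange(c.n_nodes), -vals))[:n_attacks].tolist()

    for k in range(n_attacks):
        if method == "single_choice":
            try:
                vals = _criterion_values(cur, criterion)
            except ValueError:
                status = "truncated"
                break
            local = int(np.lexsort((np.arange(cur.n_nodes), -vals))[0])
        else:
            target = frozen[k]
            local = alive.index(target)
        orig = alive.pop(local)
        order.append((orig, cur.labels[local]))
        cur = remove_nodes(cur, [local])
        eff_b.append(_safe_efficiency(cur, False))
        eff_w.append(_safe_efficiency(cur, True))
    return AttackTrace(
        criterion=criterion,
        method=method,
        removal_order=order,
        eff_binary=np.array(eff_b),
        eff_weighted=np.array(eff_w),
        status=status,
    )


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5))


def perturb_node_binary(
    c: Connectome, node: int, rate: float, rng: np.random.Generator
) -> Connectome:
    """Delete round(R * degree) randomly chosen edges of one node (min 1)."""
    if not 0 < rate <= 1:
        raise ValueError("rate must lie in (0, 1]")
    neighbors = np.flatnonzero(c.W[node] > 0)
    if neighbors.size == 0:
        raise ValueError(f"node {node} is isolated; nothing to delete")
    k = min(neighbors.size, max(1, _round_half_away(rate * neighbors.size)))
    chosen = rng.choice(neighbors, size=k, replace=False)
    W = c.W.copy()
    W[node, chosen] = 0.0
    W[chosen, node] = 0.0
    return c.with_weights(W)


def perturb_node_weighted(c: Connectome, node: int, rate: float) -> Connectome:
    """Scale all edge weights of one node by (1 - R); topology kept for R < 1."""
    if not 0 < rate <= 1:
        raise ValueError("rate must lie in (0, 1]")
    W = c.W.copy()
    W[node, :] *= 1.0 - rate
    W[:, node] *= 1.0 - rate
    np.fill_diagonal(W, 0.0)
    return c.with_weights(W)


def perturb_edges(
    c: Connectome, n_edges: int, rng: np.random.Generator
) -> tuple[Connectome, list[tuple[int, int]]]:
    """Remove ``n_edges`` distinct uniformly chosen edges sequentially.

    Returns the final network and the ordered removal list, from which any
    intermediate state can be reconstructed.
    """
    ii, jj = np.nonzero(np.triu(c.W, 1))
    m = ii.size
    if n_edges > m:
        raise ValueError(f"asked to remove {n_edges} of {m} edges")
    pick = rng.choice(m, size=n_edges, replace=False)
    removed = [(int(ii[k]), int(jj[k])) for k in pick]
    W = c.W.copy()
    for i, j in removed:
        W[i, j] = 0.0
        W[j, i] = 0.0
    return c.with_weights(W), removed


def select_targets(
    cohort: Cohort,
    mode: str,
    hemisphere: str | None,
    n_targets: int | None,
    rng: np.random.Generator,
    fixed_targets: Sequence[int] | None = None,
) -> dict[str, list[int]]:
    """Choose attack sites per subject.

    ``hubs_shared``: hubs of the cohort average network restricted to
    ``hemisphere``, ordered by descending degree; the list is shared by all
    subjects.  When ``n_targets`` is None it defaults to the floor of the
    median per-subject hub count in that hemisphere (counted on scan_a).
    ``random_shared``: one uniform draw of ``n_targets`` nodes reused for
    every subject.  ``random_individual``: an independent draw per subject
    from per-subject child streams.  ``fixed_list``: the given nodes.
    """
    ids = cohort.subject_ids
    ref = cohort.subjects[0][1]
    pool = (
        list(range(ref.n_nodes))
        if hemisphere is None
        else ref.hemisphere_nodes(hemisphere).tolist()
    )
    if mode == "fixed_list":
        if not fixed_targets:
            raise ValueError("fixed_list mode needs fixed_targets")
        return {sid: list(fixed_targets) for sid in ids}
    if mode == "hubs_shared":
        if n_targets is None:
            counts = [
                len(nm.identify_hubs(a, hemisphere_filter=hemisphere))
                for _, a, _ in cohort.subjects
            ]
            n_targets = int(math.floor(float(np.median(counts))))
        avg = build_average_network(cohort, scan_selector="both")
        hubs = nm.identify_hubs(avg, hemisphere_filter=hemisphere)
        deg = (avg.W > 0).sum(axis=1)
        ranked = sorted(hubs, key=lambda i: (-deg[i], i))
        if len(ranked) < n_targets:
            # top up with the highest-degree non-hub nodes of the hemisphere
            rest = sorted(
                (i for i in pool if i not in hubs), key=lambda i: (-deg[i], i)
            )
            ranked = ranked + rest
        targets = ranked[:n_targets]
        if len(targets) < n_targets:
            raise ValueError("not enough nodes in hemisphere for n_targets")
        return {sid: list(targets) for sid in ids}
    if n_targets is None:
        raise ValueError(f"{mode} mode needs n_targets")
    if n_targets > len(pool):
        raise ValueError("not enough nodes in hemisphere for n_targets")
    if mode == "random_shared":
        targets = sorted(rng.choice(pool, size=n_targets, replace=False).tolist())
        return {sid: targets for sid in ids}
    if mode == "random_individual":
        out = {}
        for sid in ids:
            child = np.random.default_rng(rng.integers(0, 2**31 - 1))
            out[sid] = sorted(
                child.choice(pool, size=n_targets, replace=False).tolist()
            )
        return out
    raise ValueError(f"unknown target mode {mode!r}")


@dataclass
class LongitudinalResult:
    """One repetition of the two-scan lesion experiment.

    ``baseline`` maps subject id to the baseline network; ``steps[k]`` maps
    subject id to the lesioned network after k + 1 lesion steps.  ``log``
    records seeds, coin flips, targets and removed edges for exact replay.
    """

    baseline: dict[str, Connectome]
    steps: list[dict[str, Connectome]]
    targets: dict[str, list[int]]
    log: dict

    @property
    def n_steps(self) -> int:
        return len(self.steps)

    def final(self) -> dict[str, Connectome]:
        return self.steps[-1] if self.steps else dict(self.baseline)


def run_longitudinal_experiment(
    cohort: Cohort,
    spec: LesionSpec,
    rng: np.random.Generator | None = None,
    repetition: int = 0,
) -> LongitudinalResult:
    """One repetition of the paired baseline/lesion protocol.

    Per subject a seeded coin flip assigns one scan as baseline; the other
    scan receives the cumulative lesion sequence (1..N target nodes or
    1..Ne edges), and the state after every step is recorded for the
    statistics layer.  Repetitions are independent calls with distinct
    ``repetition`` indices (fresh target draws, fresh flips).
    """
    if rng is None:
        rng = stream(spec.seed, "longitudinal", "rep", repetition)
    flips = {sid: int(rng.integers(0, 2)) for sid in cohort.subject_ids}
    baseline: dict[str, Connectome] = {}
    lesion_scan: dict[str, Connectome] = {}
    for sid, a, b in cohort.subjects:
        if flips[sid] == 0:
            baseline[sid], lesion_scan[sid] = a, b
        else:
            baseline[sid], lesion_scan[sid] = b, a

    log: dict = {
        "kind": spec.kind,
        "target_mode": spec.target_mode,
        "rate": spec.rate,
        "seed": spec.seed,
        "repetition": repetition,
        "flips": flips,
    }
    steps: list[dict[str, Connectome]] = []

    if spec.kind == "edge_removal":
        if spec.n_edges is None:
            raise ValueError("edge_removal needs n_edges")
        removed_log: dict[str, list] = {}
        shared: list[tuple[int, int]] | None = None
        current = {sid: net.copy() for sid, net in lesion_scan.items()}
        for step in range(spec.n_edges):
            snapshot: dict[str, Connectome] = {}
            if spec.target_mode == "random_shared":
                if shared is None:
                    ref = cohort.subjects[0][1]
                    # draw the shared removal sequence on the average network
                    avg = build_average_network(cohort, scan_selector="both")
                    _, shared = perturb_edges(avg, spec.n_edges, rng)
                edge = shared[step]
                for sid in current:
                    W = current[sid].W.copy()
                    W[edge[0], edge[1]] = 0.0
                    W[edge[1], edge[0]] = 0.0
                    current[sid] = current[sid].with_weights(W)
                    snapshot[sid] = current[sid]
                    removed_log.setdefault(sid, []).append(list(edge))
            else:  # random_individual
                for sid in current:
                    child = stream(
                        spec.seed, "edges", sid, "rep", repetition, "step", step
                    )
                    current[sid], removed = perturb_edges(current[sid], 1, child)
                    snapshot[sid] = current[sid]
                    removed_log.setdefault(sid, []).append(list(removed[0]))
            steps.append(snapshot)
        log["removed_edges"] = removed_log
        targets: dict[str, list[int]] = {sid: [] for sid in cohort.subject_ids}
        return LongitudinalResult(baseline, steps, targets, log)

    # node lesions
    targets = select_targets(
        cohort,
        spec.target_mode,
        spec.hemisphere,
        spec.n_targets,
        rng,
        fixed_targets=spec.fixed_targets,
    )
    log["targets"] = {sid: list(t) for sid, t in targets.items()}
    n_steps = len(next(iter(targets.values())))
    current = {sid: net.copy() for sid, net in lesion_scan.items()}
    for step in range(n_steps):
        snapshot = {}
        for sid in cohort.subject_ids:
            node = targets[sid][step]
            net = current[sid]
            if spec.kind == "node_binary":
                child = stream(
                    spec.seed, "binary", sid, "rep", repetition, "step", step
                )
                if np.count_nonzero(net.W[node]) > 0:
                    net = perturb_node_binary(net, node, spec.rate, child)
            elif spec.kind == "node_weighted":
                net = perturb_node_weighted(net, node, spec.rate)
            elif spec.kind == "node_removal":
                W = net.W.copy()
                W[node, :] = 0.0
                W[:, node] = 0.0
                net = net.with_weights(W)
            current[sid] = net
            snapshot[sid] = net
        steps.append(snapshot)
    return LongitudinalResult(baseline, steps, targets, log)


def stroke_preset(
    cohort: Cohort,
    seed: int = 0,
    site_labels: tuple[str, str] = ("Left-Thalamus", "Left-Caudate"),
    repetitions: int = 10,
    kind: str = "node_weighted",
    metrics: tuple[str, ...] = nm.NODE_METRICS,
    alpha: float = gs.ALPHA,
) -> dict:
    """Simulated subcortical stroke at the left thalamus and caudate.

    Per repetition and subject, one scan (coin flip) is the baseline and
    both sites of the other scan are lesioned with a per-subject uniform
    random rate in [0.2, 0.8] — ``node_weighted`` scales the sites' weights,
    ``node_binary`` deletes a random fraction of their edges.  Metric values
    are averaged over the repetitions before the paired comparisons.

    Returns a dict with ``global`` (paired t per metric on whole-network
    means plus Eff/Eff_w), ``hemispheric`` (per hemisphere; "L" is
    ipsilesional), ``local`` (ChangeReport per metric, FDR-corrected) and a
    replayable ``log``.
    """
    ref = cohort.subjects[0][1]
    try:
        sites = [ref.labels.index(lab) for lab in site_labels]
    except ValueError as exc:
        raise ValueError(f"lesion site label not found: {exc}")
    ids = cohort.subject_ids
    n = ref.n_nodes
    hemi = np.asarray(ref.hemisphere)

    node_base = {sid: [] for sid in ids}
    node_les = {sid: [] for sid in ids}
    glob_base = {sid: [] for sid in ids}
    glob_les = {sid: [] for sid in ids}
    rates_log: dict[str, list[float]] = {sid: [] for sid in ids}
    flips_log: dict[str, list[int]] = {sid: [] for sid in ids}

    for rep in range(repetitions):
        rng = stream(seed, "stroke", "rep", rep)
        for sid, a, b in cohort.subjects:
            flip = int(rng.integers(0, 2))
            base, target = (a, b) if flip == 0 else (b, a)
            rate = float(rng.uniform(0.2, 0.8))
            flips_log[sid].append(flip)
            rates_log[sid].append(rate)
            les = target
            for node in sites:
                if kind == "node_weighted":
                    les = perturb_node_weighted(les, node, rate)
                elif kind == "node_binary":
                    if np.count_nonzero(les.W[node]) > 0:
                        les = perturb_node_binary(les, node, rate, rng)
                else:
                    raise ValueError(f"unsupported stroke lesion kind {kind!r}")
            node_base[sid].append(nm.node_metric_table(base, metrics=metrics))
            node_les[sid].append(nm.node_metric_table(les, metrics=metrics))
            glob_base[sid].append(
                (nm.global_efficiency(base), nm.global_efficiency(base, True))
            )
            glob_les[sid].append(
                (nm.global_efficiency(les), nm.global_efficiency(les, True))
            )

    # average metric tables over repetitions, per subject
    def _avg(tables: dict[str, list[pd.DataFrame]]) -> np.ndarray:
        return np.stack(
            [np.mean([t.to_numpy() for t in tables[sid]], axis=0) for sid in ids]
        )  # subjects x nodes x metrics

    base_arr = _avg(node_base)
    les_arr = _avg(node_les)
    eff_base = np.array([np.mean(glob_base[sid], axis=0) for sid in ids])
    eff_les = np.array([np.mean(glob_les[sid], axis=0) for sid in ids])

    global_rows = []
    for m, name in enumerate(metrics):
        t, p, _ = gs.paired_ttest_per_node(
            base_arr[:, :, m].mean(axis=1, keepdims=True),
            les_arr[:, :, m].mean(axis=1, keepdims=True),
        )
        global_rows.append({"metric": name, "t": t[0], "p": p[0]})
    for j, name in enumerate(("Eff", "Effw")):
        t, p, _ = gs.paired_ttest_per_node(
            eff_base[:, [j]], eff_les[:, [j]]
        )
        global_rows.append({"metric": name, "t": t[0], "p": p[0]})
    global_df = pd.DataFrame(global_rows)

    hemi_rows = []
    for side in ("L", "R"):
        mask = hemi == side
        for m, name in enumerate(metrics):
            t, p, _ = gs.paired_ttest_per_node(
                base_arr[:, mask, m].mean(axis=1, keepdims=True),
                les_arr[:, mask, m].mean(axis=1, keepdims=True),
            )
            hemi_rows.append(
                {
                    "hemisphere": side,
                    "role": "ipsilesional" if side == "L" else "contralesional",
                    "metric": name,
                    "mean_change": float(
                        base_arr[:, mask, m].mean() - les_arr[:, mask, m].mean()
                    ),
                    "t": t[0],
                    "p": p[0],
                }
            )
    hemi_df = pd.DataFrame(hemi_rows)

    local = {
        name: gs.make_change_report(
            name, 1, base_arr[:, :, m], les_arr[:, :, m], alpha=alpha
        )
        for m, name in enumerate(metrics)
    }
    return {
        "global": global_df,
        "hemispheric": hemi_df,
        "local": local,
        "sites": sites,
        "log": {
            "seed": seed,
            "kind": kind,
            "repetitions": repetitions,
            "site_labels": list(site_labels),
            "rates": rates_log,
            "flips": flips_log,
        },
    }
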