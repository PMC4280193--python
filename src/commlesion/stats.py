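"""Group statistics for longitudinal lesion analyses.

Covers the four statistical primitives the lesion experiments need:

* a permutation test comparing two ensembles of efficiency-decay curves
  (statistic: sum over lesion steps of the difference of group means;
  two-sided via |T|; 5000 label shuffles by default);
* per-node paired t-tests between baseline and lesioned metric values
  across subjects, with Benjamini–Hochberg FDR correction per metric and
  lesion step (alpha = 0.05 after correction);
* sensitivity summaries — number of FDR-significant nodes per lesion step
  and the earliest step showing any significant change;
* distance-from-lesion vectors (hop, reciprocal-weight or Euclidean) and
  Pearson/Spearman correlations between local change and distance, with
  lesion sites excluded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .io import Connectome
from .metrics import distance_matrix

__all__ = [
    "ChangeReport",
    "permutation_test_curves",
    "paired_ttest_per_node",
    "fdr_adjust",
    "make_change_report",
    "sensitivity_summary",
    "distance_from_lesion",
    "correlate_change_distance",
    "distance_correlation_table",
    "report_change_locations",
]

ALPHA = 0.05  # corrected significance threshold


@dataclass
class ChangeReport:
    """Per-node test results for one metric at one lesion step.

    ``mean_change`` is baseline minus lesioned, so positive values mean the
    metric *dropped* after the lesion.  ``significant`` holds node indices
    with FDR-adjusted p below alpha.
    """

    metric: str
    step: int
    mean_change: np.ndarray
    t: np.ndarray
    p_raw: np.ndarray
    p_adj: np.ndarray
    alpha: float = ALPHA
    zero_variance: np.ndarray = field(default_factory=lambda: np.array([], dtype=bool))

    @property
    def significant(self) -> set[int]:
        return set(np.flatnonzero(self.p_adj < self.alpha).tolist())

    @property
    def n_significant(self) -> int:
        return len(self.significant)

    def to_frame(self, labels: Sequence[str] | None = None) -> pd.DataFrame:
        n = len(self.mean_change)
        df = pd.DataFrame(
            {
                "node": np.arange(1, n + 1),  # 1-based in outputs
                "mean_change": self.mean_change,
                "t": self.t,
                "p_raw": self.p_raw,
                "p_adj": self.p_adj,
                "significant": self.p_adj < self.alpha,
            }
        )
        if labels is not None:
            df.insert(1, "label", list(labels))
        return df


def permutation_test_curves(
    curves_a: np.ndarray,
    curves_b: np.ndarray,
    n_perm: int = 5000,
    rng: np.random.Generator | None = None,
) -> tuple[float, float]:
    """Permutation test on two sets of efficiency-decay curves.

    The observed statistic is T = sum over steps of
    (mean of group a - mean of group b); group labels are shuffled across
    the pooled curves and the two-sided p-value is
    (#{|T_perm| >= |T_obs|} + 1) / (n_perm + 1), which keeps p > 0 and valid
    under the null.  Returns ``(T_obs, p)``.

    Because T is linear in the curves, it equals the difference in group
    means of the per-curve step sums, which is what is permuted.
    """
    A = np.atleast_2d(np.asarray(curves_a, dtype=float))
    B = np.atleast_2d(np.asarray(curves_b, dtype=float))
    if A.shape[1] != B.shape[1]:
        raise ValueError("curve sets must have equal length")
    if A.shape[0] == 0 or B.shape[0] == 0:
        raise ValueError("both curve sets must be non-empty")
    rng = np.random.default_rng() if rng is None else rng
    ka = A.shape[0]
    sums = np.concatenate([A.sum(axis=1), B.sum(axis=1)])
    t_obs = sums[:ka].mean() - sums[ka:].mean()
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(sums)
        t_perm = perm[:ka].mean() - perm[ka:].mean()
        if abs(t_perm) >= abs(t_obs) - 1e-15:
            count += 1
    p = (count + 1) / (n_perm + 1)
    return float(t_obs), float(p)


def paired_ttest_per_node(
    values_baseline: np.ndarray, values_lesioned: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Two-sided paired t-test per node over subjects.

    Input arrays are subjects x nodes.  Returns ``(t, p, zero_variance)``.
    Nodes whose subject-wise differences are all exactly zero get
    ``t = 0, p = 1``; nodes with identical non-zero differences (zero
    variance, non-zero mean) get ``t = +-inf, p = 0`` and are flagged in
    ``zero_variance`` — this arises for binary metrics under purely
    weighted lesions.
    """
    base = np.asarray(values_baseline, dtype=float)
    les = np.asarray(values_lesioned, dtype=float)
    if base.shape != les.shape:
        raise ValueError("baseline and lesioned arrays must have equal shape")
    if base.shape[0] < 2:
        raise ValueError("paired t-test needs at least 2 subjects")
    d = base - les
    m = d.shape[0]
    mean = d.mean(axis=0)
    sd = d.std(axis=0, ddof=1)
    t = np.zeros(d.shape[1])
    p = np.ones(d.shape[1])
    zero_var = sd == 0
    ok = ~zero_var
    with np.errstate(divide="ignore", invalid="ignore"):
        t[ok] = mean[ok] / (sd[ok] / math.sqrt(m))
    p[ok] = 2.0 * sps.t.sf(np.abs(t[ok]), df=m - 1)
    exact_effect = zero_var & (mean != 0)
    t[exact_effect] = np.sign(mean[exact_effect]) * np.inf
    p[exact_effect] = 0.0
    return t, p, exact_effect


def fdr_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    _, p_adj, _, _ = multipletests(p, method="fdr_bh")
    return p_adj


def make_change_report(
    metric: str,
    step: int,
    values_baseline: np.ndarray,
    values_lesioned: np.ndarray,
    alpha: float = ALPHA,
) -> ChangeReport:
    """Paired t-tests plus FDR for one metric at one lesion step.

    The FDR family is the set of nodes of this metric at this step (the
    default family definition; callers pooling differently can use
    ``paired_ttest_per_node``/``fdr_adjust`` directly).
    """
    t, p_raw, zero_var = paired_ttest_per_node(values_baseline, values_lesioned)
    p_adj = fdr_adjust(p_raw)
    mean_change = np.asarray(values_baseline, dtype=float).mean(axis=0) - np.asarray(
        values_lesioned, dtype=float
    ).mean(axis=0)
    return ChangeReport(
        metric=metric,
        step=step,
        mean_change=mean_change,
        t=t,
        p_raw=p_raw,
        p_adj=p_adj,
        alpha=alpha,
        zero_variance=zero_var,
    )


def sensitivity_summary(
    reports: Sequence[ChangeReport],
    lesioned_nodes: Iterable[int] = (),
    include_lesioned: bool = True,
) -> tuple[np.ndarray, float]:
    """Counts of significant nodes per lesion step and the earliest change.

    ``reports`` must be ordered by lesion step.  With
    ``include_lesioned=False`` the directly attacked nodes are excluded from
    the counts (the convention for change-location analyses; counts of
    overall sensitivity keep them).  The earliest change is the first step
    whose count is positive, or ``inf`` if none.
    """
    if not reports:
        raise ValueError("no reports given")
    excluded = set() if include_lesioned else set(lesioned_nodes)
    counts = np.array(
        [len(r.significant - excluded) for r in reports], dtype=int
    )
    hit = np.flatnonzero(counts > 0)
    earliest = float(reports[hit[0]].step) if hit.size else math.inf
    return counts, earliest


def distance_from_lesion(
    c: Connectome, lesion_nodes: Iterable[int], kind: str = "binary"
) -> np.ndarray:
    """Per-node distance to the nearest lesion site.

    ``kind`` is ``binary`` (hop count), ``weighted`` (1/w path length) or
    ``euclidean`` (straight-line distance between node coordinates, which
    requires ``coords``).  Lesion sites themselves get distance 0 and are
    excluded from downstream correlations.
    """
    sites = sorted(set(int(i) for i in lesion_nodes))
    if not sites:
        raise ValueError("lesion_nodes must be non-empty")
    if kind in ("binary", "weighted"):
        D = distance_matrix(c, weighted=(kind == "weighted")).values
        return D[sites, :].min(axis=0)
    if kind == "euclidean":
        if c.coords is None:
            raise ValueError("euclidean distance requires node coordinates")
        diffs = c.coords[None, sites, :] - c.coords[:, None, :]
        return np.linalg.norm(diffs, axis=2).min(axis=1)
    raise ValueError(f"unknown distance kind {kind!r}")


def correlate_change_distance(
    changes: np.ndarray, distances: np.ndarray, method: str = "pearson"
) -> float | None:
    """Correlation between local change and distance from the lesion.

    Non-finite distances are dropped; inputs must leave at least 3 points
    (callers exclude the lesion sites beforehand).  By convention, Pearson
    is used against weighted distances and Spearman against the ordinal
    binary (hop) distances.  Degenerate (constant) input returns ``None``
    rather than propagating a NaN.
    """
    x = np.asarray(changes, dtype=float)
    y = np.asarray(distances, dtype=float)
    if x.shape != y.shape:
        raise ValueError("changes and distances must have equal length")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise ValueError("need at least 3 finite pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return None
    if method == "pearson":
        r = sps.pearsonr(x, y).statistic
    elif method == "spearman":
        r = sps.spearmanr(x, y).statistic
    else:
        raise ValueError(f"unknown correlation method {method!r}")
    return float(r)


def distance_correlation_table(
    changes: dict[str, np.ndarray],
    distances: dict[str, np.ndarray | list[np.ndarray]],
    exclude: Iterable[int] = (),
) -> pd.DataFrame:
    """Metric x distance-kind correlation table.

    ``changes`` maps metric name -> subjects x nodes array of per-node
    changes (baseline - lesioned); ``distances`` maps distance kind
    (``DistB``/``DistW``/``DistE``) -> per-node distance vector or one
    vector per subject.  For each (metric, kind) cell the table reports the
    mean and SD of the per-subject coefficients ("individual") and the
    coefficient of the subject-averaged change against the subject-averaged
    distance ("average").  Spearman is used for the ordinal binary distance,
    Pearson otherwise.  Excluded nodes (the lesion sites) are dropped first.
    """
    excl = sorted(set(int(i) for i in exclude))
    rows = []
    for metric, ch in changes.items():
        ch = np.atleast_2d(np.asarray(ch, dtype=float))
        n = ch.shape[1]
        keep = np.ones(n, dtype=bool)
        keep[excl] = False
        for kind, dist in distances.items():
            method = "spearman" if kind == "DistB" else "pearson"
            dlist = (
                [np.asarray(d, dtype=float) for d in dist]
                if isinstance(dist, list)
                else [np.asarray(dist, dtype=float)] * ch.shape[0]
            )
            coeffs = []
            for s in range(ch.shape[0]):
                r = correlate_change_distance(
                    ch[s, keep], dlist[s][keep], method=method
                )
                if r is not None:
                    coeffs.append(r)
            mean_d = np.mean(np.stack(dlist), axis=0)
            avg_r = correlate_change_distance(
                ch.mean(axis=0)[keep], mean_d[keep], method=method
            )
            rows.append(
                {
                    "metric": metric,
                    "distance": kind,
                    "individual_mean": np.mean(coeffs) if coeffs else np.nan,
                    "individual_sd": np.std(coeffs, ddof=1)
                    if len(coeffs) > 1
                    else np.nan,
                    "average": np.nan if avg_r is None else avg_r,
                    "n_individual": len(coeffs),
                }
            )
    return pd.DataFrame(rows)


def report_change_locations(
    reports: Sequence[ChangeReport],
    damaged_nodes: Iterable[int] = (),
    k: int = 5,
    labels: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Fraction of reports in which each node is among the top-k changes.

    For every report the significant nodes (excluding the directly damaged
    ones) are ranked by adjusted p-value and the k most significant kept;
    the table gives, per node, the fraction of reports in which it appears,
    sorted descending.  Reports without significant nodes contribute to the
    denominator but to no node.
    """
    if not reports:
        raise ValueError("no reports given")
    damaged = set(int(i) for i in damaged_nodes)
    hits: dict[int, int] = {}
    for rep in reports:
        sig = [i for i in rep.significant if i not in damaged]
        sig.sort(key=lambda i: (rep.p_adj[i], i))
        for i in sig[:k]:
            hits[i] = hits.get(i, 0) + 1
    rows = [
        {
            "node": i + 1,
            "label": labels[i] if labels is not None else str(i + 1),
            "fraction": count / len(reports),
        }
        for i, count in hits.items()
    ]
    df = pd.DataFrame(rows, columns=["node", "label", "fraction"])
    return df.sort_values(
        ["fraction", "node"], ascending=[False, True]
    ).reset_index(drop=True)
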