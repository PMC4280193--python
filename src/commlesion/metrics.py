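"""Communicability and standard connectome metrics.

The communicability between nodes i and j counts walks of every length k
between them, down-weighted by 1/k!, i.e. the matrix exponential of the
adjacency matrix:

    Cm = exp(A),            Cm[i, j] = sum_k (A^k)[i, j] / k!

For weighted networks the strength-normalized form

    Cm^w = exp(S^{-1/2} W S^{-1/2}),   S = diag(s_i), s_i = sum_j W[i, j]

damps the otherwise overwhelming influence of high-strength nodes (Crofts &
Higham's normalization).  Communicability centrality (CBC) of node r is the
K-normalized mean *relative* drop of pairwise communicability among the
remaining nodes when r's edges are removed; because removing edges from a
non-negative matrix can only remove walks, every ratio lies in [0, 1] and so
does CBC.

Alongside these the module provides the standard shortest-path metrics
(degree, strength, betweenness, distances with the 1/w length convention,
characteristic path length, global efficiency), hub identification
(degree >= mean + 1 SD), the assortativity reordering of the communicability
matrix, and the density among top-metric nodes.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.linalg import expm
from scipy.sparse.csgraph import connected_components, shortest_path

from .io import Connectome

__all__ = [
    "PairMatrix",
    "NodeMetricVector",
    "communicability_binary",
    "communicability_weighted",
    "communicability_matrix",
    "node_communicability",
    "communicability_centrality",
    "degree_strength",
    "distance_matrix",
    "betweenness",
    "global_efficiency",
    "characteristic_path_length",
    "identify_hubs",
    "communicability_assortativity",
    "top_node_density",
    "node_metric_table",
    "NODE_METRICS",
]


@dataclass
class PairMatrix:
    """Symmetric node-by-node quantity (communicability or distance).

    ``kind`` is one of ``cm_binary``, ``cm_weighted``, ``dist_binary``,
    ``dist_weighted``.  Distance matrices use ``inf`` for disconnected
    pairs; communicability matrices are exactly 0 off-diagonal between
    different connected components.
    """

    kind: str
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("PairMatrix values must be square")
        self.values = v


@dataclass
class NodeMetricVector:
    """Per-node metric values under a named metric."""

    metric: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)


# ---------------------------------------------------------------------------
# communicability


def _component_labels(M: np.ndarray) -> np.ndarray:
    _, labels = connected_components(M > 0, directed=False)
    return labels


def _expm_by_component(M: np.ndarray) -> np.ndarray:
    """exp(M) with off-diagonal entries across components pinned to 0.

    The exponential of a block-diagonal matrix is block diagonal; zeroing the
    cross-component entries explicitly protects that identity from
    round-off in the Pade evaluation.
    """
    E = expm(M)
    labels = _component_labels(M)
    diff = labels[:, None] != labels[None, :]
    E[diff] = 0.0
    return (E + E.T) / 2.0


def _normalized_matrix(W: np.ndarray) -> np.ndarray:
    """S^{-1/2} W S^{-1/2} with 1/sqrt(s)=0 for isolated (s=0) nodes."""
    s = W.sum(axis=1)
    with np.errstate(divide="ignore"):
        d = np.where(s > 0, 1.0 / np.sqrt(np.where(s > 0, s, 1.0)), 0.0)
    return W * d[:, None] * d[None, :]


def communicability_binary(c: Connectome) -> PairMatrix:
    """Binary communicability Cm = exp(A)."""
    return PairMatrix("cm_binary", _expm_by_component(c.binary_adjacency()))


def communicability_weighted(c: Connectome, normalize: bool = True) -> PairMatrix:
    """Weighted communicability exp(S^{-1/2} W S^{-1/2}) (or exp(W) raw).

    With ``normalize`` the result is invariant under a global rescaling of
    the weights.  Isolated nodes keep a unit diagonal and zero rows.
    """
    W = c.W
    M = _normalized_matrix(W) if normalize else W
    return PairMatrix("cm_weighted", _expm_by_component(M))


def communicability_matrix(
    c: Connectome, weighted: bool, normalize: bool = True
) -> PairMatrix:
    """Uniform entry point: binary or weighted, optionally normalized.

    The binary normalized variant exp(D A D) (D from degrees) is what the
    lesion analyses use for node-level binary communicability, since the raw
    exp(A) is dominated by network density.
    """
    if weighted:
        return communicability_weighted(c, normalize=normalize)
    if normalize:
        pm = communicability_weighted(c.binarized(), normalize=True)
        return PairMatrix("cm_binary", pm.values)
    return communicability_binary(c)


def node_communicability(pm: PairMatrix) -> NodeMetricVector:
    """Node-level communicability: row sum excluding the diagonal."""
    if not pm.kind.startswith("cm_"):
        raise ValueError(f"expected a communicability matrix, got {pm.kind!r}")
    v = pm.values.sum(axis=1) - np.diag(pm.values)
    metric = "Cm" if pm.kind == "cm_binary" else "Cmw"
    return NodeMetricVector(metric, v)


def communicability_centrality(
    c: Connectome,
    weighted: bool = False,
    relative: bool = True,
    recompute_normalization: bool = False,
) -> NodeMetricVector:
    """Communicability centrality: normalized communicability loss per node.

    For each node r the communicability matrix is recomputed on the network
    with all of r's edges removed (walk-equivalent, for retained pairs, to
    deleting the node) and

        CBC[r] = (1/K) * sum_{i != j, i,j != r} (Cm[i,j] - Cm_r[i,j]) / Cm[i,j]

    where the sum and the normalization constant K run over the ordered
    pairs with Cm[i, j] > 0.  Removing edges can only remove walks, so each
    ratio — and hence CBC — lies in [0, 1].  Differences are floored at 0
    and ratios capped at 1 to protect that identity from round-off.

    For ``weighted`` networks the lesioned exponential uses, by default, the
    *intact* strength normalization (row/column r of S^{-1/2} W S^{-1/2} is
    zeroed).  Re-deriving the normalization from the lesioned strengths
    (``recompute_normalization=True``) can raise the remaining normalized
    weights and push CBC outside [0, 1]; it is kept as a sensitivity option.

    With ``relative=False`` the un-normalized absolute reduction
    (1/K) * sum (Cm - Cm_r) is returned instead (no [0, 1] bound).
    """
    n = c.n_nodes
    if n < 3:
        raise ValueError("communicability centrality needs at least 3 nodes")
    M = _normalized_matrix(c.W) if weighted else c.binary_adjacency()
    Cm = _expm_by_component(M)
    offdiag = ~np.eye(n, dtype=bool)
    positive = (Cm > 0) & offdiag
    out = np.zeros(n)
    for r in range(n):
        if weighted and recompute_normalization:
            Wr = c.W.copy()
            Wr[r, :] = 0.0
            Wr[:, r] = 0.0
            Mr = _normalized_matrix(Wr)
        else:
            Mr = M.copy()
            Mr[r, :] = 0.0
            Mr[:, r] = 0.0
        Cmr = _expm_by_component(Mr)
        sel = positive.copy()
        sel[r, :] = False
        sel[:, r] = False
        K = int(sel.sum())
        if K == 0:
            out[r] = 0.0
            continue
        diff = Cm[sel] - Cmr[sel]
        if relative:
            ratio = diff / Cm[sel]
            if not recompute_normalization:
                ratio = np.clip(ratio, 0.0, 1.0)  # round-off guard only
            out[r] = ratio.sum() / K
        else:
            out[r] = diff.sum() / K
    metric = "CBCw" if weighted else "CBC"
    return NodeMetricVector(metric, out)


# ---------------------------------------------------------------------------
# standard metrics


def degree_strength(c: Connectome) -> tuple[NodeMetricVector, NodeMetricVector]:
    """Degree (edge count) and strength (weight sum) per node."""
    deg = (c.W > 0).sum(axis=1).astype(float)
    strength = c.W.sum(axis=1)
    return NodeMetricVector("Deg", deg), NodeMetricVector("Sw", strength)


def _length_matrix(c: Connectome) -> np.ndarray:
    """Edge lengths 1/w (0 = no edge, for csgraph)."""
    with np.errstate(divide="ignore"):
        L = np.where(c.W > 0, 1.0 / np.where(c.W > 0, c.W, 1.0), 0.0)
    return L


def distance_matrix(c: Connectome, weighted: bool = False) -> PairMatrix:
    """Shortest-path distances: hop counts, or lengths 1/w when weighted.

    The reciprocal-weight length convention maps strong connections to short
    distances, the standard choice for connectivity-index weights.
    Disconnected pairs get ``inf``.
    """
    if weighted:
        D = shortest_path(_length_matrix(c), method="D", directed=False)
        kind = "dist_weighted"
    else:
        D = shortest_path(
            c.binary_adjacency(), method="D", directed=False, unweighted=True
        )
        kind = "dist_binary"
    np.fill_diagonal(D, 0.0)
    return PairMatrix(kind, D)


def betweenness(c: Connectome, weighted: bool = False) -> NodeMetricVector:
    """Unnormalized shortest-path betweenness (fractional path credit)."""
    n = c.n_nodes
    G = nx.Graph()
    G.add_nodes_from(range(n))
    ii, jj = np.nonzero(np.triu(c.W, 1))
    if weighted:
        G.add_weighted_edges_from(
            zip(ii.tolist(), jj.tolist(), (1.0 / c.W[ii, jj]).tolist()),
            weight="length",
        )
        bc = nx.betweenness_centrality(G, normalized=False, weight="length")
    else:
        G.add_edges_from(zip(ii.tolist(), jj.tolist()))
        bc = nx.betweenness_centrality(G, normalized=False)
    values = np.array([bc[i] for i in range(n)])
    return NodeMetricVector("BCw" if weighted else "BC", values)


def global_efficiency(c: Connectome, weighted: bool = False) -> float:
    """Mean inverse shortest-path distance over ordered pairs (1/inf = 0)."""
    n = c.n_nodes
    if n < 2:
        raise ValueError("global efficiency needs at least 2 nodes")
    D = distance_matrix(c, weighted=weighted).values
    with np.errstate(divide="ignore"):
        inv = np.where(D > 0, 1.0 / np.where(D > 0, D, 1.0), 0.0)
    inv[~np.isfinite(D)] = 0.0
    np.fill_diagonal(inv, 0.0)
    return float(inv.sum() / (n * (n - 1)))


def characteristic_path_length(
    c: Connectome, weighted: bool = False
) -> tuple[float, float]:
    """Mean finite shortest-path distance and the disconnected-pair fraction.

    Returns ``(cpl, disconnected_fraction)``; raises if no pair is finite.
    """
    n = c.n_nodes
    if n < 2:
        raise ValueError("characteristic path length needs at least 2 nodes")
    D = distance_matrix(c, weighted=weighted).values
    off = ~np.eye(n, dtype=bool)
    vals = D[off]
    finite = np.isfinite(vals)
    if not finite.any():
        raise ValueError("no finite node pairs: network fully disconnected")
    return float(vals[finite].mean()), float(1.0 - finite.mean())


def identify_hubs(c: Connectome, hemisphere_filter: str | None = None) -> set[int]:
    """Hubs: nodes with degree >= mean degree + 1 sample SD.

    The threshold is computed on the whole network; the optional hemisphere
    restriction is applied afterwards.
    """
    deg = (c.W > 0).sum(axis=1).astype(float)
    sd = float(deg.std(ddof=1)) if c.n_nodes > 1 else 0.0
    thr = float(deg.mean()) + sd
    hubs = set(np.flatnonzero(deg >= thr).tolist())
    if hemisphere_filter is not None:
        allowed = set(c.hemisphere_nodes(hemisphere_filter).tolist())
        hubs &= allowed
    return hubs


def communicability_assortativity(
    c: Connectome, weighted: bool = False, k: int = 50, normalize: bool = True
) -> tuple[PairMatrix, dict[str, float], np.ndarray]:
    """Communicability sorted by degree (or strength) with block means.

    Rows/columns of the communicability matrix are reordered by increasing
    degree (binary) or strength (weighted); returned alongside the mean
    communicability within the bottom-k block, within the top-k block and
    across the two blocks (k capped at n // 2).  Positive assortative
    communicability shows as top-block mean > bottom-block mean.
    """
    n = c.n_nodes
    deg_v, str_v = degree_strength(c)
    key = str_v.values if weighted else deg_v.values
    order = np.lexsort((np.arange(n), key))  # ascending, ties by index
    pm = communicability_matrix(c, weighted=weighted, normalize=normalize)
    reordered = pm.values[np.ix_(order, order)]
    k_eff = max(1, min(k, n // 2)) if n >= 2 else 1
    bottom = np.arange(k_eff)
    top = np.arange(n - k_eff, n)

    def _block_mean(rows: np.ndarray, cols: np.ndarray) -> float:
        block = reordered[np.ix_(rows, cols)]
        if rows is cols or np.array_equal(rows, cols):
            mask = ~np.eye(len(rows), dtype=bool)
            return float(block[mask].mean()) if len(rows) > 1 else 0.0
        return float(block.mean())

    summary = {
        "bottom": _block_mean(bottom, bottom),
        "top": _block_mean(top, top),
        "cross": _block_mean(bottom, top),
        "k": float(k_eff),
    }
    return PairMatrix(pm.kind, reordered), summary, order


def top_node_density(c: Connectome, metric: NodeMetricVector, k: int) -> float:
    """Edge density of the subgraph induced by the k top-metric nodes.

    Ties are broken toward the lower node index.
    """
    n = c.n_nodes
    if not 2 <= k <= n:
        raise ValueError(f"k={k} out of range [2, {n}]")
    order = np.lexsort((np.arange(n), -metric.values))
    top = order[:k]
    sub = c.W[np.ix_(top, top)]
    edges = np.count_nonzero(np.triu(sub, 1) > 0)
    return float(edges / (k * (k - 1) / 2))


# ---------------------------------------------------------------------------
# per-node metric table used by the lesion/statistics layers

NODE_METRICS = ("Deg", "Sw", "BC", "BCw", "Cm", "Cmw", "CBC", "CBCw")


def node_metric_table(
    c: Connectome, metrics: tuple[str, ...] = NODE_METRICS
) -> "pd.DataFrame":
    """Per-node values of the requested metrics as a DataFrame.

    Communicability columns use the strength-normalized form in both the
    binary and weighted case, the variant the lesion analyses rely on for
    robustness against density differences.
    """
    import pandas as pd

    cols: dict[str, np.ndarray] = {}
    if "Deg" in metrics or "Sw" in metrics:
        deg_v, str_v = degree_strength(c)
        if "Deg" in metrics:
            cols["Deg"] = deg_v.values
        if "Sw" in metrics:
            cols["Sw"] = str_v.values
    if "BC" in metrics:
        cols["BC"] = betweenness(c, weighted=False).values
    if "BCw" in metrics:
        cols["BCw"] = betweenness(c, weighted=True).values
    if "Cm" in metrics:
        cols["Cm"] = node_communicability(
            communicability_matrix(c, weighted=False, normalize=True)
        ).values
    if "Cmw" in metrics:
        cols["Cmw"] = node_communicability(
            communicability_matrix(c, weighted=True, normalize=True)
        ).values
    if "CBC" in metrics:
        cols["CBC"] = communicability_centrality(c, weighted=False).values
    if "CBCw" in metrics:
        cols["CBCw"] = communicability_centrality(c, weighted=True).values
    df = pd.DataFrame(cols, index=list(c.labels))
    df.index.name = "label"
    return df[[m for m in metrics if m in df.columns]]
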