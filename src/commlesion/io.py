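"""Connectome and cohort containers with TSV/CSV/JSON round-trip.

A *connectome* is a weighted, undirected, loop-free graph over labelled
gray-matter parcels: a symmetric non-negative weight matrix ``W`` plus a node
table (label, hemisphere, optional 3-D coordinates in mm, optional node size
in voxels).  A *cohort* is a list of subjects each carrying two scans of the
same parcellation — the test–retest design the longitudinal lesion analysis
is built on.

File formats are deliberately plain: dense numeric TSV (or CSV by
extension) for matrices, TSV with a mandatory header for node tables, and a
JSON manifest tying a cohort together.  Matrix files may or may not carry a
header row; this is auto-detected.  All written node tables carry a 1-based
``index`` column alongside the label; it is ignored on load.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Connectome",
    "Cohort",
    "load_connectome",
    "save_connectome",
    "load_cohort",
    "save_cohort",
    "apply_node_size_correction",
    "build_average_network",
]

#: relative tolerance under which an asymmetric input matrix is silently
#: symmetrized by averaging; larger asymmetry is an error.
SYMMETRY_RTOL = 1e-8

_HEMI_VALUES = frozenset({"L", "R", "other"})


@dataclass
class Connectome:
    """One subject/scan structural network.

    Attributes
    ----------
    labels : list of str
        Region names, one per node, defining the node order.
    hemisphere : list of str
        Per-node hemisphere tag, each in ``{"L", "R", "other"}``.
    W : (n, n) ndarray
        Symmetric non-negative weight matrix with zero diagonal.
    coords : (n, 3) ndarray, optional
        Node coordinates in mm (used for Euclidean distance-from-lesion).
    node_size : (n,) ndarray, optional
        Positive node sizes in voxels (used by the size correction).
    """

    labels: list[str]
    hemisphere: list[str]
    W: np.ndarray
    coords: np.ndarray | None = None
    node_size: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.labels = list(self.labels)
        self.hemisphere = list(self.hemisphere)
        W = np.asarray(self.W, dtype=float)
        n = len(self.labels)
        if W.ndim != 2 or W.shape != (n, n):
            raise ValueError(
                f"weight matrix shape {W.shape} does not match {n} nodes"
            )
        if len(self.hemisphere) != n:
            raise ValueError("hemisphere list length mismatch")
        bad = set(self.hemisphere) - _HEMI_VALUES
        if bad:
            raise ValueError(f"invalid hemisphere tags: {sorted(bad)}")
        if not np.all(np.isfinite(W)):
            raise ValueError("non-finite entries in weight matrix")
        if np.any(W < 0):
            raise ValueError("negative weights are not allowed")
        asym = np.abs(W - W.T).max()
        scale = max(np.abs(W).max(), 1.0)
        if asym > SYMMETRY_RTOL * scale:
            raise ValueError(
                f"matrix asymmetry {asym:g} exceeds tolerance "
                f"{SYMMETRY_RTOL * scale:g}"
            )
        W = (W + W.T) / 2.0  # make the symmetry invariant exact
        np.fill_diagonal(W, 0.0)
        self.W = W
        if self.coords is not None:
            coords = np.asarray(self.coords, dtype=float)
            if coords.shape != (n, 3):
                raise ValueError("coords must be an (n, 3) array")
            self.coords = coords
        if self.node_size is not None:
            size = np.asarray(self.node_size, dtype=float)
            if size.shape != (n,):
                raise ValueError("node_size must be an (n,) array")
            if np.any(~np.isfinite(size)) or np.any(size <= 0):
                raise ValueError("node sizes must be positive and finite")
            self.node_size = size

    @property
    def n_nodes(self) -> int:
        return len(self.labels)

    def binary_adjacency(self) -> np.ndarray:
        """0/1 adjacency matrix A with A[i, j] = 1 iff W[i, j] > 0."""
        return (self.W > 0).astype(float)

    def with_weights(self, W: np.ndarray) -> "Connectome":
        """Copy of this connectome with a new weight matrix."""
        return replace(self, W=np.array(W, dtype=float))

    def binarized(self) -> "Connectome":
        """Copy whose weights are the 0/1 adjacency matrix."""
        return self.with_weights(self.binary_adjacency())

    def copy(self) -> "Connectome":
        return replace(
            self,
            W=self.W.copy(),
            coords=None if self.coords is None else self.coords.copy(),
            node_size=None if self.node_size is None else self.node_size.copy(),
        )

    def hemisphere_nodes(self, hemi: str) -> np.ndarray:
        """Indices of nodes in hemisphere ``hemi``."""
        return np.flatnonzero(np.asarray(self.hemisphere) == hemi)

    def n_edges(self) -> int:
        return int(np.count_nonzero(np.triu(self.W, 1) > 0))


@dataclass
class Cohort:
    """Two-scan cohort: list of (subject_id, scan_a, scan_b)."""

    subjects: list[tuple[str, Connectome, Connectome]]
    atlas_name: str = ""

    def __post_init__(self) -> None:
        ids = [sid for sid, _, _ in self.subjects]
        if len(set(ids)) != len(ids):
            raise ValueError("subject ids must be unique")
        if self.subjects:
            ref = self.subjects[0][1].labels
            for sid, a, b in self.subjects:
                for scan in (a, b):
                    if scan.labels != ref:
                        raise ValueError(
                            f"subject {sid}: node labels differ from cohort"
                        )

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def subject_ids(self) -> list[str]:
        return [sid for sid, _, _ in self.subjects]

    def scans(self, selector: str = "a") -> list[Connectome]:
        """Flat list of scans: selector in {'a', 'b', 'both'}."""
        if selector == "a":
            return [a for _, a, _ in self.subjects]
        if selector == "b":
            return [b for _, _, b in self.subjects]
        if selector == "both":
            out: list[Connectome] = []
            for _, a, b in self.subjects:
                out.extend((a, b))
            return out
        raise ValueError(f"unknown scan selector {selector!r}")


# ---------------------------------------------------------------------------
# file I/O


def _delimiter_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def _read_matrix(path: Path) -> np.ndarray:
    """Read a dense numeric matrix; a non-numeric first row is a header."""
    delim = _delimiter_for(path)
    with open(path) as fh:
        first = fh.readline()
    skip = 0
    tokens = [t for t in first.strip().split(delim) if t != ""]
    try:
        [float(t) for t in tokens]
    except ValueError:
        skip = 1
    try:
        mat = np.loadtxt(path, delimiter=delim, skiprows=skip, ndmin=2)
    except ValueError as exc:
        raise ValueError(f"non-numeric entries in matrix file {path}: {exc}")
    return mat


def load_connectome(matrix_path: str | Path, node_table_path: str | Path) -> Connectome:
    """Load a connectome from a matrix file and a node table.

    The matrix must be square and (up to a relative tolerance of
    ``SYMMETRY_RTOL``) symmetric; small asymmetries are averaged away.  The
    node table needs columns ``label`` and ``hemisphere`` and may carry
    ``x, y, z`` and ``size``.
    """
    matrix_path = Path(matrix_path)
    node_table_path = Path(node_table_path)
    W = _read_matrix(matrix_path)
    if W.shape[0] != W.shape[1]:
        raise ValueError(f"matrix in {matrix_path} is not square: {W.shape}")
    table = pd.read_csv(node_table_path, sep=_delimiter_for(node_table_path))
    table.columns = [str(c).strip().lower() for c in table.columns]
    for col in ("label", "hemisphere"):
        if col not in table.columns:
            raise ValueError(f"node table {node_table_path} lacks column {col!r}")
    if len(table) != W.shape[0]:
        raise ValueError(
            f"node table has {len(table)} rows but matrix is "
            f"{W.shape[0]}x{W.shape[0]}"
        )
    coords = None
    if {"x", "y", "z"} <= set(table.columns):
        coords = table[["x", "y", "z"]].to_numpy(dtype=float)
    node_size = None
    if "size" in table.columns:
        node_size = table["size"].to_numpy(dtype=float)
    return Connectome(
        labels=[str(l) for l in table["label"]],
        hemisphere=[str(h) for h in table["hemisphere"]],
        W=W,
        coords=coords,
        node_size=node_size,
    )


def save_connectome(
    c: Connectome, matrix_path: str | Path, node_table_path: str | Path
) -> None:
    """Write the matrix and node table; round-trips to 16 significant digits."""
    matrix_path = Path(matrix_path)
    node_table_path = Path(node_table_path)
    delim = _delimiter_for(matrix_path)
    np.savetxt(matrix_path, c.W, delimiter=delim, fmt="%.16g")
    cols: dict[str, object] = {
        "index": np.arange(1, c.n_nodes + 1),  # 1-based, for human readers
        "label": c.labels,
        "hemisphere": c.hemisphere,
    }
    if c.coords is not None:
        cols["x"], cols["y"], cols["z"] = c.coords.T
    if c.node_size is not None:
        cols["size"] = c.node_size
    pd.DataFrame(cols).to_csv(
        node_table_path,
        sep=_delimiter_for(node_table_path),
        index=False,
        float_format="%.16g",
    )


def load_cohort(manifest_path: str | Path) -> Cohort:
    """Load a cohort from a JSON manifest.

    The manifest lists subjects with per-scan matrix and node-table paths,
    resolved relative to the manifest's directory::

        {"atlas_name": "synthetic-86",
         "subjects": [{"subject_id": "s01",
                       "scan_a": {"matrix": "...", "nodes": "..."},
                       "scan_b": {"matrix": "...", "nodes": "..."}}]}
    """
    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    subjects = []
    for entry in manifest["subjects"]:
        scans = []
        for key in ("scan_a", "scan_b"):
            spec = entry[key]
            scans.append(
                load_connectome(base / spec["matrix"], base / spec["nodes"])
            )
        subjects.append((str(entry["subject_id"]), scans[0], scans[1]))
    return Cohort(subjects=subjects, atlas_name=manifest.get("atlas_name", ""))


def save_cohort(cohort: Cohort, out_dir: str | Path) -> Path:
    """Write per-scan TSV files plus ``manifest.json``; returns manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entries = []
    for sid, a, b in cohort.subjects:
        entry: dict[str, object] = {"subject_id": sid}
        for key, scan in (("scan_a", a), ("scan_b", b)):
            mat = f"{sid}_{key}_matrix.tsv"
            nodes = f"{sid}_{key}_nodes.tsv"
            save_connectome(scan, out_dir / mat, out_dir / nodes)
            entry[key] = {"matrix": mat, "nodes": nodes}
        entries.append(entry)
    manifest = {"atlas_name": cohort.atlas_name, "subjects": entries}
    manifest_path = out_dir / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest_path


# ---------------------------------------------------------------------------
# derived networks


def apply_node_size_correction(
    c: Connectome,
    divisor: Callable[[float, float], float] | None = None,
) -> Connectome:
    """Down-weight edges between large parcels.

    Connectivity indices from seed-based tractography scale with the size of
    the seed and target regions, so larger parcels get inflated weights.  The
    correction divides each weight by a symmetric function of the two node
    sizes, by default their sum::

        W'[i, j] = W[i, j] / (size_i + size_j)

    ``divisor`` may be any symmetric positive function of the two sizes.
    """
    if c.node_size is None:
        raise ValueError("node_size is required for the size correction")
    size = c.node_size
    if divisor is None:
        denom = size[:, None] + size[None, :]
    else:
        n = c.n_nodes
        denom = np.empty((n, n))
        for i in range(n):
            for j in range(n):
                denom[i, j] = divisor(size[i], size[j])
        if np.any(denom <= 0):
            raise ValueError("size-correction divisor must be positive")
    W = c.W / denom
    np.fill_diagonal(W, 0.0)
    return c.with_weights(W)


def build_average_network(
    cohort: Cohort,
    presence_threshold: float = 0.75,
    scan_selector: str = "a",
    weight_mode: str = "present",
) -> Connectome:
    """Group-average network with a presence-threshold edge rule.

    An edge is kept iff it exists (weight > 0) in at least
    ``presence_threshold`` of the selected scans; its weight is the mean
    weight over the scans where it is present (``weight_mode='present'``) or
    over all selected scans (``weight_mode='all'``).

    The default 75% threshold is the consistency level commonly used to
    suppress spurious tractography edges in group templates.
    """
    if not 0 < presence_threshold <= 1:
        raise ValueError("presence_threshold must be in (0, 1]")
    if weight_mode not in ("present", "all"):
        raise ValueError("weight_mode must be 'present' or 'all'")
    scans = cohort.scans(scan_selector)
    if not scans:
        raise ValueError("cannot average an empty cohort")
    stack = np.stack([s.W for s in scans])
    present = stack > 0
    frac = present.mean(axis=0)
    keep = frac >= presence_threshold
    if weight_mode == "present":
        counts = present.sum(axis=0)
        with np.errstate(invalid="ignore"):
            mean_w = np.where(counts > 0, stack.sum(axis=0) / np.maximum(counts, 1), 0.0)
    else:
        mean_w = stack.mean(axis=0)
    W = np.where(keep, mean_w, 0.0)
    np.fill_diagonal(W, 0.0)

    ref = scans[0]
    coords = None
    if all(s.coords is not None for s in scans):
        coords = np.mean([s.coords for s in scans], axis=0)
    node_size = None
    if all(s.node_size is not None for s in scans):
        node_size = np.mean([s.node_size for s in scans], axis=0)
    return Connectome(
        labels=list(ref.labels),
        hemisphere=list(ref.hemisphere),
        W=W,
        coords=coords,
        node_size=node_size,
    )
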