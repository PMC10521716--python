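"""Target-region connectivity graphs: types, construction, I/O, Dice.

A *target region* is a set of N voxels around (and including) an atlas ROI.
Its structure is carried by two tractography-derived matrices: an intra-region
voxel-voxel adjacency ``A`` (binary, symmetric) and an inter-region
voxel-to-ROI fibre-count matrix ``X`` (N x n, one column per atlas ROI).
Together with the voxel coordinates (mm) and optional inside/outside labels
these form a :class:`RegionGraph`, the unit every later stage consumes.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import scipy.sparse as sp
import yaml

__all__ = [
    "RegionGraph",
    "ConnectivityInputs",
    "build_region_graph",
    "dice_score",
    "save_region_graph",
    "load_region_graph",
    "graph_summary",
    "transform_features",
    "export_label_nifti",
]


class GraphValidationError(ValueError):
    """Raised when a connectivity matrix or graph field violates an invariant."""


class GraphParseError(ValueError):
    """Raised when an on-disk region-graph file is malformed."""


def _check_symmetric_zero_diag(mat: sp.spmatrix | np.ndarray, name: str) -> sp.csr_matrix:
    m = sp.csr_matrix(mat)
    if m.shape[0] != m.shape[1]:
        raise GraphValidationError(f"{name} must be square, got shape {m.shape}")
    if m.diagonal().any():
        i = int(np.nonzero(m.diagonal())[0][0])
        raise GraphValidationError(f"{name} has a nonzero diagonal entry at ({i}, {i})")
    diff = (m - m.T).tocoo()
    if diff.nnz and np.abs(diff.data).max() > 0:
        k = int(np.argmax(np.abs(diff.data)))
        raise GraphValidationError(
            f"{name} is not symmetric: first violating pair "
            f"({int(diff.row[k])}, {int(diff.col[k])})"
        )
    return m


@dataclasses.dataclass
class RegionGraph:
    """One target region as an attributed spatial graph.

    Attributes
    ----------
    adjacency : scipy.sparse.csr_matrix
        Binary symmetric N x N voxel-voxel adjacency with zero diagonal.
    features : ndarray, shape (N, n)
        Non-negative connectivity profiles; row i is voxel i's fibre counts
        to each of the n atlas ROIs.
    coords : ndarray, shape (N, 3)
        Voxel positions in millimetres.
    labels : ndarray or None
        Binary vector; 1 = voxel belongs to the parcellated ROI.
    roi_names : list of str
        Ordered atlas ROI identifiers, one per feature column.
    region_id : str
        Region identifier such as ``"PC.L"``.
    """

    adjacency: sp.csr_matrix
    features: np.ndarray
    coords: np.ndarray
    labels: np.ndarray | None = None
    roi_names: list[str] = dataclasses.field(default_factory=list)
    region_id: str = "region"

    def __post_init__(self) -> None:
        self.adjacency = _check_symmetric_zero_diag(self.adjacency, "adjacency")
        self.adjacency.data[:] = 1  # binary relation
        self.features = np.asarray(self.features)
        self.coords = np.asarray(self.coords, dtype=float)
        n = self.n_nodes
        if self.features.ndim != 2 or self.features.shape[0] != n:
            raise GraphValidationError(
                f"features must have shape ({n}, n_rois), got {self.features.shape}"
            )
        if np.any(self.features < 0):
            raise GraphValidationError("features contain negative entries")
        if self.coords.shape != (n, 3):
            raise GraphValidationError(
                f"coords must have shape ({n}, 3), got {self.coords.shape}"
            )
        if not self.roi_names:
            self.roi_names = [f"roi{i:03d}" for i in range(self.features.shape[1])]
        if len(self.roi_names) != self.features.shape[1]:
            raise GraphValidationError(
                f"{len(self.roi_names)} roi_names for {self.features.shape[1]} feature columns"
            )
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=np.int64)
            if self.labels.shape != (n,):
                raise GraphValidationError(f"labels must have length {n}")
            if not np.isin(self.labels, (0, 1)).all():
                raise GraphValidationError("labels must be binary {0, 1}")

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    @property
    def n_edges(self) -> int:
        return self.adjacency.nnz // 2

    def edge_array(self) -> np.ndarray:
        """Undirected edges as an (E, 2) int array with i < j, lexsorted."""
        coo = sp.triu(self.adjacency, k=1).tocoo()
        e = np.column_stack([coo.row, coo.col]).astype(np.int64)
        order = np.lexsort((e[:, 1], e[:, 0]))
        return e[order]

    def with_adjacency(self, adjacency: sp.spmatrix) -> "RegionGraph":
        """Copy sharing features/coords/labels but with a new edge set."""
        return RegionGraph(
            adjacency=adjacency,
            features=self.features,
            coords=self.coords,
            labels=self.labels,
            roi_names=list(self.roi_names),
            region_id=self.region_id,
        )


@dataclasses.dataclass
class ConnectivityInputs:
    """Raw tractography outputs for one target region.

    ``intra_counts`` holds voxel-voxel tracked-fibre counts (symmetric, zero
    diagonal); ``inter_counts`` holds voxel-to-ROI counts; ``coords`` are voxel
    centres in mm.
    """

    intra_counts: sp.csr_matrix
    inter_counts: np.ndarray
    coords: np.ndarray

    def __post_init__(self) -> None:
        self.intra_counts = _check_symmetric_zero_diag(self.intra_counts, "intra_counts")
        if self.intra_counts.nnz and self.intra_counts.data.min() < 0:
            raise GraphValidationError("intra_counts contains negative counts")
        self.inter_counts = np.asarray(self.inter_counts)
        if np.any(self.inter_counts < 0):
            raise GraphValidationError("inter_counts contains negative counts")
        n = self.intra_counts.shape[0]
        if self.inter_counts.shape[0] != n:
            raise GraphValidationError(
                f"inter_counts has {self.inter_counts.shape[0]} rows for {n} voxels"
            )
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (n, 3):
            raise GraphValidationError(f"coords must have shape ({n}, 3)")


def build_region_graph(
    inputs: ConnectivityInputs,
    binarize_threshold: int = 1,
    labels: np.ndarray | None = None,
    roi_names: Sequence[str] | None = None,
    region_id: str = "region",
) -> RegionGraph:
    """Binarize intra-region counts into an adjacency and assemble a graph.

    An edge (i, j) exists iff at least ``binarize_threshold`` fibres were
    tracked between voxels i and j (default 1: any tracked fibre connects).
    Features are the raw voxel-to-ROI counts; any transform is applied later,
    at the embedding stage.
    """
    if binarize_threshold < 1:
        raise ValueError("binarize_threshold must be >= 1")
    a = inputs.intra_counts.copy()
    a.data = (a.data >= binarize_threshold).astype(np.int8)
    a.eliminate_zeros()
    return RegionGraph(
        adjacency=a,
        features=inputs.inter_counts,
        coords=inputs.coords,
        labels=labels,
        roi_names=list(roi_names) if roi_names is not None else [],
        region_id=region_id,
    )


def dice_score(predicted: Iterable[int], truth: Iterable[int]) -> float:
    """Dice overlap 2|P ∩ T| / (|P| + |T|) between two voxel index sets."""
    p, t = set(predicted), set(truth)
    if not p and not t:
        raise ValueError("Dice is undefined for two empty sets")
    return 2.0 * len(p & t) / (len(p) + len(t))


def transform_features(X: np.ndarray, kind: str | None = "log1p-max") -> np.ndarray:
    """Default fibre-count transform: log1p then per-feature max-normalisation.

    Fibre counts are heavy-tailed across ROIs; the log damps the dominant
    bundles and the per-column max scaling puts every ROI on [0, 1]. ``kind``
    of ``None`` or ``"none"`` returns the counts as float, untouched.
    """
    X = np.asarray(X, dtype=float)
    if kind in (None, "none"):
        return X
    if kind == "log1p-max":
        Z = np.log1p(X)
        mx = Z.max(axis=0)
        mx[mx == 0] = 1.0
        return Z / mx
    raise ValueError(f"unknown feature transform {kind!r}")


# ---------------------------------------------------------------------------
# serialization: one directory per region
# ---------------------------------------------------------------------------

_EDGES, _FEATS, _COORDS, _LABELS, _META = (
    "edges.tsv",
    "features.tsv",
    "coords.tsv",
    "labels.tsv",
    "meta.yaml",
)


def _fmt_number(v: float) -> str:
    f = float(v)
    return str(int(f)) if f.is_integer() else repr(f)


def save_region_graph(graph: RegionGraph, path: str | Path) -> None:
    """Write a region directory: edges/features/coords/labels TSVs + meta.yaml.

    Integer-valued features and labels round-trip bit-exactly; coordinates to
    full repr precision.
    """
    d = Path(path)
    d.mkdir(parents=True, exist_ok=True)
    edges = graph.edge_array()
    with open(d / _EDGES, "w") as fh:
        for i, j in edges:
            fh.write(f"{i}\t{j}\n")
    with open(d / _FEATS, "w") as fh:
        fh.write("\t".join(graph.roi_names) + "\n")
        for row in graph.features:
            fh.write("\t".join(_fmt_number(v) for v in row) + "\n")
    with open(d / _COORDS, "w") as fh:
        fh.write("x\ty\tz\n")
        for row in graph.coords:
            fh.write("\t".join(repr(float(v)) for v in row) + "\n")
    if graph.labels is not None:
        with open(d / _LABELS, "w") as fh:
            fh.writelines(f"{int(v)}\n" for v in graph.labels)
    meta = {
        "region_id": graph.region_id,
        "n_nodes": int(graph.n_nodes),
        "n_rois": int(graph.n_features),
        "format": "sgcp-region/1",
    }
    with open(d / _META, "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=False)


def _read_table(path: Path, n_cols: int, header: bool) -> tuple[list[str], np.ndarray]:
    if not path.exists():
        raise GraphParseError(f"missing file: {path}")
    names: list[str] = []
    rows: list[list[float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if header and lineno == 1:
                names = parts
                continue
            try:
                rows.append([float(p) for p in parts])
            except ValueError as exc:
                raise GraphParseError(f"{path}:{lineno}: malformed row: {exc}") from None
            if n_cols and len(parts) != n_cols:
                raise GraphParseError(
                    f"{path}:{lineno}: expected {n_cols} columns, got {len(parts)}"
                )
    return names, np.asarray(rows, dtype=float)


def _read_edges(path: Path, n_nodes: int) -> np.ndarray:
    rows: list[tuple[int, int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise GraphParseError(f"{path}:{lineno}: expected 2 columns")
            try:
                i, j = int(parts[0]), int(parts[1])
            except ValueError:
                raise GraphParseError(f"{path}:{lineno}: non-integer edge index") from None
            if not (0 <= i < n_nodes and 0 <= j < n_nodes):
                raise GraphParseError(
                    f"{path}:{lineno}: edge index out of range for N={n_nodes}"
                )
            if i == j:
                raise GraphParseError(f"{path}:{lineno}: self-loop ({i}, {j})")
            rows.append((i, j))
    return np.asarray(rows, dtype=np.int64).reshape(-1, 2)


def load_region_graph(path: str | Path) -> RegionGraph:
    """Load a region directory written by :func:`save_region_graph`.

    Adjacency may alternatively be given as MatrixMarket ``adjacency.mtx``
    (coordinate format) when ``edges.tsv`` is absent.
    """
    d = Path(path)
    with open(d / _META) as fh:
        meta = yaml.safe_load(fh)
    n = int(meta["n_nodes"])
    roi_names, feats = _read_table(d / _FEATS, n_cols=int(meta["n_rois"]), header=True)
    if feats.shape != (n, int(meta["n_rois"])):
        raise GraphParseError(
            f"{d / _FEATS}: expected {n} rows x {meta['n_rois']} cols, got {feats.shape}"
        )
    _, coords = _read_table(d / _COORDS, n_cols=3, header=True)
    if coords.shape != (n, 3):
        raise GraphParseError(f"{d / _COORDS}: expected {n} coordinate rows")

    if (d / _EDGES).exists():
        edges = _read_edges(d / _EDGES, n)
    elif (d / "adjacency.mtx").exists():
        from scipy.io import mmread

        m = sp.coo_matrix(mmread(d / "adjacency.mtx"))
        if m.shape != (n, n):
            raise GraphParseError(f"adjacency.mtx shape {m.shape} does not match N={n}")
        mask = m.row < m.col
        edges = np.column_stack([m.row[mask], m.col[mask]]).astype(np.int64)
    else:
        raise GraphParseError(f"{d}: neither edges.tsv nor adjacency.mtx found")

    if len(edges):
        data = np.ones(len(edges), dtype=np.int8)
        adj = sp.coo_matrix((data, (edges[:, 0], edges[:, 1])), shape=(n, n))
        adj = adj + adj.T
    else:
        adj = sp.csr_matrix((n, n), dtype=np.int8)

    labels = None
    if (d / _LABELS).exists():
        _, lab = _read_table(d / _LABELS, n_cols=1, header=False)
        if lab.shape[0] != n:
            raise GraphParseError(f"{d / _LABELS}: expected {n} label rows")
        labels = lab.ravel().astype(np.int64)

    return RegionGraph(
        adjacency=adj,
        features=feats,
        coords=coords,
        labels=labels,
        roi_names=roi_names,
        region_id=str(meta.get("region_id", d.name)),
    )


def graph_summary(graph: RegionGraph) -> dict:
    """Node/edge/feature counts and the per-label voxel tally."""
    counts: dict[int, int] = {}
    if graph.labels is not None:
        vals, cnt = np.unique(graph.labels, return_counts=True)
        counts = {int(v): int(c) for v, c in zip(vals, cnt)}
    return {
        "region_id": graph.region_id,
        "n_nodes": int(graph.n_nodes),
        "n_edges": int(graph.n_edges),
        "n_features": int(graph.n_features),
        "label_counts": counts,
    }


def export_label_nifti(
    labels: np.ndarray,
    coords_ijk: np.ndarray,
    grid_shape: tuple[int, int, int],
    affine: np.ndarray,
    path: str | Path,
) -> None:
    """Write a binary label map as a NIfTI-1 volume (requires nibabel)."""
    import nibabel as nib

    vol = np.zeros(grid_shape, dtype=np.uint8)
    ijk = np.asarray(coords_ijk, dtype=int)
    vol[ijk[:, 0], ijk[:, 1], ijk[:, 2]] = np.asarray(labels, dtype=np.uint8)
    nib.save(nib.Nifti1Image(vol, np.asarray(affine, dtype=float)), str(path))
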