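"""Spatial-graph convolution encoder and the plain-GCN ablation encoder.

The spatial aggregation updates node i by summing, over its graph
neighbours j, the neighbour features gated by a learned function of the
*relative* position::

    h_bar_i = sum_{j in N_i} ReLU(U^T (p_j - p_i) + b) ⊙ h_j

with U in R^{t x d}, b in R^d. Only coordinate differences enter, so the
operation is translation-invariant and permutation-equivariant by
construction. A layer applies k such filters, concatenates their outputs,
and (by default) mixes the concatenation back to the configured width with a
learned linear map; ReLU sits between layers and the last layer stays linear
so embeddings are unconstrained for cosine similarity.

The ablation encoder replaces the geometric gate with the standard
symmetric-normalised propagation A_hat = D~^{-1/2} (A + I) D~^{-1/2},
ignoring coordinates, at matched depth and width.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import scipy.sparse as sp

from ._nn import glorot, relu
from .graphdata import RegionGraph, transform_features

__all__ = [
    "SpatialConvParams",
    "EncoderConfig",
    "spatial_aggregate",
    "spatial_conv_multi",
    "SGCNEncoder",
    "GCNEncoder",
    "make_encoder",
    "encode",
    "gcn_encode",
]


@dataclasses.dataclass
class SpatialConvParams:
    """Per-filter parameters (U_k, b_k) of one spatial-aggregation layer."""

    filters: list[tuple[np.ndarray, np.ndarray]]

    def __post_init__(self) -> None:
        if not self.filters:
            raise ValueError("at least one filter required")
        t, d = self.filters[0][0].shape
        for U, b in self.filters:
            if U.shape != (t, d) or b.shape != (d,):
                raise ValueError(
                    f"all filters must share shapes U ({t}, {d}) and b ({d},)"
                )

    @property
    def t(self) -> int:
        return self.filters[0][0].shape[0]

    @property
    def d_in(self) -> int:
        return self.filters[0][0].shape[1]


@dataclasses.dataclass
class EncoderConfig:
    """Architecture of the node-embedding encoder.

    ``type`` selects the geometric encoder (``"sgcn"``) or the plain-GCN
    ablation (``"gcn"``). With ``mixing`` on, each layer's filter
    concatenation is linearly projected to ``hidden_dim`` (``output_dim`` for
    the last layer); with it off the layer is the raw concatenation, so the
    width multiplies by ``filters`` per layer. ``input_skip`` adds a learned
    linear contribution of the layer input to the mixed output, giving nodes
    a self-term the neighbour sum lacks.
    """

    type: str = "sgcn"
    n_layers: int = 2
    filters: int = 2
    hidden_dim: int = 32
    output_dim: int = 32
    activation: str = "relu"
    mixing: bool = True
    input_skip: bool = False
    feature_transform: str | None = "log1p-max"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.type not in ("sgcn", "gcn"):
            raise ValueError("encoder type must be 'sgcn' or 'gcn'")
        if self.n_layers < 1 or self.filters < 1:
            raise ValueError("n_layers and filters must be >= 1")
        if self.hidden_dim < 1 or self.output_dim < 1:
            raise ValueError("dims must be >= 1")
        if self.activation != "relu":
            raise ValueError("only 'relu' activation is supported")


# ---------------------------------------------------------------------------
# functional spatial aggregation
# ---------------------------------------------------------------------------


def _directed_edges(adjacency: sp.spmatrix) -> tuple[np.ndarray, np.ndarray]:
    coo = sp.coo_matrix(adjacency)
    return coo.row.astype(np.int64), coo.col.astype(np.int64)


def _incidence(idx: np.ndarray, n: int, n_edges: int, dtype=np.float64) -> sp.csr_matrix:
    return sp.csr_matrix(
        (np.ones(n_edges, dtype=dtype), (idx, np.arange(n_edges))), shape=(n, n_edges)
    )


def spatial_aggregate(
    H: np.ndarray,
    P: np.ndarray,
    adjacency: sp.spmatrix,
    U: np.ndarray,
    b: np.ndarray,
) -> np.ndarray:
    """One geometric aggregation pass; nodes with no neighbours map to zero."""
    H = np.asarray(H, float)
    P = np.asarray(P, float)
    n, d = H.shape
    if P.shape[0] != n:
        raise ValueError(f"H has {n} rows but P has {P.shape[0]}")
    if U.shape != (P.shape[1], d) or b.shape != (d,):
        raise ValueError(
            f"expected U {(P.shape[1], d)} and b {(d,)}, got {U.shape} and {b.shape}"
        )
    if adjacency.shape != (n, n):
        raise ValueError("adjacency shape does not match H")
    anchors, nbrs = _directed_edges(adjacency)
    gate = relu((P[nbrs] - P[anchors]) @ U + b)
    return _incidence(anchors, n, len(anchors)) @ (gate * H[nbrs])


def spatial_conv_multi(
    H: np.ndarray, P: np.ndarray, adjacency: sp.spmatrix, params: SpatialConvParams
) -> np.ndarray:
    """Concatenate the k filter outputs, filter order preserved."""
    return np.concatenate(
        [spatial_aggregate(H, P, adjacency, U, b) for U, b in params.filters], axis=1
    )


# ---------------------------------------------------------------------------
# trainable encoders
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class _GraphTensors:
    """Per-graph (or per-view) precomputation shared across epochs of a pass."""

    X: np.ndarray  # transformed node features, N x d0
    anchors: np.ndarray
    nbrs: np.ndarray
    D: np.ndarray  # p_nbr - p_anchor, E x t
    S_a: sp.csr_matrix  # anchor incidence, N x E
    S_n: sp.csr_matrix  # neighbour incidence, N x E
    A_hat: sp.csr_matrix | None = None  # normalised propagation (GCN only)


class _EncoderBase:
    def __init__(self, config: EncoderConfig, n_features: int, dtype=np.float64):
        self.config = config
        self.n_features = n_features
        self.dtype = np.dtype(dtype)
        self.params: dict[str, np.ndarray] = {}
        self._widths = self._layer_widths()
        self._init_params(np.random.default_rng(config.seed))
        for k in self.params:
            self.params[k] = self.params[k].astype(self.dtype, copy=False)

    # layer l maps width[l] -> width[l+1]
    def _layer_widths(self) -> list[int]:
        cfg = self.config
        widths = [self.n_features]
        for l in range(cfg.n_layers):
            last = l == cfg.n_layers - 1
            if cfg.mixing or cfg.type == "gcn":
                widths.append(cfg.output_dim if last else cfg.hidden_dim)
            else:
                widths.append(widths[-1] * cfg.filters)
        return widths

    @property
    def output_dim(self) -> int:
        return self._widths[-1]

    def prepare(self, graph: RegionGraph) -> _GraphTensors:
        X = transform_features(graph.features, self.config.feature_transform)
        if X.shape[1] != self.n_features:
            raise ValueError(
                f"graph has {X.shape[1]} features, encoder expects {self.n_features}"
            )
        return self.tensors_from(X, graph.coords, graph.edge_array())

    def tensors_from(
        self, X: np.ndarray, coords: np.ndarray, edges: np.ndarray
    ) -> _GraphTensors:
        """Assemble per-view tensors from already-transformed features and an
        undirected edge list (used directly by the training loop, which caches
        the feature transform and augmentation probabilities per graph)."""
        n = X.shape[0]
        if len(edges):
            anchors = np.concatenate([edges[:, 0], edges[:, 1]])
            nbrs = np.concatenate([edges[:, 1], edges[:, 0]])
        else:
            anchors = nbrs = np.empty(0, dtype=np.int64)
        e = len(anchors)
        dt = self.dtype
        gt = _GraphTensors(
            X=np.asarray(X, dtype=dt),
            anchors=anchors,
            nbrs=nbrs,
            D=(coords[nbrs] - coords[anchors]).astype(dt, copy=False),
            S_a=_incidence(anchors, n, e, dt),
            S_n=_incidence(nbrs, n, e, dt),
        )
        if self.config.type == "gcn":
            deg = np.bincount(anchors, minlength=n).astype(float) + 1.0  # + self-loop
            dinv = 1.0 / np.sqrt(deg)
            data = dinv[anchors] * dinv[nbrs]
            gt.A_hat = (
                sp.coo_matrix((data, (anchors, nbrs)), shape=(n, n))
                + sp.diags(dinv * dinv)
            ).tocsr().astype(dt)
        return gt

    def embed(self, graph: RegionGraph) -> np.ndarray:
        """Deterministic node embeddings of the (un-augmented) graph."""
        h, _ = self.forward(self.prepare(graph), want_cache=False)
        return h

    # subclasses: _init_params, forward, backward


class SGCNEncoder(_EncoderBase):
    """Stacked multi-filter spatial-graph convolution blocks."""

    def _init_params(self, rng: np.random.Generator) -> None:
        cfg = self.config
        for l in range(cfg.n_layers):
            d_in = self._widths[l]
            for f in range(cfg.filters):
                self.params[f"l{l}.U{f}"] = glorot(rng, (3, d_in))
                self.params[f"l{l}.b{f}"] = np.zeros(d_in)
            if cfg.mixing:
                d_out = self._widths[l + 1]
                self.params[f"l{l}.W"] = glorot(rng, (cfg.filters * d_in, d_out))
                self.params[f"l{l}.c"] = np.zeros(d_out)
                if cfg.input_skip:
                    self.params[f"l{l}.Ws"] = glorot(rng, (d_in, d_out))

    def layer_params(self, l: int) -> SpatialConvParams:
        return SpatialConvParams(
            filters=[
                (self.params[f"l{l}.U{f}"], self.params[f"l{l}.b{f}"])
                for f in range(self.config.filters)
            ]
        )

    def forward(self, gt: _GraphTensors, want_cache: bool = True):
        cfg = self.config
        H = gt.X
        cache: list[dict] = []
        for l in range(cfg.n_layers):
            last = l == cfg.n_layers - 1
            parts, fcaches = [], []
            for f in range(cfg.filters):
                Z = gt.D @ self.params[f"l{l}.U{f}"] + self.params[f"l{l}.b{f}"]
                mask = Z > 0
                G = np.where(mask, Z, 0.0)
                M = G * H[gt.nbrs]
                parts.append(gt.S_a @ M)
                if want_cache:
                    fcaches.append((mask, G))
            A = np.concatenate(parts, axis=1)
            if cfg.mixing:
                Y = A @ self.params[f"l{l}.W"] + self.params[f"l{l}.c"]
                if cfg.input_skip:
                    Y = Y + H @ self.params[f"l{l}.Ws"]
            else:
                Y = A
            out = Y if last else relu(Y)
            if want_cache:
                cache.append({"H": H, "A": A, "Y": Y, "fc": fcaches, "last": last})
            H = out
        return H, cache

    def backward(self, gt: _GraphTensors, cache: list[dict], dOut: np.ndarray):
        cfg = self.config
        grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        for l in reversed(range(cfg.n_layers)):
            c = cache[l]
            dY = dOut if c["last"] else dOut * (c["Y"] > 0)
            H = c["H"]
            if cfg.mixing:
                grads[f"l{l}.W"] += c["A"].T @ dY
                grads[f"l{l}.c"] += dY.sum(axis=0)
                dA = dY @ self.params[f"l{l}.W"].T
                dH = np.zeros_like(H)
                if cfg.input_skip:
                    grads[f"l{l}.Ws"] += H.T @ dY
                    dH += dY @ self.params[f"l{l}.Ws"].T
            else:
                dA = dY
                dH = np.zeros_like(H)
            d_in = self._widths[l]
            Hn = H[gt.nbrs]
            for f in range(cfg.filters):
                dAf = dA[:, f * d_in : (f + 1) * d_in]
                mask, G = c["fc"][f]
                dM = dAf[gt.anchors]  # S_a^T scatter
                dH += gt.S_n @ (dM * G)
                dZ = dM * Hn * mask
                grads[f"l{l}.U{f}"] += gt.D.T @ dZ
                grads[f"l{l}.b{f}"] += dZ.sum(axis=0)
            dOut = dH
        return grads


class GCNEncoder(_EncoderBase):
    """Symmetric-normalised graph convolution at matched depth/width."""

    def _init_params(self, rng: np.random.Generator) -> None:
        for l in range(self.config.n_layers):
            self.params[f"l{l}.W"] = glorot(rng, (self._widths[l], self._widths[l + 1]))
            self.params[f"l{l}.c"] = np.zeros(self._widths[l + 1])

    def forward(self, gt: _GraphTensors, want_cache: bool = True):
        cfg = self.config
        H = gt.X
        cache: list[dict] = []
        for l in range(cfg.n_layers):
            last = l == cfg.n_layers - 1
            AH = gt.A_hat @ H
            Y = AH @ self.params[f"l{l}.W"] + self.params[f"l{l}.c"]
            out = Y if last else relu(Y)
            if want_cache:
                cache.append({"AH": AH, "Y": Y, "last": last})
            H = out
        return H, cache

    def backward(self, gt: _GraphTensors, cache: list[dict], dOut: np.ndarray):
        grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        for l in reversed(range(self.config.n_layers)):
            c = cache[l]
            dY = dOut if c["last"] else dOut * (c["Y"] > 0)
            grads[f"l{l}.W"] += c["AH"].T @ dY
            grads[f"l{l}.c"] += dY.sum(axis=0)
            dOut = gt.A_hat @ (dY @ self.params[f"l{l}.W"].T)  # A_hat symmetric
        return grads


def make_encoder(config: EncoderConfig, n_features: int, dtype=np.float64) -> _EncoderBase:
    cls = SGCNEncoder if config.type == "sgcn" else GCNEncoder
    return cls(config, n_features, dtype=dtype)


def encode(
    graph: RegionGraph, config: EncoderConfig, params: dict[str, np.ndarray] | None = None
) -> np.ndarray:
    """Embed a graph with a spatial-graph encoder (fresh seeded init if no
    parameters are supplied)."""
    cfg = dataclasses.replace(config, type="sgcn")
    enc = SGCNEncoder(cfg, graph.n_features)
    if params is not None:
        _set_params(enc, params)
    return enc.embed(graph)


def gcn_encode(
    graph: RegionGraph, config: EncoderConfig, params: dict[str, np.ndarray] | None = None
) -> np.ndarray:
    """Embed a graph with the plain-GCN ablation encoder."""
    cfg = dataclasses.replace(config, type="gcn")
    enc = GCNEncoder(cfg, graph.n_features)
    if params is not None:
        _set_params(enc, params)
    return enc.embed(graph)


def _set_params(enc: _EncoderBase, params: dict[str, np.ndarray]) -> None:
    for k, v in params.items():
        if k not in enc.params:
            raise KeyError(f"unknown parameter {k!r}")
        if enc.params[k].shape != v.shape:
            raise ValueError(
                f"parameter {k!r}: expected shape {enc.params[k].shape}, got {v.shape}"
            )
        enc.params[k] = np.asarray(v, dtype=float)
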