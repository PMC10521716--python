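"""Stage I: projection head, multiview InfoNCE objective, training loop.

Two stochastically augmented views of each region graph are embedded by a
shared encoder; a small MLP projection head maps the embeddings h to a
lower-dimensional metric space z = g(h) where cosine similarity is taken.
For anchor node i in one view, the node's counterpart in the other view is
the positive, and every other node — in both views — is a negative::

    l(z1_i, z2_i) = -log  e^{θ(z1_i, z2_i)/τ} /
        ( e^{θ(z1_i, z2_i)/τ} + Σ_{k≠i} e^{θ(z1_i, z2_k)/τ}
                               + Σ_{k≠i} e^{θ(z1_i, z1_k)/τ} )

with τ the temperature and θ cosine similarity; the total loss averages both
anchor directions over all N positive pairs, L = (1/2N) Σ_i [l(z1_i, z2_i) +
l(z2_i, z1_i)]. The log-sum is max-stabilised. Minimising L pulls the two
views of a node together and pushes distinct nodes apart, without labels.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np

from ._nn import Adam, glorot, relu
from .augment import (
    AugmentationConfig,
    degree_centrality,
    edge_drop_probabilities,
    edge_importance,
    feature_importance,
    feature_mask_probabilities,
    sample_view,
)
from .graphdata import RegionGraph, transform_features
from .sgcn import EncoderConfig, _EncoderBase, make_encoder

logger = logging.getLogger(__name__)

__all__ = [
    "ProjectionHead",
    "ContrastiveConfig",
    "Stage1Result",
    "cosine_similarity",
    "contrastive_loss",
    "train_stage1",
    "embed_nodes",
]


def cosine_similarity(a: np.ndarray, b: np.ndarray) -> float:
    """Cosine of the angle between two vectors; 0 for a zero vector (logged)."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        logger.warning("cosine_similarity of a zero vector defined as 0")
        return 0.0
    return float(a @ b / (na * nb))


class ProjectionHead:
    """One-hidden-layer MLP g: R^d -> R^{d'} with d' < d (default d' = d/2)."""

    def __init__(self, d_in: int, d_out: int | None = None, seed: int = 0,
                 dtype=np.float64):
        if d_out is None:
            d_out = max(d_in // 2, 1)
        if not d_out < d_in:
            raise ValueError(f"projection must reduce dimension: d'={d_out} >= d={d_in}")
        self.d_in, self.d_out = d_in, d_out
        rng = np.random.default_rng(seed)
        self.params = {
            "W1": glorot(rng, (d_in, d_in)).astype(dtype),
            "b1": np.zeros(d_in, dtype=dtype),
            "W2": glorot(rng, (d_in, d_out)).astype(dtype),
            "b2": np.zeros(d_out, dtype=dtype),
        }

    def forward(self, H: np.ndarray, want_cache: bool = True):
        Y = H @ self.params["W1"] + self.params["b1"]
        A = relu(Y)
        Z = A @ self.params["W2"] + self.params["b2"]
        return Z, ({"H": H, "Y": Y, "A": A} if want_cache else None)

    def backward(self, cache: dict, dZ: np.ndarray):
        grads = {
            "W2": cache["A"].T @ dZ,
            "b2": dZ.sum(axis=0),
        }
        dA = dZ @ self.params["W2"].T
        dY = dA * (cache["Y"] > 0)
        grads["W1"] = cache["H"].T @ dY
        grads["b1"] = dY.sum(axis=0)
        dH = dY @ self.params["W1"].T
        return grads, dH


@dataclasses.dataclass
class ContrastiveConfig:
    """Stage-I training hyperparameters."""

    tau: float = 0.5
    epochs: int = 200
    learning_rate: float = 1e-3
    optimizer: str = "adam"
    seed: int = 0
    augment1: AugmentationConfig = dataclasses.field(default_factory=AugmentationConfig)
    augment2: AugmentationConfig = dataclasses.field(default_factory=AugmentationConfig)
    double_projection: bool = False

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError("temperature tau must be positive")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.optimizer != "adam":
            raise ValueError("only 'adam' is supported")


def _normalize_rows(Z: np.ndarray, eps: float = 1e-12):
    norms = np.maximum(np.linalg.norm(Z, axis=1, keepdims=True), eps)
    return Z / norms, norms


def _loss_and_grad(Z1: np.ndarray, Z2: np.ndarray, tau: float, dtype=None):
    """InfoNCE value and gradients w.r.t. the projected embeddings.

    Cosine similarities are bounded by 1, so the soft-max is stabilised
    globally with exp((S - 1)/tau); each of the three similarity blocks
    (cross-view, and the two within-view negative blocks) is exponentiated
    exactly once and shared between the two anchor directions. ``dtype``
    defaults to the input dtype (the training loop runs in float32).
    """
    if dtype is None:
        dtype = Z1.dtype if Z1.dtype in (np.float32, np.float64) else np.float64
    dtype = np.dtype(dtype).type
    n = Z1.shape[0]
    Zn1, nrm1 = _normalize_rows(np.asarray(Z1, dtype=dtype))
    Zn2, nrm2 = _normalize_rows(np.asarray(Z2, dtype=dtype))
    tau = dtype(tau)
    one = dtype(1.0)

    def stab_exp(S):
        S -= one
        S /= tau
        with np.errstate(over="ignore"):  # inf is caught by the caller
            return np.exp(S, out=S)

    E12 = stab_exp(Zn1 @ Zn2.T)
    E11 = stab_exp(Zn1 @ Zn1.T)
    E22 = stab_exp(Zn2 @ Zn2.T)
    np.fill_diagonal(E11, 0.0)  # an anchor is never its own negative
    np.fill_diagonal(E22, 0.0)
    pos = np.diagonal(E12)
    den1 = E12.sum(axis=1) + E11.sum(axis=1)  # anchors in view 1
    den2 = E12.sum(axis=0) + E22.sum(axis=1)  # anchors in view 2
    with np.errstate(invalid="ignore"):  # inf/inf -> nan is caught by the caller
        loss = float((np.log(den1 / pos).sum() + np.log(den2 / pos).sum()) / (2.0 * n))

    c = dtype(1.0 / (2.0 * n * tau))
    with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
        # a non-finite loss (tau too small) is caught by the caller; do not
        # warn on the way there
        inv1 = c / den1
        inv2 = c / den2
        d_S12 = E12 * (inv1[:, None] + inv2[None, :])
        d_S12[np.diag_indices(n)] -= dtype(2.0) * c
        E11 *= inv1[:, None]  # in place: E11 becomes d_S11
        E22 *= inv2[:, None]
        dZn1 = d_S12 @ Zn2 + E11 @ Zn1 + E11.T @ Zn1
        dZn2 = d_S12.T @ Zn1 + E22 @ Zn2 + E22.T @ Zn2

    def denorm(dZn, Zn, nrm):
        return (dZn - (dZn * Zn).sum(axis=1, keepdims=True) * Zn) / nrm

    return loss, denorm(dZn1, Zn1, nrm1), denorm(dZn2, Zn2, nrm2)


def contrastive_loss(Z1: np.ndarray, Z2: np.ndarray, tau: float) -> float:
    """Multiview InfoNCE over two aligned sets of projected embeddings."""
    if tau <= 0:
        raise ValueError("temperature tau must be positive")
    Z1, Z2 = np.asarray(Z1, float), np.asarray(Z2, float)
    if Z1.shape != Z2.shape:
        raise ValueError(f"shape mismatch: {Z1.shape} vs {Z2.shape}")
    if Z1.ndim != 2 or Z1.shape[0] < 1:
        raise ValueError("expected N x d' arrays with N >= 1")
    loss, _, _ = _loss_and_grad(Z1, Z2, tau)
    return loss


@dataclasses.dataclass
class _CachedGraph:
    """Per-graph constants of the training loop: transformed features, edge
    list, and the augmentation probabilities (they depend only on the source
    graph, never on the draw)."""

    region_id: str
    X_t: np.ndarray
    coords: np.ndarray
    edges: np.ndarray
    p_edge: dict[int, np.ndarray]  # keyed by view index (1, 2)
    p_feat: dict[int, np.ndarray]


def _cache_graph(
    g: RegionGraph, enc_cfg: EncoderConfig, config: "ContrastiveConfig"
) -> _CachedGraph:
    edges = g.edge_array()
    cent = degree_centrality(g)
    p_edge, p_feat = {}, {}
    for i, aug in ((1, config.augment1), (2, config.augment2)):
        if len(edges):
            _, s_e = edge_importance(g, cent)
            p_edge[i] = edge_drop_probabilities(s_e, aug)
        else:
            p_edge[i] = np.empty(0)
        _, s_f = feature_importance(g, cent, binarize=aug.occurrence_binarize)
        p_feat[i] = feature_mask_probabilities(s_f, aug)
    return _CachedGraph(
        region_id=g.region_id,
        X_t=transform_features(g.features, enc_cfg.feature_transform),
        coords=g.coords,
        edges=edges,
        p_edge=p_edge,
        p_feat=p_feat,
    )


def _draw_view(cache: _CachedGraph, view: int, seed: int):
    """Fast equivalent of :func:`sgcp.augment.sample_view`: identical draws
    from the same seed, returning the view's tensors without re-validating a
    full RegionGraph. Column masking commutes with the per-column feature
    transform (a zeroed count column transforms to a zero column), so the
    cached transformed features are masked directly."""
    rng = np.random.default_rng(seed)
    edges = cache.edges
    kept = edges[rng.random(len(edges)) >= cache.p_edge[view]] if len(edges) else edges
    masked = np.flatnonzero(rng.random(cache.X_t.shape[1]) < cache.p_feat[view])
    Xv = cache.X_t.copy()
    Xv[:, masked] = 0.0
    return Xv, kept


@dataclasses.dataclass
class Stage1Result:
    """Trained encoder + head and the per-epoch loss trace."""

    encoder: _EncoderBase
    head: ProjectionHead
    loss_trace: np.ndarray
    config: ContrastiveConfig


def train_stage1(
    graphs: RegionGraph | list[RegionGraph],
    encoder_config: EncoderConfig,
    config: ContrastiveConfig,
    head: ProjectionHead | None = None,
) -> Stage1Result:
    """Fit one shared encoder self-supervisedly on one or more region graphs.

    Each epoch visits every graph: two fresh views are drawn, embedded by the
    shared encoder, projected, and the InfoNCE loss is minimised by a joint
    Adam step on encoder and head. Fully reproducible from ``config.seed``
    (view seeds are drawn from a dedicated stream). The per-epoch trace holds
    the mean loss across graphs.
    """
    if isinstance(graphs, RegionGraph):
        graphs = [graphs]
    if not graphs:
        raise ValueError("at least one graph required")
    n_features = graphs[0].n_features
    if any(g.n_features != n_features for g in graphs):
        raise ValueError("all graphs must share the feature dimensionality")

    # float32 throughout the training loop: the loss is memory-bound at
    # N x N similarity scale and single precision is ample for SGD
    encoder = make_encoder(encoder_config, n_features, dtype=np.float32)
    if head is None:
        head = ProjectionHead(encoder.output_dim, seed=config.seed + 1, dtype=np.float32)
    params = {f"enc.{k}": v for k, v in encoder.params.items()}
    params.update({f"head.{k}": v for k, v in head.params.items()})
    # containers share memory with the live encoder/head parameter dicts
    opt = Adam(params, lr=config.learning_rate)
    seed_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x5743]))

    caches = [_cache_graph(g, encoder_config, config) for g in graphs]
    trace = np.empty(config.epochs)
    for epoch in range(config.epochs):
        epoch_losses = []
        for cg in caches:
            s1, s2 = seed_rng.integers(0, 2**31, size=2)
            X1, kept1 = _draw_view(cg, 1, int(s1))
            X2, kept2 = _draw_view(cg, 2, int(s2))
            gt1 = encoder.tensors_from(X1, cg.coords, kept1)
            gt2 = encoder.tensors_from(X2, cg.coords, kept2)
            H1, c1 = encoder.forward(gt1)
            H2, c2 = encoder.forward(gt2)
            Z1, hc1 = head.forward(H1)
            Z2, hc2 = head.forward(H2)
            if config.double_projection:
                Z1, hc1b = head.forward(Z1)  # literal θ(z) = s(g(z1), g(z2))
                Z2, hc2b = head.forward(Z2)
            loss, dZ1, dZ2 = _loss_and_grad(Z1, Z2, config.tau)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite contrastive loss at epoch {epoch} "
                    f"(graph {cg.region_id}); consider a larger tau"
                )
            if config.double_projection:
                hg1b, dZ1 = head.backward(hc1b, dZ1)
                hg2b, dZ2 = head.backward(hc2b, dZ2)
            hg1, dH1 = head.backward(hc1, dZ1)
            hg2, dH2 = head.backward(hc2, dZ2)
            eg1 = encoder.backward(gt1, c1, dH1)
            eg2 = encoder.backward(gt2, c2, dH2)
            grads = {f"enc.{k}": eg1[k] + eg2[k] for k in eg1}
            head_grads = {k: hg1[k] + hg2[k] for k in hg1}
            if config.double_projection:
                for k in head_grads:
                    head_grads[k] += hg1b[k] + hg2b[k]
            grads.update({f"head.{k}": v for k, v in head_grads.items()})
            opt.step(grads)
            epoch_losses.append(loss)
        trace[epoch] = float(np.mean(epoch_losses))
    return Stage1Result(encoder=encoder, head=head, loss_trace=trace, config=config)


def embed_nodes(graph: RegionGraph, trained: Stage1Result | _EncoderBase) -> np.ndarray:
    """Frozen Stage-I embeddings of the original (un-augmented) graph."""
    encoder = trained.encoder if isinstance(trained, Stage1Result) else trained
    return encoder.embed(graph)
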