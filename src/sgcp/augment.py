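"""Centrality-adaptive graph augmentation: edge deletion and feature masking.

The two contrastive views of a region graph are produced by (i) deleting each
undirected edge independently with a probability that decreases with the
edge's degree-centrality importance, and (ii) zeroing whole feature columns
with a probability that decreases with the feature's occurrence-weighted
centrality. Log-damped importances are rescaled by their spread, scaled by an
overall level (``p_e`` / ``p_f``) and capped at a cut-off ``p_tau`` so that
no single draw over-corrupts the graph.

The printed form of the adaptive rule carries a leading ``1 -`` that inverts
the intended monotonicity (it would delete the *most* central edges almost
surely); the default here implements the stated premise — more important
edges are less likely to be deleted — and the printed form stays available
behind ``literal_formula=True``.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import scipy.sparse as sp

from .graphdata import RegionGraph

__all__ = [
    "AugmentationConfig",
    "AugmentedView",
    "degree_centrality",
    "edge_importance",
    "edge_drop_probabilities",
    "feature_importance",
    "feature_mask_probabilities",
    "sample_view",
]


@dataclasses.dataclass
class AugmentationConfig:
    """Augmentation levels: ``p_e`` edges, ``p_f`` features, cut-off ``p_tau``."""

    p_e: float = 0.3
    p_f: float = 0.3
    p_tau: float = 0.7
    literal_formula: bool = False
    occurrence_binarize: bool = True

    def __post_init__(self) -> None:
        for name in ("p_e", "p_f"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if not 0.0 < self.p_tau <= 1.0:
            raise ValueError("p_tau must lie in (0, 1]")


@dataclasses.dataclass
class AugmentedView:
    """A stochastic view of a region graph: same nodes, corrupted structure."""

    graph: RegionGraph
    kept_edges: np.ndarray  # (E_kept, 2), i < j
    masked_features: np.ndarray  # sorted indices of zeroed feature columns
    seed: int


def degree_centrality(graph: RegionGraph) -> np.ndarray:
    """Node degree phi_c(u) >= 0 (isolated nodes score 0)."""
    return np.asarray(graph.adjacency.sum(axis=1)).ravel().astype(float)


def edge_importance(
    graph: RegionGraph, centrality: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Per-edge importance w_uv = (phi_c(u) + phi_c(v)) / 2 and s_uv = log w_uv.

    Returned in the order of ``graph.edge_array()``. The log damps the pull of
    densely connected hub nodes.
    """
    if centrality is None:
        centrality = degree_centrality(graph)
    e = graph.edge_array()
    w = 0.5 * (centrality[e[:, 0]] + centrality[e[:, 1]])
    return w, np.log(w)


def _adaptive_probabilities(
    s: np.ndarray, level: float, p_tau: float, literal: bool
) -> np.ndarray:
    """Map importances s to removal probabilities.

    Default form: p = min((s_max - s) / (s_max - mean_s) * level, p_tau),
    monotone non-increasing in s. When all finite importances coincide the
    rescaling is ill-defined and every item gets min(level, p_tau).
    s = -inf (zero raw importance) takes the formula's own limit: the cap
    p_tau when the level is positive, 0 when the level is 0 (identity
    augmentation). ``literal`` replaces p by 1 - min(...), the printed
    orientation.
    """
    s = np.asarray(s, dtype=float)
    finite = np.isfinite(s)
    p = np.empty_like(s)
    if finite.any():
        s_max = s[finite].max()
        mu = s[finite].mean()
        if s_max - mu > 0:
            p[finite] = np.minimum((s_max - s[finite]) / (s_max - mu) * level, p_tau)
        else:
            p[finite] = min(level, p_tau)
    p[~finite] = p_tau if level > 0 else 0.0
    if literal:
        p = 1.0 - p
    return p


def edge_drop_probabilities(s: np.ndarray, config: AugmentationConfig) -> np.ndarray:
    """Per-edge deletion probabilities from log-importances ``s``."""
    s = np.asarray(s, dtype=float)
    if s.size == 0:
        raise ValueError("edge_drop_probabilities needs at least one edge")
    return _adaptive_probabilities(s, config.p_e, config.p_tau, config.literal_formula)


def feature_importance(
    graph: RegionGraph, centrality: np.ndarray | None = None, binarize: bool = True
) -> tuple[np.ndarray, np.ndarray]:
    """Per-dimension importance w_i = sum_u occ(u, i) * phi_c(u), s_i = log w_i.

    ``occ`` is the binarized occurrence X > 0 by default (the declared {0, 1}
    domain of the occurrence indicator); ``binarize=False`` weights by the
    raw count magnitude instead. Dimensions occurring nowhere get w = 0 and
    s = -inf (minimal importance).
    """
    if centrality is None:
        centrality = degree_centrality(graph)
    occ = (graph.features > 0).astype(float) if binarize else np.abs(graph.features)
    w = occ.T @ centrality
    with np.errstate(divide="ignore"):
        s = np.log(w)
    return w, s


def feature_mask_probabilities(s: np.ndarray, config: AugmentationConfig) -> np.ndarray:
    """Per-dimension masking probabilities from log-importances ``s``."""
    s = np.asarray(s, dtype=float)
    if s.size == 0:
        raise ValueError("feature_mask_probabilities needs at least one dimension")
    return _adaptive_probabilities(s, config.p_f, config.p_tau, config.literal_formula)


def sample_view(graph: RegionGraph, config: AugmentationConfig, seed: int) -> AugmentedView:
    """Draw one augmented view: independent edge deletions + column masks.

    Each undirected edge is deleted with its adaptive probability (both
    directions together, so the view stays symmetric); each feature column is
    zeroed across all nodes with its masking probability. Nodes, coordinates
    and labels pass through untouched.
    """
    rng = np.random.default_rng(seed)
    edges = graph.edge_array()
    n = graph.n_nodes

    if len(edges):
        _, s_e = edge_importance(graph)
        p_e = edge_drop_probabilities(s_e, config)
        kept = edges[rng.random(len(edges)) >= p_e]
    else:
        kept = edges

    _, s_f = feature_importance(graph, binarize=config.occurrence_binarize)
    p_f = feature_mask_probabilities(s_f, config)
    masked = np.flatnonzero(rng.random(len(p_f)) < p_f)

    if len(kept):
        adj = sp.coo_matrix(
            (np.ones(len(kept), dtype=np.int8), (kept[:, 0], kept[:, 1])), shape=(n, n)
        )
        adj = adj + adj.T
    else:
        adj = sp.csr_matrix((n, n), dtype=np.int8)
    features = graph.features.astype(float, copy=True)
    features[:, masked] = 0.0

    view_graph = RegionGraph(
        adjacency=adj,
        features=features,
        coords=graph.coords,
        labels=graph.labels,
        roi_names=list(graph.roi_names),
        region_id=graph.region_id,
    )
    return AugmentedView(graph=view_graph, kept_edges=kept, masked_features=masked, seed=seed)
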