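"""Centrality-adaptive augmentation: what gets dropped, and how often.

Edge deletion probabilities decrease with the mean degree centrality of the
edge's endpoints (log-damped); feature-mask probabilities decrease with the
occurrence-weighted centrality of each dimension. Both are scaled by an
overall level (p_e / p_f) and capped at the cut-off p_tau, so the most
important edge is never deleted and nothing exceeds the cap.
"""

import numpy as np

from sgcp import (
    AugmentationConfig,
    SyntheticConfig,
    degree_centrality,
    edge_drop_probabilities,
    edge_importance,
    make_region,
    sample_view,
)

g = make_region(SyntheticConfig(grid_shape=(6, 6, 5), n_rois=34,
                                signature_size=3, seed=1))
cfg = AugmentationConfig(p_e=0.3, p_f=0.3, p_tau=0.7)

w, s = edge_importance(g)
p = edge_drop_probabilities(s, cfg)
print(f"{g.n_edges} edges; degree range "
      f"{int(degree_centrality(g).min())}-{int(degree_centrality(g).max())}")
print(f"deletion probabilities: min {p.min():.3f}, mean {p.mean():.3f}, "
      f"max {p.max():.3f} (cap {cfg.p_tau})")
print(f"most important edge (s = s_max) has deletion probability {p[np.argmax(s)]:.0%}")

view = sample_view(g, cfg, seed=7)
print(f"one view: kept {len(view.kept_edges)}/{g.n_edges} edges, "
      f"masked {len(view.masked_features)}/{g.n_features} feature dims")
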