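"""Generate synthetic target regions and inspect their structure.

Each region is a voxel lattice with a contiguous ellipsoidal ROI blob
(label 1), class-specific Poisson connectivity fingerprints, and an
adjacency mixing local 6-neighbourhood edges with class-assortative
long-range edges. The separability index (between-class centroid distance
over within-class spread) quantifies how strong the fingerprint contrast
is; the noise_swap control degrades it.
"""

import dataclasses

from sgcp import SyntheticConfig, graph_summary, make_dataset, separability_index

cfg = SyntheticConfig(grid_shape=(8, 8, 6), n_rois=68, signature_size=4, seed=0)
regions = make_dataset(cfg, n_regions=3)

for g in regions:
    s = graph_summary(g)
    print(
        f"{s['region_id']}: {s['n_nodes']} voxels, {s['n_edges']} edges, "
        f"{s['label_counts'][1]} in ROI, separability {separability_index(g):.2f}"
    )

noisy = dataclasses.replace(cfg, noise_swap=0.3)
g = make_dataset(noisy, n_regions=3)[0]
print(f"with 30% fingerprint swaps: separability {separability_index(g):.2f} "
      "(harder task, same geometry)")
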