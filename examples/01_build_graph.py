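"""Build a target-region graph from tractography connectivity matrices.

Constructs a toy 4-voxel region from an intra-region fibre-count matrix
(binarised into the adjacency: an edge wherever at least one fibre was
tracked) and a voxel-to-ROI count matrix (the connectivity profiles), then
prints its summary and a Dice score between two voxel sets.
"""

import numpy as np
import scipy.sparse as sp

from sgcp import ConnectivityInputs, build_region_graph, dice_score, graph_summary

intra = np.array(
    [
        [0, 3, 0, 0],
        [3, 0, 1, 0],
        [0, 1, 0, 5],
        [0, 0, 5, 0],
    ]
)
inter = np.array(
    [
        [12, 0, 1],
        [9, 1, 0],
        [0, 7, 2],
        [1, 8, 0],
    ]
)
coords = np.array([[0, 0, 0], [1.25, 0, 0], [2.5, 0, 0], [3.75, 0, 0]])

inputs = ConnectivityInputs(sp.csr_matrix(intra), inter, coords)
graph = build_region_graph(
    inputs,
    binarize_threshold=1,
    labels=np.array([1, 1, 0, 0]),
    roi_names=["SMA", "preSMA", "M1"],
    region_id="TOY",
)

print("summary:", graph_summary(graph))
print("edges:", graph.edge_array().tolist())
# With threshold 2 the single-fibre link (1, 2) disappears:
print("edges at threshold 2:",
      build_region_graph(inputs, binarize_threshold=2).edge_array().tolist())

d = dice_score({0, 1}, {1, 2})
print(f"Dice({{0,1}}, {{1,2}}) = {d:.4f}  (one shared voxel out of 2+2)")
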