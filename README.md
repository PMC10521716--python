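# sgcp — connectivity-based parcellation via contrastive spatial-graph learning

`sgcp` delineates a cortical region from its surroundings using only
structural connectivity. Given a *target region* — an atlas ROI plus a
shell of surrounding voxels — represented as a graph whose nodes are
voxels, whose edges come from binarised voxel-voxel tractography counts,
and whose node features are voxel-to-ROI fibre-count profiles, it learns
which voxels belong to the ROI in two stages:

1. **Self-supervised embedding.** Two stochastically corrupted views of the
   graph are drawn by *centrality-adaptive* augmentation (important edges
   and feature dimensions survive; unimportant ones are dropped with
   probability up to a cut-off p_τ). A **spatial-graph convolution**
   encoder — a neighbour sum gated by a learned function of relative voxel
   position, h̄_i = Σ_{j∈N_i} ReLU(Uᵀ(p_j−p_i)+b) ⊙ h_j — embeds both
   views, and a projection head + multiview **InfoNCE** loss
   (temperature-scaled cosine similarity; each node's other-view copy is
   the positive, all other nodes are negatives) trains encoder and head
   jointly, without labels.
2. **Supervised parcellation.** The embeddings of the original graph are
   frozen; a small MLP classifies each voxel inside/outside the ROI.
   Evaluation is **leave-one-region-out**: train the classifier on the
   voxels of all other regions, test on the held-out region, score with the
   Dice overlap 2|P∩T|/(|P|+|T|).

The package is aimed at methods work on connectivity-based parcellation:
it ships a synthetic generator producing labelled target regions with
contiguous ROI blobs, class-specific Poisson connectional fingerprints and
class-assortative long-range edges, so the complete pipeline — including a
plain-GCN ablation of the encoder — runs and is tested end-to-end with no
imaging data. Tractography, atlas construction and NIfTI wrangling beyond a
simple label-map export are out of scope.

## Worked example

```python
from sgcp.pipeline import PipelineConfig, run_all

cfg = PipelineConfig()          # 5 regions, 12x12x10 voxels, 68 atlas ROIs
out = run_all(cfg, seed=1)      # simulate -> embed -> parcellate -> evaluate
print(out["report"].to_string(index=False))
```

prints (about two minutes on one CPU)

```
region_id  n_voxels  n_predicted     dice
    SYN.0      1440          596 0.959044
    SYN.1      1440          582 0.968912
    SYN.2      1440          580 0.974048
    SYN.3      1440          575 0.966116
    SYN.4      1440          602 0.962649
     mean      7200         2935 0.966154
```

Each row is one cross-validation fold: the classifier never saw that
region's voxels (nor its fingerprint ROIs — signature sets are disjoint
across regions), so a Dice of ~0.96 means the frozen embeddings carry
region-invariant structure. Raw connectivity profiles transfer at ~0.45
under the same protocol, and swapping the spatial encoder for a plain GCN
(`cfg.encoder.type = "gcn"`) drops the 5-seed mean to ~0.67 — geometry is
what makes the representation portable.

The same stages are available from the shell:

```bash
sgcp simulate --config cfg.yaml --out data/
sgcp embed --data data/ --config cfg.yaml --out ckpt.npz
sgcp parcellate --data data/ --ckpt ckpt.npz --config cfg.yaml --out report.tsv
sgcp run-all --config cfg.yaml --seed 1
```

and `examples/` contains one short narrative script per capability
(graph construction, simulation, augmentation, embedding, parcellation).

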