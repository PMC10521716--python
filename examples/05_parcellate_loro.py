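"""Full pipeline: simulate -> embed -> leave-one-region-out parcellation.

Runs the whole two-stage pipeline at reduced scale (4 regions of 8x8x6
voxels, 80 Stage-I epochs) and prints the per-region Dice table. Each fold
trains the voxel MLP on the frozen embeddings of the other regions and
scores the held-out one — the measure of whether the learned representation
generalises to an unseen region's connectional fingerprint.

The same run is available from the shell:
    sgcp run-all --config cfg.yaml --seed 1
"""

from sgcp.pipeline import PipelineConfig, run_all

cfg = PipelineConfig()
cfg.data.grid_shape = (8, 8, 6)
cfg.data.signature_size = 4
cfg.n_regions = 4
cfg.stage1.epochs = 80

out = run_all(cfg, seed=1)
print(out["report"].to_string(index=False))
print(f"\nmean leave-one-region-out Dice: {out['mean_dice']:.4f}")
print("(full-scale defaults — 12x12x10 grid, 5 regions, 200 epochs — "
      "reach ~0.96; see scripts/acceptance.py)")
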