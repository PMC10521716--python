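"""End-to-end orchestration: config handling, checkpoints, run-all.

A single YAML file with blocks ``data``, ``augment``, ``encoder``,
``stage1``, ``stage2``, ``eval`` drives the whole pipeline:
simulate (or load) target regions -> self-supervised Stage-I training of the
shared encoder -> frozen per-region embeddings -> leave-one-region-out
Stage-II classification -> Dice report. All randomness flows from the
config seeds; an integer ``seed`` argument re-keys every block
deterministically so one number reproduces a full run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import yaml

from .augment import AugmentationConfig
from .contrastive import ContrastiveConfig, ProjectionHead, Stage1Result, embed_nodes, train_stage1
from .graphdata import RegionGraph, load_region_graph, save_region_graph
from .parcellate import ClassifierConfig, evaluate_report, leave_one_region_out
from .sgcn import EncoderConfig, make_encoder
from .synthetic import SyntheticConfig, make_dataset

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "load_config",
    "simulate",
    "run_stage1",
    "run_all",
    "save_checkpoint",
    "load_checkpoint",
]

_SEED_MOD = 2**31 - 1


@dataclasses.dataclass
class PipelineConfig:
    data: SyntheticConfig = dataclasses.field(default_factory=SyntheticConfig)
    n_regions: int = 5
    augment: AugmentationConfig = dataclasses.field(default_factory=AugmentationConfig)
    encoder: EncoderConfig = dataclasses.field(default_factory=EncoderConfig)
    stage1: ContrastiveConfig = dataclasses.field(default_factory=ContrastiveConfig)
    stage2: ClassifierConfig = dataclasses.field(default_factory=ClassifierConfig)
    postprocess: bool = False

    def reseed(self, seed: int) -> "PipelineConfig":
        """Derive a fully re-keyed copy from one integer seed."""
        seed = int(seed) % _SEED_MOD
        return dataclasses.replace(
            self,
            data=dataclasses.replace(self.data, seed=seed),
            encoder=dataclasses.replace(self.encoder, seed=(seed + 1) % _SEED_MOD),
            stage1=dataclasses.replace(self.stage1, seed=(seed + 2) % _SEED_MOD),
            stage2=dataclasses.replace(self.stage2, seed=(seed + 3) % _SEED_MOD),
        )

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(dataclasses.asdict(self), sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


def _build(cls, block: dict, **extra):
    known = {f.name for f in dataclasses.fields(cls)}
    alias = {"lr": "learning_rate"}
    kwargs = {}
    for k, v in (block or {}).items():
        k = alias.get(k, k)
        if k not in known:
            raise ValueError(f"unknown {cls.__name__} option {k!r}")
        kwargs[k] = v
    kwargs.update(extra)
    return cls(**kwargs)


def load_config(source: str | Path | dict | None) -> PipelineConfig:
    """Build a :class:`PipelineConfig` from a YAML path or nested dict."""
    if source is None:
        return PipelineConfig()
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            source = yaml.safe_load(fh) or {}
    data_block = dict(source.get("data") or {})
    n_regions = int(data_block.pop("n_regions", 5))
    if "grid_shape" in data_block:
        data_block["grid_shape"] = tuple(data_block["grid_shape"])
    aug = _build(AugmentationConfig, source.get("augment"))
    stage1_block = dict(source.get("stage1") or {})
    cfg = PipelineConfig(
        data=_build(SyntheticConfig, data_block),
        n_regions=n_regions,
        augment=aug,
        encoder=_build(EncoderConfig, source.get("encoder")),
        stage1=_build(ContrastiveConfig, stage1_block, augment1=aug, augment2=aug),
        stage2=_build(ClassifierConfig, source.get("stage2")),
        postprocess=bool((source.get("eval") or {}).get("postprocess", False)),
    )
    return cfg


def simulate(cfg: PipelineConfig, out_dir: str | Path | None = None) -> list[RegionGraph]:
    """Generate the synthetic multi-region dataset (and optionally save it)."""
    regions = make_dataset(cfg.data, n_regions=cfg.n_regions)
    if out_dir is not None:
        for g in regions:
            save_region_graph(g, Path(out_dir) / g.region_id)
    return regions


def run_stage1(regions: list[RegionGraph], cfg: PipelineConfig) -> Stage1Result:
    logger.info(
        "stage1: %d region(s), encoder=%s, %d epochs, config %s",
        len(regions), cfg.encoder.type, cfg.stage1.epochs, cfg.hash(),
    )
    return train_stage1(regions, cfg.encoder, cfg.stage1)


def run_all(
    config: PipelineConfig | str | Path | dict | None = None,
    seed: int | None = None,
    out_dir: str | Path | None = None,
):
    """simulate -> embed -> parcellate -> evaluate, from one config (+seed).

    Returns a dict with the regions, the Stage-I result, the per-region
    parcellation results, the report DataFrame and the mean Dice.
    """
    cfg = config if isinstance(config, PipelineConfig) else load_config(config)
    if seed is not None:
        cfg = cfg.reseed(seed)
    logger.info("run-all: config hash %s", cfg.hash())
    regions = simulate(cfg)
    stage1 = run_stage1(regions, cfg)
    embeddings = [embed_nodes(g, stage1) for g in regions]
    results, mean_dice = leave_one_region_out(regions, embeddings, cfg.stage2)
    report = evaluate_report(results)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        report.to_csv(out / "report.tsv", sep="\t", index=False)
        np.savetxt(out / "loss_trace.tsv", stage1.loss_trace, fmt="%.10f")
        save_checkpoint(stage1, out / "checkpoint.npz")
    return {
        "config": cfg,
        "regions": regions,
        "stage1": stage1,
        "results": results,
        "report": report,
        "mean_dice": mean_dice,
    }


def save_checkpoint(stage1: Stage1Result, path: str | Path) -> None:
    """Encoder + head parameters and their configs, as one .npz archive."""
    arrays = {f"enc.{k}": v for k, v in stage1.encoder.params.items()}
    arrays.update({f"head.{k}": v for k, v in stage1.head.params.items()})
    arrays["meta"] = np.array(
        yaml.safe_dump(
            {
                "encoder_config": dataclasses.asdict(stage1.encoder.config),
                "n_features": stage1.encoder.n_features,
                "dtype": stage1.encoder.dtype.name,
                "head": {"d_in": stage1.head.d_in, "d_out": stage1.head.d_out},
            }
        )
    )
    np.savez(path, **arrays)


def load_checkpoint(path: str | Path) -> Stage1Result:
    with np.load(path, allow_pickle=False) as z:
        meta = yaml.safe_load(str(z["meta"]))
        enc_cfg = EncoderConfig(**meta["encoder_config"])
        dtype = np.dtype(meta.get("dtype", "float64"))
        encoder = make_encoder(enc_cfg, int(meta["n_features"]), dtype=dtype)
        for k in encoder.params:
            encoder.params[k] = z[f"enc.{k}"]
        head = ProjectionHead(
            int(meta["head"]["d_in"]), int(meta["head"]["d_out"]), dtype=dtype
        )
        for k in head.params:
            head.params[k] = z[f"head.{k}"]
    return Stage1Result(
        encoder=encoder, head=head, loss_trace=np.empty(0), config=ContrastiveConfig()
    )
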