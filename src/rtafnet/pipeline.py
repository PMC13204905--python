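"""End-to-end pipeline orchestration: simulate -> preprocess -> augment ->
train -> evaluate, as reproducible, configured, logged runs.

A :class:`RunConfig` nests the per-stage configurations under one master
seed; every stochastic stage receives a seed derived deterministically from
it, so re-running the same config reproduces all numeric outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .api import AFNetClassifier, AFNetResults
from .augment import AugmentConfig
from .nn.model import ModelConfig
from .preprocess import records_to_windows, split_dataset
from .synthetic import RhythmSpec, SynthConfig, default_rhythm_specs, generate_dataset
from .training import TrainConfig

__all__ = ["RunConfig", "run_pipeline", "run_ablation", "scaled_down_model_config"]

logger = logging.getLogger(__name__)

ABLATION_VARIANTS = (
    "full", "resnet_only", "transformer_only", "no_fusion", "no_weighted_loss",
)


def scaled_down_model_config(variant: str = "full") -> ModelConfig:
    """Desk-scale architecture for CPU experiments: D=64, two residual
    stages, one encoder layer; a 4000-sample window maps to L'=125."""
    return ModelConfig(
        stem_kernel=15, stem_stride=4, stem_channels=32,
        stages=((2, 32, 4), (2, 64, 2)),
        attention_stages=frozenset({2}),
        block_attention_heads=4,
        d_model=64, encoder_layers=1, num_heads=4, ffn_dim=128,
        dropout=0.1, classifier_hidden=64,
        variant=variant,
    )


@dataclass(frozen=True)
class RunConfig:
    """Nested per-stage configuration under one master seed."""

    classes: tuple[str, ...] = ("NSR", "AF")
    n_per_class: int = 10
    synth: SynthConfig = field(default_factory=lambda: SynthConfig(duration=120.0))
    specs: dict | None = None
    split_level: str = "record"
    ratios: tuple[float, float, float] = (0.70, 0.15, 0.15)
    augment: AugmentConfig | None = field(default_factory=AugmentConfig)
    model: ModelConfig = field(default_factory=scaled_down_model_config)
    train: TrainConfig = field(default_factory=lambda: TrainConfig(max_epochs=20))
    master_seed: int = 0

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage child seed below 2**31."""
        order = ("simulate", "split", "augment", "init", "train")
        if stage not in order:
            raise ValueError(f"unknown stage {stage!r}")
        ss = np.random.SeedSequence(self.master_seed)
        return int(ss.generate_state(len(order))[order.index(stage)] % (2**31))

    def resolved(self) -> "RunConfig":
        """Propagate derived stage seeds into the nested configs."""
        synth = replace(self.synth, seed=self.stage_seed("simulate"))
        aug = (
            replace(self.augment, seed=self.stage_seed("augment"))
            if self.augment is not None else None
        )
        tr = replace(self.train, seed=self.stage_seed("train"))
        return replace(self, synth=synth, augment=aug, train=tr)

    def to_json(self) -> str:
        def enc(o):
            if dataclasses.is_dataclass(o):
                return {k: enc(v) for k, v in dataclasses.asdict(o).items()}
            if isinstance(o, frozenset):
                return sorted(o)
            if isinstance(o, tuple):
                return list(o)
            if isinstance(o, dict):
                return {k: enc(v) for k, v in o.items()}
            return o
        d = {f.name: enc(getattr(self, f.name))
             for f in dataclasses.fields(self)}
        d["model"] = self.model.to_dict()
        return json.dumps(d, indent=2, default=str)


def run_pipeline(
    config: RunConfig, out_dir: str | Path | None = None, verbose: bool = False
) -> AFNetResults:
    """Execute all stages; optionally write artifacts (resolved config,
    history, metrics report, rhythm table) into ``out_dir``."""
    cfg = config.resolved()
    specs_all = default_rhythm_specs()
    if cfg.specs:
        specs_all.update(cfg.specs)
    unknown = set(cfg.classes) - set(specs_all)
    if unknown:
        raise ValueError(f"unknown rhythm classes in config: {sorted(unknown)}")
    specs = {c: specs_all[c] for c in cfg.classes}

    logger.info("simulate: %d records/class x %s", cfg.n_per_class, cfg.classes)
    records = generate_dataset(cfg.n_per_class, specs, cfg.synth)
    logger.info("preprocess: windowing %d records", len(records))
    windows = records_to_windows(records)
    splits = split_dataset(
        windows, cfg.ratios, level=cfg.split_level, seed=cfg.stage_seed("split")
    )
    logger.info("train: %d train / %d val / %d test windows",
                len(splits.train), len(splits.val), len(splits.test))
    clf = AFNetClassifier(
        splits, model_config=cfg.model, train_config=cfg.train,
        augment=cfg.augment, init_seed=cfg.stage_seed("init"),
    )
    results = clf.fit(verbose=verbose)
    report, rows = results.evaluate()
    logger.info("evaluate: weighted F1 %.2f%%", report.weighted["f1"])

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "config.json").write_text(cfg.to_json())
        (out_dir / "history.json").write_text(json.dumps({
            "train_loss": results.history.train_loss,
            "val_f1": results.history.val_f1,
            "val_accuracy": results.history.val_accuracy,
            "lrs": results.history.lrs,
            "best_epoch": results.history.best_epoch,
            "stopped_early": results.history.stopped_early,
        }, indent=2))
        (out_dir / "metrics.json").write_text(json.dumps({
            "accuracy": report.accuracy,
            "weighted": report.weighted,
            "per_class": report.per_class,
            "auc": report.auc,
            "counts": dataclasses.asdict(report.counts),
        }, indent=2))
        (out_dir / "report.txt").write_text(results.summary() + "\n")
        (out_dir / "rhythm_errors.csv").write_text(
            "rhythm,total,predicted_af,predicted_nonaf,error_rate\n"
            + "".join(
                f"{r.rhythm},{r.total},{r.predicted_af},"
                f"{r.predicted_nonaf},{r.error_rate:.2f}\n"
                for r in rows
            )
        )
    return results


def run_ablation(
    config: RunConfig, variant: str, out_dir: str | Path | None = None
) -> AFNetResults:
    """Train and evaluate one ablation variant.

    ``resnet_only`` bypasses the encoder, ``transformer_only`` bypasses the
    residual stages (the stem performs the full downsampling),
    ``no_fusion`` keeps only average pooling, and ``no_weighted_loss`` uses
    uniform class weights; ``full`` is the unmodified model.
    """
    if variant not in ABLATION_VARIANTS:
        raise ValueError(
            f"unknown variant {variant!r}; choose from {ABLATION_VARIANTS}"
        )
    cfg = config
    if variant == "no_weighted_loss":
        cfg = replace(cfg, train=replace(cfg.train, weighted_loss=False))
    elif variant != "full":
        cfg = replace(cfg, model=cfg.model.for_variant(variant))
    return run_pipeline(cfg, out_dir=out_dir)
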