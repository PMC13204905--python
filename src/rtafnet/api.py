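"""statsmodels-style modelling facade.

``AFNetClassifier`` wraps the architecture + training algorithm as a model
object built from preprocessed data; ``fit()`` returns an
``AFNetResults`` carrying the trained network, the per-epoch history and
evaluation diagnostics, with a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .augment import AugmentConfig, augment_training_set
from .evaluation import (
    MetricsReport, RhythmErrorRow, cross_db_evaluate, evaluate_model,
)
from .nn.model import ModelConfig, RTAFNet
from .preprocess import DatasetSplits, Window
from .training import TrainConfig, TrainHistory, train

__all__ = ["AFNetClassifier", "AFNetResults"]


class AFNetClassifier:
    """Binary AF/NonAF window classifier.

    Parameters
    ----------
    splits : DatasetSplits
        Preprocessed train/val/test windows (4000 samples at 400 Hz each).
    model_config : ModelConfig, optional
        Architecture; defaults to the reference configuration.
    train_config : TrainConfig, optional
        Optimization hyperparameters.
    augment : AugmentConfig or None
        Class-selective training augmentation applied to the training split
        before fitting (None disables augmentation).
    """

    def __init__(
        self,
        splits: DatasetSplits,
        model_config: ModelConfig | None = None,
        train_config: TrainConfig | None = None,
        augment: AugmentConfig | None = AugmentConfig(),
        init_seed: int = 0,
    ):
        self.splits = splits
        self.model_config = model_config or ModelConfig()
        self.train_config = train_config or TrainConfig()
        self.augment = augment
        self.init_seed = init_seed

    def fit(self, verbose: bool = False) -> "AFNetResults":
        train_windows = self.splits.train
        if self.augment is not None:
            train_windows = augment_training_set(train_windows, self.augment)
        network = RTAFNet(self.model_config, init_seed=self.init_seed)
        history = train(
            network, train_windows, self.splits.val, self.train_config,
            verbose=verbose,
        )
        return AFNetResults(model=self, network=network, history=history)


@dataclass
class AFNetResults:
    """Fit results: trained network, training history and diagnostics."""

    model: AFNetClassifier
    network: RTAFNet
    history: TrainHistory
    _test_report: MetricsReport | None = field(default=None, repr=False)
    _rhythm_rows: list[RhythmErrorRow] | None = field(default=None, repr=False)

    def evaluate(
        self, windows: list[Window] | None = None
    ) -> tuple[MetricsReport, list[RhythmErrorRow]]:
        """Evaluate on the given windows (default: the held-out test split)."""
        if windows is None:
            windows = self.model.splits.test
        report, rows, _ = evaluate_model(self.network, windows)
        if windows is self.model.splits.test:
            self._test_report, self._rhythm_rows = report, rows
        return report, rows

    def transfer(self, target_windows: list[Window],
                 source_tag: str = "source",
                 target_tag: str = "target") -> MetricsReport:
        """Zero-shot cross-dataset evaluation (no fine-tuning)."""
        return cross_db_evaluate(
            self.network, target_windows, source_tag, target_tag
        )

    def predict_proba(self, windows: list[Window]) -> np.ndarray:
        self.network.eval()
        X = np.stack([w.samples for w in windows])
        return self.network.predict_proba(X)

    def summary(self) -> str:
        cfg = self.model.model_config
        h = self.history
        lines = [
            "AF detection model fit",
            "=" * 54,
            f"architecture variant    {cfg.variant}",
            f"parameters              {self.network.count_parameters():,}",
            f"feature sequence        L'={cfg.seq_len}, D={cfg.d_model}",
            f"fused dimension         {cfg.fused_dim}",
            f"epochs run              {h.n_epochs} "
            f"(best: {h.best_epoch}, early stop: {h.stopped_early})",
            f"final train loss        {h.train_loss[-1]:.4f}"
            if h.train_loss else "final train loss        n/a",
            f"best val weighted F1    {max(h.val_f1):.4f}"
            if h.val_f1 else "best val weighted F1    n/a",
        ]
        if self._test_report is None and self.model.splits.test:
            self.evaluate()
        if self._test_report is not None:
            lines.append("-" * 54)
            lines.append(self._test_report.summary())
        return "\n".join(lines)
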