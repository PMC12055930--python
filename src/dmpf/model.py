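"""Model/Results facade over the double-mix training loop.

:class:`DoubleMixModel` is constructed from data (an in-memory cohort, a
manifest directory on disk, or a synthetic phantom recipe) plus a
configuration; :meth:`DoubleMixModel.fit` runs the semi-supervised
training and returns a :class:`DoubleMixResults` carrying the trained
state, the loss and weight trajectories as DataFrames, the validation
history, and ``predict`` / ``evaluate`` / ``summary`` methods.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .config import DMPFConfig
from .metrics import evaluate_segmentation
from .synthetic import PhantomSpec, generate_cohort
from .trainer import (Dataset, TrainState, fit, infer,
                      load_dataset_from_manifest, save_checkpoint)

__all__ = ["DoubleMixModel", "DoubleMixResults"]


class DoubleMixModel:
    """Semi-supervised segmentation model with double-mix augmentation."""

    def __init__(self, dataset: Dataset, config: Optional[DMPFConfig] = None):
        self.dataset = dataset
        self.config = config or DMPFConfig()
        if self.config.model.num_classes != dataset.num_classes:
            self.config.model.num_classes = dataset.num_classes

    @classmethod
    def from_manifest(cls, directory, config: Optional[DMPFConfig] = None) -> "DoubleMixModel":
        return cls(load_dataset_from_manifest(directory), config)

    @classmethod
    def from_synthetic(cls, spec: PhantomSpec, n_volumes: int,
                       labeled_fraction: float, n_val: int = 2,
                       config: Optional[DMPFConfig] = None) -> "DoubleMixModel":
        """Generate a phantom cohort in memory and wrap it."""
        if not 0.0 < labeled_fraction <= 1.0:
            raise ValueError("labeled_fraction must be in (0, 1]")
        cohort = generate_cohort(spec, n_volumes + n_val)
        n_labeled = max(1, int(np.floor(n_volumes * labeled_fraction)))
        dataset = Dataset(
            labeled=cohort[:n_labeled],
            unlabeled=[v for v, _ in cohort[n_labeled:n_volumes]],
            val=cohort[n_volumes:],
            num_classes=spec.num_classes,
        )
        return cls(dataset, config)

    def fit(self, max_iterations: Optional[int] = None,
            validate_every: Optional[int] = None) -> "DoubleMixResults":
        state, logs = fit(self.config, self.dataset,
                          max_iterations=max_iterations,
                          validate_every=validate_every)
        return DoubleMixResults(self, state, logs)


class DoubleMixResults:
    """Outcome of a training run."""

    def __init__(self, model: DoubleMixModel, state: TrainState, logs: dict):
        self.model = model
        self.state = state
        self.loss_log = pd.DataFrame(logs["loss"])
        self.weight_log = pd.DataFrame(logs["weights"])
        self.val_log = pd.DataFrame(logs["val"])

    @property
    def final_weights(self) -> pd.DataFrame:
        """Final per-category weight vectors of both streams."""
        k = self.state.config.model.num_classes
        return pd.DataFrame({
            "category": np.arange(k),
            "w_dis": self.state.disw.weights,
            "w_cdif": self.state.cdifw.weights,
        })

    def predict(self, volume: np.ndarray, patch_size=None, stride=None) -> np.ndarray:
        """Segment a volume by sliding-window averaged-logit inference."""
        return infer(self.state, volume, patch_size, stride)

    def evaluate(self, volume: np.ndarray, truth: np.ndarray):
        """(per-category Dice, mean Dice, mean ASD) against ground truth."""
        pred = self.predict(volume)
        return evaluate_segmentation(pred, truth,
                                     self.state.config.model.num_classes)

    def save(self, path) -> None:
        save_checkpoint(self.state, path)

    def save_logs(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.loss_log.to_csv(directory / "loss_log.csv", index=False)
        self.weight_log.to_csv(directory / "weight_log.csv", index=False)
        self.val_log.to_csv(directory / "val_log.csv", index=False)

    def summary(self) -> str:
        cfg = self.state.config
        lines = [
            "Double-Mix Pseudo-label Framework — training summary",
            "=" * 56,
            f"iterations run        : {self.state.iteration}",
            f"epochs run            : {self.state.epoch}",
            f"categories (incl. bg) : {cfg.model.num_classes}",
            f"weight streams        : A={cfg.train.weight_a}  B={cfg.train.weight_b}",
            f"augmentation          : {cfg.dmp.baseline}",
            f"best val mean Dice    : {self.state.best_val_dice:.4f}"
            if np.isfinite(self.state.best_val_dice) else
            "best val mean Dice    : n/a (no validation set)",
        ]
        if len(self.loss_log):
            last = self.loss_log.iloc[-1]
            lines += [
                f"final total loss      : {last['total']:.4f} "
                f"(sup {last['supervised']:.4f}, mix {last['mixed']:.4f}, "
                f"cps {last['unsupervised']:.4f})",
            ]
        lines.append("final category weights (w_dis / w_cdif):")
        for _, row in self.final_weights.iterrows():
            lines.append(f"  category {int(row['category'])}: "
                         f"{row['w_dis']:.4f} / {row['w_cdif']:.4f}")
        return "\n".join(lines)
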