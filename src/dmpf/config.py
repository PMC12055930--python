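"""Configuration for double-mix pseudo-label training.

Hyperparameter defaults follow the published training recipe for the
weighting scheme (alpha, beta, gamma, theta, tau, SGD settings, early
stopping), while the architecture and patch geometry default to a
desk-scale setting so the full pipeline runs on one CPU.  The
full-resolution geometry (patch 128x128x64, stride 32x32x16, five-level
V-Net with up to 512 channels) is available through
:meth:`DMPFConfig.full_scale`.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import yaml

WEIGHT_KINDS = ("disw", "cdifw", "cdisw", "uniform")
AUGMENT_KINDS = ("dmp", "cutmix", "cutout", "classmix", "none")
EMA_CONVENTIONS = ("paper", "conventional")


@dataclass
class WeightConfig:
    """Parameters of the category-weight estimators."""

    beta: float = 0.99          # EMA smoothing for DisW (Eq-style W_t update) and confidence
    alpha: float = 0.5          # outlier-damping exponent of the difficulty statistic
    gamma: float = 0.2          # information-score exponent in CDifW
    tau: int = 50               # Dice-history window length
    epsilon: float = 1e-8       # smoothing constant in the difficulty ratio
    dice_floor: float = 1e-4    # clamp for Dice values entering log-ratios
    # Cap on any weight vector consumed by the losses/sampler.  The raw
    # difficulty statistic is unbounded (a window of pure deterioration
    # drives it to ~eps**-alpha); capping keeps the loss scales of the two
    # weight streams comparable and SGD stable.
    max_weight: float = 10.0
    # Literal reading: voxel counts for DisW come from pseudo-labels on the
    # whole batch, labeled volumes included.  Set True to substitute ground
    # truth on the labeled portion.
    ground_truth_counts_for_labeled: bool = False


@dataclass
class DMPConfig:
    """Double-mix pseudo-label (DMP) augmentation options."""

    n_draws: Optional[int] = None       # None -> one draw per category (K)
    exclude_background: bool = True
    max_resample: int = 5
    # Iterations before the mixed term activates.  Early teacher
    # pseudo-labels are noise; pasting them under rare-category weights
    # can derail short training runs.
    warmup_iters: int = 0
    # Which augmentation the trainer applies: "dmp" (weighted pseudo-label
    # mixing) or one of the unweighted baselines used in ablations.
    baseline: str = "dmp"


@dataclass
class ModelConfig:
    """Encoder-decoder segmentation network geometry."""

    in_channels: int = 1
    num_classes: int = 5
    channels: Tuple[int, ...] = (8, 16, 32, 64)
    kernel_size: int = 3


@dataclass
class TrainConfig:
    lr: float = 0.03
    momentum: float = 0.9
    poly_power: float = 0.9
    theta: float = 0.1              # unsupervised-loss coefficient
    ramp_epochs: int = 40           # Gaussian ramp-up length for theta
    mu: float = 0.99                # EMA-teacher momentum
    ema_convention: str = "paper"   # "paper": teacher <- mu*student + (1-mu)*teacher
    batch_labeled: int = 2
    batch_unlabeled: int = 2
    patch_size: Tuple[int, int, int] = (32, 32, 32)
    stride: Tuple[int, int, int] = (16, 16, 16)
    max_epochs: int = 200
    iters_per_epoch: int = 50
    patience: int = 30              # early-stopping threshold in epochs
    foreground_crop_prob: float = 0.7
    grad_clip: float = 5.0          # global L2 gradient-norm clip per model (0 disables)
    # Normalise the mixed loss by 1/K so all three loss terms share one
    # scale; without it the mixed term dominates roughly K-fold.
    normalize_mixed_loss: bool = True
    weight_a: str = "cdifw"         # weight stream applied to model A
    weight_b: str = "disw"          # weight stream applied to model B
    seed: int = 0


@dataclass
class DMPFConfig:
    weights: WeightConfig = field(default_factory=WeightConfig)
    dmp: DMPConfig = field(default_factory=DMPConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    train: TrainConfig = field(default_factory=TrainConfig)

    def __post_init__(self) -> None:
        if self.train.weight_a not in WEIGHT_KINDS or self.train.weight_b not in WEIGHT_KINDS:
            raise ValueError(f"weight kinds must be one of {WEIGHT_KINDS}")
        if self.dmp.baseline not in AUGMENT_KINDS:
            raise ValueError(f"dmp.baseline must be one of {AUGMENT_KINDS}")
        if self.train.ema_convention not in EMA_CONVENTIONS:
            raise ValueError(f"ema_convention must be one of {EMA_CONVENTIONS}")

    @classmethod
    def full_scale(cls) -> "DMPFConfig":
        """Full-resolution recipe: 5-level network, 128x128x64 patches."""
        cfg = cls()
        cfg.model.channels = (32, 64, 128, 256, 512)
        cfg.train.patch_size = (128, 128, 64)
        cfg.train.stride = (32, 32, 16)
        return cfg

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "DMPFConfig":
        def build(tp, sub):
            fields = {f.name: f for f in dataclasses.fields(tp)}
            kwargs = {}
            for key, val in (sub or {}).items():
                if key not in fields:
                    raise ValueError(f"unknown config key: {key}")
                if isinstance(val, list):
                    val = tuple(val)
                kwargs[key] = val
            return tp(**kwargs)

        return cls(
            weights=build(WeightConfig, d.get("weights")),
            dmp=build(DMPConfig, d.get("dmp")),
            model=build(ModelConfig, d.get("model")),
            train=build(TrainConfig, d.get("train")),
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def load(cls, path) -> "DMPFConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})
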