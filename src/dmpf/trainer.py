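"""Dual-model cross-pseudo-supervision training with double-mix augmentation.

One training iteration runs, in order: forward both students on the
concatenated labeled+unlabeled batch; update the distribution weights from
the batch pseudo-labels; update the Dice-difficulty tracker and the
confidence state on the labeled portion; recompute the confidence-
difficulty weights; draw pseudo-labels from the two EMA teachers; build the
two weighted mixed pairs; forward each student on its mixed pair; combine
supervised, mixed and ramped cross-pseudo-supervision losses; take an SGD
step with polynomial learning-rate decay; and update both EMA teachers.

Inference tiles a volume with overlapping patches, averages the two
students' logits with overlap-count normalisation, and takes the per-voxel
argmax (ties resolve to the lowest category index).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import losses as L
from . import mixer
from . import weights as W
from .config import DMPFConfig
from .io import grid_patches, pad_to_min_shape, random_patch, read_volume
from .metrics import evaluate_segmentation, dice_per_category
from .nn import SGD, VNetLite

__all__ = [
    "Dataset", "TrainState", "ema_update", "pseudo_label",
    "train_iteration", "validate", "infer", "fit",
    "load_dataset_from_manifest", "save_checkpoint", "load_checkpoint",
]


class DivergenceError(RuntimeError):
    """Raised when the training loss turns non-finite."""

    def __init__(self, message, state=None):
        super().__init__(message)
        self.state = state


@dataclass
class Dataset:
    """In-memory training cohort."""

    labeled: List[Tuple[np.ndarray, np.ndarray]]
    unlabeled: List[np.ndarray]
    val: List[Tuple[np.ndarray, np.ndarray]]
    num_classes: int
    test: List[Tuple[np.ndarray, np.ndarray]] = field(default_factory=list)


def load_dataset_from_manifest(directory) -> Dataset:
    """Read a cohort written by :func:`dmpf.synthetic.generate_dataset`."""
    directory = Path(directory)
    with open(directory / "manifest.json") as fh:
        manifest = json.load(fh)
    pools = {"labeled": [], "unlabeled": [], "val": [], "test": []}
    for entry in manifest["entries"]:
        vol = read_volume(directory / entry["volume"]).array
        if entry["label"] is not None:
            lab = read_volume(directory / entry["label"], as_label=True).array
            pools[entry["split"]].append((vol, lab))
        else:
            pools[entry["split"]].append(vol)
    return Dataset(labeled=pools["labeled"], unlabeled=pools["unlabeled"],
                   val=pools["val"], test=pools["test"],
                   num_classes=int(manifest["num_classes"]))


# ---------------------------------------------------------------------------
# Train state
# ---------------------------------------------------------------------------

@dataclass
class TrainState:
    net_a: VNetLite
    net_b: VNetLite
    ema_a: VNetLite
    ema_b: VNetLite
    opt_a: SGD
    opt_b: SGD
    disw: W.DisWState
    cdifw: W.CDifWState
    config: DMPFConfig
    iteration: int = 0
    epoch: int = 0
    best_val_dice: float = -np.inf
    patience_counter: int = 0
    best_params_a: Optional[list] = None
    best_params_b: Optional[list] = None

    @classmethod
    def initial(cls, config: DMPFConfig) -> "TrainState":
        mc, tc, wc = config.model, config.train, config.weights
        # the experiment seed fixes both initialisations; A and B differ
        # within a run through distinct derived seeds
        net_a = VNetLite(mc.in_channels, mc.num_classes, mc.channels,
                         ksize=mc.kernel_size, seed=tc.seed * 2 + 1)
        net_b = VNetLite(mc.in_channels, mc.num_classes, mc.channels,
                         ksize=mc.kernel_size, seed=tc.seed * 2 + 2)
        ema_a, ema_b = net_a.clone(), net_b.clone()
        t_max = tc.max_epochs * tc.iters_per_epoch
        return cls(
            net_a=net_a, net_b=net_b, ema_a=ema_a, ema_b=ema_b,
            opt_a=SGD(net_a, lr=tc.lr, momentum=tc.momentum, power=tc.poly_power, t_max=t_max),
            opt_b=SGD(net_b, lr=tc.lr, momentum=tc.momentum, power=tc.poly_power, t_max=t_max),
            disw=W.DisWState.initial(mc.num_classes, beta=wc.beta),
            cdifw=W.CDifWState.initial(mc.num_classes, tau=wc.tau, alpha=wc.alpha,
                                       beta=wc.beta, gamma=wc.gamma,
                                       epsilon=wc.epsilon, dice_floor=wc.dice_floor),
            config=config,
        )


def ema_update(student: VNetLite, teacher: VNetLite, mu: float,
               convention: str = "paper") -> VNetLite:
    """Exponential-moving-average teacher update.

    ``convention="paper"`` applies the update as printed —
    ``teacher <- mu * student + (1 - mu) * teacher`` — which for large mu
    keeps the teacher close to the current student.  The ``"conventional"``
    mean-teacher form swaps the roles: ``teacher <- mu * teacher +
    (1 - mu) * student``.
    """
    sp, tp = student.parameters(), teacher.parameters()
    if len(sp) != len(tp) or any(a.shape != b.shape for a, b in zip(sp, tp)):
        raise ValueError("student/teacher architecture mismatch")
    if convention == "paper":
        new = [mu * a + (1.0 - mu) * b for a, b in zip(sp, tp)]
    elif convention == "conventional":
        new = [mu * b + (1.0 - mu) * a for a, b in zip(sp, tp)]
    else:
        raise ValueError(f"unknown EMA convention {convention!r}")
    teacher.set_parameters(new)
    return teacher


def pseudo_label(model: VNetLite, x: np.ndarray) -> np.ndarray:
    """Per-voxel argmax prediction; ties break to the lowest index."""
    logits = model.forward(x)
    return np.argmax(logits, axis=1)


# ---------------------------------------------------------------------------
# Weight selection
# ---------------------------------------------------------------------------

def _cdifw_ready(state: TrainState) -> bool:
    return len(state.cdifw.difficulty_tracker.history) >= 2


def select_weights(state: TrainState, kind: str) -> np.ndarray:
    """Resolve a weight-stream name to the current weight vector."""
    k = state.config.model.num_classes
    if kind == "uniform":
        return np.ones(k)
    if kind == "disw":
        return state.disw.weights.copy()
    if kind == "cdifw":
        return state.cdifw.weights.copy()
    if kind == "cdisw":
        return W.compute_cdisw(state.disw.weights, state.cdifw.confidence_state)
    raise ValueError(f"unknown weight kind {kind!r}")


# ---------------------------------------------------------------------------
# Batch sampling
# ---------------------------------------------------------------------------

def _category_centered_patch(lab: np.ndarray, patch, rng: np.random.Generator):
    """A patch centred on a random voxel of a uniformly chosen present
    foreground category (clipped to bounds)."""
    present = [c for c in np.unique(lab) if c > 0]
    if not present:
        return random_patch(lab.shape, patch, rng)
    cat = present[rng.integers(len(present))]
    voxels = np.argwhere(lab == cat)
    centre = voxels[rng.integers(voxels.shape[0])]
    box = []
    for c, p, n in zip(centre, patch, lab.shape):
        start = int(np.clip(c - p // 2, 0, n - p))
        box.append(slice(start, start + p))
    return tuple(box)


def sample_batches(dataset: Dataset, config: DMPFConfig, rng: np.random.Generator):
    """Random patch batches with foreground-biased cropping.

    With probability ``foreground_crop_prob`` a labeled crop is centred on
    a uniformly chosen present foreground category (forced-foreground
    sampling), which keeps rare categories visible at small patch sizes;
    otherwise the crop is uniform.  Unlabeled crops are always uniform.
    """
    tc = config.train
    patch = tc.patch_size
    xs, ys = [], []
    for _ in range(tc.batch_labeled):
        vol, lab = dataset.labeled[rng.integers(len(dataset.labeled))]
        vol = pad_to_min_shape(vol, patch)
        lab = pad_to_min_shape(lab, patch)
        if rng.random() < tc.foreground_crop_prob:
            box = _category_centered_patch(lab, patch, rng)
        else:
            box = random_patch(vol.shape, patch, rng)
        xs.append(vol[box])
        ys.append(lab[box])
    xu = []
    for _ in range(tc.batch_unlabeled):
        vol = dataset.unlabeled[rng.integers(len(dataset.unlabeled))] \
            if dataset.unlabeled else dataset.labeled[rng.integers(len(dataset.labeled))][0]
        vol = pad_to_min_shape(vol, patch)
        xu.append(vol[random_patch(vol.shape, patch, rng)])
    x_l = np.stack(xs)[:, None]       # (N_L, 1, *patch)
    y_l = np.stack(ys)
    x_u = np.stack(xu)[:, None]
    return (x_l, y_l), x_u


# ---------------------------------------------------------------------------
# One training iteration
# ---------------------------------------------------------------------------

def _update_weight_states(state: TrainState, p_a, p_b, y_l, n_labeled):
    """Steps 2-3: DisW from batch pseudo-labels, Dice tracker and
    confidence from the labeled portion of model A."""
    cfg = state.config
    k = cfg.model.num_classes

    avg_logits = 0.5 * (p_a + p_b)
    pseudo_all = np.argmax(avg_logits, axis=1)
    if cfg.weights.ground_truth_counts_for_labeled:
        pseudo_all = pseudo_all.copy()
        pseudo_all[:n_labeled] = y_l
    state.disw = W.update_disw(state.disw, pseudo_all, num_classes=k)

    pred_a_lab = np.argmax(p_a[:n_labeled], axis=1)
    dice = dice_per_category(pred_a_lab, y_l, k)
    dice = np.nan_to_num(dice, nan=1.0)  # absent-from-both counts as solved
    W.update_difficulty(state.cdifw.difficulty_tracker, dice)

    prob_a_lab = L.softmax(p_a[:n_labeled], axis=1)
    state.cdifw.confidence_state = W.update_confidence(
        state.cdifw.confidence_state, prob_a_lab, y_l)

    if _cdifw_ready(state):
        w_cdif = np.minimum(W.compute_cdifw(state.cdifw), cfg.weights.max_weight)
        # rescale to max 1 so both weight streams share the [0, 1] scale of
        # DisW: heterogeneity comes from the ordering, not the magnitude
        top = w_cdif.max()
        state.cdifw.weights = w_cdif / top if top > 0 else w_cdif


def _build_mixed_pairs(state: TrainState, x_l, y_l, x_u, w_a, w_b,
                       rng: np.random.Generator):
    """Step 4: two mixed batches, one per student, or a baseline."""
    cfg = state.config
    kind = cfg.dmp.baseline
    if kind == "none" or state.iteration < cfg.dmp.warmup_iters:
        return None, None, None, None
    n_u = x_u.shape[0]
    # teacher pseudo-labels on the unlabeled patches
    pl_a = np.argmax(state.ema_a.forward(x_u), axis=1)
    pl_b = np.argmax(state.ema_b.forward(x_u), axis=1)
    xa, ya, xb, yb = [], [], [], []
    for i in range(n_u):
        j = int(rng.integers(x_l.shape[0]))     # same-batch labeled partner
        if kind == "dmp":
            pair_a, pair_b = mixer.double_mix(
                x_u[i, 0], x_l[j, 0], y_l[j], pl_a[i], pl_b[i], w_a, w_b, rng,
                n_draws=cfg.dmp.n_draws,
                exclude_background=cfg.dmp.exclude_background,
                max_resample=cfg.dmp.max_resample)
        else:
            pair_a = mixer.baseline_augment(kind, x_u[i, 0], x_l[j, 0], pl_a[i], y_l[j], rng)
            pair_b = mixer.baseline_augment(kind, x_u[i, 0], x_l[j, 0], pl_b[i], y_l[j], rng)
        xa.append(pair_a.image)
        ya.append(pair_a.label)
        xb.append(pair_b.image)
        yb.append(pair_b.label)
    return (np.stack(xa)[:, None], np.stack(ya).astype(np.int64),
            np.stack(xb)[:, None], np.stack(yb).astype(np.int64))


def _clip_gradients(net, max_norm: float) -> None:
    """Scale all gradients so their global L2 norm is at most ``max_norm``."""
    if not max_norm:
        return
    total = np.sqrt(sum(float(np.sum(g.astype(np.float64) ** 2))
                        for g in net.gradients()))
    if total > max_norm:
        scale = max_norm / total
        for g in net.gradients():
            g *= scale


def train_iteration(state: TrainState, labeled_batch, unlabeled_batch,
                    rng: np.random.Generator) -> L.LossBreakdown:
    """Run one full framework iteration and update the state in place."""
    cfg = state.config
    tc = cfg.train
    x_l, y_l = labeled_batch
    x_u = unlabeled_batch
    n_l = x_l.shape[0]
    x_all = np.concatenate([x_l, x_u], axis=0)

    # (1) student forward on the joint batch (losses evaluated in float64)
    p_a = state.net_a.forward(x_all).astype(np.float64)
    p_b = state.net_b.forward(x_all).astype(np.float64)

    # (2)-(3) weight updates before the losses consume them
    _update_weight_states(state, p_a, p_b, y_l, n_l)
    w_a = select_weights(state, tc.weight_a)
    w_b = select_weights(state, tc.weight_b)
    if not _cdifw_ready(state) and tc.weight_a == "cdifw":
        w_a = np.ones_like(w_a)
    if not _cdifw_ready(state) and tc.weight_b == "cdifw":
        w_b = np.ones_like(w_b)

    # (4) supervised + cross-pseudo-supervision on the joint forward
    y_hat_a = np.argmax(p_a, axis=1)   # constants: no grad through these
    y_hat_b = np.argmax(p_b, axis=1)
    sup, g_sup_a, g_sup_b = L.supervised_loss(
        p_a[:n_l], p_b[:n_l], y_l, w_a, w_b, return_grads=True)
    cps, g_cps_a, g_cps_b = L.cps_loss(
        p_a, p_b, y_hat_a, y_hat_b, w_a, w_b, return_grads=True)
    ramp = cfg.train.theta * L.gaussian_rampup(state.epoch, tc.ramp_epochs)

    g1_a = ramp * g_cps_a
    g1_a[:n_l] += g_sup_a
    g1_b = ramp * g_cps_b
    g1_b[:n_l] += g_sup_b

    state.net_a.zero_grad()
    state.net_b.zero_grad()
    state.net_a.backward(g1_a)
    state.net_b.backward(g1_b)

    # (5)-(6) mixed pairs and their loss
    mixed_val = 0.0
    built = _build_mixed_pairs(state, x_l, y_l, x_u, w_a, w_b, rng)
    if built[0] is not None:
        xm_a, ym_a, xm_b, ym_b = built
        pm_a = state.net_a.forward(xm_a).astype(np.float64)
        pm_b = state.net_b.forward(xm_b).astype(np.float64)
        mixed_val, g_m_a, g_m_b = L.mixed_loss(
            pm_a, pm_b, ym_a, ym_b, w_a, w_b, return_grads=True,
            normalize=tc.normalize_mixed_loss)
        state.net_a.backward(g_m_a)
        state.net_b.backward(g_m_b)

    breakdown = L.total_loss(sup, mixed_val, cps, state.epoch,
                             tc.ramp_epochs, tc.theta)
    if not np.isfinite(breakdown.total):
        raise DivergenceError(
            f"non-finite loss at iteration {state.iteration}", state=state)

    # (7) SGD with poly decay, (8) EMA teachers
    _clip_gradients(state.net_a, tc.grad_clip)
    _clip_gradients(state.net_b, tc.grad_clip)
    state.opt_a.step()
    state.opt_b.step()
    ema_update(state.net_a, state.ema_a, tc.mu, tc.ema_convention)
    ema_update(state.net_b, state.ema_b, tc.mu, tc.ema_convention)
    state.iteration += 1
    return breakdown


# ---------------------------------------------------------------------------
# Inference and validation
# ---------------------------------------------------------------------------

def infer(state: TrainState, x: np.ndarray,
          patch_size: Optional[Sequence[int]] = None,
          stride: Optional[Sequence[int]] = None) -> np.ndarray:
    """Sliding-window inference with averaged student logits.

    The volume is reflect-padded up to the patch size if needed; logits of
    both students are averaged, accumulated over overlapping windows with
    count normalisation, and argmaxed per voxel.
    """
    tc = state.config.train
    patch = tuple(patch_size or tc.patch_size)
    step = tuple(stride or tc.stride)
    orig_shape = x.shape
    xp = pad_to_min_shape(x, patch)
    k = state.config.model.num_classes
    acc = np.zeros((k,) + xp.shape)
    count = np.zeros(xp.shape)
    for box in grid_patches(xp.shape, patch, step):
        tile = xp[box][None, None]
        logits = 0.5 * (state.net_a.forward(tile) + state.net_b.forward(tile))
        acc[(slice(None),) + box] += logits[0]
        count[box] += 1.0
    pred = np.argmax(acc / count[None], axis=0)
    # crop symmetric padding back off
    offs = [(p - o) // 2 for p, o in zip(xp.shape, orig_shape)]
    sl = tuple(slice(o, o + n) for o, n in zip(offs, orig_shape))
    return pred[sl].astype(np.int16)


def validate(state: TrainState, val_set: List[Tuple[np.ndarray, np.ndarray]],
             patch_size: Optional[Sequence[int]] = None,
             stride: Optional[Sequence[int]] = None):
    """Per-category Dice (averaged over volumes), mean Dice, mean ASD."""
    if not val_set:
        raise ValueError("empty validation set")
    k = state.config.model.num_classes
    dices, means, asds = [], [], []
    for vol, lab in val_set:
        pred = infer(state, vol, patch_size, stride)
        dice, mean_dice, mean_asd = evaluate_segmentation(pred, lab, k)
        dices.append(dice)
        means.append(mean_dice)
        asds.append(mean_asd)
    per_cat = np.nanmean(np.stack(dices), axis=0)
    return per_cat, float(np.nanmean(means)), float(np.nanmean(asds))


# ---------------------------------------------------------------------------
# Full training loop
# ---------------------------------------------------------------------------

def fit(config: DMPFConfig, dataset: Dataset,
        max_iterations: Optional[int] = None,
        validate_every: Optional[int] = None,
        log_weights: bool = True):
    """Train until early stopping or the epoch budget is exhausted.

    Returns ``(state, logs)`` where ``logs`` is a dict of row-lists for the
    loss trajectory, the weight trajectories, and the validation history.
    Early stopping monitors validation mean Dice with the configured
    patience (in epochs); the best parameters are retained on the state.
    """
    tc = config.train
    state = TrainState.initial(config)
    rng_data = np.random.default_rng((tc.seed * 7919 + 1) % (2 ** 31 - 1))
    rng_mix = np.random.default_rng((tc.seed * 7919 + 2) % (2 ** 31 - 1))

    loss_rows, weight_rows, val_rows = [], [], []
    total_budget = max_iterations if max_iterations is not None \
        else tc.max_epochs * tc.iters_per_epoch
    stop = False
    while not stop:
        for _ in range(tc.iters_per_epoch):
            if state.iteration >= total_budget:
                stop = True
                break
            labeled_batch, x_u = sample_batches(dataset, config, rng_data)
            bd = train_iteration(state, labeled_batch, x_u, rng_mix)
            loss_rows.append({
                "iteration": state.iteration, "epoch": state.epoch,
                "supervised": bd.supervised, "mixed": bd.mixed,
                "unsupervised": bd.unsupervised, "ramp_factor": bd.ramp_factor,
                "total": bd.total, "lr": state.opt_a.current_lr(),
            })
            if log_weights:
                s = W.information_score(state.cdifw.confidence_state)
                try:
                    w_dif = W.compute_difficulty_weight(state.cdifw.difficulty_tracker)
                except W.InsufficientHistoryError:
                    w_dif = np.full(config.model.num_classes, np.nan)
                for k in range(config.model.num_classes):
                    weight_rows.append({
                        "iteration": state.iteration, "category": k,
                        "w_dis": state.disw.weights[k], "w_dif": w_dif[k],
                        "s": s[k], "w_cdif": state.cdifw.weights[k],
                    })
        if stop and not loss_rows:
            break
        # validation and early stopping at epoch boundaries
        if dataset.val and (validate_every is None or state.epoch % validate_every == 0):
            per_cat, mean_dice, mean_asd = validate(state, dataset.val)
            val_rows.append({"epoch": state.epoch, "mean_dice": mean_dice,
                             "mean_asd": mean_asd,
                             **{f"dice_{k}": per_cat[k] for k in range(per_cat.size)}})
            if mean_dice > state.best_val_dice:
                state.best_val_dice = mean_dice
                state.patience_counter = 0
                state.best_params_a = [p.copy() for p in state.net_a.parameters()]
                state.best_params_b = [p.copy() for p in state.net_b.parameters()]
            else:
                state.patience_counter += 1
                if state.patience_counter >= tc.patience:
                    stop = True
        state.epoch += 1
        if state.epoch >= tc.max_epochs:
            stop = True
    return state, {"loss": loss_rows, "weights": weight_rows, "val": val_rows}


# ---------------------------------------------------------------------------
# Checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(state: TrainState, path) -> None:
    arrays = {}
    for name, net in (("a", state.net_a), ("b", state.net_b),
                      ("ema_a", state.ema_a), ("ema_b", state.ema_b)):
        for i, p in enumerate(net.parameters()):
            arrays[f"{name}_{i}"] = p
    arrays["disw"] = state.disw.weights
    arrays["cdifw"] = state.cdifw.weights
    arrays["iteration"] = np.asarray(state.iteration)
    arrays["config_json"] = np.frombuffer(
        json.dumps(state.config.to_dict()).encode(), dtype=np.uint8)
    np.savez_compressed(path, **arrays)


def load_checkpoint(path) -> TrainState:
    data = np.load(path)
    cfg = DMPFConfig.from_dict(json.loads(bytes(data["config_json"]).decode()))
    state = TrainState.initial(cfg)
    for name, net in (("a", state.net_a), ("b", state.net_b),
                      ("ema_a", state.ema_a), ("ema_b", state.ema_b)):
        n = len(net.parameters())
        net.set_parameters([data[f"{name}_{i}"] for i in range(n)])
    state.disw.weights = data["disw"]
    state.cdifw.weights = data["cdifw"]
    state.iteration = int(data["iteration"])
    return state
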