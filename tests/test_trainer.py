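"""Training loop: EMA teachers, determinism, CPS reduction, inference."""

import numpy as np
import pytest

import dmpf.losses as L
from dmpf.config import DMPFConfig
from dmpf.nn import VNetLite
from dmpf.trainer import (TrainState, ema_update, fit, infer, pseudo_label,
                          sample_batches, train_iteration, validate,
                          save_checkpoint, load_checkpoint)


def _params_equal(a, b):
    return all(np.array_equal(x, y) for x, y in zip(a.parameters(), b.parameters()))


# ---------------------------------------------------------------------------
# EMA teachers
# ---------------------------------------------------------------------------

def test_ema_mu_extremes():
    s = VNetLite(1, 2, (3,), seed=0)
    t = VNetLite(1, 2, (3,), seed=1)
    t_orig = [p.copy() for p in t.parameters()]
    ema_update(s, t, mu=0.0, convention="paper")      # paper: mu on student
    assert all(np.array_equal(p, q) for p, q in zip(t.parameters(), t_orig))
    ema_update(s, t, mu=1.0, convention="paper")
    assert _params_equal(s, t)


def test_ema_conventional_converges_geometrically():
    s = VNetLite(1, 2, (3,), seed=0)
    t = VNetLite(1, 2, (3,), seed=1)
    mu = 0.9
    gap0 = [q - p for p, q in zip(s.parameters(), t.parameters())]
    for step in range(1, 4):
        ema_update(s, t, mu=mu, convention="conventional")
        for p, q, g0 in zip(s.parameters(), t.parameters(), gap0):
            np.testing.assert_allclose(q - p, mu ** step * g0, atol=1e-5)


def test_ema_architecture_mismatch():
    with pytest.raises(ValueError):
        ema_update(VNetLite(1, 2, (3,), seed=0), VNetLite(1, 2, (4,), seed=0), 0.5)


def test_teacher_lag_shrinks_under_constant_student():
    s = VNetLite(1, 2, (3,), seed=0)
    t = VNetLite(1, 2, (3,), seed=1)
    def gap():
        return sum(float(np.abs(q - p).sum())
                   for p, q in zip(s.parameters(), t.parameters()))
    gaps = [gap()]
    for _ in range(3):
        ema_update(s, t, mu=0.9, convention="paper")
        gaps.append(gap())
    # gap contracts by (1-mu) per step until float32 rounding dominates
    assert all(b < a * 0.5 for a, b in zip(gaps, gaps[1:]))


# ---------------------------------------------------------------------------
# pseudo-labels
# ---------------------------------------------------------------------------

def test_pseudo_label_recovery_and_tiebreak(rng, tiny_config):
    state = TrainState.initial(tiny_config)
    x = rng.normal(size=(1, 1, 8, 8, 8))
    labels = pseudo_label(state.net_a, x)
    logits = state.net_a.forward(x)
    # loop-based argmax oracle with lowest-index tie-break
    want = np.zeros(labels.shape, dtype=int)
    for b in range(logits.shape[0]):
        flat = logits[b].reshape(logits.shape[1], -1)
        for j in range(flat.shape[1]):
            col = flat[:, j]
            want[b].ravel()[j] = int(np.flatnonzero(col == col.max())[0])
    np.testing.assert_array_equal(labels, want)
    # explicit tie: all-equal logits -> category 0
    tied = np.argmax(np.zeros((1, 3, 2, 2, 2)), axis=1)
    assert (tied == 0).all()


# ---------------------------------------------------------------------------
# iteration determinism and the CPS reduction
# ---------------------------------------------------------------------------

def _one_batch(dataset, cfg, seed):
    return sample_batches(dataset, cfg, np.random.default_rng(seed))


def test_iteration_bit_reproducible(tiny_config, tiny_dataset):
    outs = []
    for _ in range(2):
        state = TrainState.initial(tiny_config)
        lb, xu = _one_batch(tiny_dataset, tiny_config, 5)
        bd = train_iteration(state, lb, xu, np.random.default_rng(9))
        outs.append((bd, [p.copy() for p in state.net_a.parameters()]))
    assert outs[0][0] == outs[1][0]
    assert all(np.array_equal(p, q) for p, q in zip(outs[0][1], outs[1][1]))


def reference_cps_losses(state_snapshot, labeled_batch, x_u, epoch, theta,
                         ramp_epochs):
    """Independently coded plain-CPS loss computation (uniform weights,
    no mixing): L = sup + theta*ramp*cps with L_s = Dice + CE/2."""
    x_l, y_l = labeled_batch
    net_a, net_b = state_snapshot
    x_all = np.concatenate([x_l, x_u], axis=0)
    p_a = net_a.forward(x_all).astype(np.float64)
    p_b = net_b.forward(x_all).astype(np.float64)
    k = p_a.shape[1]
    n_l = x_l.shape[0]

    def softmax(z):
        e = np.exp(z - z.max(axis=0, keepdims=True))
        return e / e.sum(axis=0, keepdims=True)

    def ce(logits, y):
        p = softmax(logits)
        fl = p.reshape(k, -1)
        t = y.reshape(-1)
        return float(np.mean([-np.log(fl[t[j], j]) for j in range(t.size)]))

    def dice_loss(logits, y):
        p = softmax(logits).reshape(k, -1)
        t = y.reshape(-1)
        total = 0.0
        for c in range(k):
            inter = p[c][t == c].sum()
            num = 2 * inter + 1e-5
            den = p[c].sum() + (t == c).sum() + 1e-5
            total += 1 - num / den
        return total / k

    sup = sum(dice_loss(p_a[i], y_l[i]) + 0.5 * ce(p_a[i], y_l[i])
              + dice_loss(p_b[i], y_l[i]) + 0.5 * ce(p_b[i], y_l[i])
              for i in range(n_l)) / (n_l * k)
    ya = np.argmax(p_a, axis=1)
    yb = np.argmax(p_b, axis=1)
    cps = sum(ce(p_a[q], yb[q]) + ce(p_b[q], ya[q])
              for q in range(p_a.shape[0])) / (p_a.shape[0] * k)
    ramp = theta * np.exp(-5 * (1 - min(epoch / ramp_epochs, 1)) ** 2)
    return sup, cps, sup + ramp * cps


def test_reduces_to_plain_cps(tiny_config, tiny_dataset):
    """Uniform weights + no mixing + printed-EMA mu=1: per-iteration losses
    equal an independently coded CPS reference to 1e-10."""
    import dataclasses
    cfg = DMPFConfig.from_dict(tiny_config.to_dict())
    cfg.train.weight_a = "uniform"
    cfg.train.weight_b = "uniform"
    cfg.dmp.baseline = "none"
    cfg.train.mu = 1.0
    state = TrainState.initial(cfg)
    rng = np.random.default_rng(0)
    for it in range(5):
        lb, xu = _one_batch(tiny_dataset, cfg, 100 + it)
        snapshot = (state.net_a.clone(), state.net_b.clone())
        bd = train_iteration(state, lb, xu, rng)
        sup, cps, total = reference_cps_losses(
            snapshot, lb, xu, epoch=state.epoch,
            theta=cfg.train.theta, ramp_epochs=cfg.train.ramp_epochs)
        assert bd.supervised == pytest.approx(sup, abs=1e-10)
        assert bd.unsupervised == pytest.approx(cps, abs=1e-10)
        assert bd.mixed == 0.0
        assert bd.total == pytest.approx(total, abs=1e-10)
        # printed EMA with mu=1 keeps the teacher a copy of the student
        assert _params_equal(state.net_a, state.ema_a)


# ---------------------------------------------------------------------------
# validation and inference
# ---------------------------------------------------------------------------

def test_validate_perfect_prediction(tiny_config, tiny_dataset, monkeypatch):
    state = TrainState.initial(tiny_config)
    vol, lab = tiny_dataset.val[0]
    import dmpf.trainer as T
    monkeypatch.setattr(T, "infer", lambda s, x, *a, **k: lab)
    per_cat, mean_dice, mean_asd = T.validate(state, [(vol, lab)])
    present = [c for c in range(1, 3) if (lab == c).any()]
    for c in present:
        assert per_cat[c] == pytest.approx(1.0)
    assert mean_dice == pytest.approx(1.0) and mean_asd == 0.0


def test_validate_empty_set_rejected(tiny_config):
    with pytest.raises(ValueError):
        validate(TrainState.initial(tiny_config), [])


def test_infer_equals_per_patch_argmax_without_overlap(tiny_config, rng):
    """Non-overlapping tiling: output is the concatenation of per-patch
    averaged-logit argmax."""
    state = TrainState.initial(tiny_config)
    vol = rng.normal(size=(16, 8, 8))
    got = infer(state, vol, patch_size=(8, 8, 8), stride=(8, 8, 8))
    for lo in (0, 8):
        tile = vol[lo:lo + 8][None, None]
        logits = 0.5 * (state.net_a.forward(tile) + state.net_b.forward(tile))
        np.testing.assert_array_equal(got[lo:lo + 8], np.argmax(logits[0], axis=0))


def test_infer_identical_models_single_model_equivalent(tiny_config, rng):
    state = TrainState.initial(tiny_config)
    state.net_b.set_parameters(state.net_a.parameters())
    vol = rng.normal(size=(8, 8, 8))
    got = infer(state, vol, patch_size=(8, 8, 8), stride=(8, 8, 8))
    single = np.argmax(state.net_a.forward(vol[None, None])[0], axis=0)
    np.testing.assert_array_equal(got, single)


def test_infer_pads_small_volume(tiny_config, rng):
    state = TrainState.initial(tiny_config)
    vol = rng.normal(size=(5, 8, 8))
    assert infer(state, vol, patch_size=(8, 8, 8), stride=(8, 8, 8)).shape == (5, 8, 8)


# ---------------------------------------------------------------------------
# fit, seeds, config reachability, checkpoints
# ---------------------------------------------------------------------------

def test_fit_smoke_emits_logs(tiny_config, tiny_dataset):
    state, logs = fit(tiny_config, tiny_dataset, max_iterations=4)
    assert state.iteration == 4
    assert len(logs["loss"]) == 4
    assert {"supervised", "mixed", "unsupervised", "total"} <= set(logs["loss"][0])
    cats = {r["category"] for r in logs["weights"]}
    assert cats == set(range(tiny_config.model.num_classes))
    assert len(logs["val"]) >= 1


def test_seed_contract(tiny_config):
    s1 = TrainState.initial(tiny_config)
    s2 = TrainState.initial(tiny_config)
    assert _params_equal(s1.net_a, s2.net_a) and _params_equal(s1.net_b, s2.net_b)
    assert not _params_equal(s1.net_a, s1.net_b)


@pytest.mark.parametrize("wa,wb", [
    ("cdifw", "disw"), ("cdifw", "cdifw"), ("disw", "disw"),
    ("cdisw", "cdisw"), ("cdifw", "cdisw")])
def test_weight_pair_matrix_reachable(tiny_config, tiny_dataset, wa, wb):
    cfg = DMPFConfig.from_dict(tiny_config.to_dict())
    cfg.train.weight_a, cfg.train.weight_b = wa, wb
    state = TrainState.initial(cfg)
    lb, xu = _one_batch(tiny_dataset, cfg, 3)
    bd = train_iteration(state, lb, xu, np.random.default_rng(1))
    assert np.isfinite(bd.total)


@pytest.mark.parametrize("aug", ["dmp", "cutmix", "cutout", "classmix", "none"])
def test_augmentation_matrix_reachable(tiny_config, tiny_dataset, aug):
    cfg = DMPFConfig.from_dict(tiny_config.to_dict())
    cfg.dmp.baseline = aug
    state = TrainState.initial(cfg)
    lb, xu = _one_batch(tiny_dataset, cfg, 3)
    bd = train_iteration(state, lb, xu, np.random.default_rng(1))
    assert np.isfinite(bd.total)
    assert (bd.mixed == 0.0) == (aug == "none")


def test_checkpoint_roundtrip(tmp_path, tiny_config, tiny_dataset, rng):
    state, _ = fit(tiny_config, tiny_dataset, max_iterations=2)
    path = tmp_path / "ckpt.npz"
    save_checkpoint(state, path)
    back = load_checkpoint(path)
    vol = rng.normal(size=(8, 8, 8))
    np.testing.assert_array_equal(
        infer(state, vol, (8, 8, 8), (8, 8, 8)),
        infer(back, vol, (8, 8, 8), (8, 8, 8)))
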