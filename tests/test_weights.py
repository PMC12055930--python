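"""Weight-estimator formulas against hand values and brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dmpf.weights import (
    CDifWState, ConfidenceState, DifficultyTracker, DisWState,
    InsufficientHistoryError, compute_cdifw, compute_cdisw,
    compute_difficulty, compute_difficulty_weight, compute_disw_instant,
    information_score, update_confidence, update_difficulty, update_disw,
)


# ---------------------------------------------------------------------------
# Independent loop oracles
# ---------------------------------------------------------------------------

def disw_oracle(counts):
    counts = [c if c > 0 else 1 for c in counts]
    m = max(counts)
    ratios = [m / c for c in counts]
    logs = [np.log(r) for r in ratios]
    top = max(logs)
    if top == 0:
        return [1.0] * len(counts)
    return [l / top for l in logs]


def difficulty_oracle(history, alpha, eps, floor):
    z = [max(h, floor) for h in history]
    d_u = d_l = 0.0
    for i in range(1, len(history)):
        term = np.log(z[i] / z[i - 1])
        if history[i] - history[i - 1] > 0:
            d_l += term
        else:
            d_u += term
    base = (d_u + eps) / (d_l + eps)
    if base < 0:
        base = abs(base)
    return base ** alpha


def confidence_oracle(probs, labels):
    b, k = probs.shape[:2]
    out = []
    for cat in range(k):
        vals = []
        for i in range(b):
            sel = labels[i] == cat
            if sel.sum():
                vals.append(probs[i, cat][sel].sum() / sel.sum())
        out.append(np.mean(vals) if vals else np.nan)
    return np.array(out)


# ---------------------------------------------------------------------------
# Distribution weight
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("counts,expected", [
    ((1000, 10), (0.0, 1.0)),
    ((5, 5, 5), (1.0, 1.0, 1.0)),
    ((1000, 100, 10), (0.0, 0.5, 1.0)),
])
def test_disw_instant_hand_values(counts, expected):
    np.testing.assert_allclose(compute_disw_instant(counts), expected, atol=1e-12)


def test_disw_instant_rejects_all_zero():
    with pytest.raises(ValueError):
        compute_disw_instant([0, 0, 0])


def test_disw_instant_zero_count_floored(rng):
    # a zero count behaves as one voxel: finite, and the rarest category
    w = compute_disw_instant([500, 0])
    assert np.isfinite(w).all() and w[1] == 1.0


def test_disw_matches_loop_oracle(rng):
    for _ in range(300):
        k = int(rng.integers(2, 11))
        counts = rng.integers(0, 10000, size=k)
        if not counts.any():
            continue
        np.testing.assert_allclose(
            compute_disw_instant(counts), disw_oracle(list(counts)), atol=1e-12)


def test_disw_monotone_rarer_heavier():
    # decreasing psi_k (below the max) strictly increases w_k
    base = np.array([10000, 500, 10])
    w_hi = compute_disw_instant(base)
    lower = base.copy()
    lower[1] = 100
    w_lo = compute_disw_instant(lower)
    assert w_lo[1] > w_hi[1]


def test_update_disw_ema_and_limit(rng):
    # beta=0 degenerates to the instantaneous weights
    state = DisWState.initial(3, beta=0.0)
    labels = np.concatenate([np.zeros(900), np.ones(90), np.full(10, 2)]).astype(int)
    state = update_disw(state, labels)
    np.testing.assert_allclose(state.weights,
                               compute_disw_instant([900, 90, 10]), atol=1e-12)
    # geometric convergence to a constant instantaneous weight
    state = DisWState.initial(3, beta=0.99)
    target = compute_disw_instant([900, 90, 10])
    for _ in range(500):
        state = update_disw(state, labels)
    np.testing.assert_allclose(state.weights, target, atol=1e-2)
    assert state.iteration == 500


@given(beta=st.floats(0.0, 0.99), n=st.integers(2, 40))
@settings(max_examples=30, deadline=None, derandomize=True)
def test_disw_ema_stays_in_convex_hull(beta, n):
    rng = np.random.default_rng(n)
    state = DisWState.initial(2, beta=beta)
    lo = np.ones(2)
    hi = np.ones(2)
    for i in range(n):
        counts = rng.integers(1, 1000, size=2)
        inst = compute_disw_instant(counts)
        state = update_disw(state, np.repeat(np.arange(2), counts))
        lo = np.minimum(lo, inst)
        hi = np.maximum(hi, inst)
    assert np.all(state.weights >= np.minimum(lo, 1.0) - 1e-12)
    assert np.all(state.weights <= np.maximum(hi, 1.0) + 1e-12)


# ---------------------------------------------------------------------------
# Difficulty
# ---------------------------------------------------------------------------

def _tracker(history_rows, **kw):
    t = DifficultyTracker(num_classes=len(history_rows[0]), **kw)
    for row in history_rows:
        update_difficulty(t, row)
    return t


def test_difficulty_window_eviction():
    t = DifficultyTracker(num_classes=1, tau=50)
    for i in range(3):
        update_difficulty(t, [0.5])
    assert len(t.history) == 3 and t.window_start == 0
    for i in range(57):
        update_difficulty(t, [0.5])
    assert t.iteration == 60 and t.window_start == 10
    assert len(t.history) == 51  # tau+1 entries -> tau consecutive ratios


def test_difficulty_rejects_bad_dice():
    t = DifficultyTracker(num_classes=1)
    with pytest.raises(ValueError):
        update_difficulty(t, [1.5])


def test_difficulty_hand_values():
    # improving trajectory: d^u = 0, d^l = 2 ln 2
    t = _tracker([[0.2], [0.4], [0.8]], alpha=0.5, epsilon=1e-8)
    expected = (1e-8 / (2 * np.log(2) + 1e-8)) ** 0.5
    assert compute_difficulty(t, 0) == pytest.approx(expected, rel=1e-12)
    # flat trajectory: all terms ln(1)=0 on the d^u side -> d = 1
    t = _tracker([[0.5], [0.5], [0.5]])
    assert compute_difficulty(t, 0) == pytest.approx(1.0)
    # deteriorating trajectory: d > 1
    t = _tracker([[0.8], [0.4], [0.2]])
    with pytest.warns(RuntimeWarning):
        assert compute_difficulty(t, 0) > 1.0


def test_difficulty_requires_two_entries():
    t = _tracker([[0.5]])
    with pytest.raises(InsufficientHistoryError):
        compute_difficulty(t, 0)


def test_difficulty_matches_loop_oracle(rng):
    import warnings
    for _ in range(200):
        n = int(rng.integers(2, 20))
        hist = rng.uniform(0.0, 1.0, size=n)
        t = _tracker([[h] for h in hist], alpha=0.5, epsilon=1e-8)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            got = compute_difficulty(t, 0)
        want = difficulty_oracle(list(hist), 0.5, 1e-8, 1e-4)
        assert got == pytest.approx(want, rel=1e-10, abs=1e-12)


def test_difficulty_weight_hand_values():
    # perfectly segmented category carries no weight
    t = _tracker([[1.0, 0.5], [1.0, 0.5]])
    w = compute_difficulty_weight(t)
    assert w[0] == pytest.approx(0.0)
    # flat history at 0.5: d=1, w = 0.5
    assert w[1] == pytest.approx(0.5)
    # identical d, zeta (0.9, 0.2) -> ratio 1:8
    t = _tracker([[0.9, 0.2], [0.9, 0.2]])
    w = compute_difficulty_weight(t)
    assert w[1] / w[0] == pytest.approx(8.0)


# ---------------------------------------------------------------------------
# Confidence and information score
# ---------------------------------------------------------------------------

def _prob_maps(rng, b, k, shape):
    logits = rng.normal(size=(b, k) + shape)
    e = np.exp(logits - logits.max(axis=1, keepdims=True))
    return e / e.sum(axis=1, keepdims=True)


def test_confidence_perfect_and_uniform(rng):
    labels = rng.integers(0, 4, size=(2, 4, 4, 1))
    onehot = np.zeros((2, 4, 4, 4, 1))
    for c in range(4):
        onehot[:, c][labels == c] = 1.0
    state = ConfidenceState.initial(4, beta=0.0)
    state = update_confidence(state, onehot, labels)
    present = np.unique(labels)
    np.testing.assert_allclose(state.confidence[present], 1.0)
    uniform = np.full((2, 4, 4, 4, 1), 0.25)
    state = ConfidenceState.initial(4, beta=0.0)
    state = update_confidence(state, uniform, labels)
    np.testing.assert_allclose(state.confidence[present], 0.25)


def test_confidence_hand_value():
    # B=2; z_k = 10 and 5 voxels with p summing to 8 and 4 -> c_hat = 0.8
    k = 2
    labels = np.zeros((2, 15, 1, 1), dtype=int)
    labels[0, :10] = 1
    labels[1, :5] = 1
    p1 = np.zeros((2, 15, 1, 1))
    p1[0, :10] = 0.8
    p1[1, :5] = 0.8
    probs = np.stack([1 - p1, p1], axis=1)
    state = ConfidenceState.initial(k, beta=0.0)
    state = update_confidence(state, probs, labels)
    assert state.confidence[1] == pytest.approx(0.8)


def test_confidence_matches_loop_oracle(rng):
    state0 = ConfidenceState.initial(3, beta=0.0)
    for _ in range(50):
        probs = _prob_maps(rng, 2, 3, (3, 3, 2))
        labels = rng.integers(0, 3, size=(2, 3, 3, 2))
        got = update_confidence(state0, probs, labels).confidence
        want = confidence_oracle(probs, labels)
        keep = ~np.isnan(want)
        np.testing.assert_allclose(got[keep], want[keep], atol=1e-12)


def test_confidence_rejects_non_softmax(rng):
    state = ConfidenceState.initial(2)
    bad = np.full((1, 2, 2, 2, 2), 0.7)
    with pytest.raises(ValueError):
        update_confidence(state, bad, np.zeros((1, 2, 2, 2), dtype=int))


def test_confidence_absent_category_carried_forward():
    state = ConfidenceState(confidence=np.array([0.9, 0.3]), beta=0.0)
    labels = np.zeros((1, 2, 2, 2), dtype=int)   # category 1 absent
    probs = np.stack([np.ones((1, 2, 2, 2)), np.zeros((1, 2, 2, 2))], axis=1)
    new = update_confidence(state, probs, labels)
    assert new.confidence[1] == 0.3 and new.confidence[0] == 1.0


@pytest.mark.parametrize("c,expected", [
    ((0.9, 0.5), (0.2, 1.0)),
    ((0.7, 0.7), (1.0, 1.0)),
    ((1.0, 0.5), (0.0, 1.0)),
    ((1.0, 1.0), (1.0, 1.0)),   # all-confident degenerate case
])
def test_information_score(c, expected):
    state = ConfidenceState(confidence=np.array(c))
    np.testing.assert_allclose(information_score(state), expected, atol=1e-12)


def test_information_score_monotone_in_confidence():
    # lowering c_k weakly increases s_k
    lo = information_score(ConfidenceState(confidence=np.array([0.4, 0.8])))
    hi = information_score(ConfidenceState(confidence=np.array([0.6, 0.8])))
    assert lo[0] >= hi[0]


# ---------------------------------------------------------------------------
# Combined weights
# ---------------------------------------------------------------------------

def _cdifw_state(gamma, conf, history):
    state = CDifWState.initial(len(conf), gamma=gamma)
    state.confidence_state = ConfidenceState(confidence=np.array(conf), gamma=gamma)
    for row in history:
        update_difficulty(state.difficulty_tracker, row)
    return state


def test_cdifw_gamma_zero_equals_difficulty_weight():
    state = _cdifw_state(0.0, [0.9, 0.5], [[0.5, 0.5], [0.5, 0.5]])
    np.testing.assert_allclose(
        compute_cdifw(state),
        compute_difficulty_weight(state.difficulty_tracker), atol=1e-12)


def test_cdifw_hand_value():
    # s=(1, 0.2), gamma=0.2, w_dif=(0.5, 0.5)
    state = _cdifw_state(0.2, [0.0, 0.8], [[0.5, 0.5], [0.5, 0.5]])
    got = compute_cdifw(state)
    np.testing.assert_allclose(got, [0.5, 0.5 * 0.2 ** 0.2], atol=1e-12)


def test_cdifw_monotone_in_confidence():
    # lowering a category's confidence cannot lower its weight
    hi = compute_cdifw(_cdifw_state(0.2, [0.9, 0.5], [[0.5, 0.5]] * 2))
    lo = compute_cdifw(_cdifw_state(0.2, [0.6, 0.5], [[0.5, 0.5]] * 2))
    assert lo[0] >= hi[0]


@pytest.mark.parametrize("gamma,conf,disw,expected", [
    (0.0, (0.5, 0.9), (0.3, 1.0), (0.3, 1.0)),     # gamma=0 disables confidence
    (1.0, (0.5, 0.5), (0.3, 1.0), (0.3, 1.0)),     # s all 1 -> unchanged
    (1.0, (0.9, 0.5), (1.0, 1.0), (0.2, 1.0)),     # elementwise product
])
def test_cdisw(gamma, conf, disw, expected):
    state = ConfidenceState(confidence=np.array(conf), gamma=gamma)
    np.testing.assert_allclose(compute_cdisw(np.array(disw), state),
                               expected, atol=1e-12)


# ---------------------------------------------------------------------------
# Smoothness of confidence- vs Dice-based difficulty signals
# ---------------------------------------------------------------------------

def test_confidence_signal_smoother_than_dice_difficulty():
    """EMA-smoothed confidence varies far less step-to-step than the raw
    Dice-driven difficulty weight on a noisy trajectory."""
    rng = np.random.default_rng(424242)
    k = 2
    tracker = DifficultyTracker(num_classes=k, tau=50, alpha=0.5)
    conf = ConfidenceState.initial(k, beta=0.99)
    dif_seq, conf_seq = [], []
    import warnings as _w
    for t in range(300):
        zeta_small = float(np.clip(0.3 + rng.normal(0, 0.1), 0.01, 1.0))
        update_difficulty(tracker, [0.9, zeta_small])
        labels = np.ones((1, 1, 1, 1), dtype=int)
        probs = np.stack([np.full((1, 1, 1, 1), 1 - zeta_small),
                          np.full((1, 1, 1, 1), zeta_small)], axis=1)
        conf = update_confidence(conf, probs, labels)
        if t >= 2:
            with _w.catch_warnings():
                _w.simplefilter("ignore")
                dif_seq.append(compute_difficulty_weight(tracker)[1])
            conf_seq.append(information_score(conf)[1])
    var_dif = np.var(np.diff(dif_seq))
    var_conf = np.var(np.diff(conf_seq))
    assert var_conf * 5 < var_dif
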