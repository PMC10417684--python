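"""Peephole LSTM: activations, recurrence, gradients, training, persistence."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from sklearn.linear_model import LogisticRegression

from dbofuse.lstm import (
    LSTMParams,
    LSTMState,
    PeepholeLSTMClassifier,
    SequenceEncoding,
    _loss_and_grads,
    forward,
    g_activation,
    h_activation,
    init_params,
    load_params,
    lstm_step,
    sigmoid,
    train,
)


def zero_params(hidden=4, inp=3, n_classes=2) -> LSTMParams:
    template = init_params(inp, hidden, n_classes, np.random.default_rng(0))
    return LSTMParams(
        **{n: np.zeros_like(getattr(template, n)) for n in template.names()}
    )


# ------------------------------------------------------------ activations
def test_activation_point_values():
    assert sigmoid(0.0) == pytest.approx(0.5)
    assert sigmoid(2.0) == pytest.approx(0.8807970779778823)
    assert g_activation(0.0) == pytest.approx(0.0)
    # direct evaluation: 4 * sigmoid(1) - 2
    assert g_activation(1.0) == pytest.approx(0.9242343145200196)
    assert h_activation(0.0) == pytest.approx(0.0)
    assert h_activation(2.0) == pytest.approx(np.tanh(1.0))


def test_activation_saturation_limits():
    assert g_activation(50.0) == pytest.approx(2.0, abs=1e-9)
    assert g_activation(-50.0) == pytest.approx(-2.0, abs=1e-9)
    assert abs(h_activation(50.0)) < 1.0 + 1e-12


@given(st.floats(-20, 20))
def test_activation_identities(x):
    assert sigmoid(x) == pytest.approx(1.0 - sigmoid(-x), abs=1e-12)
    assert h_activation(x) == pytest.approx(g_activation(x) / 2.0, abs=1e-12)
    assert h_activation(x) == pytest.approx(np.tanh(x / 2.0), abs=1e-12)


def test_printed_output_activation_variant():
    # literal form 2/(1+x) - 1; singular at x = -1, kept for fidelity runs
    assert h_activation(0.0, "printed") == pytest.approx(1.0)
    assert h_activation(1.0, "printed") == pytest.approx(0.0)


# -------------------------------------------------------------- recurrence
def test_zero_parameter_fixed_point():
    params = zero_params()
    state = lstm_step(np.array([3.0, -1.0, 2.0]), LSTMState(np.zeros(4), np.zeros(4)), params)
    np.testing.assert_array_equal(state.c, np.zeros(4))
    np.testing.assert_array_equal(state.h, np.zeros(4))


def test_hand_chain_with_unit_cell():
    # zero weights, c0 = 1: i = f = 0.5, c1 = 0.5, o = 0.5, h1 = 0.5 h(0.5)
    params = zero_params()
    state = lstm_step(np.zeros(3), LSTMState(np.zeros(4), np.ones(4)), params)
    np.testing.assert_allclose(state.c, np.full(4, 0.5))
    np.testing.assert_allclose(state.h, np.full(4, 0.5 * h_activation(0.5)))


def test_nonfinite_state_raises():
    params = zero_params()
    with pytest.raises(FloatingPointError):
        lstm_step(np.zeros(3), LSTMState(np.full(4, np.nan), np.zeros(4)), params)


def test_cell_bounded_on_long_random_sequence():
    rng = np.random.default_rng(0)
    params = init_params(4, 6, 2, rng)
    state = LSTMState(np.zeros(6), np.zeros(6))
    for _ in range(1000):
        state = lstm_step(rng.normal(size=4), state, params)
    assert np.all(np.isfinite(state.c))
    assert np.all(np.abs(state.h) <= 1.0)


def test_gradients_match_finite_differences():
    """Analytic BPTT gradients vs central differences on random 3-step
    sequences; per-array norm relative error within 1e-5."""
    for trial in range(2):
        rng = np.random.default_rng(trial)
        params = init_params(4, 5, 3, rng)
        X = rng.normal(size=(2, 3, 4))
        y = rng.integers(0, 3, 2)
        _, grads = _loss_and_grads(X, y, params, "scaled_sigmoid")
        eps = 1e-6
        for nm in params.names():
            arr = getattr(params, nm)
            numeric = np.zeros_like(arr)
            it = np.nditer(arr, flags=["multi_index"])
            for _ in it:
                idx = it.multi_index
                orig = arr[idx]
                arr[idx] = orig + eps
                lp, _ = _loss_and_grads(X, y, params, "scaled_sigmoid")
                arr[idx] = orig - eps
                lm, _ = _loss_and_grads(X, y, params, "scaled_sigmoid")
                arr[idx] = orig
                numeric[idx] = (lp - lm) / (2 * eps)
            analytic = getattr(grads, nm)
            rel = np.linalg.norm(analytic - numeric) / max(
                np.linalg.norm(analytic), np.linalg.norm(numeric), 1e-12
            )
            assert rel < 1e-5, f"{nm}: {rel}"


# ----------------------------------------------------------------- forward
def test_forward_probabilities_sum_to_one():
    rng = np.random.default_rng(0)
    params = init_params(4, 6, 3, rng)
    enc = SequenceEncoding(chunk_count=4, chunk_length=4)
    for _ in range(10):
        p = forward(rng.normal(size=16), enc, params)
        assert p.shape == (3,)
        assert p.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(p >= 0)


def test_forward_single_chunk_degenerate():
    rng = np.random.default_rng(1)
    params = init_params(8, 5, 2, rng)
    enc = SequenceEncoding(chunk_count=1, chunk_length=8)
    x = rng.normal(size=8)
    p = forward(x, enc, params)
    # manual single step + head
    state = lstm_step(x, LSTMState(np.zeros(5), np.zeros(5)), params)
    logits = params.Whead @ state.h + params.bhead
    expected = np.exp(logits - logits.max())
    expected /= expected.sum()
    np.testing.assert_allclose(p, expected, atol=1e-12)


def test_forward_head_permutation_equivariance():
    rng = np.random.default_rng(2)
    params = init_params(2, 5, 3, rng)
    enc = SequenceEncoding(chunk_count=2, chunk_length=2)
    x = rng.normal(size=4)
    p = forward(x, enc, params)
    perm = np.array([2, 0, 1])
    permuted = params.copy()
    permuted.Whead = params.Whead[perm]
    permuted.bhead = params.bhead[perm]
    np.testing.assert_allclose(forward(x, enc, permuted), p[perm], atol=1e-12)


def test_padding_changes_output_but_is_consistent():
    rng = np.random.default_rng(3)
    X = rng.normal(size=(20, 10))
    y = rng.integers(0, 2, 20)
    clf = PeepholeLSTMClassifier(hidden_size=6, chunk_count=4, epochs=5, random_state=0)
    clf.fit(X, y)
    # 10 features into 4 chunks of 3 -> 2 zero-padded positions, applied the
    # same way at fit and predict time
    assert clf.encoding_.chunk_count * clf.encoding_.chunk_length == 12
    p1 = clf.predict_proba(X)
    p2 = clf.predict_proba(X)
    np.testing.assert_array_equal(p1, p2)


# ---------------------------------------------------------------- training
def test_training_on_separable_two_class_problem():
    rng = np.random.default_rng(0)
    n = 60
    X = np.vstack([rng.normal(-1.0, 0.5, (n // 2, 8)), rng.normal(1.0, 0.5, (n // 2, 8))])
    y = np.repeat([0, 1], n // 2)
    # independent separability oracle
    assert LogisticRegression().fit(X, y).score(X, y) >= 0.95
    clf = PeepholeLSTMClassifier(
        hidden_size=8, chunk_count=2, epochs=200, learning_rate=0.1, random_state=0
    ).fit(X, y)
    assert clf.score(X, y) >= 0.95
    # epoch-averaged loss broadly decreases
    assert clf.loss_curve_[-1] < clf.loss_curve_[0]


def test_zero_learning_rate_leaves_parameters_at_init():
    rng = np.random.default_rng(0)
    X = rng.normal(size=(12, 6))
    y = rng.integers(0, 2, 12)
    clf0 = PeepholeLSTMClassifier(epochs=3, learning_rate=0.0, random_state=5).fit(X, y)
    ref = init_params(clf0.encoding_.chunk_length, 16, 2, np.random.default_rng(5))
    np.testing.assert_array_equal(clf0.params_.Wxi, ref.Wxi)
    np.testing.assert_array_equal(clf0.params_.Whead, ref.Whead)


def test_training_determinism_same_seed(small_features):
    X, y = small_features
    kwargs = dict(hidden_size=8, epochs=20, random_state=3)
    c1 = PeepholeLSTMClassifier(**kwargs).fit(X, y)
    c2 = PeepholeLSTMClassifier(**kwargs).fit(X, y)
    assert c1.loss_curve_[-1] == c2.loss_curve_[-1]
    np.testing.assert_array_equal(c1.params_.Whead, c2.params_.Whead)


def test_train_wrapper_returns_params_and_trace(small_features):
    X, y = small_features
    params, trace = train(X, y, {"hidden_size": 8, "epochs": 10}, seed=0)
    assert params.hidden_size == 8
    assert trace.shape == (10,)


def test_serialization_round_trip_bit_exact(tmp_path, small_features):
    X, y = small_features
    clf = PeepholeLSTMClassifier(hidden_size=8, epochs=10, random_state=0).fit(X, y)
    path = tmp_path / "model.npz"
    clf.save(path)
    loaded = load_params(path)
    for nm in clf.params_.names():
        np.testing.assert_array_equal(getattr(clf.params_, nm), getattr(loaded.params_, nm))
    np.testing.assert_array_equal(clf.predict_proba(X), loaded.predict_proba(X))
    assert list(loaded.classes_) == list(clf.classes_)
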