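"""Peephole LSTM classifier over fused feature vectors.

The recurrence uses peephole connections: the input and forget gates see the
previous cell state and the output gate sees the current cell state, each
through a diagonal (elementwise) weight vector:

.. math::

    i_t &= \\sigma(W_{xi} x_t + W_{hi} h_{t-1} + w_{ci} \\circ c_{t-1} + b_i) \\\\
    f_t &= \\sigma(W_{xf} x_t + W_{hf} h_{t-1} + w_{cf} \\circ c_{t-1} + b_f) \\\\
    c_t &= f_t \\circ c_{t-1} + i_t \\circ g(W_{xc} x_t + W_{hc} h_{t-1} + b_c) \\\\
    o_t &= \\sigma(W_{xo} x_t + W_{ho} h_{t-1} + w_{co} \\circ c_t + b_o) \\\\
    h_t &= o_t \\circ h(c_t)

with the cell-input squashing ``g(x) = 4 sigma(x) - 2`` (range (-2, 2)) and the
cell-output squashing ``h(x) = 2 sigma(x) - 1 = tanh(x/2)`` (range (-1, 1)).
An alternative "printed" output squashing ``h(x) = 2/(1+x) - 1`` is kept behind
``output_activation="printed"`` for fidelity experiments; it is singular at
``x = -1`` and not recommended.

A fused feature vector is not natively sequential, so it is split into
``chunk_count`` timesteps (zero-padded on the right), the recurrence is run
from a zero state, and a linear + softmax head reads the final hidden state.
Training is plain mini-batch gradient descent on the cross-entropy, with
analytic backpropagation-through-time gradients (verified against central
finite differences in the test suite).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, fields
from typing import Sequence

import numpy as np
from scipy.special import expit, softmax as _softmax
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.multiclass import unique_labels
from sklearn.utils.validation import check_X_y, check_array, check_is_fitted

__all__ = [
    "LSTMParams",
    "LSTMState",
    "SequenceEncoding",
    "sigmoid",
    "g_activation",
    "h_activation",
    "lstm_step",
    "forward",
    "train",
    "PeepholeLSTMClassifier",
    "save_params",
    "load_params",
]

FORMAT_VERSION = 1


def sigmoid(x):
    """Standard logistic sigmoid ``1 / (1 + e^-x)``, elementwise."""
    return expit(x)


def g_activation(x):
    """Cell-input squashing ``4 / (1 + e^-x) - 2``; range (-2, 2), g(0) = 0."""
    return 4.0 * expit(x) - 2.0


def h_activation(x, variant: str = "scaled_sigmoid"):
    """Cell-output squashing.

    Default ``scaled_sigmoid``: ``2 / (1 + e^-x) - 1 = tanh(x/2)``.
    ``printed``: the literal form ``2 / (1 + x) - 1`` (singular at x = -1).
    """
    if variant == "printed":
        return 2.0 / (1.0 + x) - 1.0
    return 2.0 * expit(x) - 1.0


def _g_prime(x):
    s = expit(x)
    return 4.0 * s * (1.0 - s)


def _h_prime(x, variant: str = "scaled_sigmoid"):
    if variant == "printed":
        return -2.0 / (1.0 + x) ** 2
    s = expit(x)
    return 2.0 * s * (1.0 - s)


@dataclass
class LSTMParams:
    """All trainable arrays: gate weights, peephole vectors, biases and the
    linear classification head."""

    Wxi: np.ndarray
    Whi: np.ndarray
    wci: np.ndarray
    bi: np.ndarray
    Wxf: np.ndarray
    Whf: np.ndarray
    wcf: np.ndarray
    bf: np.ndarray
    Wxc: np.ndarray
    Whc: np.ndarray
    bc: np.ndarray
    Wxo: np.ndarray
    Who: np.ndarray
    wco: np.ndarray
    bo: np.ndarray
    Whead: np.ndarray
    bhead: np.ndarray

    @property
    def hidden_size(self) -> int:
        return self.Wxi.shape[0]

    @property
    def input_size(self) -> int:
        return self.Wxi.shape[1]

    @property
    def n_classes(self) -> int:
        return self.Whead.shape[0]

    def names(self) -> list[str]:
        return [f.name for f in fields(self)]

    def copy(self) -> "LSTMParams":
        return LSTMParams(**{n: getattr(self, n).copy() for n in self.names()})

    def validate(self) -> None:
        for n in self.names():
            if not np.all(np.isfinite(getattr(self, n))):
                raise ValueError(f"non-finite values in parameter {n}")


@dataclass
class LSTMState:
    """Recurrent state: hidden vector ``h`` (|h_j| <= 1 by the output
    squashing) and cell vector ``c``."""

    h: np.ndarray
    c: np.ndarray


@dataclass
class SequenceEncoding:
    """How a fused feature vector is reshaped into a short sequence.

    ``chunk_count * chunk_length`` must cover the fused dimension; the last
    chunk is zero-padded on the right.  Padding is part of the model contract:
    the same encoding must be used at train and predict time.
    """

    chunk_count: int
    chunk_length: int

    def __post_init__(self) -> None:
        if self.chunk_count < 1 or self.chunk_length < 1:
            raise ValueError("chunk_count and chunk_length must be positive")

    @classmethod
    def for_dim(cls, n_features: int, chunk_count: int) -> "SequenceEncoding":
        chunk_length = -(-n_features // chunk_count)
        return cls(chunk_count=chunk_count, chunk_length=chunk_length)

    def encode(self, X: np.ndarray) -> np.ndarray:
        """(n, d) -> (n, chunk_count, chunk_length) with right zero-padding."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        total = self.chunk_count * self.chunk_length
        if X.shape[1] > total:
            raise ValueError(
                f"feature dim {X.shape[1]} exceeds encoding capacity {total}"
            )
        pad = total - X.shape[1]
        if pad:
            X = np.pad(X, ((0, 0), (0, pad)))
        return X.reshape(X.shape[0], self.chunk_count, self.chunk_length)


def init_params(
    input_size: int,
    hidden_size: int,
    n_classes: int,
    rng: np.random.Generator,
) -> LSTMParams:
    """Gaussian initialization scaled by fan-in; forget-gate bias starts at 1."""

    def mat(rows, cols):
        return rng.normal(0.0, 1.0 / np.sqrt(max(cols, 1)), size=(rows, cols))

    H, L, K = hidden_size, input_size, n_classes
    return LSTMParams(
        Wxi=mat(H, L), Whi=mat(H, H), wci=rng.normal(0.0, 0.1, H), bi=np.zeros(H),
        Wxf=mat(H, L), Whf=mat(H, H), wcf=rng.normal(0.0, 0.1, H), bf=np.ones(H),
        Wxc=mat(H, L), Whc=mat(H, H), bc=np.zeros(H),
        Wxo=mat(H, L), Who=mat(H, H), wco=rng.normal(0.0, 0.1, H), bo=np.zeros(H),
        Whead=mat(K, H), bhead=np.zeros(K),
    )


def lstm_step(
    x_t: np.ndarray,
    state: LSTMState,
    params: LSTMParams,
    variant: str = "scaled_sigmoid",
) -> LSTMState:
    """One peephole-LSTM timestep for a single input vector."""
    x_t = np.asarray(x_t, dtype=float)
    h_prev, c_prev = np.asarray(state.h, float), np.asarray(state.c, float)
    if not (np.all(np.isfinite(h_prev)) and np.all(np.isfinite(c_prev))):
        raise FloatingPointError("non-finite recurrent state: training diverged")
    zi = params.Wxi @ x_t + params.Whi @ h_prev + params.wci * c_prev + params.bi
    zf = params.Wxf @ x_t + params.Whf @ h_prev + params.wcf * c_prev + params.bf
    zc = params.Wxc @ x_t + params.Whc @ h_prev + params.bc
    c_t = expit(zf) * c_prev + expit(zi) * g_activation(zc)
    zo = params.Wxo @ x_t + params.Who @ h_prev + params.wco * c_t + params.bo
    h_t = expit(zo) * h_activation(c_t, variant)
    return LSTMState(h=h_t, c=c_t)


def _forward_batch(X_seq: np.ndarray, params: LSTMParams, variant: str):
    """Run the recurrence over (B, T, L), returning final h and a cache for BPTT."""
    B, T, _ = X_seq.shape
    H = params.hidden_size
    h = np.zeros((B, H))
    c = np.zeros((B, H))
    cache = []
    for t in range(T):
        x = X_seq[:, t, :]
        zi = x @ params.Wxi.T + h @ params.Whi.T + c * params.wci + params.bi
        zf = x @ params.Wxf.T + h @ params.Whf.T + c * params.wcf + params.bf
        zc = x @ params.Wxc.T + h @ params.Whc.T + params.bc
        i_g = expit(zi)
        f_g = expit(zf)
        g_v = g_activation(zc)
        c_new = f_g * c + i_g * g_v
        zo = x @ params.Wxo.T + h @ params.Who.T + c_new * params.wco + params.bo
        o_g = expit(zo)
        h_new = o_g * h_activation(c_new, variant)
        cache.append((x, h, c, zi, zf, zc, zo, i_g, f_g, g_v, c_new, o_g))
        h, c = h_new, c_new
    return h, c, cache


def _loss_and_grads(
    X_seq: np.ndarray,
    y_idx: np.ndarray,
    params: LSTMParams,
    variant: str,
) -> tuple[float, LSTMParams]:
    """Mean cross-entropy and analytic gradients via BPTT."""
    B = X_seq.shape[0]
    h_T, _, cache = _forward_batch(X_seq, params, variant)
    logits = h_T @ params.Whead.T + params.bhead
    logits -= logits.max(axis=1, keepdims=True)
    logZ = np.log(np.exp(logits).sum(axis=1))
    loss = float(np.mean(logZ - logits[np.arange(B), y_idx]))
    probs = np.exp(logits - logZ[:, None])

    dlogits = probs.copy()
    dlogits[np.arange(B), y_idx] -= 1.0
    dlogits /= B

    g = LSTMParams(**{n: np.zeros_like(getattr(params, n)) for n in params.names()})
    g.Whead = dlogits.T @ h_T
    g.bhead = dlogits.sum(axis=0)

    dh = dlogits @ params.Whead
    dc = np.zeros_like(dh)
    for t in range(len(cache) - 1, -1, -1):
        x, h_prev, c_prev, zi, zf, zc, zo, i_g, f_g, g_v, c_t, o_g = cache[t]
        do_pre = dh * h_activation(c_t, variant) * o_g * (1.0 - o_g)
        dc_t = dc + dh * o_g * _h_prime(c_t, variant) + do_pre * params.wco
        di_pre = dc_t * g_v * i_g * (1.0 - i_g)
        df_pre = dc_t * c_prev * f_g * (1.0 - f_g)
        dg_pre = dc_t * i_g * _g_prime(zc)

        g.Wxi += di_pre.T @ x
        g.Whi += di_pre.T @ h_prev
        g.wci += (di_pre * c_prev).sum(axis=0)
        g.bi += di_pre.sum(axis=0)
        g.Wxf += df_pre.T @ x
        g.Whf += df_pre.T @ h_prev
        g.wcf += (df_pre * c_prev).sum(axis=0)
        g.bf += df_pre.sum(axis=0)
        g.Wxc += dg_pre.T @ x
        g.Whc += dg_pre.T @ h_prev
        g.bc += dg_pre.sum(axis=0)
        g.Wxo += do_pre.T @ x
        g.Who += do_pre.T @ h_prev
        g.wco += (do_pre * c_t).sum(axis=0)
        g.bo += do_pre.sum(axis=0)

        dh = (
            di_pre @ params.Whi
            + df_pre @ params.Whf
            + dg_pre @ params.Whc
            + do_pre @ params.Who
        )
        dc = dc_t * f_g + di_pre * params.wci + df_pre * params.wcf
    return loss, g


def forward(
    fused_vector: np.ndarray,
    encoding: SequenceEncoding,
    params: LSTMParams,
    variant: str = "scaled_sigmoid",
) -> np.ndarray:
    """Class probability vector for one fused feature vector (softmax head)."""
    X_seq = encoding.encode(np.atleast_2d(fused_vector))
    h_T, _, _ = _forward_batch(X_seq, params, variant)
    logits = h_T @ params.Whead.T + params.bhead
    return _softmax(logits, axis=1)[0]


class PeepholeLSTMClassifier(ClassifierMixin, BaseEstimator):
    """Sklearn-style peephole LSTM classifier for fixed-length feature vectors.

    Parameters
    ----------
    hidden_size : int
        Hidden/cell dimension.
    chunk_count : int
        Number of timesteps the feature vector is split into.
    learning_rate : float
        SGD step size (plain mini-batch gradient descent; no momentum or
        adaptive scaling, so a tuned learning rate is directly interpretable).
    epochs : int
        Full passes over the training data.
    batch_size : int
        Mini-batch size.
    standardize : bool
        Standardize features to zero mean / unit variance using training
        statistics (stored on the estimator).
    output_activation : {"scaled_sigmoid", "printed"}
        Cell-output squashing variant; see module docstring.
    max_grad_norm : float
        Global gradient-norm clip, a safeguard against divergence at large
        learning rates.
    random_state : int
        Seed for initialization and batch shuffling.

    Attributes
    ----------
    classes_ : ndarray of unique labels.
    params_ : LSTMParams, fitted weights.
    encoding_ : SequenceEncoding used at both fit and predict time.
    loss_curve_ : ndarray, epoch-averaged training loss.
    """

    def __init__(
        self,
        hidden_size: int = 16,
        chunk_count: int = 4,
        learning_rate: float = 0.05,
        epochs: int = 100,
        batch_size: int = 8,
        standardize: bool = True,
        output_activation: str = "scaled_sigmoid",
        max_grad_norm: float = 5.0,
        random_state: int = 0,
    ):
        self.hidden_size = hidden_size
        self.chunk_count = chunk_count
        self.learning_rate = learning_rate
        self.epochs = epochs
        self.batch_size = batch_size
        self.standardize = standardize
        self.output_activation = output_activation
        self.max_grad_norm = max_grad_norm
        self.random_state = random_state

    # ------------------------------------------------------------------ fit
    def fit(self, X, y):
        X, y = check_X_y(X, y)
        self.classes_ = unique_labels(y)
        if len(self.classes_) < 2:
            raise ValueError("need at least two classes")
        y_idx = np.searchsorted(self.classes_, y)
        self.n_features_in_ = X.shape[1]

        if self.standardize:
            self.mean_ = X.mean(axis=0)
            scale = X.std(axis=0)
            scale[scale == 0.0] = 1.0
            self.scale_ = scale
        else:
            self.mean_ = np.zeros(X.shape[1])
            self.scale_ = np.ones(X.shape[1])
        Xs = (X - self.mean_) / self.scale_

        self.encoding_ = SequenceEncoding.for_dim(X.shape[1], int(self.chunk_count))
        X_seq = self.encoding_.encode(Xs)

        rng = np.random.default_rng(self.random_state)
        params = init_params(
            self.encoding_.chunk_length,
            int(self.hidden_size),
            len(self.classes_),
            rng,
        )

        n = X_seq.shape[0]
        bs = max(1, min(int(self.batch_size), n))
        losses = []
        for _ in range(int(self.epochs)):
            order = rng.permutation(n)
            epoch_loss = 0.0
            n_batches = 0
            for start in range(0, n, bs):
                idx = order[start : start + bs]
                loss, grads = _loss_and_grads(
                    X_seq[idx], y_idx[idx], params, self.output_activation
                )
                if not np.isfinite(loss):
                    raise RuntimeError(
                        "training diverged: non-finite loss; lower the learning "
                        "rate or change the encoding"
                    )
                gnorm = np.sqrt(
                    sum(float((getattr(grads, nm) ** 2).sum()) for nm in grads.names())
                )
                clip = (
                    self.max_grad_norm / gnorm
                    if gnorm > self.max_grad_norm > 0
                    else 1.0
                )
                for nm in params.names():
                    getattr(params, nm)[...] -= (
                        self.learning_rate * clip * getattr(grads, nm)
                    )
                epoch_loss += loss
                n_batches += 1
            losses.append(epoch_loss / n_batches)
        params.validate()
        self.params_ = params
        self.loss_curve_ = np.asarray(losses)
        return self

    # -------------------------------------------------------------- predict
    def _decision_probs(self, X) -> np.ndarray:
        check_is_fitted(self, "params_")
        X = check_array(X)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} features; expected {self.n_features_in_}"
            )
        Xs = (X - self.mean_) / self.scale_
        X_seq = self.encoding_.encode(Xs)
        h_T, _, _ = _forward_batch(X_seq, self.params_, self.output_activation)
        logits = h_T @ self.params_.Whead.T + self.params_.bhead
        return _softmax(logits, axis=1)

    def predict_proba(self, X) -> np.ndarray:
        return self._decision_probs(X)

    def predict(self, X) -> np.ndarray:
        return self.classes_[np.argmax(self._decision_probs(X), axis=1)]

    # ---------------------------------------------------------- persistence
    def save(self, path) -> None:
        save_params(path, self)

    @classmethod
    def load(cls, path) -> "PeepholeLSTMClassifier":
        return load_params(path)


def train(
    features: np.ndarray,
    labels: Sequence,
    hyperparams: dict,
    seed: int = 0,
) -> tuple[LSTMParams, np.ndarray]:
    """Functional wrapper: fit a :class:`PeepholeLSTMClassifier` and return its
    fitted parameters and epoch-loss trace."""
    clf = PeepholeLSTMClassifier(random_state=seed, **hyperparams)
    clf.fit(features, labels)
    return clf.params_, clf.loss_curve_


def save_params(path, clf: PeepholeLSTMClassifier) -> None:
    """Serialize a fitted classifier to one ``.npz`` archive (bit-exact)."""
    check_is_fitted(clf, "params_")
    meta = {
        "format_version": FORMAT_VERSION,
        "hyperparams": clf.get_params(),
        "encoding": {
            "chunk_count": clf.encoding_.chunk_count,
            "chunk_length": clf.encoding_.chunk_length,
        },
        "n_features_in": int(clf.n_features_in_),
    }
    arrays = {nm: getattr(clf.params_, nm) for nm in clf.params_.names()}
    np.savez(
        path,
        __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
        classes=clf.classes_,
        mean=clf.mean_,
        scale=clf.scale_,
        loss_curve=clf.loss_curve_,
        **arrays,
    )


def load_params(path) -> PeepholeLSTMClassifier:
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        if meta["format_version"] != FORMAT_VERSION:
            raise ValueError(f"unsupported model format {meta['format_version']}")
        clf = PeepholeLSTMClassifier(**meta["hyperparams"])
        clf.classes_ = data["classes"]
        clf.mean_ = data["mean"]
        clf.scale_ = data["scale"]
        clf.loss_curve_ = data["loss_curve"]
        clf.n_features_in_ = meta["n_features_in"]
        clf.encoding_ = SequenceEncoding(**meta["encoding"])
        names = [f.name for f in fields(LSTMParams)]
        clf.params_ = LSTMParams(**{nm: data[nm] for nm in names})
    return clf
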