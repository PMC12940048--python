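"""A single-layer LSTM binary classifier implemented from its gate equations.

Each gate acts on the concatenation [H_{t-1}, X_t]:

    F_t = sigmoid(W_F [H_{t-1}, X_t] + b_F)        forget gate
    I_t = sigmoid(W_I [H_{t-1}, X_t] + b_I)        input gate
    C~_t = tanh(W_C [H_{t-1}, X_t] + b_C)          candidate state
    C_t = F_t * C_{t-1} + I_t * C~_t               cell-state update
    O_t = sigmoid(W_O [H_{t-1}, X_t] + b_O)        output gate
    H_t = O_t * tanh(C_t)

with element-wise products throughout, followed by a sigmoid output head
on the final hidden state.  Tabular rows enter the cell as a length-1
sequence by default (the whole feature vector is the single timestep); an
alternative mapping feeds one feature per timestep.  Training minimizes
binary cross-entropy with Adam, inverted dropout on the final hidden state,
and early stopping on validation loss; gradients are exact backpropagation
through time (verified against finite differences in the test suite).
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field

import numpy as np

from .preprocess import FeatureTable
from .rng import as_generator

_GATES = ("F", "I", "C", "O")


class LSTMError(ValueError):
    pass


def _sigmoid(x):
    return 0.5 * (1.0 + np.tanh(0.5 * x))


@dataclass
class LSTMHyper:
    """The tunable box: learning rate, batch size, unit count, dropout."""

    lr: float = 1e-3
    batch_size: int = 32
    units: int = 64
    dropout: float = 0.2

    def to_dict(self) -> dict:
        return {"lr": self.lr, "batch": self.batch_size, "units": self.units,
                "dropout": self.dropout}

    @classmethod
    def from_dict(cls, d: dict) -> "LSTMHyper":
        return cls(lr=d["lr"], batch_size=d["batch"], units=d["units"], dropout=d["dropout"])


@dataclass
class LSTMParams:
    """Gate weights/biases plus the sigmoid output head."""

    weights: dict  # gate -> (units, units + input_dim)
    biases: dict  # gate -> (units,)
    head_w: np.ndarray  # (units,)
    head_b: float
    units: int
    input_dim: int
    sequence_mode: str = "row"  # "row" (T=1) | "timesteps" (one feature per step)

    def flatten(self) -> np.ndarray:
        parts = [self.weights[g].ravel() for g in _GATES]
        parts += [self.biases[g] for g in _GATES]
        parts += [self.head_w, np.array([self.head_b])]
        return np.concatenate(parts)

    def to_dict(self) -> dict:
        return {
            "units": self.units,
            "input_dim": self.input_dim,
            "sequence_mode": self.sequence_mode,
            "weights": {g: self.weights[g].tolist() for g in _GATES},
            "biases": {g: self.biases[g].tolist() for g in _GATES},
            "head_w": self.head_w.tolist(),
            "head_b": self.head_b,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LSTMParams":
        return cls(
            weights={g: np.array(d["weights"][g]) for g in _GATES},
            biases={g: np.array(d["biases"][g]) for g in _GATES},
            head_w=np.array(d["head_w"]),
            head_b=float(d["head_b"]),
            units=d["units"],
            input_dim=d["input_dim"],
            sequence_mode=d.get("sequence_mode", "row"),
        )

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_json(cls, text: str) -> "LSTMParams":
        return cls.from_dict(json.loads(text))


def init_params(units: int, input_dim: int, seed=0, sequence_mode: str = "row") -> LSTMParams:
    """Uniform(-k, k) initialization with k = 1/sqrt(fan-in), seeded."""
    rng = as_generator(seed)
    fan_in = units + input_dim
    k = 1.0 / np.sqrt(fan_in)
    weights = {g: rng.uniform(-k, k, size=(units, fan_in)) for g in _GATES}
    biases = {g: rng.uniform(-k, k, size=units) for g in _GATES}
    head_w = rng.uniform(-1.0 / np.sqrt(units), 1.0 / np.sqrt(units), size=units)
    head_b = float(rng.uniform(-0.1, 0.1))
    return LSTMParams(weights, biases, head_w, head_b, units, input_dim, sequence_mode)


def cell_step(h_prev, c_prev, x_t, params: LSTMParams):
    """One LSTM cell update; returns (H_t, C_t, gate record).

    Inputs are (batch, units) / (batch, input_dim) arrays (1-D vectors are
    treated as a batch of one).
    """
    h_prev = np.atleast_2d(np.asarray(h_prev, dtype=float))
    c_prev = np.atleast_2d(np.asarray(c_prev, dtype=float))
    x_t = np.atleast_2d(np.asarray(x_t, dtype=float))
    if x_t.shape[1] != params.input_dim or h_prev.shape[1] != params.units:
        raise LSTMError("input width does not match parameters")
    z = np.hstack([h_prev, x_t])
    gates = {}
    for g in _GATES:
        a = z @ params.weights[g].T + params.biases[g]
        gates[g] = np.tanh(a) if g == "C" else _sigmoid(a)
        if not np.isfinite(gates[g]).all():
            raise LSTMError(f"non-finite activation in gate {g}")
    c_t = gates["F"] * c_prev + gates["I"] * gates["C"]
    h_t = gates["O"] * np.tanh(c_t)
    gates["z"] = z
    gates["c_prev"] = c_prev
    gates["c_t"] = c_t
    return h_t, c_t, gates


def _as_sequence(X: np.ndarray, params: LSTMParams) -> np.ndarray:
    """Arrange (n, features) rows into a (T, n, input_dim) sequence."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if params.sequence_mode == "row":
        if X.shape[1] != params.input_dim:
            raise LSTMError(
                f"feature width {X.shape[1]} does not match input_dim {params.input_dim}"
            )
        return X[None, :, :]
    if params.sequence_mode == "timesteps":
        return X.T[:, :, None]
    raise LSTMError(f"unknown sequence_mode {params.sequence_mode!r}")


def _forward_all(X: np.ndarray, params: LSTMParams, keep_trace: bool = False):
    seq = _as_sequence(X, params)
    T, n, _ = seq.shape
    h = np.zeros((n, params.units))
    c = np.zeros((n, params.units))
    trace = []
    for t in range(T):
        h, c, gates = cell_step(h, c, seq[t], params)
        if keep_trace:
            trace.append(gates)
    logits = h @ params.head_w + params.head_b
    probs = _sigmoid(logits)
    return probs, h, trace


def forward(X, params: LSTMParams) -> np.ndarray:
    """Probability of class 1 for each row of ``X`` (pure function)."""
    probs, _, _ = _forward_all(X, params)
    return probs


def predict(table_or_X, params: LSTMParams, threshold: float = 0.5):
    """Labels and probabilities; label 1 iff probability >= threshold."""
    X = table_or_X.values if isinstance(table_or_X, FeatureTable) else table_or_X
    probs = forward(X, params)
    return (probs >= threshold).astype(int), probs


def bce_loss(probs, y, eps: float = 1e-12) -> float:
    p = np.clip(probs, eps, 1.0 - eps)
    y = np.asarray(y, dtype=float)
    return float(-np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))


def loss_and_gradients(params: LSTMParams, X, y, dropout_mask=None):
    """Binary cross-entropy and its exact gradients via BPTT.

    ``dropout_mask`` (already scaled, same shape as the final hidden state)
    is applied before the head during training; None disables dropout.
    Returns (loss, grads) with grads keyed like the parameter fields.
    """
    y = np.asarray(y, dtype=float)
    seq = _as_sequence(X, params)
    T, n, _ = seq.shape
    U = params.units
    h = np.zeros((n, U))
    c = np.zeros((n, U))
    trace = []
    hs = []
    for t in range(T):
        h, c, gates = cell_step(h, c, seq[t], params)
        trace.append(gates)
        hs.append(h)
    h_final = hs[-1]
    h_drop = h_final if dropout_mask is None else h_final * dropout_mask
    logits = h_drop @ params.head_w + params.head_b
    probs = _sigmoid(logits)
    loss = bce_loss(probs, y)

    grads = {
        "weights": {g: np.zeros_like(params.weights[g]) for g in _GATES},
        "biases": {g: np.zeros_like(params.biases[g]) for g in _GATES},
    }
    dlogits = (probs - y) / n  # d(BCE)/d(logit) for a sigmoid head
    grads["head_w"] = h_drop.T @ dlogits
    grads["head_b"] = float(dlogits.sum())
    dh = np.outer(dlogits, params.head_w)
    if dropout_mask is not None:
        dh = dh * dropout_mask
    dc = np.zeros((n, U))
    for t in range(T - 1, -1, -1):
        g = trace[t]
        tanh_c = np.tanh(g["c_t"])
        do = dh * tanh_c
        dc = dc + dh * g["O"] * (1.0 - tanh_c**2)
        df = dc * g["c_prev"]
        di = dc * g["C"]
        dcand = dc * g["I"]
        da = {
            "F": df * g["F"] * (1.0 - g["F"]),
            "I": di * g["I"] * (1.0 - g["I"]),
            "C": dcand * (1.0 - g["C"] ** 2),
            "O": do * g["O"] * (1.0 - g["O"]),
        }
        dz = np.zeros_like(g["z"])
        for name in _GATES:
            grads["weights"][name] += da[name].T @ g["z"]
            grads["biases"][name] += da[name].sum(axis=0)
            dz += da[name] @ params.weights[name]
        dh = dz[:, :U]
        dc = dc * g["F"]
    return loss, grads


class _Adam:
    def __init__(self, params: LSTMParams, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = self._zeros_like(params)
        self.v = self._zeros_like(params)

    @staticmethod
    def _zeros_like(p):
        return {
            "weights": {g: np.zeros_like(p.weights[g]) for g in _GATES},
            "biases": {g: np.zeros_like(p.biases[g]) for g in _GATES},
            "head_w": np.zeros_like(p.head_w),
            "head_b": 0.0,
        }

    def step(self, params: LSTMParams, grads):
        self.t += 1
        bc1 = 1.0 - self.b1**self.t
        bc2 = 1.0 - self.b2**self.t

        def upd(m, v, g):
            m_new = self.b1 * m + (1 - self.b1) * g
            v_new = self.b2 * v + (1 - self.b2) * np.square(g)
            delta = self.lr * (m_new / bc1) / (np.sqrt(v_new / bc2) + self.eps)
            return m_new, v_new, delta

        for g in _GATES:
            self.m["weights"][g], self.v["weights"][g], d = upd(
                self.m["weights"][g], self.v["weights"][g], grads["weights"][g]
            )
            params.weights[g] -= d
            self.m["biases"][g], self.v["biases"][g], d = upd(
                self.m["biases"][g], self.v["biases"][g], grads["biases"][g]
            )
            params.biases[g] -= d
        self.m["head_w"], self.v["head_w"], d = upd(self.m["head_w"], self.v["head_w"], grads["head_w"])
        params.head_w -= d
        self.m["head_b"], self.v["head_b"], d = upd(self.m["head_b"], self.v["head_b"], grads["head_b"])
        params.head_b -= float(d)


@dataclass
class TrainHistory:
    train_loss: list = field(default_factory=list)
    val_loss: list = field(default_factory=list)
    best_epoch: int = 0
    stopped_epoch: int = 0


def train(
    train_table: FeatureTable,
    val_table: FeatureTable,
    hyper: LSTMHyper | None = None,
    max_epochs: int = 200,
    patience: int = 10,
    seed=0,
    sequence_mode: str = "row",
) -> tuple[LSTMParams, TrainHistory]:
    """Fit with Adam + early stopping; returns best-validation-epoch params.

    Dropout (inverted, on the final hidden state) is active during training
    updates only.  Training stops once validation loss has failed to improve
    for ``patience`` consecutive epochs, or at ``max_epochs``.
    """
    hyper = hyper or LSTMHyper()
    if max_epochs < 1 or patience < 1:
        raise LSTMError("max_epochs and patience must be >= 1")
    if not 0.0 <= hyper.dropout < 1.0:
        raise LSTMError("dropout must lie in [0, 1)")
    if len(np.unique(train_table.outcome)) < 2:
        raise LSTMError("training data must contain both classes")
    rng = as_generator(seed)
    input_dim = train_table.n_attributes if sequence_mode == "row" else 1
    params = init_params(hyper.units, input_dim, seed=rng, sequence_mode=sequence_mode)
    opt = _Adam(params, lr=hyper.lr)
    Xtr, ytr = train_table.values, train_table.outcome
    Xva, yva = val_table.values, val_table.outcome
    n = Xtr.shape[0]
    history = TrainHistory()
    best_val = np.inf
    best_params = copy.deepcopy(params)
    epochs_without_improvement = 0
    for epoch in range(1, max_epochs + 1):
        order = rng.permutation(n)
        epoch_losses = []
        for start in range(0, n, hyper.batch_size):
            idx = order[start: start + hyper.batch_size]
            if hyper.dropout > 0.0:
                mask = (rng.random((len(idx), hyper.units)) >= hyper.dropout) / (
                    1.0 - hyper.dropout
                )
            else:
                mask = None
            loss, grads = loss_and_gradients(params, Xtr[idx], ytr[idx], dropout_mask=mask)
            if not np.isfinite(loss):
                raise LSTMError(f"non-finite training loss at epoch {epoch}")
            epoch_losses.append(loss)
            opt.step(params, grads)
        val_loss = bce_loss(forward(Xva, params), yva)
        if not np.isfinite(val_loss):
            raise LSTMError(f"non-finite validation loss at epoch {epoch}")
        history.train_loss.append(float(np.mean(epoch_losses)))
        history.val_loss.append(float(val_loss))
        history.stopped_epoch = epoch
        if val_loss < best_val:
            best_val = val_loss
            best_params = copy.deepcopy(params)
            history.best_epoch = epoch
            epochs_without_improvement = 0
        else:
            epochs_without_improvement += 1
            if epochs_without_improvement >= patience:
                break
    return best_params, history
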