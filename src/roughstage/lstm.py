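"""Uni/bidirectional LSTM stage classifiers, in NumPy.

A patient's ordinal attribute vector is read as a length-T_s sequence with
one feature per step (T_s = number of conditional attributes), so each
input token influences the corresponding hidden token.  Cells follow the
standard gate algebra

    i_t = σ(w_i x_t + u_i h_{t−1} + D_i)        input gate
    f_t = σ(w_f x_t + u_f h_{t−1} + D_f)        forget gate
    O_t = σ(w_O x_t + u_O h_{t−1} + D_O)        output gate
    C̃_t = tanh(w_C x_t + u_C h_{t−1} + D_C)     candidate
    C_t = f_t ⊙ C_{t−1} + i_t ⊙ C̃_t
    h_t = O_t ⊙ tanh(C_t)

with an independent bias per gate by default (``shared_bias`` reuses one
D across all four, and ``literal_bracket`` composes w·(x_t + u·h_{t−1})
as some presentations bracket it, which requires the recurrent map to
land in the input width).  The bidirectional classifier runs a second
cell over the reversed sequence and by default concatenates the two final
hidden states; the alternative ``paper_eq20`` combiner is the convex mix
(1 − O_t) ⊙ h_{t−1} + O_t ⊙ C̃_t.

Training is backpropagation-through-time on categorical cross-entropy with
a choice of adam, rmsprop, nadam (Nesterov-momentum adam) or adamax, all
implemented here.  Everything is seeded and deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .infosys import InformationSystem
from .rsfas import OrdinalSystem

__all__ = [
    "LSTMConfig",
    "GateState",
    "CellParams",
    "cell_forward",
    "bidirectional_combine",
    "LSTMClassifier",
    "TrainedLSTM",
    "train",
    "predict",
    "make_optimizer",
    "TrainingError",
    "DivergenceError",
]

OPTIMIZERS = ("adam", "rmsprop", "nadam", "adamax")


class TrainingError(ValueError):
    """The data cannot be trained on (e.g. a single target class)."""


class DivergenceError(RuntimeError):
    """Loss became non-finite during training."""

    def __init__(self, epoch: int):
        super().__init__(f"loss diverged (NaN/inf) at epoch {epoch}")
        self.epoch = epoch


# --------------------------------------------------------------------------
# configuration
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class LSTMConfig:
    """Hyperparameters; defaults are the selected bidirectional choices of
    the tuning grid (100 units, 2 hidden layers, 100 epochs, batch 64,
    learning rate 0.02, dropout 0.2, nadam)."""

    direction: str = "bi"               # "uni" | "bi"
    units: int = 100
    hidden_layers: int = 2
    epochs: int = 100
    batch_size: int = 64
    learning_rate: float = 0.02
    dropout: float = 0.2
    optimizer: str = "nadam"
    seed: int = 0
    bidirectional_combiner: str = "concat"   # "concat" | "paper_eq20"
    timesteps: int | None = None        # T_s; inferred from the data if None
    shared_bias: bool = False

    def __post_init__(self) -> None:
        if self.direction not in ("uni", "bi"):
            raise ValueError("direction must be 'uni' or 'bi'")
        if self.optimizer not in OPTIMIZERS:
            raise ValueError(f"optimizer must be one of {OPTIMIZERS}")
        if min(self.units, self.hidden_layers, self.batch_size) < 1:
            raise ValueError("units, hidden_layers, batch_size must be >= 1")
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")


# --------------------------------------------------------------------------
# single-cell operation (spec-level, explicit gates)
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class GateState:
    """Gate activations of one cell step: all gates in (0,1), candidate in
    (−1,1)."""

    input_gate: np.ndarray
    forget_gate: np.ndarray
    output_gate: np.ndarray
    candidate: np.ndarray
    cell: np.ndarray
    hidden: np.ndarray


@dataclass(frozen=True)
class CellParams:
    """Per-gate weights w_*, recurrent maps u_*, and biases D_*."""

    w_i: np.ndarray
    w_f: np.ndarray
    w_o: np.ndarray
    w_c: np.ndarray
    u_i: np.ndarray
    u_f: np.ndarray
    u_o: np.ndarray
    u_c: np.ndarray
    b_i: np.ndarray
    b_f: np.ndarray
    b_o: np.ndarray
    b_c: np.ndarray

    @classmethod
    def zeros(cls, units: int, input_dim: int) -> "CellParams":
        w = lambda: np.zeros((units, input_dim))
        u = lambda: np.zeros((units, units))
        b = lambda: np.zeros(units)
        return cls(w(), w(), w(), w(), u(), u(), u(), u(), b(), b(), b(), b())


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def cell_forward(
    x_t: np.ndarray,
    h_prev: np.ndarray,
    c_prev: np.ndarray,
    params: CellParams,
    literal_bracket: bool = False,
) -> tuple[np.ndarray, np.ndarray, GateState]:
    """One LSTM cell step; returns (h_t, C_t, GateState).

    ``literal_bracket`` computes w·(x_t + u·h_{t−1}) instead of the
    standard affine map w·x_t + u·h_{t−1}; it requires u·h_{t−1} to have
    the input width (units == input width).
    """
    x_t = np.asarray(x_t, dtype=float)
    h_prev = np.asarray(h_prev, dtype=float)
    c_prev = np.asarray(c_prev, dtype=float)
    H, D = params.w_i.shape
    if x_t.shape[-1] != D or h_prev.shape[-1] != H or c_prev.shape[-1] != H:
        raise ValueError(
            f"shape mismatch: x has width {x_t.shape[-1]} (need {D}), "
            f"h/C have width {h_prev.shape[-1]}/{c_prev.shape[-1]} (need {H})"
        )

    def pre(w, u, b):
        if literal_bracket:
            if u.shape[0] != D:
                raise ValueError(
                    "literal bracketing needs u·h to have the input width"
                )
            return w @ (x_t + u @ h_prev) + b
        return w @ x_t + u @ h_prev + b

    i = _sigmoid(pre(params.w_i, params.u_i, params.b_i))
    f = _sigmoid(pre(params.w_f, params.u_f, params.b_f))
    o = _sigmoid(pre(params.w_o, params.u_o, params.b_o))
    g = np.tanh(pre(params.w_c, params.u_c, params.b_c))
    c = f * c_prev + i * g
    h = o * np.tanh(c)
    return h, c, GateState(i, f, o, g, c, h)


def bidirectional_combine(
    h_forward: np.ndarray,
    h_backward: np.ndarray,
    config: LSTMConfig | None = None,
    output_gate: np.ndarray | None = None,
    candidate: np.ndarray | None = None,
) -> np.ndarray:
    """Combine the two directional passes.

    Default (``concat``): concatenate the final forward and backward hidden
    states into a 2d-dimensional representation.  ``paper_eq20``: the
    convex mixture (1 − O_t) ⊙ h_backward + O_t ⊙ C̃_t, kept for fidelity
    experiments (``h_backward`` plays the previous-hidden role there and
    ``output_gate``/``candidate`` must be supplied).
    """
    mode = config.bidirectional_combiner if config is not None else "concat"
    h_forward = np.asarray(h_forward, dtype=float)
    h_backward = np.asarray(h_backward, dtype=float)
    if mode == "concat":
        if h_forward.shape != h_backward.shape:
            raise ValueError("forward/backward state lengths differ")
        return np.concatenate([h_forward, h_backward], axis=-1)
    if mode == "paper_eq20":
        if output_gate is None or candidate is None:
            raise ValueError("paper_eq20 combiner needs output_gate and candidate")
        o = np.asarray(output_gate, dtype=float)
        g = np.asarray(candidate, dtype=float)
        if not (o.shape == g.shape == h_backward.shape):
            raise ValueError("paper_eq20 operands must share one shape")
        return (1.0 - o) * h_backward + o * g
    raise ValueError(f"unknown combiner {mode!r}")


# --------------------------------------------------------------------------
# batched layers (internal representation: W stacked [i, f, o, g])
# --------------------------------------------------------------------------

def _init_layer(rng: np.random.Generator, units: int, dim: int) -> dict:
    lim_w = np.sqrt(6.0 / (dim + units))
    lim_u = np.sqrt(6.0 / (2 * units))
    W = rng.uniform(-lim_w, lim_w, (4 * units, dim))
    U = rng.uniform(-lim_u, lim_u, (4 * units, units))
    b = np.zeros(4 * units)
    b[units:2 * units] = 1.0  # forget-gate bias starts open
    return {"W": W, "U": U, "b": b}


def _cell_seq_forward(p: dict, X: np.ndarray):
    """Run one direction over X (B, T, D); returns (H_seq, cache)."""
    B, T, D = X.shape
    H = p["U"].shape[1]
    h = np.zeros((B, H))
    c = np.zeros((B, H))
    H_seq = np.empty((B, T, H))
    cache = []
    for t in range(T):
        z = X[:, t] @ p["W"].T + h @ p["U"].T + p["b"]
        i = _sigmoid(z[:, :H])
        f = _sigmoid(z[:, H:2 * H])
        o = _sigmoid(z[:, 2 * H:3 * H])
        g = np.tanh(z[:, 3 * H:])
        c_new = f * c + i * g
        tanh_c = np.tanh(c_new)
        h_new = o * tanh_c
        cache.append((X[:, t], h, c, i, f, o, g, tanh_c))
        h, c = h_new, c_new
        H_seq[:, t] = h
    return H_seq, cache


def _cell_seq_backward(p: dict, cache, dH_seq: np.ndarray):
    """BPTT for one direction; returns (dX, grads dict)."""
    B, T, H = dH_seq.shape
    D = p["W"].shape[1]
    dW = np.zeros_like(p["W"])
    dU = np.zeros_like(p["U"])
    db = np.zeros_like(p["b"])
    dX = np.zeros((B, T, D))
    dh_next = np.zeros((B, H))
    dc_next = np.zeros((B, H))
    for t in range(T - 1, -1, -1):
        x_t, h_prev, c_prev, i, f, o, g, tanh_c = cache[t]
        dh = dH_seq[:, t] + dh_next
        do = dh * tanh_c
        dc = dc_next + dh * o * (1.0 - tanh_c**2)
        df = dc * c_prev
        di = dc * g
        dg = dc * i
        dz = np.concatenate(
            [
                di * i * (1.0 - i),
                df * f * (1.0 - f),
                do * o * (1.0 - o),
                dg * (1.0 - g**2),
            ],
            axis=1,
        )
        dW += dz.T @ x_t
        dU += dz.T @ h_prev
        db += dz.sum(axis=0)
        dX[:, t] = dz @ p["W"]
        dh_next = dz @ p["U"]
        dc_next = dc * f
    return dX, {"W": dW, "U": dU, "b": db}


class _Network:
    """Stacked (bi)LSTM + softmax head; pure NumPy, explicit gradients."""

    def __init__(self, config: LSTMConfig, input_dim: int, n_classes: int):
        self.config = config
        self.n_classes = n_classes
        rng = np.random.default_rng(config.seed)
        self.layers: list[dict] = []
        dim = input_dim
        for _ in range(config.hidden_layers):
            layer = {"fw": _init_layer(rng, config.units, dim)}
            if config.direction == "bi":
                layer["bw"] = _init_layer(rng, config.units, dim)
                dim = 2 * config.units
            else:
                dim = config.units
            self.layers.append(layer)
        lim = np.sqrt(6.0 / (dim + n_classes))
        self.head = {
            "W": rng.uniform(-lim, lim, (n_classes, dim)),
            "b": np.zeros(n_classes),
        }
        self.rep_dim = dim

    # -- parameter plumbing ------------------------------------------------

    def parameters(self) -> list[np.ndarray]:
        out = []
        for layer in self.layers:
            for d in layer.values():
                out += [d["W"], d["U"], d["b"]]
        out += [self.head["W"], self.head["b"]]
        return out

    def set_parameters(self, arrays: Sequence[np.ndarray]) -> None:
        for old, new in zip(self.parameters(), arrays):
            old[...] = new

    # -- forward / backward -------------------------------------------------

    def forward(self, X: np.ndarray, train_rng: np.random.Generator | None = None):
        """X (B, T, D) → (probs (B, C), cache)."""
        S = X
        caches = []
        drop = self.config.dropout
        for layer in self.layers:
            H_fw, cache_fw = _cell_seq_forward(layer["fw"], S)
            if "bw" in layer:
                H_bw_rev, cache_bw = _cell_seq_forward(layer["bw"], S[:, ::-1])
                H_bw = H_bw_rev[:, ::-1]
                out = np.concatenate([H_fw, H_bw], axis=2)
            else:
                cache_bw = None
                out = H_fw
            mask = None
            if train_rng is not None and drop > 0.0:
                mask = (train_rng.random(out.shape) >= drop) / (1.0 - drop)
                out = out * mask
            caches.append((cache_fw, cache_bw, mask, S.shape))
            S = out
        # classifier reads: uni → last step; bi → fw last step ⊕ bw first step
        if self.config.direction == "bi":
            Hn = self.config.units
            rep = np.concatenate([S[:, -1, :Hn], S[:, 0, Hn:]], axis=1)
        else:
            rep = S[:, -1, :]
        logits = rep @ self.head["W"].T + self.head["b"]
        logits -= logits.max(axis=1, keepdims=True)
        expz = np.exp(logits)
        probs = expz / expz.sum(axis=1, keepdims=True)
        return probs, (caches, S, rep)

    def loss_and_grads(self, X: np.ndarray, y: np.ndarray,
                       train_rng: np.random.Generator | None = None):
        """Mean cross-entropy and gradients in `parameters()` order."""
        B = X.shape[0]
        probs, (caches, S, rep) = self.forward(X, train_rng)
        eps = 1e-12
        loss = float(-np.mean(np.log(probs[np.arange(B), y] + eps)))
        dlogits = probs.copy()
        dlogits[np.arange(B), y] -= 1.0
        dlogits /= B
        gW_out = dlogits.T @ rep
        gb_out = dlogits.sum(axis=0)
        drep = dlogits @ self.head["W"]

        T = X.shape[1]
        dS = np.zeros_like(S)
        if self.config.direction == "bi":
            Hn = self.config.units
            dS[:, -1, :Hn] = drep[:, :Hn]
            dS[:, 0, Hn:] = drep[:, Hn:]
        else:
            dS[:, -1, :] = drep

        grads_layers: list[dict] = [None] * len(self.layers)
        for li in range(len(self.layers) - 1, -1, -1):
            layer = self.layers[li]
            cache_fw, cache_bw, mask, in_shape = caches[li]
            if mask is not None:
                dS = dS * mask
            if "bw" in layer:
                Hn = self.config.units
                dX_fw, g_fw = _cell_seq_backward(
                    layer["fw"], cache_fw, dS[..., :Hn]
                )
                dX_bw_rev, g_bw = _cell_seq_backward(
                    layer["bw"], cache_bw, dS[:, ::-1, Hn:]
                )
                dS = dX_fw + dX_bw_rev[:, ::-1]
                grads_layers[li] = {"fw": g_fw, "bw": g_bw}
            else:
                dX_fw, g_fw = _cell_seq_backward(layer["fw"], cache_fw, dS)
                dS = dX_fw
                grads_layers[li] = {"fw": g_fw}

        grads: list[np.ndarray] = []
        for li, layer in enumerate(self.layers):
            for key in layer.keys():
                g = grads_layers[li][key]
                grads += [g["W"], g["U"], g["b"]]
        grads += [gW_out, gb_out]
        return loss, grads, probs


# --------------------------------------------------------------------------
# optimizers
# --------------------------------------------------------------------------

class _Optimizer:
    def __init__(self, lr: float):
        self.lr = lr
        self.t = 0

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        raise NotImplementedError


class Adam(_Optimizer):
    def __init__(self, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        super().__init__(lr)
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = None
        self.v = None

    def step(self, params, grads):
        if self.m is None:
            self.m = [np.zeros_like(p) for p in params]
            self.v = [np.zeros_like(p) for p in params]
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m[...] = b1 * m + (1 - b1) * g
            v[...] = b2 * v + (1 - b2) * g * g
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class RMSprop(_Optimizer):
    def __init__(self, lr, rho=0.9, eps=1e-8):
        super().__init__(lr)
        self.rho, self.eps = rho, eps
        self.v = None

    def step(self, params, grads):
        if self.v is None:
            self.v = [np.zeros_like(p) for p in params]
        self.t += 1
        for p, g, v in zip(params, grads, self.v):
            v[...] = self.rho * v + (1 - self.rho) * g * g
            p -= self.lr * g / (np.sqrt(v) + self.eps)


class Nadam(_Optimizer):
    """Adam with Nesterov momentum."""

    def __init__(self, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        super().__init__(lr)
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = None
        self.v = None

    def step(self, params, grads):
        if self.m is None:
            self.m = [np.zeros_like(p) for p in params]
            self.v = [np.zeros_like(p) for p in params]
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m[...] = b1 * m + (1 - b1) * g
            v[...] = b2 * v + (1 - b2) * g * g
            mhat = m / (1 - b1 ** (self.t + 1))
            vhat = v / (1 - b2**self.t)
            nesterov = b1 * mhat + (1 - b1) * g / (1 - b1**self.t)
            p -= self.lr * nesterov / (np.sqrt(vhat) + self.eps)


class Adamax(_Optimizer):
    def __init__(self, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        super().__init__(lr)
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = None
        self.u = None

    def step(self, params, grads):
        if self.m is None:
            self.m = [np.zeros_like(p) for p in params]
            self.u = [np.zeros_like(p) for p in params]
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, g, m, u in zip(params, grads, self.m, self.u):
            m[...] = b1 * m + (1 - b1) * g
            u[...] = np.maximum(b2 * u, np.abs(g))
            p -= self.lr / (1 - b1**self.t) * m / (u + self.eps)


def make_optimizer(name: str, lr: float) -> _Optimizer:
    return {"adam": Adam, "rmsprop": RMSprop, "nadam": Nadam,
            "adamax": Adamax}[name](lr)


# --------------------------------------------------------------------------
# model / results
# --------------------------------------------------------------------------

def _extract_xy(data) -> tuple[np.ndarray, np.ndarray, list[str], np.ndarray]:
    """(features (n, T_s), labels, feature names, class labels)."""
    is_ = data.system if isinstance(data, OrdinalSystem) else data
    if not isinstance(is_, InformationSystem):
        raise TypeError("expected an OrdinalSystem or InformationSystem")
    if is_.decision_attribute is None:
        raise TrainingError("no decision attribute to train on")
    feats = is_.conditional_attributes()
    X = np.column_stack([is_.column(a) for a in feats])
    y_raw = is_.column(is_.decision_attribute)
    classes = np.unique(y_raw)
    if len(classes) < 2:
        raise TrainingError("decision attribute has a single class")
    y = np.searchsorted(classes, y_raw)
    return X, y.astype(int), feats, classes


class LSTMClassifier:
    """Model object: configuration + data schema; ``fit`` → results."""

    def __init__(self, config: LSTMConfig | None = None):
        self.config = config or LSTMConfig()

    def fit(
        self,
        data: OrdinalSystem | InformationSystem,
        split: tuple[float, float] = (0.7, 0.3),
    ) -> "TrainedLSTM":
        """Stratified train/test split, then BPTT training.

        ``split`` is the (train, test) fraction pair; per-class membership
        is preserved.  Returns a :class:`TrainedLSTM` carrying the
        per-epoch (accuracy, loss) history and both split indices.
        """
        cfg = self.config
        X, y, feats, classes = _extract_xy(data)
        if abs(sum(split) - 1.0) > 1e-9 or min(split) < 0:
            raise ValueError("split fractions must be nonnegative and sum to 1")
        rng = np.random.default_rng(cfg.seed)
        train_idx, test_idx = _stratified_split(y, split[0], rng)

        mean = X[train_idx].mean(axis=0)
        sd = X[train_idx].std(axis=0)
        sd[sd == 0] = 1.0
        Xs = (X - mean) / sd
        seq = Xs[:, :, None]  # one feature per timestep

        net = _Network(cfg, input_dim=1, n_classes=len(classes))
        opt = make_optimizer(cfg.optimizer, cfg.learning_rate)
        history: list[tuple[float, float]] = []
        n_train = len(train_idx)
        for epoch in range(cfg.epochs):
            order = rng.permutation(n_train)
            losses = []
            correct = 0
            for start in range(0, n_train, cfg.batch_size):
                batch = train_idx[order[start:start + cfg.batch_size]]
                loss, grads, probs = net.loss_and_grads(
                    seq[batch], y[batch],
                    train_rng=rng if cfg.dropout > 0 else None,
                )
                if not np.isfinite(loss):
                    raise DivergenceError(epoch)
                opt.step(net.parameters(), grads)
                losses.append(loss * len(batch))
                correct += int((probs.argmax(axis=1) == y[batch]).sum())
            history.append((correct / n_train, sum(losses) / n_train))
        return TrainedLSTM(
            config=cfg,
            network=net,
            classes=classes,
            feature_names=feats,
            scaler=(mean, sd),
            training_history=history,
            train_idx=train_idx,
            test_idx=test_idx,
            data_X=X,
            data_y=y,
        )


def _stratified_split(y: np.ndarray, train_frac: float,
                      rng: np.random.Generator):
    train, test = [], []
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        idx = idx[rng.permutation(len(idx))]
        cut = int(round(train_frac * len(idx)))
        train += list(idx[:cut])
        test += list(idx[cut:])
    return np.sort(np.array(train, int)), np.sort(np.array(test, int))


@dataclass
class TrainedLSTM:
    """Fit results: parameters, history, and prediction methods."""

    config: LSTMConfig
    network: _Network
    classes: np.ndarray
    feature_names: list[str]
    scaler: tuple[np.ndarray, np.ndarray]
    training_history: list[tuple[float, float]]
    train_idx: np.ndarray
    test_idx: np.ndarray
    data_X: np.ndarray = field(repr=False, default=None)
    data_y: np.ndarray = field(repr=False, default=None)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != len(self.feature_names):
            raise ValueError(
                f"expected {len(self.feature_names)} features, got {X.shape[1]}"
            )
        mean, sd = self.scaler
        seq = ((X - mean) / sd)[:, :, None]
        probs, _ = self.network.forward(seq, train_rng=None)
        return probs

    def predict(self, data) -> tuple[np.ndarray, np.ndarray]:
        """(stage labels, class probabilities) for rows of a system/array."""
        if isinstance(data, (OrdinalSystem, InformationSystem)):
            is_ = data.system if isinstance(data, OrdinalSystem) else data
            missing = [a for a in self.feature_names
                       if a not in is_.attribute_names]
            if missing:
                raise ValueError(f"missing feature column(s): {missing}")
            X = np.column_stack([is_.column(a) for a in self.feature_names])
        else:
            X = np.asarray(data, dtype=float)
        probs = self.predict_proba(X)
        labels = self.classes[probs.argmax(axis=1)]
        return labels, probs

    def _split_accuracy(self, idx: np.ndarray) -> float:
        probs = self.predict_proba(self.data_X[idx])
        return float((probs.argmax(axis=1) == self.data_y[idx]).mean())

    @property
    def train_accuracy(self) -> float:
        return self._split_accuracy(self.train_idx)

    @property
    def test_accuracy(self) -> float:
        return self._split_accuracy(self.test_idx)

    def summary(self) -> str:
        c = self.config
        lines = [
            f"{c.direction}directional LSTM "
            f"({c.hidden_layers} layer(s) × {c.units} units, "
            f"optimizer={c.optimizer}, lr={c.learning_rate}, "
            f"dropout={c.dropout}, batch={c.batch_size})",
            f"classes: {list(self.classes)}   T_s = {len(self.feature_names)}",
            f"epochs run: {len(self.training_history)}",
        ]
        if self.training_history:
            acc, loss = self.training_history[-1]
            lines.append(f"final epoch: acc={acc:.4f} loss={loss:.4f}")
        if self.data_X is not None:
            lines.append(
                f"train-split accuracy = {self.train_accuracy:.4f}   "
                f"test-split accuracy = {self.test_accuracy:.4f}"
            )
        return "\n".join(lines)


def train(
    ordinal: OrdinalSystem | InformationSystem,
    config: LSTMConfig | None = None,
    split: tuple[float, float] = (0.7, 0.3),
) -> TrainedLSTM:
    """Functional wrapper: ``LSTMClassifier(config).fit(ordinal, split)``."""
    return LSTMClassifier(config).fit(ordinal, split)


def predict(model: TrainedLSTM, rows) -> tuple[np.ndarray, np.ndarray]:
    """Per-row stage label and class probabilities (sum to 1 per row)."""
    return model.predict(rows)
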