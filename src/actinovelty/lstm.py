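"""Stacked-LSTM sequence forecaster, implemented from first principles.

The model maps the last 6 s of synchronized 4-channel vertical acceleration
(60 time steps) to the next 2 s (20 steps x 4 channels = 80 values):

* layer 1: LSTM, 50 memory units, input size 4;
* layer 2: LSTM, 20 memory units, input = layer-1 hidden sequence;
* a fully connected affine map from layer 2's final hidden state to the 80
  predicted values, reshaped time-major to 20x4.

Each memory cell follows the standard gate equations with logistic sigmoid
``s`` and elementwise products::

    f_t = s(Wf x_t + Uf h_{t-1} + bf)          (forget gate)
    i_t = s(Wi x_t + Ui h_{t-1} + bi)          (input gate)
    o_t = s(Wo x_t + Uo h_{t-1} + bo)          (output gate)
    c_t = f_t * c_{t-1} + i_t * tanh(Wc x_t + Uc h_{t-1} + bc)
    h_t = y_t = o_t * tanh(c_t)

Weights are shared across time steps within a layer.  Training minimises
the mean square error of the 80-value prediction by mini-batch gradient
descent with adaptive moment estimation (Adam) and hand-written
backpropagation through time; no external NN framework is involved, so a
fitted model is a plain collection of numpy arrays.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

N_CHANNELS = 4
INPUT_STEPS = 60
OUTPUT_STEPS = 20


class ForecasterError(ValueError):
    pass


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


@dataclass
class LSTMLayerParams:
    """Gate weights of one LSTM layer: ``W*`` input-to-gate (D x H),
    ``U*`` recurrent (H x H), ``b*`` biases (H,)."""

    Wf: np.ndarray
    Wi: np.ndarray
    Wo: np.ndarray
    Wc: np.ndarray
    Uf: np.ndarray
    Ui: np.ndarray
    Uo: np.ndarray
    Uc: np.ndarray
    bf: np.ndarray
    bi: np.ndarray
    bo: np.ndarray
    bc: np.ndarray

    def __post_init__(self) -> None:
        D, H = self.Wf.shape
        for name in ("Wi", "Wo", "Wc"):
            if getattr(self, name).shape != (D, H):
                raise ForecasterError(f"{name} shape mismatch")
        for name in ("Uf", "Ui", "Uo", "Uc"):
            if getattr(self, name).shape != (H, H):
                raise ForecasterError(f"{name} shape mismatch")
        for name in ("bf", "bi", "bo", "bc"):
            if getattr(self, name).shape != (H,):
                raise ForecasterError(f"{name} shape mismatch")

    @property
    def input_size(self) -> int:
        return self.Wf.shape[0]

    @property
    def hidden_size(self) -> int:
        return self.Wf.shape[1]

    @classmethod
    def init(cls, input_size: int, hidden_size: int, rng) -> "LSTMLayerParams":
        """Glorot-uniform weights, zero biases except forget bias 1
        (the usual remedy against premature forgetting early in training)."""

        def glorot(n_in, n_out):
            lim = np.sqrt(6.0 / (n_in + n_out))
            return rng.uniform(-lim, lim, size=(n_in, n_out))

        kw = {f"W{g}": glorot(input_size, hidden_size) for g in "fioc"}
        kw |= {f"U{g}": glorot(hidden_size, hidden_size) for g in "fioc"}
        kw |= {f"b{g}": np.zeros(hidden_size) for g in "ioc"}
        kw["bf"] = np.ones(hidden_size)
        return cls(**kw)

    def arrays(self) -> list:
        return [getattr(self, n) for n in _LAYER_FIELDS]


_LAYER_FIELDS = ("Wf", "Wi", "Wo", "Wc", "Uf", "Ui", "Uo", "Uc", "bf", "bi", "bo", "bc")


@dataclass
class CellState:
    """Hidden output ``h`` and memory ``c`` of one LSTM layer."""

    h: np.ndarray
    c: np.ndarray

    @classmethod
    def zero(cls, hidden_size: int, batch: int | None = None) -> "CellState":
        shape = (hidden_size,) if batch is None else (batch, hidden_size)
        return cls(h=np.zeros(shape), c=np.zeros(shape))


def lstm_cell_step(x: np.ndarray, state: CellState, params: LSTMLayerParams) -> CellState:
    """One time step of the gate equations (single vector or batch)."""
    x = np.asarray(x, dtype=float)
    if x.shape[-1] != params.input_size:
        raise ForecasterError(
            f"input size {x.shape[-1]} != expected {params.input_size}"
        )
    if state.h.shape[-1] != params.hidden_size:
        raise ForecasterError("state dimension mismatch")
    f = _sigmoid(x @ params.Wf + state.h @ params.Uf + params.bf)
    i = _sigmoid(x @ params.Wi + state.h @ params.Ui + params.bi)
    o = _sigmoid(x @ params.Wo + state.h @ params.Uo + params.bo)
    c = f * state.c + i * np.tanh(x @ params.Wc + state.h @ params.Uc + params.bc)
    h = o * np.tanh(c)
    return CellState(h=h, c=c)


@dataclass
class ForecasterParams:
    """All parameters of the stacked forecaster plus training metadata."""

    layers: list  # of LSTMLayerParams, input sizes chained
    Wd: np.ndarray  # (H_last, OUTPUT_STEPS * N_CHANNELS)
    bd: np.ndarray  # (OUTPUT_STEPS * N_CHANNELS,)
    metadata: dict = field(default_factory=dict)
    history: list = field(default_factory=list)  # (epoch, train_mse, val_mse)

    def __post_init__(self) -> None:
        if self.Wd.shape != (self.layers[-1].hidden_size, OUTPUT_STEPS * N_CHANNELS):
            raise ForecasterError("dense layer shape mismatch")
        if self.bd.shape != (OUTPUT_STEPS * N_CHANNELS,):
            raise ForecasterError("dense bias shape mismatch")
        for a, b in zip(self.layers[:-1], self.layers[1:]):
            if b.input_size != a.hidden_size:
                raise ForecasterError("stacked layer sizes are inconsistent")

    def arrays(self) -> list:
        out = []
        for layer in self.layers:
            out.extend(layer.arrays())
        out.extend([self.Wd, self.bd])
        return out

    def copy(self) -> "ForecasterParams":
        layers = [
            LSTMLayerParams(**{n: getattr(p, n).copy() for n in _LAYER_FIELDS})
            for p in self.layers
        ]
        return ForecasterParams(
            layers=layers,
            Wd=self.Wd.copy(),
            bd=self.bd.copy(),
            metadata=dict(self.metadata),
            history=list(self.history),
        )

    @classmethod
    def init(
        cls,
        hidden_sizes: tuple = (50, 20),
        input_size: int = N_CHANNELS,
        seed: int = 0,
        metadata: dict | None = None,
    ) -> "ForecasterParams":
        rng = np.random.default_rng(seed)
        layers = []
        d = input_size
        for h in hidden_sizes:
            layers.append(LSTMLayerParams.init(d, h, rng))
            d = h
        out_dim = OUTPUT_STEPS * N_CHANNELS
        lim = np.sqrt(6.0 / (d + out_dim))
        return cls(
            layers=layers,
            Wd=rng.uniform(-lim, lim, size=(d, out_dim)),
            bd=np.zeros(out_dim),
            metadata={"seed": seed, "hidden_sizes": tuple(hidden_sizes)}
            | (metadata or {}),
        )


@dataclass
class TrainConfig:
    """Optimisation hyperparameters (unconstrained by the study design)."""

    learning_rate: float = 1e-3
    batch_size: int = 64
    max_epochs: int = 30
    patience: int = 5
    validation_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.learning_rate, self.batch_size, self.patience) <= 0:
            raise ForecasterError("learning rate, batch size, patience must be > 0")
        if self.max_epochs < 0:
            raise ForecasterError("max_epochs must be >= 0")
        if not (0.0 < self.validation_fraction < 1.0):
            raise ForecasterError("validation_fraction must be in (0, 1)")


# ---------------------------------------------------------------------------
# Forward / backward


def _layer_forward(p: LSTMLayerParams, X: np.ndarray) -> dict:
    """Run one layer over a batch sequence, caching gate activations."""
    B, T, _ = X.shape
    H = p.hidden_size
    cache = {k: np.empty((B, T, H)) for k in ("f", "i", "o", "g", "c", "h")}
    h = np.zeros((B, H))
    c = np.zeros((B, H))
    for t in range(T):
        xt = X[:, t]
        f = _sigmoid(xt @ p.Wf + h @ p.Uf + p.bf)
        i = _sigmoid(xt @ p.Wi + h @ p.Ui + p.bi)
        o = _sigmoid(xt @ p.Wo + h @ p.Uo + p.bo)
        g = np.tanh(xt @ p.Wc + h @ p.Uc + p.bc)
        c = f * c + i * g
        h = o * np.tanh(c)
        for k, v in (("f", f), ("i", i), ("o", o), ("g", g), ("c", c), ("h", h)):
            cache[k][:, t] = v
    cache["X"] = X
    return cache


def _forward_cached(params: ForecasterParams, X: np.ndarray) -> tuple:
    caches = []
    seq = X
    for layer in params.layers:
        cache = _layer_forward(layer, seq)
        caches.append(cache)
        seq = cache["h"]
    h_last = seq[:, -1]
    pred = h_last @ params.Wd + params.bd
    return pred, caches


def forward(params: ForecasterParams, x: np.ndarray) -> np.ndarray:
    """Predict the next 2 s from a 6 s input.

    Accepts a single (60, 4) window or a (B, 60, 4) batch; returns (20, 4)
    or (B, 20, 4).  The 80-value dense output is laid out time-major:
    value ``t * 4 + ch`` is channel ``ch`` at predicted step ``t``.
    """
    x = np.asarray(x, dtype=float)
    single = x.ndim == 2
    if single:
        x = x[None]
    if x.shape[1:] != (INPUT_STEPS, params.layers[0].input_size):
        raise ForecasterError(
            f"expected input shape (*, {INPUT_STEPS}, "
            f"{params.layers[0].input_size}), got {x.shape}"
        )
    if not np.all(np.isfinite(x)):
        raise ForecasterError("non-finite input")
    pred, _ = _forward_cached(params, x)
    pred = pred.reshape(-1, OUTPUT_STEPS, N_CHANNELS)
    return pred[0] if single else pred


def _layer_backward(
    p: LSTMLayerParams, cache: dict, dh_ext: np.ndarray, need_dx: bool
) -> tuple:
    """BPTT through one layer.

    ``dh_ext`` is the loss gradient w.r.t. the layer's hidden output at each
    step (zeros except where the hidden sequence feeds something).  Returns
    (grads list matching ``arrays()`` order, dX or None).
    """
    X = cache["X"]
    B, T, H = cache["h"].shape
    grads = {n: np.zeros_like(getattr(p, n)) for n in _LAYER_FIELDS}
    dX = np.empty_like(X) if need_dx else None
    dh_rec = np.zeros((B, H))
    dc_rec = np.zeros((B, H))
    for t in range(T - 1, -1, -1):
        f = cache["f"][:, t]
        i = cache["i"][:, t]
        o = cache["o"][:, t]
        g = cache["g"][:, t]
        c = cache["c"][:, t]
        tanh_c = np.tanh(c)
        c_prev = cache["c"][:, t - 1] if t > 0 else np.zeros((B, H))
        h_prev = cache["h"][:, t - 1] if t > 0 else np.zeros((B, H))
        dh = dh_ext[:, t] + dh_rec
        dc = dc_rec + dh * o * (1.0 - tanh_c**2)
        da_o = dh * tanh_c * o * (1.0 - o)
        da_f = dc * c_prev * f * (1.0 - f)
        da_i = dc * g * i * (1.0 - i)
        da_c = dc * i * (1.0 - g**2)
        xt = X[:, t]
        for gate, da in (("f", da_f), ("i", da_i), ("o", da_o), ("c", da_c)):
            grads[f"W{gate}"] += xt.T @ da
            grads[f"U{gate}"] += h_prev.T @ da
            grads[f"b{gate}"] += da.sum(axis=0)
        dh_rec = (
            da_f @ p.Uf.T + da_i @ p.Ui.T + da_o @ p.Uo.T + da_c @ p.Uc.T
        )
        dc_rec = dc * f
        if need_dx:
            dX[:, t] = (
                da_f @ p.Wf.T + da_i @ p.Wi.T + da_o @ p.Wo.T + da_c @ p.Wc.T
            )
    return [grads[n] for n in _LAYER_FIELDS], dX


def _loss_and_grads(
    params: ForecasterParams, X: np.ndarray, Y: np.ndarray
) -> tuple:
    """Mean-square error over a batch and gradients in ``arrays()`` order."""
    pred, caches = _forward_cached(params, X)
    resid = pred - Y
    loss = float(np.mean(resid**2))
    dpred = 2.0 * resid / resid.size
    h_last = caches[-1]["h"][:, -1]
    dWd = h_last.T @ dpred
    dbd = dpred.sum(axis=0)
    dh_last = dpred @ params.Wd.T
    grads_per_layer = [None] * len(params.layers)
    B, T, _ = X.shape
    dh_ext = np.zeros_like(caches[-1]["h"])
    dh_ext[:, -1] = dh_last
    for li in range(len(params.layers) - 1, -1, -1):
        grads, dX = _layer_backward(
            params.layers[li], caches[li], dh_ext, need_dx=li > 0
        )
        grads_per_layer[li] = grads
        if li > 0:
            dh_ext = dX
    flat = []
    for grads in grads_per_layer:
        flat.extend(grads)
    flat.extend([dWd, dbd])
    return loss, flat


def evaluate_mse(params: ForecasterParams, X: np.ndarray, Y: np.ndarray) -> float:
    pred, _ = _forward_cached(params, X)
    return float(np.mean((pred - Y) ** 2))


# ---------------------------------------------------------------------------
# Training


def windows_to_arrays(windows: list) -> tuple:
    """Stack WindowPairs into (M, 60, 4) inputs and (M, 80) flat targets."""
    X = np.stack([w.x for w in windows])
    Y = np.stack([w.y.reshape(-1) for w in windows])
    return X, Y


def train(
    windows: list,
    config: TrainConfig | None = None,
    bin: int | None = None,
    bins=None,
    hidden_sizes: tuple = (50, 20),
) -> ForecasterParams:
    """Fit the forecaster to control-group windows by Adam on the MSE.

    With ``bin`` given (and ``bins`` the IntensityBins), training is
    restricted to windows whose combined SD falls in that bin — one model
    per movement-intensity interval.  Seeded and single-threaded, hence
    reproducible; early stopping restores the parameters with the best
    held-out validation MSE, and the returned parameters never have a worse
    training MSE than the seeded initialisation.
    """
    from .segmentation import assign_bin  # local import to avoid cycles

    config = config or TrainConfig()
    if bin is not None:
        if bins is None:
            raise ForecasterError("bin filtering requires the IntensityBins")
        windows = [w for w in windows if assign_bin(w.intensity_sd, bins) == bin]
    if len(windows) == 0:
        raise ForecasterError("empty training set after bin filtering")
    X, Y = windows_to_arrays(windows)
    params = ForecasterParams.init(
        hidden_sizes=hidden_sizes,
        input_size=X.shape[2],
        seed=config.seed,
        metadata={"bin": "all" if bin is None else int(bin)},
    )
    rng = np.random.default_rng(config.seed)
    M = X.shape[0]
    n_val = int(round(config.validation_fraction * M)) if M >= 2 else 0
    order = rng.permutation(M)
    val_idx, tr_idx = order[:n_val], order[n_val:]
    Xtr, Ytr = X[tr_idx], Y[tr_idx]
    Xval, Yval = (X[val_idx], Y[val_idx]) if n_val else (Xtr, Ytr)

    init_train_mse = evaluate_mse(params, Xtr, Ytr)
    best = params.copy()
    best_val = evaluate_mse(params, Xval, Yval)
    params.history.append((0, init_train_mse, best_val))

    arrays = params.arrays()
    m_state = [np.zeros_like(a) for a in arrays]
    v_state = [np.zeros_like(a) for a in arrays]
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    step = 0
    stale = 0
    for epoch in range(1, config.max_epochs + 1):
        perm = rng.permutation(len(tr_idx))
        epoch_loss = 0.0
        for start in range(0, len(perm), config.batch_size):
            idx = perm[start : start + config.batch_size]
            loss, grads = _loss_and_grads(params, Xtr[idx], Ytr[idx])
            epoch_loss += loss * len(idx)
            step += 1
            lr_t = (
                config.learning_rate
                * np.sqrt(1.0 - beta2**step)
                / (1.0 - beta1**step)
            )
            for a, gr, m, v in zip(arrays, grads, m_state, v_state):
                m *= beta1
                m += (1.0 - beta1) * gr
                v *= beta2
                v += (1.0 - beta2) * gr**2
                a -= lr_t * m / (np.sqrt(v) + eps)
        val_mse = evaluate_mse(params, Xval, Yval)
        params.history.append((epoch, epoch_loss / len(tr_idx), val_mse))
        if val_mse < best_val:
            best_val = val_mse
            best = params.copy()
            best.history = list(params.history)
            stale = 0
        else:
            stale += 1
            if stale >= config.patience:
                break
    # guarantee no regression w.r.t. the seeded initialisation
    if evaluate_mse(best, Xtr, Ytr) > init_train_mse:
        best = ForecasterParams.init(
            hidden_sizes=hidden_sizes,
            input_size=X.shape[2],
            seed=config.seed,
            metadata={"bin": "all" if bin is None else int(bin)},
        )
    best.metadata |= {
        "epochs_run": len(params.history) - 1,
        "n_train": int(len(tr_idx)),
        "n_val": int(n_val),
        "train_seed": config.seed,
    }
    return best


# ---------------------------------------------------------------------------
# Serialization: npz container with a JSON metadata header


def save_params(params: ForecasterParams, path) -> None:
    """Portable container: one array per parameter + a JSON header."""
    arrays = {}
    for li, layer in enumerate(params.layers):
        for n in _LAYER_FIELDS:
            arrays[f"layer{li}_{n}"] = getattr(layer, n)
    arrays["Wd"] = params.Wd
    arrays["bd"] = params.bd
    header = {
        "n_layers": len(params.layers),
        "metadata": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in params.metadata.items()
        },
        "history": [list(h) for h in params.history],
    }
    np.savez(path, __header__=np.frombuffer(json.dumps(header).encode(), dtype=np.uint8), **arrays)


def load_params(path) -> ForecasterParams:
    with np.load(path) as data:
        header = json.loads(bytes(data["__header__"]).decode())
        layers = [
            LSTMLayerParams(**{n: data[f"layer{li}_{n}"] for n in _LAYER_FIELDS})
            for li in range(header["n_layers"])
        ]
        params = ForecasterParams(layers=layers, Wd=data["Wd"], bd=data["bd"])
    params.metadata = header["metadata"]
    params.history = [tuple(h) for h in header["history"]]
    return params
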