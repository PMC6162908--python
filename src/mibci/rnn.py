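"""Gated recurrent networks over cropped feature slices.

A single recurrent layer (vanilla tanh, LSTM with peepholes, or GRU) is
unrolled over the ``tau`` time steps of each slice:

    h_t = sigma(W x_t + U h_{t-1} + b),        y = softmax(W_y h_tau + b_y)

The unroll depth equals the slice length, so "number of hidden layers"
below always means the number of unrolled time steps.  Training is
mini-batch backpropagation through time with Adam and dropout on the
non-recurrent connections (inputs and the pre-readout hidden state); the
loss is categorical cross-entropy averaged over the batch.  A regression
head (linear readout, squared error) supports autoregressive one-step
signal prediction, used to choose the optimal unroll depth.

Everything is plain numpy in float64; gradients are derived by hand and
verified against finite differences in the test suite.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .csp import FeatureSeries
from .sequential import TimeSlice, crop_slices

__all__ = [
    "RNNConfig",
    "RNNModel",
    "TrainingTrace",
    "PredictionAggregate",
    "init_model",
    "forward",
    "cross_entropy",
    "train",
    "predict_trial",
    "autoregressive_predict",
    "sweep_depth",
]

CELLS = ("vanilla", "lstm", "gru")
GATE_MODES = ("conventional_sigmoid", "relu_gates")


@dataclass
class RNNConfig:
    """Hyperparameters of one recurrent classifier.

    ``unroll_len`` (tau) is both the slice length and the unroll depth;
    ``gate_activation_mode`` selects sigmoid gates (default, bounded) or
    ReLU gates with a sigmoid LSTM cell-output activation.
    """

    cell: str = "gru"
    unroll_len: int = 20
    hidden_width: int = 32
    init_sigma: float = 0.2
    dropout_rate: float = 0.2
    max_iterations: int = 200
    learning_rate: float = 1e-3
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    adam_eps: float = 1e-8
    batch_size: int = 64
    seed: int = 0
    gate_activation_mode: str = "conventional_sigmoid"
    head: str = "classification"  # or "regression"
    readout: str = "final"  # or "mean" over unrolled steps

    def __post_init__(self) -> None:
        if self.cell not in CELLS:
            raise ValueError(f"unknown cell {self.cell!r}; choose from {CELLS}")
        if self.gate_activation_mode not in GATE_MODES:
            raise ValueError(f"unknown gate mode {self.gate_activation_mode!r}")
        if self.unroll_len < 1 or self.hidden_width < 1:
            raise ValueError("unroll_len and hidden_width must be >= 1")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.head not in ("classification", "regression"):
            raise ValueError(f"unknown head {self.head!r}")
        if self.readout not in ("final", "mean"):
            raise ValueError(f"unknown readout {self.readout!r}")


@dataclass
class RNNModel:
    """Weights plus the metadata needed to apply them to feature slices."""

    cfg: RNNConfig
    params: dict[str, np.ndarray]
    n_inputs: int
    n_outputs: int
    class_order: list[int] | None = None
    layout: list | None = None


@dataclass
class TrainingTrace:
    """Per-epoch loss and accuracy histories."""

    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    train_accuracy: list[float] = field(default_factory=list)
    val_accuracy: list[float] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.train_loss)


@dataclass
class PredictionAggregate:
    """Slice-level probabilities and their trial-level average."""

    slice_probs: np.ndarray  # (n_slices, n_classes)
    mean_probs: np.ndarray
    final_label: int


# ---------------------------------------------------------------- activations

def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _act(name: str, x: np.ndarray) -> np.ndarray:
    if name == "tanh":
        return np.tanh(x)
    if name == "sigmoid":
        return _sigmoid(x)
    if name == "relu":
        return np.maximum(x, 0.0)
    raise ValueError(name)


def _dact(name: str, pre: np.ndarray, post: np.ndarray) -> np.ndarray:
    if name == "tanh":
        return 1.0 - post * post
    if name == "sigmoid":
        return post * (1.0 - post)
    if name == "relu":
        return (pre > 0).astype(pre.dtype)
    raise ValueError(name)


def _gate_names(cfg: RNNConfig) -> tuple[str, str]:
    """(gate activation, LSTM cell-output activation) for the config."""
    if cfg.gate_activation_mode == "relu_gates":
        return "relu", "sigmoid"
    return "sigmoid", "tanh"


# -------------------------------------------------------------- initialization

def _param_shapes(cfg: RNNConfig, d: int, k: int) -> dict[str, tuple]:
    h = cfg.hidden_width
    shapes: dict[str, tuple] = {}
    if cfg.cell == "vanilla":
        shapes.update(W=(h, d), U=(h, h), b=(h,))
    elif cfg.cell == "lstm":
        for g in ("i", "f", "o", "g"):
            shapes[f"W{g}"] = (h, d)
            shapes[f"U{g}"] = (h, h)
            shapes[f"b{g}"] = (h,)
        for g in ("i", "f", "o"):  # peepholes
            shapes[f"p{g}"] = (h,)
    else:  # gru
        for g in ("z", "r", "h"):
            shapes[f"W{g}"] = (h, d)
            shapes[f"U{g}"] = (h, h)
            shapes[f"b{g}"] = (h,)
    shapes.update(Wy=(k, h), by=(k,))
    return shapes


def init_model(
    cfg: RNNConfig,
    input_rows: int,
    n_classes: int | None = None,
    class_order: list[int] | None = None,
    layout: list | None = None,
) -> RNNModel:
    """Draw all weights i.i.d. N(0, init_sigma^2); biases start at zero.

    For a classification head ``n_classes`` outputs are created (order given
    by ``class_order``); a regression head defaults to one output per input
    row.  Deterministic given ``cfg.seed``.
    """
    if cfg.head == "classification":
        if n_classes is None:
            n_classes = len(class_order) if class_order else None
        if not n_classes or n_classes < 2:
            raise ValueError("classification head needs n_classes >= 2")
        k = n_classes
    else:
        k = n_classes if n_classes else input_rows
    rng = np.random.default_rng(cfg.seed)
    params = {}
    for name, shape in _param_shapes(cfg, input_rows, k).items():
        if name.startswith("b"):
            params[name] = np.zeros(shape)
        else:
            params[name] = rng.normal(0.0, cfg.init_sigma, size=shape)
    return RNNModel(
        cfg=cfg, params=params, n_inputs=input_rows, n_outputs=k,
        class_order=list(class_order) if class_order else None, layout=layout,
    )


# ------------------------------------------------------------------- forward

def _forward_batch(model: RNNModel, x: np.ndarray, in_mask=None):
    """Run the cell over a batch of slices.

    ``x`` has shape (B, D, tau).  Returns (hidden readout (B, H), cache).
    ``in_mask`` (B, D), if given, multiplies the input at every step
    (inverted-dropout mask, already scaled).
    """
    cfg, p = model.cfg, model.params
    b, d, tau = x.shape
    if d != model.n_inputs:
        raise ValueError(f"slice has {d} rows, model expects {model.n_inputs}")
    h = np.zeros((b, cfg.hidden_width))
    gact, oact = _gate_names(cfg)
    steps = []
    c = np.zeros_like(h)
    hs_sum = np.zeros_like(h)
    for t in range(tau):
        xt = x[:, :, t]
        if in_mask is not None:
            xt = xt * in_mask
        h_prev = h
        if cfg.cell == "vanilla":
            a = xt @ p["W"].T + h_prev @ p["U"].T + p["b"]
            h = np.tanh(a)
            steps.append({"x": xt, "h_prev": h_prev, "h": h})
        elif cfg.cell == "lstm":
            c_prev = c
            ai = xt @ p["Wi"].T + h_prev @ p["Ui"].T + p["pi"] * c_prev + p["bi"]
            af = xt @ p["Wf"].T + h_prev @ p["Uf"].T + p["pf"] * c_prev + p["bf"]
            ag = xt @ p["Wg"].T + h_prev @ p["Ug"].T + p["bg"]
            gi, gf = _act(gact, ai), _act(gact, af)
            g = np.tanh(ag)
            c = gf * c_prev + gi * g
            ao = xt @ p["Wo"].T + h_prev @ p["Uo"].T + p["po"] * c + p["bo"]
            go = _act(gact, ao)
            co = _act(oact, c)
            h = go * co
            steps.append({
                "x": xt, "h_prev": h_prev, "c_prev": c_prev, "ai": ai,
                "af": af, "ao": ao, "gi": gi, "gf": gf, "go": go,
                "g": g, "c": c, "co": co, "h": h,
            })
        else:  # gru
            az = xt @ p["Wz"].T + h_prev @ p["Uz"].T + p["bz"]
            ar = xt @ p["Wr"].T + h_prev @ p["Ur"].T + p["br"]
            z, r = _act(gact, az), _act(gact, ar)
            rh = r * h_prev
            ah = xt @ p["Wh"].T + rh @ p["Uh"].T + p["bh"]
            hh = np.tanh(ah)
            h = (1.0 - z) * h_prev + z * hh
            steps.append({
                "x": xt, "h_prev": h_prev, "az": az, "ar": ar, "z": z,
                "r": r, "rh": rh, "hh": hh, "h": h,
            })
        hs_sum += h
    readout = hs_sum / tau if cfg.readout == "mean" else h
    cache = {"steps": steps, "tau": tau, "in_mask": in_mask, "x_shape": x.shape}
    return readout, cache


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def forward_batch(model: RNNModel, x: np.ndarray) -> np.ndarray:
    """Inference outputs for a batch of slices (B, D, tau): probabilities
    (classification) or linear predictions (regression)."""
    h, _ = _forward_batch(model, x)
    logits = h @ model.params["Wy"].T + model.params["by"]
    if model.cfg.head == "classification":
        return _softmax(logits)
    return logits


def forward(model: RNNModel, ts: TimeSlice) -> np.ndarray:
    """Class probability vector for a single time slice."""
    if ts.length != model.cfg.unroll_len:
        raise ValueError(
            f"slice length {ts.length} does not match unroll depth "
            f"{model.cfg.unroll_len}"
        )
    return forward_batch(model, ts.values[None, :, :])[0]


# ------------------------------------------------------------------ backward

def _backward_batch(model: RNNModel, cache: dict, dreadout: np.ndarray,
                    grads: dict[str, np.ndarray]) -> None:
    """Backpropagate through time; accumulates into ``grads`` in place.

    ``dreadout`` is the gradient w.r.t. the hidden readout (B, H).
    """
    cfg, p = model.cfg, model.params
    steps, tau = cache["steps"], cache["tau"]
    gact, oact = _gate_names(cfg)
    b, h_w = dreadout.shape
    dh_next = np.zeros((b, h_w))
    dc_next = np.zeros((b, h_w))
    per_step = dreadout / tau if cfg.readout == "mean" else None
    for t in range(tau - 1, -1, -1):
        s = steps[t]
        dh = dh_next.copy()
        if cfg.readout == "mean":
            dh += per_step
        elif t == tau - 1:
            dh += dreadout
        xt, h_prev = s["x"], s["h_prev"]
        if cfg.cell == "vanilla":
            da = dh * (1.0 - s["h"] * s["h"])
            grads["W"] += da.T @ xt
            grads["U"] += da.T @ h_prev
            grads["b"] += da.sum(axis=0)
            dh_next = da @ p["U"]
        elif cfg.cell == "lstm":
            c_prev, c = s["c_prev"], s["c"]
            do = dh * s["co"]
            dao = do * _dact(gact, s["ao"], s["go"])
            dc = dh * s["go"] * _dact(oact, c, s["co"]) + dc_next + dao * p["po"]
            dg = dc * s["gi"]
            dag = dg * (1.0 - s["g"] * s["g"])
            di = dc * s["g"]
            dai = di * _dact(gact, s["ai"], s["gi"])
            df = dc * c_prev
            daf = df * _dact(gact, s["af"], s["gf"])
            for name, da in (("i", dai), ("f", daf), ("o", dao), ("g", dag)):
                grads[f"W{name}"] += da.T @ xt
                grads[f"U{name}"] += da.T @ h_prev
                grads[f"b{name}"] += da.sum(axis=0)
            grads["pi"] += (dai * c_prev).sum(axis=0)
            grads["pf"] += (daf * c_prev).sum(axis=0)
            grads["po"] += (dao * c).sum(axis=0)
            dh_next = dai @ p["Ui"] + daf @ p["Uf"] + dao @ p["Uo"] + dag @ p["Ug"]
            dc_next = dc * s["gf"] + dai * p["pi"] + daf * p["pf"]
        else:  # gru
            dz = dh * (s["hh"] - h_prev)
            daz = dz * _dact(gact, s["az"], s["z"])
            dhh = dh * s["z"]
            dah = dhh * (1.0 - s["hh"] * s["hh"])
            ds = dah @ p["Uh"]
            dr = ds * h_prev
            dar = dr * _dact(gact, s["ar"], s["r"])
            grads["Wz"] += daz.T @ xt
            grads["Wr"] += dar.T @ xt
            grads["Wh"] += dah.T @ xt
            grads["Uz"] += daz.T @ h_prev
            grads["Ur"] += dar.T @ h_prev
            grads["Uh"] += dah.T @ s["rh"]
            grads["bz"] += daz.sum(axis=0)
            grads["br"] += dar.sum(axis=0)
            grads["bh"] += dah.sum(axis=0)
            dh_next = dh * (1.0 - s["z"]) + ds * s["r"] + daz @ p["Uz"] + dar @ p["Ur"]


# --------------------------------------------------------------------- loss

_CLIP = 1e-12


def cross_entropy(pred_probs: np.ndarray, target) -> float:
    """Categorical cross-entropy, averaged over the batch.

    ``pred_probs`` is a probability vector or a (B, C) batch; ``target`` is
    a class index / array of indices into the probability rows.  For two
    classes this equals the binary form
    ``-(1/N) sum c log b + (1-c) log(1-b)``.  Probabilities are clipped to
    [1e-12, 1 - 1e-12] before the log.
    """
    p = np.atleast_2d(np.asarray(pred_probs, float))
    t = np.atleast_1d(np.asarray(target, int))
    if len(t) != p.shape[0]:
        raise ValueError("target count must match prediction count")
    picked = np.clip(p[np.arange(len(t)), t], _CLIP, 1.0 - _CLIP)
    return float(-np.log(picked).mean())


def loss_and_grads(model: RNNModel, x: np.ndarray, targets: np.ndarray,
                   in_mask=None, out_mask=None):
    """One forward/backward pass: mean loss and gradients for a batch.

    ``targets`` holds class indices (classification) or target vectors
    (B, K) (regression: mean squared error over batch and outputs).
    """
    cfg, p = model.cfg, model.params
    h, cache = _forward_batch(model, x, in_mask=in_mask)
    h_used = h * out_mask if out_mask is not None else h
    logits = h_used @ p["Wy"].T + p["by"]
    b = x.shape[0]
    if cfg.head == "classification":
        probs = _softmax(logits)
        t = np.asarray(targets, int)
        loss = cross_entropy(probs, t)
        dlogits = probs.copy()
        dlogits[np.arange(b), t] -= 1.0
        dlogits /= b
        extras = {"probs": probs}
    else:
        y = np.atleast_2d(np.asarray(targets, float))
        diff = logits - y
        loss = float((diff * diff).mean())
        dlogits = 2.0 * diff / diff.size
        extras = {"pred": logits}
    grads = {k: np.zeros_like(v) for k, v in p.items()}
    grads["Wy"] += dlogits.T @ h_used
    grads["by"] += dlogits.sum(axis=0)
    dh = dlogits @ p["Wy"]
    if out_mask is not None:
        dh = dh * out_mask
    _backward_batch(model, cache, dh, grads)
    return loss, grads, extras


# ------------------------------------------------------------------ training

def _stack_slices(slices: list[TimeSlice], class_order: list[int]):
    x = np.stack([s.values for s in slices])
    idx = {c: i for i, c in enumerate(class_order)}
    y = np.array([idx[s.label] for s in slices], dtype=int)
    return x, y


def _evaluate_slices(model: RNNModel, x: np.ndarray, y: np.ndarray,
                     chunk: int = 2048) -> tuple[float, float]:
    losses, correct = [], 0
    for i in range(0, len(x), chunk):
        probs = forward_batch(model, x[i : i + chunk])
        yi = y[i : i + chunk]
        picked = np.clip(probs[np.arange(len(yi)), yi], _CLIP, 1 - _CLIP)
        losses.append(-np.log(picked))
        correct += int((probs.argmax(axis=1) == yi).sum())
    return float(np.concatenate(losses).mean()), correct / len(x)


def train(
    model: RNNModel,
    slices: list[TimeSlice],
    val_slices: list[TimeSlice] | None = None,
    cfg: RNNConfig | None = None,
) -> tuple[RNNModel, TrainingTrace]:
    """Mini-batch BPTT with Adam on labelled time slices.

    Runs exactly ``cfg.max_iterations`` epochs (an iteration is one pass
    over the shuffled training slices) with no early stopping.  Dropout is
    applied to inputs and to the pre-readout hidden state during training
    only.  Deterministic given ``cfg.seed``.  Returns the trained model
    (updated in place) and its per-epoch trace.
    """
    cfg = cfg or model.cfg
    if not slices:
        raise ValueError("training slice set is empty")
    class_order = model.class_order or sorted({s.label for s in slices})
    model.class_order = class_order
    x, y = _stack_slices(slices, class_order)
    xv = yv = None
    if val_slices:
        xv, yv = _stack_slices(val_slices, class_order)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 7]))
    p = model.params
    mom = {k: np.zeros_like(v) for k, v in p.items()}
    vel = {k: np.zeros_like(v) for k, v in p.items()}
    trace = TrainingTrace()
    step = 0
    keep = 1.0 - cfg.dropout_rate
    for _ in range(cfg.max_iterations):
        order = rng.permutation(len(x))
        ep_losses, ep_hits, ep_count = [], 0, 0
        for start in range(0, len(x), cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            xb, yb = x[idx], y[idx]
            in_mask = out_mask = None
            if cfg.dropout_rate > 0:
                in_mask = rng.random((len(idx), model.n_inputs)) < keep
                in_mask = in_mask.astype(float) / keep
                out_mask = rng.random((len(idx), cfg.hidden_width)) < keep
                out_mask = out_mask.astype(float) / keep
            loss, grads, extras = loss_and_grads(
                model, xb, yb, in_mask=in_mask, out_mask=out_mask
            )
            step += 1
            b1t = 1.0 - cfg.adam_beta1**step
            b2t = 1.0 - cfg.adam_beta2**step
            for k in p:
                g = grads[k]
                mom[k] = cfg.adam_beta1 * mom[k] + (1 - cfg.adam_beta1) * g
                vel[k] = cfg.adam_beta2 * vel[k] + (1 - cfg.adam_beta2) * g * g
                p[k] -= cfg.learning_rate * (mom[k] / b1t) / (
                    np.sqrt(vel[k] / b2t) + cfg.adam_eps
                )
            ep_losses.append(loss * len(idx))
            ep_hits += int((extras["probs"].argmax(axis=1) == yb).sum())
            ep_count += len(idx)
        trace.train_loss.append(float(np.sum(ep_losses) / ep_count))
        trace.train_accuracy.append(ep_hits / ep_count)
        if xv is not None:
            vl, va = _evaluate_slices(model, xv, yv)
            trace.val_loss.append(vl)
            trace.val_accuracy.append(va)
        else:
            trace.val_loss.append(float("nan"))
            trace.val_accuracy.append(float("nan"))
    return model, trace


# ----------------------------------------------------------------- inference

def predict_trial(
    model: RNNModel, z: FeatureSeries, tau: int | None = None, stride: int = 1
) -> PredictionAggregate:
    """Classify one trial: score every crop, average the probabilities.

    The final label is the argmax of the mean probability vector, ties
    broken toward the lowest class index (first in class order).
    """
    tau = tau if tau is not None else model.cfg.unroll_len
    slices = crop_slices(z, tau, stride=stride)
    x = np.stack([s.values for s in slices])
    probs = forward_batch(model, x)
    mean = probs.mean(axis=0)
    winner = int(np.argmax(mean))  # argmax returns the first maximum: lowest index
    label = model.class_order[winner] if model.class_order else winner
    return PredictionAggregate(slice_probs=probs, mean_probs=mean, final_label=label)


def autoregressive_predict(
    model: RNNModel, seed_sequence: np.ndarray, n_steps: int
) -> np.ndarray:
    """Free-running signal prediction: feed each output back as input.

    The model must have a regression head whose outputs match its input
    rows.  ``seed_sequence`` (D, >=tau) primes the context; the returned
    array holds the ``n_steps`` predicted samples (D, n_steps).
    """
    if model.cfg.head != "regression":
        raise ValueError("autoregressive prediction needs a regression-head model")
    if model.n_outputs != model.n_inputs:
        raise ValueError("regression head must predict one value per input row")
    seed = np.atleast_2d(np.asarray(seed_sequence, float))
    tau = model.cfg.unroll_len
    if seed.shape[1] < tau:
        raise ValueError(f"seed sequence must provide at least tau = {tau} samples")
    buf = seed[:, -tau:].copy()
    out = np.empty((seed.shape[0], n_steps))
    for i in range(n_steps):
        pred = forward_batch(model, buf[None])[0]
        out[:, i] = pred
        buf = np.concatenate([buf[:, 1:], pred[:, None]], axis=1)
    return out


def make_signal_slices(z: np.ndarray, tau: int, stride: int = 1):
    """(inputs, one-step-ahead targets) pairs for signal-prediction training.

    ``z`` is (D, T); each input is a tau-column window and its target the
    column immediately after the window.
    """
    z = np.atleast_2d(np.asarray(z, float))
    t = z.shape[1]
    if tau >= t:
        raise ValueError("tau must be < T")
    xs, ys = [], []
    for off in range(0, t - tau, stride):
        xs.append(z[:, off : off + tau])
        ys.append(z[:, off + tau])
    return np.stack(xs), np.stack(ys)


def train_signal(model: RNNModel, x: np.ndarray, y: np.ndarray,
                 cfg: RNNConfig | None = None) -> tuple[RNNModel, list[float]]:
    """Adam training of a regression-head model on (inputs, next-sample)
    pairs; returns the model and the per-epoch mean-squared-error trace."""
    cfg = cfg or model.cfg
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 11]))
    p = model.params
    mom = {k: np.zeros_like(v) for k, v in p.items()}
    vel = {k: np.zeros_like(v) for k, v in p.items()}
    losses = []
    step = 0
    for _ in range(cfg.max_iterations):
        order = rng.permutation(len(x))
        ep = []
        for start in range(0, len(x), cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            loss, grads, _ = loss_and_grads(model, x[idx], y[idx])
            step += 1
            b1t = 1.0 - cfg.adam_beta1**step
            b2t = 1.0 - cfg.adam_beta2**step
            for k in p:
                g = grads[k]
                mom[k] = cfg.adam_beta1 * mom[k] + (1 - cfg.adam_beta1) * g
                vel[k] = cfg.adam_beta2 * vel[k] + (1 - cfg.adam_beta2) * g * g
                p[k] -= cfg.learning_rate * (mom[k] / b1t) / (
                    np.sqrt(vel[k] / b2t) + cfg.adam_eps
                )
            ep.append(loss * len(idx))
        losses.append(float(np.sum(ep) / len(x)))
    return model, losses


# ---------------------------------------------------------------- depth sweep

def sweep_depth(
    train_features: list[FeatureSeries],
    val_features: list[FeatureSeries],
    taus: list[int],
    cfg: RNNConfig,
    train_stride: int = 1,
    eval_stride: int = 1,
) -> tuple[int, dict[int, dict[str, float]]]:
    """Choose the optimal unroll depth (= slice length) by validation accuracy.

    One model per tau in the grid is trained on cropped training features
    and scored per-trial on the validation features; the tau with the
    highest validation accuracy wins, ties going to the smaller tau.  The
    winning depth doubles as the cropping size used downstream.
    """
    if not taus:
        raise ValueError("tau grid is empty")
    class_order = sorted({f.label for f in train_features})
    records: dict[int, dict[str, float]] = {}
    best_tau, best_acc = None, -1.0
    for tau in sorted(int(t) for t in taus):  # ties resolve to the smaller tau
        c = dataclasses.replace(cfg, unroll_len=int(tau))
        tr_slices = [s for f in train_features for s in crop_slices(f, tau, train_stride)]
        va_slices = [s for f in val_features for s in crop_slices(f, tau, eval_stride)]
        model = init_model(c, train_features[0].n_rows,
                           n_classes=len(class_order), class_order=class_order)
        model, trace = train(model, tr_slices, va_slices, c)
        hits = 0
        ce = []
        for f in val_features:
            agg = predict_trial(model, f, tau, stride=eval_stride)
            hits += int(agg.final_label == f.label)
            k = class_order.index(f.label)
            ce.append(-np.log(max(agg.mean_probs[k], _CLIP)))
        acc = hits / len(val_features)
        records[int(tau)] = {
            "val_accuracy": acc,
            "val_cross_entropy": float(np.mean(ce)),
            "final_train_loss": trace.train_loss[-1],
        }
        if acc > best_acc:
            best_tau, best_acc = int(tau), acc
    return best_tau, records
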