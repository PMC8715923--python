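"""Spatio-temporal backpropagation (STBP) with a rectangular surrogate.

Training treats the spike activation as non-differentiable and substitutes
the rectangular pulse ``h(u)`` for ``d(spike)/du``.  Credit flows along two
paths: spatially through the layer weights (including the ``-beta * w_a``
inhibitory branch) and temporally through the membrane recursion
``u[t+1] = k_tau * u[t] + I``.  The hard reset is treated as a
non-differentiable gate: after a spike the temporal path is zeroed.

The loss is the mean squared error between the one-hot label and the firing
rate of the output neurons:

    L = (1/2M) * sum_m || y_m - (1/T) * sum_t o_{m,t} ||^2
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .encoding import encode_poisson
from .network import Network, conv_windows, maxpool_spikes, propagate_shapes
from .neuron import surrogate_grad

__all__ = [
    "TrainConfig",
    "TrainHistory",
    "Trace",
    "rate_mse_loss",
    "forward_trace",
    "backward",
    "relaxed_loss",
    "train",
    "evaluate",
]


@dataclass
class TrainConfig:
    epochs: int = 30
    batch_size: int = 25
    lr: float = 1e-3
    T: int = 25
    seed: int = 0
    optimizer: str = "adam"

    def __post_init__(self) -> None:
        if self.batch_size < 1 or self.T < 1 or self.epochs < 0:
            raise ValueError("invalid training configuration")
        if self.optimizer not in ("adam", "sgd"):
            raise ValueError("optimizer must be 'adam' or 'sgd'")


@dataclass
class TrainHistory:
    train_loss: list = field(default_factory=list)
    train_accuracy: list = field(default_factory=list)
    test_accuracy: list = field(default_factory=list)


def rate_mse_loss(output_spikes: np.ndarray, labels: np.ndarray) -> float:
    """Rate-coding MSE loss over a batch.

    output_spikes : (M, T, n_out) spike record of the output layer.
    labels        : (M, n_out) one-hot targets.
    """
    o = np.asarray(output_spikes, dtype=float)
    y = np.asarray(labels, dtype=float)
    if o.ndim != 3 or y.ndim != 2 or o.shape[0] != y.shape[0] or o.shape[2] != y.shape[1]:
        raise ValueError(f"inconsistent shapes {o.shape} vs {y.shape}")
    rate = o.mean(axis=1)
    return float(0.5 * np.sum((y - rate) ** 2) / o.shape[0])


# ---------------------------------------------------------------------------
# forward with trace
# ---------------------------------------------------------------------------

@dataclass
class Trace:
    """Everything the backward pass needs, recorded per time step.

    rec[t][i] for a parameterized layer i is a dict with the layer input
    ``x`` (float), pre-reset membrane ``u_pre``, emitted output ``o`` (binary
    in hard mode, real-valued in relaxed mode), reset gate and clamp mask.
    rec[t][i] for a pooling layer holds the argmax index used for routing.
    """

    rec: list
    o_out: np.ndarray  # (B, T, n_out)
    relaxed: bool


def _soft_spike(u_pre: np.ndarray, lif) -> np.ndarray:
    """Piecewise-linear relaxation whose derivative is the rectangular h(u).

    Rises from 0 to a^2 over the surrogate band |u - V_th| <= a/2 with slope
    ``a`` — used only by the finite-difference gradient oracle, never in
    training or inference.
    """
    return np.clip(lif.a * (u_pre - lif.V_th + lif.a / 2.0), 0.0, lif.a * lif.a)


def forward_trace(net: Network, spikes: np.ndarray, relaxed: bool = False) -> Trace:
    """Run the network over (B, T, C, L) input spikes, recording the trace.

    In relaxed mode the spike nonlinearity is replaced by its piecewise
    linear surrogate (real-valued activations, hard reset gate kept), which
    makes the loss differentiable with exactly the gradients the STBP
    backward computes.
    """
    spikes = np.asarray(spikes)
    B, T = spikes.shape[0], spikes.shape[1]
    spec = net.spec
    shapes = propagate_shapes(spec)
    dtype = net.weights[net.param_layers[0]][0].dtype
    u, w_eff_t = {}, {}
    for i, layer in enumerate(spec.layers):
        if layer.kind == "maxpool":
            continue
        c, ln = shapes[i]
        u[i] = np.zeros((B, c, ln) if layer.kind == "sconv" else (B, c), dtype=dtype)
        w, w_a = net.weights[i]
        w_eff = w - layer.beta * w_a
        # conv kernels pre-flattened for the im2col product
        w_eff_t[i] = np.ascontiguousarray(
            w_eff.reshape(w_eff.shape[0], -1).T if layer.kind == "sconv" else w_eff.T
        )
    n_out = spec.layers[-1].out_channels
    o_out = np.zeros((B, T, n_out), dtype=dtype)
    rec = []

    for t in range(T):
        x = spikes[:, t].astype(dtype)
        rec_t = {}
        for i, layer in enumerate(spec.layers):
            if layer.kind == "maxpool":
                lo = x.shape[-1] // layer.window_w
                v = x[..., : lo * layer.window_w].reshape(x.shape[:-1] + (lo, layer.window_w))
                amax = v.argmax(axis=-1)
                rec_t[i] = {"argmax": amax, "in_len": x.shape[-1]}
                x = v.max(axis=-1)
                continue
            if layer.kind == "fc" and x.ndim == 3:
                x = x.reshape(B, -1)
            if layer.kind == "sconv":
                win = conv_windows(x, layer.kernel_w)
                I0 = (win @ w_eff_t[i]).transpose(0, 2, 1)
            else:
                I0 = x @ w_eff_t[i]
            mask = I0 >= 0.0
            I = I0 * mask
            u_pre = layer.lif.k_tau * u[i] + I * layer.lif.R0
            gate = u_pre >= layer.lif.V_th
            o = _soft_spike(u_pre, layer.lif) if relaxed else gate.astype(dtype)
            u[i] = np.where(gate, 0.0, u_pre)
            rec_t[i] = {"x": x, "u_pre": u_pre, "o": o, "gate": gate, "mask": mask}
            x = o
        o_out[:, t] = x
        rec.append(rec_t)
    return Trace(rec=rec, o_out=o_out, relaxed=relaxed)


def relaxed_loss(net: Network, spikes: np.ndarray, labels: np.ndarray) -> float:
    """Loss of the surrogate-relaxed model (finite-difference oracle target)."""
    tr = forward_trace(net, spikes, relaxed=True)
    return rate_mse_loss(tr.o_out, labels)


# ---------------------------------------------------------------------------
# backward
# ---------------------------------------------------------------------------

def _conv_input_grad(d_out: np.ndarray, w_eff: np.ndarray) -> np.ndarray:
    """Gradient wrt the input of a valid 1-D cross-correlation.

    Computed as the window gradient (one GEMM) scattered back to input
    positions by ``kernel_w`` shifted adds.
    """
    B, co, lo = d_out.shape
    _, ci, kw = w_eff.shape
    # dL/dwin: (B, Lo, Ci*kw)
    d_win = d_out.transpose(0, 2, 1) @ w_eff.reshape(co, -1)
    d_win = d_win.reshape(B, lo, ci, kw)
    d_x = np.zeros((B, ci, lo + kw - 1), dtype=d_out.dtype)
    for k in range(kw):
        d_x[:, :, k : k + lo] += d_win[:, :, :, k].transpose(0, 2, 1)
    return d_x


def backward(net: Network, trace: Trace, labels: np.ndarray) -> list:
    """STBP gradients of the rate-MSE loss for all (w, w_a) pairs.

    Returns a list aligned with ``net.weights``: ``(dW, dWa)`` per
    parameterized layer, None for pooling layers.  ``dL/dw_n`` accumulates
    ``sum_t dL/du_{t,n} * o_{t,n-1}`` with the surrogate h(u) standing in
    for d(spike)/du; the adaptive weights receive the same term scaled by
    ``-beta``.
    """
    spec = net.spec
    y = np.asarray(labels, dtype=float)
    B, T = trace.o_out.shape[0], trace.o_out.shape[1]
    rate = trace.o_out.mean(axis=1)
    d_o_out = (rate - y) / (B * T)  # dL/do_{m,t,out}, identical at every t

    grads = [None if w is None else (np.zeros_like(w[0]), np.zeros_like(w[1]))
             for w in net.weights]
    d_upre_next = {i: None for i in net.param_layers}
    shapes = propagate_shapes(spec)
    w_eff_all = {
        i: net.weights[i][0] - spec.layers[i].beta * net.weights[i][1]
        for i in net.param_layers
    }

    for t in range(T - 1, -1, -1):
        rec_t = trace.rec[t]
        d_x = d_o_out.copy()
        for i in range(len(spec.layers) - 1, -1, -1):
            layer = spec.layers[i]
            if layer.kind == "maxpool":
                r = rec_t[i]
                amax = r["argmax"]
                lo, ww = amax.shape[-1], layer.window_w
                d_prev = np.zeros(d_x.shape[:-1] + (r["in_len"],))
                dv = d_prev[..., : lo * ww].reshape(d_x.shape[:-1] + (lo, ww))
                np.put_along_axis(dv, amax[..., None], d_x[..., None], axis=-1)
                d_x = d_prev
                continue
            r = rec_t[i]
            lif = layer.lif
            h = surrogate_grad(r["u_pre"], lif)
            d_upre = d_x * h
            if d_upre_next[i] is not None:  # temporal path, zeroed after a spike
                d_upre = d_upre + lif.k_tau * (d_upre_next[i] * ~r["gate"])
            d_upre_next[i] = d_upre
            d_I0 = d_upre * lif.R0 * r["mask"]
            w_eff = w_eff_all[i]
            gW, gWa = grads[i]
            x_in = r["x"]
            if layer.kind == "sconv":
                win = conv_windows(x_in, layer.kernel_w)
                co = d_I0.shape[1]
                g = (d_I0.transpose(1, 0, 2).reshape(co, -1)
                     @ win.reshape(-1, win.shape[-1])).reshape(w_eff.shape)
                d_x = _conv_input_grad(d_I0, w_eff)
            else:
                g = d_I0.T @ x_in
                d_x = d_I0 @ w_eff
                # un-flatten toward a spatial layer below
                if i > 0 and spec.layers[i - 1].kind != "fc":
                    c, ln = shapes[i - 1]
                    d_x = d_x.reshape(B, c, ln)
            gW += g
            gWa += -layer.beta * g
    return grads


# ---------------------------------------------------------------------------
# optimizers and the training loop
# ---------------------------------------------------------------------------

class _Adam:
    def __init__(self, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m, self.v, self.t = {}, {}, 0

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        for k, g in grads.items():
            if k not in self.m:
                self.m[k] = np.zeros_like(g)
                self.v[k] = np.zeros_like(g)
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1 ** self.t)
            vhat = self.v[k] / (1 - self.b2 ** self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class _SGD:
    def __init__(self, lr):
        self.lr = lr

    def step(self, params: dict, grads: dict) -> None:
        for k, g in grads.items():
            params[k] -= self.lr * g


def _as_arrays(dataset):
    """Accept a BeatDataset-like object or a (Xtr, ytr, Xte, yte) tuple."""
    if isinstance(dataset, tuple):
        return dataset
    xtr, ytr = dataset.arrays("train")
    xte, yte = dataset.arrays("test")
    return xtr, ytr, xte, yte


def _one_hot(y: np.ndarray, n: int) -> np.ndarray:
    out = np.zeros((len(y), n))
    out[np.arange(len(y)), y] = 1.0
    return out


def evaluate(net: Network, X: np.ndarray, y: np.ndarray, seed: int = 0,
             batch_size: int = 50) -> float:
    """Fraction of beats whose prediction matches the label (fixed encoder seed)."""
    from .network import run_spike_train

    if len(X) == 0:
        raise ValueError("empty dataset")
    T = net.spec.T
    correct = 0
    for s in range(0, len(X), batch_size):
        xb = X[s : s + batch_size]
        spikes = np.stack(
            [encode_poisson(x[None, :], T, seed + s + j) for j, x in enumerate(xb)]
        )  # (b, T, 1, L)
        preds, _ = run_spike_train(net, spikes)
        correct += int((preds == y[s : s + batch_size]).sum())
    return correct / len(X)


def train(net: Network, dataset, cfg: TrainConfig):
    """Minibatch STBP training; returns the trained network and its history.

    The encoder draws fresh noise every epoch (stochastic regularization);
    evaluation always uses a fixed encoder seed so reported accuracies are
    reproducible.
    """
    Xtr, ytr, Xte, yte = _as_arrays(dataset)
    if len(Xtr) == 0:
        raise ValueError("empty training set")
    n_out = net.spec.layers[-1].out_channels
    ss = np.random.SeedSequence(cfg.seed)
    shuffle_rng = np.random.default_rng(ss.spawn(1)[0])
    epoch_seeds = np.random.default_rng(cfg.seed).integers(0, 2**31 - 1, size=max(cfg.epochs, 1))

    # single precision in the hot loop; restored on exit
    for i in net.param_layers:
        w, wa = net.weights[i]
        net.weights[i] = (w.astype(np.float32), wa.astype(np.float32))
    params, keys = {}, []
    for i in net.param_layers:
        params[(i, "w")] = net.weights[i][0]
        params[(i, "wa")] = net.weights[i][1]
        keys.append(i)
    opt = _Adam(cfg.lr) if cfg.optimizer == "adam" else _SGD(cfg.lr)

    hist = TrainHistory()
    for epoch in range(cfg.epochs):
        enc_seed = int(epoch_seeds[epoch])
        spikes_all = np.stack(
            [encode_poisson(x[None, :], cfg.T, enc_seed + j) for j, x in enumerate(Xtr)]
        ).astype(np.uint8)
        order = shuffle_rng.permutation(len(Xtr))
        losses, correct = [], 0
        for s in range(0, len(order), cfg.batch_size):
            idx = order[s : s + cfg.batch_size]
            sp = spikes_all[idx]
            yb = _one_hot(ytr[idx], n_out)
            tr = forward_trace(net, sp)
            losses.append(rate_mse_loss(tr.o_out, yb))
            counts = tr.o_out.sum(axis=1)
            correct += int((counts.argmax(axis=1) == ytr[idx]).sum())
            grads = backward(net, tr, yb)
            gdict = {}
            for i in keys:
                gdict[(i, "w")] = grads[i][0]
                gdict[(i, "wa")] = grads[i][1]
            opt.step(params, gdict)
        hist.train_loss.append(float(np.mean(losses)))
        hist.train_accuracy.append(correct / len(Xtr))
        hist.test_accuracy.append(evaluate(net, Xte, yte) if len(Xte) else float("nan"))
    for i in net.param_layers:
        w, wa = net.weights[i]
        net.weights[i] = (w.astype(np.float64), wa.astype(np.float64))
    return net, hist
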