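"""DiSNN: deep integrative spiking neural network.

Topology and forward pass of a spike-domain 1-D convolutional network for
beat classification: five spike-based convolution (SConv) blocks, two
max-pooling layers (after SConv2 and SConv5), and two spike-based fully
connected (FC) blocks, read out through a spike counter.

Every SConv/FC block carries two weight sets: an *integrative* kernel ``w``
and an *adaptive* (inhibitory) kernel ``w_a``.  The pre-synaptic stimulus of
a block is

    I0 = sum_j (w_j - beta * w_a_j) * o_j_prev

i.e. the adaptive path subtracts a scaled copy of the drive, which keeps
membrane excursions bounded and prevents neurons from saturating into
permanent firing ("spiking stall").  All inter-block traffic is binary.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field, replace

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .encoding import encode_poisson
from .neuron import LIFLayerState, LIFParams, clamp_stimulus, lif_step

__all__ = [
    "LayerSpec",
    "NetworkSpec",
    "Network",
    "build_network",
    "propagate_shapes",
    "maxpool_spikes",
    "block_forward",
    "forward",
    "run_spike_train",
    "save_network",
    "load_network",
]

# Fig-3 kernel chain: (out_channels, in_channels, kernel_w) per SConv block.
DEFAULT_SCONV_SHAPES = [(4, 1, 3), (16, 4, 3), (16, 16, 3), (16, 16, 2), (32, 16, 2)]


@dataclass(frozen=True)
class LayerSpec:
    """One layer of the network.

    kind : "sconv" (1-D valid cross-correlation, stride 1), "maxpool"
           (non-overlapping OR-pooling on binary spikes) or "fc".
    """

    kind: str
    out_channels: int = 0
    in_channels: int = 0
    kernel_w: int = 0
    window_w: int = 2
    lif: LIFParams = field(default_factory=LIFParams)
    beta: float = 0.25

    def __post_init__(self) -> None:
        if self.kind not in ("sconv", "maxpool", "fc"):
            raise ValueError(f"unknown layer kind {self.kind!r}")
        if self.beta < 0:
            raise ValueError("beta must be >= 0")
        if self.kind in ("sconv", "fc"):
            if self.out_channels < 1 or self.in_channels < 1:
                raise ValueError("channel counts must be positive")
        if self.kind == "sconv" and self.kernel_w < 1:
            raise ValueError("kernel_w must be positive")


@dataclass(frozen=True)
class NetworkSpec:
    layers: tuple[LayerSpec, ...]
    input_channels: int = 1
    input_len: int = 251
    T: int = 25

    @classmethod
    def default(
        cls,
        fc_hidden: int = 128,
        T: int = 25,
        beta: float = 0.25,
        k_tau: float = 0.8,
        a: float = 1.0,
        v_th: "float | list[float]" = 0.5,
        input_len: int = 251,
    ) -> "NetworkSpec":
        """The standard DiSNN topology for 1x251 inputs and 4 classes.

        Order: SConv1, SConv2, MP, SConv3, SConv4, SConv5, MP, FC1, FC2.
        ``v_th`` may be a scalar or one threshold per parameterized layer
        (5 SConv + 2 FC = 7 values).
        """
        n_param = len(DEFAULT_SCONV_SHAPES) + 2
        if np.isscalar(v_th):
            v_list = [float(v_th)] * n_param
        else:
            v_list = [float(v) for v in v_th]
            if len(v_list) != n_param:
                raise ValueError(f"need {n_param} thresholds, got {len(v_list)}")
        lifs = [LIFParams(k_tau=k_tau, a=a, V_th=v) for v in v_list]
        conv = [
            LayerSpec("sconv", co, ci, kw, lif=lifs[i], beta=beta)
            for i, (co, ci, kw) in enumerate(DEFAULT_SCONV_SHAPES)
        ]
        mp = LayerSpec("maxpool", window_w=2)
        layers = [conv[0], conv[1], mp, conv[2], conv[3], conv[4], mp]
        # flatten size after the conv stack
        flat = _flat_size(layers, input_channels=1, input_len=input_len)
        layers.append(LayerSpec("fc", fc_hidden, flat, lif=lifs[5], beta=beta))
        layers.append(LayerSpec("fc", 4, fc_hidden, lif=lifs[6], beta=beta))
        return cls(tuple(layers), input_channels=1, input_len=input_len, T=T)


def propagate_shapes(spec: NetworkSpec) -> list[tuple[int, int]]:
    """(channels, length) after each layer; FC layers get (N_out, 1).

    Valid (no-pad) convolution shrinks the length by ``kernel_w - 1``;
    pooling floor-divides it (a trailing odd element is dropped).
    """
    shapes = []
    c, ln = spec.input_channels, spec.input_len
    for layer in spec.layers:
        if layer.kind == "sconv":
            if layer.in_channels != c:
                raise ValueError(
                    f"sconv expects {layer.in_channels} input channels, got {c}"
                )
            ln = ln - layer.kernel_w + 1
            if ln < 1:
                raise ValueError("feature map shrank below 1 sample")
            c = layer.out_channels
        elif layer.kind == "maxpool":
            ln = ln // layer.window_w
        else:  # fc
            if layer.in_channels != c * ln:
                raise ValueError(
                    f"fc expects {layer.in_channels} inputs, got {c}*{ln}={c * ln}"
                )
            c, ln = layer.out_channels, 1
        shapes.append((c, ln))
    return shapes


def _flat_size(layers, input_channels, input_len):
    c, ln = input_channels, input_len
    for layer in layers:
        if layer.kind == "sconv":
            ln = ln - layer.kernel_w + 1
            c = layer.out_channels
        elif layer.kind == "maxpool":
            ln = ln // layer.window_w
    return c * ln


@dataclass
class Network:
    """A NetworkSpec plus integrative/adaptive weight arrays.

    ``weights[i]`` is ``(w, w_a)`` for the i-th layer of the spec (None for
    pooling layers).  Conv weights have shape (C_out, C_in, kernel_w), FC
    weights (N_out, N_in).
    """

    spec: NetworkSpec
    weights: list

    @property
    def param_layers(self) -> list[int]:
        return [i for i, l in enumerate(self.spec.layers) if l.kind != "maxpool"]


def build_network(spec: NetworkSpec, seed: int) -> Network:
    """Initialize integrative and adaptive weights (scaled uniform fan-in)."""
    propagate_shapes(spec)  # validates the chain
    rng = np.random.default_rng(seed)
    weights = []
    for layer in spec.layers:
        if layer.kind == "maxpool":
            weights.append(None)
            continue
        if layer.kind == "sconv":
            shape = (layer.out_channels, layer.in_channels, layer.kernel_w)
            fan_in = layer.in_channels * layer.kernel_w
        else:
            shape = (layer.out_channels, layer.in_channels)
            fan_in = layer.in_channels
        bound = 1.0 / np.sqrt(fan_in)
        w = rng.uniform(-bound, bound, size=shape)
        w_a = rng.uniform(-bound, bound, size=shape)
        weights.append((w, w_a))
    return Network(spec=spec, weights=weights)


# ---------------------------------------------------------------------------
# layer primitives (shared by training and the CIM engine)
# ---------------------------------------------------------------------------

def conv_windows(x: np.ndarray, kernel_w: int) -> np.ndarray:
    """im2col for 1-D valid convolution.

    x (B, C, L)  ->  (B, L_out, C*kernel_w), rows ordered channel-major
    (input channel varies slowest), matching the crossbar "slender bar"
    layout of one kernel.
    """
    v = sliding_window_view(x, kernel_w, axis=-1)  # (B, C, L_out, kw)
    v = v.transpose(0, 2, 1, 3)  # (B, L_out, C, kw)
    b, lo = v.shape[0], v.shape[1]
    return v.reshape(b, lo, -1)


def conv_stimulus(x: np.ndarray, w_eff: np.ndarray) -> np.ndarray:
    """Valid 1-D cross-correlation: x (B,C,L), w_eff (Co,Ci,kw) -> (B,Co,Lo)."""
    kw = w_eff.shape[-1]
    win = conv_windows(x, kw)
    out = win @ w_eff.reshape(w_eff.shape[0], -1).T  # (B, Lo, Co)
    return out.transpose(0, 2, 1)


def maxpool_spikes(spikes: np.ndarray, window_w: int = 2) -> np.ndarray:
    """Non-overlapping max-pool along the last axis (OR for binary input).

    A trailing remainder shorter than the window is dropped (floor
    division), so length 247 with window 2 yields 123.
    """
    spikes = np.asarray(spikes)
    lo = spikes.shape[-1] // window_w
    v = spikes[..., : lo * window_w].reshape(spikes.shape[:-1] + (lo, window_w))
    return v.max(axis=-1)


def _validate_binary(x: np.ndarray) -> None:
    if not np.isin(x, (0, 1)).all():
        raise ValueError("spike input must be binary (0/1)")


def block_forward(
    spikes_in: np.ndarray,
    layer: LayerSpec,
    w: np.ndarray,
    w_a: np.ndarray,
    state: LIFLayerState,
) -> tuple[LIFLayerState, np.ndarray]:
    """One SConv/FC block at one time step: weighted drive, clamp, LIF.

    ``spikes_in`` is (B, C, L) for sconv or (B, N) for fc and must be binary.
    """
    _validate_binary(spikes_in)
    x = np.asarray(spikes_in, dtype=float)
    w_eff = w - layer.beta * w_a
    if layer.kind == "sconv":
        I0 = conv_stimulus(x, w_eff)
    elif layer.kind == "fc":
        I0 = x @ w_eff.T
    else:
        raise ValueError("block_forward applies to sconv/fc layers only")
    I = clamp_stimulus(I0)
    return lif_step(state, I, layer.lif)


# ---------------------------------------------------------------------------
# full forward pass
# ---------------------------------------------------------------------------

def run_spike_train(
    net: Network, spikes: np.ndarray, mac=None
) -> tuple[np.ndarray, np.ndarray]:
    """Run an encoded batch through the network.

    Parameters
    ----------
    spikes : (B, T, C, L) binary array.
    mac : optional callable ``mac(layer_index, layer, x) -> I0`` replacing the
        digital weighted-sum of every SConv/FC block (used by the
        compute-in-memory engine).  The clamp, LIF dynamics, pooling and
        readout are identical in both modes.

    Returns
    -------
    (predictions (B,), spike counts (B, n_classes))
    """
    spikes = np.asarray(spikes)
    _validate_binary(spikes)
    B, T = spikes.shape[0], spikes.shape[1]
    shapes = propagate_shapes(net.spec)
    states = {}
    for i, layer in enumerate(net.spec.layers):
        if layer.kind == "maxpool":
            continue
        c, ln = shapes[i]
        states[i] = LIFLayerState.zeros((B, c, ln) if layer.kind == "sconv" else (B, c))
    n_out = net.spec.layers[-1].out_channels
    counts = np.zeros((B, n_out), dtype=np.int64)

    for t in range(T):
        x = spikes[:, t].astype(float)
        for i, layer in enumerate(net.spec.layers):
            if layer.kind == "maxpool":
                x = maxpool_spikes(x, layer.window_w)
                continue
            if layer.kind == "fc" and x.ndim == 3:
                x = x.reshape(B, -1)
            if mac is None:
                w, w_a = net.weights[i]
                w_eff = w - layer.beta * w_a
                I0 = conv_stimulus(x, w_eff) if layer.kind == "sconv" else x @ w_eff.T
            else:
                I0 = mac(i, layer, x)
            I = clamp_stimulus(I0)
            states[i], o = lif_step(states[i], I, layer.lif)
            x = o.astype(float)
        counts += x.astype(np.int64)

    # highest spike count wins; argmax breaks ties toward the lowest index
    preds = counts.argmax(axis=1)
    return preds, counts


def forward(net: Network, sample: np.ndarray, seed: int, mac=None):
    """Encode one normalized sample and classify it.

    Returns ``(predicted class, spike counts over the T time steps)``.
    """
    sample = np.asarray(sample, dtype=float)
    if sample.ndim == 1:
        sample = sample[None, :]
    spikes = encode_poisson(sample, net.spec.T, seed)  # (T, C, L)
    preds, counts = run_spike_train(net, spikes[None, ...], mac=mac)
    return int(preds[0]), counts[0]


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def _spec_to_json(spec: NetworkSpec) -> str:
    layers = []
    for l in spec.layers:
        layers.append(
            dict(
                kind=l.kind,
                out_channels=l.out_channels,
                in_channels=l.in_channels,
                kernel_w=l.kernel_w,
                window_w=l.window_w,
                beta=l.beta,
                lif=dict(k_tau=l.lif.k_tau, R0=l.lif.R0, V_th=l.lif.V_th, a=l.lif.a),
            )
        )
    return json.dumps(
        dict(
            layers=layers,
            input_channels=spec.input_channels,
            input_len=spec.input_len,
            T=spec.T,
        )
    )


def _spec_from_json(s: str) -> NetworkSpec:
    d = json.loads(s)
    layers = tuple(
        LayerSpec(
            kind=l["kind"],
            out_channels=l["out_channels"],
            in_channels=l["in_channels"],
            kernel_w=l["kernel_w"],
            window_w=l["window_w"],
            beta=l["beta"],
            lif=LIFParams(**l["lif"]),
        )
        for l in d["layers"]
    )
    return NetworkSpec(
        layers,
        input_channels=d["input_channels"],
        input_len=d["input_len"],
        T=d["T"],
    )


def save_network(net: Network, path) -> None:
    """Write a single-file checkpoint (spec JSON + weight arrays)."""
    arrays = {"spec_json": np.frombuffer(_spec_to_json(net.spec).encode(), dtype=np.uint8)}
    for i in net.param_layers:
        w, w_a = net.weights[i]
        arrays[f"w_{i}"] = w
        arrays[f"wa_{i}"] = w_a
    with open(path, "wb") as fh:
        np.savez(fh, **arrays)


def load_network(path) -> Network:
    with np.load(path) as z:
        spec = _spec_from_json(bytes(z["spec_json"]).decode())
        weights = []
        for i, layer in enumerate(spec.layers):
            if layer.kind == "maxpool":
                weights.append(None)
            else:
                weights.append((z[f"w_{i}"], z[f"wa_{i}"]))
    return Network(spec=spec, weights=weights)
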