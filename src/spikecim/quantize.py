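"""Signed 4-bit weight quantization and crossbar layout.

Weights are quantized per layer to signed 4-bit fixed point under the base
``{-2^3, 2^2, 2^1, 2^0}``: a code ``W[3]W[2]W[1]W[0]`` decodes to
``-8*W3 + 4*W2 + 2*W1 + W0`` (two's complement, range [-8, 7]).  Bit 1 maps
to a low-resistance ReRAM cell (LRS), bit 0 to high resistance (HRS).

Each convolution kernel is unrolled "in the input-channel direction" into a
slender bar of ``kernel_w * C_in`` rows and stored in a group of 4 adjacent
columns (one per bit, sign leftmost).  Integrative and adaptive kernels of
the same output channel occupy adjacent groups (I_1, A_1, I_2, A_2, ...) so
they share row addressing and can be subtracted after current merging.  FC
weight matrices map directly, one row per input and one 4-column I/A group
pair per output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .network import Network

__all__ = [
    "quantize_weight",
    "layer_scale",
    "encode_q4",
    "decode_q4",
    "Q4_BASE",
    "LayerLayout",
    "CrossbarLayout",
    "map_network",
    "layout_codes_to_weights",
    "save_layout",
    "load_layout",
]

Q4_BASE = (-8, 4, 2, 1)  # column weights, sign bit leftmost
Q4_MIN, Q4_MAX = -8, 7


def layer_scale(w: np.ndarray) -> float:
    """Symmetric max-abs scale: the largest |w| lands on code magnitude 8.

    (A weight exactly at +max then clips to +7; the negative end uses the
    full -8.)
    """
    m = float(np.max(np.abs(w)))
    return m / 8.0 if m > 0 else 1.0


def quantize_weight(w, scale: float):
    """Round to the signed 4-bit grid: ``clip(round(w / scale), -8, 7)``."""
    if scale <= 0:
        raise ValueError("scale must be positive")
    w = np.asarray(w, dtype=float)
    if not np.all(np.isfinite(w)):
        raise ValueError("non-finite weight")
    q = np.clip(np.rint(w / scale), Q4_MIN, Q4_MAX).astype(np.int8)
    return q if q.ndim else int(q)


def encode_q4(v: int) -> tuple[int, int, int, int]:
    """Integer in [-8, 7] -> bits (W3, W2, W1, W0), two's complement."""
    v = int(v)
    if not (Q4_MIN <= v <= Q4_MAX):
        raise ValueError(f"value {v} outside [-8, 7]")
    u = v & 0xF
    return ((u >> 3) & 1, (u >> 2) & 1, (u >> 1) & 1, u & 1)


def decode_q4(bits) -> int:
    """Bits (W3, W2, W1, W0) -> integer via -8*W3 + 4*W2 + 2*W1 + W0."""
    w3, w2, w1, w0 = (int(b) for b in bits)
    for b in (w3, w2, w1, w0):
        if b not in (0, 1):
            raise ValueError("bits must be 0/1")
    return -8 * w3 + 4 * w2 + 2 * w1 + w0


def _codes_to_bits(codes: np.ndarray) -> np.ndarray:
    """Integer code matrix (R, G) -> bit matrix (R, 4G), sign column first."""
    u = (codes.astype(np.int64) & 0xF)[..., None]
    shifts = np.array([3, 2, 1, 0])
    bits = (u >> shifts) & 1
    return bits.reshape(codes.shape[0], -1).astype(np.uint8)


@dataclass
class TileRef:
    """One physical tile: a (rows, cols) bit matrix with its layout offsets."""

    row0: int
    col0: int
    bits: np.ndarray  # uint8 (r, c), c a multiple of 4


@dataclass
class LayerLayout:
    """One network layer mapped onto crossbar columns.

    codes : (rows, 2K) signed integer codes; group order I_1, A_1, ... I_K,
            A_K, so even group indices are integrative, odd adaptive.
    """

    layer_index: int
    kind: str
    rows: int
    n_groups: int  # 2 * K (I and A interleaved)
    scale: float
    codes: np.ndarray  # int8 (rows, n_groups)
    tiles: list = field(default_factory=list)

    @property
    def bits(self) -> np.ndarray:
        return _codes_to_bits(self.codes)


@dataclass
class CrossbarLayout:
    layers: list  # of LayerLayout
    tile_size: int = 128


def _tile(bits: np.ndarray, tile_size: int) -> list:
    """Split a bit matrix into tiles of at most tile_size rows/columns.

    Column splits land on 4-bit group boundaries so no weight straddles a
    tile edge.
    """
    col_step = tile_size - (tile_size % 4)
    tiles = []
    for r0 in range(0, bits.shape[0], tile_size):
        for c0 in range(0, bits.shape[1], col_step):
            tiles.append(
                TileRef(r0, c0, bits[r0 : r0 + tile_size, c0 : c0 + col_step])
            )
    return tiles


def map_network(net: Network, tile_size: int = 128) -> CrossbarLayout:
    """Quantize every SConv/FC layer and lay it out on crossbar tiles."""
    if tile_size < 4:
        raise ValueError("tile_size must be at least 4")
    layers = []
    for i in net.param_layers:
        layer = net.spec.layers[i]
        w, w_a = net.weights[i]
        scale = layer_scale(np.concatenate([w.ravel(), w_a.ravel()]))
        qw = quantize_weight(w, scale)
        qa = quantize_weight(w_a, scale)
        if layer.kind == "sconv":
            # slender bars: rows = C_in * kernel_w (channel-major), one
            # column group per kernel
            k = layer.out_channels
            rows = layer.in_channels * layer.kernel_w
            qw2 = qw.reshape(k, rows).T  # (rows, K)
            qa2 = qa.reshape(k, rows).T
        else:
            k = layer.out_channels
            rows = layer.in_channels
            qw2 = qw.T  # (N_in, N_out)
            qa2 = qa.T
        codes = np.empty((rows, 2 * k), dtype=np.int8)
        codes[:, 0::2] = qw2
        codes[:, 1::2] = qa2
        ll = LayerLayout(
            layer_index=i,
            kind=layer.kind,
            rows=rows,
            n_groups=2 * k,
            scale=scale,
            codes=codes,
        )
        ll.tiles = _tile(ll.bits, tile_size)
        layers.append(ll)
    return CrossbarLayout(layers=layers, tile_size=tile_size)


def layout_codes_to_weights(ll: LayerLayout, spec_layer) -> tuple[np.ndarray, np.ndarray]:
    """Regroup a layer layout back into (w_q, w_a_q) quantized weight arrays.

    Reassembles the code matrix from the stored tiles (verifying the mapping
    is lossless) and undoes the slender-bar transposition.
    """
    bits = np.zeros((ll.rows, 4 * ll.n_groups), dtype=np.uint8)
    for t in ll.tiles:
        bits[t.row0 : t.row0 + t.bits.shape[0], t.col0 : t.col0 + t.bits.shape[1]] = t.bits
    b = bits.reshape(ll.rows, ll.n_groups, 4).astype(np.int64)
    codes = -8 * b[..., 0] + 4 * b[..., 1] + 2 * b[..., 2] + b[..., 3]
    qi = codes[:, 0::2].T.astype(float) * ll.scale
    qa = codes[:, 1::2].T.astype(float) * ll.scale
    if ll.kind == "sconv":
        qi = qi.reshape(spec_layer.out_channels, spec_layer.in_channels, spec_layer.kernel_w)
        qa = qa.reshape(spec_layer.out_channels, spec_layer.in_channels, spec_layer.kernel_w)
    return qi, qa


def quantized_network(net: Network, layout: CrossbarLayout | None = None) -> Network:
    """Digital twin: the network with weights snapped to their 4-bit values."""
    if layout is None:
        layout = map_network(net)
    weights = list(net.weights)
    for ll in layout.layers:
        qi, qa = layout_codes_to_weights(ll, net.spec.layers[ll.layer_index])
        weights[ll.layer_index] = (qi, qa)
    return Network(spec=net.spec, weights=weights)


def save_layout(layout: CrossbarLayout, path) -> None:
    """Single-file container: per-layer codes, scales and the group map."""
    meta = dict(
        tile_size=layout.tile_size,
        layers=[
            dict(layer_index=ll.layer_index, kind=ll.kind, rows=ll.rows,
                 n_groups=ll.n_groups, scale=ll.scale)
            for ll in layout.layers
        ],
    )
    arrays = {"meta_json": np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)}
    for j, ll in enumerate(layout.layers):
        arrays[f"codes_{j}"] = ll.codes
    with open(path, "wb") as fh:
        np.savez(fh, **arrays)


def load_layout(path) -> CrossbarLayout:
    with np.load(path) as z:
        meta = json.loads(bytes(z["meta_json"]).decode())
        layers = []
        for j, m in enumerate(meta["layers"]):
            ll = LayerLayout(codes=np.asarray(z[f"codes_{j}"], dtype=np.int8), **m)
            ll.tiles = _tile(ll.bits, meta["tile_size"])
            layers.append(ll)
    return CrossbarLayout(layers=layers, tile_size=meta["tile_size"])
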