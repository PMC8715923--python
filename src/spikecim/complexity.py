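"""Cycle-count complexity model: frame-based CNN vs spike-based CNN.

For a convolution layer producing an ``MH x MW`` feature map with an
``KH x KW`` kernel over ``C_in`` input and ``C_out`` output channels, the
frame-based CNN needs

    T_CNN  = sum MH*MW*(KH*KW + KH + KW - 1)*C_in*C_out * Ops * bit
             + sum N_in*N_out * Ops * bit                       (FC layers)

cycles (each MAC costed at the multiplier's cycle count, data ``bit`` wide),
while the spike-based network replaces every multiply by an add of 1-bit
data repeated over ``t`` time steps:

    T_SCNN = sum MH*MW*(KH + KW - 1)*C_in*C_out * Ops * bit * t
             + sum N_in*N_out * Ops * bit * t

Defaults: multiply = 10 cycles, add = 1 cycle, 32-bit vs 1-bit data, t = 25.
Pooling layers cost nothing.  The headline figure is the relative reduction
``1 - T_SCNN / T_CNN``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .network import NetworkSpec, propagate_shapes

__all__ = ["ComplexityReport", "cnn_cost", "scnn_cost", "reduction", "breakdown"]


@dataclass
class ComplexityReport:
    T_CNN: float
    T_SCNN: float
    reduction: float
    per_layer: pd.DataFrame


def _layer_terms(spec: NetworkSpec):
    """(index, kind, conv factor pieces) for every costed layer."""
    shapes = propagate_shapes(spec)
    c, ln = spec.input_channels, spec.input_len
    terms = []
    for i, layer in enumerate(spec.layers):
        if layer.kind == "sconv":
            co, lo = shapes[i]
            # 1-D kernels: KH = 1, KW = kernel_w; MH = 1, MW = output length
            kh, kw = 1, layer.kernel_w
            terms.append(dict(index=i, kind="sconv", MH=1, MW=lo, KH=kh, KW=kw,
                              C_in=layer.in_channels, C_out=co))
        elif layer.kind == "fc":
            terms.append(dict(index=i, kind="fc", N_in=layer.in_channels,
                              N_out=layer.out_channels))
    return terms


def cnn_cost(spec: NetworkSpec, ops_mult: int = 10, bit: int = 32) -> float:
    """Cycle count of the frame-based CNN of identical structure."""
    total = 0.0
    for t in _layer_terms(spec):
        if t["kind"] == "sconv":
            total += (t["MH"] * t["MW"] * (t["KH"] * t["KW"] + t["KH"] + t["KW"] - 1)
                      * t["C_in"] * t["C_out"] * ops_mult * bit)
        else:
            total += t["N_in"] * t["N_out"] * ops_mult * bit
    return total


def scnn_cost(spec: NetworkSpec, ops_add: int = 1, bit: int = 1, t: int = 25) -> float:
    """Cycle count of the spike-based network over ``t`` time steps."""
    total = 0.0
    for term in _layer_terms(spec):
        if term["kind"] == "sconv":
            total += (term["MH"] * term["MW"] * (term["KH"] + term["KW"] - 1)
                      * term["C_in"] * term["C_out"] * ops_add * bit * t)
        else:
            total += term["N_in"] * term["N_out"] * ops_add * bit * t
    return total


def reduction(spec: NetworkSpec, ops_mult: int = 10, ops_add: int = 1,
              bit_cnn: int = 32, bit_scnn: int = 1, t: int = 25) -> float:
    """Relative complexity reduction ``1 - T_SCNN / T_CNN``."""
    tc = cnn_cost(spec, ops_mult=ops_mult, bit=bit_cnn)
    if tc == 0:
        raise ZeroDivisionError("CNN cost is zero")
    return 1.0 - scnn_cost(spec, ops_add=ops_add, bit=bit_scnn, t=t) / tc


def breakdown(spec: NetworkSpec, ops_mult: int = 10, ops_add: int = 1,
              bit_cnn: int = 32, bit_scnn: int = 1, t: int = 25) -> ComplexityReport:
    """Per-layer table plus totals and the overall reduction."""
    rows = []
    for term in _layer_terms(spec):
        if term["kind"] == "sconv":
            cnn = (term["MW"] * (term["KH"] * term["KW"] + term["KH"] + term["KW"] - 1)
                   * term["C_in"] * term["C_out"] * ops_mult * bit_cnn)
            scnn = (term["MW"] * (term["KH"] + term["KW"] - 1)
                    * term["C_in"] * term["C_out"] * ops_add * bit_scnn * t)
        else:
            cnn = term["N_in"] * term["N_out"] * ops_mult * bit_cnn
            scnn = term["N_in"] * term["N_out"] * ops_add * bit_scnn * t
        rows.append(dict(layer=term["index"], kind=term["kind"],
                         T_CNN=float(cnn), T_SCNN=float(scnn),
                         reduction=1.0 - scnn / cnn))
    df = pd.DataFrame(rows)
    tc, ts = df["T_CNN"].sum(), df["T_SCNN"].sum()
    return ComplexityReport(T_CNN=tc, T_SCNN=ts, reduction=1.0 - ts / tc, per_layer=df)
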