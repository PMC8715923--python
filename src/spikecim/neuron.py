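"""Adaptive leaky integrate-and-fire (LIF) neuron.

The iterative membrane update (Euler discretization of the leaky integrator)

    u[t+1] = k_tau * u[t] + I * R0

with hard reset to 0 on spiking, non-negative stimulus clamping, and the
rectangular surrogate derivative used for training.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["LIFParams", "LIFLayerState", "clamp_stimulus", "lif_step", "surrogate_grad"]


@dataclass(frozen=True)
class LIFParams:
    """Per-layer neuron constants.

    k_tau : membrane decay constant in (0, 1), ``k_tau = 1 - dt/tau``.
    R0    : unit resistance (value 1 in the model).
    V_th  : firing threshold, > 0; a distinct constant per layer.
    a     : surrogate rectangular-pulse length, > 0.
    """

    k_tau: float = 0.8
    R0: float = 1.0
    V_th: float = 0.5
    a: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 < self.k_tau < 1.0):
            raise ValueError("k_tau must lie in (0, 1)")
        if self.V_th <= 0.0:
            raise ValueError("V_th must be positive")
        if self.a <= 0.0:
            raise ValueError("a must be positive")


@dataclass
class LIFLayerState:
    """Membrane potentials of one layer (post-reset, so always < V_th)."""

    u: np.ndarray

    @classmethod
    def zeros(cls, shape) -> "LIFLayerState":
        return cls(u=np.zeros(shape, dtype=float))


def clamp_stimulus(I0: np.ndarray) -> np.ndarray:
    """Self-modulation: negative pre-synaptic stimulus is clipped to zero."""
    return np.maximum(np.asarray(I0, dtype=float), 0.0)


def lif_step(
    state: LIFLayerState, I: np.ndarray, p: LIFParams
) -> tuple[LIFLayerState, np.ndarray]:
    """Advance one time step: decay + integrate, fire, hard-reset.

    ``I`` must already be clamped non-negative.  The spike is emitted in the
    same step the threshold is crossed; the membrane is then reset to exactly
    zero (hard reset, not subtraction), so the returned state always
    satisfies ``u < V_th``.

    Returns the new state and the binary spike array (uint8).
    """
    I = np.asarray(I, dtype=float)
    if not np.all(np.isfinite(I)):
        raise ValueError("non-finite stimulus")
    if not np.all(np.isfinite(state.u)):
        raise ValueError("non-finite membrane state")
    u_pre = p.k_tau * state.u + I * p.R0
    spikes = (u_pre >= p.V_th).astype(np.uint8)
    u_post = np.where(spikes == 1, 0.0, u_pre)
    return LIFLayerState(u=u_post), spikes


def surrogate_grad(u: np.ndarray, p: LIFParams) -> np.ndarray:
    """Rectangular surrogate for d(spike)/du.

    ``h(u) = a`` where ``|u - V_th| <= a/2`` (boundary inclusive), else 0.
    """
    u = np.asarray(u)
    if not np.issubdtype(u.dtype, np.floating):
        u = u.astype(float)
    band = np.abs(u - p.V_th) <= p.a / 2.0
    return np.where(band, u.dtype.type(p.a), u.dtype.type(0))
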