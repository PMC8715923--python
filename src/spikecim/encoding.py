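"""Poisson rate-coding spike encoder.

A normalized input intensity ``I_i`` in [0, 1] is turned into a binary spike
train over ``T`` discrete time steps: at each step, element *i* emits a spike
iff a fresh uniform draw ``X_i`` on (0, 1) satisfies ``X_i < I_i``.  Spike
counts per position are therefore Binomial(T, I_i), approximately Poisson with
mean ``T * I_i`` for small rates — hence "Poisson encoder".
"""

from __future__ import annotations

import numpy as np

__all__ = ["encode_poisson", "expected_spike_count", "validate_sample"]


def validate_sample(sample: np.ndarray) -> np.ndarray:
    """Validate a normalized sample: finite values in [0, 1].

    Returns the sample as a float ndarray; raises ``ValueError`` otherwise.
    """
    arr = np.asarray(sample, dtype=float)
    if arr.size == 0:
        raise ValueError("empty sample")
    if not np.all(np.isfinite(arr)):
        raise ValueError("sample contains non-finite values")
    if arr.min() < 0.0 or arr.max() > 1.0:
        raise ValueError(
            f"sample values must lie in [0, 1]; got range "
            f"[{arr.min():.4g}, {arr.max():.4g}]"
        )
    return arr


def encode_poisson(sample: np.ndarray, T: int, seed: int) -> np.ndarray:
    """Encode a normalized sample into a binary spike train.

    Parameters
    ----------
    sample : array, shape (C, L) or any shape, values in [0, 1]
        Normalized input intensities.
    T : int
        Number of time steps (length of the encoding window).
    seed : int
        Seed for the per-call random generator; encoding is deterministic
        given ``(sample, T, seed)``.

    Returns
    -------
    spikes : uint8 array, shape (T, *sample.shape)
        Binary spike train.  A fresh uniform tensor is drawn at every time
        step (i.i.d. across steps), so the spike count at each position is
        Binomial(T, I_i) with mean ``T * I_i``.
    """
    arr = validate_sample(sample)
    T = int(T)
    if T < 1:
        raise ValueError("T must be a positive integer")
    rng = np.random.default_rng(seed)
    # uniform() samples on [0, 1); the strict `<` makes I=0 silent and I=1
    # fire every step, matching the open-interval (0,1) semantics.
    x = rng.uniform(size=(T,) + arr.shape)
    return (x < arr[None, ...]).astype(np.uint8)


def expected_spike_count(sample: np.ndarray, T: int) -> np.ndarray:
    """Expected spike count per position: ``lambda_i = T * I_i``."""
    arr = validate_sample(sample)
    if int(T) < 1:
        raise ValueError("T must be a positive integer")
    return float(T) * arr
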