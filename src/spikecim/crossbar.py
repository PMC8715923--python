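"""Behavioral ReRAM crossbar compute-in-memory engine.

Simulates inference of a quantized spiking network executed inside 1T1R
memory tiles: weights live as conductances (bit 1 -> G_LRS, bit 0 -> G_HRS),
binary input spikes select rows in batches of at most six, and each bit line
sums its column currents by Kirchhoff's current law.  The four bit-line
currents of a weight group are merged with weights {-8, 4, 2, 1}; the sign
line is only connected when its current exceeds the all-HRS background
``6 * I_HRS`` (i.e. at least one of the six selected weights is negative).
Integrative and adaptive group currents are then subtracted
(``I_I - beta * I_A``), rescaled to weight units, and fed to the same LIF
dynamics, pooling and spike-counter readout as the digital network.

Device non-idealities: multiplicative conductance variation split into a
device-to-device part (drawn once when the array is programmed) and a
cycle-to-cycle part (redrawn at every read), and stuck-at faults that pin a
cell to HRS (SAH) or LRS (SAL) regardless of the programmed bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .encoding import encode_poisson
from .network import Network, conv_windows, run_spike_train
from .quantize import CrossbarLayout, LayerLayout

__all__ = [
    "DeviceModel",
    "NonIdealityConfig",
    "ProgrammedTile",
    "ProgrammedLayer",
    "ProgrammedNetwork",
    "program",
    "bitline_currents",
    "wcma_merge",
    "group_output",
    "current_to_mac",
    "make_cim_backend",
    "cim_forward",
    "cim_evaluate",
    "sweep_nonideality",
    "saf_fractions",
]

PARALLEL_ROWS = 6  # WL/SL driver selects six rows at a time


@dataclass(frozen=True)
class DeviceModel:
    """ReRAM cell constants.  ``G_HRS = 0`` models an infinite on/off ratio."""

    G_LRS: float = 1e-4  # siemens
    G_HRS: float = 1e-7
    V_read: float = 0.2  # volts

    def __post_init__(self) -> None:
        if self.G_LRS <= 0 or self.G_HRS < 0 or self.V_read <= 0:
            raise ValueError("conductances/voltage must be positive (G_HRS may be 0)")
        if self.G_HRS > 0 and self.G_LRS / self.G_HRS <= 100:
            raise ValueError("on/off ratio must exceed 100")

    @property
    def I_LRS(self) -> float:
        return self.V_read * self.G_LRS

    @property
    def I_HRS(self) -> float:
        return self.V_read * self.G_HRS


@dataclass(frozen=True)
class NonIdealityConfig:
    """Conductance variation and stuck-at-fault injection.

    variation_ratio : fluctuation range divided by the mean conductance; a
        cell's conductance is scaled by Uniform(1 - r/2, 1 + r/2).
    c2c_share : fraction of the variation ratio that is cycle-to-cycle
        (redrawn per read); the remainder is device-to-device.
    p_SAL / p_SAH : per-cell stuck-at-LRS / stuck-at-HRS probabilities.
    cluster_mode : "cell" (i.i.d. cells, default), "row" or "col" (faults
        take out whole lines, as manufacturing defects sometimes do).
    """

    variation_ratio: float = 0.0
    c2c_share: float = 0.0
    p_SAL: float = 0.0
    p_SAH: float = 0.0
    seed: int = 0
    cluster_mode: str = "cell"

    def __post_init__(self) -> None:
        if self.variation_ratio < 0 or not (0 <= self.c2c_share <= 1):
            raise ValueError("invalid variation parameters")
        if not (0 <= self.p_SAL <= 1 and 0 <= self.p_SAH <= 1):
            raise ValueError("fault probabilities must lie in [0, 1]")
        if self.p_SAL + self.p_SAH > 1:
            raise ValueError("p_SAL + p_SAH must not exceed 1")
        if self.cluster_mode not in ("cell", "row", "col"):
            raise ValueError("cluster_mode must be cell/row/col")

    @property
    def r_d2d(self) -> float:
        return self.variation_ratio * (1.0 - self.c2c_share)

    @property
    def r_c2c(self) -> float:
        return self.variation_ratio * self.c2c_share


# SAF states
SAF_NONE, SAF_SAH, SAF_SAL = 0, 1, 2


@dataclass
class ProgrammedTile:
    row0: int
    col0: int
    bits: np.ndarray       # programmed codes (uint8)
    saf: np.ndarray        # int8, {0 none, 1 SAH, 2 SAL}
    d2d: np.ndarray        # multiplicative device-to-device factor
    G: np.ndarray          # effective static conductance (SAF + d2d applied)


@dataclass
class ProgrammedLayer:
    layout: LayerLayout
    tiles: list
    G: np.ndarray           # assembled (rows, 4 * n_groups)
    saf: np.ndarray
    row_chunks: list        # list of slices, each <= 6 rows, within tile rows


@dataclass
class ProgrammedNetwork:
    layers: list  # of ProgrammedLayer
    dev: DeviceModel
    ni: NonIdealityConfig


def _row_chunks(rows: int, tile_size: int) -> list:
    """Six-row batches that never straddle a row-tile boundary."""
    chunks = []
    for r0 in range(0, rows, tile_size):
        top = min(r0 + tile_size, rows)
        for s in range(r0, top, PARALLEL_ROWS):
            chunks.append(slice(s, min(s + PARALLEL_ROWS, top)))
    return chunks


def program(layout: CrossbarLayout, dev: DeviceModel, ni: NonIdealityConfig) -> ProgrammedNetwork:
    """Write the layout into (simulated) hardware.

    Nominal conductance is ``G_LRS`` for bit 1 and ``G_HRS`` for bit 0;
    stuck-at states override the programmed bit; device-to-device factors
    are drawn once per cell.
    """
    rng = np.random.default_rng(ni.seed)
    players = []
    for ll in layout.layers:
        tiles = []
        rows, cols = ll.rows, 4 * ll.n_groups
        G_full = np.zeros((rows, cols))
        saf_full = np.zeros((rows, cols), dtype=np.int8)
        for t in ll.tiles:
            shape = t.bits.shape
            if ni.cluster_mode == "cell":
                u = rng.uniform(size=shape)
            elif ni.cluster_mode == "row":
                u = np.broadcast_to(rng.uniform(size=(shape[0], 1)), shape)
            else:
                u = np.broadcast_to(rng.uniform(size=(1, shape[1])), shape)
            saf = np.where(u < ni.p_SAL, SAF_SAL, np.where(u < ni.p_SAL + ni.p_SAH, SAF_SAH, SAF_NONE)).astype(np.int8)
            eff_bits = np.where(saf == SAF_SAL, 1, np.where(saf == SAF_SAH, 0, t.bits))
            G_nom = np.where(eff_bits == 1, dev.G_LRS, dev.G_HRS)
            r = ni.r_d2d
            d2d = rng.uniform(1 - r / 2, 1 + r / 2, size=shape) if r > 0 else np.ones(shape)
            G = G_nom * d2d
            tiles.append(ProgrammedTile(t.row0, t.col0, t.bits, saf, d2d, G))
            G_full[t.row0 : t.row0 + shape[0], t.col0 : t.col0 + shape[1]] = G
            saf_full[t.row0 : t.row0 + shape[0], t.col0 : t.col0 + shape[1]] = saf
        players.append(
            ProgrammedLayer(
                layout=ll,
                tiles=tiles,
                G=G_full,
                saf=saf_full,
                row_chunks=_row_chunks(rows, layout.tile_size),
            )
        )
    return ProgrammedNetwork(layers=players, dev=dev, ni=ni)


def saf_fractions(pn: ProgrammedNetwork) -> tuple[float, float, int]:
    """(SAL fraction, SAH fraction, total cell count) over all tiles."""
    sal = sah = n = 0
    for pl in pn.layers:
        sal += int((pl.saf == SAF_SAL).sum())
        sah += int((pl.saf == SAF_SAH).sum())
        n += pl.saf.size
    return sal / n, sah / n, n


# ---------------------------------------------------------------------------
# current-domain primitives
# ---------------------------------------------------------------------------

def bitline_currents(tile: ProgrammedTile, active_rows, input_bits, dev: DeviceModel,
                     ni: NonIdealityConfig | None = None, rng=None) -> np.ndarray:
    """Column currents for one <=6-row read of a tile (KCL sum).

    ``active_rows`` are row indices within the tile; ``input_bits`` the
    binary input per listed row.  A fresh cycle-to-cycle factor is drawn per
    cell when configured.
    """
    active_rows = np.asarray(active_rows, dtype=int)
    input_bits = np.asarray(input_bits, dtype=float)
    if active_rows.size > PARALLEL_ROWS:
        raise ValueError(f"at most {PARALLEL_ROWS} rows may be selected at once")
    if not np.isin(input_bits, (0, 1)).all():
        raise ValueError("input bits must be binary")
    G = tile.G[active_rows]
    if ni is not None and ni.r_c2c > 0:
        rng = rng or np.random.default_rng(ni.seed)
        G = G * rng.uniform(1 - ni.r_c2c / 2, 1 + ni.r_c2c / 2, size=G.shape)
    return dev.V_read * (input_bits[:, None] * G).sum(axis=0)


def wcma_merge(I_BL, dev: DeviceModel):
    """Weighted current-mirror addition over one 4-column group.

    ``I_BL`` is ordered sign-first: ``[I[3], I[2], I[1], I[0]]``.  The sign
    current enters with weight -8 only when it exceeds the all-positive
    background ``6 * I_HRS`` (a transmission gate keeps a purely positive
    group from being polluted by its HRS leakage).
    """
    I_BL = np.asarray(I_BL, dtype=float)
    i3, i2, i1, i0 = I_BL[..., 0], I_BL[..., 1], I_BL[..., 2], I_BL[..., 3]
    gate = i3 > PARALLEL_ROWS * dev.I_HRS
    out = np.where(gate, -8.0 * i3, 0.0) + 4.0 * i2 + 2.0 * i1 + i0
    return out if out.ndim else float(out)


def group_output(I_sum_I, I_sum_A, beta: float):
    """Lateral inhibition in the current domain: ``I_I - beta * I_A``."""
    return I_sum_I - beta * np.asarray(I_sum_A, dtype=float)


def current_to_mac(I, dev: DeviceModel, n_active: int | np.ndarray = PARALLEL_ROWS,
                   sign_included: bool | np.ndarray = False):
    """Convert a merged group current back to weight units.

    Subtracts the expected all-HRS background for ``n_active`` driven rows
    (``7 * n * I_HRS`` with the sign line gated off, ``-1 * n * I_HRS`` with
    it connected) and divides by ``I_LRS - I_HRS``.  Exact integer recovery
    when devices are ideal and the on/off ratio is infinite; with a finite
    ratio a residual HRS-leakage error remains, as in the physical circuit.
    """
    n_active = np.asarray(n_active, dtype=float)
    sgn = np.asarray(sign_included)
    offset = np.where(sgn, -1.0, 7.0) * n_active * dev.I_HRS
    out = (np.asarray(I, dtype=float) - offset) / (dev.I_LRS - dev.I_HRS)
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# full-network CIM execution
# ---------------------------------------------------------------------------

def _chunk_tensors(pl: ProgrammedLayer, cols: np.ndarray):
    """Pad the six-row schedule into dense tensors for one-shot evaluation.

    Returns ``idx`` (n_chunks, 6) of row indices (padding rows point at a
    dummy all-zero slot) and ``G3`` (n_chunks, 6, len(cols)) restricted to
    the given columns, with zero conductance on padding rows.
    """
    n_chunks = len(pl.row_chunks)
    idx = np.full((n_chunks, PARALLEL_ROWS), pl.G.shape[0], dtype=np.intp)
    G3 = np.zeros((n_chunks, PARALLEL_ROWS, len(cols)))
    Gc = pl.G[:, cols]
    for k, sl in enumerate(pl.row_chunks):
        r = sl.stop - sl.start
        idx[k, :r] = np.arange(sl.start, sl.stop)
        G3[k, :r] = Gc[sl]
    return idx, G3


def make_cim_backend(net: Network, pn: ProgrammedNetwork, rng=None):
    """A ``mac(layer_index, layer, x)`` callable for ``run_spike_train``.

    Vectorizes the hardware schedule over the batch, all output positions
    and all six-row batches while keeping its exact arithmetic.  The three
    magnitude bit lines carry no gate, so by KCL their per-batch currents
    sum to one full-array product and are computed in a single matrix
    multiply with column weights {4, 2, 1}; the sign lines are evaluated
    per six-row batch, gated against the ``6 * I_HRS`` background, merged
    with weight -8 and background-corrected, then all partial MACs are
    accumulated digitally.  I/A groups are finally subtracted and rescaled
    to weight units.
    """
    dev, ni = pn.dev, pn.ni
    by_index = {pl.layout.layer_index: pl for pl in pn.layers}
    pre = {}
    for pl in pn.layers:
        n_groups = pl.layout.n_groups
        sign_cols = np.arange(0, 4 * n_groups, 4)
        # magnitude lines weighted 4/2/1 and pre-summed per group
        G_mag = 4.0 * pl.G[:, 1::4] + 2.0 * pl.G[:, 2::4] + pl.G[:, 3::4]
        idx, G3_sign = _chunk_tensors(pl, sign_cols)
        pre[pl.layout.layer_index] = (G_mag, idx, G3_sign)
    if ni.r_c2c > 0 and rng is None:
        rng = np.random.default_rng(ni.seed + 1)
    thr = PARALLEL_ROWS * dev.I_HRS
    denom = dev.I_LRS - dev.I_HRS

    def mac(i: int, layer, x: np.ndarray) -> np.ndarray:
        pl = by_index[i]
        if layer.kind == "sconv":
            win = conv_windows(x, layer.kernel_w)  # (B, Lo, rows)
        else:
            win = x[:, None, :]  # (B, 1, rows)
        B, Lo = win.shape[0], win.shape[1]
        n_groups = pl.layout.n_groups
        if ni.r_c2c > 0:
            macs = _mac_c2c(pl, win, dev, ni, rng)
        else:
            G_mag, idx, G3_sign = pre[i]
            I_mag = dev.V_read * (win @ G_mag)  # (B, Lo, n_groups)
            winp = np.concatenate([win, np.zeros((B, Lo, 1))], axis=-1)
            Xc = winp[:, :, idx]  # (B, Lo, n_chunks, 6)
            I_sign = dev.V_read * np.einsum(
                "blkr,krg->blkg", Xc, G3_sign, optimize=True)
            gate = I_sign > thr
            sign_term = np.where(gate, -8.0 * I_sign, 0.0).sum(axis=2)
            n_act = Xc.sum(axis=-1)  # (B, Lo, n_chunks)
            offset = (np.where(gate, -1.0, 7.0)
                      * n_act[..., None] * dev.I_HRS).sum(axis=2)
            macs = (I_mag + sign_term - offset) / denom
        qi = macs[..., 0::2]
        qa = macs[..., 1::2]
        I0 = (qi - layer.beta * qa) * pl.layout.scale  # (B, Lo, K)
        if layer.kind == "sconv":
            return I0.transpose(0, 2, 1)
        return I0[:, 0, :]

    return mac


def _mac_c2c(pl: ProgrammedLayer, win: np.ndarray, dev: DeviceModel,
             ni: NonIdealityConfig, rng) -> np.ndarray:
    """Slow path with per-cell, per-read cycle-to-cycle conductance draws."""
    B, Lo = win.shape[0], win.shape[1]
    n_groups = pl.layout.n_groups
    macs = np.zeros((B, Lo, n_groups))
    thr = PARALLEL_ROWS * dev.I_HRS
    denom = dev.I_LRS - dev.I_HRS
    for sl in pl.row_chunks:
        Xc = win[:, :, sl]
        n_act = Xc.sum(axis=-1)
        G = pl.G[sl]
        noise = rng.uniform(1 - ni.r_c2c / 2, 1 + ni.r_c2c / 2,
                            size=(B, Lo) + G.shape)
        I = dev.V_read * np.einsum("blr,rc,blrc->blc", Xc, G, noise,
                                   optimize=True)
        Ig = I.reshape(B, Lo, n_groups, 4)
        sign_open = Ig[..., 0] > thr
        merged = (np.where(sign_open, -8.0 * Ig[..., 0], 0.0)
                  + 4.0 * Ig[..., 1] + 2.0 * Ig[..., 2] + Ig[..., 3])
        offset = np.where(sign_open, -1.0, 7.0) * n_act[..., None] * dev.I_HRS
        macs += (merged - offset) / denom
    return macs


def cim_forward(net: Network, pn: ProgrammedNetwork, sample: np.ndarray, seed: int = 0):
    """Encode one sample and classify it on the programmed crossbar."""
    sample = np.asarray(sample, dtype=float)
    if sample.ndim == 1:
        sample = sample[None, :]
    spikes = encode_poisson(sample, net.spec.T, seed)
    preds, counts = run_spike_train(net, spikes[None, ...], mac=make_cim_backend(net, pn))
    return int(preds[0]), counts[0]


def cim_evaluate(net: Network, pn: ProgrammedNetwork, X: np.ndarray, y: np.ndarray,
                 seed: int = 0, batch_size: int = 25) -> float:
    """Crossbar-inference accuracy on a labeled fixture set."""
    mac = make_cim_backend(net, pn)
    T = net.spec.T
    correct = 0
    for s in range(0, len(X), batch_size):
        xb = X[s : s + batch_size]
        spikes = np.stack(
            [encode_poisson(x[None, :], T, seed + s + j) for j, x in enumerate(xb)]
        )
        preds, _ = run_spike_train(net, spikes, mac=mac)
        correct += int((preds == y[s : s + batch_size]).sum())
    return correct / len(X)


def sweep_nonideality(net: Network, layout: CrossbarLayout, dev: DeviceModel,
                      grid, X: np.ndarray, y: np.ndarray, n_seeds: int = 20,
                      base_seed: int = 0, encoder_seed: int = 0) -> pd.DataFrame:
    """Accuracy under a grid of non-ideality settings.

    ``grid`` is an iterable of dicts with any of ``variation_ratio``,
    ``c2c_share``, ``p_SAL``, ``p_SAH``; each point is re-programmed and
    evaluated with ``n_seeds`` independent device draws (same encoder seed,
    so only device randomness varies).  Returns one row per grid point with
    mean accuracy and its standard deviation.
    """
    grid = list(grid)
    if not grid:
        raise ValueError("empty non-ideality grid")
    rows = []
    for point in grid:
        accs = []
        for s in range(n_seeds):
            ni = NonIdealityConfig(seed=base_seed + 7919 * s + 1, **point)
            pn = program(layout, dev, ni)
            accs.append(cim_evaluate(net, pn, X, y, seed=encoder_seed))
        rows.append(dict(point, n_seeds=n_seeds,
                         accuracy_mean=float(np.mean(accs)),
                         accuracy_sd=float(np.std(accs, ddof=1)) if n_seeds > 1 else 0.0))
    return pd.DataFrame(rows)
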