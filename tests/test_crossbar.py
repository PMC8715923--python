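import numpy as np
import pytest

import spikecim as sc
from spikecim.crossbar import (
    PARALLEL_ROWS,
    DeviceModel,
    NonIdealityConfig,
    SAF_NONE,
    SAF_SAH,
    SAF_SAL,
    bitline_currents,
    cim_forward,
    current_to_mac,
    group_output,
    make_cim_backend,
    program,
    saf_fractions,
    sweep_nonideality,
    wcma_merge,
)
from spikecim.network import build_network
from spikecim.quantize import encode_q4, map_network, quantized_network

IDEAL = DeviceModel(G_LRS=1e-4, G_HRS=0.0, V_read=0.2)
FINITE = DeviceModel(G_LRS=1e-4, G_HRS=1e-7, V_read=0.2)
CLEAN = NonIdealityConfig(seed=0)


def small_net(seed=0, T=6):
    spec = sc.NetworkSpec.default(T=T)
    return build_network(spec, seed=seed)


def programmed(net, dev=IDEAL, ni=CLEAN):
    return program(map_network(net), dev, ni)


# ---------------------------------------------------------------------------
# device / config validation
# ---------------------------------------------------------------------------

def test_device_requires_on_off_ratio_over_100():
    with pytest.raises(ValueError):
        DeviceModel(G_LRS=1e-4, G_HRS=1e-5)
    DeviceModel(G_LRS=1e-4, G_HRS=9e-7)  # ratio > 100 passes


def test_zero_hrs_means_infinite_ratio():
    dev = DeviceModel(G_LRS=1e-4, G_HRS=0.0)
    assert dev.I_HRS == 0.0
    assert dev.I_LRS == pytest.approx(0.2 * 1e-4)


@pytest.mark.parametrize(
    "kw",
    [
        dict(variation_ratio=-0.1),
        dict(c2c_share=1.5),
        dict(p_SAL=0.7, p_SAH=0.6),
        dict(p_SAH=-0.1),
        dict(cluster_mode="diag"),
    ],
)
def test_invalid_nonideality_config_rejected(kw):
    with pytest.raises(ValueError):
        NonIdealityConfig(**kw)


def test_variation_split_between_d2d_and_c2c():
    ni = NonIdealityConfig(variation_ratio=1.0, c2c_share=0.3)
    assert ni.r_d2d == pytest.approx(0.7)
    assert ni.r_c2c == pytest.approx(0.3)


# ---------------------------------------------------------------------------
# programming
# ---------------------------------------------------------------------------

def test_ideal_programming_maps_bits_to_conductances():
    net = small_net()
    pn = programmed(net, FINITE, CLEAN)
    for pl in pn.layers:
        bits = pl.layout.bits
        expect = np.where(bits == 1, FINITE.G_LRS, FINITE.G_HRS)
        np.testing.assert_array_equal(pl.G, expect)
        assert (pl.saf == SAF_NONE).all()


def test_programming_is_deterministic_per_seed():
    net = small_net()
    ni = NonIdealityConfig(variation_ratio=0.5, p_SAH=0.05, seed=9)
    a = programmed(net, FINITE, ni)
    b = programmed(net, FINITE, ni)
    np.testing.assert_array_equal(a.layers[0].G, b.layers[0].G)
    c = programmed(net, FINITE, NonIdealityConfig(variation_ratio=0.5, p_SAH=0.05, seed=10))
    assert not np.array_equal(a.layers[0].G, c.layers[0].G)


def test_d2d_variation_stays_in_configured_band():
    net = small_net()
    r = 0.5
    pn = programmed(net, FINITE, NonIdealityConfig(variation_ratio=r, seed=1))
    for pl in pn.layers:
        np.testing.assert_array_less(np.abs(pl.tiles[0].d2d - 1.0), r / 2 + 1e-12)


def test_stuck_at_faults_pin_conductance():
    net = small_net()
    pn = programmed(net, FINITE, NonIdealityConfig(p_SAL=0.3, p_SAH=0.3, seed=2))
    for pl in pn.layers:
        assert np.all(pl.G[pl.saf == SAF_SAL] == FINITE.G_LRS)
        assert np.all(pl.G[pl.saf == SAF_SAH] == FINITE.G_HRS)


def test_saf_fractions_match_binomial_rates():
    net = small_net()
    p_sal, p_sah = 0.03, 0.0904
    pn = programmed(net, FINITE, NonIdealityConfig(p_SAL=p_sal, p_SAH=p_sah, seed=3))
    f_sal, f_sah, n = saf_fractions(pn)
    assert n > 100_000
    for frac, p in ((f_sal, p_sal), (f_sah, p_sah)):
        sd = np.sqrt(p * (1 - p) / n)
        assert abs(frac - p) <= 4 * sd


def test_row_and_column_cluster_modes():
    net = small_net()
    for mode, axis in (("row", 1), ("col", 0)):
        pn = programmed(
            net, FINITE, NonIdealityConfig(p_SAH=0.2, seed=4, cluster_mode=mode)
        )
        t = pn.layers[-2].tiles[0]  # a full-width FC tile
        faulty = t.saf == SAF_SAH
        # faults cover entire lines: each line is all-faulty or fault-free
        line_frac = faulty.mean(axis=axis)
        assert set(np.round(line_frac, 12)) <= {0.0, 1.0}


def test_row_chunks_are_at_most_six_rows_and_cover_layer():
    net = small_net()
    pn = programmed(net)
    for pl in pn.layers:
        covered = np.zeros(pl.layout.rows, dtype=bool)
        for sl in pl.row_chunks:
            assert sl.stop - sl.start <= PARALLEL_ROWS
            covered[sl] = True
        assert covered.all()


# ---------------------------------------------------------------------------
# current-domain primitives
# ---------------------------------------------------------------------------

def _single_tile(codes_col, dev=FINITE):
    """Program one 6-row x 1-group tile holding the given integer codes."""
    bits = np.array([encode_q4(c) for c in codes_col], dtype=np.uint8)
    from spikecim.crossbar import ProgrammedTile

    G = np.where(bits == 1, dev.G_LRS, dev.G_HRS)
    return ProgrammedTile(0, 0, bits, np.zeros_like(bits, dtype=np.int8), np.ones_like(G), G)


def test_bitline_current_is_kcl_sum():
    dev = FINITE
    tile = _single_tile([3, -5, 7, 0, -8, 1], dev)
    x = np.array([1, 1, 0, 1, 1, 0])
    I = bitline_currents(tile, np.arange(6), x, dev)
    # column currents = V * sum of active-row conductances
    G = tile.G
    np.testing.assert_allclose(I, dev.V_read * (x[:, None] * G).sum(axis=0))


def test_bitline_additivity_over_rows():
    dev = FINITE
    tile = _single_tile([2, -1, 5, -7, 0, 6], dev)
    full = bitline_currents(tile, np.arange(6), np.ones(6), dev)
    parts = sum(
        bitline_currents(tile, [r], [1], dev) for r in range(6)
    )
    np.testing.assert_allclose(full, parts, rtol=1e-12)


def test_bitline_rejects_more_than_six_rows():
    tile = _single_tile([0, 0, 0, 0, 0, 0])
    with pytest.raises(ValueError):
        bitline_currents(tile, np.arange(7) % 6, np.ones(7), FINITE)


def test_wcma_gate_blocks_all_positive_group():
    dev = FINITE
    # all-positive codes: sign column all HRS -> I3 = 6 * I_HRS, gate closed
    tile = _single_tile([3, 7, 1, 0, 2, 4], dev)
    I = bitline_currents(tile, np.arange(6), np.ones(6), dev)
    assert I[0] == pytest.approx(6 * dev.I_HRS)
    merged = wcma_merge(I, dev)
    # merged current counts only the magnitude lines
    assert merged == pytest.approx(4 * I[1] + 2 * I[2] + I[3])


def test_wcma_gate_opens_with_one_negative_weight():
    dev = FINITE
    tile = _single_tile([3, 7, 1, 0, 2, -4], dev)
    I = bitline_currents(tile, np.arange(6), np.ones(6), dev)
    assert I[0] > 6 * dev.I_HRS
    merged = wcma_merge(I, dev)
    assert merged == pytest.approx(-8 * I[0] + 4 * I[1] + 2 * I[2] + I[3])


def test_group_output_subtracts_scaled_adaptive_current():
    assert group_output(10.0, 4.0, 0.25) == pytest.approx(9.0)


@pytest.mark.parametrize("codes", [[3, -5, 7, 0, -8, 1], [0, 0, 0, 0, 0, 0], [7, 7, 7, 7, 7, 7], [-8, -8, -8, -8, -8, -8]])
@pytest.mark.parametrize("dev", [IDEAL, FINITE])
def test_six_row_mac_recovers_integer_dot_product(codes, dev):
    tile = _single_tile(codes, dev)
    x = np.array([1, 0, 1, 1, 0, 1])
    I = bitline_currents(tile, np.arange(6), x, dev)
    sign_open = I[0] > 6 * dev.I_HRS
    mac = current_to_mac(wcma_merge(I, dev), dev, n_active=int(x.sum()),
                         sign_included=sign_open)
    exact = int(np.dot(np.array(codes), x))
    if dev.G_HRS == 0.0:
        assert mac == pytest.approx(exact, abs=1e-9)
    else:
        # finite on/off ratio leaves only HRS-leakage error
        assert abs(mac - exact) < 16 * dev.G_HRS / dev.G_LRS * 6 * 8


def test_exhaustive_mac_oracle_all_weights_and_patterns():
    """All 16 weight codes x all 64 input patterns, weight alone in a chunk."""
    dev = IDEAL
    for w in range(-8, 8):
        tile = _single_tile([w, 0, 0, 0, 0, 0], dev)
        for pat in range(64):
            x = np.array([(pat >> k) & 1 for k in range(6)])
            I = bitline_currents(tile, np.arange(6), x, dev)
            sign_open = I[0] > 6 * dev.I_HRS
            mac = current_to_mac(wcma_merge(I, dev), dev, n_active=int(x.sum()),
                                 sign_included=sign_open)
            assert mac == pytest.approx(w * x[0], abs=1e-9)


# ---------------------------------------------------------------------------
# full-network CIM
# ---------------------------------------------------------------------------

def test_ideal_cim_matches_digital_quantized_network():
    net = small_net(T=6)
    qnet = quantized_network(net)
    pn = programmed(net, IDEAL, CLEAN)
    rng = np.random.default_rng(0)
    for k in range(3):
        sample = rng.uniform(0, 1, size=251)
        p_dig, c_dig = sc.forward(qnet, sample, seed=k)
        p_cim, c_cim = cim_forward(qnet, pn, sample, seed=k)
        assert p_cim == p_dig
        np.testing.assert_array_equal(c_cim, c_dig)


def test_finite_on_off_ratio_cim_stays_close_to_digital():
    net = small_net(T=6)
    qnet = quantized_network(net)
    pn = programmed(net, FINITE, CLEAN)
    sample = np.linspace(0, 1, 251)
    p_dig, c_dig = sc.forward(qnet, sample, seed=1)
    p_cim, c_cim = cim_forward(qnet, pn, sample, seed=1)
    assert int(np.abs(c_cim - c_dig).max()) <= 1


def test_c2c_noise_path_changes_reads_but_not_validity():
    net = small_net(T=4)
    qnet = quantized_network(net)
    ni = NonIdealityConfig(variation_ratio=0.6, c2c_share=1.0, seed=5)
    pn = program(map_network(net), FINITE, ni)
    sample = np.linspace(0, 1, 251)
    p, counts = cim_forward(qnet, pn, sample, seed=0)
    assert 0 <= p < 4
    assert counts.min() >= 0 and counts.max() <= 4


def test_sweep_returns_one_row_per_grid_point(small_trained, fixture_beats):
    X, y = fixture_beats
    layout = map_network(small_trained)
    qnet = quantized_network(small_trained, layout)
    grid = [dict(variation_ratio=0.0), dict(p_SAH=0.5)]
    df = sweep_nonideality(qnet, layout, FINITE, grid, X[:8], y[:8],
                           n_seeds=2, base_seed=0)
    assert list(df["n_seeds"]) == [2, 2]
    assert df["accuracy_mean"].between(0, 1).all()
    assert len(df) == 2


def test_sweep_rejects_empty_grid(small_trained, fixture_beats):
    X, y = fixture_beats
    layout = map_network(small_trained)
    with pytest.raises(ValueError):
        sweep_nonideality(small_trained, layout, FINITE, [], X, y)
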