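import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from spikecim.data import (
    BEAT_WIDTH,
    DEFAULT_CLASS_MAP,
    BeatDataset,
    beats_from_record,
    load_wfdb,
    minmax_normalize,
    segment_beats,
    split,
    synth_beat,
    synth_dataset,
)

# ---------------------------------------------------------------------------
# synthetic generator
# ---------------------------------------------------------------------------

def test_beats_are_normalized_251_samples():
    for c in range(4):
        b = synth_beat(c, seed=c)
        assert b.signal.shape == (BEAT_WIDTH,)
        assert b.signal.min() == pytest.approx(0.0)
        assert b.signal.max() == pytest.approx(1.0)
        assert b.label == c


def test_synth_beat_deterministic_per_seed():
    a = synth_beat(1, seed=7)
    b = synth_beat(1, seed=7)
    c = synth_beat(1, seed=8)
    np.testing.assert_array_equal(a.signal, b.signal)
    assert not np.array_equal(a.signal, c.signal)


def test_invalid_class_rejected():
    with pytest.raises(ValueError):
        synth_beat(4)


def test_class_templates_are_morphologically_distinct():
    """Noise-free class means are pairwise farther apart than the beat-level
    within-class scatter, so the 4 classes are learnable but not trivial."""
    means = []
    for c in range(4):
        sigs = np.stack([synth_beat(c, noise_sd=0.0, seed=s).signal for s in range(30)])
        means.append(sigs.mean(axis=0))
    means = np.stack(means)
    for i in range(4):
        for j in range(i + 1, 4):
            assert np.linalg.norm(means[i] - means[j]) > 1.0


def test_dataset_sizes_and_balance():
    ds = synth_dataset(n_per_class=10, seed=0)
    assert len(ds) == 40
    _, y = ds.arrays(None)
    assert np.bincount(y, minlength=4).tolist() == [10, 10, 10, 10]


def test_split_is_stratified_4_to_1():
    ds = synth_dataset(n_per_class=10, seed=0)
    Xtr, ytr = ds.arrays("train")
    Xte, yte = ds.arrays("test")
    assert np.bincount(ytr, minlength=4).tolist() == [8, 8, 8, 8]
    assert np.bincount(yte, minlength=4).tolist() == [2, 2, 2, 2]
    assert len(Xtr) + len(Xte) == 40


def test_split_floor_behavior_on_odd_counts():
    ds = BeatDataset(beats=[synth_beat(c % 4, seed=i) for i, c in enumerate([0] * 7 + [1] * 7)])
    # relabel beats to two classes of 7
    for i, b in enumerate(ds.beats):
        b.label = 0 if i < 7 else 1
    split(ds, seed=0)
    _, ytr = ds.arrays("train")
    assert np.bincount(ytr).tolist() == [5, 5]  # floor(0.8 * 7)


def test_dataset_deterministic_per_seed():
    a = synth_dataset(n_per_class=5, seed=3)
    b = synth_dataset(n_per_class=5, seed=3)
    np.testing.assert_array_equal(a.arrays(None)[0], b.arrays(None)[0])
    assert a.split_tags == b.split_tags


def test_frame_round_trip():
    ds = synth_dataset(n_per_class=3, seed=0)
    df = ds.to_frame()
    assert df.shape == (12, BEAT_WIDTH + 2)
    ds2 = BeatDataset.from_frame(df)
    np.testing.assert_allclose(ds2.arrays(None)[0], ds.arrays(None)[0])
    assert ds2.split_tags == ds.split_tags


# ---------------------------------------------------------------------------
# normalization and segmentation
# ---------------------------------------------------------------------------

@given(st.lists(st.floats(-100, 100, allow_nan=False), min_size=2, max_size=50))
def test_minmax_lands_in_unit_interval(vals):
    x = minmax_normalize(np.array(vals))
    assert x.min() >= 0.0 and x.max() <= 1.0


def test_minmax_constant_signal_maps_to_zeros():
    np.testing.assert_array_equal(minmax_normalize(np.full(5, 3.3)), np.zeros(5))


def test_minmax_is_affine_invariant():
    x = np.array([1.0, 2.0, 5.0])
    np.testing.assert_allclose(minmax_normalize(x), minmax_normalize(10 * x - 3))


def test_segment_centers_window_on_r_peak():
    sig = np.zeros(1000)
    sig[500] = 1.0
    (w,) = segment_beats(sig, [500])
    assert len(w) == BEAT_WIDTH
    assert w[BEAT_WIDTH // 2] == 1.0  # R peak at index 125


def test_segment_drops_boundary_beats():
    sig = np.zeros(300)
    assert segment_beats(sig, [10]) == []  # too close to start
    assert segment_beats(sig, [290]) == []  # too close to end
    assert len(segment_beats(sig, [150])) == 1


# ---------------------------------------------------------------------------
# WFDB reading (byte-level fixture written on the fly)
# ---------------------------------------------------------------------------

def _pack_212(samples: np.ndarray) -> bytes:
    """Two 12-bit two's-complement samples into three bytes (format 212)."""
    s = samples.astype(np.int32) & 0xFFF
    if len(s) % 2:
        s = np.append(s, 0)
    out = bytearray()
    for s1, s2 in s.reshape(-1, 2):
        out.append(s1 & 0xFF)
        out.append(((s1 >> 8) & 0x0F) | (((s2 >> 8) & 0x0F) << 4))
        out.append(s2 & 0xFF)
    return bytes(out)


def _write_record(tmp_path, name, adc, fs=360, gain=200, baseline=0, beats=()):
    """adc: (n_samp, 2) integer samples; beats: list of (sample, code)."""
    n_samp = adc.shape[0]
    hea = [f"{name} 2 {fs} {n_samp}"]
    for _ in range(2):
        hea.append(f"{name}.dat 212 {gain}({baseline})/mV 12 0 0 0 0 sig")
    (tmp_path / f"{name}.hea").write_text("\n".join(hea) + "\n")
    interleaved = adc.reshape(-1)  # sample-major: s0ch0, s0ch1, s1ch0, ...
    (tmp_path / f"{name}.dat").write_bytes(_pack_212(interleaved))
    words = []
    prev = 0
    for sample, code in beats:
        words.append((code << 10) | (sample - prev))
        prev = sample
    words.append(0)  # EOF
    (tmp_path / f"{name}.atr").write_bytes(
        np.array(words, dtype="<u2").tobytes()
    )


def test_wfdb_round_trip_signal_and_annotations(tmp_path):
    rng = np.random.default_rng(0)
    adc = rng.integers(-2048, 2048, size=(600, 2), dtype=np.int32)
    # codes: 1 = N (class 0), 5 = V (class 2), 8 = A (class 1)
    _write_record(tmp_path, "r01", adc, gain=200, baseline=100,
                  beats=[(150, 1), (300, 5), (450, 8)])
    signal, ann, fs = load_wfdb(tmp_path / "r01")
    assert fs == 360.0
    np.testing.assert_allclose(signal, (adc[:, 0] - 100) / 200.0)
    assert list(ann["sample"]) == [150, 300, 450]
    assert list(ann["symbol"]) == ["N", "V", "A"]
    assert list(ann["label"]) == [0, 2, 1]


def test_wfdb_negative_samples_decode_correctly(tmp_path):
    adc = np.tile(np.array([[-2048, 2047]], dtype=np.int32), (10, 1))
    _write_record(tmp_path, "r02", adc, gain=100, baseline=0, beats=[(5, 1)])
    signal, _, _ = load_wfdb(tmp_path / "r02")
    np.testing.assert_allclose(signal, -2048 / 100.0)


def test_wfdb_unmapped_symbols_skipped(tmp_path):
    adc = np.zeros((400, 2), dtype=np.int32)
    # code 16 = "|" (non-beat artifact): in the symbol table, not the class map
    _write_record(tmp_path, "r03", adc, beats=[(100, 1), (200, 16), (300, 5)])
    _, ann, _ = load_wfdb(tmp_path / "r03")
    assert list(ann["symbol"]) == ["N", "V"]


def test_wfdb_custom_class_map(tmp_path):
    adc = np.zeros((400, 2), dtype=np.int32)
    _write_record(tmp_path, "r04", adc, beats=[(200, 5)])
    _, ann, _ = load_wfdb(tmp_path / "r04", class_map={"V": 3})
    assert list(ann["label"]) == [3]


def test_wfdb_missing_files_raise(tmp_path):
    with pytest.raises(FileNotFoundError):
        load_wfdb(tmp_path / "nope")


def test_beats_from_record_windows_and_normalizes(tmp_path):
    rng = np.random.default_rng(1)
    adc = rng.integers(-500, 500, size=(800, 2), dtype=np.int32)
    _write_record(tmp_path, "r05", adc, beats=[(60, 1), (400, 5)])
    beats = beats_from_record(tmp_path / "r05")
    # the beat at sample 60 is dropped (too close to the record start)
    assert len(beats) == 1
    assert beats[0].label == 2
    assert beats[0].signal.shape == (BEAT_WIDTH,)
    assert beats[0].signal.min() == pytest.approx(0.0)
    assert beats[0].signal.max() == pytest.approx(1.0)


def test_default_class_map_covers_four_classes():
    assert set(DEFAULT_CLASS_MAP.values()) == {0, 1, 2, 3}
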