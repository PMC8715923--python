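"""Heartbeat data: synthetic 4-class generator, WFDB reading, windowing.

The synthetic generator is a testable stand-in for a real single-lead
arrhythmia database.  Each beat is a sum of Gaussian bumps emulating the
P-QRS-T complex on a 251-sample window (R peak centered), with four fixed,
morphologically distinct class templates:

  0  "normal"        : full P-QRS-T with a narrow tall R wave
  1  "wide-QRS"      : ventricular-like — no P wave, broad R, deep slurred S
  2  "absent-P"      : supraventricular-like — missing P, retrograde bump
                       after the QRS, low flat T
  3  "elevated-T"    : fusion-like — small R, low P, dominant broad T wave

Per-beat timing (+-3 samples), amplitude (+-10%) and width jitter plus white
noise make the classes overlap realistically; every beat is min-max
normalized into [0, 1].

Real-data path: MIT-BIH-style records (.hea header, format-212 .dat signal,
MIT-format annotation file) are read by a small built-in reader and the
annotation symbols are grouped into the same four classes through an
editable mapping table (`DEFAULT_CLASS_MAP`, an assumption, not a property
of the recordings).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger("spikecim")

__all__ = [
    "Beat",
    "BeatDataset",
    "synth_beat",
    "synth_dataset",
    "minmax_normalize",
    "segment_beats",
    "split",
    "load_wfdb",
    "DEFAULT_CLASS_MAP",
    "BEAT_WIDTH",
]

BEAT_WIDTH = 251
N_CLASSES = 4

# class templates: list of (center sample, amplitude, width in samples)
_TEMPLATES = {
    0: [(85, 0.18, 6.0), (118, -0.12, 2.5), (125, 1.00, 3.0), (131, -0.18, 2.5), (172, 0.32, 11.0)],
    1: [(120, 0.95, 11.0), (142, -0.45, 9.0), (185, 0.50, 14.0)],
    2: [(125, 1.00, 3.0), (133, -0.15, 2.5), (150, 0.18, 4.0), (168, 0.12, 8.0)],
    3: [(85, 0.12, 6.0), (125, 0.55, 5.0), (178, 0.60, 16.0)],
}


@dataclass
class Beat:
    signal: np.ndarray  # length 251, min-max normalized to [0, 1]
    label: int


@dataclass
class BeatDataset:
    beats: list
    split_tags: list = field(default_factory=list)  # "train" / "test" per beat

    def __len__(self) -> int:
        return len(self.beats)

    def arrays(self, which: str | None = None):
        """(X, y) matrices, optionally restricted to the train/test split."""
        idx = range(len(self.beats)) if which is None else [
            i for i, tag in enumerate(self.split_tags) if tag == which
        ]
        X = np.stack([self.beats[i].signal for i in idx]) if idx else np.empty((0, BEAT_WIDTH))
        y = np.array([self.beats[i].label for i in idx], dtype=int)
        return X, y

    def to_frame(self) -> pd.DataFrame:
        X, y = self.arrays(None)
        df = pd.DataFrame(X, columns=[f"s{i}" for i in range(BEAT_WIDTH)])
        df["label"] = y
        if self.split_tags:
            df["split"] = self.split_tags
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "BeatDataset":
        cols = [f"s{i}" for i in range(BEAT_WIDTH)]
        beats = [Beat(row[cols].to_numpy(dtype=float), int(row["label"]))
                 for _, row in df.iterrows()]
        tags = list(df["split"]) if "split" in df.columns else []
        return cls(beats=beats, split_tags=tags)


def minmax_normalize(signal: np.ndarray) -> np.ndarray:
    """Scale into [0, 1]; a constant signal maps to all zeros."""
    x = np.asarray(signal, dtype=float)
    if x.size == 0:
        raise ValueError("empty signal")
    lo, hi = x.min(), x.max()
    if hi == lo:
        return np.zeros_like(x)
    return (x - lo) / (hi - lo)


def synth_beat(class_id: int, noise_sd: float = 0.05, seed: int = 0) -> Beat:
    """One synthetic beat of the given class, deterministic per seed."""
    if class_id not in _TEMPLATES:
        raise ValueError(f"class_id must be in 0..{N_CLASSES - 1}, got {class_id}")
    rng = np.random.default_rng(seed)
    n = np.arange(BEAT_WIDTH)
    x = np.zeros(BEAT_WIDTH)
    shift = rng.integers(-3, 4)
    for center, amp, width in _TEMPLATES[class_id]:
        a = amp * rng.normal(1.0, 0.10)
        w = width * rng.normal(1.0, 0.10)
        w = max(w, 0.5)
        x += a * np.exp(-0.5 * ((n - (center + shift)) / w) ** 2)
    # slow baseline wander
    x += 0.03 * np.sin(2 * np.pi * n / BEAT_WIDTH + rng.uniform(0, 2 * np.pi))
    x += rng.normal(0.0, noise_sd, size=BEAT_WIDTH)
    return Beat(signal=minmax_normalize(x), label=int(class_id))


def synth_dataset(n_per_class: int = 200, noise_sd: float = 0.05, seed: int = 0) -> BeatDataset:
    """Balanced 4-class dataset with a stratified 4:1 train/test split."""
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    ss = np.random.SeedSequence(seed)
    beat_seeds = np.random.default_rng(ss.spawn(1)[0]).integers(0, 2**31 - 1,
                                                                size=N_CLASSES * n_per_class)
    beats = []
    k = 0
    for c in range(N_CLASSES):
        for _ in range(n_per_class):
            beats.append(synth_beat(c, noise_sd=noise_sd, seed=int(beat_seeds[k])))
            k += 1
    ds = BeatDataset(beats=beats)
    return split(ds, seed=seed + 1)


def split(dataset: BeatDataset, seed: int = 0, train_frac: float = 0.8) -> BeatDataset:
    """Random stratified split: floor(train_frac * n) per class to train."""
    if len(dataset) < 5:
        raise ValueError("need at least 5 beats to split 4:1")
    rng = np.random.default_rng(seed)
    tags = [""] * len(dataset)
    labels = np.array([b.label for b in dataset.beats])
    for c in np.unique(labels):
        idx = np.flatnonzero(labels == c)
        rng.shuffle(idx)
        n_train = int(np.floor(train_frac * len(idx)))
        for i in idx[:n_train]:
            tags[i] = "train"
        for i in idx[n_train:]:
            tags[i] = "test"
    dataset.split_tags = tags
    return dataset


def segment_beats(signal: np.ndarray, r_locations, width: int = BEAT_WIDTH) -> list:
    """Centered windows around R locations (125 left / 125 right for 251).

    Beats too close to either record boundary are dropped.
    """
    signal = np.asarray(signal, dtype=float)
    left = width // 2
    right = width - left  # 126 for odd widths: [loc-125, loc+126)
    out = []
    for loc in r_locations:
        loc = int(loc)
        if loc - left < 0 or loc + right > len(signal):
            continue
        out.append(signal[loc - left : loc + right])
    return out


# ---------------------------------------------------------------------------
# WFDB-format reading (header + format-212 signal + MIT annotations)
# ---------------------------------------------------------------------------

# MIT annotation code -> symbol, for the beat types that occur in practice
_ANN_SYMBOLS = {
    1: "N", 2: "L", 3: "R", 4: "a", 5: "V", 6: "F", 7: "J", 8: "A", 9: "S",
    10: "E", 11: "j", 12: "/", 13: "Q", 16: "|", 34: "e", 35: "n", 38: "f",
}

# symbol -> 4-class grouping (AAMI-style: normal-like, supraventricular-like,
# ventricular-like, fusion/paced/unknown).  Editable; an assumption of this
# package, not a property of the source recordings.
DEFAULT_CLASS_MAP = {
    "N": 0, "L": 0, "R": 0, "e": 0, "j": 0,
    "A": 1, "a": 1, "J": 1, "S": 1,
    "V": 2, "E": 2,
    "F": 3, "f": 3, "Q": 3, "/": 3,
}


def _read_header(hea_path: Path):
    lines = [ln.strip() for ln in hea_path.read_text().splitlines()
             if ln.strip() and not ln.startswith("#")]
    head = lines[0].split()
    name, n_sig = head[0], int(head[1])
    fs = float(head[2].split("/")[0]) if len(head) > 2 else 250.0
    n_samp = int(head[3]) if len(head) > 3 else 0
    signals = []
    for ln in lines[1 : 1 + n_sig]:
        tok = ln.split()
        fmt = int(tok[1].split("x")[0].split(":")[0].split("+")[0])
        gain_tok = tok[2] if len(tok) > 2 else "200"
        gain_str = gain_tok.split("/")[0]
        if "(" in gain_str:
            gain, baseline = gain_str.split("(")
            baseline = int(baseline.rstrip(")"))
        else:
            gain, baseline = gain_str, int(tok[4]) if len(tok) > 4 else 0
        signals.append(dict(file=tok[0], fmt=fmt, gain=float(gain) or 200.0,
                            baseline=baseline))
    return dict(name=name, n_sig=n_sig, fs=fs, n_samp=n_samp, signals=signals)


def _read_dat_212(dat_path: Path, n_sig: int, n_samp: int) -> np.ndarray:
    raw = np.frombuffer(dat_path.read_bytes(), dtype=np.uint8)
    if len(raw) % 3:
        raw = raw[: len(raw) - len(raw) % 3]
    b = raw.reshape(-1, 3).astype(np.int32)
    s1 = ((b[:, 1] & 0x0F) << 8) | b[:, 0]
    s2 = ((b[:, 1] & 0xF0) << 4) | b[:, 2]
    pairs = np.stack([s1, s2], axis=1).reshape(-1)
    pairs = np.where(pairs > 2047, pairs - 4096, pairs)
    total = n_samp * n_sig if n_samp else len(pairs)
    sig = pairs[:total].reshape(-1, n_sig)
    return sig


def _read_annotations(atr_path: Path) -> list:
    """MIT-format annotations: list of (sample index, type code)."""
    raw = atr_path.read_bytes()
    words = np.frombuffer(raw[: len(raw) - len(raw) % 2], dtype="<u2")
    out, time, i = [], 0, 0
    while i < len(words):
        w = int(words[i])
        code, interval = w >> 10, w & 0x3FF
        i += 1
        if code == 0 and interval == 0:  # EOF
            break
        if code == 59:  # SKIP: 32-bit interval in the next two words
            if i + 1 >= len(words):
                break
            time += (int(words[i]) << 16) | int(words[i + 1])
            i += 2
        elif code == 63:  # AUX: interval = byte count, padded to even
            i += (interval + 1) // 2
        elif code in (60, 61, 62):  # NUM / SUB / CHN modifiers
            continue
        else:
            time += interval
            out.append((time, code))
    return out


def load_wfdb(record_path, annotation_ext: str = "atr", class_map: dict | None = None):
    """Read one WFDB record (first signal channel) with beat annotations.

    Parameters
    ----------
    record_path : path to the record without extension (``.../100``).
    annotation_ext : annotation file extension (``atr`` for reference beats).
    class_map : symbol -> class id table; defaults to ``DEFAULT_CLASS_MAP``.
        Annotations with symbols missing from the table (or non-beat codes)
        are skipped and logged.

    Returns
    -------
    signal : float array, first channel in physical units (mV).
    annotations : DataFrame with columns ``sample``, ``symbol``, ``label``.
    fs : sampling frequency in Hz.
    """
    record_path = Path(record_path)
    hea = record_path.with_suffix(".hea")
    if not hea.exists():
        raise FileNotFoundError(f"missing header for record {record_path.name}: {hea}")
    header = _read_header(hea)
    sig0 = header["signals"][0]
    if sig0["fmt"] != 212:
        raise ValueError(f"record {record_path.name}: unsupported signal format {sig0['fmt']}")
    dat = record_path.parent / sig0["file"]
    if not dat.exists():
        raise FileNotFoundError(f"missing signal file for record {record_path.name}: {dat}")
    adc = _read_dat_212(dat, header["n_sig"], header["n_samp"])
    signal = (adc[:, 0] - sig0["baseline"]) / sig0["gain"]

    atr = record_path.with_suffix("." + annotation_ext)
    if not atr.exists():
        raise FileNotFoundError(f"missing annotation file for record {record_path.name}: {atr}")
    class_map = DEFAULT_CLASS_MAP if class_map is None else class_map
    rows, skipped = [], 0
    for sample, code in _read_annotations(atr):
        sym = _ANN_SYMBOLS.get(code)
        if sym is None or sym not in class_map:
            skipped += 1
            continue
        rows.append(dict(sample=sample, symbol=sym, label=class_map[sym]))
    if skipped:
        logger.info("record %s: skipped %d unmapped annotations", record_path.name, skipped)
    ann = pd.DataFrame(rows, columns=["sample", "symbol", "label"])
    return signal, ann, header["fs"]


def beats_from_record(record_path, annotation_ext: str = "atr",
                      class_map: dict | None = None) -> list:
    """Windowed, normalized, labeled beats from one WFDB record."""
    signal, ann, _ = load_wfdb(record_path, annotation_ext, class_map)
    beats = []
    for _, row in ann.iterrows():
        win = segment_beats(signal, [row["sample"]])
        if win:
            beats.append(Beat(signal=minmax_normalize(win[0]), label=int(row["label"])))
    return beats
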