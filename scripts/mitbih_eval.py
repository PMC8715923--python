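#!/usr/bin/env python
"""Opt-in: train and evaluate on a local copy of an MIT-BIH-style database.

This script is NOT run by the test suite and requires data that is not
bundled with the package: a directory of WFDB records (``<name>.hea``,
format-212 ``<name>.dat``, MIT-format ``<name>.atr``), e.g. the MIT-BIH
Arrhythmia Database obtained separately from PhysioNet (records 100-234,
360 Hz, two channels).  Download it yourself and point ``--data-dir`` at it:

    python scripts/mitbih_eval.py --data-dir /path/to/mitdb --out runs/mitbih

Beats are windowed 251 samples around each annotated R location, min-max
normalized, grouped into 4 classes by ``spikecim.data.DEFAULT_CLASS_MAP``
(AAMI-style: normal-like / supraventricular-like / ventricular-like /
fusion-paced-unknown), split 4:1 stratified, and used to train the spiking
network with the package defaults (T=25, batch 25, 30 epochs).  Optionally
the trained network is quantized and re-evaluated on the crossbar simulator.

Accuracy on the real database depends on the class map, the record list and
class balance, and is expected to differ from results obtained with other
pipelines; this script documents one reasonable, reproducible configuration.
"""

import argparse
import logging
from pathlib import Path

import numpy as np
import pandas as pd

import spikecim as sc
from spikecim.crossbar import DeviceModel, NonIdealityConfig, cim_evaluate, program
from spikecim.data import BeatDataset, beats_from_record, split
from spikecim.quantize import map_network, quantized_network
from spikecim.training import TrainConfig, evaluate, train

logging.basicConfig(level=logging.INFO, format="%(levelname)s %(name)s: %(message)s")
log = logging.getLogger("mitbih")


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__,
                                 formatter_class=argparse.RawDescriptionHelpFormatter)
    ap.add_argument("--data-dir", type=Path, required=True,
                    help="directory containing WFDB records (.hea/.dat/.atr)")
    ap.add_argument("--records", nargs="*", default=None,
                    help="record names to use (default: every .hea in the directory)")
    ap.add_argument("--max-per-class", type=int, default=2000,
                    help="cap per class to limit imbalance and runtime")
    ap.add_argument("--epochs", type=int, default=30)
    ap.add_argument("--time-steps", type=int, default=25)
    ap.add_argument("--batch-size", type=int, default=25)
    ap.add_argument("--lr", type=float, default=1e-3)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--cim", action="store_true",
                    help="also quantize and evaluate on the ideal crossbar simulator")
    ap.add_argument("--out", type=Path, default=Path("runs/mitbih"))
    args = ap.parse_args()

    names = args.records or sorted(p.stem for p in args.data_dir.glob("*.hea"))
    if not names:
        raise SystemExit(f"no records found in {args.data_dir}")
    beats = []
    for name in names:
        try:
            beats.extend(beats_from_record(args.data_dir / name))
        except (FileNotFoundError, ValueError) as exc:
            log.warning("skipping record %s: %s", name, exc)
    if not beats:
        raise SystemExit("no usable beats")

    # cap per class, preserving record order
    rng = np.random.default_rng(args.seed)
    kept = []
    for c in range(4):
        idx = [i for i, b in enumerate(beats) if b.label == c]
        rng.shuffle(idx)
        kept.extend(idx[: args.max_per_class])
    ds = split(BeatDataset(beats=[beats[i] for i in sorted(kept)]), seed=args.seed + 1)
    counts = np.bincount([b.label for b in ds.beats], minlength=4)
    log.info("beats per class: %s", counts.tolist())

    spec = sc.NetworkSpec.default(T=args.time_steps)
    net = sc.build_network(spec, seed=args.seed)
    cfg = TrainConfig(epochs=args.epochs, batch_size=args.batch_size,
                      lr=args.lr, T=args.time_steps, seed=args.seed)
    net, hist = train(net, ds, cfg)

    args.out.mkdir(parents=True, exist_ok=True)
    sc.save_network(net, args.out / "checkpoint.npz")
    pd.DataFrame(dict(epoch=np.arange(1, args.epochs + 1),
                      train_loss=hist.train_loss,
                      train_accuracy=hist.train_accuracy,
                      test_accuracy=hist.test_accuracy)).to_csv(
        args.out / "history.csv", index=False)
    print(f"held-out accuracy (digital): {hist.test_accuracy[-1]:.4f}")

    if args.cim:
        layout = map_network(net)
        qnet = quantized_network(net, layout)
        dev = DeviceModel(G_LRS=1e-4, G_HRS=0.0, V_read=0.2)
        pn = program(layout, dev, NonIdealityConfig(seed=args.seed))
        X, y = ds.arrays("test")
        acc = cim_evaluate(qnet, pn, X, y, seed=0)
        print(f"held-out accuracy (ideal crossbar, 4-bit): {acc:.4f}")


if __name__ == "__main__":
    main()
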