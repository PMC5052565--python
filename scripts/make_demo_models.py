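#!/usr/bin/env python
"""Regenerate the two demo models (and their hexamer tables) shipped in models/.

Both models are trained on synthetic data (see lncclass.synthetic), one per
noncoding background model.  The model JSONs in models/ are committed; the
hexamer tables they depend on are large and are rebuilt here, deterministically,
from the recorded seeds.

Usage:  python scripts/make_demo_models.py [--out-dir models]

A real-data (GENCODE) model is built the same way: supply transcript FASTA,
CDS FASTA and noncoding FASTA to `lncclass train` (see README).
"""

import argparse
import os

import numpy as np

import lncclass as lc
from lncclass import model as md


def build(noncoding_model: str, seed: int, out_dir: str) -> None:
    cfg = lc.GeneratorConfig(seed=seed, n_coding=500, n_noncoding=500,
                             noncoding_model=noncoding_model)
    records, truth = lc.generate_dataset(cfg)
    table = lc.build_hexamer_table(
        lc.cds_sequences(records, truth),
        [r.sequence for r in records if r.label == "noncoding"],
    )
    x = lc.feature_matrix(table, records)
    y = np.array([1 if r.label == "coding" else 0 for r in records])
    model, cv_acc = md.train(x, y, seed=0, hexamer_table_digest=table.digest())
    model.provenance["training_data"] = (
        f"synthetic ({noncoding_model} noncoding background, generator seed {seed})"
    )
    stem = os.path.join(out_dir, f"demo_synthetic_{noncoding_model}.model.json")
    md.save_model(model, stem)
    lc.save_table(table, stem + ".hexamers.tsv")
    print(f"{stem}: 10-fold CV accuracy {cv_acc:.4f}, C={model.C:g}")


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--out-dir", default="models")
    args = parser.parse_args()
    os.makedirs(args.out_dir, exist_ok=True)
    build("markov1", seed=42, out_dir=args.out_dir)
    build("uniform", seed=42, out_dir=args.out_dir)


if __name__ == "__main__":
    main()
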