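import numpy as np
import pytest
from click.testing import CliRunner

import lncclass as lc
from lncclass.cli import main as cli_main


@pytest.fixture(scope="session")
def toy_table():
    """Small hexamer table with clear coding/noncoding contrast."""
    rng = np.random.default_rng(11)
    codons = [c for c in lc.synthetic.SENSE_CODONS]
    w = np.exp(-np.arange(len(codons)) / 10.0)
    w /= w.sum()
    cds = [
        "".join(codons[i] for i in rng.choice(len(codons), size=100, p=w))
        for _ in range(30)
    ]
    nc = [
        "".join("ACGT"[b] for b in rng.integers(0, 4, size=300))
        for _ in range(30)
    ]
    return lc.build_hexamer_table(cds, nc)


@pytest.fixture(scope="session")
def benchmark_pipeline():
    """Full train/test pipeline on the default synthetic benchmark (seed 42).

    Returns a dict with the trained model, probabilities, class/truncation
    masks and the per-subset AUCs reused by several end-to-end checks.
    """
    (train_recs, train_truth), (test_recs, test_truth) = lc.benchmark_datasets(42)
    cds = lc.cds_sequences(train_recs, train_truth)
    nc = [r.sequence for r in train_recs if r.label == "noncoding"]
    table = lc.build_hexamer_table(cds, nc)

    x = lc.feature_matrix(table, train_recs)
    y = np.array([1 if r.label == "coding" else 0 for r in train_recs])
    model, cv_acc = lc.train(x, y, seed=0)

    xt = lc.feature_matrix(table, test_recs)
    yt = np.array([1 if r.label == "coding" else 0 for r in test_recs])
    probs = lc.predict_proba(model, xt)
    truncated = np.array([row.truncated for row in test_truth])
    full_mask = ~truncated | (yt == 0)
    partial_mask = truncated | (yt == 0)

    orf_cols = [6, 7, 8, 9, 10]
    orf_model, _ = lc.train(
        x[:, orf_cols], y, seed=0,
        feature_names=[lc.FEATURE_NAMES[i] for i in orf_cols],
    )
    orf_probs = lc.predict_proba(orf_model, xt[:, orf_cols])

    return {
        "table": table,
        "model": model,
        "cv_acc": cv_acc,
        "x_train": x,
        "y_train": y,
        "x_test": xt,
        "y_test": yt,
        "probs": probs,
        "orf_probs": orf_probs,
        "full_mask": full_mask,
        "partial_mask": partial_mask,
        "auc_full": lc.roc_auc(probs[full_mask], yt[full_mask]),
        "auc_partial": lc.roc_auc(probs[partial_mask], yt[partial_mask]),
        "auc_orf_partial": lc.roc_auc(orf_probs[partial_mask], yt[partial_mask]),
        "test_records": test_recs,
        "test_truth": test_truth,
    }


def run_cli(*args):
    result = CliRunner().invoke(cli_main, [str(a) for a in args])
    assert result.exit_code == 0, f"CLI failed ({args[0]}): {result.output}"
    return result


@pytest.fixture(scope="session")
def cli_demo(tmp_path_factory):
    """Small simulate -> train demo shared by the CLI-level checks."""
    root = tmp_path_factory.mktemp("cli_demo")
    coding_prefix = root / "train_coding"
    noncoding_prefix = root / "train_noncoding"
    test_prefix = root / "test"
    run_cli("simulate", "--out-prefix", coding_prefix, "--seed", 7,
            "--n-coding", 40, "--n-noncoding", 0)
    run_cli("simulate", "--out-prefix", noncoding_prefix, "--seed", 17,
            "--n-coding", 0, "--n-noncoding", 40)
    run_cli("simulate", "--out-prefix", test_prefix, "--seed", 8,
            "--n-coding", 20, "--n-noncoding", 20, "--partial-fraction", 0.5)
    model = root / "model.json"
    run_cli("train", f"{coding_prefix}.fa", f"{coding_prefix}.cds.fa",
            f"{noncoding_prefix}.fa", "--coding-gtf", f"{coding_prefix}.gtf",
            "--noncoding-gtf", f"{noncoding_prefix}.gtf",
            "--out-model", model, "--seed", 0)
    return {
        "root": root,
        "coding_prefix": coding_prefix,
        "noncoding_prefix": noncoding_prefix,
        "test_prefix": test_prefix,
        "model": model,
        "table": root / "model.json.hexamers.tsv",
    }
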