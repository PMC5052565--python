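"""In-frame hexamer usage tables and log-likelihood-ratio scoring.

Coding sequence exhibits strong 6-mer (dicodon) usage bias because adjacent
amino acids are not independent.  A hexamer table stores, for each of the
4096 hexamers h, its codon-phased relative frequency F(h) in coding CDS
training sequences and F'(h) in noncoding training sequences, plus the
log-ratio score

    score(h) = ln(F(h) / F'(h))

clamped to +/- ``score_floor`` when one class has zero frequency (hexamers
spanning a stop codon have F(h) = 0; a finite penalty lets maximum-subarray
scoring terminate runs at stop codons without infinities).  "In-frame" means
windows are taken at step 3 from the reading-frame offset, so each hexamer
covers two whole codons.

Hexamers containing N are skipped everywhere: they contribute to no count
and no score sum.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

#: clamp applied to ln(F/F') when one class frequency is zero
DEFAULT_SCORE_FLOOR = 10.0

K = 6
N_HEXAMERS = 4 ** K  # 4096

_BASES = "ACGT"
_BASE_CODE = np.full(256, -1, dtype=np.int64)
for _i, _b in enumerate(_BASES):
    _BASE_CODE[ord(_b)] = _i

#: powers of 4 for the big-endian hexamer index
_POW4 = 4 ** np.arange(K - 1, -1, -1, dtype=np.int64)


def encode(seq: str) -> np.ndarray:
    """Map a normalized DNA string to integer codes (A,C,G,T -> 0..3, N -> -1)."""
    return _BASE_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def hexamer_index(hexamer: str) -> int:
    """Index of a 6-mer in lexicographic (A<C<G<T) order."""
    codes = encode(hexamer)
    if len(codes) != K or (codes < 0).any():
        raise ValueError(f"not an unambiguous hexamer: {hexamer!r}")
    return int(codes @ _POW4)


def index_to_hexamer(idx: int) -> str:
    chars = []
    for p in range(K - 1, -1, -1):
        chars.append(_BASES[(idx >> (2 * p)) & 3])
    return "".join(chars)


def _window_indices(codes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Hexamer index at every window start, plus a validity mask (no N)."""
    n = codes.shape[0] - K + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=bool)
    idx = np.zeros(n, dtype=np.int64)
    valid = np.ones(n, dtype=bool)
    for j in range(K):
        c = codes[j : j + n]
        valid &= c >= 0
        idx += np.where(c >= 0, c, 0) * _POW4[j]
    return idx, valid


def inframe_window_indices(seq: str, frame: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Hexamer indices at positions frame, frame+3, ... with N-validity mask."""
    codes = encode(seq)
    idx, valid = _window_indices(codes)
    return idx[frame::3], valid[frame::3]


@dataclass
class HexamerTable:
    """Per-hexamer class frequencies and precomputed log-ratio scores."""

    coding_freq: np.ndarray       # F(h), sums to 1 over observed counts
    noncoding_freq: np.ndarray    # F'(h)
    scores: np.ndarray            # clamped ln(F/F'), finite for all 4096 h
    score_floor: float = DEFAULT_SCORE_FLOOR
    metadata: dict = field(default_factory=dict)

    def score_of(self, hexamer: str) -> float:
        return float(self.scores[hexamer_index(hexamer)])

    def digest(self) -> str:
        """Stable checksum over the serialized frequencies (ties a model to its table)."""
        h = hashlib.sha256()
        h.update(np.round(self.coding_freq, 12).tobytes())
        h.update(np.round(self.noncoding_freq, 12).tobytes())
        h.update(f"{self.score_floor:.6g}".encode())
        return h.hexdigest()[:16]


def _count_class(seqs: Iterable[str]) -> np.ndarray:
    counts = np.zeros(N_HEXAMERS, dtype=np.int64)
    for seq in seqs:
        idx, valid = inframe_window_indices(seq, 0)
        if idx.size:
            counts += np.bincount(idx[valid], minlength=N_HEXAMERS)
    return counts


def _ratio_scores(f: np.ndarray, fp: np.ndarray, floor: float) -> np.ndarray:
    scores = np.zeros(N_HEXAMERS)
    both = (f > 0) & (fp > 0)
    scores[both] = np.log(f[both] / fp[both])
    scores[(f == 0) & (fp > 0)] = -floor
    scores[(f > 0) & (fp == 0)] = floor
    np.clip(scores, -floor, floor, out=scores)
    return scores


def build_hexamer_table(
    cds_seqs: Sequence[str],
    noncoding_seqs: Sequence[str],
    score_floor: float = DEFAULT_SCORE_FLOOR,
) -> HexamerTable:
    """Count codon-phased hexamers per class and derive log-ratio scores.

    CDS sequences must be in frame 0 (first base = first codon base);
    windows are taken at step 3 from position 0 in every sequence of both
    classes.  Frequencies are normalized per class over observed counts.
    """
    if not cds_seqs or not noncoding_seqs:
        raise ValueError("both training classes must be non-empty")
    coding_counts = _count_class(cds_seqs)
    noncoding_counts = _count_class(noncoding_seqs)
    for name, counts in (("coding", coding_counts), ("noncoding", noncoding_counts)):
        if counts.sum() == 0:
            raise ValueError(f"no hexamers observed in the {name} training set")
    f = coding_counts / coding_counts.sum()
    fp = noncoding_counts / noncoding_counts.sum()
    return HexamerTable(
        coding_freq=f,
        noncoding_freq=fp,
        scores=_ratio_scores(f, fp, score_floor),
        score_floor=score_floor,
        metadata={
            "n_coding_seqs": len(cds_seqs),
            "n_noncoding_seqs": len(noncoding_seqs),
            "n_coding_hexamers": int(coding_counts.sum()),
            "n_noncoding_hexamers": int(noncoding_counts.sum()),
            "log_base": "e",
            "score_floor": score_floor,
        },
    )


def frame_hexamer_score(table: HexamerTable, seq: str, frame: int) -> float:
    """Mean log-ratio score over in-frame hexamers starting at ``frame``.

    Returns 0.0 when no complete (N-free) hexamer exists in that frame.
    """
    if frame not in (0, 1, 2):
        raise ValueError(f"frame must be 0, 1 or 2, got {frame}")
    idx, valid = inframe_window_indices(seq, frame)
    n = int(valid.sum())
    if n == 0:
        return 0.0
    return float(table.scores[idx[valid]].sum() / n)


def hexamer_score_and_distance(table: HexamerTable, seq: str) -> tuple[float, float]:
    """Best-frame hexamer score S_m and the frame-contrast distance D.

    S_i is the mean in-frame score of reading frame i (i = 1..3, offsets
    0..2), S_m = max_i S_i, and

        D = sum_i (S_m - S_i) / 2

    the mean excess of the best frame over the other two.  D >= 0, and
    D = 0 iff all three frame scores are equal.  A sequence shorter than
    6 nt yields (0, 0).
    """
    if len(seq) < K:
        return 0.0, 0.0
    s = [frame_hexamer_score(table, seq, f) for f in (0, 1, 2)]
    s_m = max(s)
    d = sum(s_m - s_i for s_i in s) / 2.0
    return s_m, d


# ---------------------------------------------------------------------------
# serialization: TSV (hexamer, F, F') + JSON metadata sidecar


def save_table(table: HexamerTable, tsv_path, meta_path=None) -> None:
    """Write the table as a 3-column TSV plus a JSON metadata sidecar."""
    if meta_path is None:
        meta_path = str(tsv_path) + ".json"
    with open(tsv_path, "w") as out:
        out.write("hexamer\tcoding_freq\tnoncoding_freq\n")
        for i in range(N_HEXAMERS):
            out.write(
                f"{index_to_hexamer(i)}\t{table.coding_freq[i]:.12g}\t{table.noncoding_freq[i]:.12g}\n"
            )
    meta = dict(table.metadata)
    meta.update({"score_floor": table.score_floor, "digest": table.digest()})
    with open(meta_path, "w") as out:
        json.dump(meta, out, indent=1)
        out.write("\n")


def load_table(tsv_path, meta_path=None) -> HexamerTable:
    if meta_path is None:
        meta_path = str(tsv_path) + ".json"
    try:
        with open(meta_path) as fh:
            meta = json.load(fh)
    except FileNotFoundError:
        meta = {}
    floor = float(meta.get("score_floor", DEFAULT_SCORE_FLOOR))
    f = np.zeros(N_HEXAMERS)
    fp = np.zeros(N_HEXAMERS)
    with open(tsv_path) as fh:
        header = fh.readline()
        if not header.startswith("hexamer\t"):
            raise ValueError(f"{tsv_path}: not a hexamer table (bad header)")
        for line in fh:
            hexa, f_s, fp_s = line.rstrip("\n").split("\t")
            i = hexamer_index(hexa)
            f[i] = float(f_s)
            fp[i] = float(fp_s)
    return HexamerTable(
        coding_freq=f,
        noncoding_freq=fp,
        scores=_ratio_scores(f, fp, floor),
        score_floor=floor,
        metadata=meta,
    )
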