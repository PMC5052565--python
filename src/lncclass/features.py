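"""The 11 sequence features: exon, MCSS and ORF feature groups.

Exon group (computed per exon, maxima taken over exons, independently per
feature): exon hexamer score, exon hexamer score distance, exon GC-content.

MCSS group: the maximum coding subsequence — the contiguous run of in-frame
hexamers with maximal summed log-ratio score, found per reading frame with
Kadane's maximum-subarray recursion and compared across the three forward
frames.  Being independent of start/stop codons, it locates coding-like
sequence even in CDS-incomplete transcripts.  Features: MCSS length,
coding score, coding score percentage.

ORF group: the putative ORF is the longest ATG-initiated open reading frame
over the three forward frames (a terminal stop is optional when the frame
runs off the sequence end, supporting 3'-truncated transcripts).  Features:
ORF length, ORF coverage, Fickett TESTCODE score of the ORF, ORF hexamer
score and distance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .hexamer import HexamerTable, hexamer_score_and_distance, inframe_window_indices
from .seqio import TranscriptRecord, segments_from_spans

FEATURE_NAMES = (
    "exon_hexamer_score",
    "exon_hexamer_distance",
    "exon_gc",
    "mcss_length",
    "mcss_score",
    "mcss_score_percentage",
    "orf_length",
    "orf_coverage",
    "orf_fickett",
    "orf_hexamer_score",
    "orf_hexamer_distance",
)

STOP_CODONS = ("TAA", "TAG", "TGA")


# ---------------------------------------------------------------------------
# ORF detection


@dataclass
class ORFResult:
    """Longest ATG-initiated ORF over the three forward frames."""

    frame: int
    start: int          # 0-based, position of the A of ATG
    end: int            # half-open; includes the stop codon when complete
    length: int         # nt, multiple of 3; 0 if no ATG anywhere
    coverage: float     # length / transcript length
    complete: bool      # an in-frame stop codon terminates the ORF


def find_orf(seq: str) -> ORFResult:
    """Longest ORF across frames 0,1,2 of the forward strand.

    An ORF starts at ATG and extends to the first in-frame stop codon
    (inclusive), or to the last complete codon before the sequence end if
    no stop occurs (``complete=False``).  Ties on length are broken by
    smaller start, then smaller frame.  No ATG -> zero-length result.
    """
    n = len(seq)
    best = ORFResult(frame=0, start=0, end=0, length=0, coverage=0.0, complete=False)
    for frame in range(3):
        pos = frame
        while pos + 3 <= n:
            if seq[pos : pos + 3] == "ATG":
                end = pos + 3
                complete = False
                q = pos + 3
                while q + 3 <= n:
                    if seq[q : q + 3] in STOP_CODONS:
                        end = q + 3
                        complete = True
                        break
                    q += 3
                else:
                    end = q  # last complete codon boundary
                if not complete:
                    end = q
                length = end - pos
                better = length > best.length or (
                    length == best.length
                    and length > 0
                    and (pos, frame) < (best.start, best.frame)
                )
                if better:
                    best = ORFResult(
                        frame=frame,
                        start=pos,
                        end=end,
                        length=length,
                        coverage=length / n,
                        complete=complete,
                    )
                # later ATGs in this frame before the same stop give shorter
                # ORFs, but an ATG after this stop can start a new one
                pos = end if complete else n
            else:
                pos += 3
    return best


# ---------------------------------------------------------------------------
# Fickett TESTCODE statistic (Fickett 1982)
#
# Eight parameters: for each base B, the position parameter
#   max(count of B at codon positions 1,2,3) / (min(count) + 1)
# and the composition parameter (fraction of B in the sequence).  Each is
# converted to a coding probability via the published lookup tables and the
# eight probabilities are combined with the published weights.

_FICKETT_POSITION_PROB = {
    "A": [0.94, 0.68, 0.84, 0.93, 0.58, 0.68, 0.45, 0.34, 0.20, 0.22],
    "C": [0.80, 0.70, 0.70, 0.81, 0.66, 0.48, 0.51, 0.33, 0.30, 0.23],
    "G": [0.90, 0.88, 0.74, 0.64, 0.53, 0.48, 0.27, 0.16, 0.08, 0.08],
    "T": [0.97, 0.97, 0.91, 0.68, 0.69, 0.44, 0.54, 0.20, 0.09, 0.09],
}
_FICKETT_POSITION_WEIGHT = {"A": 0.26, "C": 0.18, "G": 0.31, "T": 0.33}
_FICKETT_POSITION_BOUNDS = [1.9, 1.8, 1.7, 1.6, 1.5, 1.4, 1.3, 1.2, 1.1, 0.0]

_FICKETT_CONTENT_PROB = {
    "A": [0.28, 0.49, 0.44, 0.55, 0.62, 0.49, 0.67, 0.65, 0.81, 0.21],
    "C": [0.82, 0.64, 0.51, 0.64, 0.59, 0.59, 0.43, 0.44, 0.39, 0.31],
    "G": [0.40, 0.54, 0.47, 0.64, 0.64, 0.73, 0.41, 0.41, 0.33, 0.29],
    "T": [0.28, 0.24, 0.39, 0.40, 0.55, 0.75, 0.56, 0.69, 0.51, 0.58],
}
_FICKETT_CONTENT_WEIGHT = {"A": 0.11, "C": 0.12, "G": 0.15, "T": 0.14}
_FICKETT_CONTENT_BOUNDS = [0.33, 0.31, 0.29, 0.27, 0.25, 0.23, 0.21, 0.19, 0.17, 0.0]


def _lookup(value: float, bounds: list[float], probs: list[float]) -> float:
    for i, bound in enumerate(bounds):
        if value >= bound:
            return probs[i]
    return probs[-1]


def fickett_score(seq: str) -> float:
    """Fickett TESTCODE statistic of a sequence (deterministic; < 2 nt -> 0)."""
    if len(seq) < 2:
        return 0.0
    total = 0.0
    n_counted = sum(seq.count(b) for b in "ACGT")
    for base in "ACGT":
        counts = [seq[off::3].count(base) for off in range(3)]
        position = max(counts) / (min(counts) + 1)
        composition = seq.count(base) / n_counted if n_counted else 0.0
        total += _FICKETT_POSITION_WEIGHT[base] * _lookup(
            position, _FICKETT_POSITION_BOUNDS, _FICKETT_POSITION_PROB[base]
        )
        total += _FICKETT_CONTENT_WEIGHT[base] * _lookup(
            composition, _FICKETT_CONTENT_BOUNDS, _FICKETT_CONTENT_PROB[base]
        )
    return total


# ---------------------------------------------------------------------------
# Maximum coding subsequence (modified Kadane)


@dataclass
class MCSSResult:
    """Best maximal-score hexamer run over the three reading frames."""

    frame: int
    start: int                  # nt position of the run's first hexamer
    end: int                    # half-open nt end (last hexamer start + 6)
    coding_score: float         # S = S_m, summed hexamer scores of the run
    length: int                 # nt spanned: 3*k + 3 for k hexamers
    frame_scores: tuple[float, float, float]   # S_1, S_2, S_3
    coding_score_percentage: float


def max_subarray(scores: np.ndarray) -> tuple[float, int, int]:
    """Nonempty maximum-sum contiguous run (Kadane via prefix sums).

    Returns ``(best_sum, i, j)`` with the run covering ``scores[i:j+1]``.
    Ties resolve to the earliest qualifying run (first maximal end, then
    the earliest minimal prefix before it), deterministically.
    """
    if scores.size == 0:
        raise ValueError("empty score array")
    prefix = np.concatenate([[0.0], np.cumsum(scores)])
    # best run ending at j is prefix[j+1] - min(prefix[0..j])
    run_min = np.minimum.accumulate(prefix[:-1])
    gains = prefix[1:] - run_min
    j = int(np.argmax(gains))
    i = int(np.argmin(prefix[: j + 1]))
    return float(gains[j]), i, j


def coding_score_percentage(s1: float, s2: float, s3: float) -> float:
    """CSP = S_m / (S_1+S_2+S_3), guarded to 1.0 when the sum is <= 0."""
    total = s1 + s2 + s3
    if total <= 0:
        return 1.0
    return max(s1, s2, s3) / total


def find_mcss(table: HexamerTable, seq: str) -> MCSSResult:
    """Locate the maximum coding subsequence of a transcript.

    Per frame, the in-frame hexamer score sequence (step 3; N-containing
    windows contribute 0) is scanned with Kadane's recursion for its
    nonempty maximum-sum run.  The best frame is the argmax of the run
    scores (tie -> lowest frame).  A run of k hexamers spans k+1 codons,
    hence length = 3k + 3 nt.  Sequences shorter than 6 nt give an
    all-zero result.
    """
    if len(seq) < 6:
        return MCSSResult(0, 0, 0, 0.0, 0, (0.0, 0.0, 0.0), 1.0)
    frame_scores = []
    runs = []
    for frame in range(3):
        idx, valid = inframe_window_indices(seq, frame)
        if idx.size == 0:
            frame_scores.append(0.0)
            runs.append((0, -1))
            continue
        scores = np.where(valid, table.scores[idx], 0.0)
        best, i, j = max_subarray(scores)
        frame_scores.append(best)
        runs.append((i, j))
    best_frame = int(np.argmax(frame_scores))  # argmax -> lowest frame on ties
    s_m = frame_scores[best_frame]
    i, j = runs[best_frame]
    if j < 0:
        start = end = best_frame
    else:
        start = best_frame + 3 * i
        end = best_frame + 3 * j + 6
    s1, s2, s3 = frame_scores
    return MCSSResult(
        frame=best_frame,
        start=start,
        end=end,
        coding_score=s_m,
        length=end - start,
        frame_scores=(s1, s2, s3),
        coding_score_percentage=coding_score_percentage(s1, s2, s3),
    )


# ---------------------------------------------------------------------------
# feature assembly


def gc_content(seq: str) -> float:
    n = len(seq)
    if n == 0:
        return 0.0
    return (seq.count("G") + seq.count("C")) / n


def exon_features(table: HexamerTable, exon_seqs: list[str]) -> tuple[float, float, float]:
    """Per-exon hexamer score, distance and GC; maxima taken independently."""
    if not exon_seqs:
        raise ValueError("at least one exon subsequence required")
    scores, distances, gcs = [], [], []
    for exon in exon_seqs:
        s_m, d = hexamer_score_and_distance(table, exon)
        scores.append(s_m)
        distances.append(d)
        gcs.append(gc_content(exon))
    return max(scores), max(distances), max(gcs)


def feature_vector(table: HexamerTable, record: TranscriptRecord) -> np.ndarray:
    """The 11 features of one transcript, in ``FEATURE_NAMES`` order.

    ORF hexamer score/distance and the Fickett statistic are computed on
    the ORF subsequence (which starts at a codon boundary by construction);
    with no ORF they fall back to the whole transcript while orf_length and
    orf_coverage stay 0.
    """
    seq = record.sequence
    exon_hs, exon_hsd, exon_gc = exon_features(table, segments_from_spans(record))

    mcss = find_mcss(table, seq)

    orf = find_orf(seq)
    orf_seq = seq[orf.start : orf.end] if orf.length > 0 else seq
    orf_hs, orf_hsd = hexamer_score_and_distance(table, orf_seq)

    return np.array(
        [
            exon_hs,
            exon_hsd,
            exon_gc,
            float(mcss.length),
            mcss.coding_score,
            mcss.coding_score_percentage,
            float(orf.length),
            orf.coverage,
            fickett_score(orf_seq),
            orf_hs,
            orf_hsd,
        ]
    )


def feature_matrix(table: HexamerTable, records: list[TranscriptRecord]) -> np.ndarray:
    """Stack feature vectors for many transcripts (rows in input order)."""
    if not records:
        return np.empty((0, len(FEATURE_NAMES)))
    return np.vstack([feature_vector(table, rec) for rec in records])
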