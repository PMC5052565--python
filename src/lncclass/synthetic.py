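"""Synthetic labeled transcripts with known ground truth.

Emulates the three populations the classifier must separate:

* full-length coding transcripts — 5'UTR + ATG + codon-biased stop-free
  body + stop codon + 3'UTR, with exon boundaries partitioning the length;
* partial-length coding transcripts — the same construction with a random
  prefix and/or suffix removed so that the start and/or stop codon is lost,
  as happens to CDS-incomplete transcripts assembled from short reads;
* noncoding transcripts — drawn from a first-order Markov model (or a
  uniform model), with total length drawn from the same UTR+CDS+UTR
  composition law as the coding class so that transcript length alone is
  not a class giveaway; a configurable fraction carry an embedded
  codon-sampled fragment, emulating the small-ORF and pseudogene-derived
  coding-like stretches found in real lncRNAs.

Codon usage in the coding body follows a fixed exponential weight table
over the 61 sense codons (max/min weight ratio ~55, comparable to the
spread of genome-wide human codon frequencies); UTRs are drawn from the
noncoding model.  The default noncoding Markov transitions are the
composition-matched null of the codon weights (same mono/dinucleotide
composition, no reading-frame structure), so the two classes differ in
frame-phased higher-order statistics rather than trivial base content —
the regime that makes real lncRNA/mRNA discrimination imperfect.  Every transcript is longer than 200 nt, the conventional
lncRNA length floor.  Everything is reproducible from the config seed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .seqio import CODING, NONCODING, TranscriptRecord, write_fasta

BASES = "ACGT"
STOPS = ("TAA", "TAG", "TGA")
SENSE_CODONS = tuple(
    "".join(c) for c in itertools.product(BASES, repeat=3) if "".join(c) not in STOPS
)

#: fixed exponential codon weights: rank r (lexicographic) gets exp(-r/15)
DEFAULT_CODON_WEIGHTS = np.exp(-np.arange(len(SENSE_CODONS)) / 15.0)
DEFAULT_CODON_WEIGHTS = DEFAULT_CODON_WEIGHTS / DEFAULT_CODON_WEIGHTS.sum()

_CODON_BASE_IDX = np.array(
    [["ACGT".index(b) for b in codon] for codon in SENSE_CODONS]
)


def coding_matched_transitions(codon_weights: np.ndarray) -> np.ndarray:
    """First-order Markov transitions matching the coding-class composition.

    The dinucleotide joint distribution of a long codon-sampled CDS is
    computed analytically (two within-codon pair positions plus the
    cross-codon junction, equally weighted) and row-normalized.  Sequence
    drawn from this chain shares the coding class's mono- and dinucleotide
    composition but has no period-3 frame structure — the composition-
    matched null that makes the classification problem realistically hard.
    """
    w = np.asarray(codon_weights, dtype=float)
    w = w / w.sum()
    joint = np.zeros((4, 4))
    b1, b2, b3 = _CODON_BASE_IDX.T
    np.add.at(joint, (b1, b2), w)
    np.add.at(joint, (b2, b3), w)
    # cross-codon junction: last base of one codon, first base of the next
    p_last = np.bincount(b3, weights=w, minlength=4)
    p_first = np.bincount(b1, weights=w, minlength=4)
    joint += np.outer(p_last, p_first)
    joint /= joint.sum()
    return joint / joint.sum(axis=1, keepdims=True)


#: default noncoding transitions: the composition-matched null of the
#: default codon weights
DEFAULT_MARKOV_TRANSITIONS = coding_matched_transitions(DEFAULT_CODON_WEIGHTS)

MIN_TRANSCRIPT_LENGTH = 201  # the > 200 nt convention
MIN_EXON_LENGTH = 20
MAX_RETRIES = 50


@dataclass
class GeneratorConfig:
    seed: int = 42
    n_coding: int = 500
    n_noncoding: int = 500
    cds_len_range: tuple[int, int] = (120, 1500)      # nt incl. start+stop, multiples of 3
    utr_len_range: tuple[int, int] = (50, 400)        # per UTR
    codon_weights: np.ndarray = field(default_factory=lambda: DEFAULT_CODON_WEIGHTS.copy())
    noncoding_model: str = "markov1"                  # or "uniform"
    markov_transitions: np.ndarray = field(
        default_factory=lambda: DEFAULT_MARKOV_TRANSITIONS.copy()
    )
    partial_fraction: float = 0.0
    truncation_mode: str = "cut_both"                 # cut5 | cut3 | cut_both
    exon_count_range: tuple[int, int] = (1, 6)
    #: share of noncoding transcripts carrying an embedded codon-sampled
    #: fragment (no start/stop guarantee), emulating the small-ORF and
    #: pseudogene-derived coding-like stretches found in real lncRNAs
    pseudo_cds_fraction: float = 0.3
    pseudo_cds_len_range: tuple[int, int] = (90, 300)

    def __post_init__(self) -> None:
        self.codon_weights = np.asarray(self.codon_weights, dtype=float)
        if self.codon_weights.shape != (len(SENSE_CODONS),):
            raise ValueError(f"codon_weights must have {len(SENSE_CODONS)} entries")
        self.codon_weights = self.codon_weights / self.codon_weights.sum()
        lo, hi = self.cds_len_range
        if lo % 3 or hi % 3 or lo < 9 or hi < lo:
            raise ValueError("cds_len_range must be multiples of 3 with 9 <= lo <= hi")
        if not 0.0 <= self.partial_fraction <= 1.0:
            raise ValueError("partial_fraction must be in [0, 1]")
        if self.truncation_mode not in ("cut5", "cut3", "cut_both"):
            raise ValueError(f"unknown truncation_mode {self.truncation_mode!r}")
        if not 0.0 <= self.pseudo_cds_fraction <= 1.0:
            raise ValueError("pseudo_cds_fraction must be in [0, 1]")
        if self.noncoding_model not in ("uniform", "markov1"):
            raise ValueError(f"unknown noncoding_model {self.noncoding_model!r}")
        t = np.asarray(self.markov_transitions, dtype=float)
        if t.shape != (4, 4) or not np.allclose(t.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("markov_transitions must be 4x4 with rows summing to 1")
        self.markov_transitions = t


@dataclass
class TruthRow:
    """Ground truth for one generated transcript."""

    transcript_id: str
    label: str
    cds_start: int = -1      # -1 for noncoding or when the start codon was cut away
    cds_end: int = -1
    truncated: bool = False
    truncation_mode: str = ""
    n_exons: int = 1
    pseudo_cds: bool = False   # noncoding transcript with an embedded coding-like fragment


def _noncoding_fragment(rng: np.random.Generator, length: int, config: GeneratorConfig) -> str:
    if length <= 0:
        return ""
    if config.noncoding_model == "uniform":
        return "".join(np.array(list(BASES))[rng.integers(0, 4, size=length)])
    cum = np.cumsum(config.markov_transitions, axis=1)
    u = rng.random(length)
    out = np.empty(length, dtype=np.int64)
    out[0] = rng.integers(0, 4)
    for i in range(1, length):
        out[i] = np.searchsorted(cum[out[i - 1]], u[i])
    return "".join(np.array(list(BASES))[out])


def _coding_sequence(rng: np.random.Generator, cds_len: int, config: GeneratorConfig) -> str:
    n_body = cds_len // 3 - 2
    body_idx = rng.choice(len(SENSE_CODONS), size=n_body, p=config.codon_weights)
    body = "".join(SENSE_CODONS[i] for i in body_idx)
    stop = STOPS[rng.integers(0, len(STOPS))]
    return "ATG" + body + stop


def _draw_exon_spans(rng: np.random.Generator, length: int, config: GeneratorConfig) -> list[tuple[int, int]]:
    lo, hi = config.exon_count_range
    max_exons = min(hi, max(lo, length // MIN_EXON_LENGTH))
    n = int(rng.integers(lo, max_exons + 1)) if max_exons > lo else lo
    if n <= 1:
        return [(0, length)]
    # boundaries keeping every exon >= MIN_EXON_LENGTH
    interior = np.sort(
        rng.choice(
            np.arange(MIN_EXON_LENGTH, length - MIN_EXON_LENGTH + 1, MIN_EXON_LENGTH),
            size=n - 1,
            replace=False,
        )
    ) if length >= 2 * MIN_EXON_LENGTH * n else None
    if interior is None:
        return [(0, length)]
    bounds = [0, *interior.tolist(), length]
    return [(bounds[i], bounds[i + 1]) for i in range(len(bounds) - 1)]


#: smallest CDS remnant left in a truncated transcript (10 codons); real
#: assembly fragments can retain arbitrarily little of the CDS
MIN_CDS_REMNANT = 30

#: under cut_both, per-transcript choice of which end(s) are lost:
#: (5' only, 3' only, both) — 5' loss dominates under 3'-biased coverage
CUT_BOTH_WEIGHTS = (0.5, 0.3, 0.2)


def _truncate(
    rng: np.random.Generator, seq: str, cds_start: int, cds_end: int, mode: str
) -> Optional[tuple[str, int, int]]:
    """Remove a prefix and/or suffix crossing the start and/or stop codon.

    ``cut5``/``cut3`` always lose the corresponding end; ``cut_both`` picks
    per transcript which end(s) are lost (5' only / 3' only / both, with
    ``CUT_BOTH_WEIGHTS``).  Cut points fall uniformly inside the CDS, so
    the retained CDS remnant ranges from ``MIN_CDS_REMNANT`` up to nearly
    the whole CDS.  Returns (sequence, new_cds_start, new_cds_end) with -1
    marking a codon position cut away, or None when no cut satisfying the
    length floor exists.
    """
    n = len(seq)
    if mode == "cut_both":
        r = rng.random()
        if r < CUT_BOTH_WEIGHTS[0]:
            do5, do3 = True, False
        elif r < CUT_BOTH_WEIGHTS[0] + CUT_BOTH_WEIGHTS[1]:
            do5, do3 = False, True
        else:
            do5, do3 = True, True
    else:
        do5, do3 = mode == "cut5", mode == "cut3"

    # in-transcript CDS cut points a < b: keep seq[a:n-(n-b)] remnant of CDS
    a = cds_start  # first retained position when cutting 5'
    b = cds_end    # last retained position (exclusive) when cutting 3'
    if do5 and do3:
        lo_a, hi_a = cds_start + 3, cds_end - 3 - MIN_CDS_REMNANT
        if lo_a > hi_a:
            return None
        a = int(rng.integers(lo_a, hi_a + 1))
        b = int(rng.integers(a + MIN_CDS_REMNANT, cds_end - 3 + 1))
    elif do5:
        lo_a, hi_a = cds_start + 3, cds_end - MIN_CDS_REMNANT
        if lo_a > hi_a:
            return None
        a = int(rng.integers(lo_a, hi_a + 1))
    elif do3:
        lo_b, hi_b = cds_start + MIN_CDS_REMNANT, cds_end - 3
        if lo_b > hi_b:
            return None
        b = int(rng.integers(lo_b, hi_b + 1))
    cut5 = a if do5 else 0
    cut3 = (n - b) if do3 else 0
    if n - cut5 - cut3 < MIN_TRANSCRIPT_LENGTH:
        return None
    truncated = seq[cut5 : n - cut3]
    new_start = cds_start - cut5 if not do5 else -1
    new_end = cds_end - cut5 if not do3 else -1
    return truncated, new_start, new_end


def generate_dataset(config: GeneratorConfig) -> tuple[list[TranscriptRecord], list[TruthRow]]:
    """Generate labeled transcripts plus their ground-truth table.

    The first ``round(partial_fraction * n_coding)`` coding transcripts, in
    a seeded random order, are truncated per ``truncation_mode``.  Records
    carry exon spans; all transcripts are > 200 nt.
    """
    rng = np.random.default_rng(config.seed)
    records: list[TranscriptRecord] = []
    truth: list[TruthRow] = []

    n_partial = int(round(config.partial_fraction * config.n_coding))
    partial_flags = np.zeros(config.n_coding, dtype=bool)
    partial_flags[rng.permutation(config.n_coding)[:n_partial]] = True

    for i in range(config.n_coding):
        tid = f"coding_{i:05d}"
        for _attempt in range(MAX_RETRIES):
            cds_len = 3 * int(rng.integers(config.cds_len_range[0] // 3,
                                           config.cds_len_range[1] // 3 + 1))
            utr5 = int(rng.integers(config.utr_len_range[0], config.utr_len_range[1] + 1))
            utr3 = int(rng.integers(config.utr_len_range[0], config.utr_len_range[1] + 1))
            seq = (
                _noncoding_fragment(rng, utr5, config)
                + _coding_sequence(rng, cds_len, config)
                + _noncoding_fragment(rng, utr3, config)
            )
            cds_start, cds_end = utr5, utr5 + cds_len
            if len(seq) < MIN_TRANSCRIPT_LENGTH:
                continue
            if partial_flags[i]:
                cut = _truncate(rng, seq, cds_start, cds_end, config.truncation_mode)
                if cut is None:
                    continue
                seq, cds_start, cds_end = cut
            spans = _draw_exon_spans(rng, len(seq), config)
            records.append(TranscriptRecord(id=tid, sequence=seq,
                                            exon_spans=spans, label=CODING))
            truth.append(TruthRow(
                transcript_id=tid, label=CODING,
                cds_start=cds_start, cds_end=cds_end,
                truncated=bool(partial_flags[i]),
                truncation_mode=config.truncation_mode if partial_flags[i] else "",
                n_exons=len(spans),
            ))
            break
        else:
            raise RuntimeError(
                f"could not generate transcript {tid} within the length constraints"
            )

    for i in range(config.n_noncoding):
        tid = f"noncoding_{i:05d}"
        for _attempt in range(MAX_RETRIES):
            # same composition law as coding lengths: UTR5 + CDS + UTR3
            length = (
                3 * int(rng.integers(config.cds_len_range[0] // 3,
                                     config.cds_len_range[1] // 3 + 1))
                + int(rng.integers(config.utr_len_range[0], config.utr_len_range[1] + 1))
                + int(rng.integers(config.utr_len_range[0], config.utr_len_range[1] + 1))
            )
            if length < MIN_TRANSCRIPT_LENGTH:
                continue
            seq = _noncoding_fragment(rng, length, config)
            has_pseudo = rng.random() < config.pseudo_cds_fraction
            if has_pseudo:
                lo, hi = config.pseudo_cds_len_range
                frag_len = 3 * int(rng.integers(lo // 3, hi // 3 + 1))
                frag_len = min(frag_len, length)
                frag_idx = rng.choice(len(SENSE_CODONS), size=frag_len // 3,
                                      p=config.codon_weights)
                frag = "".join(SENSE_CODONS[i] for i in frag_idx)
                pos = int(rng.integers(0, length - len(frag) + 1))
                seq = seq[:pos] + frag + seq[pos + len(frag):]
            spans = _draw_exon_spans(rng, length, config)
            records.append(TranscriptRecord(id=tid, sequence=seq,
                                            exon_spans=spans, label=NONCODING))
            truth.append(TruthRow(transcript_id=tid, label=NONCODING,
                                  n_exons=len(spans), pseudo_cds=has_pseudo))
            break
        else:
            raise RuntimeError(
                f"could not generate transcript {tid} within the length constraints"
            )

    return records, truth


def cds_sequences(records: list[TranscriptRecord], truth: list[TruthRow]) -> list[str]:
    """Frame-0 CDS subsequences of the full-length coding transcripts.

    These are the sequences a hexamer table is trained on; truncated
    transcripts (start or stop codon missing) are excluded because their
    CDS register is unknown to a real annotation pipeline.
    """
    out = []
    for rec, row in zip(records, truth):
        if row.label == CODING and not row.truncated and row.cds_start >= 0:
            out.append(rec.sequence[row.cds_start : row.cds_end])
    return out


# ---------------------------------------------------------------------------
# on-disk triplet: FASTA + GTF exon lines + truth TSV

_TRUTH_COLUMNS = ("transcript_id", "label", "cds_start", "cds_end",
                  "truncated", "truncation_mode", "n_exons", "pseudo_cds")


def write_dataset(
    records: list[TranscriptRecord],
    truth: list[TruthRow],
    fasta_path,
    gtf_path,
    truth_path,
    intron_len: int = 200,
) -> None:
    """Write the generated dataset as FASTA + GTF + truth TSV.

    Genomic exon coordinates are laid out on synthetic chromosomes with
    fixed-length introns; strands alternate so both GTF orientations are
    exercised.  Re-reading through seqio reproduces sequences and exon
    segment lengths exactly.
    """
    write_fasta(records, fasta_path)
    with open(gtf_path, "w") as gtf:
        for i, rec in enumerate(records):
            chrom = f"chrS{1 + i % 5}"
            strand = "+" if i % 2 == 0 else "-"
            spans = rec.exon_spans or [(0, len(rec.sequence))]
            lengths = [e - s for s, e in spans]
            if strand == "-":
                lengths = lengths[::-1]  # genomic order = reverse of transcript order
            gstart = 1 + 10_000 * i
            genomic = []
            for L in lengths:
                genomic.append((gstart, gstart + L - 1))
                gstart += L + intron_len
            for start, end in genomic:
                gtf.write(
                    f"{chrom}\tlncclass_sim\texon\t{start}\t{end}\t.\t{strand}\t.\t"
                    f'gene_id "{rec.id}.g"; transcript_id "{rec.id}";\n'
                )
    with open(truth_path, "w") as out:
        out.write("\t".join(_TRUTH_COLUMNS) + "\n")
        for row in truth:
            out.write(
                f"{row.transcript_id}\t{row.label}\t{row.cds_start}\t{row.cds_end}\t"
                f"{int(row.truncated)}\t{row.truncation_mode}\t{row.n_exons}\t"
                f"{int(row.pseudo_cds)}\n"
            )


def read_truth(path) -> list[TruthRow]:
    rows = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != _TRUTH_COLUMNS:
            raise ValueError(f"{path}: unexpected truth-table header {header}")
        for line in fh:
            tid, label, cs, ce, trunc, mode, nex, pseudo = line.rstrip("\n").split("\t")
            rows.append(TruthRow(tid, label, int(cs), int(ce), bool(int(trunc)),
                                 mode, int(nex), bool(int(pseudo))))
    return rows


def benchmark_datasets(seed: int = 42):
    """The default train/test pair used throughout the package's own checks.

    Train: 500 coding + 500 noncoding, all full-length.  Test: 200 + 200
    with half of the coding transcripts truncated.  The test config uses
    ``seed + 1`` so the two sets are disjoint draws.
    """
    train_cfg = GeneratorConfig(seed=seed, n_coding=500, n_noncoding=500,
                                partial_fraction=0.0)
    test_cfg = GeneratorConfig(seed=seed + 1, n_coding=200, n_noncoding=200,
                               partial_fraction=0.5)
    train = generate_dataset(train_cfg)
    test = generate_dataset(test_cfg)
    return train, test
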