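# Methods

## The classification model

`lncclass` treats coding-potential assessment as binary classification with
coding as the positive class. A transcript *x* is mapped to 11 real-valued
features and scored with an L2-regularized logistic regression,
p(coding | x) = σ(w·x + b). The features deliberately mix three kinds of
evidence with different failure modes:

* **ORF evidence** (ORF length, coverage, Fickett TESTCODE, ORF hexamer
  score/distance) is the strongest signal for full-length mRNAs but is
  anchored on start/stop codons, so it degrades when the CDS is
  incomplete.
* **MCSS evidence** (length, coding score, coding score percentage of the
  maximum coding subsequence) measures frame-phased hexamer bias in the
  best-scoring contiguous run, with no reference to start or stop codons;
  it is the feature group designed for partial-length transcripts.
* **Exon evidence** (per-exon hexamer score, hexamer score distance,
  GC-content, maxima over exons) is local: a truncated transcript still
  contains intact internal exons, so per-exon maxima are less affected by
  missing ends than whole-transcript statistics.

### Hexamer scoring

The hexamer table stores codon-phased (step-3) 6-mer frequencies F(h) from
coding CDS training sequences (frame 0 = annotated reading frame) and
F'(h) from noncoding training sequences. Each hexamer scores
ln F(h)/F'(h). Natural log throughout. Zero frequencies are handled with a
symmetric clamp at ±10 (configurable `score_floor`): hexamers absent from
CDS — typically those spanning a stop codon — score −10, which lets the
maximum-subarray recursion terminate runs at stop codons without
infinities; hexamers absent from the noncoding set score +10; absent from
both, 0. Hexamers containing N contribute to no count, no mean and no sum.

The frame score S_i (i = 1..3, offsets 0..2) is the *mean* hexamer score
over the in-frame windows; the score distance D = Σᵢ(S_m − S_i)/2 is the
mean excess of the best frame over the other two, zero exactly when the
three frames are indistinguishable. Both the distance definition and the
log base are recorded in model provenance so that alternative definitions
version the model file rather than silently changing scores.

### MCSS

Per frame, the sequence of in-frame hexamer scores is scanned for its
maximum-sum **nonempty** contiguous run (Kadane's recursion via prefix
sums; ties resolve to the earliest run, deterministically). Nonempty means
the MCSS is defined even for noncoding input where every score is
negative, so the length and score features never degenerate. A run of k
hexamers spans k+1 codons, hence MCSS length = 3k+3 nt. The best frame is
the argmax of run scores (tie → lowest frame). The coding score
percentage is S_m/(S₁+S₂+S₃), guarded to 1.0 when the denominator is ≤ 0:
this keeps the feature bounded without infinities in the all-nonpositive
regime.

### ORF and Fickett

The putative ORF is the longest ATG-initiated open reading frame over the
three forward frames. It ends at the first in-frame stop codon
(inclusive) or — supporting 3'-truncated transcripts — at the last
complete codon when the frame runs off the end (`complete=False`). Ties on
length break to the smaller start, then the smaller frame. The Fickett
TESTCODE statistic is computed from the published 1982 lookup tables
(eight parameters: per-base codon-position asymmetry max/(min+1) and
per-base composition, each mapped to a probability and combined with the
published weights); it is evaluated on the ORF subsequence, falling back
to the whole transcript when no ORF exists (ORF length/coverage stay 0 in
that case).

### Training

C (inverse regularization strength) is selected by stratified 10-fold
cross-validation over a 10-point logarithmic grid 1e-4..1e4, scored by
held-out accuracy; ties break toward the smaller C (stronger
regularization), and the model is refit on all data at the chosen C.
Fold assignment is seeded (default 0), so training is deterministic given
(data, seed, grid). Features are not standardized by default — the raw
nt-scale features are what the decision weights are reported on — but
`--standardize` stores train-set means/sds in the model and applies them
at prediction. Prediction itself is a plain dot product on the serialized
weights (numpy), independent of the fitting library, which makes model
files portable and bit-reproducible.

The model JSON records the feature ordering, chosen C, cutoff, a digest of
the hexamer table (prediction warns when the table at hand differs from
the training table), and provenance (sample sizes, folds, seed, grid, CV
accuracy, distance/ORF conventions).

### Evaluation

ACC, Sn, Sp, PPV, NPV and MCC use coding as positive; degenerate ratios
are reported as NaN with a flag and excluded from summaries. AUC is the
normalized Mann–Whitney U with midrank tie handling (ties count 0.5),
identical to the trapezoidal area under the ROC over all thresholds. The
operating-cutoff sweep evaluates accuracy at the midpoints between
consecutive unique scores (plus the two all-one-class extremes) and
returns the smallest maximizing cutoff; `grid_step` only rounds the
reported cutoff and never when rounding would change a classification.

### Parallel prediction

Per-transcript cost is dominated by sequence length, so worker assignments
are built with the longest-processing-time greedy rule: records sorted by
length descending, each assigned to the currently lightest worker. Workers
process disjoint subsets and rows are merged by original input index;
output is byte-identical for any `--threads` value.

## The synthetic generator

The generator provides labeled data with known CDS ground truth in the
three populations the tool must separate. Defaults (one `GeneratorConfig`):

| parameter | default | rationale |
|---|---|---|
| cds_len_range | 120–1500 nt | short ORFs up to median-mRNA scale; multiples of 3 |
| utr_len_range | 50–400 nt per UTR | typical UTR scale |
| codon_weights | exp(−rank/15) over the 61 sense codons | max/min ratio ≈ 55, comparable to the spread of genome-wide human codon frequencies |
| noncoding_model | markov1, composition-matched | see below |
| pseudo_cds_fraction | 0.3 (len 90–300 nt) | sORF/pseudogene-like fragments in real lncRNAs |
| exon_count_range | 1–6 | transcript-scale exon counts |
| truncation (cut_both) | 5'/3'/both ends, weights 0.5/0.3/0.2 | 5'-loss dominates under 3'-biased coverage |
| length floor | > 200 nt | the lncRNA length convention |

Coding transcripts are 5'UTR + ATG + stop-free codon-sampled body + stop +
3'UTR; UTRs are drawn from the noncoding model. Noncoding transcript
*lengths* follow the same UTR+CDS+UTR law, so length alone carries no
class information. The noncoding *sequence* model is the
**composition-matched null**: a first-order Markov chain whose transition
matrix is derived analytically from the codon weights (two within-codon
pair positions plus the cross-codon junction, equally weighted). Matched
mono/dinucleotide composition removes trivial GC/base-content separation
and leaves exactly the signal the hexamer machinery is built to detect —
frame-phased higher-order structure. Without this (and without the
pseudo-CDS fragments) the synthetic task is near-perfectly separable and
says nothing about the partial-length regime.

Truncation removes a random prefix and/or suffix whose cut point falls
uniformly inside the CDS (≥ 30 nt CDS remnant retained), so the start
and/or stop codon is always lost and the retained coding fraction varies
widely, as in real assembly fragments. Records violating the 200-nt floor
are redrawn (bounded retries).

What the generator does **not** emulate: splice-site sequence context,
repeat elements, sequencing error, per-gene codon-usage variation,
isoform redundancy between train and test, and real lncRNA biology beyond
composition. Passing end-to-end tests therefore demonstrates the
machinery is correct and the expected qualitative behaviour (degradation
on partial-length input; complementary feature groups), not a performance
claim for any real annotation set.

## Problem sizes used by the packaged checks

The default benchmark is 500+500 training and 200+200 test transcripts
(half the coding test set truncated), a scale at which the hexamer table
is well-populated (~4096 6-mers vs ~4·10⁵ training windows) while the
whole pipeline runs in seconds. Oracle-equivalence checks use exhaustive
brute force at small n (score arrays ≤ 60, 300-nt ORF scans), where
enumeration is exact.

## Numerical and convention choices

* GTF is 1-based inclusive; internal spans 0-based half-open; one
  conversion point in `seqio`.
* Minus-strand GTF entries only reorder exon lengths (the FASTA is always
  the sense-strand transcript, as assemblers emit); no
  reverse-complementing.
* FASTA input is uppercased, U→T, IUPAC ambiguity codes collapse to N;
  any other character is an error with its position.
* A transcript without GTF annotation is one exon: exon features degrade
  to transcript-level features instead of failing.
* Annotated exon lengths must sum exactly to the sequence length;
  mismatches are errors (no silent truncation).
* All tie-breaks (Kadane run, best frame, ORF, cutoff sweep, LPT worker
  choice) resolve to the earliest/smallest index, making every output
  deterministic.

## Known limitations

* Only the forward strand is scanned (assembled transcripts are assumed
  sense-oriented).
* Single-species hexamer tables; cross-species use inherits whatever bias
  the training species carries.
* The packaged human/mouse cutoffs are presets for models trained on the
  corresponding real annotation sets; models trained on other data should
  select a cutoff with the sweep utility.
* No isoform-aware deduplication: if train and test share near-identical
  transcripts, CV accuracy will be optimistic.
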