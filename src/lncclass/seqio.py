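"""Transcript and annotation I/O.

Reads transcript sequences from FASTA and exon structure from GTF/GFF2.5
exon lines, and converts genomic exon annotations into transcript-relative
exon segments.  Coordinate conventions: GTF is 1-based inclusive; all
internal spans are 0-based half-open.  The FASTA sequence is always assumed
to be the transcript (sense-strand) sequence, as produced by assemblers;
the GTF contributes only exon lengths and order, never reverse-complementing.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: characters accepted in transcript sequences after normalization
_VALID = set("ACGTN")

#: IUPAC ambiguity codes collapsed to N on input
_IUPAC_AMBIG = set("RYSWKMBDHVN")

CODING = "coding"
NONCODING = "noncoding"


@dataclass
class TranscriptRecord:
    """One transcript: id, sense-strand sequence, optional exon segmentation.

    ``exon_spans`` (when present) are transcript-relative 0-based half-open
    intervals that are sorted, disjoint and contiguous, covering
    ``[0, len(sequence))`` exactly.
    """

    id: str
    sequence: str
    exon_spans: Optional[list[tuple[int, int]]] = None
    label: Optional[str] = None

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise ValueError(f"transcript {self.id!r}: empty sequence")
        if self.exon_spans is not None:
            pos = 0
            for start, end in self.exon_spans:
                if start != pos or end <= start:
                    raise ValueError(
                        f"transcript {self.id!r}: exon spans must tile "
                        f"[0, {len(self.sequence)}) contiguously, got {self.exon_spans}"
                    )
                pos = end
            if pos != len(self.sequence):
                raise ValueError(
                    f"transcript {self.id!r}: exon spans cover [0, {pos}) but "
                    f"sequence has length {len(self.sequence)}"
                )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class ExonAnnotation:
    """Genomic exons of one transcript (1-based inclusive, as in GTF)."""

    transcript_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]] = field(default_factory=list)

    @property
    def total_length(self) -> int:
        return sum(end - start + 1 for start, end in self.exons)


def normalize_sequence(raw: str, *, ident: str = "?") -> str:
    """Uppercase, map U->T, collapse IUPAC ambiguity codes to N.

    Raises ``ValueError`` with the 1-based position of the first character
    that is not an IUPAC nucleotide code.
    """
    seq = raw.upper().replace("U", "T")
    out = []
    for i, ch in enumerate(seq):
        if ch in _VALID:
            out.append(ch)
        elif ch in _IUPAC_AMBIG:
            out.append("N")
        else:
            raise ValueError(
                f"record {ident!r}: non-IUPAC character {ch!r} at position {i + 1}"
            )
    return "".join(out)


def read_fasta(path) -> list[TranscriptRecord]:
    """Read transcripts from a FASTA file, in file order.

    The record id is the first whitespace-delimited token of the header.
    Sequences are uppercased and U is mapped to T.  Duplicate ids raise.
    """
    records: list[TranscriptRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate transcript id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(
            TranscriptRecord(id=rec.id, sequence=normalize_sequence(str(rec.seq), ident=rec.id))
        )
    if not records:
        warnings.warn(f"no FASTA records found in {path}", stacklevel=2)
    return records


def write_fasta(records: Iterable[TranscriptRecord], path, width: int = 70) -> None:
    """Write transcripts to FASTA (fixed line width, id-only headers)."""
    seq_records = [
        SeqRecord(Seq(rec.sequence), id=rec.id, description="") for rec in records
    ]
    with open(path, "w") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=width)
        writer.write_file(seq_records)


# GTF attribute:  transcript_id "ENST..."  (quotes optional; GFF2.5 dialect)
_TRANSCRIPT_ID_RE = re.compile(r'transcript_id\s+"?([^";\s]+)"?')


def read_exon_annotations(path) -> dict[str, ExonAnnotation]:
    """Parse exon lines of a GTF/GFF2.5 file, grouped by transcript_id.

    Only lines with feature type ``exon`` are consumed; every other feature
    type is ignored.  An exon line without a transcript_id attribute, an
    exon with end < start, and mixed strands within one transcript are
    errors (reported with the offending line number / transcript id).
    """
    annotations: dict[str, ExonAnnotation] = {}
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 9:
                continue
            chrom, _source, feature, start_s, end_s, _score, strand, _frame, attrs = fields[:9]
            if feature != "exon":
                continue
            match = _TRANSCRIPT_ID_RE.search(attrs)
            if match is None:
                raise ValueError(
                    f"{path}: exon line {lineno} lacks a transcript_id attribute"
                )
            tid = match.group(1)
            start, end = int(start_s), int(end_s)
            if end < start:
                raise ValueError(
                    f"{path}: exon line {lineno} has end < start ({start}..{end})"
                )
            ann = annotations.get(tid)
            if ann is None:
                annotations[tid] = ExonAnnotation(
                    transcript_id=tid, chrom=chrom, strand=strand, exons=[(start, end)]
                )
            else:
                if ann.strand != strand:
                    raise ValueError(
                        f"{path}: transcript {tid!r} has exons on mixed strands"
                    )
                ann.exons.append((start, end))
    return annotations


def exon_segments(record: TranscriptRecord, annotation: Optional[ExonAnnotation]) -> list[str]:
    """Split a transcript into its exon subsequences, 5'->3'.

    Exons are ordered in transcript orientation: genomic order for ``+``
    strand, reversed genomic order for ``-``.  Concatenating the returned
    segments reproduces ``record.sequence``.  With no annotation the whole
    transcript is one segment, so exon features degrade gracefully to
    transcript-level features.
    """
    if annotation is None or not annotation.exons:
        return [record.sequence]
    total = annotation.total_length
    if total != len(record.sequence):
        raise ValueError(
            f"transcript {record.id!r}: annotated exon length {total} != "
            f"sequence length {len(record.sequence)}"
        )
    exons = sorted(annotation.exons)
    if annotation.strand == "-":
        exons = exons[::-1]
    segments = []
    pos = 0
    for start, end in exons:
        length = end - start + 1
        segments.append(record.sequence[pos : pos + length])
        pos += length
    return segments


def attach_exon_spans(
    records: Iterable[TranscriptRecord], annotations: dict[str, ExonAnnotation]
) -> None:
    """Set ``exon_spans`` on each record from its annotation, in place.

    Records without annotation are left untouched (single implicit segment).
    """
    for rec in records:
        ann = annotations.get(rec.id)
        if ann is None:
            continue
        segs = exon_segments(rec, ann)
        spans = []
        pos = 0
        for seg in segs:
            spans.append((pos, pos + len(seg)))
            pos += len(seg)
        rec.exon_spans = spans


def segments_from_spans(record: TranscriptRecord) -> list[str]:
    """Exon subsequences from a record's own spans (whole sequence if none)."""
    if not record.exon_spans:
        return [record.sequence]
    return [record.sequence[s:e] for s, e in record.exon_spans]
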