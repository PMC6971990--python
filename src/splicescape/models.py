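"""Core in-memory model of genomes, genes, transcripts and splice sites.

Coordinates are 0-based, half-open, genomic (exons sorted by genomic start
regardless of strand).  Conversion to/from the 1-based inclusive GTF
convention happens only at the I/O boundary (:mod:`splicescape.annotation_io`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional

COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (case preserved, N-safe)."""
    return seq.translate(COMPLEMENT)[::-1]


class ModelError(ValueError):
    """A structurally invalid gene/transcript construct."""


class CoordinateError(ValueError):
    """A feature lies outside its contig or violates coordinate sanity."""


@dataclass
class GenomeSequence:
    """Uppercase-normalized contig sequences, keyed by contig id."""

    contigs: dict[str, str]

    def __contains__(self, contig: str) -> bool:
        return contig in self.contigs

    def length(self, contig: str) -> int:
        return len(self.contigs[contig])

    def fetch(self, contig: str, start: int, end: int, strand: str = "+") -> str:
        """Sequence of ``[start, end)``; reverse-complemented on '-'."""
        seq = self.contigs[contig]
        if start < 0 or end > len(seq) or start > end:
            raise CoordinateError(
                f"{contig}:{start}-{end} outside contig of length {len(seq)}"
            )
        sub = seq[start:end]
        return revcomp(sub) if strand == "-" else sub


@dataclass
class TranscriptModel:
    """One isoform: an ordered exon chain with strand and optional CDS span.

    ``cds`` is the genomic (start, end) span of the annotated coding region,
    including the stop codon.  ``class_code`` carries the assembler comparison
    vocabulary ('=' identical intron chain, 'j' shared junction, ...).
    """

    transcript_id: str
    gene_id: str
    contig: str
    strand: str
    exons: list[tuple[int, int]]
    cds: Optional[tuple[int, int]] = None
    class_code: Optional[str] = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ModelError(f"{self.transcript_id}: bad strand {self.strand!r}")
        exons = sorted(self.exons)
        for s, e in exons:
            if s >= e:
                raise ModelError(f"{self.transcript_id}: empty exon ({s}, {e})")
        for (_, e1), (s2, _) in zip(exons, exons[1:]):
            if s2 <= e1:
                raise ModelError(
                    f"{self.transcript_id}: exons overlap or abut without intron"
                )
        self.exons = exons
        if self.cds is not None:
            cs, ce = self.cds
            if not (exons[0][0] <= cs < ce <= exons[-1][1]):
                raise ModelError(f"{self.transcript_id}: CDS outside exon span")

    # -- derived geometry ---------------------------------------------------

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)

    def introns(self) -> list[tuple[int, int]]:
        """Genomic intron intervals (gaps between consecutive exons)."""
        return [
            (e1, s2) for (_, e1), (s2, _) in zip(self.exons, self.exons[1:])
        ]

    def junction_set(self) -> set[tuple[int, int]]:
        return set(self.introns())

    def exon_lengths(self) -> list[int]:
        return [e - s for s, e in self.exons]

    def cdna_length(self) -> int:
        return sum(self.exon_lengths())

    def is_exonic(self, pos: int) -> bool:
        return any(s <= pos < e for s, e in self.exons)

    def genomic_to_transcript(self, pos: int) -> Optional[int]:
        """Transcript coordinate of genomic base ``pos``, or None if intronic.

        Transcript coordinates run 5'->3' in transcription direction.
        """
        off = 0
        if self.strand == "+":
            for s, e in self.exons:
                if s <= pos < e:
                    return off + (pos - s)
                off += e - s
            return None
        for s, e in reversed(self.exons):
            if s <= pos < e:
                return off + (e - 1 - pos)
            off += e - s
        return None

    def transcript_to_genomic(self, tpos: int) -> int:
        """Genomic base under transcript coordinate ``tpos``."""
        if tpos < 0 or tpos >= self.cdna_length():
            raise CoordinateError(f"{self.transcript_id}: tpos {tpos} out of range")
        off = tpos
        if self.strand == "+":
            for s, e in self.exons:
                if off < e - s:
                    return s + off
                off -= e - s
        else:
            for s, e in reversed(self.exons):
                if off < e - s:
                    return e - 1 - off
                off -= e - s
        raise AssertionError("unreachable")


@dataclass
class GeneModel:
    """All isoforms of one locus (shared contig and strand)."""

    gene_id: str
    contig: str
    strand: str
    transcripts: list[TranscriptModel] = field(default_factory=list)
    reference_transcript_ids: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.transcripts:
            raise ModelError(f"{self.gene_id}: gene without transcripts")
        for t in self.transcripts:
            if t.contig != self.contig or t.strand != self.strand:
                raise ModelError(
                    f"{self.gene_id}: transcript {t.transcript_id} on different "
                    "contig/strand (mixed-strand constructs are rejected)"
                )

    def __iter__(self) -> Iterator[TranscriptModel]:
        return iter(self.transcripts)

    def get(self, transcript_id: str) -> TranscriptModel:
        for t in self.transcripts:
            if t.transcript_id == transcript_id:
                return t
        raise KeyError(transcript_id)

    def reference_transcripts(self) -> list[TranscriptModel]:
        return [
            t for t in self.transcripts
            if t.transcript_id in self.reference_transcript_ids
        ]
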