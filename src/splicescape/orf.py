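"""ORF projection onto AS isoforms and premature-termination-codon calls.

The annotated start codon of the reference isoform is mapped through each
alternative isoform's exon chain (no de-novo ORF prediction): translation
then runs to the first in-frame stop.  A stop whose genomic position differs
from the reference stop and truncates the protein is a premature termination
codon (PTC).  A stop more than 50 nt upstream of the last exon-exon junction
additionally flags the isoform as a classic nonsense-mediated-decay
candidate; the flag is advisory and never used for filtering.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .models import GenomeSequence, ModelError, TranscriptModel

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

#: standard genetic code (DNA alphabet), stops as '*'
_CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

NMD_DISTANCE_NT = 50


@dataclass
class OrfResult:
    transcript_id: str
    cdna_length: int
    start_used: Optional[int]          # transcript coordinate of the start
    stop_position: Optional[int]       # transcript coordinate of stop codon
    protein_length: Optional[int]      # aa, stop excluded
    protein: Optional[str] = None
    is_ptc: bool = False
    run_through: bool = False          # no in-frame stop before transcript end
    distance_stop_to_last_junction: Optional[int] = None
    nmd_candidate: bool = False
    reference_protein_length: Optional[int] = None
    start_projected: bool = True


def extract_cdna(t: TranscriptModel, genome: GenomeSequence) -> str:
    """Spliced transcript sequence in transcription orientation."""
    parts = [genome.fetch(t.contig, s, e, "+") for s, e in t.exons]
    seq = "".join(parts)
    if t.strand == "-":
        from .models import revcomp
        seq = revcomp(seq)
    return seq


def reference_start_genomic(reference: TranscriptModel) -> int:
    """Genomic position of the first base of the annotated start codon."""
    if reference.cds is None:
        raise ModelError(
            f"{reference.transcript_id}: reference transcript lacks a CDS"
        )
    cs, ce = reference.cds
    return cs if reference.strand == "+" else ce - 1


def project_start(reference: TranscriptModel,
                  isoform: TranscriptModel) -> Optional[int]:
    """Transcript coordinate of the reference start codon in ``isoform``,
    or None when the start's genomic position is not exonic there."""
    if reference.gene_id != isoform.gene_id:
        raise ModelError("start projection across genes")
    gpos = reference_start_genomic(reference)
    return isoform.genomic_to_transcript(gpos)


def translate(cdna: str, start: int) -> tuple[str, Optional[int]]:
    """Translate from ``start`` to the first in-frame stop.

    Returns (protein, stop_tpos); stop_tpos is None when translation runs
    through the transcript end (partial trailing codons ignored).
    """
    protein = []
    for i in range(start, len(cdna) - 2, 3):
        codon = cdna[i : i + 3]
        aa = _CODON_TABLE.get(codon, "X")
        if aa == "*":
            return "".join(protein), i
        protein.append(aa)
    return "".join(protein), None


def _last_junction_tpos(t: TranscriptModel) -> Optional[int]:
    """Transcript coordinate of the last exon-exon junction (first base of
    the final exon in transcription order); None for mono-exonic."""
    if len(t.exons) < 2:
        return None
    lens = t.exon_lengths()
    if t.strand == "-":
        lens = lens[::-1]
    return sum(lens[:-1])


def scan_orf(isoform: TranscriptModel, reference: TranscriptModel,
             genome: GenomeSequence) -> OrfResult:
    """Project the reference ORF onto ``isoform`` and call PTC/NMD status."""
    cdna = extract_cdna(isoform, genome)
    res = OrfResult(
        transcript_id=isoform.transcript_id,
        cdna_length=len(cdna),
        start_used=None, stop_position=None, protein_length=None,
    )

    ref_cdna = extract_cdna(reference, genome)
    ref_start = project_start(reference, reference)
    assert ref_start is not None
    ref_protein, ref_stop = translate(ref_cdna, ref_start)
    res.reference_protein_length = len(ref_protein)
    ref_stop_genomic = (
        reference.transcript_to_genomic(ref_stop) if ref_stop is not None else None
    )

    start = project_start(reference, isoform)
    if start is None:
        res.start_projected = False
        return res
    res.start_used = start

    protein, stop = translate(cdna, start)
    res.protein = protein
    res.protein_length = len(protein)
    if stop is None:
        res.run_through = True
        return res
    res.stop_position = stop

    stop_genomic = isoform.transcript_to_genomic(stop)
    res.is_ptc = (
        ref_stop_genomic is not None
        and stop_genomic != ref_stop_genomic
        and len(protein) < len(ref_protein)
    )

    last_junc = _last_junction_tpos(isoform)
    if last_junc is not None:
        # distance from the stop codon's end to the last junction
        res.distance_stop_to_last_junction = last_junc - (stop + 3)
        res.nmd_candidate = (
            res.distance_stop_to_last_junction is not None
            and res.distance_stop_to_last_junction > NMD_DISTANCE_NT
        )
    return res


def gene_orf_results(gene, reference: TranscriptModel,
                     genome: GenomeSequence) -> list[OrfResult]:
    return [scan_orf(t, reference, genome) for t in gene.transcripts]
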