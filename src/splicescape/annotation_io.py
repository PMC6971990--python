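"""Read/write genome FASTA and transcript GTF; isoform-inclusion filtering.

GTF records are the GTF2.2 dialect (``key "value";`` attributes) with
``gene_id``/``transcript_id`` on every feature and an optional ``class_code``
attribute carrying the assembler comparison class.  GTF coordinates are
1-based inclusive and are converted to the internal 0-based half-open
convention on read (and back on write).
"""

from __future__ import annotations

import collections
from pathlib import Path
from typing import Iterable, Optional, Sequence, TextIO, Union

from Bio import SeqIO
from gffutils.feature import feature_from_line

from .models import CoordinateError, GeneModel, GenomeSequence, ModelError, TranscriptModel

PathLike = Union[str, Path]

#: class codes accepted as isoforms of known genes by default
DEFAULT_ALLOWED_CODES = frozenset({"=", "j"})

_VALID_BASES = set("ACGTN")


class ParseError(ValueError):
    """Malformed FASTA/GTF input."""


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_genome(path: PathLike) -> GenomeSequence:
    """Load a FASTA genome, uppercase-normalized, U converted to T.

    Raises :class:`ParseError` on duplicate contig ids or non-nucleotide
    alphabet.
    """
    contigs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in contigs:
            raise ParseError(f"duplicate contig id {rec.id!r} in {path}")
        seq = str(rec.seq).upper().replace("U", "T")
        bad = set(seq) - _VALID_BASES
        if bad:
            raise ParseError(
                f"contig {rec.id!r}: invalid characters {sorted(bad)}"
            )
        contigs[rec.id] = seq
    return GenomeSequence(contigs)


def write_genome(genome: GenomeSequence, path: PathLike, width: int = 70) -> None:
    with open(path, "w") as fh:
        for cid, seq in genome.contigs.items():
            fh.write(f">{cid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# GTF
# ---------------------------------------------------------------------------

def _parse_gtf_line(line: str, lineno: int):
    try:
        return feature_from_line(line)
    except Exception as exc:  # gffutils raises bare exceptions on bad lines
        raise ParseError(f"GTF line {lineno}: {exc}") from exc


def read_gtf(path: PathLike, genome: Optional[GenomeSequence] = None) -> list[GeneModel]:
    """Parse a GTF into :class:`GeneModel` objects.

    Exon features are grouped per transcript (sorted by genomic start) and
    transcripts per gene.  CDS features, when present, define the genomic CDS
    span of their transcript.  Records on contigs absent from ``genome`` (when
    given) raise :class:`CoordinateError`, as do exons beyond the contig end.
    """
    exons: dict[str, list[tuple[int, int]]] = collections.defaultdict(list)
    meta: dict[str, dict] = {}
    cds_spans: dict[str, list[tuple[int, int]]] = collections.defaultdict(list)
    order: list[str] = []

    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            feat = _parse_gtf_line(line, lineno)
            if feat.featuretype not in ("exon", "CDS"):
                continue
            try:
                tid = feat.attributes["transcript_id"][0]
                gid = feat.attributes["gene_id"][0]
            except KeyError as exc:
                raise ParseError(
                    f"GTF line {lineno}: missing {exc} attribute"
                ) from exc
            start, end = feat.start - 1, feat.end  # to 0-based half-open
            if genome is not None:
                if feat.seqid not in genome:
                    raise CoordinateError(
                        f"GTF line {lineno}: contig {feat.seqid!r} not in genome"
                    )
                if end > genome.length(feat.seqid) or start < 0:
                    raise CoordinateError(
                        f"GTF line {lineno}: {feat.seqid}:{start}-{end} beyond "
                        f"contig end {genome.length(feat.seqid)}"
                    )
            if tid not in meta:
                meta[tid] = {
                    "gene_id": gid,
                    "contig": feat.seqid,
                    "strand": feat.strand,
                    "class_code": (feat.attributes["class_code"][0]
                                   if "class_code" in feat.attributes else None),
                }
                order.append(tid)
            else:
                if meta[tid]["strand"] != feat.strand:
                    raise ModelError(
                        f"transcript {tid}: exons on mixed strands"
                    )
                if meta[tid]["contig"] != feat.seqid:
                    raise ModelError(f"transcript {tid}: exons on mixed contigs")
            if feat.featuretype == "exon":
                exons[tid].append((start, end))
            else:
                cds_spans[tid].append((start, end))

    genes: dict[str, GeneModel] = {}
    gene_order: list[str] = []
    for tid in order:
        m = meta[tid]
        if not exons[tid]:
            continue
        cds = None
        if cds_spans[tid]:
            cds = (min(s for s, _ in cds_spans[tid]), max(e for _, e in cds_spans[tid]))
        t = TranscriptModel(
            transcript_id=tid, gene_id=m["gene_id"], contig=m["contig"],
            strand=m["strand"], exons=exons[tid], cds=cds,
            class_code=m["class_code"],
        )
        gid = m["gene_id"]
        if gid not in genes:
            genes[gid] = GeneModel(gid, m["contig"], m["strand"], [t])
            gene_order.append(gid)
        else:
            genes[gid].transcripts.append(t)
            # re-validate shared contig/strand
            GeneModel(gid, genes[gid].contig, genes[gid].strand,
                      genes[gid].transcripts)
    return [genes[g] for g in gene_order]


def _fmt_attrs(t: TranscriptModel) -> str:
    parts = [f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}";']
    if t.class_code is not None:
        parts.append(f'class_code "{t.class_code}";')
    return " ".join(parts)


def write_gtf(genes: Iterable[GeneModel], path_or_fh: Union[PathLike, TextIO],
              source: str = "splicescape") -> None:
    """Emit genes as GTF (exon + CDS features), 1-based inclusive."""
    own = not hasattr(path_or_fh, "write")
    fh = open(path_or_fh, "w") if own else path_or_fh
    try:
        for gene in genes:
            for t in gene.transcripts:
                attrs = _fmt_attrs(t)
                for s, e in t.exons:
                    fh.write(
                        f"{t.contig}\t{source}\texon\t{s + 1}\t{e}\t.\t"
                        f"{t.strand}\t.\t{attrs}\n"
                    )
                if t.cds is not None:
                    cs, ce = t.cds
                    for s, e in t.exons:
                        os_, oe = max(s, cs), min(e, ce)
                        if os_ < oe:
                            fh.write(
                                f"{t.contig}\t{source}\tCDS\t{os_ + 1}\t{oe}\t.\t"
                                f"{t.strand}\t.\t{attrs}\n"
                            )
    finally:
        if own:
            fh.close()


def write_transcript_summary(genes: Iterable[GeneModel], path: PathLike) -> None:
    """Transcript summary TSV: transcript-id, gene-id, n-exons, class-code."""
    with open(path, "w") as fh:
        fh.write("transcript_id\tgene_id\tn_exons\tclass_code\n")
        for gene in genes:
            for t in gene.transcripts:
                code = t.class_code if t.class_code is not None else "."
                fh.write(f"{t.transcript_id}\t{t.gene_id}\t{len(t.exons)}\t{code}\n")


# ---------------------------------------------------------------------------
# isoform-inclusion filter and class-code classification
# ---------------------------------------------------------------------------

def classify_class_code(candidate: TranscriptModel,
                        reference: TranscriptModel) -> str:
    """Assembler-style comparison class of ``candidate`` against ``reference``.

    '=' identical intron chains; 'j' at least one shared splice junction but
    different chains; 'o' exonic overlap without a shared junction; 'u' no
    junction shared and no exonic overlap.
    """
    if candidate.contig != reference.contig:
        raise ModelError("class-code comparison across contigs")
    cj, rj = candidate.junction_set(), reference.junction_set()
    if candidate.strand == reference.strand and cj == rj and (cj or _overlap(candidate, reference)):
        return "="
    if candidate.strand == reference.strand and cj & rj:
        return "j"
    return "o" if _overlap(candidate, reference) else "u"


def _overlap(a: TranscriptModel, b: TranscriptModel) -> bool:
    return any(
        max(s1, s2) < min(e1, e2)
        for s1, e1 in a.exons for s2, e2 in b.exons
    )


def assign_class_codes(genes: Sequence[GeneModel],
                       reference: Sequence[GeneModel]) -> None:
    """Fill in missing class codes by comparing against reference isoforms.

    A transcript gets the best class across the reference transcripts of its
    gene ('=' beats 'j' beats 'o' beats 'u').  Genes absent from the reference
    yield 'u'.
    """
    rank = {"=": 0, "j": 1, "o": 2, "u": 3}
    ref_by_gene = {g.gene_id: g for g in reference}
    for gene in genes:
        ref = ref_by_gene.get(gene.gene_id)
        for t in gene.transcripts:
            if t.class_code is not None:
                continue
            if ref is None:
                t.class_code = "u"
                continue
            codes = [classify_class_code(t, r) for r in ref.transcripts]
            t.class_code = min(codes, key=rank.__getitem__)


def filter_isoforms(genes: Sequence[GeneModel],
                    allowed_codes: frozenset = DEFAULT_ALLOWED_CODES,
                    reference: Optional[Sequence[GeneModel]] = None,
                    ) -> list[GeneModel]:
    """Keep only transcripts whose class code is in ``allowed_codes``.

    Reference-derived transcripts (no class code) are implicitly '='.  When
    ``reference`` is given, transcripts lacking a class code are classified on
    the fly.  Genes left without transcripts are dropped.
    """
    if reference is not None:
        assign_class_codes(genes, reference)
    out: list[GeneModel] = []
    for gene in genes:
        kept = [
            t for t in gene.transcripts
            if (t.class_code or "=") in allowed_codes
        ]
        if kept:
            out.append(GeneModel(gene.gene_id, gene.contig, gene.strand, kept,
                                 set(gene.reference_transcript_ids)))
    return out
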