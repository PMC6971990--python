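"""Splice-junction characterization: novelty and gene-region classes,
donor-acceptor dinucleotide usage, branch-point and polypyrimidine-tract
search, intron statistics, and sequence-logo frequency matrices.

A splice junction is a deduplicated intron — multiple splicing events (or
transcripts) spanning the same intron are one junction.  Junctions at the
same coordinates on opposite strands are distinct: donor/acceptor identity is
strand-defined.

The branch-point search scans a window upstream of the 3' splice site for the
best match to the C-T-R-A-Y consensus (branch A mandatory); it is a declared,
reproducible concretization of the usual intronic-motif searching approach,
with every window and scoring constant exposed in :class:`BranchParams`.
"""

from __future__ import annotations

import collections
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .models import GeneModel, GenomeSequence, TranscriptModel

NOVELTY_CLASSES = ("annotated", "partial_novel", "complete_novel")
LOCATION_CLASSES = ("CDS", "5UTR", "3UTR", "5UTR-CDS", "CDS-3UTR", "noncoding")
DINUCLEOTIDE_CLASSES = ("GT-AG", "GC-AG", "AT-AC", "other")

PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")


class JunctionError(ValueError):
    pass


@dataclass(frozen=True)
class SpliceJunction:
    """A deduplicated intron.  ``start``/``end`` are the genomic half-open
    intron interval; donor/acceptor positions are the transcription-direction
    boundaries (donor = 5' end of the intron in transcription direction)."""

    contig: str
    strand: str
    start: int
    end: int
    novelty: Optional[str] = None
    location: Optional[str] = None
    dinucleotide_pair: Optional[str] = None
    gene_id: Optional[str] = None

    @property
    def donor(self) -> int:
        return self.start if self.strand == "+" else self.end

    @property
    def acceptor(self) -> int:
        return self.end if self.strand == "+" else self.start

    @property
    def length(self) -> int:
        return self.end - self.start

    def key(self) -> tuple:
        return (self.contig, self.strand, self.start, self.end)


@dataclass
class BranchParams:
    """Constants of the branch-point / PPT search.

    window_max/window_min: the scan covers [3'ss - window_max, 3'ss -
    window_min] in intronic nucleotides, clipped to the intron and never
    overlapping the first ``donor_exclusion`` intronic nt.  Consensus scoring:
    the A at 5-mer position 4 is mandatory; C, T, R={A,G}, Y={C,T} at
    positions 1, 2, 3, 5 each score +1.  PPT: maximal-scoring interval between
    the branch A and the 3'ss under +1 pyrimidine / -2 purine, reported when
    at least ``ppt_min_len`` long.
    """

    window_max: int = 150
    window_min: int = 15
    donor_exclusion: int = 10
    min_intron: int = 25
    ppt_min_len: int = 9


@dataclass
class IntronFeatures:
    """Per-intron branch-point / PPT features (positions genomic)."""

    junction: SpliceJunction
    intron_length: int
    branch_a_position: Optional[int] = None
    bp_offset_3ss: Optional[int] = None
    bp_offset_5ss: Optional[int] = None
    bp_score: Optional[int] = None
    ppt_interval: Optional[tuple[int, int]] = None  # intron-relative, tx orient
    ppt_length: Optional[int] = None
    reason_absent: Optional[str] = None


@dataclass
class LogoMatrix:
    """Position x base count matrix around a splice region."""

    region: str                      # {5ss, 3ss, branch}
    offsets: list[int]               # window positions relative to the site
    counts: pd.DataFrame             # index offsets, columns A/C/G/T/N
    n_skipped: int = 0


# ---------------------------------------------------------------------------
# junction collection and classification
# ---------------------------------------------------------------------------

def iter_junctions(genes: Iterable[GeneModel]) -> Iterable[tuple[GeneModel, TranscriptModel, tuple[int, int]]]:
    for gene in genes:
        for t in gene.transcripts:
            for intron in t.introns():
                yield gene, t, intron


def collect_junctions(reference: Sequence[GeneModel],
                      assembled: Sequence[GeneModel],
                      genome: Optional[GenomeSequence] = None,
                      ) -> tuple[list[SpliceJunction], int]:
    """Deduplicated junctions from reference plus assembled annotations,
    with novelty classes assigned against the reference junction/site sets.

    Returns ``(junctions, n_incidences)`` where the second value counts
    junction-transcript incidences before deduplication.
    """
    ref_pairs: set[tuple] = set()
    ref_donors: set[tuple] = set()
    ref_acceptors: set[tuple] = set()
    for _, t, (s, e) in iter_junctions(reference):
        j = SpliceJunction(t.contig, t.strand, s, e)
        ref_pairs.add(j.key())
        ref_donors.add((t.contig, t.strand, j.donor))
        ref_acceptors.add((t.contig, t.strand, j.acceptor))

    seen: dict[tuple, SpliceJunction] = {}
    incidences = 0
    cds_frame = reference_cds_frames(reference)
    for source in (reference, assembled):
        for gene, t, (s, e) in iter_junctions(source):
            incidences += 1
            j = SpliceJunction(t.contig, t.strand, s, e, gene_id=gene.gene_id)
            if j.key() in seen:
                continue
            donor_known = (t.contig, t.strand, j.donor) in ref_donors
            acc_known = (t.contig, t.strand, j.acceptor) in ref_acceptors
            if j.key() in ref_pairs:
                novelty = "annotated"
            elif donor_known or acc_known:
                novelty = "partial_novel"
            else:
                novelty = "complete_novel"
            frame_t = cds_frame.get(gene.gene_id)
            location = None
            if frame_t is not None:
                try:
                    location = classify_location(j, frame_t)
                except JunctionError:
                    location = None
            dinuc = None
            if genome is not None:
                dinuc = junction_dinucleotides(j, genome)
            seen[j.key()] = SpliceJunction(
                j.contig, j.strand, j.start, j.end,
                novelty=novelty, location=location,
                dinucleotide_pair=dinuc, gene_id=gene.gene_id,
            )
    ordered = sorted(seen.values(), key=lambda j: (j.contig, j.start, j.end, j.strand))
    return ordered, incidences


def reference_cds_frames(reference: Sequence[GeneModel]
                         ) -> dict[str, Optional[TranscriptModel]]:
    """The coding frame-of-reference per gene: the isoform with the longest
    CDS (deterministic tie-break by transcript id), or None for noncoding."""
    out: dict[str, Optional[TranscriptModel]] = {}
    for gene in reference:
        coding = [t for t in gene.transcripts if t.cds is not None]
        if not coding:
            out[gene.gene_id] = None
        else:
            out[gene.gene_id] = max(
                coding, key=lambda t: (t.cds[1] - t.cds[0], t.transcript_id)
            )
    return out


def classify_location(j: SpliceJunction, t: TranscriptModel) -> str:
    """Gene-region class of a junction relative to a coding transcript.

    Each extremity is classified against the annotated CDS genomic span
    (5'UTR upstream of the CDS in transcription direction, 3'UTR downstream);
    a junction spanning a boundary gets the strand-oriented 5UTR-CDS or
    CDS-3UTR label.  A transcript without CDS yields ``noncoding``.
    """
    if not (t.start <= j.start and j.end <= t.end):
        raise JunctionError(
            f"junction {j.contig}:{j.start}-{j.end} not contained in "
            f"transcript {t.transcript_id}"
        )
    if t.cds is None:
        return "noncoding"
    cs, ce = t.cds

    def region(pos: int) -> str:
        # pos is a boundary coordinate in half-open space
        if cs <= pos <= ce:
            return "CDS"
        upstream = pos < cs if t.strand == "+" else pos > ce
        return "5UTR" if upstream else "3UTR"

    r_donor, r_acceptor = region(j.donor), region(j.acceptor)
    if r_donor == r_acceptor:
        return r_donor
    pair = {r_donor, r_acceptor}
    if pair == {"5UTR", "CDS"}:
        return "5UTR-CDS"
    if pair == {"CDS", "3UTR"}:
        return "CDS-3UTR"
    return "5UTR-CDS" if "5UTR" in pair else "CDS-3UTR"  # UTR-UTR spanning CDS


def junction_dinucleotides(j: SpliceJunction, genome: GenomeSequence
                           ) -> Optional[str]:
    """Donor/acceptor dinucleotide pair read in transcription orientation
    ("GT-AG" for a canonical intron); None for introns shorter than 4 nt."""
    if j.length < 4:
        return None
    intron = genome.fetch(j.contig, j.start, j.end, j.strand)
    return f"{intron[:2]}-{intron[-2:]}"


def dinucleotide_usage(junctions: Sequence[SpliceJunction],
                       genome: GenomeSequence) -> pd.DataFrame:
    """Count and percentage table of donor-acceptor dinucleotide classes.

    Reported in the DNA alphabet (GT-AG is the RNA GU-AG).  Introns shorter
    than 4 nt are excluded and counted under ``undefined``.
    """
    counter: collections.Counter = collections.Counter()
    undefined = 0
    for j in junctions:
        pair = j.dinucleotide_pair or junction_dinucleotides(j, genome)
        if pair is None:
            undefined += 1
            continue
        cls = pair if pair in ("GT-AG", "GC-AG", "AT-AC") else "other"
        counter[(cls, pair)] += 1
    total = sum(counter.values())
    rows = []
    for cls in DINUCLEOTIDE_CLASSES:
        n = sum(v for (c, _), v in counter.items() if c == cls)
        rows.append({
            "class": cls, "count": n,
            "percent": 100.0 * n / total if total else 0.0,
        })
    df = pd.DataFrame(rows)
    df.attrs["n_undefined"] = undefined
    return df


# ---------------------------------------------------------------------------
# branch point / PPT
# ---------------------------------------------------------------------------

def _branch_score(window: str) -> int:
    """Consensus score of a CTRAY 5-mer with A fixed at position 4."""
    score = 0
    if window[0] == "C":
        score += 1
    if window[1] == "T":
        score += 1
    if window[2] in PURINES:
        score += 1
    if window[4] in PYRIMIDINES:
        score += 1
    return score


def find_branch_point(j: SpliceJunction, genome: GenomeSequence,
                      params: BranchParams = BranchParams()) -> IntronFeatures:
    """Branch-point and PPT features of one intron.

    Scans intronic positions whose distance to the 3'ss lies within the
    configured window for the best CTRAY match (ties broken toward the 3'ss);
    the PPT is the maximal-scoring pyrimidine interval between branch A and
    the 3'ss.
    """
    length = j.length
    feats = IntronFeatures(junction=j, intron_length=length)
    if length < params.min_intron:
        feats.reason_absent = "intron_too_short"
        return feats
    intron = genome.fetch(j.contig, j.start, j.end, j.strand)

    # candidate branch-A indices (intron-relative, transcription orientation)
    # offset from 3'ss for index i is length - 1 - i
    lo = max(params.donor_exclusion + 3, length - 1 - params.window_max)
    hi = length - 1 - params.window_min
    best: Optional[tuple[int, int]] = None  # (score, index)
    for i in range(lo, hi + 1):
        if i - 3 < 0 or i + 1 >= length:
            continue
        if intron[i] != "A":
            continue
        score = _branch_score(intron[i - 3 : i + 2])
        # ties broken toward the 3'ss: >= keeps the later (nearer) site
        if best is None or score >= best[0]:
            best = (score, i)
    if best is None:
        feats.reason_absent = "no_branch_A_in_window"
        return feats

    score, idx = best
    feats.bp_score = score
    feats.bp_offset_3ss = length - 1 - idx
    feats.bp_offset_5ss = idx
    if j.strand == "+":
        feats.branch_a_position = j.start + idx
    else:
        feats.branch_a_position = j.end - 1 - idx

    # PPT: maximal-scoring subarray strictly between branch A and the 3'ss
    region = intron[idx + 1 :]
    if region:
        vals = np.where(np.isin(list(region), list("CT")), 1, -2)
        best_sum, cur_sum = 0, 0
        best_iv: Optional[tuple[int, int]] = None
        cur_start = 0
        for k, v in enumerate(vals):
            if cur_sum <= 0:
                cur_sum, cur_start = int(v), k
            else:
                cur_sum += int(v)
            if cur_sum > best_sum:
                best_sum = cur_sum
                best_iv = (cur_start, k + 1)
        if best_iv is not None:
            plen = best_iv[1] - best_iv[0]
            if plen >= params.ppt_min_len:
                feats.ppt_interval = (idx + 1 + best_iv[0], idx + 1 + best_iv[1])
                feats.ppt_length = plen
    return feats


def find_branch_points(junctions: Sequence[SpliceJunction],
                       genome: GenomeSequence,
                       params: BranchParams = BranchParams()
                       ) -> list[IntronFeatures]:
    return [find_branch_point(j, genome, params) for j in junctions]


# ---------------------------------------------------------------------------
# statistics and logos
# ---------------------------------------------------------------------------

def length_histogram(lengths: Sequence[int], cap: int = 2000) -> pd.DataFrame:
    """Intron-length histogram: <=50, 51-150, then 100-wide bins to ``cap``,
    plus an open top bin."""
    edges = [0, 50, 150] + list(range(250, cap + 1, 100))
    if edges[-1] != cap:
        edges.append(cap)
    labels = ["<=50", "51-150"] + [
        f"{a + 1}-{b}" for a, b in zip(edges[2:-1], edges[3:])
    ] + [f">{cap}"]
    arr = np.asarray(lengths)
    counts = []
    for a, b in zip(edges, edges[1:]):
        counts.append(int(((arr > a) & (arr <= b)).sum()))
    counts.append(int((arr > cap).sum()))
    return pd.DataFrame({"bin": labels, "count": counts})


def intron_statistics(features: Sequence[IntronFeatures],
                      cap: int = 2000) -> dict:
    """Summary of intron lengths and branch offsets.

    Includes mean +/- sd and median length, mean +/- sd of the branch-A to
    3'ss offset, the length histogram, and the Pearson correlation between
    intron length and the branch offset from the 5'ss.
    """
    if not features:
        raise ValueError("intron_statistics requires a non-empty feature list")
    lengths = np.array([f.intron_length for f in features], dtype=float)
    off3 = np.array([f.bp_offset_3ss for f in features
                     if f.bp_offset_3ss is not None], dtype=float)
    off5 = np.array([(f.intron_length, f.bp_offset_5ss) for f in features
                     if f.bp_offset_5ss is not None], dtype=float)
    summary = {
        "n_introns": int(len(lengths)),
        "length_mean": float(lengths.mean()),
        "length_sd": float(lengths.std(ddof=1)) if len(lengths) > 1 else 0.0,
        "length_median": float(np.median(lengths)),
        "n_with_branch": int(len(off3)),
        "bp_offset_3ss_mean": float(off3.mean()) if len(off3) else None,
        "bp_offset_3ss_sd": (float(off3.std(ddof=1)) if len(off3) > 1 else 0.0)
        if len(off3) else None,
        "histogram": length_histogram(lengths, cap=cap),
    }
    if len(off5) > 2 and np.ptp(off5[:, 0]) > 0 and np.ptp(off5[:, 1]) > 0:
        r, p = stats.pearsonr(off5[:, 0], off5[:, 1])
        summary["length_vs_bp5ss_r"] = float(r)
        summary["length_vs_bp5ss_p"] = float(p)
    else:
        summary["length_vs_bp5ss_r"] = None
        summary["length_vs_bp5ss_p"] = None
    return summary


#: default logo windows: (region, exonic-side bases, intronic-side bases)
DEFAULT_LOGO_WINDOWS = {
    "5ss": (3, 6),     # exon -3..-1, intron +1..+6
    "3ss": (12, 3),    # intron -12..-1, exon +1..+3
    "branch": (4, 2),  # -4..+2 around the branch A
}


def _logo_offsets(region: str, a: int, b: int) -> list[int]:
    if region == "5ss":
        return list(range(-a, 0)) + list(range(1, b + 1))
    if region == "3ss":
        return list(range(-a, 0)) + list(range(1, b + 1))
    return list(range(-a, b + 1))  # branch window includes 0


def build_logos(features: Sequence[IntronFeatures], genome: GenomeSequence,
                windows: Optional[dict] = None) -> list[LogoMatrix]:
    """Position-frequency count matrices for the 5'ss, 3'ss and branch
    regions (transcription orientation; counts per contributing intron)."""
    windows = dict(DEFAULT_LOGO_WINDOWS, **(windows or {}))
    bases = "ACGTN"
    out = []
    for region, (a, b) in windows.items():
        offsets = _logo_offsets(region, a, b)
        counts = np.zeros((len(offsets), len(bases)), dtype=int)
        skipped = 0
        for f in features:
            j = f.junction
            if region == "branch":
                if f.branch_a_position is None:
                    skipped += 1
                    continue
                center = f.branch_a_position
                # window -a..+b around branch A in transcription direction
                if j.strand == "+":
                    gstart, gend = center - a, center + b + 1
                else:
                    gstart, gend = center - b, center + a + 1
            elif region == "5ss":
                # exon -3..-1 then intron +1..+6 around the donor boundary
                if j.strand == "+":
                    gstart, gend = j.start - a, j.start + b
                else:
                    gstart, gend = j.end - b, j.end + a
            else:  # 3ss
                if j.strand == "+":
                    gstart, gend = j.end - a, j.end + b
                else:
                    gstart, gend = j.start - b, j.start + a
            if gstart < 0 or gend > genome.length(j.contig):
                skipped += 1
                continue
            seq = genome.fetch(j.contig, gstart, gend, j.strand)
            if len(seq) != len(offsets):
                skipped += 1
                continue
            for row, base in enumerate(seq):
                counts[row, bases.index(base)] += 1
        out.append(LogoMatrix(
            region=region, offsets=offsets,
            counts=pd.DataFrame(counts, index=offsets, columns=list(bases)),
            n_skipped=skipped,
        ))
    return out


def junctions_to_bed(junctions: Sequence[SpliceJunction]) -> pd.DataFrame:
    """Six-column BED (0-based half-open) with name novelty|location|dinuc."""
    rows = []
    for j in junctions:
        name = "|".join([
            j.novelty or ".", j.location or ".", j.dinucleotide_pair or ".",
        ])
        rows.append((j.contig, j.start, j.end, name, 0, j.strand))
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "name", "score", "strand"],
    )
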