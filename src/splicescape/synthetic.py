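"""Synthetic genomes, AS isoforms, expression and metabolite tables with
fully known ground truth.

Every downstream stage of the package is testable against this generator:
genes are built around a planted AS event (one of the eleven coded
structures), every splice site used by any isoform carries a planted
donor/acceptor dinucleotide, every controlled intron carries a planted
C-T-R-A-Y branch motif and polypyrimidine tract, intron-retention isoforms
optionally carry a planted in-frame stop, expression matrices carry planted
fold changes, and metabolite tables carry planted transcript correlations.

Intron interiors are A-free outside the planted branch motif, so the motif
search has a unique maximal hit and motif-recovery tests are exact.  Branch
offsets are drawn from a normal distribution truncated *symmetrically*
around its mean so the planted mean is preserved exactly.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .annotation_io import write_genome, write_gtf
from .differential import ExpressionMatrix
from .events import CODE_TABLE
from .metabolites import MetaboliteMatrix
from .models import GeneModel, GenomeSequence, TranscriptModel, revcomp

#: canonical code string per event type
TYPE_TO_CODE = {v: k for k, v in CODE_TABLE.items()}

STOPS = ("TAA", "TAG", "TGA")

_NONSTOP_CODONS = [
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if a + b + c not in STOPS
]

_DONOR = {"GT-AG": "GT", "GC-AG": "GC", "AT-AC": "AT"}
_ACCEPTOR = {"GT-AG": "AG", "GC-AG": "AG", "AT-AC": "AC"}
_OTHER_DONORS = ("CT", "TT", "GG")
_OTHER_ACCEPTORS = ("GC", "CC", "TG")

DEFAULT_EVENT_MIX = {
    "IR": 0.30, "A3SS": 0.16, "A5SS": 0.11, "ES": 0.10, "MXE": 0.05,
    "IR1+IR2": 0.06, "A5SS_or_A3SS": 0.05, "IR1_or_IR2": 0.05,
    "A5SS+A3SS": 0.05, "ES1+ES2": 0.04, "A5SS+ES+A3SS": 0.03,
}

DEFAULT_DINUCLEOTIDE_MIX = {
    "GT-AG": 0.965, "GC-AG": 0.017, "AT-AC": 0.005, "other": 0.013,
}


class ConfigError(ValueError):
    pass


class _RetryGene(Exception):
    """Internal: the current random draw is infeasible; redraw."""


@dataclass
class SimulationConfig:
    """Study-condition parameters of the simulated dataset.

    Defaults follow the cold-acclimation study design: five time points
    (NA, CS, CA1, CA2, DA) with two biological replicates for expression,
    and six replicates for the metabolite table.
    """

    seed: int = 0
    n_genes: int = 60
    exons_per_gene: tuple[int, int] = (3, 6)
    exon_length: tuple[int, int] = (90, 240)
    intron_log_mean: float = math.log(260.0)
    intron_log_sd: float = 0.45
    intron_floor: int = 110
    strand_fraction: float = 0.5
    as_fraction: float = 0.85
    event_mix: dict = field(default_factory=lambda: dict(DEFAULT_EVENT_MIX))
    dinucleotide_mix: dict = field(
        default_factory=lambda: dict(DEFAULT_DINUCLEOTIDE_MIX))
    branch_offset_mean: float = 55.0
    branch_offset_sd: float = 30.0
    branch_offset_halfwidth: float = 39.0   # symmetric truncation; keeps mean
    ppt_length: tuple[int, int] = (9, 18)
    ptc_fraction: float = 0.5               # of IR isoforms
    conditions: tuple[str, ...] = ("NA", "CS", "CA1", "CA2", "DA")
    replicates: int = 2
    conserved_as_fraction: float = 0.6
    as_presence_p: float = 0.5
    de_fraction: float = 0.1
    log2fc: float = 2.0
    expr_noise_sd: float = 0.25             # log2-scale replicate noise
    base_log2_expr: float = 5.5
    base_log2_expr_sd: float = 1.5
    metabolite_conditions: tuple[str, ...] = ("NA", "CA2", "DA")
    metabolite_replicates: int = 6
    n_metabolites: int = 20
    metabolite_link_fraction: float = 0.5
    metabolite_target_r: float = 0.8
    metabolite_noise_sd: float = 0.05       # log2-scale replicate noise
    n_contigs: int = 3
    intergenic: int = 400

    def validate(self) -> None:
        for name, mix in (("event_mix", self.event_mix),
                          ("dinucleotide_mix", self.dinucleotide_mix)):
            if abs(sum(mix.values()) - 1.0) > 1e-9:
                raise ConfigError(f"{name} probabilities must sum to 1")
        unknown = set(self.event_mix) - set(TYPE_TO_CODE)
        if unknown:
            raise ConfigError(f"unknown event types {unknown}")
        if self.exon_length[0] < 70:
            raise ConfigError("exon length below splice-site context minimum")
        if self.intron_floor < 60:
            raise ConfigError("intron floor below branch-window minimum (60)")
        if self.replicates < 1 or self.metabolite_replicates < 2:
            raise ConfigError("replicate counts too small")


# ---------------------------------------------------------------------------
# ground truth containers
# ---------------------------------------------------------------------------

@dataclass
class PlantedJunction:
    contig: str
    strand: str
    start: int
    end: int
    dinucleotide_pair: str
    branch_a_position: Optional[int]
    bp_offset_3ss: Optional[int]
    ppt_interval: Optional[tuple[int, int]]


@dataclass
class PlantedGene:
    gene_id: str
    contig: str
    strand: str
    event_type: Optional[str]
    code: Optional[str]
    reference_id: str
    isoform_id: Optional[str]
    ptc_planted: Optional[bool]
    as_samples: tuple[str, ...]
    de_log2fc: dict = field(default_factory=dict)   # condition -> planted lfc
    junctions: list = field(default_factory=list)    # PlantedJunction


@dataclass
class PlantedMetabolite:
    metabolite_id: str
    linked_transcript: Optional[str]
    probe_transcript: str       # the transcript the planted r refers to
    target_r: float             # exact planted condition-mean correlation
    sign: int


@dataclass
class GroundTruth:
    genes: list[PlantedGene]
    metabolites: list[PlantedMetabolite]
    conditions: tuple[str, ...]

    def gene(self, gene_id: str) -> PlantedGene:
        return next(g for g in self.genes if g.gene_id == gene_id)

    def as_gene_sets(self) -> dict[str, set[str]]:
        sets: dict[str, set[str]] = {c: set() for c in self.conditions}
        for g in self.genes:
            for s in g.as_samples:
                sets[s].add(g.gene_id)
        return sets

    def to_json(self) -> str:
        def default(o):
            if dataclasses.is_dataclass(o):
                return dataclasses.asdict(o)
            if isinstance(o, (set, tuple)):
                return list(o)
            raise TypeError(type(o))
        return json.dumps(dataclasses.asdict(self), default=default,
                          indent=1, sort_keys=True)


# ---------------------------------------------------------------------------
# structural event planting (pure coordinate transforms)
# ---------------------------------------------------------------------------

class InfeasibleEventError(ValueError):
    """The reference has too few exons (or too little room) for the event."""


_MIN_EXONS = {
    "IR": 2, "ES": 3, "A3SS": 2, "A5SS": 2, "MXE": 4,
    "IR1+IR2": 3, "A5SS_or_A3SS": 2, "IR1_or_IR2": 2,
    "A5SS+A3SS": 2, "ES1+ES2": 4, "A5SS+ES+A3SS": 3,
}


def _delta(rng: np.random.Generator, lo: int = 3, hi: int = 12) -> int:
    return int(rng.integers(lo, hi + 1))


def plant_event(reference: TranscriptModel, event_type: str,
                rng: np.random.Generator,
                isoform_id: Optional[str] = None,
                deltas: Optional[dict] = None) -> TranscriptModel:
    """Construct an isoform whose detected event against ``reference`` is
    exactly ``event_type`` (a pure coordinate transform; sequence context is
    the simulator's concern).

    ``deltas`` may pin the internal random choices (``j`` the intron/exon
    index and the site-shift offsets ``d1``/``d2``), which the simulator uses
    to coordinate sequence planting.
    """
    if event_type not in TYPE_TO_CODE:
        raise InfeasibleEventError(f"unknown event type {event_type!r}")
    exons = list(reference.exons)
    k = len(exons)
    if k < _MIN_EXONS[event_type]:
        raise InfeasibleEventError(
            f"{event_type} needs >= {_MIN_EXONS[event_type]} exons, "
            f"reference has {k}"
        )
    d = dict(deltas or {})
    introns = reference.introns()

    def pick(lo: int, hi: int) -> int:
        return d.get("j", int(rng.integers(lo, hi + 1)))

    def shift_donor(j: int, d1: int) -> list[tuple[int, int]]:
        # the donor-side exon is exon j on '+', exon j+1 on '-'
        if reference.strand == "+":
            s, e = exons[j]
            return exons[:j] + [(s, e + d1)] + exons[j + 1:]
        s, e = exons[j + 1]
        return exons[:j + 1] + [(s - d1, e)] + exons[j + 2:]

    def shift_acceptor(j: int, d1: int) -> list[tuple[int, int]]:
        if reference.strand == "+":
            s, e = exons[j + 1]
            return exons[:j + 1] + [(s - d1, e)] + exons[j + 2:]
        s, e = exons[j]
        return exons[:j] + [(s, e + d1)] + exons[j + 1:]

    if event_type == "IR":
        j = pick(0, k - 2)
        new = exons[:j] + [(exons[j][0], exons[j + 1][1])] + exons[j + 2:]
    elif event_type == "IR1+IR2":
        j = pick(0, k - 3)
        new = exons[:j] + [(exons[j][0], exons[j + 2][1])] + exons[j + 3:]
    elif event_type == "ES":
        j = pick(1, k - 2)
        new = exons[:j] + exons[j + 1:]
    elif event_type == "ES1+ES2":
        j = pick(1, k - 3)
        new = exons[:j] + exons[j + 2:]
    elif event_type == "A5SS":
        j = pick(0, k - 2)
        d1 = d.get("d1", _delta(rng, 1, max(1, min(12, introns[j][1] - introns[j][0] - 2))))
        new = shift_donor(j, d1)
    elif event_type == "A3SS":
        j = pick(0, k - 2)
        d1 = d.get("d1", _delta(rng, 1, max(1, min(12, introns[j][1] - introns[j][0] - 2))))
        new = shift_acceptor(j, d1)
    elif event_type == "A5SS+A3SS":
        j = pick(0, k - 2)
        ilen = introns[j][1] - introns[j][0]
        d1 = d.get("d1", _delta(rng, 1, max(1, min(6, ilen // 4))))
        d2 = d.get("d2", _delta(rng, 1, max(1, min(6, ilen // 4))))
        s1, e1 = exons[j]
        s2, e2 = exons[j + 1]
        new = exons[:j] + [(s1, e1 + d1), (s2 - d2, e2)] + exons[j + 2:]
    elif event_type == "A5SS_or_A3SS":
        j = pick(0, k - 2)
        ilen = introns[j][1] - introns[j][0]
        d1 = d.get("d1", _delta(rng, 1, max(1, min(6, ilen // 4))))
        s2, e2 = exons[j + 1]
        d2 = d.get("d2", _delta(rng, 1, max(1, min(6, (e2 - s2) // 4))))
        s1, e1 = exons[j]
        new = exons[:j] + [(s1, e1 + d1), (s2 + d2, e2)] + exons[j + 2:]
    elif event_type == "IR1_or_IR2":
        j = pick(0, k - 2)
        s2, e2 = exons[j + 1]
        width = e2 - s2
        if width < 8:
            raise InfeasibleEventError("exon too short for a latent intron")
        x = d.get("d1", int(rng.integers(2, width // 2)))
        y = d.get("d2", int(rng.integers(width // 2 + 1, width - 1)))
        new = exons[:j] + [(exons[j][0], s2 + x), (s2 + y, e2)] + exons[j + 2:]
    elif event_type == "MXE":
        j = pick(1, k - 2)          # exon to swap out
        gs, ge = introns[j - 1]     # host intron for the novel exon
        ilen = ge - gs
        if ilen < 12:
            raise InfeasibleEventError("host intron too short for a novel exon")
        x = d.get("d1", int(rng.integers(2, max(3, ilen // 3))))
        y = d.get("d2", int(rng.integers(x + 4, ilen - 1)))
        if not (0 < x < y < ilen):
            raise InfeasibleEventError("novel exon does not fit the intron")
        new = exons[:j] + [(gs + x, gs + y)] + exons[j + 1:]
    elif event_type == "A5SS+ES+A3SS":
        j = pick(1, k - 2)
        s0, e0 = exons[j - 1]
        s2, e2 = exons[j + 1]
        d1 = d.get("d1", _delta(rng, 1, max(1, min(6, (e0 - s0) // 4))))
        d2 = d.get("d2", _delta(rng, 1, max(1, min(6, (e2 - s2) // 4))))
        new = exons[:j - 1] + [(s0, e0 - d1), (s2 + d2, e2)] + exons[j + 2:]
    else:  # pragma: no cover
        raise InfeasibleEventError(event_type)

    return TranscriptModel(
        transcript_id=isoform_id or reference.transcript_id + ".as",
        gene_id=reference.gene_id, contig=reference.contig,
        strand=reference.strand, exons=new, class_code="j",
    )


# ---------------------------------------------------------------------------
# sequence-level gene construction (transcription space)
# ---------------------------------------------------------------------------

@dataclass
class _IntronPlan:
    start: int                 # t-space
    end: int
    dinuc_class: str
    donor: str
    acceptor: str
    branch_idx: int            # t-space position of the branch A
    offset3: int
    ppt: tuple[int, int]       # t-space interval


class _SeqBuilder:
    """Mutable transcription-space sequence with planted-feature maps."""

    def __init__(self, length: int, rng: np.random.Generator):
        self.seq = list(rng.choice(list("ACGT"), size=length))
        self.protected: set[int] = set()
        self.no_cds: set[int] = set()           # intron interiors: codon
        self.donor_at: dict[int, str] = {}      # writing must not touch them
        self.acceptor_at: dict[int, tuple[str, Optional[int]]] = {}
        self.rng = rng

    def write(self, pos: int, text: str, protect: bool = True) -> None:
        for i, ch in enumerate(text):
            self.seq[pos + i] = ch
            if protect:
                self.protected.add(pos + i)

    def text(self) -> str:
        return "".join(self.seq)


def _draw_dinuc_class(rng: np.random.Generator, mix: dict) -> str:
    classes = sorted(mix)
    probs = np.array([mix[c] for c in classes])
    return str(rng.choice(classes, p=probs / probs.sum()))


def _class_dinucs(rng: np.random.Generator, cls: str) -> tuple[str, str]:
    if cls in _DONOR:
        return _DONOR[cls], _ACCEPTOR[cls]
    return (str(rng.choice(_OTHER_DONORS)), str(rng.choice(_OTHER_ACCEPTORS)))


def _draw_offset(rng: np.random.Generator, cfg: SimulationConfig,
                 length: int, min_offset: int = 16) -> int:
    """Branch offset: normal truncated symmetrically around the mean,
    re-drawn until it fits this intron's searchable window."""
    lo = max(min_offset, cfg.branch_offset_mean - cfg.branch_offset_halfwidth)
    hi = min(cfg.branch_offset_mean + cfg.branch_offset_halfwidth, length - 17)
    if hi < lo:
        raise _RetryGene("intron too short for a branch window")
    for _ in range(200):
        o = cfg.branch_offset_mean + cfg.branch_offset_sd * rng.standard_normal()
        if abs(o - cfg.branch_offset_mean) <= cfg.branch_offset_halfwidth:
            o_int = int(round(o))
            if lo <= o_int <= hi:
                return o_int
    return int((lo + hi) // 2)


def _plant_intron(b: _SeqBuilder, start: int, end: int,
                  cfg: SimulationConfig, rng: np.random.Generator,
                  dinuc_class: Optional[str] = None,
                  offset3: Optional[int] = None) -> _IntronPlan:
    """Fill one intron segment: planted dinucleotides, A-free body, CTAAC
    branch, G-gap, polypyrimidine tract, acceptor dinucleotide."""
    length = end - start
    cls = dinuc_class or _draw_dinuc_class(rng, cfg.dinucleotide_mix)
    don, acc = _class_dinucs(rng, cls)
    if offset3 is None:
        offset3 = _draw_offset(rng, cfg, length)
    branch_idx = end - 1 - offset3
    if branch_idx - 3 < start + 2:
        raise _RetryGene("branch overlaps the donor context")
    # A-free interior
    body = rng.choice(list("CGT"), size=length - 4)
    b.write(start + 2, "".join(body), protect=False)
    b.write(start, don)
    b.write(end - 2, acc)
    b.write(branch_idx - 3, "CTAAC")
    # PPT immediately upstream of the acceptor; G-gap in between
    space = (end - 2) - (branch_idx + 2)
    plen = int(rng.integers(cfg.ppt_length[0],
                            min(cfg.ppt_length[1], max(cfg.ppt_length[0], space)) + 1))
    plen = min(plen, space)
    ppt_start = end - 2 - plen
    gap = "G" * (ppt_start - (branch_idx + 2))
    b.write(branch_idx + 2, gap, protect=False)
    ppt = "".join(rng.choice(list("TC"), size=plen, p=[0.75, 0.25]))
    b.write(ppt_start, ppt, protect=False)
    b.donor_at[start] = don
    b.acceptor_at[end] = (acc, branch_idx)
    b.no_cds.update(range(start, end))
    return _IntronPlan(start, end, cls, don, acc, branch_idx, offset3,
                       (ppt_start, ppt_start + plen))


def _scan_first_stop(cdna: str, start: int) -> Optional[int]:
    for i in range(start, len(cdna) - 2, 3):
        if cdna[i:i + 3] in STOPS:
            return i
    return None


def _extract(b: _SeqBuilder, exons: Sequence[tuple[int, int]]) -> str:
    return "".join(b.text()[s:e] for s, e in exons)


def _tpos_to_t(exons: Sequence[tuple[int, int]], tpos: int) -> int:
    """Transcript coordinate -> t-space coordinate (plus-orientation)."""
    off = tpos
    for s, e in exons:
        if off < e - s:
            return s + off
        off -= e - s
    raise IndexError(tpos)


class _GeneResult:
    def __init__(self, gene_id, tlen, builder, ref_exons, iso_exons,
                 event_type, intron_plans, ptc_planted, cds_t):
        self.gene_id = gene_id
        self.tlen = tlen
        self.builder = builder
        self.ref_exons = ref_exons
        self.iso_exons = iso_exons
        self.event_type = event_type
        self.intron_plans = intron_plans
        self.ptc_planted = ptc_planted
        self.cds_t = cds_t  # (start, end) t-space CDS span


def _build_gene(gene_id: str, cfg: SimulationConfig,
                rng: np.random.Generator,
                event_type: Optional[str]) -> _GeneResult:
    """One attempt at constructing a gene around its planted event."""
    k_lo, k_hi = cfg.exons_per_gene
    k = int(rng.integers(max(k_lo, _MIN_EXONS.get(event_type, 2)
                             if event_type else k_lo),
                         k_hi + 1))
    k = max(k, _MIN_EXONS.get(event_type, 2) if event_type else 2)
    exon_lens = [int(rng.integers(cfg.exon_length[0], cfg.exon_length[1] + 1))
                 for _ in range(k)]
    intron_lens = []
    for _ in range(k - 1):
        L = int(round(float(rng.lognormal(cfg.intron_log_mean, cfg.intron_log_sd))))
        L = max(L, cfg.intron_floor)
        L += (3 - L % 3) % 3     # multiples of 3: frame-neutral when retained
        intron_lens.append(L)

    # MXE needs a host structure E1 I1 B I2 C I3 D: realized as k=4 exons
    # where the reference skips exon 2 (C) and the isoform skips exon 1 (B).
    exons_t: list[tuple[int, int]] = []
    pos = 0
    bounds = []
    for i, el in enumerate(exon_lens):
        exons_t.append((pos, pos + el))
        pos += el
        if i < k - 1:
            bounds.append((pos, pos + intron_lens[i]))
            pos += intron_lens[i]
    tlen = pos

    b = _SeqBuilder(tlen, rng)
    plans = [_plant_intron(b, s, e, cfg, rng) for s, e in bounds]

    iso_exons: Optional[list[tuple[int, int]]] = None
    ref_exons = list(exons_t)
    ptc_planted: Optional[bool] = None
    extra_acc_reuse: dict[int, int] = {}   # novel acceptor t-pos -> branch idx

    if event_type is not None:
        j_opts = {
            "IR": (0, k - 2), "IR1+IR2": (0, k - 3), "ES": (1, k - 2),
            "ES1+ES2": (1, k - 3), "A5SS": (0, k - 2), "A3SS": (0, k - 2),
            "A5SS+A3SS": (0, k - 2), "A5SS_or_A3SS": (0, k - 2),
            "IR1_or_IR2": (0, k - 2), "MXE": (1, k - 2),
            "A5SS+ES+A3SS": (1, k - 2),
        }[event_type]
        j = int(rng.integers(j_opts[0], j_opts[1] + 1))

        if event_type == "MXE":
            # reference skips exon j, isoform skips exon j-1 (resp. j+? );
            # realized below by rebuilding ref_exons
            if k < 4 or not (1 <= j <= k - 2):
                raise _RetryGene("MXE needs two internal swap exons")
            # use exons j and j+1 as the mutually exclusive pair
            if j > k - 3:
                j = k - 3
            ref_exons = exons_t[:j + 1] + exons_t[j + 2:]       # keeps B=j
            iso_exons = exons_t[:j] + exons_t[j + 1:]           # keeps C=j+1
            ptc_planted = None
        elif event_type == "IR1_or_IR2":
            if j > k - 2:
                j = k - 2
            # reference retains intron j+1 if it exists, else a latent one;
            # simplest: reference retains nothing extra -> use two real
            # introns: ref = [.., Ej, E(j+1)+I(j+1)+E(j+2), ..] needs j+2
            if j > k - 3 or k < 3:
                # fall back to first feasible position
                if k < 3:
                    raise _RetryGene("IR1_or_IR2 needs 3 exon segments")
                j = 0
            ref_exons = (exons_t[:j + 1]
                         + [(exons_t[j + 1][0], exons_t[j + 2][1])]
                         + exons_t[j + 3:])
            iso_exons = (exons_t[:j]
                         + [(exons_t[j][0], exons_t[j + 1][1])]
                         + exons_t[j + 2:])
        else:
            ref_t = TranscriptModel(
                transcript_id="t", gene_id=gene_id, contig="t", strand="+",
                exons=ref_exons,
            )
            deltas: dict = {"j": j}
            plan = plans[min(j, len(plans) - 1)] if plans else None
            if event_type in ("A5SS", "A5SS+A3SS", "A5SS_or_A3SS"):
                # donor shift into the intron: keep clear of the branch motif
                assert plan is not None
                room = (plan.branch_idx - 3) - (plan.start + 2) - 2
                deltas["d1"] = _delta(rng, 3, max(3, min(12, room)))
            if event_type == "A3SS" or event_type == "A5SS+A3SS":
                room = plan.offset3 - 16
                if room < 3:
                    raise _RetryGene("branch too close to 3'ss for A3SS shift")
                key = "d1" if event_type == "A3SS" else "d2"
                deltas[key] = _delta(rng, 3, min(12, room))
            if event_type in ("A5SS_or_A3SS", "A5SS+ES+A3SS"):
                deltas["d2"] = _delta(rng, 3, 12)
            if event_type == "A5SS+ES+A3SS":
                deltas["d1"] = _delta(rng, 3, 12)
            iso = plant_event(ref_t, event_type, rng, deltas=deltas)
            iso_exons = list(iso.exons)

        # plant sequence context at novel splice sites
        if iso_exons is not None and event_type not in ("MXE", "IR1_or_IR2"):
            ref_set = set()
            for (s1, e1), (s2, e2) in zip(ref_exons, ref_exons[1:]):
                ref_set.add(("D", e1))
                ref_set.add(("A", s2))
            for (s1, e1), (s2, e2) in zip(iso_exons, iso_exons[1:]):
                if ("D", e1) not in ref_set and e1 not in b.donor_at:
                    host = next((p for p in plans if p.start <= e1 < p.end), None)
                    cls = host.dinuc_class if host else _draw_dinuc_class(
                        rng, cfg.dinucleotide_mix)
                    don, _ = _class_dinucs(rng, cls)
                    b.write(e1, don)
                    b.donor_at[e1] = don
                if ("A", s2) not in ref_set and s2 not in b.acceptor_at:
                    # novel acceptor: AG planted just upstream; the branch of
                    # the enclosing/nearest planted acceptor is reused
                    host = next((p for p in plans if p.start < s2 <= p.end), None)
                    if host is not None:
                        cls_acc = host.acceptor if host else "AG"
                        branch = host.branch_idx
                        if s2 - 2 <= branch + 1:
                            raise _RetryGene("novel acceptor clashes with branch")
                    else:
                        # acceptor shifted into an exon: reuse the upstream
                        # planted acceptor's branch
                        upstream = [p for p in plans if p.end <= s2]
                        if not upstream:
                            raise _RetryGene("no upstream branch for novel acceptor")
                        cls_acc = upstream[-1].acceptor
                        branch = upstream[-1].branch_idx
                    b.write(s2 - 2, cls_acc)
                    b.acceptor_at[s2] = (cls_acc, branch)
                    extra_acc_reuse[s2] = branch

    # ------------------------------------------------------------------ CDS
    ref_len = sum(e - s for s, e in ref_exons)
    utr5 = int(rng.integers(24, 61))
    utr3 = int(rng.integers(24, 61))
    cds_len = ref_len - utr5 - utr3
    cds_len -= cds_len % 3
    if cds_len < 60:
        raise _RetryGene("transcript too short for a CDS")
    tpositions = [_tpos_to_t(ref_exons, utr5 + i) for i in range(cds_len)]
    blocked = b.protected | b.no_cds
    if any(p in blocked for p in tpositions[:3]) or \
       any(p in blocked for p in tpositions[-3:]):
        raise _RetryGene("CDS start/stop collides with a planted motif")
    # start codon, body of non-stop codons, final stop
    b.write(tpositions[0], "A")
    b.write(tpositions[1], "T")
    b.write(tpositions[2], "G")
    for c in range(1, cds_len // 3 - 1):
        codon = _NONSTOP_CODONS[int(rng.integers(len(_NONSTOP_CODONS)))]
        for i in range(3):
            p = tpositions[3 * c + i]
            if p not in blocked:
                b.seq[p] = codon[i]
    for i, ch in enumerate("TAA"):
        b.write(tpositions[cds_len - 3 + i], ch)

    def repair(exons: Sequence[tuple[int, int]], start_t: int,
               stop_before: int) -> None:
        """Mutate unprotected bases to C until no in-frame stop precedes
        ``stop_before`` (a transcript coordinate) in this isoform."""
        for _ in range(200):
            cdna = _extract(b, exons)
            s = _scan_first_stop(cdna, start_t)
            if s is None or s >= stop_before:
                return
            for i in range(3):
                p = _tpos_to_t(exons, s + i)
                if p not in b.protected:
                    b.seq[p] = "C"
                    break
            else:
                raise _RetryGene("premature stop made entirely of motif bases")
        raise _RetryGene("stop repair did not converge")

    repair(ref_exons, utr5, utr5 + cds_len - 3)
    ref_cdna = _extract(b, ref_exons)
    assert _scan_first_stop(ref_cdna, utr5) == utr5 + cds_len - 3

    # ---------------------------------------------------- PTC control (IR)
    if event_type in ("IR", "IR1+IR2") and iso_exons is not None:
        start_gt = _tpos_to_t(ref_exons, utr5)
        iso_t = TranscriptModel("i", gene_id, "t", "+", list(iso_exons))
        iso_start = iso_t.genomic_to_transcript(start_gt)
        if iso_start is None:
            raise _RetryGene("start codon not exonic in IR isoform")
        ref_stop_t = tpositions[cds_len - 3]
        iso_stop_tpos = iso_t.genomic_to_transcript(ref_stop_t)
        ptc_planted = bool(rng.random() < cfg.ptc_fraction)
        retained = [p for p in plans
                    if any(s <= p.start and p.end <= e for s, e in iso_exons)]
        if not retained:
            raise _RetryGene("no retained intron found")
        target = retained[0]
        if ptc_planted:
            # in-frame TAA early in the retained intron, upstream of the
            # CTAAC motif and farther from the 3'ss than the branch A
            iso_intron_start = iso_t.genomic_to_transcript(target.start)
            assert iso_intron_start is not None
            frame = (iso_intron_start - iso_start) % 3
            p0 = target.start + ((3 - frame) % 3)
            # keep within the donor-side body
            limit = min(target.branch_idx - 24, target.start + 60)
            placed = False
            for p in range(p0 + 3, limit, 3):
                if all(q not in b.protected for q in (p, p + 1, p + 2)):
                    b.write(p, "TAA")
                    placed = True
                    break
            if not placed:
                raise _RetryGene("no room for a planted in-frame stop")
            stop_t = iso_t.genomic_to_transcript(p)
            assert stop_t is not None
            repair(iso_exons, iso_start, stop_t)
            iso_cdna = _extract(b, iso_exons)
            if _scan_first_stop(iso_cdna, iso_start) != stop_t:
                raise _RetryGene("planted PTC not the first stop")
        else:
            if iso_stop_tpos is None:
                raise _RetryGene("reference stop not exonic in IR isoform")
            repair(iso_exons, iso_start, iso_stop_tpos)
            iso_cdna = _extract(b, iso_exons)
            if _scan_first_stop(iso_cdna, iso_start) != iso_stop_tpos:
                raise _RetryGene("in-frame motif stop in retained intron")
    elif event_type is not None:
        ptc_planted = None

    cds_t_span = (min(tpositions[0], tpositions[-1]),
                  max(tpositions[0], tpositions[-1]) + 1)
    return _GeneResult(gene_id, tlen, b, ref_exons, iso_exons, event_type,
                       plans, ptc_planted, cds_t_span)


# ---------------------------------------------------------------------------
# genome assembly and simulation entry point
# ---------------------------------------------------------------------------

def _map_interval(iv: tuple[int, int], strand: str, tlen: int,
                  offset: int) -> tuple[int, int]:
    s, e = iv
    if strand == "+":
        return (offset + s, offset + e)
    return (offset + tlen - e, offset + tlen - s)


def _map_pos(p: int, strand: str, tlen: int, offset: int) -> int:
    """Map a t-space base index to its genomic base index."""
    return offset + p if strand == "+" else offset + tlen - 1 - p


@dataclass
class SimulatedBundle:
    """Everything one simulation run emits, plus its ground truth."""

    genome: GenomeSequence
    reference: list[GeneModel]
    assembled: dict[str, list[GeneModel]]     # condition -> gene models
    expression: ExpressionMatrix
    metabolites: MetaboliteMatrix
    truth: GroundTruth
    config: SimulationConfig

    def write(self, outdir) -> dict[str, Path]:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {"genome": out / "genome.fa",
                 "reference": out / "reference.gtf",
                 "expression": out / "expression.tsv",
                 "metabolites": out / "metabolites.tsv",
                 "truth": out / "ground_truth.json"}
        write_genome(self.genome, paths["genome"])
        write_gtf(self.reference, paths["reference"])
        for cond, genes in self.assembled.items():
            p = out / f"assembled_{cond}.gtf"
            write_gtf(genes, p)
            paths[f"assembled_{cond}"] = p
        self.expression.values.round(3).to_csv(paths["expression"], sep="\t")
        self.metabolites.values.round(3).to_csv(paths["metabolites"], sep="\t")
        paths["truth"].write_text(self.truth.to_json())
        return paths


def _gene_models(res: _GeneResult, strand: str, contig: str, offset: int
                 ) -> tuple[GeneModel, Optional[TranscriptModel], list[PlantedJunction]]:
    """Map a t-space gene build onto the genome; return the reference gene
    model, the AS isoform (if any) and the planted junction records."""
    tlen = res.tlen
    gid = res.gene_id

    def conv_exons(exons):
        mapped = [_map_interval(iv, strand, tlen, offset) for iv in exons]
        return sorted(mapped)

    cds = _map_interval(res.cds_t, strand, tlen, offset)
    ref = TranscriptModel(f"{gid}.1", gid, contig, strand,
                          conv_exons(res.ref_exons), cds=cds)
    iso = None
    if res.iso_exons is not None:
        iso = TranscriptModel(f"{gid}.2", gid, contig, strand,
                              conv_exons(res.iso_exons), class_code="j")

    b = res.builder
    juncs: dict[tuple, PlantedJunction] = {}
    chains = [res.ref_exons] + ([res.iso_exons] if res.iso_exons else [])
    plan_by_end = {p.end: p for p in res.intron_plans}
    for chain in chains:
        for (s1, e1), (s2, e2) in zip(chain, chain[1:]):
            ts, te = e1, s2
            don = b.donor_at.get(ts)
            acc = b.acceptor_at.get(te)
            assert don is not None and acc is not None, (gid, ts, te)
            acc_dinuc, branch_t = acc
            gstart, gend = _map_interval((ts, te), strand, tlen, offset)
            branch_g = (_map_pos(branch_t, strand, tlen, offset)
                        if branch_t is not None else None)
            plan = plan_by_end.get(te)
            ppt = None
            if plan is not None and plan.start == ts:
                ppt = tuple(sorted(
                    _map_interval(plan.ppt, strand, tlen, offset)))
            key = (gstart, gend, strand)
            if key not in juncs:
                juncs[key] = PlantedJunction(
                    contig=contig, strand=strand, start=gstart, end=gend,
                    dinucleotide_pair=f"{don}-{acc_dinuc}",
                    branch_a_position=branch_g,
                    bp_offset_3ss=(te - 1 - branch_t
                                   if branch_t is not None else None),
                    ppt_interval=ppt,
                )
    transcripts = [ref] + ([iso] if iso else [])
    gene = GeneModel(gid, contig, strand, transcripts, {ref.transcript_id})
    return gene, iso, sorted(juncs.values(), key=lambda j: (j.start, j.end))


def plant_expression(planted: Sequence[PlantedGene],
                     transcripts: Sequence[str],
                     gene_of: dict[str, str],
                     cfg: SimulationConfig,
                     rng: np.random.Generator) -> pd.DataFrame:
    """TPM-scale transcripts x samples matrix with planted fold changes.

    Per-transcript base abundance is log-normal; a DE gene's planted log2
    fold change shifts all its transcripts in the affected conditions;
    replicate noise is multiplicative log-normal; columns are normalized to
    sum to 1e6.
    """
    lfc_of = {g.gene_id: g.de_log2fc for g in planted}
    base = cfg.base_log2_expr + cfg.base_log2_expr_sd * rng.standard_normal(
        len(transcripts))
    cols = {}
    for cond in cfg.conditions:
        shift = np.array([
            lfc_of.get(gene_of[t], {}).get(cond, 0.0) for t in transcripts
        ])
        for rep in range(1, cfg.replicates + 1):
            noise = cfg.expr_noise_sd * rng.standard_normal(len(transcripts))
            vals = np.power(2.0, base + shift + noise)
            cols[f"{cond}_{rep}"] = vals
    df = pd.DataFrame(cols, index=pd.Index(transcripts, name="transcript_id"))
    df = df / df.sum(axis=0) * 1e6
    return df


def _orthonormal_pair(x: np.ndarray, rng: np.random.Generator
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Centered unit-norm version of x and a centered unit vector orthogonal
    to it (within the mean-zero subspace)."""
    xc = x - x.mean()
    nx = np.linalg.norm(xc)
    if nx == 0:
        raise ValueError("flat profile cannot carry a planted correlation")
    xc = xc / nx
    for _ in range(100):
        e = rng.standard_normal(len(x))
        e = e - e.mean()
        e = e - (e @ xc) * xc
        ne = np.linalg.norm(e)
        if ne > 1e-9:
            return xc, e / ne
    raise RuntimeError("could not draw an orthogonal direction")


def plant_metabolites(expression: pd.DataFrame,
                      planted: Sequence[PlantedGene],
                      cfg: SimulationConfig,
                      rng: np.random.Generator
                      ) -> tuple[pd.DataFrame, list[PlantedMetabolite]]:
    """Metabolite table whose condition-mean correlation with its probe
    transcript is planted exactly (then blurred only by replicate noise)."""
    conds = list(cfg.metabolite_conditions)
    sample_cond = {c: [f"{c}_{r}" for r in range(1, cfg.replicates + 1)]
                   for c in cfg.conditions}
    # measured condition-mean profiles of candidate probe transcripts
    profiles = {}
    for tid in expression.index:
        prof = np.array([
            expression.loc[tid, sample_cond[c]].mean() for c in conds
        ])
        if np.ptp(prof) > 0:
            profiles[tid] = prof
    # probes: prefer AS isoforms of DE genes (their profiles actually move)
    de_iso = [g.isoform_id for g in planted
              if g.isoform_id and g.de_log2fc and g.isoform_id in profiles]
    others = [t for t in profiles if t not in set(de_iso)]
    pool = de_iso + others

    n_linked = int(round(cfg.n_metabolites * cfg.metabolite_link_fraction))
    rows = {}
    truth: list[PlantedMetabolite] = []
    for i in range(cfg.n_metabolites):
        mid = f"M{i + 1:03d}"
        probe = pool[i % len(pool)]
        x = profiles[probe]
        xc, e_perp = _orthonormal_pair(x, rng)
        linked = i < n_linked
        sign = 1 if rng.random() < 0.5 else -1
        rho = sign * cfg.metabolite_target_r if linked else 0.0
        z = rho * xc + math.sqrt(max(0.0, 1 - rho * rho)) * e_perp
        z = z / max(np.abs(z).max(), 1e-9)          # bounded in [-1, 1]
        mu = float(np.power(2.0, 8 + 2 * rng.standard_normal()))
        means = mu * (1 + 0.4 * z)
        reps = {}
        for c, m in zip(conds, means):
            for r in range(1, cfg.metabolite_replicates + 1):
                noise = np.power(2.0, cfg.metabolite_noise_sd
                                 * rng.standard_normal())
                reps[f"{c}_{r}"] = m * noise
        rows[mid] = reps
        truth.append(PlantedMetabolite(
            metabolite_id=mid,
            linked_transcript=probe if linked else None,
            probe_transcript=probe,
            target_r=rho, sign=sign if linked else 0,
        ))
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "metabolite_id"
    df = df[[f"{c}_{r}" for c in conds
             for r in range(1, cfg.metabolite_replicates + 1)]]
    return df, truth


def simulate(config: SimulationConfig) -> SimulatedBundle:
    """Generate the full synthetic bundle for one seeded configuration."""
    cfg = config
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    event_names = sorted(cfg.event_mix)
    event_probs = np.array([cfg.event_mix[e] for e in event_names])
    event_probs = event_probs / event_probs.sum()

    contig_seqs: dict[str, list[str]] = {
        f"chr{i + 1}": [] for i in range(cfg.n_contigs)}
    contig_len: dict[str, int] = {c: 0 for c in contig_seqs}

    reference: list[GeneModel] = []
    planted_genes: list[PlantedGene] = []
    isoforms: dict[str, TranscriptModel] = {}

    for i in range(cfg.n_genes):
        gid = f"G{i + 1:04d}"
        etype = (str(rng.choice(event_names, p=event_probs))
                 if rng.random() < cfg.as_fraction else None)
        strand = "+" if rng.random() < cfg.strand_fraction else "-"
        res = None
        for _attempt in range(60):
            try:
                res = _build_gene(gid, cfg, rng, etype)
                break
            except _RetryGene:
                continue
        if res is None:
            raise ConfigError(
                f"gene construction infeasible for event {etype!r} under "
                "the current configuration"
            )
        contig = f"chr{(i % cfg.n_contigs) + 1}"
        spacer = "".join(rng.choice(list("ACGT"), size=cfg.intergenic))
        contig_seqs[contig].append(spacer)
        contig_len[contig] += len(spacer)
        offset = contig_len[contig]
        tseq = res.builder.text()
        gseq = tseq if strand == "+" else revcomp(tseq)
        contig_seqs[contig].append(gseq)
        contig_len[contig] += len(gseq)

        gene, iso, juncs = _gene_models(res, strand, contig, offset)
        reference.append(GeneModel(
            gid, contig, strand, [gene.get(f"{gid}.1")], {f"{gid}.1"}))
        if iso is not None:
            isoforms[gid] = iso

        # planted AS presence across conditions
        if iso is not None:
            if rng.random() < cfg.conserved_as_fraction:
                samples = tuple(cfg.conditions)
            else:
                mask = rng.random(len(cfg.conditions)) < cfg.as_presence_p
                if not mask.any():
                    mask[int(rng.integers(len(cfg.conditions)))] = True
                samples = tuple(c for c, m in zip(cfg.conditions, mask) if m)
        else:
            samples = ()

        de_log2fc: dict[str, float] = {}
        if rng.random() < cfg.de_fraction:
            sgn = 1.0 if rng.random() < 0.5 else -1.0
            de_log2fc = {c: sgn * cfg.log2fc for c in cfg.conditions[1:]}

        planted_genes.append(PlantedGene(
            gene_id=gid, contig=contig, strand=strand,
            event_type=etype, code=TYPE_TO_CODE.get(etype) if etype else None,
            reference_id=f"{gid}.1",
            isoform_id=iso.transcript_id if iso else None,
            ptc_planted=res.ptc_planted,
            as_samples=samples, de_log2fc=de_log2fc, junctions=juncs,
        ))

    for contig in contig_seqs:   # trailing spacer keeps motif windows inside
        tail = "".join(rng.choice(list("ACGT"), size=cfg.intergenic))
        contig_seqs[contig].append(tail)
    genome = GenomeSequence({c: "".join(parts)
                             for c, parts in contig_seqs.items()})

    # per-condition assembled annotations
    assembled: dict[str, list[GeneModel]] = {}
    for cond in cfg.conditions:
        genes_c: list[GeneModel] = []
        for g, pg in zip(reference, planted_genes):
            ref_t = dataclasses.replace(g.transcripts[0], class_code="=",
                                        cds=None)
            ts = [ref_t]
            if pg.isoform_id and cond in pg.as_samples:
                ts.append(dataclasses.replace(isoforms[pg.gene_id]))
            genes_c.append(GeneModel(g.gene_id, g.contig, g.strand, ts))
        assembled[cond] = genes_c

    transcripts = [t.transcript_id for g in reference for t in g.transcripts]
    transcripts += [iso.transcript_id for iso in isoforms.values()]
    transcripts = sorted(transcripts)
    gene_of = {t: t.rsplit(".", 1)[0] for t in transcripts}
    expr_df = plant_expression(planted_genes, transcripts, gene_of, cfg, rng)
    expr = ExpressionMatrix(
        expr_df, {c: c.rsplit("_", 1)[0] for c in expr_df.columns}, gene_of)

    metab_df, metab_truth = plant_metabolites(expr_df, planted_genes, cfg, rng)
    metab = MetaboliteMatrix(
        metab_df, {c: c.rsplit("_", 1)[0] for c in metab_df.columns})

    truth = GroundTruth(planted_genes, metab_truth, tuple(cfg.conditions))
    return SimulatedBundle(genome, reference, assembled, expr, metab, truth,
                           cfg)
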