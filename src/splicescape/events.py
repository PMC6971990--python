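"""Alternative-splicing event detection and splice-chain code nomenclature.

Events are detected pairwise between isoforms of a gene, rendered as
splice-chain code strings and classified into eleven named structures (plus a
``complex`` bucket).  A code string lists each variant's internal splice
sites, numbered 1..n in transcription order across both variants, a donor
suffixed ``^`` and an acceptor ``-``; a variant with no internal site renders
as ``0``.  Example: intron retention is ``1^2-,0``.

The two variants of an event are the maximal run of splice sites not shared
between the two chains, flanked on both sides by a shared site or by a
position where both isoforms are exonic at the boundary of their genomic
overlap.  Terminal variation (alternative transcription start/end) is not an
event: no code in the table describes it.
"""

from __future__ import annotations

import collections
import itertools
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .models import GeneModel, ModelError, TranscriptModel

#: code string -> event type label (codes in ASCII, transcription order)
CODE_TABLE: dict[str, str] = {
    "1^2-,0": "IR",
    "1-2^,0": "ES",
    "1-,2-": "A3SS",
    "1^,2^": "A5SS",
    "1^2-3^4-,0": "IR1+IR2",
    "1^3-,2^4-": "A5SS_or_A3SS",
    "1^2-,3^4-": "IR1_or_IR2",
    "1^4-,2^3-": "A5SS+A3SS",
    "1-2^3-4^,0": "ES1+ES2",
    "1-2^,3-4^": "MXE",
    "1^6-,2^3-4^5-": "A5SS+ES+A3SS",
}

EVENT_TYPES: tuple[str, ...] = tuple(CODE_TABLE.values()) + ("complex",)

DONOR = "donor"
ACCEPTOR = "acceptor"
_KIND_SUFFIX = {DONOR: "^", ACCEPTOR: "-"}


@dataclass(frozen=True)
class SpliceSite:
    """An internal splice boundary: position is the genomic boundary
    coordinate (half-open space); a donor sits at the exon's 3' end in
    transcription direction, an acceptor at the next exon's 5' end."""

    position: int
    kind: str
    strand: str

    def tx_key(self) -> int:
        """Sort key in transcription direction."""
        return self.position if self.strand == "+" else -self.position


@dataclass(frozen=True)
class ASEvent:
    """A detected alternative-splicing event between two variants."""

    gene_id: str
    anchor_left: Optional[int]   # genomic coord of 5' (transcription) anchor
    anchor_right: Optional[int]  # genomic coord of 3' anchor
    variants: tuple[tuple[SpliceSite, ...], tuple[SpliceSite, ...]]
    code: str
    event_type: str
    witnesses: tuple[str, str]

    def identity(self) -> tuple:
        """Structural identity for deduplication (anchors that are shared
        splice sites plus the two variant site-chains; exonic-boundary
        anchors are coordinate-free so the same retained intron seen against
        isoforms of different extent collapses to one event)."""
        chains = frozenset(
            tuple((s.position, s.kind) for s in v) for v in self.variants
        )
        return (self.gene_id, self.anchor_left, self.anchor_right, chains)


def splice_chain(t: TranscriptModel) -> list[SpliceSite]:
    """Internal splice sites of a transcript in transcription order.

    Alternates donor/acceptor starting with a donor; empty for mono-exonic
    transcripts.
    """
    introns = t.introns()
    if t.strand == "+":
        return [
            site
            for gstart, gend in introns
            for site in (SpliceSite(gstart, DONOR, "+"),
                         SpliceSite(gend, ACCEPTOR, "+"))
        ]
    return [
        site
        for gstart, gend in reversed(introns)
        for site in (SpliceSite(gend, DONOR, "-"),
                     SpliceSite(gstart, ACCEPTOR, "-"))
    ]


def _render(variant_chains: Sequence[Sequence[SpliceSite]],
            strand: str) -> str:
    """Number the union of variant sites in transcription order and render
    the comma-joined code string (non-empty chains by ascending first site
    number, '0' last)."""
    all_sites = sorted(
        {s for chain in variant_chains for s in chain},
        key=lambda s: (s.tx_key(), s.kind),
    )
    number = {s: i + 1 for i, s in enumerate(all_sites)}
    rendered = []
    for chain in variant_chains:
        if not chain:
            rendered.append((float("inf"), "0"))
        else:
            ordered = sorted(chain, key=lambda s: (s.tx_key(), s.kind))
            text = "".join(
                f"{number[s]}{_KIND_SUFFIX[s.kind]}" for s in ordered
            )
            rendered.append((number[ordered[0]], text))
    rendered.sort(key=lambda p: p[0])
    return ",".join(text for _, text in rendered)


def classify_code(code: str) -> str:
    """Event type for a code string; unknown structures are ``complex``."""
    return CODE_TABLE.get(code, "complex")


def detect_pair_events(t1: TranscriptModel, t2: TranscriptModel) -> list[ASEvent]:
    """All events between two isoforms of the same gene.

    Implements: shared sites are exact (position, kind) matches; variant runs
    are maximal runs of unshared sites within the genomic overlap, anchored on
    both sides by a shared site or by a both-exonic overlap boundary.
    """
    if t1.gene_id != t2.gene_id or t1.strand != t2.strand or t1.contig != t2.contig:
        raise ModelError(
            f"{t1.transcript_id} vs {t2.transcript_id}: event detection "
            "requires the same gene, contig and strand"
        )
    ov_start = max(t1.start, t2.start)
    ov_end = min(t1.end, t2.end)
    if ov_start >= ov_end:
        return []

    chain1, chain2 = splice_chain(t1), splice_chain(t2)
    set1, set2 = set(chain1), set(chain2)
    common = set1 & set2

    def in_overlap(s: SpliceSite) -> bool:
        # shared sites may sit on the overlap boundary (they anchor runs);
        # an unshared site exactly on the boundary is terminal variation
        if s in common:
            return ov_start <= s.position <= ov_end
        return ov_start < s.position < ov_end

    merged = sorted(
        (s for s in set1 | set2 if in_overlap(s)),
        key=lambda s: (s.tx_key(), s.kind),
    )

    # transcription-direction overlap boundaries
    if t1.strand == "+":
        left_bound, right_bound = ov_start, ov_end
    else:
        left_bound, right_bound = ov_end, ov_start
    # both-exonic test just inside the boundary
    def exonic_at_left() -> bool:
        p = left_bound if t1.strand == "+" else left_bound - 1
        return t1.is_exonic(p) and t2.is_exonic(p)

    def exonic_at_right() -> bool:
        p = right_bound - 1 if t1.strand == "+" else right_bound
        return t1.is_exonic(p) and t2.is_exonic(p)

    events: list[ASEvent] = []
    run: list[SpliceSite] = []
    prev_anchor: Optional[SpliceSite] = None
    left_ok = exonic_at_left()

    def flush(next_anchor: Optional[SpliceSite], right_ok: bool) -> None:
        if not run:
            return
        if prev_anchor is None and not left_ok:
            return
        if next_anchor is None and not right_ok:
            return
        v1 = tuple(s for s in run if s in set1)
        v2 = tuple(s for s in run if s in set2)
        if not v1 and not v2:
            return
        code = _render([v1, v2], t1.strand)
        events.append(ASEvent(
            gene_id=t1.gene_id,
            anchor_left=prev_anchor.position if prev_anchor else None,
            anchor_right=next_anchor.position if next_anchor else None,
            variants=(v1, v2),
            code=code,
            event_type=classify_code(code),
            witnesses=(t1.transcript_id, t2.transcript_id),
        ))

    for site in merged:
        if site in common:
            flush(site, True)
            run = []
            prev_anchor = site
        else:
            run.append(site)
    flush(None, exonic_at_right())
    return events


def detect_gene_events(gene: GeneModel) -> list[ASEvent]:
    """Union of pairwise events over all unordered isoform pairs,
    deduplicated by structural identity."""
    seen: dict[tuple, ASEvent] = {}
    for t1, t2 in itertools.combinations(gene.transcripts, 2):
        for ev in detect_pair_events(t1, t2):
            seen.setdefault(ev.identity(), ev)
    return list(seen.values())


def detect_gene_events_with_raw_count(gene: GeneModel) -> tuple[list[ASEvent], int]:
    """Deduplicated events plus the pre-dedup (pairwise incidence) count."""
    raw = 0
    seen: dict[tuple, ASEvent] = {}
    for t1, t2 in itertools.combinations(gene.transcripts, 2):
        for ev in detect_pair_events(t1, t2):
            raw += 1
            seen.setdefault(ev.identity(), ev)
    return list(seen.values()), raw


def count_by_type(events: Iterable[ASEvent]) -> dict[str, int]:
    counts: dict[str, int] = collections.Counter(e.event_type for e in events)
    return dict(counts)


def per_sample_summary(samples: Mapping[str, Sequence[GeneModel]]
                       ) -> tuple[pd.DataFrame, dict[str, set[str]], dict]:
    """Per-sample event-type counts and AS-gene sets.

    Returns ``(table, as_gene_sets, venn)`` where ``table`` is a
    sample x event-type count DataFrame, ``as_gene_sets`` maps sample id to
    the set of genes with at least one event, and ``venn`` holds the
    all-sample intersection ("conserved") and per-sample-specific set sizes.
    """
    rows = {}
    as_sets: dict[str, set[str]] = {}
    for sample, genes in samples.items():
        counter: collections.Counter = collections.Counter()
        as_genes: set[str] = set()
        for gene in genes:
            evs = detect_gene_events(gene)
            if evs:
                as_genes.add(gene.gene_id)
            counter.update(e.event_type for e in evs)
        rows[sample] = counter
        as_sets[sample] = as_genes
    table = pd.DataFrame(
        [[rows[s].get(t, 0) for t in EVENT_TYPES] for s in samples],
        index=list(samples), columns=list(EVENT_TYPES),
    )
    table["total"] = table.sum(axis=1)
    conserved = set.intersection(*as_sets.values()) if as_sets else set()
    specific = {
        s: len(as_sets[s] - set.union(set(), *(v for k, v in as_sets.items() if k != s)))
        for s in as_sets
    }
    venn = {
        "conserved": len(conserved),
        "union": len(set.union(set(), *as_sets.values())),
        "specific": specific,
    }
    return table, as_sets, venn


def events_to_frame(events: Iterable[ASEvent]) -> pd.DataFrame:
    """Events as a DataFrame with 1-based inclusive anchor output coords."""
    recs = []
    for e in events:
        recs.append({
            "gene_id": e.gene_id,
            "anchor_left": e.anchor_left + 1 if e.anchor_left is not None else ".",
            "anchor_right": e.anchor_right if e.anchor_right is not None else ".",
            "code": e.code,
            "type": e.event_type,
            "witness_1": e.witnesses[0],
            "witness_2": e.witnesses[1],
        })
    return pd.DataFrame(
        recs, columns=["gene_id", "anchor_left", "anchor_right", "code",
                       "type", "witness_1", "witness_2"],
    )
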