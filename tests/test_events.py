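import numpy as np
import pytest

from splicescape import events
from splicescape.models import ModelError, TranscriptModel
from splicescape.synthetic import TYPE_TO_CODE, plant_event

from conftest import random_transcript
from oracles import oracle_pair_events


def _t(exons, strand="+", tid="t", gid="g"):
    return TranscriptModel(tid, gid, "chr1", strand, exons)


class TestSpliceChain:
    def test_plus_strand_two_exons(self):
        chain = events.splice_chain(_t([(0, 100), (200, 300)]))
        assert [(s.position, s.kind) for s in chain] == [
            (100, "donor"), (200, "acceptor")]

    def test_minus_strand_transcription_order(self):
        chain = events.splice_chain(_t([(0, 100), (200, 300)], strand="-"))
        assert [(s.position, s.kind) for s in chain] == [
            (200, "donor"), (100, "acceptor")]

    def test_single_exon_empty(self):
        assert events.splice_chain(_t([(0, 100)])) == []

    def test_alternation_and_length(self, rng):
        for _ in range(50):
            t = random_transcript(rng)
            chain = events.splice_chain(t)
            assert len(chain) == 2 * (len(t.exons) - 1)
            kinds = [s.kind for s in chain]
            assert kinds == ["donor", "acceptor"] * (len(chain) // 2)


class TestDetectPairEvents:
    def test_intron_retention_code(self):
        t1 = _t([(0, 100), (200, 300)], tid="a")
        t2 = _t([(0, 300)], tid="b")
        (ev,) = events.detect_pair_events(t1, t2)
        assert ev.code == "1^2-,0" and ev.event_type == "IR"

    def test_exon_skipping_code(self):
        t1 = _t([(0, 100), (200, 300), (400, 500)], tid="a")
        t2 = _t([(0, 100), (400, 500)], tid="b")
        (ev,) = events.detect_pair_events(t1, t2)
        assert ev.code == "1-2^,0" and ev.event_type == "ES"

    def test_identical_chains_no_event(self):
        t1 = _t([(0, 100), (200, 300)], tid="a")
        t2 = _t([(0, 100), (200, 300)], tid="b")
        assert events.detect_pair_events(t1, t2) == []

    def test_terminal_variation_not_an_event(self):
        # the shorter isoform simply ends between the longer one's exons
        t1 = _t([(0, 100), (200, 300), (400, 500)], tid="a")
        t2 = _t([(0, 100), (200, 300)], tid="b")
        assert events.detect_pair_events(t1, t2) == []

    def test_alternative_tss_inside_intron_not_an_event(self):
        t1 = _t([(0, 100), (200, 300)], tid="a")
        t2 = _t([(150, 300)], tid="b")
        assert events.detect_pair_events(t1, t2) == []

    def test_different_gene_rejected(self):
        t1 = _t([(0, 100), (200, 300)], tid="a", gid="g1")
        t2 = _t([(0, 300)], tid="b", gid="g2")
        with pytest.raises(ModelError):
            events.detect_pair_events(t1, t2)


REFERENCE_EXONS = [(0, 100), (300, 400), (700, 800), (1100, 1200),
                   (1500, 1600), (1900, 2000)]


class TestElevenCodes:
    """Every coded event structure, planted and recovered on both strands."""

    @pytest.mark.parametrize("event_type", sorted(TYPE_TO_CODE))
    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_planted_code_recovered(self, event_type, strand):
        rng = np.random.default_rng(5)
        ref = _t(REFERENCE_EXONS, strand=strand, tid="ref")
        iso = plant_event(ref, event_type, rng)
        evs = events.detect_pair_events(ref, iso)
        assert len(evs) == 1
        assert evs[0].code == TYPE_TO_CODE[event_type]
        assert evs[0].event_type == event_type

    def test_too_few_exons_infeasible(self):
        from splicescape.synthetic import InfeasibleEventError
        rng = np.random.default_rng(0)
        ref = _t([(0, 100), (300, 400), (700, 800)], tid="ref")
        with pytest.raises(InfeasibleEventError):
            plant_event(ref, "MXE", rng)


def _mirror(t: TranscriptModel, locus_end: int) -> TranscriptModel:
    """Reflect a transcript through the locus midpoint and flip strand."""
    exons = sorted((locus_end - e, locus_end - s) for s, e in t.exons)
    strand = "-" if t.strand == "+" else "+"
    return TranscriptModel(t.transcript_id, t.gene_id, t.contig, strand,
                           exons)


class TestInvariances:
    def test_strand_reflection_preserves_codes(self):
        """Reverse-complementing the locus leaves codes and types unchanged."""
        rng = np.random.default_rng(17)
        for _ in range(200):
            ref = random_transcript(rng, tid="a", strand="+")
            iso = _perturb(ref, rng)
            fwd = events.detect_pair_events(ref, iso)
            L = max(ref.end, iso.end) + 10
            rev = events.detect_pair_events(_mirror(ref, L), _mirror(iso, L))
            assert [(e.code, e.event_type) for e in fwd] == \
                   [(e.code, e.event_type) for e in rev]

    def test_dedup_independent_of_enumeration_order(self):
        from splicescape.models import GeneModel
        t1 = _t([(0, 100), (200, 300), (400, 500)], tid="a")
        t2 = _t([(0, 300), (400, 500)], tid="b")     # retains intron 1
        t3 = _t([(0, 320), (400, 520)], tid="c")     # retains intron 1 too
        g1 = GeneModel("g", "chr1", "+", [t1, t2, t3])
        g2 = GeneModel("g", "chr1", "+", [t3, t1, t2])
        e1 = events.detect_gene_events(g1)
        e2 = events.detect_gene_events(g2)
        assert {e.identity() for e in e1} == {e.identity() for e in e2}

    def test_same_event_from_two_pairs_deduplicated(self):
        from splicescape.models import GeneModel
        t1 = _t([(0, 100), (200, 300), (400, 500)], tid="a")
        t2 = _t([(0, 300), (400, 500)], tid="b")
        t3 = _t([(0, 320), (400, 520)], tid="c")
        gene = GeneModel("g", "chr1", "+", [t1, t2, t3])
        evs = [e for e in events.detect_gene_events(gene)
               if e.event_type == "IR"]
        assert len(evs) == 1

    def test_single_transcript_gene_no_events(self):
        from splicescape.models import GeneModel
        gene = GeneModel("g", "chr1", "+", [_t([(0, 100), (200, 300)])])
        assert events.detect_gene_events(gene) == []


def _perturb(ref: TranscriptModel, rng: np.random.Generator) -> TranscriptModel:
    """A random second isoform: planted event, or an independent random
    chain over the same locus (produces complex codes too)."""
    from splicescape.synthetic import InfeasibleEventError
    if rng.random() < 0.6:
        for _ in range(5):
            etype = str(rng.choice(sorted(TYPE_TO_CODE)))
            try:
                return plant_event(ref, etype, rng, isoform_id="b")
            except InfeasibleEventError:
                continue
    lo, hi = ref.start, ref.end
    t = random_transcript(rng, tid="b", strand=ref.strand)
    shift = lo - t.start + int(rng.integers(-30, 30))
    exons = [(max(0, s + shift), e + shift) for s, e in t.exons]
    exons = [(s, e) for s, e in exons if s < e]
    return TranscriptModel("b", ref.gene_id, ref.contig, ref.strand, exons)


class TestOracleEquivalence:
    def test_random_pairs_match_bruteforce(self):
        """Pairwise detection agrees with the per-base membership
        enumerator on code, type and anchors (1,000 random cases)."""
        rng = np.random.default_rng(2)
        n_events = 0
        for _ in range(1000):
            ref = random_transcript(rng, tid="a")
            iso = _perturb(ref, rng)
            got = events.detect_pair_events(ref, iso)
            want = oracle_pair_events(ref, iso)
            assert [(e.code, e.event_type, e.anchor_left, e.anchor_right)
                    for e in got] == \
                   [(w["code"], w["type"], w["anchor_left"], w["anchor_right"])
                    for w in want]
            n_events += len(got)
        assert n_events > 500  # the comparison is not vacuous


class TestPerSampleSummary:
    def test_single_sample_ir_counts(self):
        from splicescape.models import GeneModel
        genes = []
        for i in range(10):
            t1 = _t([(0, 100), (200, 300)], tid=f"t{i}.1", gid=f"g{i}")
            t2 = _t([(0, 300)], tid=f"t{i}.2", gid=f"g{i}")
            genes.append(GeneModel(f"g{i}", "chr1", "+", [t1, t2]))
        table, as_sets, venn = events.per_sample_summary({"s1": genes})
        assert table.loc["s1", "IR"] == 10
        assert len(as_sets["s1"]) == 10
        assert venn["conserved"] == 10

    def test_disjoint_samples(self):
        from splicescape.models import GeneModel
        def gene(gid):
            t1 = _t([(0, 100), (200, 300)], tid=f"{gid}.1", gid=gid)
            t2 = _t([(0, 300)], tid=f"{gid}.2", gid=gid)
            return GeneModel(gid, "chr1", "+", [t1, t2])
        table, as_sets, venn = events.per_sample_summary(
            {"s1": [gene("a")], "s2": [gene("b")]})
        assert venn["conserved"] == 0
        assert venn["specific"] == {"s1": 1, "s2": 1}

    def test_planted_presence_structure_recovered(self, small_bundle):
        """Per-sample AS-gene sets equal the planted presence masks."""
        table, as_sets, venn = events.per_sample_summary(
            small_bundle.assembled)
        truth_sets = small_bundle.truth.as_gene_sets()
        assert as_sets == truth_sets
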