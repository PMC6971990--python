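import numpy as np
import pytest

from splicescape import features
from splicescape.models import GeneModel, GenomeSequence, TranscriptModel
from splicescape.features import BranchParams, SpliceJunction


def _t(exons, strand="+", tid="t", gid="g", cds=None):
    return TranscriptModel(tid, gid, "chr1", strand, exons, cds=cds)


def _gene(transcripts, gid="g", strand="+"):
    return GeneModel(gid, "chr1", strand, transcripts)


class TestCollectJunctions:
    def _reference(self):
        return [_gene([_t([(0, 100), (200, 300), (400, 500)], tid="r")])]

    def test_identical_junction_annotated(self):
        asm = [_gene([_t([(0, 100), (200, 300), (400, 500)], tid="a")])]
        juncs, _ = features.collect_junctions(self._reference(), asm)
        assert all(j.novelty == "annotated" for j in juncs)

    def test_shifted_acceptor_partial_novel(self):
        asm = [_gene([_t([(0, 100), (230, 300), (400, 500)], tid="a")])]
        juncs, _ = features.collect_junctions(self._reference(), asm)
        by_key = {(j.start, j.end): j.novelty for j in juncs}
        assert by_key[(100, 230)] == "partial_novel"
        assert by_key[(100, 200)] == "annotated"

    def test_unannotated_region_complete_novel(self):
        asm = [_gene([_t([(600, 700), (800, 900)], tid="a", gid="g2")],
                     gid="g2")]
        juncs, _ = features.collect_junctions(self._reference(), asm)
        by_key = {(j.start, j.end): j.novelty for j in juncs}
        assert by_key[(700, 800)] == "complete_novel"

    def test_dedup_independent_of_spanning_transcripts(self):
        # three transcripts across two samples share one intron
        asm = [
            _gene([_t([(0, 100), (200, 300), (400, 500)], tid=f"a{i}")
                   for i in range(3)]),
        ]
        juncs, incidences = features.collect_junctions(self._reference(), asm)
        assert len(juncs) == 2
        assert incidences == 2 + 3 * 2

    def test_opposite_strand_same_coordinates_distinct(self):
        ref = self._reference()
        asm = [
            _gene([_t([(0, 100), (200, 300)], tid="a")]),
            GeneModel("g2", "chr1", "-",
                      [_t([(0, 100), (200, 300)], tid="b", gid="g2",
                          strand="-")]),
        ]
        juncs, _ = features.collect_junctions(ref, asm)
        strands = {(j.start, j.end, j.strand) for j in juncs}
        assert (100, 200, "+") in strands and (100, 200, "-") in strands


class TestClassifyLocation:
    def test_junction_within_cds(self):
        t = _t([(0, 100), (200, 300)], cds=(20, 280))
        j = SpliceJunction("chr1", "+", 100, 200)
        assert features.classify_location(j, t) == "CDS"

    def test_utr_to_cds_plus_strand(self):
        t = _t([(0, 100), (200, 300)], cds=(150, 280))
        # donor at 100 upstream of CDS start, acceptor at 200 inside CDS
        j = SpliceJunction("chr1", "+", 100, 200)
        assert features.classify_location(j, t) == "5UTR-CDS"

    def test_minus_strand_mirror_is_strand_aware(self):
        # mirror of the previous case: on '-' the 5'UTR is genomically right
        t = _t([(0, 100), (200, 300)], strand="-", cds=(20, 150))
        j = SpliceJunction("chr1", "-", 100, 200)
        assert features.classify_location(j, t) == "5UTR-CDS"

    def test_noncoding_transcript(self):
        t = _t([(0, 100), (200, 300)])
        j = SpliceJunction("chr1", "+", 100, 200)
        assert features.classify_location(j, t) == "noncoding"

    def test_junction_outside_transcript_error(self):
        t = _t([(0, 100), (200, 300)], cds=(20, 280))
        j = SpliceJunction("chr1", "+", 400, 500)
        with pytest.raises(features.JunctionError):
            features.classify_location(j, t)

    def test_both_in_3utr(self):
        t = _t([(0, 100), (200, 300)], cds=(10, 60))
        j = SpliceJunction("chr1", "+", 100, 200)
        assert features.classify_location(j, t) == "3UTR"


class TestDinucleotideUsage:
    def test_plus_strand_pair(self):
        genome = GenomeSequence({"chr1": "AAAA" + "GT" + "C" * 20 + "AG" + "AAAA"})
        j = SpliceJunction("chr1", "+", 4, 28)
        assert features.junction_dinucleotides(j, genome) == "GT-AG"

    def test_minus_strand_reverse_complement(self):
        # plus-strand text CT....AC reads GT-AG on the minus strand
        genome = GenomeSequence({"chr1": "AAAA" + "CT" + "G" * 20 + "AC" + "AAAA"})
        j = SpliceJunction("chr1", "-", 4, 28)
        assert features.junction_dinucleotides(j, genome) == "GT-AG"

    def test_short_intron_undefined_and_counted(self):
        genome = GenomeSequence({"chr1": "A" * 50})
        juncs = [SpliceJunction("chr1", "+", 10, 13),
                 SpliceJunction("chr1", "+", 20, 40)]
        table = features.dinucleotide_usage(juncs, genome)
        assert table.attrs["n_undefined"] == 1
        assert table["count"].sum() == 1

    def test_percentages_sum_to_100(self, small_bundle):
        all_genes = [g for gs in small_bundle.assembled.values() for g in gs]
        juncs, _ = features.collect_junctions(
            small_bundle.reference, all_genes, small_bundle.genome)
        table = features.dinucleotide_usage(juncs, small_bundle.genome)
        assert table["percent"].sum() == pytest.approx(100.0, abs=1e-9)


def _intron_genome(intron: str, flank: int = 30):
    """Genome with one two-exon transcript around the given intron text."""
    left = "C" * flank
    right = "G" * flank
    seq = left + intron + right
    genome = GenomeSequence({"chr1": seq})
    j = SpliceJunction("chr1", "+", flank, flank + len(intron))
    return genome, j


class TestFindBranchPoint:
    def test_constructed_intron_recovered_by_hand(self):
        # GT + A-free filler + CTAAC + G gap + T-run PPT + AG
        filler = "C" * 40
        intron = "GT" + filler + "CTAAC" + "GGG" + "T" * 12 + "AG"
        genome, j = _intron_genome(intron)
        f = features.find_branch_point(j, genome)
        branch_idx = 2 + 40 + 3          # index of the A inside CTAAC
        assert f.branch_a_position == j.start + branch_idx
        assert f.bp_offset_3ss == len(intron) - 1 - branch_idx
        assert f.bp_score == 4
        # PPT covers the planted T-run
        lo, hi = f.ppt_interval
        assert intron[lo:hi] == "T" * 12

    def test_equal_scores_tie_broken_toward_3ss(self):
        intron = ("GT" + "C" * 30 + "CTAAC" + "G" * 10 + "CTAAC"
                  + "G" * 3 + "T" * 12 + "AG")
        genome, j = _intron_genome(intron)
        f = features.find_branch_point(j, genome)
        second = 2 + 30 + 5 + 10 + 3     # branch A of the nearer motif
        assert f.branch_a_position == j.start + second

    def test_intron_too_short_features_absent(self):
        genome, j = _intron_genome("GTCCCCCCAG")
        f = features.find_branch_point(j, genome)
        assert f.branch_a_position is None
        assert f.reason_absent == "intron_too_short"

    def test_no_branch_a_in_window(self):
        intron = "GT" + "C" * 60 + "AG"
        genome, j = _intron_genome(intron)
        f = features.find_branch_point(j, genome)
        assert f.branch_a_position is None
        assert f.reason_absent == "no_branch_A_in_window"

    def test_minus_strand_recovery(self, small_bundle):
        """Planted branch points recover exactly on both strands."""
        truth = {}
        for pg in small_bundle.truth.genes:
            for tj in pg.junctions:
                truth[(tj.contig, tj.strand, tj.start, tj.end)] = tj
        all_genes = [g for gs in small_bundle.assembled.values() for g in gs]
        juncs, _ = features.collect_junctions(
            small_bundle.reference, all_genes, small_bundle.genome)
        n_minus = 0
        for j in juncs:
            tj = truth[j.key()]
            if tj.branch_a_position is None:
                continue
            f = features.find_branch_point(j, small_bundle.genome)
            assert f.branch_a_position == tj.branch_a_position
            assert f.bp_offset_3ss == tj.bp_offset_3ss
            n_minus += j.strand == "-"
        assert n_minus > 0


class TestIntronStatistics:
    def _features(self, lengths, offsets=None):
        out = []
        for i, L in enumerate(lengths):
            j = SpliceJunction("chr1", "+", 0, L)
            f = features.IntronFeatures(junction=j, intron_length=L)
            if offsets is not None:
                f.bp_offset_3ss = offsets[i]
                f.bp_offset_5ss = L - 1 - offsets[i]
            out.append(f)
        return out

    def test_constant_lengths(self):
        s = features.intron_statistics(self._features([100, 100, 100]))
        assert s["length_mean"] == 100
        assert s["length_sd"] == 0
        assert s["length_median"] == 100

    def test_offset_linear_in_length_gives_r_one(self):
        lengths = [100, 200, 300, 400, 500]
        s = features.intron_statistics(
            self._features(lengths, offsets=[30] * 5))
        assert s["length_vs_bp5ss_r"] == pytest.approx(1.0)

    def test_empty_input_error(self):
        with pytest.raises(ValueError):
            features.intron_statistics([])

    def test_histogram_closure(self):
        lengths = [20, 60, 100, 151, 800, 1999, 2500, 5000]
        hist = features.length_histogram(lengths)
        assert hist["count"].sum() == len(lengths)
        assert hist.loc[hist["bin"] == "<=50", "count"].item() == 1
        assert hist.loc[hist["bin"] == "51-150", "count"].item() == 2
        assert hist.loc[hist["bin"] == ">2000", "count"].item() == 2

    def test_planted_lognormal_mean_recovered(self):
        """Sample mean of planted log-normal lengths within 3 sd/sqrt(n)."""
        rng = np.random.default_rng(3)
        draws = np.maximum(rng.lognormal(np.log(300), 0.4, size=400), 110)
        s = features.intron_statistics(self._features(draws.astype(int)))
        assert abs(s["length_mean"] - draws.astype(int).mean()) < 1e-9
        sd = draws.std(ddof=1)
        assert abs(s["length_mean"] - np.exp(np.log(300) + 0.08)) \
            < 3 * sd / np.sqrt(len(draws)) + 10


class TestLogos:
    def test_all_gt_introns_give_pure_gt_positions(self, small_bundle):
        all_genes = [g for gs in small_bundle.assembled.values() for g in gs]
        juncs, _ = features.collect_junctions(
            small_bundle.reference, all_genes, small_bundle.genome)
        gt = [j for j in juncs
              if features.junction_dinucleotides(j, small_bundle.genome)
              == "GT-AG"]
        feats = features.find_branch_points(gt, small_bundle.genome)
        logos = {l.region: l for l in features.build_logos(
            feats, small_bundle.genome)}
        five = logos["5ss"].counts
        n = len(gt) - logos["5ss"].n_skipped
        assert five.loc[1, "G"] == n
        assert five.loc[2, "T"] == n
        three = logos["3ss"].counts
        assert three.loc[-1, "G"] == n
        assert three.loc[-2, "A"] == n

    def test_branch_logo_modal_bases_are_ctaac(self, small_bundle):
        all_genes = [g for gs in small_bundle.assembled.values() for g in gs]
        juncs, _ = features.collect_junctions(
            small_bundle.reference, all_genes, small_bundle.genome)
        feats = features.find_branch_points(juncs, small_bundle.genome)
        logos = {l.region: l for l in features.build_logos(
            feats, small_bundle.genome)}
        br = logos["branch"].counts
        modal = "".join(br.loc[o].idxmax() for o in (-3, -2, -1, 0, 1))
        assert modal == "CTAAC"

    def test_single_intron_rows_sum_to_one(self):
        filler = "C" * 40
        intron = "GT" + filler + "CTAAC" + "GGG" + "T" * 12 + "AG"
        genome, j = _intron_genome(intron)
        f = features.find_branch_point(j, genome)
        logos = features.build_logos([f], genome)
        for logo in logos:
            assert (logo.counts.sum(axis=1) == 1).all()
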