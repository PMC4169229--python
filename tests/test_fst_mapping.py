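import pytest

import paraprimer as pp
from paraprimer.fst_mapping import (merge_close_predictions, predict,
                                    segment_regions)
from paraprimer.genome import GenomicInterval
from paraprimer.local_search import LocalHit, bitscore


def make_hit(qs, qe, chrom="chr1", ss=None, se=None, strand="+",
             score=100, ev=1e-50):
    ss = ss if ss is not None else 1000
    se = se if se is not None else ss + (qe - qs)
    return LocalHit(query_start=qs, query_end=qe,
                    subject=GenomicInterval(chrom, ss, se, strand),
                    strand=strand, length=qe - qs, identity=1.0,
                    matches=qe - qs, mismatches=0, score=score,
                    bitscore=bitscore(score), evalue=ev)


class TestSegmentRegions:
    def test_identical_intervals_one_region(self):
        hits = [make_hit(0, 150, ss=1000), make_hit(0, 150, ss=5000)]
        assert len(segment_regions(hits)) == 1

    def test_disjoint_intervals_two_regions(self):
        hits = [make_hit(0, 150), make_hit(160, 300, ss=9000)]
        regions = segment_regions(hits)
        assert [(r.query_start, r.query_end) for r, _ in regions] == \
            [(0, 150), (160, 300)]

    def test_overlap_25_below_threshold_two_regions(self):
        hits = [make_hit(0, 100), make_hit(75, 175, ss=9000)]
        assert len(segment_regions(hits)) == 2

    def test_overlap_30_joins(self):
        hits = [make_hit(0, 100), make_hit(70, 170, ss=9000)]
        assert len(segment_regions(hits)) == 1

    def test_transitive_closure(self):
        hits = [make_hit(0, 100), make_hit(60, 160, ss=5000),
                make_hit(120, 220, ss=9000)]
        assert len(segment_regions(hits)) == 1


class TestPredict:
    def test_unique_flank_single_cat0(self, unique_genome):
        genome, idx = unique_genome
        ins = pp.simulate_insertions(genome, 5, seed=21)
        fsts = pp.generate_fsts(genome, ins, fst_len=200, seed=22)
        for f, i in zip(fsts, ins):
            preds = predict(f, genome, idx)
            assert len(preds) == 1
            p = preds[0]
            assert p.category == 0
            assert p.position.chrom == i.position.chrom
            assert abs(p.position.start - i.position.start) <= 5

    def test_paralog_family_cat0_plus_two_cat1(self):
        """An FST inside a paralog family yields the true locus as
        category 0 and the sibling copies as category 1, all in one
        region. Divergence is kept low enough (1%) that sibling hits
        stay within the 1e10 e-value factor of the best hit."""
        genome, truths = pp.generate_genome(
            n_chrom=2, chrom_len=40_000, n_families=1, members_per_family=3,
            divergence=0.01, seed=203, segment_len=1500)
        idx = pp.build_index(genome)
        fam = truths[0]
        ins = pp.simulate_insertions(genome, 1, seed=23,
                                     inside=[fam.members[0]])
        fsts = pp.generate_fsts(genome, ins, fst_len=100, seed=24)
        preds = predict(fsts[0], genome, idx)
        cats = sorted(p.category for p in preds)
        assert cats == [0, 1, 1]
        assert len({p.region_index for p in preds}) == 1
        # category 0 is the true locus for an error-free FST
        assert abs(preds[0].position.start - ins[0].position.start) <= 5
        # category 1 positions fall inside the sibling members
        member_spans = [(m.chrom, m.start, m.end) for m in fam.members[1:]]
        for p in preds[1:]:
            assert any(c == p.position.chrom and s <= p.position.start < e
                       for c, s, e in member_spans)

    def test_distant_sibling_discarded_by_evalue_factor(self):
        # 10% pairwise divergence over a 300 bp flank: the sibling hit is
        # more than a factor 1e10 worse than the best hit and is dropped
        genome, truths = pp.generate_genome(
            n_chrom=1, chrom_len=40_000, n_families=1, members_per_family=2,
            divergence=0.10, seed=25, segment_len=1500)
        idx = pp.build_index(genome)
        fam = truths[0]
        ins = pp.simulate_insertions(genome, 1, seed=26,
                                     inside=[fam.members[0]])
        fsts = pp.generate_fsts(genome, ins, fst_len=300, seed=27)
        preds = predict(fsts[0], genome, idx)
        assert [p.category for p in preds] == [0]

    def test_composite_fst_two_regions_two_predictions(self, unique_genome):
        genome, idx = unique_genome
        ins = pp.simulate_insertions(genome, 1, insertions_per_line=2, seed=28)
        fsts = pp.generate_fsts(genome, ins, fst_len=300,
                                composite_fraction=1.0, seed=29)
        preds = predict(fsts[0], genome, idx)
        assert len(preds) == 2
        assert {p.category for p in preds} == {0, 1}
        assert len({p.region_index for p in preds}) == 2
        truth = {(i.position.chrom, i.position.start) for i in ins}
        found = {(p.position.chrom, p.position.start) for p in preds}
        assert all(any(c == tc and abs(s - ts) <= 5 for tc, ts in truth)
                   for c, s in found)

    def test_no_hits_empty(self, unique_genome):
        genome, idx = unique_genome
        fst = pp.FST("f1", "lineZ", "A" * 80)  # homopolymer absent by chance
        assert predict(fst, genome, idx) == []

    def test_never_two_category0(self, family_genome):
        genome, idx, fam = family_genome
        ins = pp.simulate_insertions(genome, 10, seed=30,
                                     inside=list(fam.members))
        fsts = pp.generate_fsts(genome, ins, fst_len=150, error_rate=0.01,
                                seed=31)
        for f in fsts:
            preds = predict(f, genome, idx)
            assert sum(p.category == 0 for p in preds) <= 1


class TestMergeClosePredictions:
    def test_close_predictions_merge_keeping_better(self):
        a = pp.InsertionPrediction("l", "f", 0, GenomicInterval("c", 5000, 5001),
                                   0, make_hit(0, 100, ss=5000, ev=1e-40))
        b = pp.InsertionPrediction("l", "f", 0, GenomicInterval("c", 5600, 5601),
                                   1, make_hit(0, 100, ss=5600, ev=1e-30))
        merged = merge_close_predictions([a, b])
        assert merged == [a]

    def test_distant_predictions_kept(self):
        a = pp.InsertionPrediction("l", "f", 0, GenomicInterval("c", 5000, 5001),
                                   0, make_hit(0, 100, ss=5000, ev=1e-40))
        b = pp.InsertionPrediction("l", "f", 0, GenomicInterval("c", 6100, 6101),
                                   1, make_hit(0, 100, ss=6100, ev=1e-30))
        assert len(merge_close_predictions([a, b])) == 2


def test_evalue_ratio_example():
    """A sibling 1e15-fold worse than the best hit is discarded; the
    stated factor is 1e10."""
    from paraprimer import config
    assert 1e-35 > 1e-50 * config.EVALUE_RATIO_LIMIT
    assert not 1e-42 > 1e-50 * config.EVALUE_RATIO_LIMIT
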