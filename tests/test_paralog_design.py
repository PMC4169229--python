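import numpy as np
import pytest

import paraprimer as pp
from paraprimer.genome import Genome, GenomicInterval, extract, revcomp
from paraprimer.msa import align_zone
from paraprimer.paralog_design import (confirm_locus, design_paralog,
                                       _candidate_columns)
from paraprimer.standard_design import DesignFailure

from conftest import mismatches_to_paralog, random_seq, two_copy_genome


class TestDesignParalog:
    def test_single_snp_three_prime_lands_on_it(self):
        genome, idx, a_iv, b_iv = two_copy_genome(1, snp_offsets=(250,),
                                                  designable_at=250)
        cand = design_paralog(genome, idx, a_iv, "forward", 60.5)
        assert isinstance(cand, pp.PrimerCandidate)
        # the only discriminating column is the SNP: the 3' base sits on it
        assert cand.three_prime == a_iv.start + 250
        # exact match to the target copy, mismatch to the paralog at 3'
        assert cand.sequence == extract(genome, cand.placement)
        assert mismatches_to_paralog(cand, genome, a_iv, b_iv) >= 1
        assert cand.mismatch_points >= 1
        assert cand.total_points >= 15

    def test_identical_copies_degrade_gracefully(self):
        genome, idx, a_iv, b_iv = two_copy_genome(2, snp_offsets=())
        cand = design_paralog(genome, idx, a_iv, "forward", 60.5)
        assert isinstance(cand, pp.PrimerCandidate)
        assert cand.end12_hits >= 2       # no unique site can exist
        assert cand.mismatch_points == 0

    def test_reverse_orientation_snp(self):
        genome, idx, a_iv, b_iv = two_copy_genome(3, snp_offsets=(250,),
                                                  designable_at=250)
        cand = design_paralog(genome, idx, a_iv, "reverse", 60.5)
        assert cand.strand == "-"
        assert cand.three_prime == a_iv.start + 250
        assert cand.sequence[-1] == revcomp(
            genome.sequences["c"][a_iv.start + 250])

    def test_double_mismatch_column_preferred(self):
        """In a 3-copy family, a column where both siblings differ beats
        single-mismatch columns."""
        rng = np.random.default_rng(4)
        seg = random_seq(rng, 400)
        repl = {"A": "C", "C": "G", "G": "T", "T": "A"}
        # copies B and C both differ from A at 200; B alone differs at 120
        seg_b = list(seg)
        seg_b[200] = repl[seg_b[200]]
        seg_b[120] = repl[seg_b[120]]
        seg_c = list(seg)
        seg_c[200] = repl[repl[seg_c[200]]]   # different substitution
        genome = Genome({"c": random_seq(rng, 3000) + seg
                         + random_seq(rng, 3000) + "".join(seg_b)
                         + random_seq(rng, 3000) + "".join(seg_c)
                         + random_seq(rng, 3000)})
        idx = pp.build_index(genome)
        zone = GenomicInterval("c", 3000, 3400)
        zone_seq = extract(genome, zone)
        aln = align_zone(zone_seq, ["".join(seg_b), "".join(seg_c)])
        cols = _candidate_columns(aln, len(zone_seq))
        assert cols[0] == 200      # count 2 outranks count 1
        assert 120 in cols
        cand = design_paralog(genome, idx, zone, "forward", 60.5)
        assert cand.three_prime == zone.start + 200

    def test_exclude_yields_other_candidate(self):
        genome, idx, a_iv, b_iv = two_copy_genome(
            5, snp_offsets=(150, 250, 350))
        first = design_paralog(genome, idx, a_iv, "forward", 60.5)
        second = design_paralog(genome, idx, a_iv, "forward", 60.5,
                                exclude=[first])
        assert isinstance(second, pp.PrimerCandidate)
        assert second.key() != first.key()

    def test_zone_without_paralogs_fails_explicitly(self, unique_genome):
        genome, idx = unique_genome
        zone = GenomicInterval("chr1", 40_000, 40_500)
        result = design_paralog(genome, idx, zone, "forward", 60.5)
        assert isinstance(result, DesignFailure)

    def test_returned_points_always_above_threshold(self):
        for seed in (6, 7, 8):
            genome, idx, a_iv, _ = two_copy_genome(
                seed, snp_offsets=(100, 200, 300, 400))
            cand = design_paralog(genome, idx, a_iv, "forward", 60.5)
            if isinstance(cand, pp.PrimerCandidate):
                assert cand.total_points >= 15


def test_discrimination_rate_two_paralog_zones():
    """>= 90% of random two-paralog zones at 1-5% divergence yield a
    primer that matches the target copy exactly and mismatches the other
    copy within its 3'-terminal 5 bases."""
    rng = np.random.default_rng(99)
    n, designed, discriminating = 30, 0, 0
    for trial in range(n):
        divergence = rng.uniform(0.01, 0.05)
        n_snps = max(1, int(round(divergence * 400)))
        offsets = tuple(sorted(rng.choice(400, size=n_snps, replace=False)))
        genome, idx, a_iv, b_iv = two_copy_genome(
            1000 + trial, snp_offsets=offsets, copy_len=400, spacer=3000)
        cand = design_paralog(genome, idx, a_iv, "forward", 60.5)
        if not isinstance(cand, pp.PrimerCandidate):
            continue
        designed += 1
        if (cand.sequence == extract(genome, cand.placement)
                and mismatches_to_paralog(cand, genome, a_iv, b_iv) >= 1):
            discriminating += 1
    assert designed == n
    assert discriminating / n >= 0.9


class TestConfirmLocus:
    def test_snp_margin_is_three_per_snp(self):
        genome, idx, a_iv, b_iv = two_copy_genome(
            20, snp_offsets=(50, 150, 250, 350, 450))
        amplicon = extract(genome, a_iv)   # covers all 5 SNPs
        result = confirm_locus(amplicon, [a_iv, b_iv], genome)
        assert result.status == "confirmed"
        assert result.winner == a_iv
        assert result.margin == 3 * 5

    def test_identical_loci_ambiguous(self):
        genome, idx, a_iv, b_iv = two_copy_genome(21, snp_offsets=())
        amplicon = extract(genome, a_iv)
        result = confirm_locus(amplicon, [a_iv, b_iv], genome)
        assert result.status == "ambiguous"

    def test_random_amplicon_unconfirmed(self):
        genome, idx, a_iv, b_iv = two_copy_genome(22)
        rng = np.random.default_rng(23)
        result = confirm_locus(random_seq(rng, 300), [a_iv, b_iv], genome)
        assert result.status == "unconfirmed"
        assert result.winner is None

    def test_requires_two_loci(self):
        genome, idx, a_iv, _ = two_copy_genome(24)
        with pytest.raises(ValueError):
            confirm_locus("ACGT" * 30, [a_iv], genome)
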