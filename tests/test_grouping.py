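import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

import paraprimer as pp
from paraprimer.fst_mapping import predict_all
from paraprimer.grouping import build_groups, flank_identity


def _family_predictions(divergence, seed, members=2, n_families=1,
                        chrom_len=40_000, fst_len=200):
    """One line with an error-free FST at the homologous position of
    every member of every planted family; returns predictions + truth."""
    genome, truths = pp.generate_genome(
        n_chrom=2, chrom_len=chrom_len, n_families=n_families,
        members_per_family=members, divergence=divergence, seed=seed,
        segment_len=1500)
    idx = pp.build_index(genome)
    insertions = []
    labels = {}
    for fi, fam in enumerate(truths):
        for iv in fam.members:
            pos = iv.start + 700   # same offset in every member
            insertions.append(pp.SimulatedInsertion(
                "line0001", pp.GenomicInterval(iv.chrom, pos, pos + 1),
                right_border=True))
            labels[(iv.chrom, pos)] = fi
    fsts = pp.generate_fsts(genome, insertions, fst_len=fst_len,
                            error_rate=0.0, seed=seed + 1)
    preds = predict_all(fsts, genome, idx)
    return genome, preds, labels


class TestFlankIdentity:
    def test_identical_flanks(self):
        genome, preds, _ = _family_predictions(0.0, seed=50)
        cat0 = [p for p in preds if p.category == 0]
        assert flank_identity(cat0[0], cat0[1], genome) == 1.0

    def test_diverged_family_flanks(self):
        genome, preds, _ = _family_predictions(0.05, seed=51)
        cat0 = [p for p in preds if p.category == 0]
        ident = flank_identity(cat0[0], cat0[1], genome)
        assert ident == pytest.approx(0.95, abs=0.03)

    def test_unrelated_flanks_low_identity(self, unique_genome):
        genome, idx = unique_genome
        ins = pp.simulate_insertions(genome, 1, insertions_per_line=2, seed=52)
        fsts = pp.generate_fsts(genome, ins, fst_len=150, seed=53)
        preds = predict_all(fsts, genome, idx)
        assert len(preds) == 2
        ident = flank_identity(preds[0], preds[1], genome)
        assert ident < 0.6   # random-alignment background


class TestBuildGroups:
    def test_same_region_predictions_form_group(self):
        """Three predictions from one FST region cluster regardless of
        flank identity."""
        genome, truths = pp.generate_genome(
            n_chrom=2, chrom_len=40_000, n_families=1, members_per_family=3,
            divergence=0.01, seed=54, segment_len=1500)
        idx = pp.build_index(genome)
        ins = pp.simulate_insertions(genome, 1, seed=55,
                                     inside=[truths[0].members[0]])
        fsts = pp.generate_fsts(genome, ins, fst_len=100, seed=56)
        preds = predict_all(fsts, genome, idx)
        assert len(preds) == 3
        groups = build_groups(preds, genome)
        assert len(groups) == 1
        assert len(groups[0].members) == 3

    def test_high_identity_different_fsts_merge(self):
        genome, preds, _ = _family_predictions(0.10, seed=57)
        groups = build_groups(preds, genome)
        assert len(groups) == 1
        assert len(groups[0].members) == 2

    def test_low_identity_yields_no_groups(self):
        # ~70% flank identity: below the >79% rule, and different FSTs
        genome, preds, _ = _family_predictions(0.30, seed=58)
        assert len(preds) == 2
        assert build_groups(preds, genome) == []

    def test_group_members_over_1000bp_apart(self):
        genome, preds, _ = _family_predictions(0.05, seed=59, members=3)
        for group in build_groups(preds, genome):
            pos = group.positions
            for i in range(len(pos)):
                for j in range(i + 1, len(pos)):
                    if pos[i].chrom == pos[j].chrom:
                        assert abs(pos[i].start - pos[j].start) > 1000

    def test_category2_excluded(self):
        """Category-2 predictions never participate in grouping."""
        genome, preds, _ = _family_predictions(0.05, seed=62)
        demoted = [pp.InsertionPrediction(p.line_id, p.fst_id,
                                          p.region_index, p.position, 2, p.hit)
                   for p in preds]
        assert build_groups(demoted, genome) == []


def test_permutation_invariance():
    genome, preds, _ = _family_predictions(0.05, seed=60, members=3,
                                           n_families=2, chrom_len=60_000)
    base = build_groups(preds, genome)
    base_sets = {frozenset((m.position.chrom, m.position.start)
                           for m in g.members) for g in base}
    rng = np.random.default_rng(0)
    for _ in range(4):
        perm = list(preds)
        rng.shuffle(perm)
        got = build_groups(perm, genome)
        got_sets = {frozenset((m.position.chrom, m.position.start)
                              for m in g.members) for g in got}
        assert got_sets == base_sets


@pytest.mark.parametrize("divergence", [0.05, 0.10, 0.15])
def test_planted_families_recovered_exactly(divergence):
    """Recovered groups equal planted families (ARI = 1.0) up to 15%
    pairwise divergence with error-free FSTs."""
    genome, preds, labels = _family_predictions(
        divergence, seed=61 + int(divergence * 100), members=2,
        n_families=2, chrom_len=60_000)
    groups = build_groups(preds, genome)
    true_labels, found_labels = [], []
    for gid, g in enumerate(groups):
        for m in g.members:
            true_labels.append(labels[(m.position.chrom, m.position.start)])
            found_labels.append(gid)
    assert len(true_labels) == len(labels)   # nothing dropped
    assert adjusted_rand_score(true_labels, found_labels) == 1.0


def test_multiple_lines_grouped_independently():
    genome, truths = pp.generate_genome(
        n_chrom=2, chrom_len=40_000, n_families=1, members_per_family=2,
        divergence=0.05, seed=70, segment_len=1500)
    idx = pp.build_index(genome)
    ins = []
    for li, fam in enumerate([truths[0], truths[0]]):
        for iv in fam.members:
            pos = iv.start + 400 + 150 * li
            ins.append(pp.SimulatedInsertion(
                f"line{li + 1:04d}", pp.GenomicInterval(iv.chrom, pos, pos + 1),
                right_border=True))
    fsts = pp.generate_fsts(genome, ins, fst_len=150, seed=71)
    preds = predict_all(fsts, genome, idx)
    groups = pp.grouping.build_groups_by_line(preds, genome)
    assert len(groups) == 2
    assert {g.line_id for g in groups} == {"line0001", "line0002"}
    with pytest.raises(ValueError):
        build_groups(preds, genome)
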