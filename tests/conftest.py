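import numpy as np
import pytest

import paraprimer as pp

BASES = "ACGT"


def random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, size=n))


def naive_overlapping_count(haystack: str, needle: str) -> int:
    """Brute-force overlapping substring count (independent oracle)."""
    n = 0
    start = 0
    while True:
        i = haystack.find(needle, start)
        if i < 0:
            return n
        n += 1
        start = i + 1


def full_smith_waterman(a: str, b: str, match=1, mismatch=-2,
                        gap_open=-5, gap_extend=-2) -> int:
    """Unbanded affine-gap local alignment score (test oracle)."""
    m, n = len(a), len(b)
    NEG = -10**9
    H = [[0] * (n + 1) for _ in range(m + 1)]
    E = [[NEG] * (n + 1) for _ in range(m + 1)]
    F = [[NEG] * (n + 1) for _ in range(m + 1)]
    best = 0
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            E[i][j] = max(H[i][j - 1] + gap_open, E[i][j - 1] + gap_extend)
            F[i][j] = max(H[i - 1][j] + gap_open, F[i - 1][j] + gap_extend)
            sub = match if (a[i - 1] == b[j - 1] and a[i - 1] != "N") else mismatch
            H[i][j] = max(0, H[i - 1][j - 1] + sub, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


def _designable_patch(rng, half=40):
    """A (2*half+1)-mer in which a fully flag-passing, near-60.5degC
    primer ends exactly on the centre base, in both orientations."""
    from paraprimer.primer_core import quality_flags
    while True:
        patch = random_seq(rng, 2 * half + 1)
        fwd = patch[half - 19:half + 1]
        rev = pp.revcomp(patch[half:half + 20])
        try:
            ok = (quality_flags(fwd).all_pass()
                  and quality_flags(rev).all_pass()
                  and abs(pp.melting_temperature(fwd) - 60.5) <= 1.0
                  and abs(pp.melting_temperature(rev) - 60.5) <= 1.0)
        except ValueError:
            ok = False
        if ok:
            return patch


def two_copy_genome(seed, snp_offsets=(), copy_len=500, spacer=4000,
                    designable_at=None):
    """Genome with two copies of one segment; copy B carries the SNPs.

    ``designable_at`` plants a stretch around that offset in which a
    quality primer ending exactly there is guaranteed to exist (so
    tests of 3'-end placement are not confounded by Tm/flag failures of
    random sequence).
    """
    rng = np.random.default_rng(seed)
    seg_a = random_seq(rng, copy_len)
    if designable_at is not None:
        patch = _designable_patch(rng)
        half = 40
        seg_a = (seg_a[:designable_at - half] + patch
                 + seg_a[designable_at + half + 1:])
        assert len(seg_a) == copy_len
    seg_b = list(seg_a)
    repl = {"A": "C", "C": "G", "G": "T", "T": "A"}
    for off in snp_offsets:
        seg_b[off] = repl[seg_b[off]]
    seq = (random_seq(rng, spacer) + seg_a + random_seq(rng, spacer)
           + "".join(seg_b) + random_seq(rng, spacer))
    genome = pp.Genome({"c": seq})
    a_iv = pp.GenomicInterval("c", spacer, spacer + copy_len)
    b_iv = pp.GenomicInterval("c", 2 * spacer + copy_len,
                              2 * spacer + 2 * copy_len)
    return genome, pp.build_index(genome), a_iv, b_iv


def mismatches_to_paralog(cand, genome, a_iv, b_iv, window=5):
    """Count mismatches of the primer's 3'-terminal columns against the
    homologous stretch of the other copy (independent recount)."""
    off = cand.placement.start - a_iv.start
    other = pp.GenomicInterval(b_iv.chrom, b_iv.start + off,
                               b_iv.start + off + len(cand.sequence),
                               cand.strand)
    other_seq = pp.extract(genome, other)
    return sum(a != b for a, b in
               zip(cand.sequence[-window:], other_seq[-window:]))


@pytest.fixture(scope="session")
def unique_genome():
    """100 kb random genome with no planted repeats, plus its index."""
    genome, _ = pp.generate_genome(n_chrom=2, chrom_len=50_000,
                                   n_families=0, divergence=0.0, seed=101)
    return genome, pp.build_index(genome)


@pytest.fixture(scope="session")
def family_genome():
    """Genome with one 3-member paralog family at 2% pairwise divergence."""
    genome, truths = pp.generate_genome(
        n_chrom=2, chrom_len=40_000, n_families=1, members_per_family=3,
        divergence=0.02, seed=202, segment_len=1500)
    return genome, pp.build_index(genome), truths[0]
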