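"""Primer arithmetic: melting temperature, quality criteria, point
scoring, and elongation of a fixed 3' end to a target Tm.

The quality score is a weighted sum of four binary criteria plus one
point per discriminating mismatch against paralogous sequence:

* GC clamp, 1-3 G/C among the last 5 bases        -> 8 points
* no homopolymer run longer than 5 bases          -> 4 points
* overall GC content between 40% and 60%          -> 2 points
* reverse complement of the last 5 bases does not
  occur in the primer (no 3' hairpin)             -> 1 point

A candidate is retained only with at least 15 points, i.e. a primer
with no discriminating mismatch must satisfy all four criteria.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from . import config
from .genome import Genome, GenomicInterval, extract


@dataclass(frozen=True)
class QualityFlags:
    gc_clamp: bool
    no_runs: bool
    gc_ok: bool
    no_hairpin: bool

    def points(self) -> int:
        return (config.POINTS_GC_CLAMP * self.gc_clamp
                + config.POINTS_NO_RUNS * self.no_runs
                + config.POINTS_GC_OK * self.gc_ok
                + config.POINTS_NO_HAIRPIN * self.no_hairpin)

    def all_pass(self) -> bool:
        return self.gc_clamp and self.no_runs and self.gc_ok and self.no_hairpin


@dataclass
class PrimerCandidate:
    sequence: str
    placement: GenomicInterval     # plus-strand span; strand = priming strand
    three_prime: int               # genomic 0-based coordinate of the 3' base
    tm: float
    gc: float
    flags: QualityFlags
    mismatch_points: int = 0
    end12_hits: int | None = None

    @property
    def total_points(self) -> int:
        return self.mismatch_points + self.flags.points()

    @property
    def strand(self) -> str:
        return self.placement.strand

    def key(self) -> tuple:
        return (self.placement.chrom, self.three_prime, self.strand,
                self.sequence)


def gc_content(seq: str) -> float:
    """GC percentage; primers may not contain N."""
    if not seq:
        raise ValueError("empty sequence")
    if "N" in seq:
        raise ValueError("primer contains N")
    return 100.0 * (seq.count("G") + seq.count("C")) / len(seq)


def melting_temperature(seq: str) -> float:
    """Tm(degC) = 81.5 - 11.6 + 0.41*%GC - 600/length.

    The basic GC/length formula with a fixed salt-correction term, the
    same closed form classic design engines use, so temperatures are
    comparable between the two design methods.
    """
    if len(seq) < 12:
        raise ValueError("sequence shorter than 12 nt")
    return 81.5 - 11.6 + 0.41 * gc_content(seq) - 600.0 / len(seq)


def quality_flags(seq: str, max_run: int = config.MAX_RUN) -> QualityFlags:
    if len(seq) < 10:
        raise ValueError("sequence shorter than 10 nt")
    last5 = seq[-5:]
    gc_clamp = 1 <= (last5.count("G") + last5.count("C")) <= 3
    no_runs = not re.search(r"(.)\1{%d,}" % max_run, seq)
    gc = gc_content(seq)
    gc_ok = config.GC_MIN <= gc <= config.GC_MAX
    rc = last5.translate(str.maketrans("ACGT", "TGCA"))[::-1]
    no_hairpin = rc not in seq
    return QualityFlags(gc_clamp, no_runs, gc_ok, no_hairpin)


def score(seq: str, mismatch_points: int = 0) -> int:
    if mismatch_points < 0:
        raise ValueError("mismatch_points must be >= 0")
    return mismatch_points + quality_flags(seq).points()


def retained(total_points: int) -> bool:
    return total_points >= config.MIN_POINTS


def elongate_to_tm(genome: Genome, chrom: str, three_prime: int, strand: str,
                   target_tm: float,
                   min_len: int = config.MIN_PRIMER_LEN,
                   max_len: int = config.MAX_PRIMER_LEN,
                   tolerance: float = config.TM_TOLERANCE
                   ) -> PrimerCandidate | None:
    """Grow a primer 5'-ward from a fixed 3'-end base to match a Tm.

    Returns the candidate whose Tm is closest to ``target_tm`` among
    lengths in [min_len, max_len] (shorter wins ties), or None when no
    length fits within ``tolerance`` or elongation runs off the
    chromosome. Regions containing N yield None.
    """
    if not config.TM_BOUNDS[0] <= target_tm <= config.TM_BOUNDS[1]:
        raise ValueError(f"target Tm {target_tm} outside {config.TM_BOUNDS}")
    chrom_len = genome.lengths[chrom]
    best: tuple[float, int, str, GenomicInterval] | None = None
    for length in range(min_len, max_len + 1):
        if strand == "+":
            start, end = three_prime - length + 1, three_prime + 1
        else:
            start, end = three_prime, three_prime + length
        if start < 0 or end > chrom_len:
            continue
        iv = GenomicInterval(chrom, start, end, strand)
        seq = extract(genome, iv)
        if "N" in seq:
            continue
        delta = abs(melting_temperature(seq) - target_tm)
        if best is None or delta < best[0]:
            best = (delta, length, seq, iv)
    if best is None or best[0] > tolerance:
        return None
    _, _, seq, iv = best
    return PrimerCandidate(
        sequence=seq, placement=iv, three_prime=three_prime,
        tm=melting_temperature(seq), gc=gc_content(seq),
        flags=quality_flags(seq))
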