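"""Seed-and-extend local similarity search over a genome.

This is the in-package stand-in for a BLAST-style nucleotide search:
shared 12-mers between query and genome seed diagonal bands, each band
is extended by banded affine-gap local dynamic programming, and hit
significance is expressed as an e-value through a Karlin-Altschul-style
bit-score surrogate. Absolute e-values are an internal calibration (a
24 bp exact match scores near the 1e-5 boundary); contracts downstream
rely only on thresholds and orderings.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from . import config
from ._dp import banded_sw, encode
from .genome import Genome, GenomicInterval, revcomp
from .kmer_index import KmerIndex, seed_positions


@dataclass(frozen=True)
class LocalHit:
    """One local alignment between a query region and a genome region.

    ``query_start``/``query_end`` are 0-based half-open offsets in the
    original query orientation; ``subject`` is always a plus-strand
    interval, with ``strand`` recording which query strand matched it.
    """

    query_start: int
    query_end: int
    subject: GenomicInterval
    strand: str
    length: int          # alignment columns
    identity: float      # matches / alignment columns
    matches: int
    mismatches: int
    score: int
    bitscore: float
    evalue: float

    def sort_key(self):
        return (self.evalue, -self.score, self.subject.chrom,
                self.subject.start, self.strand, self.query_start)


def bitscore(raw_score: int) -> float:
    return (config.KA_LAMBDA * raw_score - math.log(config.KA_K)) / math.log(2)


def evalue(raw_score: int, query_len: int, genome_len: int) -> float:
    """E = m * n * 2^-bits with n counting both strands of the genome."""
    return query_len * (2 * genome_len) * 2.0 ** (-bitscore(raw_score))


def _clusters(seeds: list[tuple[int, int]], query_len: int):
    """Group (diag, qpos) seeds into diagonal bands, split along diagonals.

    Seeds whose diagonals differ by more than the band width start a new
    band; within a band, seeds separated by more than a query length
    along the subject are treated as distinct copies.
    """
    band = config.SEED_BAND
    seeds = sorted(seeds)
    groups: list[list[tuple[int, int]]] = []
    for diag, qpos in seeds:
        if groups and diag - groups[-1][-1][0] <= band:
            groups[-1].append((diag, qpos))
        else:
            groups.append([(diag, qpos)])
    out = []
    for grp in groups:
        by_pos = sorted((d + q, d, q) for d, q in grp)
        cur = [by_pos[0]]
        for item in by_pos[1:]:
            if item[0] - cur[-1][0] > query_len + 2 * band:
                out.append(cur)
                cur = []
            cur.append(item)
        out.append(cur)
    return out


def search(query: str, genome: Genome, index: KmerIndex,
           evalue_cutoff: float = config.EVALUE_DESIGN,
           min_hit_len: int = config.FST_MIN_HIT_LEN) -> list[LocalHit]:
    """All local hits of ``query`` against both strands of ``genome``.

    Hits shorter than ``min_hit_len`` alignment columns or less
    significant than ``evalue_cutoff`` are dropped. The result is sorted
    by ascending e-value, ties broken by descending raw score, then by
    subject position, which makes downstream "best hit" selection
    deterministic.
    """
    k = index.k
    if len(query) < k:
        raise ValueError(f"query shorter than seed size {k}")
    positions = seed_positions(index, genome)
    chrom_names = list(genome.sequences)
    total_len = genome.total_length
    m = len(query)

    hits: dict[tuple, LocalHit] = {}
    for strand in ("+", "-"):
        q = query if strand == "+" else revcomp(query)
        q_codes = encode(q)
        # seeds per chromosome: (diag, qpos) with diag = subject - query offset
        per_chrom: dict[int, list[tuple[int, int]]] = {}
        for qpos in range(m - k + 1):
            kmer = q[qpos:qpos + k]
            for ci, gpos in positions.get(kmer, ()):
                per_chrom.setdefault(ci, []).append((gpos - qpos, qpos))
        for ci, seeds in per_chrom.items():
            chrom = chrom_names[ci]
            seq = genome.sequences[chrom]
            for cluster in _clusters(seeds, m):
                diags = [d for _, d, _ in cluster]
                lo_diag, hi_diag = min(diags), max(diags)
                ss0 = max(0, lo_diag - config.SEED_BAND)
                se0 = min(len(seq), hi_diag + m + config.SEED_BAND)
                window = encode(seq[ss0:se0])
                res = banded_sw(
                    q_codes, window,
                    lo_diag - ss0 - config.SEED_BAND,
                    hi_diag - ss0 + config.SEED_BAND,
                    config.MATCH, config.MISMATCH,
                    config.GAP_OPEN, config.GAP_EXTEND)
                raw = int(res[0])
                if raw <= 0:
                    continue
                cols = int(res[7])
                e = evalue(raw, m, total_len)
                if cols < min_hit_len or e > evalue_cutoff:
                    continue
                qs, qe = int(res[1]), int(res[2])
                if strand == "-":
                    qs, qe = m - qe, m - qs
                sstart, send = ss0 + int(res[3]), ss0 + int(res[4])
                key = (chrom, strand, sstart, send, qs, qe)
                matches, mism = int(res[5]), int(res[6])
                hit = LocalHit(
                    query_start=qs, query_end=qe,
                    subject=GenomicInterval(chrom, sstart, send, strand),
                    strand=strand, length=cols,
                    identity=matches / cols,
                    matches=matches, mismatches=mism,
                    score=raw, bitscore=bitscore(raw), evalue=e)
                prev = hits.get(key)
                if prev is None or hit.score > prev.score:
                    hits[key] = hit
    return sorted(hits.values(), key=LocalHit.sort_key)


def hits_to_table(query_id: str, hits: list[LocalHit]) -> str:
    """Tabular rendering in BLAST outfmt-6 column order (1-based positions)."""
    rows = []
    for h in hits:
        s1, s2 = h.subject.start + 1, h.subject.end
        if h.strand == "-":
            s1, s2 = s2, s1
        gaps = h.length - h.matches - h.mismatches
        rows.append("\t".join(map(str, [
            query_id, h.subject.chrom, f"{100 * h.identity:.2f}", h.length,
            h.mismatches, gaps, h.query_start + 1, h.query_end,
            s1, s2, f"{h.evalue:.2e}", f"{h.bitscore:.1f}"])))
    return "\n".join(rows)
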