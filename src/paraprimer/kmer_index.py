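"""Genome-wide k-mer occurrence index (default k = 12).

Mispriming can start from as little as a perfect 12 bp match at a
primer's 3' end, so candidate primers are ranked by how often their
3'-terminal 12-mer occurs in the genome. Counts are precomputed once per
genome and can be persisted to a TSV keyed by the genome fingerprint.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path

from .genome import Genome, revcomp

log = logging.getLogger(__name__)


@dataclass
class KmerIndex:
    """Exact occurrence counts of every k-mer on the genome plus strand.

    A k-mer and its reverse complement are separate keys; duplex-aware
    queries combine them (see :func:`end_hits`). Windows containing N are
    not counted.
    """

    k: int
    counts: dict[str, int]
    fingerprint: str
    # plus-strand positions per k-mer, built lazily for seed lookup
    _positions: dict[str, list[tuple[int, int]]] | None = field(
        default=None, repr=False, compare=False)

    def count(self, kmer: str) -> int:
        return self.counts.get(kmer, 0)

    def duplex_count(self, kmer: str) -> int:
        """Occurrences of ``kmer`` on either strand of the duplex."""
        rc = revcomp(kmer)
        n = self.counts.get(kmer, 0)
        if rc != kmer:
            n += self.counts.get(rc, 0)
        return n


def build_index(genome: Genome, k: int = 12) -> KmerIndex:
    """Count every full k-mer window on the plus strand of every chromosome."""
    if k < 8:
        raise ValueError(f"k must be >= 8, got {k}")
    counts: dict[str, int] = defaultdict(int)
    any_window = False
    for name, seq in genome.sequences.items():
        if len(seq) < k:
            continue
        any_window = True
        for i in range(len(seq) - k + 1):
            kmer = seq[i:i + k]
            if "N" in kmer:
                continue
            counts[kmer] += 1
    if not any_window:
        log.warning("genome shorter than k=%d; index is empty", k)
    return KmerIndex(k=k, counts=dict(counts), fingerprint=genome.fingerprint())


def seed_positions(index: KmerIndex, genome: Genome) -> dict[str, list[tuple[int, int]]]:
    """Plus-strand (chrom_idx, offset) occurrence lists for every k-mer.

    Built once per index and cached; this is the seed table of the local
    search.
    """
    if index.fingerprint != genome.fingerprint():
        raise ValueError("index does not match this genome (stale fingerprint)")
    if index._positions is None:
        pos: dict[str, list[tuple[int, int]]] = defaultdict(list)
        k = index.k
        for ci, (name, seq) in enumerate(genome.sequences.items()):
            for i in range(len(seq) - k + 1):
                kmer = seq[i:i + k]
                if "N" not in kmer:
                    pos[kmer].append((ci, i))
        index._positions = dict(pos)
    return index._positions


def end_hits(index: KmerIndex, primer: str) -> int:
    """Genome-wide duplex occurrence count of the primer's 3' k-mer.

    A primer is "unique" iff this equals 1 (its own intended site). The
    count is duplex-aware: the annealing site exists on both strands of
    the template, so occurrences of the k-mer and of its reverse
    complement on the indexed strand both count.
    """
    if len(primer) < index.k:
        raise ValueError(
            f"primer shorter than k={index.k}: {len(primer)} nt")
    tail = primer[-index.k:]
    if "N" in tail:
        log.warning("primer 3' end contains N; counting exact matches only")
        return 0
    return index.duplex_count(tail)


def save_index(index: KmerIndex, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"#k\t{index.k}\n#fingerprint\t{index.fingerprint}\n")
        for kmer in sorted(index.counts):
            fh.write(f"{kmer}\t{index.counts[kmer]}\n")


def load_index(path) -> KmerIndex:
    k = None
    fingerprint = None
    counts: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#k\t"):
                k = int(line.split("\t")[1])
            elif line.startswith("#fingerprint\t"):
                fingerprint = line.split("\t", 1)[1]
            elif line:
                kmer, n = line.split("\t")
                counts[kmer] = int(n)
    if k is None or fingerprint is None:
        raise ValueError(f"{path}: missing index header")
    return KmerIndex(k=k, counts=counts, fingerprint=fingerprint)


def load_or_build(genome: Genome, path=None, k: int = 12) -> KmerIndex:
    """Load a persisted index if fresh for this genome, else (re)build.

    Mirrors a database-backed precomputed table: the index is keyed by
    the genome fingerprint and silently rebuilt when stale.
    """
    if path is not None and Path(path).exists():
        idx = load_index(path)
        if idx.k == k and idx.fingerprint == genome.fingerprint():
            return idx
        log.info("index at %s is stale; rebuilding", path)
    idx = build_index(genome, k=k)
    if path is not None:
        save_index(idx, path)
    return idx
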