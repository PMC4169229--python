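"""Synthetic genomes, paralog families, T-DNA insertions and FSTs.

The generator states a small world with known truth: i.i.d. background
sequence, paralog families planted as diverged copies of one ancestral
segment, point insertions, and flanking sequence tags (FSTs) read off
the genome next to each insertion — optionally "composite" FSTs that
concatenate flanks of two independent insertions of the same line, the
shorter-amplicon flank first. The mutation model is substitution-only by
default: the discriminating signal this tool exploits is SNPs between
paralogs, and indels would only complicate truth bookkeeping.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .genome import Genome, GenomicInterval

log = logging.getLogger(__name__)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class ParalogTruth:
    """Planted family: member placements and where each member differs."""

    family_id: str
    members: list[GenomicInterval]
    # per member, segment offsets where it differs from the ancestor
    distinguishing: list[list[int]]
    # realised identity per member pair, keyed (i, j) with i < j
    pairwise_identity: dict[tuple[int, int], float] = field(default_factory=dict)


@dataclass(frozen=True)
class SimulatedInsertion:
    """One T-DNA insertion: a point position plus which flank was read."""

    line_id: str
    position: GenomicInterval      # width-1 interval
    right_border: bool             # True: flank extends rightward of position


@dataclass
class FST:
    id: str
    line_id: str
    sequence: str
    truncated: bool = False
    # truth bookkeeping (not part of the mapping contract)
    source_insertions: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if len(self.sequence) < 50 and not self.truncated:
            raise ValueError(f"FST {self.id}: sequence shorter than 50 nt")


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return _BASES[rng.integers(0, 4, size=n)].tobytes().decode()


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> tuple[str, list[int]]:
    """Substitution-only mutation; returns the mutant and mutated offsets."""
    if rate <= 0:
        return seq, []
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hit = np.nonzero(rng.random(arr.size) < rate)[0]
    for i in hit:
        choices = _BASES[_BASES != arr[i]]
        arr[i] = rng.choice(choices)
    return arr.tobytes().decode(), hit.tolist()


def generate_genome(n_chrom: int = 2, chrom_len: int = 50_000,
                    n_families: int = 2, members_per_family: int = 2,
                    divergence: float = 0.02, seed: int = 0,
                    segment_len: int = 1000,
                    min_separation: int = 1000) -> tuple[Genome, list[ParalogTruth]]:
    """Background genome with planted paralog families.

    ``divergence`` controls the expected per-base divergence *between
    any two members* of a family: every copy of the ancestral segment
    receives substitutions at rate divergence/2, so two members differ
    at ~divergence of their positions (e.g. 0.05 -> ~95% pairwise
    identity). Members are placed at least ``min_separation`` bp apart
    so the downstream distance rules are exercised. Deterministic given
    ``seed``.
    """
    if not 0 <= divergence <= 0.5:
        raise ValueError("divergence must lie in [0, 0.5]")
    rng = np.random.default_rng(seed)
    chrom_names = [f"chr{i + 1}" for i in range(n_chrom)]
    chroms = {name: bytearray(_random_seq(rng, chrom_len).encode())
              for name in chrom_names}

    # non-overlapping member slots, >= min_separation apart
    occupied: dict[str, list[tuple[int, int]]] = {n: [] for n in chrom_names}

    def place_one() -> GenomicInterval:
        for _ in range(200):
            chrom = chrom_names[rng.integers(0, n_chrom)]
            if chrom_len < segment_len + 2:
                break
            start = int(rng.integers(0, chrom_len - segment_len))
            lo, hi = start - min_separation, start + segment_len + min_separation
            if all(e <= lo or s >= hi for s, e in occupied[chrom]):
                occupied[chrom].append((start, start + segment_len))
                return GenomicInterval(chrom, start, start + segment_len)
        raise RuntimeError(
            f"cannot place a {segment_len} bp family member >= "
            f"{min_separation} bp from others in {n_chrom}x{chrom_len} bp")

    truths: list[ParalogTruth] = []
    for fam in range(n_families):
        ancestor = _random_seq(rng, segment_len)
        members, distinguishing, seqs = [], [], []
        for _ in range(members_per_family):
            iv = place_one()
            mutant, positions = _mutate(rng, ancestor, divergence / 2.0)
            chroms[iv.chrom][iv.start:iv.end] = mutant.encode()
            members.append(iv)
            distinguishing.append(positions)
            seqs.append(mutant)
        truth = ParalogTruth(f"fam{fam + 1}", members, distinguishing)
        for i in range(len(seqs)):
            for j in range(i + 1, len(seqs)):
                same = sum(a == b for a, b in zip(seqs[i], seqs[j]))
                truth.pairwise_identity[(i, j)] = same / segment_len
        truths.append(truth)

    genome = Genome({n: bytes(b).decode() for n, b in chroms.items()})
    return genome, truths


def simulate_insertions(genome: Genome, n_lines: int,
                        insertions_per_line: int = 1, seed: int = 0,
                        margin: int = 400,
                        inside: list[GenomicInterval] | None = None,
                        line_spacing: int = 2000) -> list[SimulatedInsertion]:
    """Random insertion points, ``margin`` bp clear of chromosome ends.

    If ``inside`` intervals are given, positions are drawn within them
    (used to plant insertions inside paralog family members). Multiple
    insertions of one line are kept >= ``line_spacing`` bp apart: in a
    real genome two independent integrations are effectively never
    adjacent, and on a toy-sized genome uniform draws would regularly
    collide with the 1000 bp same-insertion merge rule.
    """
    rng = np.random.default_rng(seed)
    chrom_names = list(genome.sequences)
    out = []
    for li in range(n_lines):
        line = f"line{li + 1:04d}"
        placed: list[tuple[str, int]] = []
        for _ in range(insertions_per_line):
            for _attempt in range(200):
                if inside:
                    iv = inside[int(rng.integers(0, len(inside)))]
                    pos = int(rng.integers(iv.start + margin // 4,
                                           iv.end - margin // 4))
                    chrom = iv.chrom
                else:
                    chrom = chrom_names[int(rng.integers(0, len(chrom_names)))]
                    length = genome.lengths[chrom]
                    pos = int(rng.integers(margin, length - margin))
                if all(c != chrom or abs(p - pos) >= line_spacing
                       for c, p in placed):
                    break
            else:
                raise RuntimeError(
                    f"cannot place {insertions_per_line} insertions "
                    f">= {line_spacing} bp apart for {line}")
            placed.append((chrom, pos))
            out.append(SimulatedInsertion(
                line, GenomicInterval(chrom, pos, pos + 1),
                right_border=bool(rng.integers(0, 2))))
    return out


def _flank(genome: Genome, ins: SimulatedInsertion, length: int) -> tuple[str, bool]:
    """Flank sequence reading away from the junction; truncated at ends."""
    seq = genome.sequences[ins.position.chrom]
    pos = ins.position.start
    if ins.right_border:
        end = min(len(seq), pos + length)
        return seq[pos:end], end - pos < length
    start = max(0, pos - length)
    from .genome import revcomp
    return revcomp(seq[start:pos]), pos - start < length


def generate_fsts(genome: Genome, insertions: list[SimulatedInsertion],
                  fst_len: int = 300, error_rate: float = 0.0,
                  composite_fraction: float = 0.0, seed: int = 0) -> list[FST]:
    """FSTs for each insertion, with sequencing-style substitution errors.

    With probability ``composite_fraction`` an FST for a line carrying
    several insertions concatenates two flanks, the shorter one (the
    stronger PCR signal) first.
    """
    if fst_len < 50:
        raise ValueError("fst_len must be >= 50")
    rng = np.random.default_rng(seed)
    by_line: dict[str, list[SimulatedInsertion]] = {}
    for ins in insertions:
        by_line.setdefault(ins.line_id, []).append(ins)

    fsts: list[FST] = []
    counter = 0
    for ins in insertions:
        counter += 1
        siblings = [s for s in by_line[ins.line_id] if s is not ins]
        composite = bool(siblings) and rng.random() < composite_fraction
        if composite:
            other = siblings[int(rng.integers(0, len(siblings)))]
            short_len = int(round(0.4 * fst_len))
            head, t1 = _flank(genome, ins, short_len)
            tail, t2 = _flank(genome, other, fst_len - short_len)
            raw, truncated = head + tail, t1 or t2
            sources = (_ins_key(ins), _ins_key(other))
        else:
            raw, truncated = _flank(genome, ins, fst_len)
            sources = (_ins_key(ins),)
        seq, _ = _mutate(rng, raw, error_rate)
        if truncated:
            log.warning("FST for %s truncated at a chromosome end", ins.line_id)
        fsts.append(FST(id=f"fst{counter:05d}", line_id=ins.line_id,
                        sequence=seq, truncated=truncated,
                        source_insertions=sources))
    return fsts


def _ins_key(ins: SimulatedInsertion) -> str:
    return f"{ins.position.chrom}:{ins.position.start + 1}"


# --- truth TSV writers ------------------------------------------------------

def write_paralog_truth(truths: list[ParalogTruth], path) -> None:
    with open(path, "w") as fh:
        fh.write("family\tmember\tchrom\tstart1\tend1\tdistinguishing_offsets\n")
        for t in truths:
            for i, iv in enumerate(t.members):
                s1, e1 = iv.to_1based()
                offs = ",".join(map(str, t.distinguishing[i]))
                fh.write(f"{t.family_id}\t{i}\t{iv.chrom}\t{s1}\t{e1}\t{offs}\n")


def write_insertion_truth(insertions: list[SimulatedInsertion], path) -> None:
    with open(path, "w") as fh:
        fh.write("line\tchrom\tposition1\tright_border\n")
        for ins in insertions:
            fh.write(f"{ins.line_id}\t{ins.position.chrom}\t"
                     f"{ins.position.start + 1}\t{int(ins.right_border)}\n")


def write_fst_fasta(fsts: list[FST], path) -> None:
    with open(path, "w") as fh:
        for fst in fsts:
            fh.write(f">{fst.id} line={fst.line_id}"
                     f" sources={';'.join(fst.source_insertions)}\n")
            fh.write(fst.sequence + "\n")
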