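"""Genome container, FASTA I/O and coordinate conventions.

Internally every position is 0-based half-open; anything rendered for a
user (reports, TSVs, CLI output) is converted to 1-based inclusive, the
convention genome browsers and annotation databases use.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

log = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_VALID = frozenset("ACGTN")
# IUPAC ambiguity codes collapse to N on load; anything else is an error.
_IUPAC_AMBIGUOUS = frozenset("RYSWKMBDHV")


def revcomp(seq: str) -> str:
    """Reverse complement of an A/C/G/T/N string (involution; N -> N)."""
    if not _VALID.issuperset(seq):
        bad = sorted(set(seq) - _VALID)
        raise ValueError(f"non-ACGTN characters in sequence: {bad}")
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open 0-based interval on a named chromosome.

    ``to_1based()`` yields the inclusive 1-based coordinates used in all
    user-facing output.
    """

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("empty chromosome name")
        if not (0 <= self.start < self.end):
            raise ValueError(f"bad interval [{self.start}, {self.end})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def to_1based(self) -> tuple[int, int]:
        return self.start + 1, self.end

    @classmethod
    def from_1based(cls, chrom: str, start1: int, end1: int,
                    strand: str = "+") -> "GenomicInterval":
        return cls(chrom, start1 - 1, end1, strand)

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (self.chrom == other.chrom
                and self.start < other.end and other.start < self.end)


@dataclass
class Genome:
    """Named uppercase chromosome sequences over the {A,C,G,T,N} alphabet."""

    sequences: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, seq in self.sequences.items():
            if not name:
                raise ValueError("empty chromosome name")
            if not _VALID.issuperset(seq):
                bad = sorted(set(seq) - _VALID)
                raise ValueError(f"{name}: non-ACGTN characters {bad}")

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.sequences.items()}

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.sequences.values())

    def fingerprint(self) -> str:
        """Stable identity of this assembly (names, lengths, CRC of bases)."""
        crc = 0
        for name in self.sequences:
            crc = zlib.crc32(name.encode(), crc)
            crc = zlib.crc32(self.sequences[name].encode(), crc)
        parts = ",".join(f"{n}:{l}" for n, l in self.lengths.items())
        return f"{parts};crc{crc:08x}"

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.sequences


def _clean_record(name: str, raw: str) -> str:
    seq = raw.upper()
    if _VALID.issuperset(seq):
        return seq
    chars = set(seq) - _VALID
    if not chars.issubset(_IUPAC_AMBIGUOUS):
        bad = sorted(chars - _IUPAC_AMBIGUOUS)
        raise ValueError(f"record {name!r}: non-nucleotide characters {bad}")
    n_amb = sum(seq.count(c) for c in chars)
    log.warning("record %r: %d IUPAC ambiguity base(s) converted to N",
                name, n_amb)
    table = str.maketrans({c: "N" for c in chars})
    return seq.translate(table)


def read_fasta(path) -> Genome:
    """Load a (multi-)FASTA into a Genome.

    Lowercase bases are uppercased; ambiguity codes other than N become N
    with a warning; duplicate record names or an empty file are errors.
    """
    sequences: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in sequences:
            raise ValueError(f"duplicate record name {rec.id!r}")
        sequences[rec.id] = _clean_record(rec.id, str(rec.seq))
    if not sequences:
        raise ValueError(f"no FASTA records in {path}")
    return Genome(sequences)


def write_fasta(genome: Genome, path, width: int = 70) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="")
               for name, seq in genome.sequences.items()]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def extract(genome: Genome, iv: GenomicInterval) -> str:
    """Sequence of an interval; minus strand returns the reverse complement."""
    if iv.chrom not in genome.sequences:
        raise KeyError(f"unknown chromosome {iv.chrom!r}")
    seq = genome.sequences[iv.chrom]
    if iv.end > len(seq):
        raise ValueError(
            f"interval [{iv.start},{iv.end}) beyond end of {iv.chrom} "
            f"(length {len(seq)})")
    sub = seq[iv.start:iv.end]
    return revcomp(sub) if iv.strand == "-" else sub


def read_gff3_genes(path) -> dict[str, GenomicInterval]:
    """Gene-ID -> interval lookup from a GFF3 (``gene`` features only).

    Convenience for targeting a design by gene identifier; everything else
    in the GFF3 is ignored.
    """
    genes: dict[str, GenomicInterval] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9 or parts[2].lower() != "gene":
                continue
            chrom, start1, end1, strand = parts[0], parts[3], parts[4], parts[6]
            attrs = dict(kv.split("=", 1) for kv in parts[8].split(";") if "=" in kv)
            gid = attrs.get("ID") or attrs.get("Name")
            if gid is None:
                continue
            gid = gid.removeprefix("gene:")
            genes[gid] = GenomicInterval.from_1based(
                chrom, int(start1), int(end1), strand if strand in "+-" else "+")
    return genes
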