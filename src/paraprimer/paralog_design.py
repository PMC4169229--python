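"""Paralog-discriminating primer design.

Where a target zone has paralogous copies elsewhere in the genome, a
unique annealing site may not exist, but the copies usually differ at
scattered positions. This method aligns the zone with all of its
paralogous counterparts, places candidate 3' ends on the alignment
columns with the most mismatches to the zone (a 3'-terminal mismatch is
what blocks extension on the wrong paralog), elongates each to the
requested Tm, scores candidates with the point scheme (one point per
discriminating mismatch in the 3'-terminal window plus the four quality
criteria), and returns the first candidate whose 3' 12-mer is unique in
the genome — or, failing that, the least-redundant candidate examined.

``confirm_locus`` is the downstream adjudication step: given a sequenced
amplicon and the candidate paralogous loci, it ranks loci by local
alignment score; SNPs covered by the amplicon separate the scores.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio import Align

from . import config
from .genome import Genome, GenomicInterval, extract
from .kmer_index import KmerIndex, end_hits
from .local_search import LocalHit, search
from .msa import ZoneAlignment, align_zone
from .primer_core import PrimerCandidate, elongate_to_tm
from .standard_design import DesignFailure


def paralogous_hits(zone_seq: str, zone: GenomicInterval, genome: Genome,
                    index: KmerIndex) -> list[LocalHit]:
    """Hits of the zone elsewhere in the genome (self-hits masked)."""
    hits = search(zone_seq, genome, index,
                  evalue_cutoff=config.EVALUE_DESIGN,
                  min_hit_len=config.MIN_PARALOG_HIT_LEN)
    return [h for h in hits if not h.subject.overlaps(zone)]


def elongate_hit_to_zone(hit: LocalHit, zone_len: int,
                         genome: Genome) -> str:
    """Extend a hit's subject interval so it covers the whole zone length.

    The extension keeps the hit collinear with the zone: missing query
    bases on either side are added to the corresponding subject side
    (strand-aware), clamped at chromosome ends.
    """
    chrom_len = genome.lengths[hit.subject.chrom]
    head = hit.query_start
    tail = zone_len - hit.query_end
    if hit.strand == "+":
        start = hit.subject.start - head
        end = hit.subject.end + tail
    else:
        start = hit.subject.start - tail
        end = hit.subject.end + head
    start = max(0, start)
    end = min(chrom_len, end)
    iv = GenomicInterval(hit.subject.chrom, start, end, hit.strand)
    seq = extract(genome, iv)
    # keep the row in register with the zone when clamping truncated the
    # zone-head side (for '-' hits that side is the high-coordinate end)
    if hit.strand == "+":
        pad_left = max(0, head - hit.subject.start)
    else:
        pad_left = max(0, hit.subject.end + head - chrom_len)
    return "N" * pad_left + seq


def _candidate_columns(aln: ZoneAlignment, zone_len: int) -> list[int]:
    """Zone offsets ordered for 3'-end placement.

    Descending mismatch count; ties resolved toward the zone centre,
    then leftmost. Columns with no mismatch are appended as a fallback
    when discriminating columns are scarce.
    """
    centre = (zone_len - 1) / 2.0
    per_offset = {ref: aln.mismatch_counts[col]
                  for col, ref in enumerate(aln.column_ref) if ref is not None}

    def order(offsets):
        return sorted(offsets,
                      key=lambda o: (-per_offset[o], abs(o - centre), o))

    with_mm = order([o for o, c in per_offset.items() if c >= 1])
    if len(with_mm) < config.MIN_FALLBACK_COLUMNS:
        with_mm += order([o for o, c in per_offset.items() if c == 0])
    return with_mm[:config.MAX_PARALOG_COLUMNS]


def _terminal_mismatch_points(aln: ZoneAlignment, offset: int, strand: str,
                              zone_len: int,
                              window: int = config.MISMATCH_WINDOW) -> int:
    """Mismatch counts summed over the primer's 3'-terminal columns."""
    per_offset = {ref: aln.mismatch_counts[col]
                  for col, ref in enumerate(aln.column_ref) if ref is not None}
    if strand == "+":
        span = range(max(0, offset - window + 1), offset + 1)
    else:
        span = range(offset, min(zone_len, offset + window))
    return sum(per_offset.get(o, 0) for o in span)


def design_paralog(genome: Genome, index: KmerIndex, zone: GenomicInterval,
                   orientation: str, target_tm: float,
                   exclude: list[PrimerCandidate] | None = None
                   ) -> PrimerCandidate | DesignFailure:
    if orientation not in ("forward", "reverse"):
        raise ValueError(f"bad orientation {orientation!r}")
    strand = "+" if orientation == "forward" else "-"
    excluded = {c.key() for c in (exclude or [])}
    zone_seq = extract(genome, GenomicInterval(zone.chrom, zone.start,
                                               zone.end, "+"))
    hits = paralogous_hits(zone_seq, zone, genome, index)
    if not hits:
        return DesignFailure("zone has no paralogous hits",
                             {"note": "standard method applies here"})
    paralog_seqs = [elongate_hit_to_zone(h, len(zone_seq), genome)
                    for h in hits]
    aln = align_zone(zone_seq, paralog_seqs)

    fail_counts = {"tm_unreachable": 0, "below_15_points": 0, "excluded": 0}
    kept: list[tuple[int, PrimerCandidate]] = []
    for rank, offset in enumerate(_candidate_columns(aln, len(zone_seq))):
        cand = elongate_to_tm(genome, zone.chrom, zone.start + offset,
                              strand, target_tm)
        if cand is None:
            fail_counts["tm_unreachable"] += 1
            continue
        if cand.placement.start < zone.start or cand.placement.end > zone.end:
            fail_counts["tm_unreachable"] += 1
            continue
        cand.mismatch_points = _terminal_mismatch_points(
            aln, offset, strand, len(zone_seq))
        if cand.total_points < config.MIN_POINTS:
            fail_counts["below_15_points"] += 1
            continue
        if cand.key() in excluded:
            fail_counts["excluded"] += 1
            continue
        cand.end12_hits = end_hits(index, cand.sequence)
        if cand.end12_hits == 1:
            return cand
        kept.append((rank, cand))

    if not kept:
        return DesignFailure("no paralog-discriminating primer found",
                             fail_counts)
    kept.sort(key=lambda rc: (rc[1].end12_hits, -rc[1].total_points, rc[0]))
    return kept[0][1]


# --- amplicon-based locus confirmation -------------------------------------

def _local_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = config.MATCH
    aligner.mismatch_score = config.MISMATCH
    aligner.open_gap_score = config.GAP_OPEN
    aligner.extend_gap_score = config.GAP_EXTEND
    return aligner


_LOCAL_ALIGNER = _local_aligner()


@dataclass
class LocusConfirmation:
    """Ranked candidate loci for a sequenced amplicon."""

    ranking: list[tuple[GenomicInterval, int]]   # (locus, raw score) desc
    status: str                                  # confirmed/ambiguous/unconfirmed

    @property
    def winner(self) -> GenomicInterval | None:
        return self.ranking[0][0] if self.ranking else None

    @property
    def margin(self) -> int | None:
        if len(self.ranking) < 2:
            return None
        return self.ranking[0][1] - self.ranking[1][1]


def confirm_locus(amplicon_seq: str, candidate_loci: list[GenomicInterval],
                  genome: Genome,
                  min_len: int = config.MIN_PARALOG_HIT_LEN
                  ) -> LocusConfirmation:
    """Rank candidate loci by local-alignment score of the amplicon.

    A SNP covered by the amplicon changes the raw score by 3 under the
    +1/-2 scoring, so even one difference separates otherwise identical
    paralogs. "ambiguous" means the top two scores are equal;
    "unconfirmed" means the amplicon does not align to any locus over at
    least ``min_len`` columns.
    """
    if len(candidate_loci) < 2:
        raise ValueError("need at least two candidate loci")
    scored = []
    for locus in candidate_loci:
        locus_seq = extract(genome, locus)
        alns = _LOCAL_ALIGNER.align(locus_seq, amplicon_seq)
        if len(alns) == 0:
            continue
        best = alns[0]
        counts = best.counts()
        cols = counts.identities + counts.mismatches + counts.gaps
        if cols < min_len:
            continue
        scored.append((locus, int(best.score)))
    if not scored:
        return LocusConfirmation([], "unconfirmed")
    scored.sort(key=lambda ls: (-ls[1], ls[0].chrom, ls[0].start))
    status = "confirmed"
    if len(scored) >= 2 and scored[0][1] == scored[1][1]:
        status = "ambiguous"
    return LocusConfirmation(scored, status)
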