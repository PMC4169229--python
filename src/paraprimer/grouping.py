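"""Hierarchical clustering of a line's insertion predictions into
paralog groups.

Two predictions belong together when the FST evidence cannot tell them
apart: either they were deduced from the same part of one FST (>= 30 bp
query overlap), or the 400 bp of genomic sequence next to the two
predicted sites align at more than 79% identity. Groups are merged only
when *every* cross pair satisfies one of the two conditions, repeated to
a fixpoint, and only groups with at least two distinct insertions
(> 1000 bp apart) are kept — singletons are not paralog problems.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio import Align

from . import config
from .fst_mapping import InsertionPrediction, merge_close_predictions
from .genome import Genome, GenomicInterval, extract


@dataclass
class ParalogGroup:
    line_id: str
    members: list[InsertionPrediction]

    @property
    def positions(self) -> list[GenomicInterval]:
        return [m.position for m in self.members]


def _global_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = config.MATCH
    aligner.mismatch_score = config.MISMATCH
    aligner.open_gap_score = config.GAP_OPEN
    aligner.extend_gap_score = config.GAP_EXTEND
    return aligner


_ALIGNER = _global_aligner()


def _proximal_flank(pred: InsertionPrediction, genome: Genome,
                    length: int = config.FLANK_LEN) -> str:
    """Flank on the side of the predicted site the FST evidence covers.

    Strand-normalised: returned 5'->3' reading away from the junction,
    truncated at chromosome ends.
    """
    chrom = pred.position.chrom
    pos = pred.position.start
    chrom_len = genome.lengths[chrom]
    if pred.hit.strand == "+":
        end = min(chrom_len, pos + length)
        iv = GenomicInterval(chrom, pos, end, "+")
    else:
        start = max(0, pos + 1 - length)
        iv = GenomicInterval(chrom, start, pos + 1, "-")
    return extract(genome, iv)


def flank_identity(a: InsertionPrediction, b: InsertionPrediction,
                   genome: Genome) -> float:
    """Global-alignment identity (matches / alignment columns) of the
    400 bp flanks next to the two predicted sites."""
    sa = _proximal_flank(a, genome)
    sb = _proximal_flank(b, genome)
    aln = _ALIGNER.align(sa, sb)[0]
    counts = aln.counts()
    columns = counts.identities + counts.mismatches + counts.gaps
    return counts.identities / columns if columns else 0.0


def _same_region(a: InsertionPrediction, b: InsertionPrediction) -> bool:
    if a.fst_id != b.fst_id:
        return False
    ov = (min(a.hit.query_end, b.hit.query_end)
          - max(a.hit.query_start, b.hit.query_start))
    return ov >= config.REGION_OVERLAP


def build_groups(predictions: list[InsertionPrediction], genome: Genome,
                 identity_min: float = config.FLANK_IDENTITY_MIN
                 ) -> list[ParalogGroup]:
    """Merge-to-fixpoint clustering of one line's category-0/1 predictions.

    Predictions closer than 1000 bp are first collapsed into a single
    insertion (they are the same event seen through different FSTs);
    the all-pairs merge condition makes the outcome independent of merge
    order, but when several merges are admissible the pair with the
    highest minimum cross-pair identity goes first.
    """
    preds = [p for p in predictions if p.category in (0, 1)]
    if not preds:
        return []
    lines = {p.line_id for p in preds}
    if len(lines) > 1:
        raise ValueError(f"predictions from several lines: {sorted(lines)}")
    preds = merge_close_predictions(preds)

    identity_cache: dict[tuple[int, int], float] = {}

    def ident(i: int, j: int) -> float:
        key = (min(i, j), max(i, j))
        if key not in identity_cache:
            identity_cache[key] = flank_identity(preds[key[0]], preds[key[1]],
                                                 genome)
        return identity_cache[key]

    def pair_ok(i: int, j: int) -> tuple[bool, float]:
        if _same_region(preds[i], preds[j]):
            return True, 1.0
        idv = ident(i, j)
        return idv > identity_min, idv

    groups: list[list[int]] = [[i] for i in range(len(preds))]
    while True:
        best_pair = None
        best_key = -1.0
        for gi in range(len(groups)):
            for gj in range(gi + 1, len(groups)):
                ok = True
                min_ident = 1.0
                for i in groups[gi]:
                    for j in groups[gj]:
                        good, idv = pair_ok(i, j)
                        if not good:
                            ok = False
                            break
                        min_ident = min(min_ident, idv)
                    if not ok:
                        break
                if ok and min_ident > best_key:
                    best_key = min_ident
                    best_pair = (gi, gj)
        if best_pair is None:
            break
        gi, gj = best_pair
        groups[gi] = sorted(groups[gi] + groups[gj])
        del groups[gj]

    out = []
    for idxs in groups:
        if len(idxs) < 2:
            continue
        members = sorted((preds[i] for i in idxs),
                         key=lambda p: (p.position.chrom, p.position.start))
        out.append(ParalogGroup(members[0].line_id, members))
    out.sort(key=lambda g: (g.members[0].position.chrom,
                            g.members[0].position.start))
    return out


def build_groups_by_line(predictions: list[InsertionPrediction],
                         genome: Genome) -> list[ParalogGroup]:
    by_line: dict[str, list[InsertionPrediction]] = {}
    for p in predictions:
        by_line.setdefault(p.line_id, []).append(p)
    groups: list[ParalogGroup] = []
    for line in sorted(by_line):
        groups.extend(build_groups(by_line[line], genome))
    return groups


def groups_to_tsv(groups: list[ParalogGroup]) -> str:
    lines = ["line\tgroup\tchrom\tposition1\tcategory\tfst"]
    for gid, g in enumerate(groups, start=1):
        for m in g.members:
            lines.append("\t".join(map(str, [
                g.line_id, gid, m.position.chrom, m.position.start + 1,
                m.category, m.fst_id])))
    return "\n".join(lines) + "\n"
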