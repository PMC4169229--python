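"""FST evaluation: categorised insertion-site predictions (1-to-N).

One FST can legitimately point at several genomic loci — paralogous
copies of the flank, or two genuinely different insertions read into one
"composite" FST. Each hit-derived prediction is categorised by e-value:

* category 0 — the single best hit of the FST, if its e-value < 1e-3;
* category 2 — the best hit when its e-value is 1e-3 or worse;
* category 1 — further hits with e-value < 1e-3, at most 3 per FST
  region, and never more than a factor 1e10 worse than the region best.

Hits whose query intervals overlap by at least 30 bp form one "region"
of the FST; distinct regions are evaluated independently so composite
FSTs yield predictions for each of their insertions. Predicted sites
closer than 1000 bp are one insertion and are merged, keeping the
better-supported hit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from . import config
from .genome import Genome, GenomicInterval
from .kmer_index import KmerIndex
from .local_search import LocalHit, search
from .simulate import FST

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class FSTRegion:
    """Maximal set of hits covering one part of the FST sequence."""

    fst_id: str
    query_start: int
    query_end: int


@dataclass(frozen=True)
class InsertionPrediction:
    line_id: str
    fst_id: str
    region_index: int
    position: GenomicInterval      # width-1, T-DNA-proximal end of the hit
    category: int                  # 0, 1 or 2
    hit: LocalHit

    @property
    def evalue(self) -> float:
        return self.hit.evalue


def _query_overlap(a: LocalHit, b: LocalHit) -> int:
    return min(a.query_end, b.query_end) - max(a.query_start, b.query_start)


def segment_regions(hits: list[LocalHit], fst_id: str = "",
                    min_overlap: int = config.REGION_OVERLAP
                    ) -> list[tuple[FSTRegion, list[LocalHit]]]:
    """Partition hits of one FST into regions by transitive query overlap.

    Hits whose query intervals overlap by >= ``min_overlap`` bp describe
    the same stretch of the FST and belong to one region; regions are
    the connected components of that relation, reported in query order.
    """
    if not hits:
        return []
    parent = list(range(len(hits)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(len(hits)):
        for j in range(i + 1, len(hits)):
            if _query_overlap(hits[i], hits[j]) >= min_overlap:
                parent[find(i)] = find(j)

    groups: dict[int, list[LocalHit]] = {}
    for i, h in enumerate(hits):
        groups.setdefault(find(i), []).append(h)
    regions = []
    for members in groups.values():
        qs = min(h.query_start for h in members)
        qe = max(h.query_end for h in members)
        regions.append((FSTRegion(fst_id, qs, qe), members))
    regions.sort(key=lambda r: (r[0].query_start, r[0].query_end))
    return regions


def predicted_position(hit: LocalHit) -> GenomicInterval:
    """Genome coordinate adjacent to the T-DNA side of the hit.

    FSTs read from the junction into the genome, so the T-DNA-proximal
    terminus is the hit's low query offset; on a minus-strand hit that
    offset aligns to the high end of the subject interval.
    """
    if hit.strand == "+":
        pos = hit.subject.start
    else:
        pos = hit.subject.end - 1
    return GenomicInterval(hit.subject.chrom, pos, pos + 1)


def predict(fst: FST, genome: Genome, index: KmerIndex,
            evalue_cutoff: float = 10.0,
            min_hit_len: int = config.FST_MIN_HIT_LEN
            ) -> list[InsertionPrediction]:
    """Categorised insertion predictions for one FST (empty if no hits)."""
    hits = search(fst.sequence, genome, index,
                  evalue_cutoff=evalue_cutoff, min_hit_len=min_hit_len)
    if not hits:
        log.info("FST %s: no hits", fst.id)
        return []

    best = hits[0]          # deterministic: ties resolved by sort order
    best_cat = 0 if best.evalue < config.EVALUE_SIGNIFICANT else 2
    predictions = [InsertionPrediction(
        fst.line_id, fst.id, 0, predicted_position(best), best_cat, best)]

    regions = segment_regions(hits, fst.id)
    for ridx, (_, members) in enumerate(regions):
        region_best_e = min(h.evalue for h in members)
        extras = [h for h in members if h is not best
                  and h.evalue < config.EVALUE_SIGNIFICANT]
        extras.sort(key=LocalHit.sort_key)
        kept = 0
        for h in extras:
            if kept >= config.MAX_CAT1_PER_REGION:
                break
            if region_best_e > 0 and h.evalue > region_best_e * config.EVALUE_RATIO_LIMIT:
                continue
            predictions.append(InsertionPrediction(
                fst.line_id, fst.id, ridx, predicted_position(h), 1, h))
            kept += 1

    # fix the best hit's region index now that regions are known
    for ridx, (_, members) in enumerate(regions):
        if best in members:
            predictions[0] = InsertionPrediction(
                fst.line_id, fst.id, ridx, predicted_position(best),
                best_cat, best)
            break

    return merge_close_predictions(predictions)


def merge_close_predictions(predictions: list[InsertionPrediction],
                            distance: int = config.MERGE_DISTANCE
                            ) -> list[InsertionPrediction]:
    """Collapse predicted sites closer than ``distance`` bp into one.

    The better e-value (lower category on ties) represents the merged
    prediction, so a category-0 prediction always survives merging.
    """
    ordered = sorted(
        predictions,
        key=lambda p: (p.category, p.evalue, -p.hit.score,
                       p.position.chrom, p.position.start))
    kept: list[InsertionPrediction] = []
    for p in ordered:
        if any(k.position.chrom == p.position.chrom
               and abs(k.position.start - p.position.start) < distance
               for k in kept):
            continue
        kept.append(p)
    kept.sort(key=lambda p: (p.category, p.evalue,
                             p.position.chrom, p.position.start))
    return kept


def predict_all(fsts: list[FST], genome: Genome, index: KmerIndex
                ) -> list[InsertionPrediction]:
    out: list[InsertionPrediction] = []
    for fst in fsts:
        out.extend(predict(fst, genome, index))
    return out


def predictions_to_tsv(predictions: list[InsertionPrediction]) -> str:
    lines = ["line\tfst\tregion\tchrom\tposition1\tcategory\tevalue\tscore"]
    for p in predictions:
        lines.append("\t".join(map(str, [
            p.line_id, p.fst_id, p.region_index, p.position.chrom,
            p.position.start + 1, p.category,
            f"{p.evalue:.3e}", p.hit.score])))
    return "\n".join(lines) + "\n"
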