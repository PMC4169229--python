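"""Design orchestration: target zones, method selection, primer pairs,
amplimer and genotyping reports.

A design request names a target position; two target zones are laid out
at a configurable distance band left and right of it. Each zone is
independently probed against the genome: if it contains a sufficiently
long segment (>= 100 bp) with no hit elsewhere, the standard windowed
method designs there; otherwise the paralog-discriminating method is
used. The forward primer comes from the left zone on the plus strand,
the reverse primer from the right zone on the minus strand, so the two
3' ends face the target and the amplimer spans it — in a wild-type
template the pair yields an amplicon, while a T-DNA insertion between
them suppresses it, which is the genotyping readout.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

from . import config
from .fst_mapping import InsertionPrediction
from .genome import Genome, GenomicInterval, extract
from .kmer_index import KmerIndex
from .local_search import search
from .paralog_design import design_paralog
from .primer_core import PrimerCandidate
from .standard_design import DesignFailure, design_standard

log = logging.getLogger(__name__)


@dataclass
class DesignRequest:
    chrom: str
    position: int                 # 0-based internal coordinate
    min_dist: int = config.DEFAULT_MIN_DIST
    max_dist: int = config.DEFAULT_MAX_DIST
    target_tm: float = config.DEFAULT_TM
    n_pairs: int = 1

    def __post_init__(self) -> None:
        lo, hi = config.DIST_BOUNDS
        if not lo <= self.min_dist < self.max_dist <= hi:
            raise ValueError(
                f"distances must satisfy {lo} <= min < max <= {hi}; "
                f"got {self.min_dist}..{self.max_dist}")
        if self.max_dist - self.min_dist < config.MIN_RANGE_PER_SIDE:
            raise ValueError(
                f"range per side must be >= {config.MIN_RANGE_PER_SIDE} bp")
        tlo, thi = config.TM_BOUNDS
        if not tlo <= self.target_tm <= thi:
            raise ValueError(f"target Tm outside [{tlo}, {thi}]")
        if self.position < 0:
            raise ValueError("negative target position")

    @classmethod
    def from_1based(cls, chrom: str, position1: int, **kw) -> "DesignRequest":
        return cls(chrom, position1 - 1, **kw)


def choose_method(genome: Genome, index: KmerIndex, zone: GenomicInterval
                  ) -> tuple[str, GenomicInterval | None]:
    """Route a zone to the standard or the paralog design method.

    The zone is searched against the genome (cutoff 1e-5); self-hits are
    masked and the longest subsegment of the zone with no other hit is
    measured. At least 100 hit-free bp mean paralogy cannot interfere
    there and the standard method runs on that subsegment; otherwise the
    paralog method takes the zone.
    """
    zone_seq = extract(genome, GenomicInterval(zone.chrom, zone.start,
                                               zone.end, "+"))
    hits = search(zone_seq, genome, index,
                  evalue_cutoff=config.EVALUE_DESIGN,
                  min_hit_len=config.FST_MIN_HIT_LEN)
    covered: list[tuple[int, int]] = []
    for h in hits:
        if h.subject.overlaps(zone):
            continue
        covered.append((h.query_start, h.query_end))
    covered.sort()
    merged: list[list[int]] = []
    for s, e in covered:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])

    best_len, best_span = 0, None
    prev = 0
    for s, e in merged + [[len(zone_seq), len(zone_seq)]]:
        if s - prev > best_len:
            best_len, best_span = s - prev, (prev, s)
        prev = max(prev, e)
    if best_len >= config.MIN_UNIQUE_SEGMENT and best_span is not None:
        seg = GenomicInterval(zone.chrom, zone.start + best_span[0],
                              zone.start + best_span[1])
        return "standard", seg
    return "paralog", None


@dataclass
class AmplimerReport:
    request: DesignRequest
    forward: PrimerCandidate | DesignFailure
    reverse: PrimerCandidate | DesignFailure
    method_left: str
    method_right: str
    product_size: int | None = None
    spanned: list[InsertionPrediction] = field(default_factory=list)
    genotyping: list[dict] = field(default_factory=list)

    @property
    def complete(self) -> bool:
        return (isinstance(self.forward, PrimerCandidate)
                and isinstance(self.reverse, PrimerCandidate))

    def to_dict(self) -> dict:
        def primer_dict(p):
            if isinstance(p, DesignFailure):
                return {"failed": True, "reason": p.reason,
                        "diagnostics": p.diagnostics}
            s1, e1 = p.placement.to_1based()
            return {"sequence": p.sequence, "chrom": p.placement.chrom,
                    "start1": s1, "end1": e1, "strand": p.strand,
                    "three_prime1": p.three_prime + 1,
                    "tm": round(p.tm, 2), "gc": round(p.gc, 2),
                    "points": p.total_points,
                    "mismatch_points": p.mismatch_points,
                    "end12_hits": p.end12_hits}

        return {
            "schema_version": config.REPORT_SCHEMA_VERSION,
            "target": {"chrom": self.request.chrom,
                       "position1": self.request.position + 1},
            "parameters": {"min_dist": self.request.min_dist,
                           "max_dist": self.request.max_dist,
                           "target_tm": self.request.target_tm},
            "method": {"left": self.method_left, "right": self.method_right},
            "forward": primer_dict(self.forward),
            "reverse": primer_dict(self.reverse),
            "product_size": self.product_size,
            "spanned_predictions": [
                {"line": p.line_id, "fst": p.fst_id,
                 "chrom": p.position.chrom,
                 "position1": p.position.start + 1,
                 "category": p.category} for p in self.spanned],
            "genotyping": self.genotyping,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n"


def _zones(req: DesignRequest, genome: Genome
           ) -> tuple[GenomicInterval, GenomicInterval]:
    chrom_len = genome.lengths[req.chrom]
    t = req.position
    left = GenomicInterval(req.chrom,
                           max(0, t - req.max_dist),
                           max(1, t - req.min_dist))
    right_start = min(chrom_len - 1, t + req.min_dist + 1)
    right = GenomicInterval(req.chrom, right_start,
                            min(chrom_len, t + req.max_dist + 1))
    if left.start != t - req.max_dist or right.end != t + req.max_dist + 1:
        log.warning("target zones truncated at chromosome ends")
    return left, right


def design_pair(req: DesignRequest, genome: Genome, index: KmerIndex,
                predictions: list[InsertionPrediction] | None = None,
                exclude: list[PrimerCandidate] | None = None,
                border_primer: str | None = None) -> AmplimerReport:
    """One forward/reverse pair around the target, with the amplimer
    report (product size, spanned insertion predictions, genotyping
    combinations)."""
    if req.chrom not in genome:
        raise KeyError(f"unknown chromosome {req.chrom!r}")
    left, right = _zones(req, genome)

    primers: list[PrimerCandidate | DesignFailure] = []
    methods: list[str] = []
    for zone, orientation in ((left, "forward"), (right, "reverse")):
        method, segment = choose_method(genome, index, zone)
        methods.append(method)
        if method == "standard":
            result = design_standard(genome, index, zone, orientation,
                                     req.target_tm, exclude=exclude,
                                     unique_segment=segment)
        else:
            result = design_paralog(genome, index, zone, orientation,
                                    req.target_tm, exclude=exclude)
            if isinstance(result, DesignFailure):
                # degenerate: hits vanished below the paralog length floor
                result = design_standard(genome, index, zone, orientation,
                                         req.target_tm, exclude=exclude)
        primers.append(result)
        if isinstance(result, DesignFailure):
            log.warning("%s design failed in %s zone: %s",
                        method, orientation, result.reason)

    report = AmplimerReport(req, primers[0], primers[1],
                            methods[0], methods[1])
    if report.complete:
        fwd, rev = report.forward, report.reverse
        # amplimer span on the reference: forward 5' end to reverse 5' end
        report.product_size = rev.placement.end - fwd.placement.start
        if predictions:
            report.spanned = [
                p for p in predictions
                if p.position.chrom == req.chrom
                and fwd.three_prime < p.position.start < rev.three_prime]
        report.genotyping = _genotyping(report, border_primer)
    return report


def _genotyping(report: AmplimerReport, border_primer: str | None) -> list[dict]:
    combos = [{
        "assay": "wild-type allele",
        "primers": ["forward", "reverse"],
        "expected": f"amplicon of {report.product_size} bp from the "
                    "wt allele; no product when the insertion "
                    "interrupts the amplimer",
    }]
    if border_primer:
        combos.append({
            "assay": "insertion allele (left)",
            "primers": ["forward", "border"],
            "border_sequence": border_primer,
            "expected": "junction amplicon only when the T-DNA is present",
        })
        combos.append({
            "assay": "insertion allele (right)",
            "primers": ["border", "reverse"],
            "border_sequence": border_primer,
            "expected": "junction amplicon only when the T-DNA is present",
        })
    return combos


def design_pairs(req: DesignRequest, genome: Genome, index: KmerIndex,
                 predictions: list[InsertionPrediction] | None = None,
                 border_primer: str | None = None) -> list[AmplimerReport]:
    """``req.n_pairs`` pairwise-distinct primer pairs (prior primers are
    excluded from later designs)."""
    reports: list[AmplimerReport] = []
    exclude: list[PrimerCandidate] = []
    for _ in range(req.n_pairs):
        report = design_pair(req, genome, index, predictions=predictions,
                             exclude=exclude, border_primer=border_primer)
        reports.append(report)
        if not report.complete:
            break
        exclude.extend([report.forward, report.reverse])
    return reports


def reports_to_tsv(reports: list[AmplimerReport]) -> str:
    header = ("pair\trole\tmethod\tsequence\tchrom\tstart1\tend1\tstrand\t"
              "tm\tgc\tpoints\tend12_hits\tproduct_size")
    rows = [header]
    for i, rep in enumerate(reports, start=1):
        for role, primer, method in (("forward", rep.forward, rep.method_left),
                                     ("reverse", rep.reverse, rep.method_right)):
            if isinstance(primer, DesignFailure):
                rows.append(f"{i}\t{role}\t{method}\tFAILED:{primer.reason}"
                            "\t.\t.\t.\t.\t.\t.\t.\t.\t.")
                continue
            s1, e1 = primer.placement.to_1based()
            rows.append("\t".join(map(str, [
                i, role, method, primer.sequence, primer.placement.chrom,
                s1, e1, primer.strand, f"{primer.tm:.2f}",
                f"{primer.gc:.1f}", primer.total_points, primer.end12_hits,
                rep.product_size if rep.product_size is not None else "."])))
    return "\n".join(rows) + "\n"
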