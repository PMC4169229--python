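"""Windowed, temperature-stepping primer design for target zones that
contain a unique segment.

The zone (or, first, its unique subsegment) is divided into overlapping
windows; within each window candidate primers are generated at the
requested melting temperature and then at temperatures stepped by 0.4degC
up to +-1.2degC. Design finishes as soon as a primer whose 3'-terminal
12-mer occurs exactly once in the genome is found; otherwise the whole
zone is retried with larger windows, and failing that the candidate with
the fewest 12-mer hits over the entire run is returned.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from . import config
from .genome import Genome, GenomicInterval
from .kmer_index import KmerIndex, end_hits
from .primer_core import PrimerCandidate, elongate_to_tm


@dataclass
class DesignFailure:
    """Explicit no-primer-found result with per-stage diagnostics."""

    reason: str
    diagnostics: dict = field(default_factory=dict)

    def __bool__(self) -> bool:
        return False


def windows(start: int, end: int, size: int,
            overlap: int = config.STD_OVERLAP) -> list[tuple[int, int]]:
    """Cover [start, end) with windows of >= ``size`` bp overlapping
    ``overlap`` bp; a short segment becomes a single window."""
    length = end - start
    if length <= size:
        return [(start, end)]
    step = size - overlap
    out = []
    s = start
    while s + size < end:
        out.append((s, s + size))
        s += step
    out.append((end - size, end))
    return out


def _window_candidates(genome: Genome, index: KmerIndex,
                       zone: GenomicInterval, ws: int, we: int,
                       strand: str, tm: float,
                       cache: dict) -> list[PrimerCandidate]:
    """All fully-passing candidates with a 3' end inside [ws, we)."""
    out = []
    for p in range(ws, we):
        key = (p, strand, round(tm, 1))
        if key in cache:
            cand = cache[key]
        else:
            cand = elongate_to_tm(genome, zone.chrom, p, strand, tm)
            if cand is not None:
                if (cand.placement.start < zone.start
                        or cand.placement.end > zone.end
                        or not cand.flags.all_pass()):
                    cand = None
                else:
                    cand.end12_hits = end_hits(index, cand.sequence)
            cache[key] = cand
        if cand is not None:
            out.append(cand)
    return out


def design_standard(genome: Genome, index: KmerIndex, zone: GenomicInterval,
                    orientation: str, target_tm: float,
                    exclude: list[PrimerCandidate] | None = None,
                    unique_segment: GenomicInterval | None = None
                    ) -> PrimerCandidate | DesignFailure:
    """Design one primer in ``zone``.

    ``orientation`` is "forward" (plus-strand primer, 3' end pointing
    right) or "reverse" (minus strand, 3' end pointing left).
    ``unique_segment`` is the hit-free part of the zone identified during
    method selection; phase 1 searches only there, phase 2 widens to the
    whole zone with larger windows. A unique (single 3' 12-mer hit)
    primer short-circuits the search; with no unique primer anywhere the
    least-redundant candidate is returned.
    """
    if orientation not in ("forward", "reverse"):
        raise ValueError(f"bad orientation {orientation!r}")
    strand = "+" if orientation == "forward" else "-"
    excluded = {c.key() for c in (exclude or [])}
    cache: dict = {}
    all_candidates: list[PrimerCandidate] = []
    n_windows = 0

    phases = []
    if unique_segment is not None and len(unique_segment) > 0:
        phases.append((unique_segment.start, unique_segment.end,
                       config.STD_WINDOW))
    phases.append((zone.start, zone.end, config.STD_WINDOW_FALLBACK))

    for seg_start, seg_end, size in phases:
        for ws, we in windows(seg_start, seg_end, size):
            n_windows += 1
            for step in config.TM_STEPS:
                cands = _window_candidates(
                    genome, index, zone, ws, we, strand,
                    target_tm + step, cache)
                unique = [c for c in cands
                          if c.end12_hits == 1 and c.key() not in excluded]
                if unique:
                    unique.sort(key=lambda c: (abs(c.tm - target_tm - step),
                                               c.placement.start))
                    return unique[0]
                all_candidates.extend(cands)

    usable = [c for c in all_candidates if c.key() not in excluded]
    if not usable:
        return DesignFailure(
            "no primer found",
            {"windows_examined": n_windows,
             "candidates_seen": len(all_candidates),
             "all_excluded": bool(all_candidates)})
    usable.sort(key=lambda c: (c.end12_hits, abs(c.tm - target_tm),
                               c.placement.start))
    return usable[0]
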