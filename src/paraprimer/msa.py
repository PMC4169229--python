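"""Windowed progressive multiple alignment of a target zone with its
paralogous counterparts.

The zone is split into overlapping windows (~220 bp, 30 bp overlap) to
bound dynamic-programming cost; each window is aligned progressively
(pairwise identities -> UPGMA guide tree -> profile-profile global DP)
and the windows are stitched back on the reference coordinate system,
earlier windows taking precedence in overlaps. The product is a
per-column mismatch annotation: how many paralog rows differ from the
zone at that column, gaps counting as mismatches (a gap disrupts
annealing just as a substitution does).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio import Align
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from . import config
from ._dp import nw_profile

# symbol codes: A C G T N -
_SYM = {c: i for i, c in enumerate("ACGTN-")}
_PAIR = np.full((6, 6), -1.0)
for _i in range(4):
    _PAIR[_i, _i] = 1.0          # base identity
_PAIR[4, :] = _PAIR[:, 4] = -1.0  # N matches nothing
_PAIR[5, :] = _PAIR[:, 5] = -2.0  # base vs gap
_PAIR[5, 5] = 0.0                 # gap vs gap
_GAP_COL = _PAIR[:, 5].copy()


@dataclass
class ZoneAlignment:
    """Stitched alignment of the zone (row 0) with its paralogs."""

    rows: list[str]
    mismatch_counts: list[int]
    # per column, the zone offset of the reference base (None on ref gaps)
    column_ref: list[int | None]
    low_confidence: set[int] = field(default_factory=set)  # paralog indices

    @property
    def n_paralogs(self) -> int:
        return len(self.rows) - 1

    def reference_columns(self) -> dict[int, int]:
        """zone offset -> column index (reference bases only)."""
        return {ref: col for col, ref in enumerate(self.column_ref)
                if ref is not None}


def _identity_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -2.0
    aligner.extend_gap_score = -2.0
    return aligner


_ID_ALIGNER = _identity_aligner()


def _pairwise_identity(a: str, b: str) -> float:
    if not a or not b:
        return 0.0
    aln = _ID_ALIGNER.align(a, b)[0]
    counts = aln.counts()
    cols = counts.identities + counts.mismatches + counts.gaps
    return counts.identities / cols if cols else 0.0


def _counts_matrix(rows: list[str]) -> np.ndarray:
    length = len(rows[0])
    C = np.zeros((length, 6))
    for row in rows:
        for i, ch in enumerate(row):
            C[i, _SYM[ch]] += 1
    return C


def _merge_profiles(a: list[str], b: list[str]) -> tuple[list[str], list[str]]:
    """Align two gapped profiles; returns both with gap columns inserted."""
    CA = _counts_matrix(a)
    CB = _counts_matrix(b)
    S = CA @ _PAIR @ CB.T
    gap_a = CA @ _GAP_COL * len(b)
    gap_b = CB @ _GAP_COL * len(a)
    n_ops, ops = nw_profile(S, np.asarray(gap_a), np.asarray(gap_b))
    new_a = [[] for _ in a]
    new_b = [[] for _ in b]
    ia = len(a[0])
    ib = len(b[0])
    for k in range(n_ops):       # ops run 3'-to-5'
        op = ops[k]
        if op in (0, 1):
            ia -= 1
        if op in (0, 2):
            ib -= 1
        for rows, out, idx, take in ((a, new_a, ia, op in (0, 1)),
                                     (b, new_b, ib, op in (0, 2))):
            for r, col in zip(rows, out):
                col.append(r[idx] if take else "-")
    return (["".join(reversed(c)) for c in new_a],
            ["".join(reversed(c)) for c in new_b])


def _progressive_align(rows: list[str]) -> list[str]:
    """Progressive MSA of raw sequences; result preserves input row order."""
    n = len(rows)
    if n == 1:
        return list(rows)
    if n == 2:
        a, b = _merge_profiles([rows[0]], [rows[1]])
        return [a[0], b[0]]
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dist[i, j] = dist[j, i] = 1.0 - _pairwise_identity(rows[i], rows[j])
    tree = linkage(squareform(dist, checks=False), method="average")
    profiles: dict[int, tuple[list[int], list[str]]] = {
        i: ([i], [rows[i]]) for i in range(n)}
    next_id = n
    for a_id, b_id, _, _ in tree:
        ia, pa = profiles.pop(int(a_id))
        ib, pb = profiles.pop(int(b_id))
        na, nb = _merge_profiles(pa, pb)
        profiles[next_id] = (ia + ib, na + nb)
        next_id += 1
    order, aligned = profiles.popitem()[1]
    result = [""] * n
    for idx, row in zip(order, aligned):
        result[idx] = row
    return result


def _windows(length: int) -> list[tuple[int, int]]:
    """~220 bp windows overlapping 30 bp, covering [0, length)."""
    size, overlap = config.MSA_WINDOW, config.MSA_OVERLAP
    if length <= size:
        return [(0, length)]
    step = size - overlap
    out = []
    s = 0
    while True:
        e = min(s + size, length)
        out.append((s, e))
        if e >= length:
            break
        s += step
    # avoid a stub window: fold a short final window into the previous one
    if len(out) >= 2 and out[-1][1] - out[-1][0] < 2 * overlap:
        out[-2] = (out[-2][0], out[-1][1])
        out.pop()
    return out


def align_zone(zone_seq: str, paralog_seqs: list[str]) -> ZoneAlignment:
    """Windowed progressive alignment and per-column mismatch counts.

    Paralog sequences must already be elongated to the zone length
    (shorter rows are padded with N, which counts as mismatching).
    """
    if not paralog_seqs:
        raise ValueError("at least one paralog sequence required")
    L = len(zone_seq)
    padded = [(p[:L] + "N" * (L - len(p))) if len(p) < L else p[:L]
              for p in paralog_seqs]

    all_rows: list[list[str]] = [[] for _ in range(len(padded) + 1)]
    all_counts: list[int] = []
    all_ref: list[int | None] = []
    low_confidence: set[int] = set()
    next_ref = 0

    for ws, we in _windows(L):
        rows = [zone_seq[ws:we]] + [p[ws:we] for p in padded]
        aligned = _progressive_align(rows)
        ref = aligned[0]
        # per-row identity vs reference within the window
        for pi, row in enumerate(aligned[1:]):
            cols = sum(1 for r, c in zip(ref, row) if not (r == c == "-"))
            same = sum(1 for r, c in zip(ref, row) if r == c and r != "-")
            if cols and same / cols < 0.5:
                low_confidence.add(pi)

        ref_offset = ws
        started = False
        for col in range(len(ref)):
            if ref[col] != "-":
                coord = ref_offset
                ref_offset += 1
            else:
                coord = None
            if coord is not None:
                if coord < next_ref:
                    continue
                started = True
                next_ref = coord + 1
            elif not started:
                continue
            chars = [row[col] for row in aligned]
            mismatches = sum(
                1 for c in chars[1:] if c != chars[0] or c in "-N")
            for row_out, ch in zip(all_rows, chars):
                row_out.append(ch)
            all_counts.append(mismatches)
            all_ref.append(coord)

    return ZoneAlignment(
        rows=["".join(r) for r in all_rows],
        mismatch_counts=all_counts,
        column_ref=all_ref,
        low_confidence=low_confidence)
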