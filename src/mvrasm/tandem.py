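"""Tandem-array detection and wraparound dynamic programming.

Two jobs live here: segmenting a known array against a given repeat unit
(wraparound DP, the same primitive TRF-style tools use to count copies),
and de-novo detection of tandem arrays in a sequence via k-mer spacing
periodicity followed by consensus refinement.  Both the bait masker and
the allele decoder build on these.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .align import seq_to_u8


@dataclass
class TandemRepeatAnnotation:
    """A detected tandem array.

    interval is 0-based half-open on the scanned sequence; copy_number is
    fractional (array length / period, 1 decimal); mean_unit_identity is
    the mean percent identity of complete units to the consensus.
    """

    interval: tuple[int, int]
    period: int
    consensus_unit: str
    copy_number: float
    mean_unit_identity: float

    @property
    def length(self) -> int:
        return self.interval[1] - self.interval[0]


@njit(cache=True)
def _wraparound_dp(seq, unit):
    """Wraparound edit-distance DP of ``seq`` against ``unit`` repeated.

    State (i, j): seq[0:i] consumed, next unit position to align is j
    (phase).  The alignment starts at phase 0 and may end mid-unit for
    free (terminal partial units carry no penalty for the unmatched unit
    remainder).  Moves into state (i, j) with jp = (j-1) mod p:
    0 = diag from (i-1, jp), consuming seq[i-1] vs unit[jp];
    1 = up from (i-1, j), seq[i-1] inserted;
    2 = left from (i, jp), unit[jp] deleted.
    Returns (cost, ptr, end_phase).
    """
    n = seq.size
    p = unit.size
    INF = 1 << 30
    D = np.full((n + 1, p), INF, dtype=np.int32)
    ptr = np.full((n + 1, p), -1, dtype=np.int8)
    D[0, 0] = 0
    for j in range(1, p):
        D[0, j] = D[0, j - 1] + 1
        ptr[0, j] = 2
    for i in range(1, n + 1):
        # two relaxation passes handle the wraparound left edge (p-1 -> 0)
        for _ in range(2):
            for j in range(p):
                jp = j - 1 if j > 0 else p - 1
                sub = 0 if seq[i - 1] == unit[jp] else 1
                cand = D[i - 1, jp] + sub
                if cand < D[i, j]:
                    D[i, j] = cand
                    ptr[i, j] = 0
                cand = D[i - 1, j] + 1
                if cand < D[i, j]:
                    D[i, j] = cand
                    ptr[i, j] = 1
                cand = D[i, jp] + 1
                if cand < D[i, j]:
                    D[i, j] = cand
                    ptr[i, j] = 2
    best = INF
    bj = 0
    for j in range(p):
        if D[n, j] < best:
            best = D[n, j]
            bj = j
    return best, ptr, bj


def wraparound_segment(seq: str, unit: str):
    """Segment ``seq`` into consecutive unit copies against ``unit``.

    Returns (total_cost, segments) where segments is an ordered list of
    (start, end, is_complete) half-open intervals tiling [0, len(seq)).
    The final segment is partial (is_complete False) when the alignment
    ends mid-unit.  Zero-length segments (fully deleted units) are
    dropped.
    """
    s = seq_to_u8(seq)
    u = seq_to_u8(unit)
    if s.size == 0:
        return 0, []
    cost, ptr, bj = _wraparound_dp(s, u)
    p = u.size
    n = s.size
    # walk back, recording seq positions at which the phase is 0
    # (unit start positions)
    starts = set()
    i, j = n, bj
    if j == 0:
        starts.add(i)
    while i > 0 or j != 0:
        move = ptr[i, j]
        jp = j - 1 if j > 0 else p - 1
        if move == 0:
            i -= 1
            j = jp
        elif move == 1:
            i -= 1
        elif move == 2:
            j = jp
        else:  # pragma: no cover - DP always leaves a pointer
            break
        if j == 0:
            starts.add(i)
    bs = sorted(starts)
    ends_complete = bs[-1] == n
    if not ends_complete:
        bs.append(n)
    segments = []
    for idx in range(len(bs) - 1):
        start, end = bs[idx], bs[idx + 1]
        if end <= start:
            continue
        complete = ends_complete or idx < len(bs) - 2
        segments.append((start, end, complete))
    return int(cost), segments


def _unit_distance(a: str, b: str) -> int:
    """Plain Levenshtein via edlib (falls back to DP for empty input)."""
    if not a or not b:
        return max(len(a), len(b))
    import edlib
    return edlib.align(a, b, task="distance")["editDistance"]


def _consensus_from_segments(seq: str, segments, period: int) -> str:
    """Plurality base call per unit column over complete unit copies."""
    votes = np.zeros((period, 4), dtype=np.int64)
    for start, end, complete in segments:
        if not complete or end - start != period:
            continue  # indel-bearing copies are skipped for speed
        u = seq_to_u8(seq[start:end])
        for col in range(period):
            if u[col] < 4:
                votes[col, u[col]] += 1
    if votes.sum() == 0:
        return ""
    return "".join("ACGT"[int(np.argmax(votes[c]))] for c in range(period))


def _smallest_period(unit: str) -> str:
    """Reduce a consensus to its smallest exactly-repeating sub-unit."""
    p = len(unit)
    for d in range(1, p):
        if p % d == 0 and unit == unit[:d] * (p // d):
            return unit[:d]
    return unit


def _reduced_period(unit: str, tol_frac: float = 0.15) -> str | None:
    """Smallest sub-unit that near-periodically tiles the consensus.

    Variant-rich arrays seed candidate periods at harmonics (a k-mer
    containing a variant base recurs at a multiple of the true period);
    a consensus whose plurality sub-unit tiling explains it within
    ``tol_frac`` mismatches is reduced to that sub-unit.
    """
    p = len(unit)
    for d in range(1, p):
        if p % d != 0:
            continue
        chunks = [unit[i:i + d] for i in range(0, p, d)]
        cons = "".join(
            max("ACGT", key=lambda b: sum(c[j] == b for c in chunks))
            for j in range(d))
        mism = sum(unit[i] != cons[i % d] for i in range(p))
        if mism <= tol_frac * p:
            return cons
    return None


def _xdrop_boundary(seq: str, pattern, anchor: int, direction: int,
                    mismatch_penalty: int = 3, xdrop: int = 9) -> int:
    """Maximal-scoring extension of the periodic pattern from ``anchor``.

    ``pattern(i)`` gives the expected base at sequence position i.  Walks
    base by base (+1 match, -penalty mismatch) until the running score
    falls ``xdrop`` below its maximum; returns the argmax position (the
    outermost base included going left, or one past it going right).
    """
    n = len(seq)
    score = 0
    best = 0
    best_pos = anchor if direction < 0 else anchor
    i = anchor - 1 if direction < 0 else anchor
    while 0 <= i < n:
        score += 1 if seq[i] == pattern(i) else -mismatch_penalty
        if score > best:
            best = score
            best_pos = i if direction < 0 else i + 1
        if score < best - xdrop:
            break
        i += direction
    return best_pos


def _refine_region(seq: str, start: int, end: int, period: int,
                   min_unit_identity: float, max_unit_distance=None,
                   min_period: int = 1):
    """Polish a candidate array: infer consensus, set boundaries.

    The consensus is learned by iterated wraparound segmentation and
    plurality vote; boundaries are then set phase-free by an X-drop walk
    of the periodic pattern out of an interior anchor, a tolerant
    unit-level extension (robust to indel-bearing edge units), and a
    final bounded base-level extension.  On substitution-only arrays with
    non-pattern-continuing flanks, boundaries are recovered to within a
    couple of bases regardless of the (arbitrary) consensus phase.
    """
    n = len(seq)
    core = seq[start:end]
    if len(core) < period:
        return None
    # seed the consensus from the middle of the candidate window: its
    # edges may overhang into flank sequence
    mid0 = (len(core) - period) // 2
    unit = core[mid0:mid0 + period]
    segments = None
    for _ in range(3):
        _, segments = wraparound_segment(core, unit)
        new_unit = _consensus_from_segments(core, segments, period)
        if not new_unit or new_unit == unit:
            break
        unit = new_unit
    if not unit:
        return None
    # a harmonic candidate period re-refines at its reduced sub-unit
    reduced = _reduced_period(unit)
    if reduced is not None and min_period <= len(reduced) < len(unit):
        ann = _refine_region(seq, start, end, len(reduced),
                             min_unit_identity, max_unit_distance, min_period)
        if ann is not None:
            return ann
    p = len(unit)
    tol = max_unit_distance if max_unit_distance is not None else max(1, p // 3)
    ext_tol = max(1, p // 4)

    # interior anchor: the complete-unit start closest to the core middle
    complete = [(s, e) for s, e, c in segments if c and e - s == p]
    if not complete:
        complete = [(s, e) for s, e, c in segments if c]
    if not complete:
        return None
    mid = len(core) // 2
    m = min(complete, key=lambda se: abs(se[0] - mid))[0] + start

    def pattern(i: int) -> str:
        return unit[(i - m) % p]

    lo = _xdrop_boundary(seq, pattern, m, -1)
    hi = _xdrop_boundary(seq, pattern, m, +1)

    # tolerant unit-level extension for indel-bearing edge copies
    while lo - p >= 0 and _unit_distance(seq[lo - p:lo], unit) <= ext_tol:
        lo -= p
    while hi + p <= n and _unit_distance(seq[hi:hi + p], unit) <= ext_tol:
        hi += p
    # bounded base-level adjustment: among small outward shifts d, keep
    # the one whose boundary p-window best matches the pattern (ties to
    # the smaller shift), so exact arrays keep exact boundaries while a
    # substituted outermost base costs at most a base or two
    def _window_mm(s: int) -> int:
        w = seq[s:s + p]
        return sum(w[j] != pattern(s + j) for j in range(p)) + (p - len(w))

    best_d, best_mm = 0, _window_mm(lo)
    for d in range(1, ext_tol + 1):
        if lo - d >= 0:
            mm = _window_mm(lo - d)
            if mm < best_mm:
                best_d, best_mm = d, mm
    lo -= best_d
    best_d, best_mm = 0, _window_mm(hi - p)
    for d in range(1, ext_tol + 1):
        if hi + d <= n:
            mm = _window_mm(hi + d - p)
            if mm < best_mm:
                best_d, best_mm = d, mm
    hi += best_d
    if hi - lo < p:
        return None

    # re-anchor the consensus phase at the detected start
    unit_anchored = "".join(pattern(lo + j) for j in range(p))
    _, segments = wraparound_segment(seq[lo:hi], unit_anchored)
    complete = [(s, e) for s, e, c in segments if c]
    if not complete:
        return None
    idents = [100.0 * (1.0 - _unit_distance(seq[lo + s:lo + e],
                                            unit_anchored) / p)
              for s, e in complete]
    mean_ident = float(np.mean(idents))
    if mean_ident < min_unit_identity:
        return None
    small = _smallest_period(unit_anchored)
    period_out = len(small)
    return TandemRepeatAnnotation(
        interval=(lo, hi),
        period=period_out,
        consensus_unit=small,
        copy_number=round((hi - lo) / period_out, 1),
        mean_unit_identity=round(mean_ident, 1),
    )


def detect_tandem_repeats(seq: str, min_period: int = 4, max_period: int = 200,
                          min_copies: float = 3.0,
                          min_unit_identity: float = 75.0,
                          spacing_k: int = 5) -> list[TandemRepeatAnnotation]:
    """Find tandem arrays by k-mer spacing periodicity, then refine.

    Positions whose k-mer recurs at a short, locally consistent spacing
    seed candidate regions; each candidate's period is the modal spacing
    and its boundaries/consensus are refined by wraparound DP.
    """
    n = len(seq)
    if n < min_period * 2:
        return []
    codes = seq_to_u8(seq)
    k = spacing_k
    mask = (1 << (2 * k)) - 1
    last: dict[int, int] = {}
    spacing = np.zeros(n, dtype=np.int64)
    h = 0
    run = 0
    for i in range(n):
        c = int(codes[i])
        if c < 4:
            h = ((h << 2) | c) & mask
            run += 1
        else:
            run = 0
            h = 0
        if run >= k:
            pos = i - k + 1
            prev = last.get(h)
            if prev is not None:
                d = pos - prev
                if min_period <= d <= max_period:
                    spacing[pos] = d
            last[h] = pos

    # per-period clustering: positions sharing one spacing value, with
    # gaps <= 2 periods, form a candidate run (random recurrences rarely
    # sustain a constant spacing long enough to pass min_copies)
    flagged = np.nonzero(spacing)[0]
    annotations: list[TandemRepeatAnnotation] = []
    if flagged.size == 0:
        return annotations
    for period in np.unique(spacing[flagged]):
        period = int(period)
        members = flagged[spacing[flagged] == period]
        cluster_start = 0
        for idx in range(1, members.size + 1):
            if idx == members.size or members[idx] - members[idx - 1] > 2 * period:
                run = members[cluster_start:idx]
                cluster_start = idx
                lo = max(0, int(run[0]) - period)
                hi = min(n, int(run[-1]) + k)
                if hi - lo < period * min_copies or hi - lo < period + k:
                    continue
                ann = _refine_region(seq, lo, hi, period, min_unit_identity,
                                     min_period=min_period)
                if ann is not None and ann.copy_number >= min_copies:
                    annotations.append(ann)

    # merge overlapping annotations, preferring the longer one, then the
    # smaller period (harmonics of the same array resolve to the true one)
    annotations.sort(key=lambda a: (a.interval[0], -a.length, a.period))
    merged: list[TandemRepeatAnnotation] = []
    for ann in annotations:
        if merged and ann.interval[0] < merged[-1].interval[1]:
            prev = merged[-1]
            if (ann.length, -ann.period) > (prev.length, -prev.period):
                merged[-1] = ann
            continue
        merged.append(ann)
    return merged
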