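"""Seed-and-extend banded local alignment with affine gap penalties.

This is the single alignment engine used throughout the package: read
recruitment against the bait, read-vs-read overlap detection, consensus
polishing and contig-vs-reference selection all call into it.  The strategy
is the classic long-read one: exact k-mer seeds, co-linear chaining, then a
banded affine-gap Smith-Waterman extension whose band follows the chained
seed diagonals (so large net indel drift between distant anchors stays
inside the band).

Scores follow the convention that the first base of a gap costs
``gap_open`` and every further base ``gap_extend`` (a length-L gap scores
``gap_open + (L-1) * gap_extend``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

_COMP = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")

#: numeric codes for edit-path operations
OP_MATCH, OP_MISMATCH, OP_INS, OP_DEL = 0, 1, 2, 3
_OP_CHARS = "=XID"


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (case preserved)."""
    return seq.translate(_COMP)[::-1]


def seq_to_u8(seq: str) -> np.ndarray:
    """Encode A/C/G/T as 0..3, anything else (incl. N) as 4."""
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    out = np.full(arr.size, 4, dtype=np.uint8)
    for i, base in enumerate(b"ACGT"):
        out[arr == base] = i
    return out


@dataclass(frozen=True)
class AlignScoring:
    """Alignment scores and seeding parameters.

    match must be positive; mismatch and gap penalties non-positive.
    ``seed_length`` is the exact-match k-mer size used for seeding and
    ``band_width`` the half-width of the extension band around the chained
    seed diagonal.
    """

    match: int = 1
    mismatch: int = -1
    gap_open: int = -2
    gap_extend: int = -1
    seed_length: int = 13
    band_width: int = 100

    def __post_init__(self):
        if self.match <= 0:
            raise ValueError("match score must be > 0")
        if self.mismatch > 0 or self.gap_open > 0 or self.gap_extend > 0:
            raise ValueError("penalties must be <= 0")
        if self.seed_length < 4 or self.band_width < 1:
            raise ValueError("bad seed_length/band_width")


@dataclass
class Alignment:
    """A local alignment of a query against a target.

    Intervals are 0-based half-open on the respective sequences as passed
    in; ``cigar`` is run-length encoded over the ops =, X, I (query
    insertion) and D (query deletion / target base skipped).
    """

    score: int
    q_start: int
    q_end: int
    t_start: int
    t_end: int
    cigar: str
    n_match: int
    n_cols: int

    @property
    def identity(self) -> float:
        """Percent matches over alignment columns (gaps included)."""
        return 100.0 * self.n_match / self.n_cols if self.n_cols else 0.0


def cigar_ops(cigar: str):
    """Yield (length, op_char) pairs from a run-length CIGAR string."""
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            yield int(num), ch
            num = ""


def ops_to_cigar(ops: np.ndarray) -> str:
    """Run-length encode an array of numeric op codes."""
    parts = []
    i = 0
    n = ops.size
    while i < n:
        j = i
        while j < n and ops[j] == ops[i]:
            j += 1
        parts.append(f"{j - i}{_OP_CHARS[ops[i]]}")
        i = j
    return "".join(parts)


def score_cigar(cigar: str, scoring: AlignScoring) -> int:
    """Score an edit path under ``scoring`` (affine gap convention above)."""
    total = 0
    for length, op in cigar_ops(cigar):
        if op in "=M":
            total += length * scoring.match
        elif op == "X":
            total += length * scoring.mismatch
        elif op in "ID":
            total += scoring.gap_open + (length - 1) * scoring.gap_extend
        else:
            raise ValueError(f"unknown cigar op {op!r}")
    return total


# ---------------------------------------------------------------------------
# k-mer index and seeding


class KmerIndex:
    """Exact k-mer index over a target sequence.

    With ``respect_case=True``, windows containing any lowercase
    (soft-masked) base are excluded, so seeding only lands in unmasked
    sequence while extension may still cross masked regions.
    """

    def __init__(self, seq: str, k: int, respect_case: bool = False):
        self.k = k
        self.length = len(seq)
        codes = seq_to_u8(seq)
        valid = codes < 4
        if respect_case:
            upper = np.frombuffer(seq.encode("ascii"), dtype=np.uint8) < 97
            valid &= upper
        self._index: dict[int, list[int]] = {}
        if self.length < k:
            return
        # rolling 2-bit hash; reset across invalid windows
        mask = (1 << (2 * k)) - 1
        h = 0
        run = 0
        for i in range(self.length):
            if valid[i]:
                h = ((h << 2) | int(codes[i])) & mask
                run += 1
            else:
                run = 0
                h = 0
            if run >= k:
                self._index.setdefault(h, []).append(i - k + 1)

    def lookup(self, code: int) -> list[int]:
        return self._index.get(code, [])

    def seeds(self, query: str, max_per_kmer: int = 8) -> np.ndarray:
        """Anchors (qpos, tpos) of exact k-mer matches, sorted by qpos.

        K-mers with more than ``max_per_kmer`` target hits are dropped:
        in near-periodic arrays the windows that avoid all distinguishing
        bases match tens of repeat units and would drown the informative
        anchors.
        """
        return self._seeds(query, max_per_kmer)

    def _seeds(self, query: str, max_per_kmer: int) -> np.ndarray:
        """Anchors (qpos, tpos) of exact k-mer matches, sorted by qpos."""
        k = self.k
        codes = seq_to_u8(query)
        anchors = []
        mask = (1 << (2 * k)) - 1
        h = 0
        run = 0
        for i in range(len(query)):
            c = int(codes[i])
            if c < 4:
                h = ((h << 2) | c) & mask
                run += 1
            else:
                run = 0
                h = 0
            if run >= k:
                hits = self._index.get(h)
                if hits and len(hits) <= max_per_kmer:
                    q = i - k + 1
                    for t in hits:
                        anchors.append((q, t))
        if not anchors:
            return np.empty((0, 2), dtype=np.int64)
        return np.asarray(anchors, dtype=np.int64)


@njit(cache=True)
def _chain_dp(qpos, tpos, max_gap, max_drift):
    """Best co-linear chain over anchors (sorted by qpos, then tpos).

    Returns indices of chain members in query order.
    """
    n = qpos.size
    f = np.ones(n, dtype=np.int64)
    back = np.full(n, -1, dtype=np.int64)
    for i in range(n):
        di = qpos[i] - tpos[i]
        # look back over a window; anchors are dense so a bounded window
        # keeps this near-linear without hurting chain quality
        j0 = max(0, i - 128)
        for j in range(i - 1, j0 - 1, -1):
            if qpos[j] >= qpos[i] or tpos[j] >= tpos[i]:
                continue
            if qpos[i] - qpos[j] > max_gap:
                break
            dj = qpos[j] - tpos[j]
            drift = di - dj
            if drift < 0:
                drift = -drift
            # indel drift accumulates with distance; a tight bound for
            # nearby anchors rejects repeat-induced register jumps
            lim = 25 + (qpos[i] - qpos[j]) // 10
            if lim > max_drift:
                lim = max_drift
            if drift > lim:
                continue
            cand = f[j] + 1
            if cand > f[i]:
                f[i] = cand
                back[i] = j
    best = 0
    for i in range(1, n):
        if f[i] > f[best]:
            best = i
    # backtrack
    count = 0
    i = best
    while i >= 0:
        count += 1
        i = back[i]
    out = np.empty(count, dtype=np.int64)
    i = best
    p = count - 1
    while i >= 0:
        out[p] = i
        p -= 1
        i = back[i]
    return out


def chain_anchors(anchors: np.ndarray, max_gap: int = 20000,
                  max_drift: int = 1000) -> np.ndarray:
    """Select the best co-linear anchor chain; returns (m, 2) array."""
    if anchors.shape[0] == 0:
        return anchors
    order = np.lexsort((anchors[:, 1], anchors[:, 0]))
    a = anchors[order]
    idx = _chain_dp(np.ascontiguousarray(a[:, 0]),
                    np.ascontiguousarray(a[:, 1]), max_gap, max_drift)
    return a[idx]


def _band_centers(chain: np.ndarray, m: int, n: int) -> np.ndarray:
    """Per-query-row target band centre, interpolated through the chain."""
    centers = np.empty(m + 1, dtype=np.int64)
    q = chain[:, 0]
    t = chain[:, 1]
    rows = np.arange(m + 1)
    centers[:] = np.interp(rows, q, t).astype(np.int64)
    # extrapolate with slope 1 beyond the terminal anchors
    first_q, first_t = int(q[0]), int(t[0])
    last_q, last_t = int(q[-1]), int(t[-1])
    left = rows < first_q
    centers[left] = first_t - (first_q - rows[left])
    right = rows > last_q
    centers[right] = last_t + (rows[right] - last_q)
    np.clip(centers, 0, n, out=centers)
    return centers


@njit(cache=True)
def _banded_sw(q, t, centers, W, match, mismatch, gap_open, gap_extend):
    """Banded affine-gap local DP.  Returns (score, bi, bj, ops_reversed).

    Rows follow the query; row i spans target columns
    [centers[i]-W, centers[i]+W].  Cells outside the band are -inf.
    """
    m = q.size
    n = t.size
    width = 2 * W + 1
    NEG = np.int32(-(10 ** 9) // 2)
    # rolling score rows; full pointer matrices for traceback
    # pH 0=local start, 1=diag, 2=fromE, 3=fromF; pE/pF 1 = gap extension
    h_prev = np.full(width, NEG, dtype=np.int32)
    h_cur = np.full(width, NEG, dtype=np.int32)
    e_cur = np.full(width, NEG, dtype=np.int32)  # gap consuming target (D)
    f_prev = np.full(width, NEG, dtype=np.int32)  # gap consuming query (I)
    f_cur = np.full(width, NEG, dtype=np.int32)
    pH = np.zeros((m + 1, width), dtype=np.uint8)
    pE = np.zeros((m + 1, width), dtype=np.uint8)
    pF = np.zeros((m + 1, width), dtype=np.uint8)

    best = np.int32(0)
    bi = -1
    bj = -1
    for i in range(0, m + 1):
        c = centers[i]
        off = c - W
        lo = off
        if lo < 0:
            lo = 0
        hi = c + W
        if hi > n:
            hi = n
        cprev = centers[i - 1] if i > 0 else 0
        offp = cprev - W
        for k in range(width):
            h_cur[k] = NEG
            e_cur[k] = NEG
            f_cur[k] = NEG
        if i == 0:
            for j in range(lo, hi + 1):
                h_cur[j - off] = 0
        else:
            for j in range(lo, hi + 1):
                k = j - off
                # previous-row offsets for columns j-1 (diag) and j (up)
                kd = (j - 1) - offp
                ku = j - offp
                h = np.int32(0)
                ph = np.uint8(0)
                # E: consume target base j — same row, col j-1
                kl = k - 1
                if j > lo and kl >= 0:
                    e_open = h_cur[kl] + gap_open
                    e_ext = e_cur[kl] + gap_extend
                    if e_ext > e_open:
                        e_cur[k] = e_ext
                        pE[i, k] = 1
                    else:
                        e_cur[k] = e_open
                        pE[i, k] = 0
                # F: consume query base i — previous row, col j
                if 0 <= ku < width:
                    f_open = h_prev[ku] + gap_open
                    f_ext = f_prev[ku] + gap_extend
                    if f_ext > f_open:
                        f_cur[k] = f_ext
                        pF[i, k] = 1
                    else:
                        f_cur[k] = f_open
                        pF[i, k] = 0
                # diagonal
                if j > 0 and 0 <= kd < width:
                    qc = q[i - 1]
                    tc = t[j - 1]
                    if qc == tc and qc < 4:
                        s = match
                    else:
                        s = mismatch
                    d = h_prev[kd] + s
                    if d > h:
                        h = d
                        ph = 1
                if e_cur[k] > h:
                    h = e_cur[k]
                    ph = 2
                if f_cur[k] > h:
                    h = f_cur[k]
                    ph = 3
                h_cur[k] = h
                pH[i, k] = ph
                if h > best:
                    best = h
                    bi = i
                    bj = j
        tmp = h_prev
        h_prev = h_cur
        h_cur = tmp
        tmp = f_prev
        f_prev = f_cur
        f_cur = tmp

    if bi < 0:
        return 0, 0, 0, np.empty(0, dtype=np.uint8)

    # traceback
    ops = np.empty(m + n + 2, dtype=np.uint8)
    nops = 0
    i = bi
    j = bj
    state = 0  # 0 = H
    while True:
        c = centers[i]
        k = j - (c - W)
        if state == 0:
            ph = pH[i, k]
            if ph == 0:
                break
            if ph == 1:
                if q[i - 1] == t[j - 1] and q[i - 1] < 4:
                    ops[nops] = 0
                else:
                    ops[nops] = 1
                nops += 1
                i -= 1
                j -= 1
            elif ph == 2:
                state = 1
            else:
                state = 2
        elif state == 1:  # in E: consume target (D)
            ext = pE[i, k]
            ops[nops] = 3
            nops += 1
            j -= 1
            if ext == 0:
                state = 0
        else:  # in F: consume query (I)
            ext = pF[i, k]
            ops[nops] = 2
            nops += 1
            i -= 1
            if ext == 0:
                state = 0
    return int(best), i, j, ops[:nops][::-1].copy()


def extend_alignment(query: str, target: str, chain: np.ndarray,
                     scoring: AlignScoring) -> Alignment | None:
    """Banded local extension through a seed chain."""
    qa = seq_to_u8(query)
    ta = seq_to_u8(target)
    centers = _band_centers(chain, qa.size, ta.size)
    score, qs, ts, ops = _banded_sw(
        qa, ta, centers, scoring.band_width,
        scoring.match, scoring.mismatch, scoring.gap_open, scoring.gap_extend)
    if ops.size == 0 or score <= 0:
        return None
    n_match = int(np.sum(ops == OP_MATCH))
    q_len = int(np.sum((ops == OP_MATCH) | (ops == OP_MISMATCH) | (ops == OP_INS)))
    t_len = int(np.sum((ops == OP_MATCH) | (ops == OP_MISMATCH) | (ops == OP_DEL)))
    return Alignment(score=int(score), q_start=qs, q_end=qs + q_len,
                     t_start=ts, t_end=ts + t_len,
                     cigar=ops_to_cigar(ops), n_match=n_match,
                     n_cols=int(ops.size))


def align_to_indexed(query: str, target: str, index: KmerIndex,
                     scoring: AlignScoring) -> Alignment | None:
    """Seed, chain and extend a query against an indexed target.

    Returns None when no seed chain is found (the recruitment contract:
    fully masked targets recruit nothing).
    """
    anchors = index.seeds(query)
    if anchors.shape[0] == 0:
        return None
    chain = chain_anchors(anchors)
    if chain.shape[0] == 0:
        return None
    return extend_alignment(query, target, chain, scoring)


def align_pair(query: str, target: str, scoring: AlignScoring,
               respect_case: bool = False) -> Alignment | None:
    """Convenience one-shot alignment (builds a throwaway index)."""
    index = KmerIndex(target, scoring.seed_length, respect_case=respect_case)
    return align_to_indexed(query, target, index, scoring)


def map_target_to_query(aln: Alignment, t_coord: int) -> int:
    """Query coordinate aligned at target coordinate ``t_coord``.

    For coordinates inside a deletion the query cursor position is
    returned; coordinates outside the aligned target interval clamp to the
    alignment's query ends.
    """
    if t_coord <= aln.t_start:
        return aln.q_start
    if t_coord >= aln.t_end:
        return aln.q_end
    q, t = aln.q_start, aln.t_start
    for length, op in cigar_ops(aln.cigar):
        if op in "=X":
            if t + length > t_coord:
                return q + (t_coord - t)
            q += length
            t += length
        elif op == "I":
            q += length
        else:  # D
            if t + length > t_coord:
                return q
            t += length
    return q
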