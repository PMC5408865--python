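"""Overlap-layout-consensus assembly of score-binned read sets.

A minimal OLC assembler for targeted local assembly: seed-based overlap
candidates, banded overlap alignment, greedy dovetail chaining after
containment removal, and plurality-vote realignment polishing of a
stitched backbone.  Each score bin is assembled independently, plus a
pooled bin; the contig with the highest-scoring alignment back to the
(unmasked) bait wins.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .align import (AlignScoring, KmerIndex, align_pair, align_to_indexed,
                    chain_anchors, cigar_ops, extend_alignment, revcomp,
                    seq_to_u8)
from .insilico_pcr import Bait

logger = logging.getLogger(__name__)

DEFAULT_MIN_OVERLAP = 500
DEFAULT_MIN_OVERLAP_IDENTITY = 70.0
END_SLOP = 150  # bp of unaligned overhang tolerated at overlap ends


class AssemblyError(RuntimeError):
    pass


@dataclass
class Overlap:
    """A pairwise read overlap.

    ``read_a`` is the earlier read (lexicographically smaller id); the
    later read ``read_b`` was aligned as query, reverse-complemented
    first when orientation is "opposite" (``b_interval`` is in that
    aligned frame).  ``kind`` classifies the overlap geometry: dovetail
    (a left of b / b left of a) or containment.
    """

    read_a: str
    read_b: str
    a_interval: tuple[int, int]
    b_interval: tuple[int, int]
    orientation: str
    score: int
    identity: float
    kind: str
    length: int
    cigar: str = ""


@dataclass
class Layout:
    """An ordered read tiling: (read_id, contig offset, orientation).

    orientation +1 uses the read as stored, -1 its reverse complement.
    ``contained`` maps removed reads to their containing read.
    """

    entries: list[tuple[str, int, int]]
    contained: dict[str, str] = field(default_factory=dict)
    edges: dict[tuple[str, str], "Overlap"] = field(default_factory=dict)

    @property
    def read_ids(self) -> list[str]:
        return [e[0] for e in self.entries]


@dataclass
class Contig:
    """An assembled consensus with per-column read support."""

    sequence: str
    support: np.ndarray
    contributing_reads: list[str]
    bin_id: str

    def __post_init__(self):
        assert len(self.support) == len(self.sequence)


def _kmer_hashes(seq: str, k: int):
    """Yield (pos, 2-bit rolling hash) for every ACGT-only k-mer."""
    codes = seq_to_u8(seq)
    mask = (1 << (2 * k)) - 1
    h = 0
    run = 0
    for i in range(codes.size):
        c = int(codes[i])
        if c < 4:
            h = ((h << 2) | c) & mask
            run += 1
        else:
            run = 0
            h = 0
        if run >= k:
            yield i - k + 1, h


def _classify_overlap(aln, len_a: int, len_b: int, slop: int = END_SLOP):
    """Dovetail/containment classification from aligned intervals.

    Query is read b (aligned frame), target is read a.  Returns None for
    internal matches that reach neither end cleanly.
    """
    a_s, a_e = aln.t_start, aln.t_end
    b_s, b_e = aln.q_start, aln.q_end
    # how far each read genuinely extends beyond the other
    ext_l_b = b_s - a_s
    ext_r_b = (len_b - b_e) - (len_a - a_e)
    b_in_a = (b_s <= slop and len_b - b_e <= slop
              and ext_l_b <= 0 and ext_r_b <= 0)
    a_in_b = (a_s <= slop and len_a - a_e <= slop
              and ext_l_b >= 0 and ext_r_b >= 0)
    if b_in_a:
        return "contains_b"  # near-identical pairs also land here
    if a_in_b:
        return "contains_a"
    if len_a - a_e <= slop and b_s <= slop and ext_r_b > 0:
        return "dovetail_ab"  # suffix of a joins prefix of b
    if len_b - b_e <= slop and a_s <= slop and ext_l_b > 0:
        return "dovetail_ba"
    return None


def all_pairs_overlaps(reads: dict[str, str],
                       scoring: AlignScoring | None = None,
                       min_overlap: int = DEFAULT_MIN_OVERLAP,
                       min_overlap_identity: float = DEFAULT_MIN_OVERLAP_IDENTITY,
                       min_seed_hits: int = 8,
                       max_kmer_occ: int = 256) -> list[Overlap]:
    """Seed-based candidate detection + banded overlap alignment.

    Deterministic: reads are processed in sorted-id order; each unordered
    pair yields at most one Overlap (best orientation).
    """
    scoring = scoring or AlignScoring()
    k = scoring.seed_length
    ids = sorted(reads)
    index: dict[int, list[tuple[int, int]]] = {}
    overlaps: list[Overlap] = []
    for bi, rid in enumerate(ids):
        seq = reads[rid]
        # gather anchors against all earlier reads, both orientations
        cands: dict[tuple[int, str], list[tuple[int, int]]] = {}
        for label, qseq in (("same", seq), ("opposite", revcomp(seq))):
            for qpos, h in _kmer_hashes(qseq, k):
                bucket = index.get(h)
                if bucket is None or len(bucket) > max_kmer_occ:
                    continue
                for ai, tpos in bucket:
                    cands.setdefault((ai, label), []).append((qpos, tpos))
        best_by_pair: dict[int, Overlap] = {}
        for (ai, label), anchors in cands.items():
            if len(anchors) < min_seed_hits:
                continue
            arr = np.asarray(anchors, dtype=np.int64)
            span = arr[:, 0].max() - arr[:, 0].min() + k
            if span < 0.5 * min_overlap:
                continue
            aid = ids[ai]
            target = reads[aid]
            qseq = seq if label == "same" else revcomp(seq)
            chain = chain_anchors(arr)
            if chain.shape[0] == 0:
                continue
            aln = extend_alignment(qseq, target, chain, scoring)
            if aln is None:
                continue
            length = max(aln.q_end - aln.q_start, aln.t_end - aln.t_start)
            if length < min_overlap or aln.identity < min_overlap_identity:
                continue
            kind = _classify_overlap(aln, len(target), len(qseq))
            if kind is None:
                continue
            ov = Overlap(read_a=aid, read_b=rid,
                         a_interval=(aln.t_start, aln.t_end),
                         b_interval=(aln.q_start, aln.q_end),
                         orientation=label, score=aln.score,
                         identity=round(aln.identity, 2), kind=kind,
                         length=length, cigar=aln.cigar)
            prev = best_by_pair.get(ai)
            if prev is None or ov.score > prev.score:
                best_by_pair[ai] = ov
        overlaps.extend(best_by_pair[ai] for ai in sorted(best_by_pair))
        for tpos, h in _kmer_hashes(seq, k):
            index.setdefault(h, []).append((bi, tpos))
    return overlaps


class _UnionFind:
    def __init__(self):
        self.parent: dict[str, str] = {}

    def find(self, x: str) -> str:
        p = self.parent.setdefault(x, x)
        while p != self.parent[p]:
            self.parent[p] = self.parent[self.parent[p]]
            p = self.parent[p]
        self.parent[x] = p
        return p

    def union(self, a: str, b: str) -> bool:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return False
        self.parent[rb] = ra
        return True


def greedy_layout(overlaps: list[Overlap],
                  reads: dict[str, str]) -> list[Layout]:
    """Containment removal + greedy best-score dovetail chaining.

    Edges are taken in decreasing (score, length) order (ties by read
    ids); an edge is accepted when both involved read ends are still free
    and it does not close a cycle.  One layout per connected component is
    returned, largest (most reads, then most bases) first.
    """
    contained: dict[str, str] = {}
    for ov in overlaps:
        if ov.kind == "contains_b" and ov.read_b not in contained:
            if ov.read_a not in contained:
                contained[ov.read_b] = ov.read_a
        elif ov.kind == "contains_a" and ov.read_a not in contained:
            if ov.read_b not in contained:
                contained[ov.read_a] = ov.read_b
    alive = {r for r in reads if r not in contained}

    dovetails = [ov for ov in overlaps
                 if ov.kind in ("dovetail_ab", "dovetail_ba")
                 and ov.read_a in alive and ov.read_b in alive]
    dovetails.sort(key=lambda o: (-o.score, -o.length, o.read_a, o.read_b))

    used_ends: set[tuple[str, str]] = set()
    uf_chain = _UnionFind()
    uf_comp = _UnionFind()
    accepted: dict[str, list[Overlap]] = {}
    for ov in dovetails:
        uf_comp.union(ov.read_a, ov.read_b)
        # ends in each read's own stored frame; the query read's frame
        # flips for opposite-orientation overlaps
        flip = ov.orientation == "opposite"
        if ov.kind == "dovetail_ab":
            end_a = (ov.read_a, "R")
            end_b = (ov.read_b, "R" if flip else "L")
        else:
            end_a = (ov.read_a, "L")
            end_b = (ov.read_b, "L" if flip else "R")
        if end_a in used_ends or end_b in used_ends:
            continue
        if not uf_chain.union(ov.read_a, ov.read_b):
            logger.warning("cycle detected in overlap graph; dropping edge "
                           "%s-%s", ov.read_a, ov.read_b)
            continue
        used_ends.add(end_a)
        used_ends.add(end_b)
        accepted.setdefault(ov.read_a, []).append(ov)
        accepted.setdefault(ov.read_b, []).append(ov)

    # build chains by BFS over accepted edges
    placed: set[str] = set()
    chains: list[Layout] = []
    for root in sorted(alive):
        if root in placed:
            continue
        pos: dict[str, tuple[int, int]] = {root: (0, +1)}  # offset, orient
        queue = [root]
        while queue:
            u = queue.pop()
            o_u, w_u = pos[u]
            len_u = len(reads[u])
            for ov in accepted.get(u, []):
                v = ov.read_b if ov.read_a == u else ov.read_a
                if v in pos:
                    continue
                len_v = len(reads[v])
                rel = +1 if ov.orientation == "same" else -1
                a_int, b_int = ov.a_interval, ov.b_interval
                # a_int lives in a's stored frame, b_int in b's edge
                # frame (rc of stored when orientation is opposite);
                # equate the chain coordinate of one overlap boundary
                if ov.read_a == u:
                    if w_u == +1:
                        o_v = o_u + a_int[0] - b_int[0]
                    else:
                        o_v = o_u + (len_u - a_int[1]) - (len_v - b_int[1])
                else:
                    if w_u == rel:
                        o_v = o_u + b_int[0] - a_int[0]
                    else:
                        o_v = o_u + (len_u - b_int[1]) - (len_v - a_int[1])
                w_v = w_u * rel
                pos[v] = (o_v, w_v)
                placed.add(v)
                queue.append(v)
        placed.add(root)
        shift = min(o for o, _ in pos.values())
        entries = sorted(((rid, o - shift, w) for rid, (o, w) in pos.items()),
                         key=lambda e: (e[1], e[0]))
        edge_map = {}
        for rid in pos:
            for ov in accepted.get(rid, []):
                key = (min(ov.read_a, ov.read_b), max(ov.read_a, ov.read_b))
                edge_map[key] = ov
        chains.append(Layout(entries=entries, edges=edge_map))

    # one layout per component: keep the largest chain of each component
    best_by_comp: dict[str, Layout] = {}
    for chain in chains:
        comp = uf_comp.find(chain.entries[0][0])
        size = (len(chain.entries),
                sum(len(reads[r]) for r in chain.read_ids))
        prev = best_by_comp.get(comp)
        if prev is None:
            best_by_comp[comp] = chain
        else:
            prev_size = (len(prev.entries),
                         sum(len(reads[r]) for r in prev.read_ids))
            if size > prev_size:
                best_by_comp[comp] = chain
    layouts = sorted(best_by_comp.values(),
                     key=lambda l: (-len(l.entries),
                                    -sum(len(reads[r]) for r in l.read_ids),
                                    l.entries[0][0]))
    for l in layouts:
        l.contained = {r: c for r, c in contained.items()}
    return layouts


def _overlap_mid_pair(ov: Overlap, min_exact: int = 8):
    """An exactly-aligned (read_a pos, read_b pos) pair near the overlap
    middle, taken from the centre of a long match run so the splice is
    locally unambiguous.  Positions are in the overlap's aligned frames.
    """
    cols = 0
    for length, op in cigar_ops(ov.cigar):
        cols += length
    target_col = cols // 2
    best = None
    col = 0
    t, q = ov.a_interval[0], ov.b_interval[0]
    for length, op in cigar_ops(ov.cigar):
        if op == "=":
            mid = col + length // 2
            cand = (t + (mid - col), q + (mid - col))
            dist = abs(mid - target_col)
            score = (length >= min_exact, -dist)
            if best is None or score > best[0]:
                best = (score, cand)
        if op in "=X":
            t += length
            q += length
        elif op == "I":
            q += length
        else:
            t += length
        col += length
    return best[1] if best else (ov.a_interval[0], ov.b_interval[0])


def _stitch_backbone(layout: Layout, reads: dict[str, str]) -> str:
    """Splice layout reads at exactly-aligned overlap columns.

    Using aligned column pairs (rather than offset-projected midpoints)
    keeps the backbone structurally faithful even when accumulated read
    indels make layout offsets drift by tens of bases over long
    overlaps.
    """
    # traverse in chain-path order (accepted edges form a path); layout
    # offsets are indel-noisy over long overlaps and can swap neighbours
    entries = sorted(layout.entries, key=lambda e: (e[1], e[0]))
    by_id = {rid: (rid, off, w) for rid, off, w in entries}
    adj: dict[str, list[str]] = {rid: [] for rid in by_id}
    for (a, b) in layout.edges:
        if a in adj and b in adj:
            adj[a].append(b)
            adj[b].append(a)
    ends = [rid for rid, nb in adj.items() if len(nb) <= 1]
    if ends and all(len(nb) <= 2 for nb in adj.values()):
        start = min(ends, key=lambda r: (by_id[r][1], r))
        order = [start]
        seen = {start}
        while True:
            nxt = [n for n in adj[order[-1]] if n not in seen]
            if not nxt:
                break
            order.append(nxt[0])
            seen.add(nxt[0])
        if len(order) == len(entries):
            entries = [by_id[r] for r in order]
    rid0, off0, w0 = entries[0]
    backbone = reads[rid0] if w0 == +1 else revcomp(reads[rid0])
    # true backbone start coordinate of each placed read
    actual_start: dict[str, int] = {rid0: 0}
    orient_of: dict[str, int] = {rid0: w0}
    placed = [rid0]
    for rid, offset, orient in entries[1:]:
        seq = reads[rid] if orient == +1 else revcomp(reads[rid])
        ov = None
        prid = None
        for cand in reversed(placed):
            key = (min(cand, rid), max(cand, rid))
            if key in layout.edges:
                ov = layout.edges[key]
                prid = cand
                break
        if ov is None:
            # no direct edge to a placed read: append (chains always
            # have one, so this is purely defensive)
            actual_start[rid] = len(backbone)
            orient_of[rid] = orient
            backbone += seq
            placed.append(rid)
            continue
        pa, pb = _overlap_mid_pair(ov)

        def _oriented(read_id: str, edge_pos: int, w: int) -> int:
            n = len(reads[read_id])
            edge_is_stored = (read_id == ov.read_a
                              or ov.orientation == "same")
            if (edge_is_stored and w == +1) or \
                    (not edge_is_stored and w == -1):
                return edge_pos
            return n - edge_pos
        if ov.read_a == prid:
            cut_left = _oriented(prid, pa, orient_of[prid])
            cut_right = _oriented(rid, pb, orient)
        else:
            cut_left = _oriented(prid, pb, orient_of[prid])
            cut_right = _oriented(rid, pa, orient)
        abs_cut = actual_start[prid] + cut_left
        if 0 < abs_cut <= len(backbone) and 0 <= cut_right < len(seq):
            backbone = backbone[:abs_cut] + seq[cut_right:]
            actual_start[rid] = abs_cut - cut_right
        else:
            actual_start[rid] = len(backbone) - max(0, cut_right)
            backbone += seq[max(0, cut_right):]
        orient_of[rid] = orient
        placed.append(rid)
    return backbone



def _polish(backbone: str, read_seqs: dict[str, str],
            scoring: AlignScoring, min_identity: float):
    """One round of realignment polishing.

    Column-wise plurality over match/substitution/deletion events, with
    two refinements that matter for indel-dominant long reads: insertion
    evidence pooled by first inserted base, and "suspect windows" —
    short stretches where per-column disagreement or junction-insertion
    load shows the column votes cannot be trusted (homopolymer and
    short-motif repeats, coupled indels) — re-called as the modal read
    segment spanning the window.  Returns (new_seq, coverage,
    contributing ids, mean identity of contributors).
    """
    L = len(backbone)
    index = KmerIndex(backbone, scoring.seed_length)
    votes = np.zeros((L, 5), dtype=np.int32)
    cov = np.zeros(L, dtype=np.int32)
    inserts: dict[int, dict[str, int]] = {}
    ins_total = np.zeros(L + 1, dtype=np.int32)
    contributing = []
    identities = []
    base_of = {0: "A", 1: "C", 2: "G", 3: "T"}
    # per-read target->query cursor maps, kept for window re-calling
    read_info: list[tuple[str, int, int, np.ndarray]] = []

    for rid in sorted(read_seqs):
        seq = read_seqs[rid]
        aln = align_to_indexed(seq, backbone, index, scoring)
        if aln is None or aln.identity < min_identity:
            continue
        if aln.t_end - aln.t_start < min(300, len(seq) // 2):
            continue
        contributing.append(rid)
        identities.append(aln.identity)
        cov[aln.t_start:aln.t_end] += 1
        q, t = aln.q_start, aln.t_start
        qcodes = seq_to_u8(seq)
        # first_q[c] = read cursor at the first event on column c (i.e.
        # before any insertion placed at that junction)
        first_q = np.full(L + 1, -1, dtype=np.int32)
        for length, op in cigar_ops(aln.cigar):
            if op in "=X":
                idx = qcodes[q:q + length]
                cols = np.arange(t, t + length)
                valid = idx < 4
                np.add.at(votes, (cols[valid], idx[valid]), 1)
                qs = np.arange(q, q + length, dtype=np.int32)
                if first_q[t] == -1:
                    first_q[t] = q
                first_q[t + 1:t + length] = qs[1:]
                q += length
                t += length
            elif op == "I":
                ins_seq = seq[q:q + length]
                d = inserts.setdefault(t, {})
                d[ins_seq] = d.get(ins_seq, 0) + 1
                ins_total[t] += 1
                if first_q[t] == -1:
                    first_q[t] = q
                q += length
            else:  # D
                votes[t:t + length, 4] += 1
                if first_q[t] == -1:
                    first_q[t] = q
                first_q[t + 1:t + length] = q
                t += length
        if t <= L and first_q[t] == -1:
            first_q[t] = q
        read_info.append((rid, aln.t_start, aln.t_end, first_q))

    # --- suspect windows -------------------------------------------------
    best_votes = votes[:, :4].max(axis=1) if L else np.zeros(0, np.int32)
    covf = np.maximum(cov, 1)
    suspect = np.zeros(L, dtype=bool)
    enough = cov >= 4
    suspect |= enough & ((cov - best_votes) >= 0.15 * covf)
    for j, n in enumerate(ins_total):
        if n == 0:
            continue
        j_cov = cov[min(j, L - 1)] if j == 0 or j == L else \
            min(cov[j - 1], cov[j])
        if j_cov >= 4 and n >= 0.15 * j_cov:
            if j > 0:
                suspect[j - 1] = True
            if j < L:
                suspect[j] = True

    def _in_run(c: int) -> bool:
        return (0 < c < L and backbone[c] == backbone[c - 1]) or \
               (0 <= c < L - 1 and backbone[c] == backbone[c + 1])

    def _segment_census(ws: int, we: int, cap_extra: int = 12):
        """Spanning-read segments across target interval [ws, we)."""
        segs: dict[str, int] = {}
        n_span = 0
        for rid, ts, te, first_q in read_info:
            if ts < ws and te > we and first_q[ws] >= 0 and first_q[we] >= 0:
                s = read_seqs[rid][int(first_q[ws]):int(first_q[we])]
                if len(s) <= (we - ws) + cap_extra:
                    n_span += 1
                    segs[s] = segs.get(s, 0) + 1
        return segs, n_span

    def _centroid(segs: dict[str, int]) -> str:
        """Observed segment minimizing total edit distance to the rest.

        More robust than the plain mode when read errors fragment the
        vote: every read still pulls the centroid toward the truth.
        """
        import edlib as _edlib
        cands = sorted(segs.items(), key=lambda kv: (-kv[1], kv[0]))[:15]
        best = None
        for c, cn in cands:
            total = 0.0
            for s, n in segs.items():
                if c == s:
                    continue
                if not c or not s:
                    d = abs(len(c) - len(s))
                else:
                    d = _edlib.align(c, s, task="distance")["editDistance"]
                total += n * d
            key = (total, -cn, c)
            if best is None or key < best[0]:
                best = (key, c)
        return best[1]

    windows: list[list[int]] = []
    cols = np.nonzero(suspect)[0]
    for c in cols:
        if windows and c - windows[-1][1] <= 4:
            windows[-1][1] = c + 1
        else:
            windows.append([int(c), int(c) + 1])
    window_call: dict[int, tuple[int, str | None]] = {}
    for ws, we in windows:
        # extend edges out of repeat runs plus one clean anchor column
        guard = 0
        while ws > 0 and _in_run(ws - 1) and guard < 8:
            ws -= 1
            guard += 1
        guard = 0
        while we < L and _in_run(we) and guard < 8:
            we += 1
            guard += 1
        ws = max(0, ws - 1)
        we = min(L, we + 1)
        if ws in window_call:
            continue
        if we - ws > 16:
            window_call[ws] = (we, None)
            continue
        segs, n_span = _segment_census(ws, we)
        call: str | None = None
        if n_span >= 4 and segs:
            call = _centroid(segs)
        window_call[ws] = (we, call)

    in_window = np.zeros(L, dtype=bool)
    for ws, (we, call) in window_call.items():
        if call is not None:
            in_window[ws:we] = True

    # homopolymer runs outside accepted windows get run-level calls:
    # modal spanning segment, falling back to the modal run-base count
    # (gap placement inside a run is alignment-arbitrary, so column
    # votes alone systematically miss run-length errors)
    run_call: dict[int, tuple[int, str]] = {}
    suppress: set[int] = set()
    i = 0
    while i < L:
        j = i
        b = backbone[i]
        while j < L and backbone[j] == b:
            j += 1
        if j - i >= 2 and not in_window[i:j].any():
            segs, n_span = _segment_census(i, j)
            if n_span >= 3 and segs:
                run_call[i] = (j, _centroid(segs))
                suppress.update(range(i, j))
        i = j

    # --- rebuild ---------------------------------------------------------
    def _ins_call(col: int) -> str | None:
        if col in suppress:
            return None
        j_cov = cov[min(col, L - 1)] if col == 0 or col == L else \
            min(cov[col - 1], cov[col])
        pooled: dict[str, int] = {}
        for s, n in inserts[col].items():
            pooled[s[0]] = pooled.get(s[0], 0) + n
        base, n = max(pooled.items(), key=lambda kv: (kv[1], kv[0]))
        if n >= max(2.0, 0.4 * j_cov):
            return base
        return None

    def _column_call(col: int) -> str:
        col_votes = votes[col]
        best = int(np.argmax(col_votes[:4]))
        if cov[col] == 0 or col_votes[best] == 0:
            return backbone[col]
        if col_votes[4] > col_votes[best]:
            return ""  # deletion wins
        return base_of[best]

    out: list[str] = []
    col = 0
    while col < L:
        win = window_call.get(col)
        if win is not None and win[1] is not None and win[0] > col:
            # modal segment covers cols [col, we) and their junctions
            out.append(win[1])
            col = win[0]
            continue
        if col in inserts:
            ins = _ins_call(col)
            if ins is not None:
                out.append(ins)
        run = run_call.get(col)
        if run is not None:
            out.append(run[1])
            col = run[0]
            continue
        out.append(_column_call(col))
        col += 1
    if L in inserts:
        ins = _ins_call(L)
        if ins is not None:
            out.append(ins)
    mean_ident = float(np.mean(identities)) if identities else 0.0
    return "".join(out), cov, contributing, mean_ident
def consensus(layout: Layout, reads: dict[str, str], rounds: int = 2,
              scoring: AlignScoring | None = None,
              min_overlap_identity: float = DEFAULT_MIN_OVERLAP_IDENTITY,
              polish_reads: dict[str, str] | None = None,
              bin_id: str = "bin") -> Contig:
    """Backbone stitching followed by plurality-vote polishing rounds.

    ``polish_reads`` (default: the layout's reads) are realigned to the
    backbone each round; a final pass records per-column support and the
    contributing-read set.
    """
    scoring = scoring or AlignScoring()
    pool = polish_reads if polish_reads is not None else {
        r: reads[r] for r in layout.read_ids}
    backbone = _stitch_backbone(layout, reads)
    if len(layout.entries) == 1 and len(pool) == 1:
        rid = layout.entries[0][0]
        return Contig(sequence=backbone,
                      support=np.ones(len(backbone), dtype=np.int32),
                      contributing_reads=[rid], bin_id=bin_id)
    # polishing accepts weak alignments in early rounds (raw backbone)
    for _ in range(rounds):
        backbone, _, _, _ = _polish(backbone, pool, scoring, min_identity=50.0)
    # final pass measures support and contributors on the polished backbone
    _, cov, contributing, mean_ident = _polish(
        backbone, pool, scoring, min_identity=min_overlap_identity)
    logger.info("bin %s: consensus %d bp from %d contributing reads "
                "(mean identity %.1f%%)", bin_id, len(backbone),
                len(contributing), mean_ident)
    return Contig(sequence=backbone, support=cov,
                  contributing_reads=contributing, bin_id=bin_id)


def assemble_bin(bin_id: str, read_ids, oriented: dict[str, str],
                 scoring: AlignScoring | None = None,
                 min_overlap: int = DEFAULT_MIN_OVERLAP,
                 min_overlap_identity: float = DEFAULT_MIN_OVERLAP_IDENTITY,
                 rounds: int = 2) -> Contig | None:
    """OLC-assemble one score bin's reads."""
    scoring = scoring or AlignScoring()
    subset = {rid: oriented[rid] for rid in read_ids}
    if not subset:
        return None
    if len(subset) == 1:
        rid = next(iter(subset))
        return Contig(sequence=subset[rid],
                      support=np.ones(len(subset[rid]), dtype=np.int32),
                      contributing_reads=[rid], bin_id=bin_id)
    overlaps = all_pairs_overlaps(subset, scoring, min_overlap,
                                  min_overlap_identity)
    layouts = greedy_layout(overlaps, subset)
    if not layouts:
        return None
    return consensus(layouts[0], subset, rounds, scoring,
                     min_overlap_identity, polish_reads=subset,
                     bin_id=bin_id)


def assemble_and_select(bins, oriented: dict[str, str], bait: Bait,
                        scoring: AlignScoring | None = None,
                        min_overlap: int = DEFAULT_MIN_OVERLAP,
                        min_overlap_identity: float = DEFAULT_MIN_OVERLAP_IDENTITY,
                        rounds: int = 2):
    """Assemble every bin plus the pooled set; pick the contig whose
    alignment to the unmasked bait scores highest.

    Returns (best contig, its bait alignment, table rows).
    """
    scoring = scoring or AlignScoring()
    jobs = [(f"bin{i}", b.read_ids) for i, b in enumerate(bins)]
    pooled = sorted({rid for b in bins for rid in b.read_ids})
    jobs.append(("pooled", pooled))
    results = []
    for bin_id, rids in jobs:
        contig = assemble_bin(bin_id, rids, oriented, scoring, min_overlap,
                              min_overlap_identity, rounds)
        if contig is None:
            continue
        aln = align_pair(contig.sequence, bait.unmasked_sequence, scoring)
        if aln is None:
            continue
        results.append((contig, aln, len(rids)))
    if not results:
        raise AssemblyError("assembly failed")
    results.sort(key=lambda r: (-r[1].score, -len(r[0].sequence),
                                r[0].bin_id))
    best_contig, best_aln, best_n = results[0]
    # finishing: polish the winning contig with the full recruited read
    # set, which restores full coverage depth over a contig assembled
    # from a single score bin
    all_reads = {rid: oriented[rid] for rid in pooled}
    seq = best_contig.sequence
    for _ in range(rounds):
        seq, _, _, _ = _polish(seq, all_reads, scoring, min_identity=50.0)
    _, cov, contributing, _ = _polish(seq, all_reads, scoring,
                                      min_identity=min_overlap_identity)
    best_contig = Contig(sequence=seq, support=cov,
                         contributing_reads=contributing,
                         bin_id=best_contig.bin_id)
    refreshed = align_pair(seq, bait.unmasked_sequence, scoring)
    if refreshed is not None:
        best_aln = refreshed
    results[0] = (best_contig, best_aln, best_n)
    table = [{
        "bin": c.bin_id,
        "n_reads": n,
        "contig_len": len(c.sequence),
        "score_vs_bait": a.score,
        "identity_vs_bait": round(a.identity, 1),
        "selected": c is best_contig,
    } for c, a, n in sorted(results, key=lambda r: r[0].bin_id)]
    return best_contig, best_aln, table
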