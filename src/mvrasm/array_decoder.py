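"""Decoding an assembled tandem array into an MVR-style allele code.

The array is located in a contig by its flank anchors against the bait,
segmented into repeat units by wraparound DP against the consensus unit,
and each unit is assigned the variant code with minimum Levenshtein
distance.  The result is a fractional copy number and a code string (the
allele's interspersion pattern), plus a unit-level comparison between two
such code strings.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import edlib

from . import tandem
from .align import Alignment, AlignScoring, align_pair, map_target_to_query
from .insilico_pcr import Bait

logger = logging.getLogger(__name__)


class ArrayLocationError(ValueError):
    """The tandem array could not be localized in the contig."""


@dataclass
class VariantTable:
    """Consensus repeat unit plus single-letter-coded sequence variants."""

    consensus_unit: str
    codes: dict[str, str]
    null_code: str = "?"

    def __post_init__(self):
        if not self.consensus_unit:
            raise ValueError("empty consensus unit")
        seqs = list(self.codes.values())
        if len(set(seqs)) != len(seqs):
            raise ValueError("variant sequences must be distinct")
        for code in self.codes:
            if len(code) != 1:
                raise ValueError(f"codes must be single letters: {code!r}")

    @property
    def period(self) -> int:
        return len(self.consensus_unit)

    def save_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"consensus\t{self.consensus_unit}\n")
            for code in sorted(self.codes):
                fh.write(f"{code}\t{self.codes[code]}\n")

    @classmethod
    def load_tsv(cls, path) -> "VariantTable":
        consensus = None
        codes: dict[str, str] = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                key, seq = line.split("\t")
                if key == "consensus":
                    consensus = seq
                else:
                    codes[key] = seq
        if consensus is None:
            raise ValueError("variant table lacks a consensus row")
        return cls(consensus_unit=consensus, codes=codes)


@dataclass
class UnitCall:
    """One repeat unit's classification."""

    interval: tuple[int, int]
    observed_seq: str
    code: str
    edit_distance: int
    tie: bool


@dataclass
class AlleleDecoding:
    """A decoded allele: the headline output of the pipeline."""

    array_interval: tuple[int, int]
    unit_calls: list[UnitCall]
    complete_units: int
    copy_number: float
    code_string: str
    partial_length: int = 0

    def to_dict(self) -> dict:
        return {
            "array_interval": list(self.array_interval),
            "complete_units": self.complete_units,
            "copy_number": self.copy_number,
            "code_string": self.code_string,
            "partial_length": self.partial_length,
            "unit_calls": [
                {"interval": list(u.interval), "observed": u.observed_seq,
                 "code": u.code, "edit_distance": u.edit_distance,
                 "tie": u.tie}
                for u in self.unit_calls],
        }


@dataclass
class AlleleComparison:
    """Unit-level global alignment of two allele code strings."""

    aligned_a: str
    aligned_b: str
    n_match: int
    n_mismatch: int
    n_indel: int
    five_prime_consistent: bool
    three_prime_consistent: bool


def locate_array(contig_seq: str, bait: Bait,
                 scoring: AlignScoring | None = None,
                 min_anchor: int = 500,
                 alignment: Alignment | None = None):
    """Find the tandem array interval in a contig via its flank anchors.

    The contig is aligned to the bait (seeding only in unmasked flanks);
    the array spans the contig strictly between the positions aligned to
    the two ROI edges.  If only one flank anchors, falls back to de-novo
    tandem detection on the contig with a warning.
    """
    if bait.roi_interval is None:
        raise ArrayLocationError("bait has no ROI")
    scoring = scoring or AlignScoring()
    aln = alignment
    if aln is None:
        aln = align_pair(contig_seq, bait.sequence, scoring, respect_case=True)
    if aln is None:
        raise ArrayLocationError("array not localized: contig does not align")
    rs, re_ = bait.roi_local
    left = aln.t_start <= rs - min_anchor and aln.t_end >= rs
    right = aln.t_end >= re_ + min_anchor and aln.t_start <= re_
    if left and right:
        return (map_target_to_query(aln, rs), map_target_to_query(aln, re_))
    if left or right:
        logger.warning("only one flank anchors; falling back to tandem "
                       "detection on the contig")
        anns = tandem.detect_tandem_repeats(contig_seq)
        if anns:
            best = max(anns, key=lambda a: a.length)
            return best.interval
    raise ArrayLocationError("array not localized")


def refine_array_interval(seq: str, interval: tuple[int, int],
                          table: VariantTable,
                          tol: int | None = None) -> tuple[int, int]:
    """Snap an approximate array interval to exact unit boundaries.

    Walks the repeat-unit grid outward from an anchor near the located
    start: a p-window is array-like when it is within ``tol`` edits of
    any table unit (every coded variant is close to the consensus, so
    this classifies units regardless of which variant they are).  Small
    grid shifts re-anchor across consensus indels, but any shifted or
    skipping step must be confirmed by a second consecutive good window,
    which keeps the walk out of non-repeat flank sequence.  The terminal
    partial unit is recovered as the longest exact consensus prefix.
    """
    p = table.period
    units = [table.consensus_unit] + [table.codes[c] for c in sorted(table.codes)]
    if tol is None:
        tol = max(1, p // 12)
    n = len(seq)

    def wdist(s: int) -> int:
        """Min distance of window [s, s+p) to any table unit (capped)."""
        if s < 0 or s + p > n:
            return tol + 1
        w = seq[s:s + p]
        best = tol + 1
        for u in units:
            if w == u:
                return 0
            d = edlib.align(w, u, task="distance", k=tol)["editDistance"]
            if d != -1 and d < best:
                best = d
        return best

    def good(s: int) -> bool:
        return wdist(s) <= tol

    # anchor on the grid offset with the longest clean window chain and,
    # among equals, the lowest total distance (a slightly shifted grid
    # can sneak under the tolerance on long units)
    s0 = interval[0]
    best_s, best_key = None, None
    for s in range(max(0, s0 - 2 * p), min(max(0, n - p), s0 + 2 * p) + 1):
        c = 0
        total = 0
        while c < 4 and s + (c + 1) * p <= n:
            d = wdist(s + c * p)
            if d > tol:
                break
            total += d
            c += 1
        key = (c, -total)
        if c > 0 and (best_key is None or key > best_key):
            best_key, best_s = key, s
    if best_s is None:
        return interval

    shifts = (0, -1, 1, -2, 2)

    s = best_s
    while True:
        nxt = None
        for d in shifts:
            cand = s - p + d
            if cand < 0 or not good(cand):
                continue
            if d == 0 or good(cand - p):
                nxt = cand
                break
        if nxt is None:
            # tolerate one unreadable unit, re-anchoring past it
            for d in shifts:
                cand = s - 2 * p + d
                if cand >= 0 and good(cand) and good(cand - p):
                    nxt = cand
                    break
        if nxt is None:
            break
        s = nxt

    e = s
    while True:
        nxt = None
        for d in shifts:
            cand = e + d
            if cand + p > n or not good(cand):
                continue
            if d == 0 or good(cand + p):
                nxt = cand + p
                break
        if nxt is None:
            for d in shifts:
                cand = e + p + d
                if cand + p <= n and good(cand) and good(cand + p):
                    nxt = cand + p
                    break
        if nxt is None:
            break
        e = nxt

    cons = table.consensus_unit

    # a boundary "unit" at distance >= 1 whose mismatches all sit in its
    # outermost two bases is better explained as partial + flank
    if e - p >= s:
        w = seq[e - p:e]
        if not any(w == u for u in units):
            lp = 0
            for i in range(p):
                if w[i] != cons[i]:
                    break
                lp += 1
            if p - 2 <= lp < p:
                e -= p
    if s + p <= e:
        w = seq[s:s + p]
        if not any(w == u for u in units):
            ls = 0
            for i in range(p - 1, -1, -1):
                if w[i] != cons[i]:
                    break
                ls += 1
            if p - 2 <= ls < p:
                s += p

    # terminal partial units: longest exact consensus prefix on the
    # right, longest exact consensus suffix on the left
    for lp in range(p - 1, 0, -1):
        if e + lp <= n and seq[e:e + lp] == cons[:lp]:
            e += lp
            break
    for lp in range(p - 1, 0, -1):
        if s - lp >= 0 and seq[s - lp:s] == cons[p - lp:]:
            s -= lp
            break

    # sanity: boundary refinement corrects a few bases, never rewrites
    # the interval wholesale; fall back when the walk went astray
    if abs((e - s) - (interval[1] - interval[0])) > 4 * p:
        logger.warning("array boundary refinement diverged; keeping the "
                       "flank-anchored interval")
        return interval
    return (s, e)


def decompose_array(array_seq: str, consensus_unit: str):
    """Tile an array into unit segments by wraparound DP.

    Returns an ordered list of (start, end, is_complete) intervals; the
    terminal segment may be a partial unit.
    """
    if len(array_seq) < len(consensus_unit):
        return [(0, len(array_seq), False)] if array_seq else []
    _, segments = tandem.wraparound_segment(array_seq, consensus_unit)
    return segments


def classify_unit(observed_seq: str, table: VariantTable,
                  max_unit_distance: int | None = None):
    """Assign the minimum-edit-distance variant code to one unit.

    Ties go to the lexicographically smallest code with tie=True; units
    farther than ``max_unit_distance`` (default floor(period/3)) from
    every variant get the null code.
    """
    if not table.codes:
        raise ValueError("empty variant table")
    p = table.period
    threshold = max_unit_distance if max_unit_distance is not None else p // 3
    if not observed_seq:
        return table.null_code, p, False
    best_code = None
    best_dist = None
    n_best = 0
    for code in sorted(table.codes):
        d = edlib.align(observed_seq, table.codes[code],
                        task="distance")["editDistance"]
        if best_dist is None or d < best_dist:
            best_dist = d
            best_code = code
            n_best = 1
        elif d == best_dist:
            n_best += 1
    if best_dist > threshold:
        return table.null_code, best_dist, False
    return best_code, best_dist, n_best > 1


def decode_array_seq(array_seq: str, table: VariantTable,
                     max_unit_distance: int | None = None,
                     offset: int = 0) -> AlleleDecoding:
    """Decompose and classify a known array sequence."""
    p = table.period
    segments = decompose_array(array_seq, table.consensus_unit)
    calls: list[UnitCall] = []
    partial_length = 0
    for start, end, complete in segments:
        if not complete:
            partial_length += end - start
            continue
        obs = array_seq[start:end]
        code, dist, tie = classify_unit(obs, table, max_unit_distance)
        calls.append(UnitCall((start + offset, end + offset), obs, code,
                              dist, tie))
    copy_number = round(len(array_seq) / p, 1)
    if len(array_seq) < p:
        logger.warning("array shorter than one repeat unit")
    return AlleleDecoding(
        array_interval=(offset, offset + len(array_seq)),
        unit_calls=calls,
        complete_units=len(calls),
        copy_number=copy_number,
        code_string="".join(c.code for c in calls),
        partial_length=partial_length,
    )


def decode_allele(contig_seq: str, bait: Bait, table: VariantTable,
                  scoring: AlignScoring | None = None,
                  min_anchor: int = 500,
                  max_unit_distance: int | None = None,
                  alignment: Alignment | None = None,
                  refine: bool = True) -> AlleleDecoding:
    """Locate, decompose and classify the array of an assembled contig.

    The flank-anchor location is approximate at the base level (alignment
    wobble at the array edges); with ``refine`` the interval is snapped
    to exact unit-grid boundaries using the variant table before
    decomposition.  The code string reads 5'->3' in bait-forward
    orientation (contigs are assembled in that orientation by the
    recruitment stage).
    """
    start, end = locate_array(contig_seq, bait, scoring, min_anchor,
                              alignment=alignment)
    if refine:
        start, end = refine_array_interval(contig_seq, (start, end), table)
    return decode_array_seq(contig_seq[start:end], table,
                            max_unit_distance, offset=start)


def compare_alleles(code_a: str, code_b: str,
                    end_window: int = 10) -> AlleleComparison:
    """Global unit-level alignment of two allele code strings.

    Scoring: match +1, mismatch -1, gap -2 per unit.  The 5'/3'
    consistency booleans report zero mismatches/indels within the first/
    last ``end_window`` alignment columns.
    """
    GAP = -2
    la, lb = len(code_a), len(code_b)
    score = [[0] * (lb + 1) for _ in range(la + 1)]
    for i in range(1, la + 1):
        score[i][0] = i * GAP
    for j in range(1, lb + 1):
        score[0][j] = j * GAP
    for i in range(1, la + 1):
        row = score[i]
        prev = score[i - 1]
        ca = code_a[i - 1]
        for j in range(1, lb + 1):
            d = prev[j - 1] + (1 if ca == code_b[j - 1] else -1)
            row[j] = max(d, prev[j] + GAP, row[j - 1] + GAP)
    # traceback (prefer diagonal, then gap in b, then gap in a)
    out_a: list[str] = []
    out_b: list[str] = []
    i, j = la, lb
    while i > 0 or j > 0:
        if i > 0 and j > 0 and score[i][j] == score[i - 1][j - 1] + (
                1 if code_a[i - 1] == code_b[j - 1] else -1):
            out_a.append(code_a[i - 1])
            out_b.append(code_b[j - 1])
            i -= 1
            j -= 1
        elif i > 0 and score[i][j] == score[i - 1][j] + GAP:
            out_a.append(code_a[i - 1])
            out_b.append("-")
            i -= 1
        else:
            out_b.append(code_b[j - 1])
            out_a.append("-")
            j -= 1
    aligned_a = "".join(reversed(out_a))
    aligned_b = "".join(reversed(out_b))
    n_match = n_mismatch = n_indel = 0
    clean = []
    for x, y in zip(aligned_a, aligned_b):
        if x == "-" or y == "-":
            n_indel += 1
            clean.append(False)
        elif x == y:
            n_match += 1
            clean.append(True)
        else:
            n_mismatch += 1
            clean.append(False)
    w = min(end_window, len(clean))
    five = all(clean[:w])
    three = all(clean[-w:]) if w else True
    return AlleleComparison(aligned_a, aligned_b, n_match, n_mismatch,
                            n_indel, five, three)


def render_comparison(comp: AlleleComparison, width: int = 60) -> str:
    """Aligned text rendering of an allele-structure comparison."""
    lines = []
    for i in range(0, len(comp.aligned_a), width):
        a = comp.aligned_a[i:i + width]
        b = comp.aligned_b[i:i + width]
        marks = "".join("|" if x == y and x != "-" else " "
                        for x, y in zip(a, b))
        lines += [a, marks, b, ""]
    return "\n".join(lines)
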