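"""Read recruitment: align long reads to the masked bait, classify their
anchoring relative to the ROI, and partition them into alignment-score bins.

Seeding only lands in unmasked (flank) bait sequence, so reads lying
entirely inside the masked tandem array are never recruited; extension is
free to cross the array, which is what lets spanning reads constrain the
array length.  No identity cutoff is applied beyond seed-based
recruitment: long, lower-identity alignments carry the contiguity
information, and the score binning exists precisely to separate them from
short high-identity noise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .align import (Alignment, AlignScoring, KmerIndex, align_to_indexed,
                    cigar_ops, revcomp, score_cigar)
from .insilico_pcr import Bait

logger = logging.getLogger(__name__)

SPANNING = "spanning"
LEFT_ANCHORED = "left_anchored"
RIGHT_ANCHORED = "right_anchored"
NON_INFORMATIVE = "non_informative"


class RecruitmentError(ValueError):
    pass


@dataclass
class LongRead:
    """A single long read (qualities optional)."""

    id: str
    sequence: str
    qualities: str | None = None

    def __post_init__(self):
        if not self.sequence:
            raise ValueError(f"empty read {self.id!r}")


@dataclass
class LocalAlignment:
    """A read-vs-bait local alignment (bait-local coordinates).

    ``read_interval`` is in original read coordinates; for minus-strand
    hits the read's reverse complement was aligned and the interval
    mapped back.  ``score`` is always consistent with ``edit_path`` under
    the scoring in force.
    """

    read_id: str
    bait_interval: tuple[int, int]
    read_interval: tuple[int, int]
    strand: str
    score: int
    identity: float
    edit_path: str


@dataclass
class ScoreBin:
    """One alignment-score histogram bin ([lower, upper); top bin closed)."""

    lower: float
    upper: float
    read_ids: list[str]


def bait_index(bait: Bait, scoring: AlignScoring | None = None) -> KmerIndex:
    """Seed index over the bait honoring soft masking."""
    scoring = scoring or AlignScoring()
    return KmerIndex(bait.sequence, scoring.seed_length, respect_case=True)


MIN_ALIGNED_COLS = 50  # chance single-seed hits never reach this


def align_read(bait: Bait, read: LongRead,
               scoring: AlignScoring | None = None,
               index: KmerIndex | None = None) -> LocalAlignment | None:
    """Best local alignment of a read against the bait, both strands.

    Returns None when no unmasked seed exists or only a spurious
    sub-``MIN_ALIGNED_COLS`` match is found (the read is not recruited).
    Ties between strands resolve to plus.
    """
    scoring = scoring or AlignScoring()
    if index is None:
        index = bait_index(bait, scoring)
    fwd = align_to_indexed(read.sequence, bait.sequence, index, scoring)
    rc_seq = revcomp(read.sequence)
    rev = align_to_indexed(rc_seq, bait.sequence, index, scoring)
    for cand in (fwd, rev):
        if cand is not None and cand.n_cols < MIN_ALIGNED_COLS:
            if cand is fwd:
                fwd = None
            else:
                rev = None
    if fwd is None and rev is None:
        return None
    if rev is None or (fwd is not None and fwd.score >= rev.score):
        aln, strand = fwd, "+"
        read_interval = (aln.q_start, aln.q_end)
    else:
        aln, strand = rev, "-"
        n = len(read.sequence)
        read_interval = (n - aln.q_end, n - aln.q_start)
    return LocalAlignment(
        read_id=read.id,
        bait_interval=(aln.t_start, aln.t_end),
        read_interval=read_interval,
        strand=strand,
        score=aln.score,
        identity=aln.identity,
        edit_path=aln.cigar,
    )


def classify_read(alignment: LocalAlignment, bait: Bait,
                  min_anchor: int = 500) -> str:
    """Spanning / left_anchored / right_anchored / non_informative.

    Anchoring means the alignment covers at least ``min_anchor`` bases of
    unique flank on that side of the ROI.
    """
    roi = bait.roi_local
    if roi is None:
        raise ValueError("bait has no ROI; classification undefined")
    s, e = alignment.bait_interval
    left = min(e, roi[0]) - s >= min_anchor
    right = e - max(s, roi[1]) >= min_anchor
    if left and right:
        return SPANNING
    if left:
        return LEFT_ANCHORED
    if right:
        return RIGHT_ANCHORED
    return NON_INFORMATIVE


def recruit(bait: Bait, reads, scoring: AlignScoring | None = None):
    """Align every read; returns (alignments, oriented_seqs).

    ``oriented_seqs`` maps read id -> sequence in bait-forward
    orientation (minus-strand reads reverse-complemented once, here), the
    orientation the assembler works in.
    """
    scoring = scoring or AlignScoring()
    index = bait_index(bait, scoring)
    alignments: list[LocalAlignment] = []
    oriented: dict[str, str] = {}
    for read in reads:
        aln = align_read(bait, read, scoring, index)
        if aln is None:
            continue
        alignments.append(aln)
        oriented[read.id] = (read.sequence if aln.strand == "+"
                             else revcomp(read.sequence))
    logger.info("recruited %d reads", len(alignments))
    return alignments, oriented


def build_score_bins(alignments, n_bins: int = 5,
                     bin_width: float | None = None) -> list[ScoreBin]:
    """Equal-width histogram bins over alignment scores.

    Bins partition the recruited set: [lower, upper) half-open with the
    top bin closed.  Empty bins are dropped.
    """
    if not alignments:
        raise RecruitmentError("nothing recruited")
    scores = [a.score for a in alignments]
    lo, hi = min(scores), max(scores)
    if bin_width is not None:
        n_bins = max(1, int((hi - lo) / bin_width) + 1)
        edges = [lo + i * bin_width for i in range(n_bins + 1)]
    elif hi == lo:
        edges = [lo, lo + 1]
        n_bins = 1
    else:
        step = (hi - lo) / n_bins
        edges = [lo + i * step for i in range(n_bins)] + [float(hi)]
    bins = [ScoreBin(edges[i], edges[i + 1], []) for i in range(len(edges) - 1)]
    for a in alignments:
        idx = len(bins) - 1
        for i in range(len(bins)):
            if a.score < bins[i].upper:
                idx = i
                break
        bins[idx].read_ids.append(a.read_id)
    bins = [b for b in bins if b.read_ids]
    assert sum(len(b.read_ids) for b in bins) == len(alignments), \
        "score bins must partition the recruited reads"
    for b in bins:
        b.read_ids.sort()
    return bins


# ---------------------------------------------------------------------------
# external alignment import (SAM via pysam, minimal PAF)


def _alignment_from_pairs(read_seq: str, bait_seq: str, read_start: int,
                          bait_start: int, cigar, scoring: AlignScoring):
    """Rebuild =/X/I/D ops by comparing sequences along a CIGAR."""
    from .align import OP_DEL, OP_INS, OP_MATCH, OP_MISMATCH, ops_to_cigar
    import numpy as np
    ops: list[int] = []
    q, t = read_start, bait_start
    for length, op in cigar:
        if op in "M=X":
            for i in range(length):
                same = read_seq[q + i].upper() == bait_seq[t + i].upper()
                ops.append(OP_MATCH if same else OP_MISMATCH)
            q += length
            t += length
        elif op in "IS":
            if op == "I":
                ops.extend([OP_INS] * length)
            q += length
        elif op in "DN":
            ops.extend([OP_DEL] * length)
            t += length
        elif op == "H":
            pass
        else:
            raise ValueError(f"unsupported cigar op {op!r}")
    arr = np.asarray(ops, dtype=np.uint8)
    cig = ops_to_cigar(arr)
    n_match = int((arr == OP_MATCH).sum())
    identity = 100.0 * n_match / arr.size if arr.size else 0.0
    return cig, score_cigar(cig, scoring), identity, q, t


def import_alignments(path, fmt: str, bait: Bait, reads=None,
                      scoring: AlignScoring | None = None) -> list[LocalAlignment]:
    """Convert SAM or PAF records into LocalAlignments.

    Unmapped/secondary/supplementary records are dropped; scores are
    recomputed from the edit path under the scoring in force so binning
    is independent of the external aligner.  PAF lines without a cg:Z
    tag are re-aligned (needs ``reads``: id -> LongRead).
    """
    scoring = scoring or AlignScoring()
    fmt = fmt.upper()
    out: list[LocalAlignment] = []
    if fmt == "SAM":
        import pysam
        with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
            for rec in fh:
                try:
                    if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                        continue
                    seq = rec.query_sequence
                    if seq is None or not rec.cigartuples:
                        raise ValueError("missing sequence or CIGAR")
                    cig = [(l, "MIDNSHP=X"[op]) for op, l in rec.cigartuples]
                    lead = cig[0][0] if cig[0][1] in "SH" else 0
                    edit, score, ident, q_end, t_end = _alignment_from_pairs(
                        seq, bait.unmasked_sequence, lead,
                        rec.reference_start, cig, scoring)
                    strand = "-" if rec.is_reverse else "+"
                    q_start = lead
                    if strand == "-":
                        n = len(seq)
                        read_interval = (n - q_end, n - q_start)
                    else:
                        read_interval = (q_start, q_end)
                    out.append(LocalAlignment(
                        read_id=rec.query_name,
                        bait_interval=(rec.reference_start, t_end),
                        read_interval=read_interval,
                        strand=strand,
                        score=score,
                        identity=round(ident, 2),
                        edit_path=edit,
                    ))
                except (ValueError, IndexError) as exc:
                    logger.warning("skipping malformed SAM record %s: %s",
                                   getattr(rec, "query_name", "?"), exc)
    elif fmt == "PAF":
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line:
                    continue
                try:
                    f = line.split("\t")
                    rid, rlen, rs, re_ = f[0], int(f[1]), int(f[2]), int(f[3])
                    strand, ts, te = f[4], int(f[7]), int(f[8])
                    cg = None
                    for t in f[12:]:
                        if t.startswith("cg:Z:"):
                            cg = t[5:]
                    if reads is not None and rid in reads:
                        rseq = reads[rid].sequence
                        oriented = rseq if strand == "+" else revcomp(rseq)
                        q0 = rs if strand == "+" else rlen - re_
                        q1 = re_ if strand == "+" else rlen - rs
                        if cg is not None:
                            cigar = list(cigar_ops(cg))
                        else:
                            import edlib
                            res = edlib.align(oriented[q0:q1],
                                              bait.unmasked_sequence[ts:te],
                                              mode="NW", task="path")
                            cigar = list(cigar_ops(res["cigar"]))
                        edit, score, ident, _, _ = _alignment_from_pairs(
                            oriented, bait.unmasked_sequence, q0, ts,
                            cigar, scoring)
                    else:
                        raise ValueError("read sequence required for PAF import")
                    out.append(LocalAlignment(
                        read_id=rid,
                        bait_interval=(ts, te),
                        read_interval=(rs, re_),
                        strand=strand,
                        score=score,
                        identity=round(ident, 2),
                        edit_path=edit,
                    ))
                except (ValueError, IndexError, KeyError) as exc:
                    logger.warning("skipping malformed PAF line %d: %s",
                                   lineno, exc)
    else:
        raise ValueError(f"unknown alignment format {fmt!r}")
    if not out:
        raise RecruitmentError("zero usable records")
    return out
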