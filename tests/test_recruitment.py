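"""Read recruitment, ROI-anchoring classification, score binning, and
external alignment import."""

import random

import pytest

from mvrasm.align import AlignScoring, revcomp
from mvrasm.recruitment import (LongRead, RecruitmentError, align_read,
                                build_score_bins, classify_read,
                                import_alignments, recruit)
from conftest import mutate


def test_read_matching_unmasked_flank_aligns_perfectly(small_bait):
    scoring = AlignScoring()
    read = LongRead("r", small_bait.unmasked_sequence[0:800])
    aln = align_read(small_bait, read, scoring)
    assert aln.identity == 100.0
    assert aln.score == 800 * scoring.match
    assert aln.strand == "+"
    assert aln.bait_interval == (0, 800)


def test_read_inside_masked_roi_is_not_recruited(small_bait):
    rs, re_ = small_bait.roi_local
    read = LongRead("r", small_bait.unmasked_sequence[rs + 2:re_ - 2])
    assert align_read(small_bait, read, AlignScoring()) is None


def test_recruitment_is_strand_symmetric(small_bait):
    rng = random.Random(5)
    seq = mutate(small_bait.unmasked_sequence[100:1300], rng)
    fwd = align_read(small_bait, LongRead("f", seq), AlignScoring())
    rev = align_read(small_bait, LongRead("r", revcomp(seq)), AlignScoring())
    assert fwd.score == rev.score
    assert {fwd.strand, rev.strand} == {"+", "-"}
    assert fwd.bait_interval == rev.bait_interval
    n = len(seq)
    assert rev.read_interval == (n - fwd.read_interval[1],
                                 n - fwd.read_interval[0])


def test_classification_against_roi(small_bait):
    scoring = AlignScoring()
    seq = small_bait.unmasked_sequence
    rs, re_ = small_bait.roi_local
    full = align_read(small_bait, LongRead("a", seq), scoring)
    assert classify_read(full, small_bait, min_anchor=300) == "spanning"
    left = align_read(small_bait, LongRead("b", seq[:rs + 100]), scoring)
    assert classify_read(left, small_bait, min_anchor=300) == "left_anchored"
    right = align_read(small_bait, LongRead("c", seq[re_ - 100:]), scoring)
    assert classify_read(right, small_bait, min_anchor=300) == "right_anchored"
    tiny = align_read(small_bait, LongRead("d", seq[rs - 80:rs + 40]),
                      scoring)
    assert classify_read(tiny, small_bait, min_anchor=300) == "non_informative"


def _fake_alignment(rid, score):
    from mvrasm.recruitment import LocalAlignment
    return LocalAlignment(read_id=rid, bait_interval=(0, 10),
                          read_interval=(0, 10), strand="+", score=score,
                          identity=100.0, edit_path="10=")


def test_identical_scores_fall_in_one_bin():
    alns = [_fake_alignment(f"r{i}", 50) for i in range(10)]
    bins = build_score_bins(alns, n_bins=4)
    assert len(bins) == 1
    assert len(bins[0].read_ids) == 10


def test_hand_histogram_two_bins():
    alns = [_fake_alignment(f"r{i}", s)
            for i, s in enumerate([10, 20, 30, 40])]
    bins = build_score_bins(alns, n_bins=2)
    assert [b.read_ids for b in bins] == [["r0", "r1"], ["r2", "r3"]]
    assert bins[0].lower == 10 and bins[1].upper == 40


def test_bins_partition_recruited_reads(small_bait, small_truth):
    rng = random.Random(9)
    reads = []
    locus = small_truth.locus
    for i in range(40):
        s = rng.randrange(0, len(locus) - 400)
        seq = mutate(locus[s:s + rng.randrange(400, 1200)], rng)
        reads.append(LongRead(f"n{i:03d}", seq))
    alignments, oriented = recruit(small_bait, reads, AlignScoring())
    bins = build_score_bins(alignments, n_bins=5)
    ids = [rid for b in bins for rid in b.read_ids]
    assert sorted(ids) == sorted(a.read_id for a in alignments)
    assert len(set(ids)) == len(ids)
    assert set(oriented) == set(ids)


def test_empty_recruitment_raises():
    with pytest.raises(RecruitmentError, match="nothing recruited"):
        build_score_bins([])


SAM_TEMPLATE = """@HD\tVN:1.6\tSO:unknown
@SQ\tSN:{bid}\tLN:{blen}
{records}"""


def test_sam_import_roundtrip(small_bait, tmp_path):
    scoring = AlignScoring()
    seq = small_bait.unmasked_sequence[50:150]
    rec = f"q1\t0\t{small_bait.id}\t51\t60\t100M\t*\t0\t0\t{seq}\t*"
    unmapped = f"q2\t4\t*\t0\t0\t*\t*\t0\t0\tACGT\t*"
    sam = tmp_path / "in.sam"
    sam.write_text(SAM_TEMPLATE.format(bid=small_bait.id,
                                       blen=len(small_bait.sequence),
                                       records=rec + "\n" + unmapped + "\n"))
    alns = import_alignments(sam, "SAM", small_bait)
    assert len(alns) == 1
    a = alns[0]
    assert a.bait_interval == (50, 150)
    assert a.identity == 100.0
    assert a.score == 100 * scoring.match
    assert a.edit_path == "100="


def test_sam_import_all_unmapped_raises(small_bait, tmp_path):
    sam = tmp_path / "un.sam"
    sam.write_text(SAM_TEMPLATE.format(
        bid=small_bait.id, blen=len(small_bait.sequence),
        records="q1\t4\t*\t0\t0\t*\t*\t0\t0\tACGT\t*\n"))
    with pytest.raises(RecruitmentError, match="zero usable"):
        import_alignments(sam, "SAM", small_bait)


def test_paf_import_minus_strand(small_bait, tmp_path):
    # a read equal to the reverse complement of bait[200:500)
    sub = small_bait.unmasked_sequence[200:500]
    read = LongRead("p1", revcomp(sub))
    line = (f"p1\t300\t0\t300\t-\t{small_bait.id}\t"
            f"{len(small_bait.sequence)}\t200\t500\t300\t300\t60\tcg:Z:300=\n")
    paf = tmp_path / "in.paf"
    paf.write_text(line)
    alns = import_alignments(paf, "PAF", small_bait, reads={"p1": read})
    assert len(alns) == 1
    a = alns[0]
    assert a.strand == "-"
    assert a.bait_interval == (200, 500)
    assert a.read_interval == (0, 300)
    assert a.identity == 100.0
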