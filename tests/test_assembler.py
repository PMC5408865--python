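"""Overlap detection, greedy layout, consensus polishing, and selection."""

import random

import pytest

from mvrasm.align import AlignScoring, revcomp
from mvrasm.assembler import (AssemblyError, all_pairs_overlaps,
                              assemble_and_select, assemble_bin, consensus,
                              greedy_layout)
from mvrasm.recruitment import ScoreBin
from conftest import mutate, random_seq

SCORING = AlignScoring()


def test_exact_suffix_prefix_overlap():
    rng = random.Random(0)
    truth = random_seq(rng, 3000)
    reads = {"a": truth[:2000], "b": truth[1000:3000]}
    ovls = all_pairs_overlaps(reads, SCORING)
    assert len(ovls) == 1
    ov = ovls[0]
    assert ov.kind == "dovetail_ab"
    assert ov.identity == 100.0
    assert ov.length == 1000
    assert ov.a_interval == (1000, 2000)
    assert ov.b_interval == (0, 1000)


def test_disjoint_reads_have_no_overlap():
    rng = random.Random(1)
    reads = {"a": random_seq(rng, 2000), "b": random_seq(rng, 2000)}
    assert all_pairs_overlaps(reads, SCORING) == []


def test_perfect_tiling_layout_and_exact_consensus():
    rng = random.Random(2)
    truth = random_seq(rng, 10000)
    reads = {f"r{i:02d}": truth[i * 1000:i * 1000 + 2000] for i in range(9)}
    ovls = all_pairs_overlaps(reads, SCORING)
    layouts = greedy_layout(ovls, reads)
    assert len(layouts) == 1
    assert layouts[0].read_ids == [f"r{i:02d}" for i in range(9)]
    assert [off for _, off, _ in layouts[0].entries] == \
        [i * 1000 for i in range(9)]
    contig = consensus(layouts[0], reads, rounds=2, scoring=SCORING)
    assert contig.sequence == truth
    assert len(contig.support) == len(contig.sequence)
    assert contig.contributing_reads == sorted(reads)


def test_single_read_layout_returns_the_read():
    reads = {"solo": random_seq(random.Random(3), 1500)}
    layouts = greedy_layout([], reads)
    assert len(layouts) == 1
    contig = consensus(layouts[0], reads, scoring=SCORING)
    assert contig.sequence == reads["solo"]


def test_two_components_largest_first():
    rng = random.Random(4)
    t1 = random_seq(rng, 5000)
    t2 = random_seq(rng, 2500)
    reads = {f"x{i}": t1[i * 800:i * 800 + 1600] for i in range(5)}
    reads.update({f"y{i}": t2[i * 800:i * 800 + 1600] for i in range(2)})
    ovls = all_pairs_overlaps(reads, SCORING)
    layouts = greedy_layout(ovls, reads)
    assert len(layouts) == 2
    assert len(layouts[0].entries) >= len(layouts[1].entries)
    assert all(r.startswith("x") for r in layouts[0].read_ids)


def test_opposite_orientation_reads_merge():
    rng = random.Random(5)
    truth = random_seq(rng, 3000)
    reads = {"a": truth[:2000], "b": revcomp(truth[1000:3000])}
    ovls = all_pairs_overlaps(reads, SCORING)
    assert len(ovls) == 1 and ovls[0].orientation == "opposite"
    layouts = greedy_layout(ovls, reads)
    contig = consensus(layouts[0], reads, scoring=SCORING)
    assert contig.sequence in (truth, revcomp(truth))


def test_containment_is_removed_from_layout():
    rng = random.Random(6)
    truth = random_seq(rng, 4000)
    reads = {"big": truth, "small": truth[1000:2000]}
    ovls = all_pairs_overlaps(reads, SCORING)
    assert any("contains" in ov.kind for ov in ovls)
    layouts = greedy_layout(ovls, reads)
    assert layouts[0].read_ids == ["big"]
    assert layouts[0].contained == {"small": "big"}


def test_noisy_consensus_recovers_truth_to_high_identity():
    """50x indel-dominant reads over a 6 kb locus polish to >=99%."""
    import edlib
    rng = random.Random(7)
    truth = random_seq(rng, 6000)
    reads = {}
    total, i = 0, 0
    while total < 50 * 6000:
        s = rng.randrange(0, 5000)
        ln = min(rng.randrange(1500, 4000), 6000 - s)
        i += 1
        reads[f"n{i:03d}"] = mutate(truth[s:s + ln], rng)
        total += ln
    contig = assemble_bin("t", sorted(reads), reads, SCORING)
    d = edlib.align(contig.sequence, truth, mode="HW",
                    task="distance")["editDistance"]
    # interior accuracy is what matters; allow ragged ends
    assert d <= 0.01 * len(truth)
    assert len(contig.contributing_reads) >= 0.9 * len(reads)


def test_assembly_is_deterministic():
    rng = random.Random(8)
    truth = random_seq(rng, 4000)
    reads = {}
    for i in range(30):
        s = rng.randrange(0, 3000)
        reads[f"d{i:02d}"] = mutate(truth[s:s + 1500], rng)
    c1 = assemble_bin("t", sorted(reads), reads, SCORING)
    c2 = assemble_bin("t", sorted(reads), reads, SCORING)
    assert c1.sequence == c2.sequence
    assert c1.contributing_reads == c2.contributing_reads


def test_selection_prefers_highest_bait_score(small_bait):
    seq = small_bait.unmasked_sequence
    # bin0 reproduces the bait exactly; bin1 holds a flank fragment
    oriented = {"full": seq, "frag": seq[:700]}
    bins = [ScoreBin(0, 1, ["frag"]), ScoreBin(1, 2, ["full"])]
    contig, aln, table = assemble_and_select(bins, oriented, small_bait,
                                             SCORING)
    assert contig.sequence == seq
    assert aln.identity == 100.0
    rows = {r["bin"]: r for r in table}
    assert rows["bin1"]["selected"] or rows["pooled"]["selected"]
    best_score = max(r["score_vs_bait"] for r in table)
    assert aln.score == best_score


def test_assemble_and_select_empty_is_error(small_bait):
    with pytest.raises(AssemblyError):
        assemble_and_select([], {}, small_bait, SCORING)
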