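"""Synthetic locus and read simulator: truth bookkeeping, error model and
determinism."""

import random

import pytest

import edlib

from mvrasm.align import revcomp
from mvrasm.simulate import (LocusSpec, ReadSimConfig,
                             make_locus, make_variant_table, simulate_reads,
                             write_fastq)
from conftest import levenshtein


def test_variant_table_single_substitution_structure():
    table = make_variant_table(9, 19, seed=1)
    assert len(table.codes) == 19
    assert sorted(table.codes) == [chr(65 + i) for i in range(19)]
    seqs = list(table.codes.values())
    assert len(set(seqs)) == 19
    for v in seqs:
        assert len(v) == 9
        assert sum(a != b for a, b in zip(v, table.consensus_unit)) == 1


def test_variant_table_capacity_error():
    with pytest.raises(ValueError):
        make_variant_table(5, 16, seed=0)


def test_minimal_table():
    table = make_variant_table(9, 1, seed=2)
    assert list(table.codes) == ["A"]


def test_locus_arithmetic(small_table):
    spec = LocusSpec(table=small_table, allele="AAAA", partial_bp=0,
                     flank_length=500, pad_length=100)
    truth = make_locus(spec, seed=0)
    assert truth.array_length == 36
    assert truth.code_string == "AAAA"
    a0, a1 = truth.array_interval
    assert truth.locus[a0:a1] == small_table.codes["A"] * 4


def test_ms1_scale_array_length():
    table = make_variant_table(9, 19, seed=1)
    spec = LocusSpec(table=table, n_complete_units=523, partial_bp=7)
    truth = make_locus(spec, seed=1)
    assert truth.array_length == 523 * 9 + 7 == 4714
    assert len(truth.code_string) == 523


def test_error_free_reads_are_locus_substrings(small_truth):
    cfg = ReadSimConfig(coverage=5.0, ins_rate=0, del_rate=0, sub_rate=0,
                        min_len=300, seed=4)
    reads, origins = simulate_reads(small_truth, cfg)
    for rid, seq in reads:
        s, e, strand = origins[rid]
        frag = small_truth.locus[s:e]
        assert seq == (frag if strand == "+" else revcomp(frag))


def test_same_seed_gives_byte_identical_fastq(small_truth, tmp_path):
    cfg = ReadSimConfig(coverage=3.0, seed=9)
    r1, _ = simulate_reads(small_truth, cfg)
    r2, _ = simulate_reads(small_truth, cfg)
    p1, p2 = tmp_path / "a.fastq", tmp_path / "b.fastq"
    write_fastq(r1, p1)
    write_fastq(r2, p2)
    assert p1.read_bytes() == p2.read_bytes()


def test_coverage_close_to_requested(small_truth):
    cfg = ReadSimConfig(coverage=30.0, min_len=300, seed=5)
    reads, origins = simulate_reads(small_truth, cfg)
    true_bases = sum(e - s for s, e, _ in origins.values())
    fold = true_bases / len(small_truth.locus)
    assert abs(fold - 30.0) / 30.0 <= 0.15


def test_empirical_error_rates_match_nominal(small_truth):
    """Realized per-category error rates over >=100 kb of simulated
    bases sit within 10% relative of nominal, and the minimal edit
    distance of each read to its origin is consistent with ~15% total
    error (independent alignment cross-check)."""
    cfg = ReadSimConfig(coverage=40.0, seed=6)
    reads, origins, stats = simulate_reads(small_truth, cfg,
                                           return_stats=True)
    n_true = stats["true_bases"]
    assert n_true >= 100_000
    assert abs(stats["ins"] / n_true - 0.10) / 0.10 <= 0.10
    assert abs(stats["del"] / n_true - 0.04) / 0.04 <= 0.10
    assert abs(stats["sub"] / n_true - 0.01) / 0.01 <= 0.10
    # cross-check with an independent aligner: minimal edit distance can
    # only be at or below the number of applied errors
    total_dist = 0
    for rid, seq in reads[:20]:
        s, e, strand = origins[rid]
        frag = small_truth.locus[s:e]
        if strand == "-":
            frag = revcomp(frag)
        total_dist += edlib.align(seq, frag, mode="NW",
                                  task="distance")["editDistance"]
        assert seq != frag
    sampled = sum(e - s for s, e, _ in
                  [origins[r] for r, _ in reads[:20]])
    assert 0.10 <= total_dist / sampled <= 0.15


def test_zero_coverage_is_an_error(small_truth):
    with pytest.raises(ValueError):
        ReadSimConfig(coverage=0.0)


def test_boundary_guards_hold(small_truth, small_table):
    """Flank bases adjacent to the planted array cannot continue the
    repeat pattern (makes truth boundaries unambiguous)."""
    a0, a1 = small_truth.array_interval
    locus = small_truth.locus
    cons = small_table.consensus_unit
    p = len(cons)
    phase = small_truth.array_length % p
    right_cont = (cons[phase:] + cons)[:p]
    assert locus[a1] != right_cont[0]
    assert locus[a1 + 1] != right_cont[1]
    assert locus[a0 - 1] != cons[-1]
    assert locus[a0 - 2] != cons[-2]
    assert levenshtein(locus[a1:a1 + p], right_cont) > 3
    assert levenshtein(locus[a0 - p:a0], cons) > 3
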