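"""Array location, wraparound decomposition, MVR unit classification, and
allele-structure comparison."""

import random

import pytest

from mvrasm.align import AlignScoring, revcomp
from mvrasm.array_decoder import (ArrayLocationError, VariantTable,
                                  classify_unit, compare_alleles,
                                  decode_allele, decode_array_seq,
                                  decompose_array, locate_array)
from mvrasm.insilico_pcr import PrimerPair, detect_and_mask_tandem_repeats, extract_bait
from mvrasm.simulate import make_variant_table
from conftest import levenshtein, random_seq

SCORING = AlignScoring()


# --- classify_unit -------------------------------------------------------

def test_classify_exact_variant(small_table):
    code = sorted(small_table.codes)[2]
    got, dist, tie = classify_unit(small_table.codes[code], small_table)
    assert (got, dist, tie) == (code, 0, False)


def test_classify_tie_breaks_lexicographically():
    table = VariantTable(consensus_unit="AAAAAAAAA",
                         codes={"A": "CAAAAAAAA", "D": "AAAAAAAAC"})
    # equidistant (distance 1) from both variants
    got, dist, tie = classify_unit("AAAAAAAAA", table)
    assert (got, dist, tie) == ("A", 1, True)


def test_classify_far_unit_gets_null_code(small_table):
    rng = random.Random(0)
    while True:  # find a 9-mer beyond the distance threshold of every variant
        probe = random_seq(rng, 9)
        if min(levenshtein(probe, v)
               for v in small_table.codes.values()) > 3:
            break
    got, dist, tie = classify_unit(probe, small_table)
    assert got == small_table.null_code
    assert dist > 3


def test_classify_empty_unit(small_table):
    got, dist, tie = classify_unit("", small_table)
    assert got == small_table.null_code
    assert dist == small_table.period


@pytest.mark.parametrize("seed", range(6))
def test_classify_distance_matches_textbook_dp(seed, small_table):
    rng = random.Random(seed)
    observed = random_seq(rng, rng.randrange(6, 12))
    _, dist, _ = classify_unit(observed, small_table,
                               max_unit_distance=100)
    oracle = min(levenshtein(observed, v)
                 for v in small_table.codes.values())
    assert dist == oracle


# --- decompose_array -----------------------------------------------------

def test_decompose_exact_copies(small_table):
    unit = small_table.consensus_unit
    segs = decompose_array(unit * 20, unit)
    assert len(segs) == 20
    assert all(c for *_, c in segs)


def test_decompose_counts_partial_separately(small_table):
    unit = small_table.consensus_unit
    segs = decompose_array(unit * 4 + unit[:6], unit)
    complete = [s for s in segs if s[2]]
    partial = [s for s in segs if not s[2]]
    assert len(complete) == 4
    assert len(partial) == 1 and partial[0][1] - partial[0][0] == 6


def test_decode_array_arithmetic_at_ms1_scale():
    """523 complete units + 7 bp partial = 4714 bp = 523.8 copies."""
    table = make_variant_table(9, 19, seed=1)
    rng = random.Random(1)
    codes = sorted(table.codes)
    code_string = "".join(rng.choice(codes) for _ in range(523))
    array = "".join(table.codes[c] for c in code_string) \
        + table.consensus_unit[:7]
    assert len(array) == 4714
    decoding = decode_array_seq(array, table)
    assert decoding.complete_units == 523
    assert decoding.partial_length == 7
    assert decoding.copy_number == 523.8
    assert decoding.code_string == code_string


def test_error_free_roundtrip_of_code_string(small_table):
    rng = random.Random(17)
    codes = sorted(small_table.codes)
    code_string = "".join(rng.choice(codes) for _ in range(40))
    array = "".join(small_table.codes[c] for c in code_string)
    decoding = decode_array_seq(array, small_table)
    assert decoding.code_string == code_string
    assert decoding.complete_units == 40
    assert all(not u.tie and u.edit_distance == 0
               for u in decoding.unit_calls)
    # units tile the interval without overlap
    cursor = decoding.array_interval[0]
    for u in decoding.unit_calls:
        assert u.interval[0] == cursor
        cursor = u.interval[1]


def test_complete_units_times_period_plus_partial_is_length(small_table):
    unit = small_table.consensus_unit
    array = unit * 7 + unit[:3]
    d = decode_array_seq(array, small_table)
    assert d.complete_units * 9 + d.partial_length == len(array)


# --- locate_array / decode_allele ---------------------------------------

def test_locate_on_bait_itself_matches_roi(small_bait):
    loc = locate_array(small_bait.unmasked_sequence, small_bait, SCORING,
                       min_anchor=300)
    assert loc == small_bait.roi_local


def test_locate_fallback_with_one_flank(small_bait, caplog):
    rs, re_ = small_bait.roi_local
    # contig missing the right flank entirely
    contig = small_bait.unmasked_sequence[:re_ + 20]
    with caplog.at_level("WARNING"):
        loc = locate_array(contig, small_bait, SCORING, min_anchor=300)
    assert "one flank" in caplog.text
    assert abs(loc[0] - rs) <= 10


def test_locate_without_any_anchor_raises(small_bait):
    rng = random.Random(23)
    with pytest.raises(ArrayLocationError):
        locate_array(random_seq(rng, 2000), small_bait, SCORING)


def test_decode_allele_on_bait_reproduces_truth(small_bait, small_truth,
                                                small_table):
    decoding = decode_allele(small_bait.unmasked_sequence, small_bait,
                             small_table, SCORING, min_anchor=300)
    truth_copies = round(small_truth.array_length / 9, 1)
    assert decoding.copy_number == truth_copies
    assert decoding.code_string == small_truth.code_string
    assert decoding.complete_units == len(small_truth.code_string)


def test_copy_number_invariant_under_joint_revcomp(small_truth, small_table):
    """Reverse-complementing contig, bait and unit table together (the
    mirror experiment) yields the same decoded copy number."""
    fwd = decode_allele_from_locus(small_truth.locus, small_truth.primers,
                                   small_table)
    rc_pair = PrimerPair(forward=small_truth.primers.reverse,
                         reverse=small_truth.primers.forward)
    rc_table = VariantTable(
        consensus_unit=revcomp(small_table.consensus_unit),
        codes={k: revcomp(v) for k, v in small_table.codes.items()})
    rev = decode_allele_from_locus(revcomp(small_truth.locus), rc_pair,
                                   rc_table)
    assert fwd.copy_number == rev.copy_number


def decode_allele_from_locus(locus, primers, table):
    bait = extract_bait(locus, primers, flank_length=1000)
    bait, _ = detect_and_mask_tandem_repeats(bait)
    return decode_allele(bait.unmasked_sequence, bait, table, SCORING,
                         min_anchor=300)


def test_sub_period_array_decodes_to_fraction(small_table, small_bait):
    d = decode_array_seq(small_table.consensus_unit[:4], small_table)
    assert d.copy_number < 1.0
    assert d.code_string == ""


# --- compare_alleles -----------------------------------------------------

def test_identical_code_strings_fully_match():
    comp = compare_alleles("ABCABC", "ABCABC")
    assert (comp.n_match, comp.n_mismatch, comp.n_indel) == (6, 0, 0)
    assert comp.five_prime_consistent and comp.three_prime_consistent


def test_single_unit_loss_is_one_indel():
    comp = compare_alleles("AAABBB", "AAABB")
    assert comp.n_match == 5
    assert comp.n_indel == 1
    assert comp.n_mismatch == 0


def test_internal_expansion_keeps_ends_consistent():
    """An allele carrying a 20-unit internal expansion still shows 5' and
    3' structural consistency (the recovered-missing-sequence case)."""
    left, right = "ABCDABCDABCD", "DCBADCBADCBA"
    short = left + right
    long = left + "Q" * 20 + right
    comp = compare_alleles(short, long, end_window=10)
    assert comp.n_indel >= 20
    assert comp.five_prime_consistent
    assert comp.three_prime_consistent


def test_comparison_counts_sum_to_columns():
    comp = compare_alleles("ABCAB", "ACBAB")
    assert comp.n_match + comp.n_mismatch + comp.n_indel \
        == len(comp.aligned_a)
    assert len(comp.aligned_a) == len(comp.aligned_b)
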