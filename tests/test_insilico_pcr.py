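"""In-silico PCR scanning/extraction and tandem-repeat masking."""

import random

import pytest

from mvrasm.align import revcomp
from mvrasm.insilico_pcr import (AmpliconError, PrimerPair,
                                 detect_and_mask_tandem_repeats, extract_bait,
                                 scan_primer_sites)
from mvrasm.simulate import LocusSpec, make_locus
from conftest import random_seq

MS1_FWD = "GCTTTTCTGTGATGAGCCTTGATG"
MS1_REV = "AGAAGCATATGCAACCCATGAGG"


def brute_force_scan(reference, primer, max_mm, three_exact):
    """Exhaustive position/strand scan (test oracle)."""
    hits = []
    m = len(primer)
    for pattern, strand in ((primer, "+"), (revcomp(primer), "-")):
        for pos in range(len(reference) - m + 1):
            window = reference[pos:pos + m].upper()
            mism = sum(1 for a, b in zip(window, pattern.upper())
                       if a != b or a not in "ACGT")
            if strand == "+":
                zone = range(m - three_exact, m)
            else:
                zone = range(0, three_exact)
            exact = all(window[i] == pattern[i].upper() and window[i] in "ACGT"
                        for i in zone)
            if mism <= max_mm and exact:
                hits.append((pos, pos + m, strand, mism))
    return sorted(hits)


@pytest.mark.parametrize("seed", range(5))
def test_primer_scan_matches_exhaustive_oracle(seed):
    rng = random.Random(seed)
    reference = random_seq(rng, 2000)
    primer = random_seq(rng, 8)  # short primer: plenty of chance hits
    got = scan_primer_sites(reference, primer, max_mismatches=2,
                            three_prime_exact=3)
    want = brute_force_scan(reference, primer, 2, 3)
    assert [(s.start, s.end, s.strand, s.mismatches) for s in got] == want


def test_embedded_ms1_forward_primer_found_exactly():
    rng = random.Random(42)
    reference = random_seq(rng, 1000) + MS1_FWD + random_seq(rng, 1000)
    sites = [s for s in scan_primer_sites(reference, MS1_FWD,
                                          max_mismatches=0)
             if s.strand == "+"]
    assert [(s.start, s.mismatches) for s in sites] == [(1000, 0)]


def test_absent_primer_yields_no_sites():
    assert scan_primer_sites("ACGT" * 100, "TTTTTTTTTTTTTTTTTTTT") == []


def test_scan_input_validation():
    with pytest.raises(ValueError):
        scan_primer_sites("", "ACGTACGTAA")
    with pytest.raises(ValueError):
        scan_primer_sites("ACGTACGT", "ACNT")
    with pytest.raises(ValueError):
        PrimerPair(forward="ACGTN", reverse="ACGTA")


def test_extract_bait_coordinates_roundtrip():
    rng = random.Random(7)
    insert = random_seq(rng, 1000)
    pair = PrimerPair(forward=MS1_FWD, reverse=MS1_REV)
    reference = (random_seq(rng, 6000) + MS1_FWD + insert
                 + revcomp(MS1_REV) + random_seq(rng, 6000))
    bait = extract_bait(reference, pair, flank_length=5000)
    s, e = bait.source_interval
    assert bait.sequence == reference[s:e]
    fs, fe = bait.amplicon_interval
    assert fs == 6000
    assert fe == 6000 + len(MS1_FWD) + 1000 + len(MS1_REV)
    assert bait.amplicon_length == fe - fs


def test_extract_bait_wrong_orientation_is_no_amplicon():
    rng = random.Random(8)
    pair = PrimerPair(forward=MS1_FWD, reverse=MS1_REV)
    # reverse primer planted as-synthesized (not reverse-complemented):
    # no valid product geometry exists
    reference = (random_seq(rng, 2000) + MS1_FWD + random_seq(rng, 500)
                 + MS1_REV + random_seq(rng, 2000))
    with pytest.raises(AmpliconError, match="no amplicon"):
        extract_bait(reference, pair)


def test_extract_bait_prefers_shortest_product():
    rng = random.Random(9)
    pair = PrimerPair(forward=MS1_FWD, reverse=MS1_REV)
    rc = revcomp(MS1_REV)
    reference = (random_seq(rng, 1000) + MS1_FWD + random_seq(rng, 300)
                 + rc + random_seq(rng, 2000) + rc + random_seq(rng, 1000))
    bait = extract_bait(reference, pair, flank_length=100)
    assert bait.amplicon_length == len(MS1_FWD) + 300 + len(MS1_REV)


def test_simulated_amplicon_recovered(small_truth):
    """Cross-module truth check: extraction matches the simulator's
    bookkeeping exactly."""
    bait = extract_bait(small_truth.locus, small_truth.primers,
                        flank_length=1000)
    assert bait.amplicon_interval == small_truth.amplicon_interval


def test_soft_masking_preserves_bases(small_bait, small_truth):
    s, e = small_bait.source_interval
    assert small_bait.unmasked_sequence == small_truth.locus[s:e].upper()
    assert small_bait.mask_intervals  # the array was found and masked
    ms, me = small_bait.mask_intervals[0]
    assert small_bait.sequence[ms - s:me - s].islower()


def test_roi_matches_simulated_array(small_bait, small_truth):
    """Detector boundaries land within a couple of bases of truth on a
    substituted array (a boundary substitution is indistinguishable from
    flank at the sequence level; the decoder resolves it exactly using
    the variant table)."""
    (rs, re_), (ts, te) = small_bait.roi_interval, small_truth.array_interval
    assert abs(rs - ts) <= 2
    assert abs(re_ - te) <= 2


def test_detection_on_exact_copy_array(small_table):
    """A clean planted array of exact consensus copies is annotated with
    the exact period and copy number (boundary-guarded flanks)."""
    unit = small_table.consensus_unit
    spec = LocusSpec(table=small_table, allele="A", partial_bp=0,
                     flank_length=600, pad_length=100)
    # splice an exact 20-copy array into a guarded locus scaffold
    truth = make_locus(spec, seed=5)
    a0, a1 = truth.array_interval
    locus = truth.locus[:a0] + unit * 20 + truth.locus[a1:]
    bait = extract_bait(locus, truth.primers, flank_length=600)
    masked, anns = detect_and_mask_tandem_repeats(bait)
    assert len(anns) == 1
    ann = anns[0]
    assert ann.period == len(unit)
    assert ann.copy_number == 20.0
    assert ann.mean_unit_identity == 100.0
    # consensus may be reported in a rotated phase
    assert ann.consensus_unit in [unit[i:] + unit[:i] for i in range(9)]


def test_detection_on_substituted_array(small_truth):
    """A 30-copy array of single-substitution variants is recovered to
    within half a copy."""
    bait = extract_bait(small_truth.locus, small_truth.primers,
                        flank_length=1000)
    _, anns = detect_and_mask_tandem_repeats(bait)
    long_anns = [a for a in anns if a.length > 100]
    assert len(long_anns) == 1
    truth_copies = round(small_truth.array_length / 9, 1)
    assert abs(long_anns[0].copy_number - truth_copies) <= 0.5
    assert long_anns[0].period == 9
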