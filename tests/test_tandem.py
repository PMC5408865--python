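"""Wraparound DP segmentation against an exhaustive cut-point oracle."""

import random
from functools import lru_cache

import pytest

from mvrasm.tandem import wraparound_segment
from conftest import levenshtein, mutate, random_seq


def exhaustive_segmentation_cost(seq: str, unit: str) -> int:
    """Minimal total edit cost over all tilings of ``seq`` into complete
    unit copies plus one optional terminal partial (oracle, O(n^2)
    segmentations x O(n p) distances; arrays <= ~40 bp only)."""
    p = len(unit)
    n = len(seq)

    @lru_cache(maxsize=None)
    def best(i: int) -> int:
        if i == n:
            return 0
        out = None
        for j in range(i + 1, n + 1):
            seg = seq[i:j]
            cost = levenshtein(seg, unit) + best(j)
            if out is None or cost < out:
                out = cost
        # terminal partial: align the remainder against a unit prefix
        partial = min(levenshtein(seq[i:], unit[:q]) for q in range(p))
        if partial < out:
            out = partial
        return out

    return best(0)


def test_exact_copies_segment_cleanly():
    unit = "GACGTGCAG"
    cost, segs = wraparound_segment(unit * 20, unit)
    assert cost == 0
    assert len(segs) == 20
    assert all(c for *_, c in segs)
    assert all(e - s == 9 for s, e, c in segs)


def test_single_deletion_costs_one():
    unit = "GACGTGCAG"
    arr = unit + unit[:4] + unit[5:] + unit
    cost, segs = wraparound_segment(arr, unit)
    assert cost == 1
    assert len(segs) == 3
    assert [e - s for s, e, _ in segs] == [9, 8, 9]


def test_terminal_partial_unit():
    unit = "GACGTGCAG"
    arr = unit * 3 + unit[:7]
    cost, segs = wraparound_segment(arr, unit)
    assert cost == 0
    assert segs[-1] == (27, 34, False)
    assert sum(1 for *_, c in segs if c) == 3


def test_segments_tile_input_without_gaps():
    rng = random.Random(4)
    unit = random_seq(rng, 7)
    arr = mutate(unit * 6, rng, ins=0.05, dele=0.05, sub=0.05)
    _, segs = wraparound_segment(arr, unit)
    cursor = 0
    for s, e, _ in segs:
        assert s == cursor
        cursor = e
    assert cursor == len(arr)


@pytest.mark.parametrize("seed", range(8))
def test_cost_matches_exhaustive_oracle(seed):
    """Total wraparound cost equals the exhaustive-segmentation oracle on
    small mutated arrays."""
    rng = random.Random(seed)
    p = rng.choice([3, 4, 5])
    unit = random_seq(rng, p)
    n_units = rng.randrange(2, max(3, 38 // p))
    arr = mutate(unit * n_units, rng, ins=0.06, dele=0.06, sub=0.08)
    arr = arr[:40]
    if len(arr) < p:
        arr = unit
    cost, _ = wraparound_segment(arr, unit)
    assert cost == exhaustive_segmentation_cost(arr, unit)
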