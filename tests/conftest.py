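"""Shared fixtures: deterministic RNG helpers, small synthetic loci, and
read-error injection used across the suite."""

import random

import pytest

from mvrasm.simulate import LocusSpec, make_locus, make_variant_table


def random_seq(rng: random.Random, n: int) -> str:
    return "".join(rng.choice("ACGT") for _ in range(n))


def mutate(seq: str, rng: random.Random, ins: float = 0.10,
           dele: float = 0.04, sub: float = 0.01) -> str:
    """Apply indel-dominant per-base errors (test-local implementation)."""
    out = []
    for ch in seq:
        r = rng.random()
        if r < dele:
            continue
        if r < dele + sub:
            ch = rng.choice([c for c in "ACGT" if c != ch])
        out.append(ch)
        if rng.random() < ins:
            out.append(rng.choice("ACGT"))
    return "".join(out)


def levenshtein(a: str, b: str) -> int:
    """Textbook edit-distance DP (the tests' independent oracle)."""
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[j - 1] + 1,
                           prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


def smith_waterman_affine(q: str, t: str, match=1, mismatch=-1,
                          gap_open=-2, gap_extend=-1) -> int:
    """Unbanded local alignment with affine gaps (oracle).

    Gap convention: first gap base costs gap_open, later ones gap_extend.
    """
    m, n = len(q), len(t)
    NEG = -(10 ** 9)
    H = [[0] * (n + 1) for _ in range(m + 1)]
    E = [[NEG] * (n + 1) for _ in range(m + 1)]
    F = [[NEG] * (n + 1) for _ in range(m + 1)]
    best = 0
    for i in range(1, m + 1):
        qi = q[i - 1]
        for j in range(1, n + 1):
            E[i][j] = max(H[i][j - 1] + gap_open, E[i][j - 1] + gap_extend)
            F[i][j] = max(H[i - 1][j] + gap_open, F[i - 1][j] + gap_extend)
            d = H[i - 1][j - 1] + (match if qi == t[j - 1] else mismatch)
            H[i][j] = max(0, d, E[i][j], F[i][j])
            if H[i][j] > best:
                best = H[i][j]
    return best


@pytest.fixture(scope="session")
def small_table():
    """9 bp consensus with 5 single-substitution variants."""
    return make_variant_table(9, 5, seed=3)


@pytest.fixture(scope="session")
def small_truth(small_table):
    """A compact locus: 1 kb flanks around a 30-unit array + 5 bp partial."""
    spec = LocusSpec(table=small_table, n_complete_units=30, partial_bp=5,
                     flank_length=1000, pad_length=150)
    return make_locus(spec, seed=11)


@pytest.fixture(scope="session")
def tiling_reads(small_truth):
    """Error-free 1.2 kb reads tiling the small locus at 200 bp steps."""
    locus = small_truth.locus
    reads = []
    step, length = 200, 1200
    i = 0
    pos = 0
    while pos < len(locus):
        seq = locus[pos:pos + length]
        if len(seq) >= 300:
            reads.append((f"tile{i:04d}", seq))
        i += 1
        pos += step
    # make sure the locus tail is covered by a full-length read
    reads.append((f"tile{i:04d}", locus[-length:]))
    return reads


@pytest.fixture(scope="session")
def small_bait(small_truth):
    from mvrasm.insilico_pcr import detect_and_mask_tandem_repeats, extract_bait
    bait = extract_bait(small_truth.locus, small_truth.primers,
                        flank_length=1000)
    bait, _ = detect_and_mask_tandem_repeats(bait)
    return bait
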