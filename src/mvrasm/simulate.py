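"""Synthetic minisatellite loci and PacBio-like long reads with known truth.

The generator emulates the study design the package targets: a haploid
locus carrying a GC-rich tandem array of a short unit between unique
multi-kilobase flanks, sequenced with indel-dominant errors (~15% total,
insertion-heavy) at ~50-fold coverage with multi-kilobase reads.  Every
structural coordinate and the allele's code string are recorded so each
pipeline stage can be checked against ground truth.
"""

from __future__ import annotations

import json
import math
import string
from dataclasses import dataclass, field

import edlib
import numpy as np

from .align import revcomp
from .array_decoder import VariantTable
from .insilico_pcr import PrimerPair
from .tandem import detect_tandem_repeats

# primer pairs used by the original study (5'->3' as synthesized)
MS1_PRIMERS = PrimerPair(forward="GCTTTTCTGTGATGAGCCTTGATG",
                         reverse="AGAAGCATATGCAACCCATGAGG", name="MS1")
PRDM9_PRIMERS = PrimerPair(forward="TGAGGTTACCTAGTCTGGCA",
                           reverse="ATAAGGGGTCAGCAGACTTC", name="PRDM9")

_CODE_ALPHABET = string.ascii_uppercase + string.ascii_lowercase + string.digits


class SimulationError(RuntimeError):
    pass


@dataclass
class LocusSpec:
    """Recipe for one synthetic minisatellite locus.

    The allele is either an explicit ``allele`` code string over the
    table's codes, or ``n_complete_units`` random codes (drawn from the
    interspersion RNG) plus ``partial_bp`` bases of a terminal partial
    unit.  ``gc_bias`` sets the flank GC fraction (None = uniform).
    """

    table: VariantTable
    allele: str | None = None
    n_complete_units: int | None = None
    partial_bp: int = 0
    flank_length: int = 5000
    primers: PrimerPair = field(default_factory=lambda: MS1_PRIMERS)
    pad_length: int = 300
    gc_bias: float | None = 0.55

    def __post_init__(self):
        if self.allele is None and self.n_complete_units is None:
            raise ValueError("either allele or n_complete_units is required")
        if self.partial_bp >= self.table.period:
            raise ValueError("partial_bp must be < period")


@dataclass
class ReadSimConfig:
    """Read simulator settings (defaults emulate P5-C3-like data).

    Lengths are lognormal (mean ~8 kb) truncated to [min_len, max_len];
    error rates are per-base probabilities by category, insertion-
    dominant and summing to ~15%.
    """

    coverage: float = 50.0
    mean_log: float = math.log(8000.0)
    sd_log: float = 0.35
    min_len: int = 500
    max_len: int = 30000
    ins_rate: float = 0.10
    del_rate: float = 0.04
    sub_rate: float = 0.01
    seed: int = 0

    def __post_init__(self):
        rates = (self.ins_rate, self.del_rate, self.sub_rate)
        if any(r < 0 for r in rates) or sum(rates) >= 1.0:
            raise ValueError("error rates must be >= 0 and sum < 1")
        if self.coverage <= 0:
            raise ValueError("coverage must be > 0")


@dataclass
class SimulatedTruth:
    """Ground truth for a simulated locus and its reads."""

    locus: str
    amplicon_interval: tuple[int, int]
    array_interval: tuple[int, int]
    code_string: str
    partial_length: int
    table: VariantTable
    primers: PrimerPair
    read_origins: dict[str, tuple[int, int, str]] = field(default_factory=dict)

    @property
    def array_length(self) -> int:
        return self.array_interval[1] - self.array_interval[0]

    def save_json(self, path) -> None:
        payload = {
            "amplicon_interval": list(self.amplicon_interval),
            "array_interval": list(self.array_interval),
            "code_string": self.code_string,
            "partial_length": self.partial_length,
            "consensus_unit": self.table.consensus_unit,
            "codes": self.table.codes,
            "primers": {"forward": self.primers.forward,
                        "reverse": self.primers.reverse,
                        "name": self.primers.name},
            "read_origins": {k: list(v) for k, v in self.read_origins.items()},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def make_variant_table(period: int, n_variants: int,
                       seed: int = 0) -> VariantTable:
    """Random consensus unit plus single-substitution variants.

    Variants are coded 'A', 'B', ... in generation order; all are at
    Hamming distance 1 from the consensus and pairwise distinct.
    """
    if n_variants > 3 * period:
        raise ValueError("n_variants exceeds single-substitution capacity")
    if n_variants > len(_CODE_ALPHABET):
        raise ValueError("n_variants exceeds the code alphabet")
    rng = np.random.default_rng(seed)
    bases = "ACGT"
    consensus = "".join(rng.choice(list(bases)) for _ in range(period))
    seen = {consensus}
    codes: dict[str, str] = {}
    i = 0
    while len(codes) < n_variants:
        pos = int(rng.integers(period))
        alt = bases[int(rng.integers(4))]
        if alt == consensus[pos]:
            continue
        variant = consensus[:pos] + alt + consensus[pos + 1:]
        if variant in seen:
            continue
        seen.add(variant)
        codes[_CODE_ALPHABET[i]] = variant
        i += 1
    return VariantTable(consensus_unit=consensus, codes=codes)


def _random_seq(rng, n: int, gc: float | None = None) -> str:
    if gc is None:
        probs = None
    else:
        at = (1.0 - gc) / 2.0
        probs = [at, gc / 2.0, gc / 2.0, at]
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=n, p=probs)])


def _has_tandem(seq: str, max_period: int = 200) -> bool:
    return bool(detect_tandem_repeats(seq, max_period=max_period))


def _boundary_ok(flank_side: str, continuation: str, tol: int) -> bool:
    """True when ``flank_side`` cannot be mistaken for ``continuation``.

    Guards the boundary-extension rules of the tandem detector and the
    allele decoder (unit-grid walks, exact partial extension), so the
    simulated array boundary is unambiguous at single-base resolution:
    the first two flank bases must each break the repeat pattern and the
    whole adjacent window must be far from the pattern continuation.
    """
    if not flank_side or not continuation:
        return True
    for i in range(min(2, len(flank_side), len(continuation))):
        if flank_side[i] == continuation[i]:
            return False
    d = edlib.align(flank_side, continuation, task="distance")["editDistance"]
    return d > tol


def make_locus(spec: LocusSpec, seed: int = 0,
               max_tries: int = 50) -> SimulatedTruth:
    """Assemble a synthetic locus with planted primers and array.

    Layout: left flank | fwd primer | pad | array | pad | rc(rev primer)
    | right flank.  Flanks and pads are rejection-sampled so they contain
    no tandem arrays, no extra primer sites, and no chance continuation of
    the repeat pattern at the array boundaries.
    """
    rng = np.random.default_rng(seed)
    table = spec.table
    p = table.period
    codes = sorted(table.codes)
    if spec.allele is not None:
        unknown = set(spec.allele) - set(codes)
        if unknown:
            raise ValueError(f"allele uses unknown codes {unknown}")
        code_string = spec.allele
    else:
        code_string = "".join(codes[int(rng.integers(len(codes)))]
                              for _ in range(spec.n_complete_units))
    array = "".join(table.codes[c] for c in code_string)
    array += table.consensus_unit[:spec.partial_bp]

    # continuations of the repeat pattern just outside the array
    left_cont = table.consensus_unit[::-1]  # left guard is checked reversed
    phase = len(array) % p
    right_cont = (table.consensus_unit[phase:] + table.consensus_unit)[:p]
    # guard tolerance comfortably exceeds every boundary-extension
    # tolerance used downstream (detector and decoder)
    tol = max(3, p // 3)

    fwd = spec.primers.forward
    rev_rc = revcomp(spec.primers.reverse)

    def sample_segment(n: int, check_tandem=True) -> str:
        for _ in range(max_tries):
            seg = _random_seq(rng, n, spec.gc_bias)
            if check_tandem and _has_tandem(seg):
                continue
            return seg
        raise SimulationError("rejection sampling failed for a segment")

    for _ in range(max_tries):
        left_flank = sample_segment(spec.flank_length)
        right_flank = sample_segment(spec.flank_length)
        pad_l = sample_segment(spec.pad_length)
        pad_r = sample_segment(spec.pad_length)
        if not _boundary_ok(pad_l[::-1], left_cont, tol):
            continue
        if not _boundary_ok(pad_r, right_cont, tol):
            continue
        locus = (left_flank + fwd + pad_l + array + pad_r + rev_rc
                 + right_flank)
        # primer sites must be unique so in-silico PCR is unambiguous
        from .insilico_pcr import scan_primer_sites
        fwd_sites = scan_primer_sites(locus, spec.primers.forward,
                                      spec.primers.max_mismatches,
                                      spec.primers.three_prime_exact)
        rev_sites = scan_primer_sites(locus, spec.primers.reverse,
                                      spec.primers.max_mismatches,
                                      spec.primers.three_prime_exact)
        if len([s for s in fwd_sites if s.strand == "+"]) != 1:
            continue
        if len([s for s in rev_sites if s.strand == "-"]) != 1:
            continue
        amp_start = spec.flank_length
        amp_end = len(locus) - spec.flank_length
        arr_start = amp_start + len(fwd) + spec.pad_length
        return SimulatedTruth(
            locus=locus,
            amplicon_interval=(amp_start, amp_end),
            array_interval=(arr_start, arr_start + len(array)),
            code_string=code_string,
            partial_length=spec.partial_bp,
            table=table,
            primers=spec.primers,
        )
    raise SimulationError("rejection sampling failed for the locus")


def _apply_errors(seq: str, rng, ins: float, dele: float, sub: float,
                  counts: dict | None = None) -> str:
    bases = "ACGT"
    out: list[str] = []
    n = len(seq)
    r1 = rng.random(n)
    r_ins = rng.random(n)
    # pre-drawn choices keep the two RNG streams aligned per position
    subs = rng.integers(0, 3, size=n)
    inss = rng.integers(0, 4, size=n)
    n_ins = n_del = n_sub = 0
    for i, ch in enumerate(seq):
        r = r1[i]
        if r < dele:
            n_del += 1
        else:
            if r < dele + sub:
                others = [b for b in bases if b != ch]
                ch = others[subs[i]] if ch in bases else bases[inss[i]]
                n_sub += 1
            out.append(ch)
        if r_ins[i] < ins:
            out.append(bases[inss[i]])
            n_ins += 1
    if counts is not None:
        counts["ins"] = counts.get("ins", 0) + n_ins
        counts["del"] = counts.get("del", 0) + n_del
        counts["sub"] = counts.get("sub", 0) + n_sub
        counts["true_bases"] = counts.get("true_bases", 0) + n
    return "".join(out)


def simulate_reads(truth: SimulatedTruth, config: ReadSimConfig,
                   return_stats: bool = False):
    """Draw error-bearing long reads from the locus.

    Returns (reads, origins): reads is a list of (id, sequence) in
    generation order; origins maps read id -> (start, end, strand) on the
    locus.  With ``return_stats`` a third element reports the applied
    per-category error counts (truth bookkeeping).  Deterministic per
    config.seed.
    """
    rng = np.random.default_rng(config.seed)
    L = len(truth.locus)
    target = config.coverage * L
    reads: list[tuple[str, str]] = []
    origins: dict[str, tuple[int, int, str]] = {}
    stats: dict[str, int] = {}
    total = 0
    idx = 0
    attempts = 0
    while total < target:
        attempts += 1
        if attempts > 100 * (target / max(config.min_len, 1) + 10):
            break
        start = int(rng.integers(0, L))
        length = int(np.clip(rng.lognormal(config.mean_log, config.sd_log),
                             config.min_len, config.max_len))
        end = min(L, start + length)
        if end - start < 100:
            continue
        strand = "+" if rng.random() < 0.5 else "-"
        fragment = truth.locus[start:end]
        if strand == "-":
            fragment = revcomp(fragment)
        seq = _apply_errors(fragment, rng, config.ins_rate, config.del_rate,
                            config.sub_rate, counts=stats)
        idx += 1
        rid = f"read{idx:05d}"
        reads.append((rid, seq))
        origins[rid] = (start, end, strand)
        total += end - start
    if not reads:
        raise SimulationError("coverage yielded zero reads")
    truth.read_origins.update(origins)
    if return_stats:
        return reads, origins, stats
    return reads, origins


def write_fastq(reads, path) -> None:
    """Plain FASTQ with constant placeholder qualities."""
    with open(path, "w") as fh:
        for rid, seq in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")


def write_fasta(records, path) -> None:
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i:i + 80] + "\n")
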