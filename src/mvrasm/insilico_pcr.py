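"""In-silico PCR bait extraction and tandem-repeat soft masking.

A primer pair defines an amplicon on a reference; the bait is the amplicon
plus flanking context (default 5 kb per side), with tandem-repeat content
soft-masked (lowercased) so that downstream read recruitment seeds only in
unique flank sequence.  Masking never alters base identity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .align import revcomp, seq_to_u8
from .tandem import TandemRepeatAnnotation, detect_tandem_repeats

logger = logging.getLogger(__name__)

DEFAULT_FLANK = 5000
DEFAULT_MAX_PRODUCT = 50_000


class AmpliconError(ValueError):
    """No or ambiguous in-silico PCR product."""


@dataclass(frozen=True)
class PrimerPair:
    """A PCR primer pair, both written 5'->3' as synthesized.

    The reverse primer anneals to the plus strand downstream of the
    forward site, i.e. its reverse complement occurs on the plus strand.
    """

    forward: str
    reverse: str
    max_mismatches: int = 2
    three_prime_exact: int = 5
    name: str = "locus"

    def __post_init__(self):
        for primer in (self.forward, self.reverse):
            if not primer:
                raise ValueError("empty primer")
            if set(primer.upper()) - set("ACGT"):
                raise ValueError(f"ambiguous bases in primer {primer!r}")
        if self.max_mismatches < 0:
            raise ValueError("max_mismatches must be >= 0")
        if self.three_prime_exact > min(len(self.forward), len(self.reverse)):
            raise ValueError("three_prime_exact exceeds primer length")


@dataclass(frozen=True)
class PrimerSite:
    """One primer match on the reference (0-based half-open)."""

    start: int
    end: int
    strand: str
    mismatches: int


@dataclass
class Bait:
    """An amplicon plus flanks: the read-recruitment mapping target.

    ``sequence`` carries soft masking as lowercase.  All intervals are in
    reference coordinates; ``to_local`` converts to bait-local ones.
    """

    id: str
    sequence: str
    source_interval: tuple[int, int]
    amplicon_interval: tuple[int, int]
    flank_length: int
    mask_intervals: list[tuple[int, int]] = field(default_factory=list)
    roi_interval: tuple[int, int] | None = None
    annotations: list[TandemRepeatAnnotation] = field(default_factory=list)

    @property
    def unmasked_sequence(self) -> str:
        return self.sequence.upper()

    def to_local(self, interval: tuple[int, int]) -> tuple[int, int]:
        off = self.source_interval[0]
        return (interval[0] - off, interval[1] - off)

    @property
    def roi_local(self) -> tuple[int, int] | None:
        return self.to_local(self.roi_interval) if self.roi_interval else None

    @property
    def amplicon_length(self) -> int:
        return self.amplicon_interval[1] - self.amplicon_interval[0]


def _mismatch_counts(ref_codes: np.ndarray, pat_codes: np.ndarray) -> np.ndarray:
    """Hamming mismatches of the pattern at every reference offset.

    Non-ACGT reference bases (N) never match.
    """
    n = ref_codes.size
    m = pat_codes.size
    n_pos = n - m + 1
    counts = np.zeros(n_pos, dtype=np.int32)
    for j in range(m):
        window = ref_codes[j:j + n_pos]
        counts += (window != pat_codes[j]) | (window > 3)
    return counts


def _exact_zone(ref_codes: np.ndarray, pat_codes: np.ndarray,
                lo: int, hi: int) -> np.ndarray:
    """Boolean per-offset: pattern positions [lo, hi) match exactly."""
    sub = pat_codes[lo:hi]
    if sub.size == 0:
        return np.ones(ref_codes.size - pat_codes.size + 1, dtype=bool)
    n_pos = ref_codes.size - pat_codes.size + 1
    ok = np.ones(n_pos, dtype=bool)
    for j, c in enumerate(sub, start=lo):
        window = ref_codes[j:j + n_pos]
        ok &= (window == c) & (window <= 3)
    return ok


def scan_primer_sites(reference: str, primer: str, max_mismatches: int = 2,
                      three_prime_exact: int = 5) -> list[PrimerSite]:
    """All primer binding sites on both strands of the reference.

    A site passes when its Hamming distance is <= max_mismatches and its
    ``three_prime_exact`` 3'-terminal bases match exactly.  On the plus
    strand the 3' end is the window's right edge; on the minus strand
    (where the window holds the primer's reverse complement) it is the
    left edge.  Sites are sorted by start.
    """
    if not reference:
        raise ValueError("empty reference")
    if set(primer.upper()) - set("ACGT"):
        raise ValueError("ambiguous bases in primer")
    m = len(primer)
    if len(reference) < m:
        return []
    ref_codes = seq_to_u8(reference)
    sites: list[PrimerSite] = []
    fwd = seq_to_u8(primer)
    counts = _mismatch_counts(ref_codes, fwd)
    ok = _exact_zone(ref_codes, fwd, m - three_prime_exact, m)
    for pos in np.nonzero((counts <= max_mismatches) & ok)[0]:
        sites.append(PrimerSite(int(pos), int(pos) + m, "+", int(counts[pos])))
    rc = seq_to_u8(revcomp(primer))
    counts = _mismatch_counts(ref_codes, rc)
    ok = _exact_zone(ref_codes, rc, 0, three_prime_exact)
    for pos in np.nonzero((counts <= max_mismatches) & ok)[0]:
        sites.append(PrimerSite(int(pos), int(pos) + m, "-", int(counts[pos])))
    sites.sort(key=lambda s: (s.start, s.strand))
    return sites


def extract_bait(reference: str, pair: PrimerPair,
                 flank_length: int = DEFAULT_FLANK,
                 max_product: int = DEFAULT_MAX_PRODUCT,
                 reference_id: str = "ref") -> Bait:
    """Run in-silico PCR and cut the bait (amplicon +/- flanks).

    The amplicon runs from a plus-strand forward-primer site to the end
    of a minus-strand reverse-primer site downstream, primers included.
    With several possible products the shortest wins (with a warning);
    ties and absence are errors.
    """
    fwd_sites = [s for s in scan_primer_sites(
        reference, pair.forward, pair.max_mismatches, pair.three_prime_exact)
        if s.strand == "+"]
    rev_sites = [s for s in scan_primer_sites(
        reference, pair.reverse, pair.max_mismatches, pair.three_prime_exact)
        if s.strand == "-"]
    products = []
    for f in fwd_sites:
        for r in rev_sites:
            if r.start >= f.end and r.end - f.start <= max_product:
                products.append((r.end - f.start, f, r))
    if not products:
        raise AmpliconError("no amplicon")
    products.sort(key=lambda p: p[0])
    if len(products) > 1:
        if products[1][0] == products[0][0]:
            raise AmpliconError("ambiguous amplicon")
        logger.warning("multiple in-silico PCR products (%d); keeping the "
                       "shortest (%d bp)", len(products), products[0][0])
    size, f, r = products[0]
    src_start = max(0, f.start - flank_length)
    src_end = min(len(reference), r.end + flank_length)
    return Bait(
        id=f"{reference_id}:{src_start}-{src_end}",
        sequence=reference[src_start:src_end],
        source_interval=(src_start, src_end),
        amplicon_interval=(f.start, r.end),
        flank_length=flank_length,
    )


def detect_and_mask_tandem_repeats(bait: Bait, min_period: int = 4,
                                   max_period: int = 200,
                                   min_copies: float = 3.0,
                                   min_unit_identity: float = 75.0):
    """Annotate tandem arrays in the bait and soft-mask them.

    The ROI becomes the longest annotated array inside the amplicon; when
    none is found a warning is logged and the ROI stays unset (flank-only
    mode).  Returns (masked bait, annotations); the input bait is not
    modified.
    """
    seq = bait.unmasked_sequence
    if not seq:
        raise ValueError("empty bait sequence")
    annotations = detect_tandem_repeats(
        seq, min_period=min_period, max_period=max_period,
        min_copies=min_copies, min_unit_identity=min_unit_identity)
    off = bait.source_interval[0]
    chars = list(seq)
    mask_intervals = []
    for ann in annotations:
        s, e = ann.interval
        mask_intervals.append((s + off, e + off))
        for i in range(s, e):
            chars[i] = chars[i].lower()
    amp_local = bait.to_local(bait.amplicon_interval)
    inside = [a for a in annotations
              if a.interval[0] >= amp_local[0] and a.interval[1] <= amp_local[1]]
    roi = None
    if inside:
        best = max(inside, key=lambda a: a.length)
        roi = (best.interval[0] + off, best.interval[1] + off)
    else:
        logger.warning("no tandem array inside the amplicon; ROI unset "
                       "(flank-only mode)")
    return Bait(
        id=bait.id,
        sequence="".join(chars),
        source_interval=bait.source_interval,
        amplicon_interval=bait.amplicon_interval,
        flank_length=bait.flank_length,
        mask_intervals=mask_intervals,
        roi_interval=roi,
        annotations=annotations,
    ), annotations


def write_bait_fasta(bait: Bait, path) -> None:
    """Bait FASTA with lowercase soft masking."""
    with open(path, "w") as fh:
        fh.write(f">{bait.id}\n")
        for i in range(0, len(bait.sequence), 80):
            fh.write(bait.sequence[i:i + 80] + "\n")


def write_annotations_bed(bait: Bait, path) -> None:
    """Annotations as BED6 (name = consensus unit, score = int copies)."""
    off = bait.source_interval[0]
    with open(path, "w") as fh:
        for ann in bait.annotations:
            s, e = ann.interval
            fh.write(f"{bait.id}\t{s + off}\t{e + off}\t{ann.consensus_unit}"
                     f"\t{int(ann.copy_number)}\t+\n")
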