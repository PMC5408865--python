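# Methods

This note documents the models, algorithms and numerical choices behind
`mvrasm`, what the synthetic data emulate, and the known limits of both.

## Alignment engine

All alignment in the package goes through one engine
(`mvrasm.align`): exact k-mer seeding, co-linear chaining, and a banded
affine-gap Smith–Waterman extension whose band follows the chained seed
diagonals.

* **Scoring.** match +1, mismatch −1, gap open −2, gap extend −1 (the
  first base of a gap costs the open penalty, later bases the extend
  penalty). These defaults favour long, weak alignments over short
  high-identity ones, which is the right trade-off for indel-dominant
  long reads: score is used only *relatively* (recruitment binning,
  contig selection), so absolute calibration is immaterial.
* **Seeding.** 13-mers, exact. Against the bait, seeds are restricted to
  unmasked (flank) positions; extension may cross masked sequence.
  K-mers with more than 8 target hits are dropped: in a near-periodic
  array the windows that avoid all distinguishing bases match tens of
  repeat units and otherwise drown the informative anchors.
* **Chaining.** Best co-linear chain under a gap limit of 20 kb (a chain
  must be able to jump the masked array, whose extent in read
  coordinates is inflated by the ~6% net insertion bias of the error
  model) and a drift limit that scales with anchor distance
  (25 bp + 10% of the gap). The scaled drift limit is load-bearing: a
  repeat-induced anchor on a register shifted by one or more units shows
  up as a sudden diagonal jump that a flat limit would accept.
* **Band.** Half-width 100 around the per-row interpolated chain
  diagonal. Between dense anchors the true path deviates from the
  interpolation by a Brownian-bridge-scale wobble (tens of bases over
  kilobase gaps), far inside the band.

On sub-kilobase sequences at ≤10% divergence the banded score equals the
unbanded local-alignment optimum exactly (tested against a textbook DP).

## Tandem-repeat detection and wraparound DP

Arrays are segmented against a repeat unit by wraparound dynamic
programming: unit-cost edit alignment of the sequence against the
infinitely repeated unit, starting at unit phase 0, with a free terminal
partial unit. Total cost equals an exhaustive cut-point segmentation
oracle on small arrays (tested to 40 bp).

De-novo detection seeds candidates from k-mer spacing periodicity
(k = 5): positions whose k-mer recurred at a constant small distance form
runs; each run's modal spacing is the candidate period. Candidates are
refined by iterated consensus voting and an X-drop boundary walk of the
periodic pattern out of an interior anchor (phase-free, so the arbitrary
rotation of the learned consensus cannot bias the boundary), followed by
a tolerant unit-level extension and a bounded base-level adjustment.
Harmonic candidates (a k-mer containing a variant base recurs at a
multiple of the true period) are folded down by near-periodic consensus
reduction. Defaults: period 4–200, ≥3 copies, ≥75% mean unit identity —
spanning 9 bp MS1-like units through tens-of-bp zinc-finger-like units.

Boundaries from detection alone are accurate to ±2 bp on substitution-
variant arrays: a substituted outermost base is indistinguishable from
flank sequence without knowing the variant inventory. The decoder closes
that gap (below). Detection reports the consensus in the phase anchored
at the detected start, which may be a rotation of the planted unit.

## Bait extraction and masking

In-silico PCR accepts primer sites with ≤2 mismatches and an exact
5-base 3' terminus, products ≤50 kb; with several possible products the
shortest is taken (ties are an error). The bait is the amplicon ±5 kb of
flank. Masking is soft (lowercase), never altering bases, so the final
contig-to-bait alignment still sees the reference array. Only tandem
content is masked; interspersed-element masking is out of scope, which is
adequate for minisatellite baits because recruitment anchoring only
requires the array itself to be excluded from seeding.

## Recruitment and score bins

Reads align against the masked bait on both strands; minus-strand reads
are reverse-complemented once at recruitment so assembly operates in
bait-forward orientation. A read is recruited if it produces any seeded
alignment of ≥50 columns (a floor that rejects chance single-seed hits,
not an identity cutoff). Classification against the ROI uses 500 bp of
flank anchoring per side (spanning / left- / right-anchored /
non-informative). Score bins are equal-width histogram bins (default 5)
over recruited alignment scores; bins always partition the recruited set
(asserted at run time). SAM (via pysam) and minimal PAF import re-score
records from their edit paths so binning is aligner-independent.

## Assembly

A deliberately minimal OLC assembler, adequate for a single haploid
locus at ≥30× coverage:

* **Overlaps.** Seed-based candidates (both orientations), banded
  overlap alignment, classification as dovetail or containment with a
  150 bp end slop. Containment requires that the contained read has *no
  net extension* beyond its container, so error-free reads that stick
  out by a few bases still contribute dovetails. Thresholds: ≥500 bp,
  ≥70% identity (two 15%-error reads share ≈72–75% pairwise identity).
* **Layout.** Containment removal, then greedy chaining over dovetail
  edges in decreasing score order, with cycle breaking; one layout per
  connected component, largest first. This global greedy order is an
  equivalent formulation of "extend from the best dovetail at each end"
  and is deterministic after canonical id sorting.
* **Backbone.** Consecutive chain reads are spliced at an exactly
  aligned column pair near the middle of their overlap (taken from the
  centre of a long match run). Offset-projected midpoint cuts would be
  wrong by the accumulated inter-read indel drift — tens of bases over
  kilobase overlaps — which inside a repeat array is unrepairable
  downstream; aligned-pair splicing keeps the backbone structurally
  faithful.
* **Polishing.** Per round, every read is realigned to the backbone and
  a new consensus is called: column-wise plurality over match /
  substitution / deletion events; insertion evidence pooled by first
  inserted base; and *suspect windows* — short stretches where ≥15% of
  events disagree with the column call or a junction carries ≥15%
  insertion load — re-called as the **centroid read segment** (the
  observed spanning segment minimizing total edit distance to all
  others). The centroid call is what resolves homopolymer run lengths
  and short-motif tangles where plurality votes fragment; homopolymer
  runs outside suspect windows get the same segment-centroid treatment.
  Two polishing rounds (configurable), then a support/contributor pass.
* **Selection.** Every bin's contig plus the pooled-bin contig are
  aligned to the unmasked bait; the highest score wins (ties: longer
  contig, then bin id). The winner is then polished once more against
  the *full* recruited read set, since a single score bin holds only
  part of the coverage depth.

With 50× coverage of 15%-error reads over a 12 kb locus the polished
consensus carries roughly 1 residual error per 2–3 kb in well-covered
regions; error-free input reproduces the truth exactly.

## Allele decoding

The array interval in a contig is the span strictly between the
positions aligned to the two ROI edges of the bait (each flank must
anchor ≥500 bp); if only one flank anchors, de-novo detection on the
contig is the fallback. Because alignment wobbles by a few bases at a
repeat boundary, the interval is then snapped to exact unit-grid
boundaries using the variant table: a p-window is array-like when it is
within max(1, p/12) edits of *any* table unit; the walk anchors on the
grid offset with the cleanest window chain, re-anchors across consensus
indels via small confirmed shifts, and distinguishes a terminal partial
unit from a final complete unit by where the mismatches sit. This makes
copy number base-exact on simulated data while staying bounded: a
refinement that moves a boundary by more than four periods is discarded
in favour of the flank-anchored interval.

Units are classified by minimum unit-cost Levenshtein distance over the
table; ties go to the lexicographically smallest code (flagged), units
farther than floor(p/3) from every variant get the null code `?`. Copy
number is array length / period at one decimal (TRF convention). Code
strings are compared by global unit-level alignment (match +1, mismatch
−1, gap −2) with 5'/3' consistency judged over a 10-unit end window.

The variant table is an input (TSV): real MVR inventories are locus
specific and published elsewhere, so no variant sequence is hard-coded;
the simulator fabricates tables for testing.

## Synthetic data

`make_variant_table` builds a random consensus of the requested period
and n distinct single-substitution variants coded 'A', 'B', … in
generation order. `make_locus` plants the primer pair around
pad – array – pad between rejection-sampled unique flanks (default 55%
GC, mimicking the GC-rich context of such loci); rejection enforces that
flanks and pads contain no tandem arrays and no extra primer sites, and
that the two flank bases adjacent to the array break the repeat-pattern
continuation while the whole adjacent window stays ≥max(3, p/3) edits
from it. The last guard is what makes truth coordinates well defined at
single-base resolution: a flank base that happens to continue the
pattern would make the array boundary genuinely ambiguous.

`simulate_reads` draws start positions uniformly over the locus
(truncating at the ends, so coverage ramps up over roughly one read
length at the left tip), lognormal lengths (mean ≈8 kb, capped at 30 kb
so single reads can span a 5 kb array plus anchors), uniform strands,
and i.i.d. per-base errors of 10% insertion / 4% deletion / 1%
substitution — ~15% total, insertion-dominant, standing in for early
single-molecule chemistry error profiles. Applied error counts are
recorded as truth bookkeeping. Identical seeds give byte-identical
output.

What the simulator does *not* model: chimeric or adapter artefacts,
quality-value structure, coverage bias, diploidy (the pipeline targets a
haploid sample by design), and interspersed repeats in the flanks.
Passing tests therefore demonstrate correct recovery under clean
haploid, uniform-coverage conditions, not robustness to every artefact
of real single-molecule data.

## Pipeline, sizes and defaults

`run_pipeline` executes bait → recruit → bins → assemble → decode →
report, checkpointing each stage to the output directory; a rerun with
an identical configuration resumes after the last completed stage, and
reports are byte-stable for a fixed configuration and seed. The report
mirrors the field's summary-table shape: copy number (reference and
assembly), assembly-to-reference identity, in-silico PCR product sizes
in kb (the assembly size from re-running primer matching on the contig),
and read accounting (recruited / spanning / contributing).

The test suite exercises two study-scale scenarios chosen to match the
loci the method targets: a 9 bp-unit array of 523 complete units plus a
7 bp partial (4714 bp, 523.8 copies) and an 84 bp-unit array of 12.5
copies, both between 5 kb flanks at 50× coverage. The MS1-scale run
takes a few minutes on one CPU; smaller fixtures (1–2 kb flanks, tens of
units, error-free tiling reads) cover the remaining behaviour at
negligible cost.

## Known limitations

* Haploid only; no phasing (deliberate scope).
* Interval refinement assumes the assembly and reference arrays share a
  unit inventory; an allele made of variants absent from the table
  decodes to null codes and falls back to flank-anchored boundaries.
* The greedy layout can fragment at coverage gaps (e.g. the simulated
  locus's left tip); selection against the bait then prefers a
  spanning-bin contig, but a locus with no spanning or dovetailing read
  path across the array cannot be reconstructed at full length.
* Copy-number exactness depends on a consensus with zero net indels
  across the array; below ~30× array coverage the residual error rate
  makes ±0.1–0.2 copy deviations increasingly likely.
* Detector boundaries (without a variant table) carry an intrinsic
  ±2 bp ambiguity on substitution-variant arrays.
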