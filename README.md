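# mvrasm

Targeted local assembly and MVR decoding of minisatellite alleles from
single-molecule long reads.

Minisatellites are tandem arrays of short (6–100 bp), often GC-rich repeat
units whose length polymorphism routinely defeats short-read assembly:
reference genomes collapse or gap them. Long noisy reads (PacBio-like,
~15% indel-dominant error) can span such arrays, and at modest coverage a
local assembly around a single locus recovers the allele. `mvrasm`
implements that workflow end to end for a haploid sample:

1. **In-silico PCR** — a primer pair locates the region of interest on a
   reference; the amplicon ± 5 kb flanks become the *bait*.
2. **Tandem masking** — the array inside the bait is detected (k-mer
   spacing periodicity + wraparound dynamic programming) and soft-masked,
   so read recruitment anchors only in unique flank sequence.
3. **Recruitment & score binning** — reads are aligned to the masked bait
   (seed, chain, banded affine-gap extension), classified as spanning /
   flank-anchored, and partitioned into alignment-score bins. No identity
   cutoff is applied: long, lower-identity alignments carry the
   contiguity information.
4. **Per-bin OLC assembly** — each bin (and the pooled set) is assembled
   by overlap–layout–consensus with realignment polishing; the contig
   with the highest-scoring alignment back to the bait is selected and
   polished once more with all recruited reads.
5. **Allele decoding** — the array is located between its flank anchors,
   segmented into repeat units by wraparound DP against the consensus
   unit, and each unit is assigned a single-letter variant code by
   minimum Levenshtein distance against a variant table (MVR coding).
   The result is a fractional copy number (array length / period, one
   decimal) and the allele's code string; two code strings can be
   compared at the unit level.

A synthetic-locus and read simulator (module `mvrasm.simulate`) generates
ground-truth data for every stage, so the whole pipeline is testable
without downloads.

## Worked example

```
python examples/simulate_and_run.py
```

simulates a 5 kb locus with a 60-unit, 9 bp array (plus a 4 bp terminal
partial → 60.4 copies), draws 40× noisy reads, and runs the pipeline:

```
simulated locus: 4991 bp, array 544 bp (60.4 copies), 98 reads
reference copy number : 60.4
assembly copy number  : 60.4
identity to reference : 99.5%
recruited/spanning    : 98/31
decoded == truth      : True
```

The assembly copy number equals the truth, the contig aligns to the
reference at 99.5% identity, and the decoded code string — the allele's
interspersion pattern, one letter per repeat unit — matches the planted
one exactly. `examples/decode_reference_allele.py` decodes a reference
allele directly, and `examples/compare_allele_structures.py` shows the
unit-level comparison of two alleles with an internal expansion.

The same workflow is scriptable from the shell:

```
mvrasm simulate --outdir sim --units 60 --coverage 40
mvrasm run --reference sim/locus.fasta --reads sim/reads.fastq \
           --variant-table sim/variants.tsv --primers sim/primers.tsv \
           --outdir sim/run
```

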