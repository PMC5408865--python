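"""Decode a known allele directly from a reference sequence.

Extracts the bait by in-silico PCR, masks the tandem array, and decodes
the reference's own array into a fractional copy number and an MVR code
string — the "Copy number (Ref.)" side of the pipeline's report.
"""

from mvrasm.array_decoder import decode_allele
from mvrasm.insilico_pcr import detect_and_mask_tandem_repeats, extract_bait
from mvrasm.simulate import LocusSpec, make_locus, make_variant_table

table = make_variant_table(period=9, n_variants=8, seed=5)
spec = LocusSpec(table=table, n_complete_units=25, partial_bp=6,
                 flank_length=1500, pad_length=150)
truth = make_locus(spec, seed=5)

bait = extract_bait(truth.locus, truth.primers, flank_length=1500)
bait, annotations = detect_and_mask_tandem_repeats(bait)
print(f"amplicon {bait.amplicon_interval}, "
      f"{len(annotations)} tandem annotation(s), ROI {bait.roi_interval}")

decoding = decode_allele(truth.locus, bait, table)
print(f"copy number    : {decoding.copy_number}")
print(f"complete units : {decoding.complete_units}")
print(f"code string    : {decoding.code_string}")
print(f"matches truth  : {decoding.code_string == truth.code_string}")
# copy number is array length / period (TRF convention, one decimal);
# each letter types one repeat unit by minimum edit distance
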