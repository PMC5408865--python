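"""Compare two allele code strings at the repeat-unit level.

Shows the recovered-expansion situation: an assembly allele carrying
units missing from the reference still agrees with it at both ends.
"""

from mvrasm.array_decoder import compare_alleles, render_comparison

reference = "AABBCADDCABBCCADAB"
assembly = "AABBCADDCA" + "EEFFEEFF" + "BBCCADAB"  # 8 extra internal units

comp = compare_alleles(reference, assembly, end_window=6)
print(render_comparison(comp))
print(f"matches {comp.n_match}, mismatches {comp.n_mismatch}, "
      f"unit indels {comp.n_indel}")
print(f"5' consistent: {comp.five_prime_consistent}, "
      f"3' consistent: {comp.three_prime_consistent}")
# unit-level indels mark sequence present in one allele only; consistent
# ends are the signature of a true internal expansion rather than a
# misassembly
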