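"""Score sequences against a reference and round-trip the field notation.

Builds a 40-bp toy reference, introduces one transition and one
transversion into a copy, and shows how variants are scored and printed:
a bare position means a transition, a trailing base a transversion.
"""

from mthaplo import (ReferenceSequence, apply_variants, call_variants,
                     parse_mutation)

ref = ReferenceSequence("ACGTACGTACGTACGTACGTACGTACGTACGTACGTACGT", "toy")
seq = list(ref.bases)
seq[9] = "T"    # C -> T at position 10: transition
seq[14] = "C"   # G -> C at position 15: transversion
profile = call_variants("".join(seq), ref, sample_id="sample1")

print("mutation tokens:", profile.tokens())
print("parsed back:", [parse_mutation(t, ref) for t in profile.tokens()])
print("sequence reconstructed identically:",
      apply_variants(profile, ref) == "".join(seq))
# '10' is the transition (positions only), '15C' the transversion with its
# derived base; applying the profile to the reference restores the sequence.
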