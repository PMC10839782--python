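"""Parse sequence-level STR alleles and collapse them to CE designations.

Two alleles with the same total repeat count are indistinguishable by
capillary electrophoresis but may differ in motif arrangement; bracket
notation captures that difference.
"""

from strpopgen import (
    ce_designation,
    collapse_to_length,
    emit_bracket_notation,
    parse_bracket_notation,
    SequenceAllele,
)

for text in ("[AGAT]9", "[TCTA]4[TCTG]6", "[TCTA]10", "[AGAT]9 AGA"):
    s = parse_bracket_notation(text, period=4)
    print(f"{text:20s} -> CE {ce_designation(s):>4s}  ({len(s.blocks)} blocks,"
          f" partial={s.partial or '-'})")

a = SequenceAllele("D8S1132", parse_bracket_notation("[TCTA]4[TCTG]6", 4))
b = SequenceAllele("D8S1132", parse_bracket_notation("[TCTA]10", 4))
print("\ndistinct sequence alleles:", a != b)
print("same length allele after collapse:", collapse_to_length(a) == collapse_to_length(b))
# Both print True: sequence typing distinguishes iso-length variants that
# the length level merges into the single CE allele "10".
print("canonical form round-trips:", emit_bracket_notation(a.structure))
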