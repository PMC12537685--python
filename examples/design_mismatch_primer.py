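"""Design a wild-type-specific mismatch primer over a Cas9 cut site.

The primer's 3' end sits exactly on the cut (between protospacer bases
17 and 18, 3 bp from the PAM) and carries one intentional mismatch at
the third base from the 3' end, so edited alleles — whose indels pile up
under the terminus — fail to extend while the wild type still amplifies.
"""

from cnvedit import (
    Protospacer,
    design_mismatch_primer,
    find_cut_site,
    wildtype_specificity_check,
)

proto_seq = "GATTACAGATTACAGATTAC"
pam = "TGG"
flank5 = "ATCCGGTTAACCGGATCTTAGCCATGGTCA"
flank3 = "TTGACCATGGCTAAGATCCGGTTAACC"
reference = flank5 + proto_seq + pam + flank3

proto = Protospacer(sequence=proto_seq, pam=pam, strand="+", start=len(flank5))
cut = find_cut_site(reference, proto)
primer = design_mismatch_primer(reference, cut, length=22, direction="forward")
template = reference[primer.anneal_start : primer.anneal_end]

print(f"cut site (0-based inter-base index): {cut.position}")
print(f"template  5'-{template}-3'")
print(f"primer    5'-{primer.sequence}-3'  (Tm ~ {primer.tm:.1f} C)")
print(
    f"intentional mismatch: {primer.template_base} -> {primer.substituted_base} "
    f"at {primer.mismatch_offset_from_3prime} bases from the 3' end"
)

wild_type = reference
one_del = reference[: cut.position - 1] + reference[cut.position :]
flags = wildtype_specificity_check(primer, [wild_type, one_del], reference)
print(f"predicted amplification -> wild type: {flags[0]}, -1 bp edited allele: {flags[1]}")
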