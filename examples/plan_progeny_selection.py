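"""Plan T1 progeny selection for a locus with 8 tandem copies per haplotype.

We want plants homozygous for 5 copies per haplotype.  The FAS rule says
T0 plants carrying 2*5 - 1 = 9 or 2*5 + 1 = 11 functional alleles (out
of 16) are the efficient parents: they most often hide a 5-carrying
homolog, and selfing then yields the 5/5 homozygote in a quarter of
seeds.
"""

from cnvedit import fas, selection_table

n, x = 8, 5
result = fas(x, n)
print(f"FAS({x}) for n={n}: {' or '.join(map(str, result.values))} functional alleles")

table = selection_table(n, x)
print(table.to_dataframe().to_string(index=False))
print(
    "\nacquisition_percent is the share of all selfed T1 seeds that are "
    f"{x}/{x} homozygous;\nit peaks at the FAS rows (m = 9 and 11), about "
    "three times the non-FAS rows (m = 7 and 13)."
)
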