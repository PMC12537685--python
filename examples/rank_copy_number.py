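"""Infer a gene's copy number from clone-sequencing allele counts.

A sequencing batch of 117 plasmid clones from an edited line showed
three indel classes near a 1:2:3 ratio — impossible for a two-copy gene
(4 allele slots cannot produce 6ths).  The chi-square goodness of fit
over candidate copy numbers quantifies that intuition.
"""

import warnings

from cnvedit import AlleleCountTable, min_cnv_from_distinct_alleles, rank_hypotheses

observed = AlleleCountTable.from_dict({"-3": 19, "-1": 38, "+1": 60})
print(f"observed counts: {dict(zip([c.label for c in observed.classes], observed.counts))}")

with warnings.catch_warnings():
    warnings.simplefilter("ignore")  # near-tie advisory printed as table below
    results = rank_hypotheses(observed, range(2, 5))
for r in results:
    print(
        f"  CNV={r.hypothesis.c}: best allocation {r.hypothesis.allocation}, "
        f"chi2={r.chi2:.3f}, p={r.p:.4f}"
    )
best = results[0].hypothesis.c
print(f"most plausible copy number: {best}")
print(
    "\nIndependent lower bound: a line with 5 distinct mutant alleles "
    f"needs CNV >= {min_cnv_from_distinct_alleles(5)} (2c allele slots must fit them)."
)
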