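"""Simulate a T0 editing screen under normal and attenuated Cas9 activity.

Appending 30 cytosines to the guide's 5' end throttles Cas9, trading
complete knockouts for a spread of partially edited lines — exactly the
diversity a copy-number-reduction screen needs.  Here a three-copy locus
(6 allele slots) is edited at per-allele probabilities calibrated to the
two regimes, and the functional-allele histograms are compared.
"""

from collections import Counter
from math import sqrt

from cnvedit import SimConfig, gen_t0_population

for label, p_edit in (("native sgRNA", sqrt(0.7)), ("C30+sgRNA", sqrt(0.4))):
    cfg = SimConfig(seed=7, n=3, p_edit=p_edit, n_lines=200)
    lines = gen_t0_population(cfg)
    hist = Counter(ln.functional_alleles for ln in lines)
    row = "  ".join(f"{k}:{hist.get(k, 0):3d}" for k in range(7))
    fully_edited = hist.get(0, 0) / len(lines)
    print(f"{label:13s} functional-allele counts {row}   all-copies-edited: {fully_edited:.0%}")

print(
    "\nThe attenuated guide shifts mass from 0 functional alleles toward "
    "intermediate counts,\nincluding the FAS-relevant single-allele and "
    "five-allele classes used for progeny selection."
)
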