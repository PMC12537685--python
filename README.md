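# cnvedit

Toolkit for planning and verifying **genome-editing-mediated copy
number variation (CNV) modification** in crops — the situation where a
gene of agronomic interest exists as `n` near-identical tandem copies
per haplotype (2n alleles in a diploid) and the goal is a line fixed at
a *desired* lower copy number `x`, not a blanket knockout.

It is a library first (`import cnvedit`), with narrative scripts under
`examples/` and a thin `cnvedit` command-line front end.

## What it computes

**Progeny-selection planning.** Editing knocks out a random subset of
the 2n allele slots. Conditional on `m` surviving ("functional")
alleles, their split `{a, b}` across the two homologs is hypergeometric,

    P({a, b}) = C(n, a) C(n, b) (2 − [a = b]) / C(2n, m),   a + b = m,

and because the tandem copies are tightly linked, each homolog
segregates as a unit at selfing (1/4 a/a : 1/2 a/b : 1/4 b/b). The
**functional allele numbers for selection** follow:

    FAS(x) = 2x − 1 or 2x + 1,   0 < x < n

— T0 plants with those odd totals most often carry an `x` homolog, and a
quarter of their selfed seeds are the desired `x/x` homozygote.

**Copy-number inference.** Clone-sequencing counts `O_i` over `K` indel
classes are scored against candidate copy numbers `c` by Pearson's
`χ² = Σ (O_i − E_i)² / E_i` (df = K − 1), with expected counts
`E_i = N k_i / 2c` from the best-fitting integer allocation of the 2c
allele slots; candidates are ranked by p-value with near-ties flagged.
A companion rule bounds `c` from below by `⌈k_mutant / 2⌉` distinct
mutant alleles.

**ddPCR quantification.** Droplet counts give concentration by the
Poisson law `λ = −ln(1 − P/T)`; target/reference ratios normalised to a
one-copy calibrator put lines on half-integer allele levels
(delta-method 95% intervals), classified as unedited / heterozygous /
homozygous deletions.

**Mismatch primer design.** Wild-type-specific primers whose 3′ end
sits on the Cas9 cut site (protospacer 17/18 boundary) with an
intentional mismatch at the third base from the 3′ end, plus a
specificity check predicting which alleles still amplify.

**Synthetic data.** Seeded generators for every input above (edited T0
populations under normal or cytosine-attenuated Cas9, multinomial clone
batches, binomial droplet wells, selfed progeny, unidirectional Cas3
deletions), so the whole pipeline is testable at desk scale.

## Worked example

```sh
$ cnvedit plan -n 8 -x 5
FAS(5) = 9 or 11 (n = 8)
 m genotype  percent  acquisition_percent  is_fas  phase_ambiguous
 7      7/0      0.1                  NaN   False            False
 7      6/1      3.9                  NaN   False            False
 7      5/2     27.4                  6.9   False            False
 7      4/3     68.5                  NaN   False            False
 9      8/1      0.1                  NaN    True            False
 9      7/2      3.9                  NaN    True            False
 9      6/3     27.4                  NaN    True            False
 9      5/4     68.5                 17.1    True            False
11      8/3      2.6                  NaN    True            False
11      7/4     25.6                  NaN    True            False
11      6/5     71.8                 18.0    True            False
13      8/5     20.0                  5.0   False            False
13      7/6     80.0                  NaN   False            False
```

Reading: for a wild type with 8 copies per haplotype and a target of 5,
screen T0 plants totalling **9 or 11** functional alleles. A 9-allele
T0 is `{5, 4}` with probability 68.5%, and 17.1% of *all* its selfed
seeds are the desired 5/5 homozygote; picking 7- or 13-allele T0s
instead drops that yield to 6.9% or 5.0% — about a three-fold penalty.
(`acquisition_percent` quarters the rounded genotype percentage, the
convention of the published table this reproduces; exact fractions are
available via the API.)

The other capabilities are shown in `examples/`:

```sh
python examples/plan_progeny_selection.py
python examples/rank_copy_number.py       # chi-square CNV ranking, p=0.96 for c=3 on a 1:2:3 batch
python examples/quantify_ddpcr.py         # 0/2/3/4-allele lines recovered from simulated droplets
python examples/design_mismatch_primer.py
python examples/simulate_editing_screen.py
```

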