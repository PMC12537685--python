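# Methods

`cnvedit` models the dry-lab side of reducing the copy number of a
tandem-duplicated crop gene with CRISPR nucleases: planning which
primary transformants (T0) to self, verifying the true copy number from
clone sequencing, quantifying surviving alleles by droplet digital PCR
(ddPCR), and designing the allele-discriminating primers that make the
ddPCR assay wild-type-specific. This note records the models, the
defaults, and the choices made where the design was genuinely open.

## Selection model (`cnvedit.breeding`)

**Setting.** A locus with `n` tandem copies per haplotype contributes
`2n` allele slots per diploid plant, `n` per homolog. Editing
inactivates a subset; the surviving slots are "functional alleles". The
copies sit in a near-identical gene block of tens of kilobases, so we
treat each homolog's block as a single non-recombining Mendelian unit:
selfing a T0 whose homologs carry `(a, b)` functional alleles yields
`a/a : a/b : b/b` progeny at `1/4 : 1/2 : 1/4`.

**Genotype distribution.** The single probabilistic assumption is
uniform random editing: conditional on `m` of the `2n` slots surviving,
the surviving set is uniform over slots, which makes the homolog split
hypergeometric,

    P({a, b}) = C(n, a) C(n, b) (2 - [a = b]) / C(2n, m),   a + b = m.

An exhaustive-enumeration oracle in the test suite confirms this
closed form exactly (rational arithmetic) for all `n <= 5`.

**FAS.** The functional allele numbers for selection for a desired copy
number `x` per haplotype are `FAS(x) = 2x - 1 or 2x + 1` with
`0 < x < n`. At those odd totals the most probable genotype is
`{x, x±1}`, and a quarter of its selfed seeds are `x/x`. Values shared
with an adjacent target's FAS are flagged rather than dropped, since
dropping versus deprioritising is a screening-policy question, not a
mathematical one.

**Even totals.** An even `m = 2x` admits the already homozygous
`(x, x)` T0, which breeds true (inner factor 1 instead of 1/4). Total
allele counting cannot distinguish `(x, x)` from `(x+1, x-1)`, so even-m
rows carry a `phase_ambiguous` flag in the selection table.

**Arithmetic and rendering.** All probabilities are exact
`fractions.Fraction` values. Percentages round half-up to one decimal.
The *rendered* acquisition percentage follows the convention of the
published selection tables this model reproduces: the genotype
percentage is rounded first and then multiplied by the transmission
factor (so 71.8 / 4 = 17.95 renders as 18.0, where the exact fraction
17.9487 would render 17.9). Both the exact fraction and the rendered
figure are exposed; consumers doing further arithmetic should use the
fractions. For the `n = 8` reference table the hypergeometric model
reproduces every printed cell except the two rarest genotypes (`7/0`,
`8/1`), where it gives 0.14% (rendered 0.1%) against a printed 0.2% —
most plausibly a rounding or transcription artefact in the original,
retained here as a documented discrepancy.

## Copy-number inference (`cnvedit.inference`)

Observed clone counts `O_i` over `K` indel classes are tested against a
candidate copy number `c` via Pearson's statistic
`chi2 = sum (O_i - E_i)^2 / E_i` with `df = K - 1` and upper-tail
p-values from the chi-square distribution (verified against a numerical
integration oracle to 1e-10). Expected counts need an integer
allocation `k_i >= 1, sum k_i = 2c` of allele slots to classes; nothing
in the data fixes it, so `best_allocation` takes the minimum-chi-square
composition, breaking ties toward allocations ordered like the observed
counts. A hypothesis with more classes than slots is infeasible (p = 0).

This best-fit construction is deliberately conservative about what it
claims: because larger `c` offers a finer grid of compositions, its
best fit is systematically at least as good, and ranking by p-value is
biased toward larger copy numbers. `rank_hypotheses` therefore returns
every candidate's result, resolves exact p ties toward the smaller
(parsimonious) `c`, and warns when the top two candidates sit within
0.05 in p. The bias is quantitative as well as qualitative: adjacent
candidates (e.g. allele fractions 1/6 versus 1/8) differ by roughly one
binomial standard error of a class proportion at a ~100-clone batch, so
no decision rule can reliably separate them at that depth — the
end-to-end recovery experiment in the test suite measures exactly how
often ranking finds the truth at 117- and 500-clone depth, and deeper
batches (a few thousand clones) are needed before recovery is
near-certain. Orthogonal evidence (the distinct-allele lower bound
`ceil(k_mutant / 2)`, ddPCR dosage) should accompany the chi-square
rank, which is how the assay is meant to be used.

`classify_clones` is deliberately simple plumbing: global pairwise
alignment (match 1, mismatch -1, gap open -2, gap extend -0.5 — all
configurable), class = net indel within ±20 bases of the cut site,
sequences under 80% identity excluded with a tally. Classes are keyed
by signed indel size, not inserted-base identity, because chromatogram
decomposition tools are known to misread the inserted base.

## ddPCR quantification (`cnvedit.ddpcr`)

With template molecules Poisson-distributed over `T` droplets and `P`
droplets positive, the concentration is `lambda = -ln(1 - P/T)` copies
per droplet. The interval is the delta-method normal interval,
`lambda ± z sqrt(p(1-p)/T) / (1-p)` with `z = 1.96` by default — the
convention of droplet-reader software; only "Poisson's law" is specified
upstream, so the exact interval form is a package choice and nothing
downstream depends on its width. A fully positive well raises an error
(dilute and re-run) rather than returning a pseudo-estimate.

Relative copy number is the sample's target/reference ratio divided by
the calibrator's, with the four channel variances propagated on the log
scale (the estimate is a product of four lambdas). Replicate wells are
pooled by summing droplet counts before estimation. A sample with zero
positive target droplets reports value 0 with a degenerate interval: no
surviving allele, the strongest call the assay makes.

Classification snaps the relative value to the nearest multiple of 0.5
in `[0, wildtype_level]` (each 0.5 = one allele against a one-copy
calibrator): wild-type level = `no_edit`, one step down =
`heterozygous_deletion`, two = `homozygous_deletion`, zero =
`double_homozygous_deletion`; anything farther than the ±0.25 default
tolerance from every level, or on an unnamed level, is `ambiguous`
rather than force-assigned.

## Mismatch primers (`cnvedit.primers`)

Coordinates are 0-based half-open throughout, with a cut site as an
inter-base index; Cas9 cuts between protospacer bases 17 and 18 (3 bp
from the NGG PAM), `start + 17` on the plus strand and `start + 3` for
a minus-strand protospacer stored at plus-strand offset `start`.

The primer copies the template ending on the cut site (default length
22, 3' terminus exactly at the cut, both configurable within ±2) and
substitutes exactly one base at the third position from the 3' end.
The default substitution is the transition swap A↔G / C↔T on the
primer-strand base; the upstream method states only that a mismatch is
placed, so the rule is a configurable default, not a reconstruction.
Melting temperature (nearest-neighbor) is advisory only. The
specificity check is a terminal-stability heuristic: an allele
amplifies iff the primer's 3' tetramer pairs perfectly apart from the
intentional mismatch, and any indel overlapping the tetramer kills
extension. Mutations outside the tetramer are invisible to it — a
distant insertion still reads "amplifiable" — which is the documented
blind spot; the check screens candidates, it does not replace an
empirical no-template control.

## Synthetic data (`cnvedit.simulate`)

The generators produce exactly the statistical structure the consumers
assume, and only that:

- **T0 editing**: each of the `2n` slots edited independently with
  probability `p_edit`; indel size from a configurable spectrum
  (default small deletions dominating — a stand-in exercising
  classification paths, with no biological weight). Defaults calibrate
  the attenuated-guide regime `p_edit = 0.632` (40% of single-copy
  lines bi-allelically edited, `0.632² ≈ 0.4`) versus `0.837` for a
  native guide (70%).
- **Clone counts**: multinomial over `k_i / 2c`, default batch 117.
- **Droplets**: positives ~ `Binomial(T, 1 - e^-lambda)` per channel,
  default 15,000 droplets, reference lambda 0.5 per-copy scale.
- **Selfing**: i.i.d. draws from the 1:2:1 block segregation.
- **Cas3 deletions**: unidirectional intervals from the crRNA site
  toward the PAM side, exponential lengths (mean 4 kb) censored at
  12 kb — bracketing observed deletion sizes of roughly 3.6–8.5 kb,
  but a testing device, not a biological length law.

What the generators deliberately omit: sequencing and cloning errors,
chimeric clones, PCR amplification bias between alleles, droplet rain
and misthresholding, partial gene-block recombination, and any
correlation between alleles during editing. Passing tests therefore
certify the estimators against their own model assumptions; they do not
certify robustness to these real-data artefacts.

## Problem sizes and numerical choices

The seeded checks run at desk scale, chosen to finish in seconds while
keeping Monte-Carlo error far below the asserted margins: 10⁴ selfed
progeny (binomial SE ≈ 0.4% on a 25% fraction), 500 simulated wells for
interval coverage, 200 replicates per depth for copy-number recovery.
Exact quantities (genotype distributions, FAS, selfing fractions) use
rational arithmetic and are asserted with equality, not tolerance.
Degenerate inputs are defined, not patched around: `m = 0` and
`m = 2n` give point-mass genotype distributions, two 50/50 classes fit
every candidate copy number perfectly (p = 1 for all — reported as a
degeneracy with a parsimony tie-break), and zero-positive wells give
exact zeros.

## Known limitations

- The selection model assumes zero recombination within the gene block
  and exactly one segregating locus; outcrossing designs are out of
  scope.
- Chi-square ranking alone under-determines copy number at shallow
  clone depth (see above); the package surfaces this rather than hiding
  it.
- The primer specificity check ignores thermodynamics beyond the 3'
  tetramer (no dimer/hairpin screening, no probe design).
- ddPCR classification presumes the calibrator truly carries one copy
  and the reference assay one copy per haplotype; a wrong calibrator
  shifts every level coherently and is not detectable from within.
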