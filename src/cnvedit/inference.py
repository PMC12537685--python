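"""Copy-number inference from clone-sequencing allele counts.

After partial editing of a tandem-duplicated gene, PCR products spanning
the cut site are cloned and a batch of plasmid clones is Sanger
sequenced.  Each clone reports one allele; with ``c`` copies per
haplotype there are ``2c`` allele slots, so under a candidate copy
number the observed indel-class counts ``O_i`` should follow expected
counts ``E_i = N * k_i / (2c)`` for some positive integer allocation
``k_1..k_K`` summing to ``2c``.  A chi-square goodness-of-fit statistic

    chi2 = sum_i (O_i - E_i)^2 / E_i,   df = K - 1

scores each candidate, and candidates are ranked by p-value.

Because the source counts only fix the allele *classes*, not which class
occupies how many slots, the allocation for each candidate c is chosen
as the minimum-chi-square composition.  This choice favours larger c
(more compositions to choose from), so :func:`rank_hypotheses` returns
every candidate's result and flags near-ties rather than reporting only
the winner.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.stats import chi2 as _chi2_dist

__all__ = [
    "AlleleClass",
    "AlleleCountTable",
    "CNVHypothesis",
    "GofResult",
    "NoFeasibleCNVError",
    "classify_clones",
    "best_allocation",
    "chi_square_gof",
    "rank_hypotheses",
    "min_cnv_from_distinct_alleles",
]


class NoFeasibleCNVError(ValueError):
    """No candidate copy number in the range can host the observed classes."""


@dataclass(frozen=True)
class AlleleClass:
    """An allele category, usually keyed by net indel size ("wt" = 0, "-3", "+1").

    ``indel_size`` is descriptive metadata; class identity rests on the
    label alone, so tables from sources that do not report indel sizes
    may leave it None.
    """

    label: str
    indel_size: int | None = None

    @classmethod
    def from_indel(cls, indel_size: int) -> "AlleleClass":
        label = "wt" if indel_size == 0 else f"{indel_size:+d}"
        return cls(label=label, indel_size=indel_size)


@dataclass(frozen=True)
class AlleleCountTable:
    """Observed clone counts per allele class (O_i)."""

    classes: tuple[AlleleClass, ...]
    counts: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.classes) != len(self.counts):
            raise ValueError("classes and counts length mismatch")
        labels = [c.label for c in self.classes]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate allele class labels")
        if any(c < 0 for c in self.counts):
            raise ValueError("counts must be non-negative")
        if self.total == 0:
            raise ValueError("total count must be positive")

    @property
    def total(self) -> int:
        return sum(self.counts)

    @property
    def n_classes(self) -> int:
        return len(self.classes)

    @classmethod
    def from_dict(cls, counts: dict[str, int]) -> "AlleleCountTable":
        classes = []
        for label in counts:
            if label == "wt":
                size: int | None = 0
            else:
                try:
                    size = int(label)
                except ValueError:
                    size = None
            classes.append(AlleleClass(label=label, indel_size=size))
        return cls(classes=tuple(classes), counts=tuple(counts.values()))


@dataclass(frozen=True)
class CNVHypothesis:
    """Candidate copy number c with an allele-slot allocation k_i (sum = 2c)."""

    c: int
    allocation: tuple[int, ...] | None
    feasible: bool = True

    def expected(self, total: int) -> np.ndarray:
        if not self.feasible or self.allocation is None:
            raise ValueError("infeasible hypothesis has no expected counts")
        return total * np.asarray(self.allocation, dtype=float) / (2 * self.c)


@dataclass(frozen=True)
class GofResult:
    hypothesis: CNVHypothesis
    chi2: float
    df: int
    p: float


def _compositions(total: int, k: int) -> Iterable[tuple[int, ...]]:
    """All ordered compositions of `total` into k positive integer parts."""
    for cuts in itertools.combinations(range(1, total), k - 1):
        prev = 0
        parts = []
        for c in cuts:
            parts.append(c - prev)
            prev = c
        parts.append(total - prev)
        yield tuple(parts)


def best_allocation(c: int, observed: AlleleCountTable) -> CNVHypothesis:
    """Minimum-chi-square integer allocation of 2c allele slots to the classes.

    Ties are broken in favour of the allocation whose ordering matches the
    observed count ordering (largest k on the most frequent class first).
    Marked infeasible when there are more classes than slots.
    """
    K = observed.n_classes
    if K > 2 * c:
        return CNVHypothesis(c=c, allocation=None, feasible=False)
    O = np.asarray(observed.counts, dtype=float)
    N = observed.total
    order = np.argsort(-O, kind="stable")
    best: tuple[int, ...] | None = None
    best_chi = math.inf
    best_key: tuple | None = None
    for alloc in _compositions(2 * c, K):
        E = N * np.asarray(alloc, dtype=float) / (2 * c)
        chi = float(((O - E) ** 2 / E).sum())
        key = tuple(-alloc[i] for i in order)  # prefer big slots on big counts
        if chi < best_chi - 1e-12 or (abs(chi - best_chi) <= 1e-12 and key < best_key):
            best, best_chi, best_key = alloc, chi, key
    return CNVHypothesis(c=c, allocation=best)


def chi_square_gof(observed: AlleleCountTable, hypothesis: CNVHypothesis) -> GofResult:
    """Pearson goodness of fit of observed counts against one CNV hypothesis."""
    df = observed.n_classes - 1
    if not hypothesis.feasible:
        return GofResult(hypothesis=hypothesis, chi2=math.inf, df=df, p=0.0)
    E = hypothesis.expected(observed.total)
    if np.any(E <= 0):
        return GofResult(hypothesis=hypothesis, chi2=math.inf, df=df, p=0.0)
    O = np.asarray(observed.counts, dtype=float)
    chi2 = float(((O - E) ** 2 / E).sum())
    p = float(_chi2_dist.sf(chi2, df)) if df > 0 else 1.0
    return GofResult(hypothesis=hypothesis, chi2=chi2, df=df, p=p)


def rank_hypotheses(
    observed: AlleleCountTable,
    c_range: Sequence[int] | range,
    near_tie_delta: float = 0.05,
) -> list[GofResult]:
    """Score every candidate copy number and sort by p-value (descending).

    Ties in p are resolved toward the smaller (more parsimonious) c.  A
    warning is emitted when the top two feasible candidates differ by
    less than ``near_tie_delta`` in p — with a best-fit allocation per
    candidate, adjacent copy numbers are often nearly indistinguishable.
    Raises :class:`NoFeasibleCNVError` when no candidate can host the
    observed number of classes.
    """
    c_values = list(c_range)
    if not c_values:
        raise ValueError("empty candidate range")
    results = [chi_square_gof(observed, best_allocation(c, observed)) for c in c_values]
    results.sort(key=lambda r: (-r.p, r.hypothesis.c))
    feasible = [r for r in results if r.hypothesis.feasible]
    if not feasible:
        raise NoFeasibleCNVError(
            f"no feasible CNV in {c_values}: {observed.n_classes} allele classes "
            f"exceed every candidate's 2c slots"
        )
    if len(feasible) > 1 and feasible[0].p - feasible[1].p < near_tie_delta:
        warnings.warn(
            f"top CNV hypotheses c={feasible[0].hypothesis.c} and "
            f"c={feasible[1].hypothesis.c} are within {near_tie_delta} in p; "
            "consider orthogonal evidence (ddPCR, distinct-allele count)",
            stacklevel=2,
        )
    return results


def min_cnv_from_distinct_alleles(k_mutant: int) -> int:
    """Smallest copy number consistent with k distinct mutant alleles.

    A diploid with c copies per haplotype has 2c allele slots, so at most
    2c distinct mutant alleles: more than four distinct mutants rules out
    c = 2.  Returns ceil(k/2).
    """
    if k_mutant < 1:
        raise ValueError("k_mutant must be >= 1")
    return (k_mutant + 1) // 2


def classify_clones(
    sequences: Sequence[str],
    reference: str,
    cut_site: int,
    window: int = 20,
    identity_threshold: float = 0.8,
    match_score: float = 1.0,
    mismatch_score: float = -1.0,
    open_gap_score: float = -2.0,
    extend_gap_score: float = -0.5,
) -> tuple[AlleleCountTable, int]:
    """Assign each clone sequence an indel class by alignment to the reference.

    Clones are globally aligned to the reference amplicon; the net indel
    size (insertions minus deletions) within ``±window`` bases of the
    Cas9 ``cut_site`` (0-based inter-base index) keys the class.  Clones
    whose alignment identity falls below ``identity_threshold`` are
    excluded and counted in the returned unclassified tally.

    Returns ``(table, n_unclassified)``.
    """
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match_score
    aligner.mismatch_score = mismatch_score
    aligner.open_gap_score = open_gap_score
    aligner.extend_gap_score = extend_gap_score

    lo, hi = cut_site - window, cut_site + window
    counts: dict[int, int] = {}
    unclassified = 0
    for seq in sequences:
        aln = aligner.align(reference, seq)[0]
        ref_blocks, qry_blocks = aln.aligned
        matches = 0
        for (rs, re), (qs, qe) in zip(ref_blocks, qry_blocks):
            matches += sum(
                reference[rs + i] == seq[qs + i] for i in range(re - rs)
            )
        if matches / max(len(reference), len(seq)) < identity_threshold:
            unclassified += 1
            continue
        net = 0
        prev_r, prev_q = 0, 0
        blocks = list(zip(ref_blocks, qry_blocks)) + [
            ((len(reference), len(reference)), (len(seq), len(seq)))
        ]
        for (rs, re), (qs, qe) in blocks:
            gap_r = rs - prev_r  # deletion from the reference
            gap_q = qs - prev_q  # insertion into the clone
            if gap_r and lo <= (prev_r + rs) / 2 <= hi:
                net -= gap_r
            if gap_q and lo <= rs <= hi:
                net += gap_q
            prev_r, prev_q = re, qe
        counts[net] = counts.get(net, 0) + 1
    classes = tuple(AlleleClass.from_indel(s) for s in sorted(counts))
    table = AlleleCountTable(
        classes=classes, counts=tuple(counts[c.indel_size] for c in classes)
    )
    return table, unclassified
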