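"""Progeny-selection model for tandem gene-copy (CNV) editing.

A plant carrying ``n`` tandem copies of a gene per haplotype has ``2n``
allele slots (``n`` on each homologous chromosome).  Partial genome
editing knocks out a random subset of those slots; the surviving
("functional") alleles are distributed across the two homologs.  Because
the copies sit in one tightly linked block, each homolog segregates as a
unit at selfing (1:2:1), so a primary transformant (T0) whose homologs
carry ``a`` and ``b`` functional alleles yields ``a/a`` homozygous
progeny at rate 1/4 when ``a != b``.

This module answers the breeder's question: *which total functional
allele counts in T0 make recovery of an x/x homozygote in T1 most
likely?*  The answer is the FAS rule ``FAS(x) = 2x - 1 or 2x + 1`` for
``0 < x < n``, and the supporting genotype probabilities follow a
hypergeometric placement model: conditional on ``m`` functional alleles
out of ``2n``, the edited subset is uniform over slots, so

    P({a, b}) = C(n, a) * C(n, b) * (2 - [a == b]) / C(2n, m),  a + b = m.

All probabilities are carried as exact :class:`fractions.Fraction`
values; percentage rendering rounds half-up to one decimal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from math import comb
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "EditingLocus",
    "T0Genotype",
    "GenotypeDistribution",
    "FASResult",
    "SelectionRow",
    "SelectionTable",
    "fas",
    "genotype_distribution",
    "selfing_distribution",
    "homozygote_acquisition_prob",
    "selection_table",
    "round_half_up_percent",
]


class InvalidTargetError(ValueError):
    """Desired copy number x is outside the open interval (0, n)."""


def round_half_up_percent(p: Fraction | float, ndigits: int = 1) -> float:
    """Round a probability to a percentage with half-up ties (0.685314 -> 68.5).

    Exact Fraction arithmetic avoids binary-float artefacts at .x5 ties.
    """
    frac = Fraction(p) * 100 * 10**ndigits
    q, rem = divmod(frac.numerator, frac.denominator)
    if 2 * rem >= frac.denominator:
        q += 1
    return q / 10**ndigits


@dataclass(frozen=True)
class EditingLocus:
    """A target gene with ``copies_per_haplotype`` tandem copies (n >= 1)."""

    name: str
    copies_per_haplotype: int

    def __post_init__(self) -> None:
        if self.copies_per_haplotype < 1:
            raise ValueError("copies_per_haplotype must be >= 1")

    @property
    def total_alleles(self) -> int:
        return 2 * self.copies_per_haplotype


@dataclass(frozen=True)
class T0Genotype:
    """Unordered pair of functional-allele counts on the two homologs.

    Stored in canonical form a >= b; ``T0Genotype(4, 5) == T0Genotype(5, 4)``.
    """

    a: int
    b: int
    locus: EditingLocus | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.a < 0 or self.b < 0:
            raise ValueError("allele counts must be non-negative")
        if self.a < self.b:
            object.__setattr__(self, "a", self.b)
            object.__setattr__(self, "b", self.a)
        if self.locus is not None and self.a > self.locus.copies_per_haplotype:
            raise ValueError(
                f"homolog carries {self.a} functional alleles but the locus "
                f"has only {self.locus.copies_per_haplotype} copies per haplotype"
            )

    @property
    def total(self) -> int:
        return self.a + self.b

    @property
    def is_homozygous(self) -> bool:
        return self.a == self.b

    def __str__(self) -> str:  # pragma: no cover - display helper
        return f"{self.a}/{self.b}"


@dataclass(frozen=True)
class GenotypeDistribution:
    """Conditional distribution of T0 genotypes given m functional alleles."""

    locus: EditingLocus
    m: int
    entries: Mapping[T0Genotype, Fraction]

    def __post_init__(self) -> None:
        total = sum(self.entries.values())
        if total != 1:
            raise ValueError(f"genotype probabilities sum to {total}, not 1")
        for g in self.entries:
            if g.total != self.m:
                raise ValueError(f"genotype {g} inconsistent with m={self.m}")

    def __getitem__(self, key: tuple[int, int] | T0Genotype) -> Fraction:
        if isinstance(key, tuple):
            key = T0Genotype(*key)
        return self.entries[key]

    def items(self):
        return self.entries.items()


@dataclass(frozen=True)
class FASResult:
    """Functional allele numbers for selection: FAS(x) = 2x ± 1, 0 < x < n.

    ``flagged`` holds the subset shared with an adjacent target copy
    number's FAS (the table-footnote overlap rule); they are reported,
    not dropped, since the source leaves their treatment open.
    """

    x: int
    n: int
    values: tuple[int, ...]
    flagged: tuple[int, ...]

    def __iter__(self):
        return iter(self.values)


def fas(x: int, n: int) -> FASResult:
    """Functional-allele counts in T0 that best feed selection of an x/x T1.

    Raises :class:`InvalidTargetError` unless 0 < x < n (x = 0 is a plain
    knockout, x = n means no editing; neither is a CNV-reduction target).
    """
    if not 0 < x < n:
        raise InvalidTargetError(f"desired copy number x={x} must satisfy 0 < x < n={n}")
    values = tuple(v for v in (2 * x - 1, 2 * x + 1) if 0 < v < 2 * n)
    flagged = []
    for v in values:
        for adj in (x - 1, x + 1):
            if 0 < adj < n and v in (2 * adj - 1, 2 * adj + 1):
                flagged.append(v)
                break
    return FASResult(x=x, n=n, values=values, flagged=tuple(flagged))


def genotype_distribution(n: int, m: int) -> GenotypeDistribution:
    """Distribution of {a, b} homolog splits given m of 2n alleles functional.

    Uniform-random editing over the 2n slots makes the split
    hypergeometric: P(a on homolog 1) = C(n,a) C(n,m-a) / C(2n,m);
    unordered genotypes pool a/b with b/a.
    """
    if not 0 <= m <= 2 * n:
        raise ValueError(f"m={m} out of range [0, {2 * n}]")
    locus = EditingLocus("locus", n)
    denom = comb(2 * n, m)
    entries: dict[T0Genotype, Fraction] = {}
    for a in range(m, (m - 1) // 2, -1):  # a from m down to ceil(m/2)
        b = m - a
        if a > n or b < 0 or b > n:
            continue
        weight = comb(n, a) * comb(n, b)
        if a != b:
            weight *= 2
        entries[T0Genotype(a, b, locus)] = Fraction(weight, denom)
    return GenotypeDistribution(locus=locus, m=m, entries=entries)


def selfing_distribution(g: T0Genotype) -> dict[T0Genotype, Fraction]:
    """Segregation of homolog blocks at selfing: 1/4 a/a, 1/2 a/b, 1/4 b/b.

    The copies are tandem and tightly linked, so each homolog transmits as
    an intact unit; a homozygous parent breeds true.
    """
    if g.is_homozygous:
        return {g: Fraction(1)}
    return {
        T0Genotype(g.a, g.a, g.locus): Fraction(1, 4),
        T0Genotype(g.a, g.b, g.locus): Fraction(1, 2),
        T0Genotype(g.b, g.b, g.locus): Fraction(1, 4),
    }


def homozygote_acquisition_prob(n: int, m: int, x: int) -> Fraction:
    """P(a selfed T1 seed is x/x homozygous | T0 has m functional alleles).

    Sums genotype probability times the selfing fraction yielding x/x:
    1/4 for heterozygous genotypes containing an x homolog, 1 for an
    already-homozygous x/x T0 (only possible at even m = 2x), 0 otherwise.
    """
    if not 0 < x <= n:
        raise InvalidTargetError(f"x={x} must satisfy 0 < x <= n={n}")
    dist = genotype_distribution(n, m)
    total = Fraction(0)
    for g, p in dist.items():
        if g.a == x and g.b == x:
            total += p
        elif x in (g.a, g.b):
            total += p * Fraction(1, 4)
    return total


@dataclass(frozen=True)
class SelectionRow:
    m: int
    genotype: T0Genotype
    prob: Fraction
    percent: float
    acquisition: Fraction | None
    acquisition_percent: float | None
    is_fas: bool
    phase_ambiguous: bool


@dataclass(frozen=True)
class SelectionTable:
    """Machine form of the breeder's selection table for a locus and target x.

    One row per (m, genotype); rows whose genotype contains an x homolog
    carry the x/x acquisition probability among selfed T1 seeds.  Rendered
    percentages follow the published convention: the genotype percentage
    is rounded to one decimal first and the acquisition percentage is
    derived from that rounded figure (71.8 / 4 -> 18.0); the exact
    fractions are kept alongside.
    """

    locus: EditingLocus
    x: int
    rows: tuple[SelectionRow, ...]

    @property
    def fas_values(self) -> tuple[int, ...]:
        return fas(self.x, self.locus.copies_per_haplotype).values

    def acquisition_by_m(self, rendered: bool = False) -> dict[int, float | Fraction]:
        """Total x/x acquisition probability per T0 functional-allele count m."""
        out: dict[int, Fraction | float] = {}
        for row in self.rows:
            if row.acquisition is None:
                continue
            if rendered:
                out[row.m] = out.get(row.m, 0.0) + row.acquisition_percent
            else:
                out[row.m] = out.get(row.m, Fraction(0)) + row.acquisition
        return out

    def to_dataframe(self) -> pd.DataFrame:
        records = []
        for r in self.rows:
            records.append(
                {
                    "m": r.m,
                    "genotype": str(r.genotype),
                    "percent": r.percent,
                    "acquisition_percent": r.acquisition_percent,
                    "is_fas": r.is_fas,
                    "phase_ambiguous": r.phase_ambiguous,
                }
            )
        return pd.DataFrame.from_records(records)


def selection_table(
    n: int, x: int, m_values: Iterable[int] | None = None
) -> SelectionTable:
    """Build the selection plan for a locus with n copies and target x.

    ``m_values`` defaults to {2x-3, 2x-1, 2x+1, 2x+3} clipped to [0, 2n]:
    the two FAS counts plus their non-FAS neighbours, which is the
    comparison a breeder screens against.  Even m values are flagged
    phase-ambiguous: total allele counting cannot tell an (x, x) T0 from
    an (x+1, x-1) one.
    """
    result = fas(x, n)
    if m_values is None:
        m_values = [v for v in (2 * x - 3, 2 * x - 1, 2 * x + 1, 2 * x + 3) if 0 <= v <= 2 * n]
    rows: list[SelectionRow] = []
    locus = EditingLocus("locus", n)
    for m in sorted(set(m_values)):
        dist = genotype_distribution(n, m)
        for g in sorted(dist.entries, key=lambda g: g.b):
            p = dist[g]
            percent = round_half_up_percent(p)
            acquisition = None
            acquisition_percent = None
            if g.a == x and g.b == x:
                acquisition = p
                acquisition_percent = percent
            elif x in (g.a, g.b):
                acquisition = p * Fraction(1, 4)
                # published convention: quarter the rounded genotype percentage
                acquisition_percent = round_half_up_percent(
                    Fraction(round(percent * 10), 1000) / 4
                )
            rows.append(
                SelectionRow(
                    m=m,
                    genotype=T0Genotype(g.a, g.b, locus),
                    prob=p,
                    percent=percent,
                    acquisition=acquisition,
                    acquisition_percent=acquisition_percent,
                    is_fas=m in result.values,
                    phase_ambiguous=m % 2 == 0,
                )
            )
    return SelectionTable(locus=locus, x=x, rows=tuple(rows))
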