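"""Breeding-model tests: FAS rule, hypergeometric genotype splits, selfing."""

from __future__ import annotations

import itertools
from fractions import Fraction

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cnvedit.breeding import (
    InvalidTargetError,
    T0Genotype,
    fas,
    genotype_distribution,
    homozygote_acquisition_prob,
    round_half_up_percent,
    selection_table,
    selfing_distribution,
)


def brute_force_distribution(n: int, m: int) -> dict[tuple[int, int], Fraction]:
    """Oracle: enumerate every m-subset of the 2n allele slots exactly.

    Slots 0..n-1 sit on homolog 1; the functional count there defines the
    genotype together with its complement on homolog 2.
    """
    counts: dict[tuple[int, int], int] = {}
    total = 0
    for subset in itertools.combinations(range(2 * n), m):
        a = sum(1 for s in subset if s < n)
        b = m - a
        key = (max(a, b), min(a, b))
        counts[key] = counts.get(key, 0) + 1
        total += 1
    return {k: Fraction(v, total) for k, v in counts.items()}


class TestFAS:
    @pytest.mark.parametrize(
        "x, n, expected",
        [(5, 8, (9, 11)), (1, 2, (1, 3)), (2, 3, (3, 5)), (1, 3, (1, 3)), (7, 8, (13, 15))],
    )
    def test_values(self, x, n, expected):
        assert fas(x, n).values == expected

    @pytest.mark.parametrize("x, n", [(0, 2), (2, 2), (3, 2), (-1, 5), (5, 5)])
    def test_invalid_targets_rejected(self, x, n):
        with pytest.raises(InvalidTargetError):
            fas(x, n)

    def test_overlap_flags_match_adjacent_targets(self):
        # n=3: FAS(1) and FAS(2) share the value 3, flagged on both sides
        assert fas(1, 3).flagged == (3,)
        assert fas(2, 3).flagged == (3,)
        # n=2 has a single valid x, nothing to overlap with
        assert fas(1, 2).flagged == ()

    @given(st.integers(2, 20).flatmap(lambda n: st.tuples(st.just(n), st.integers(1, n - 1))))
    @settings(max_examples=60, derandomize=True)
    def test_values_odd_and_interior(self, nx):
        n, x = nx
        result = fas(x, n)
        assert all(v % 2 == 1 and 0 < v < 2 * n for v in result.values)


class TestGenotypeDistribution:
    def test_matches_brute_force_exactly_for_small_n(self):
        for n in range(1, 6):
            for m in range(0, 2 * n + 1):
                oracle = brute_force_distribution(n, m)
                dist = genotype_distribution(n, m)
                got = {(g.a, g.b): p for g, p in dist.items()}
                assert got == oracle, (n, m)

    def test_table_anchor_n8_m9(self):
        dist = genotype_distribution(8, 9)
        assert round_half_up_percent(dist[(5, 4)]) == 68.5

    @pytest.mark.parametrize("n, m, genotype, expected", [(1, 2, (1, 1), 1), (3, 5, (3, 2), 1)])
    def test_forced_genotypes(self, n, m, genotype, expected):
        assert genotype_distribution(n, m)[genotype] == expected

    def test_sums_to_one_exhaustive(self):
        for n in range(1, 13):
            for m in range(0, 2 * n + 1):
                assert sum(genotype_distribution(n, m).entries.values()) == 1

    def test_functional_edited_symmetry(self):
        # relabeling functional<->edited maps (n, m) onto (n, 2n - m)
        for n in range(1, 9):
            for m in range(0, 2 * n + 1):
                lhs = {(g.a, g.b): p for g, p in genotype_distribution(n, m).items()}
                rhs = {
                    (n - g.b, n - g.a): p
                    for g, p in genotype_distribution(n, 2 * n - m).items()
                }
                assert lhs == rhs

    def test_out_of_range_m(self):
        with pytest.raises(ValueError):
            genotype_distribution(3, 7)


class TestSelfing:
    def test_heterozygote_quarters(self):
        dist = selfing_distribution(T0Genotype(5, 4))
        assert dist[T0Genotype(5, 5)] == Fraction(1, 4)
        assert dist[T0Genotype(5, 4)] == Fraction(1, 2)
        assert dist[T0Genotype(4, 4)] == Fraction(1, 4)

    def test_homozygote_breeds_true(self):
        assert selfing_distribution(T0Genotype(3, 3)) == {T0Genotype(3, 3): Fraction(1)}

    @given(st.tuples(st.integers(0, 10), st.integers(0, 10)))
    @settings(max_examples=50, derandomize=True)
    def test_distribution_is_normalized(self, ab):
        dist = selfing_distribution(T0Genotype(*ab))
        assert sum(dist.values()) == 1


class TestAcquisition:
    @pytest.mark.parametrize(
        "n, m, x, expected",
        [
            (8, 9, 5, Fraction(7840, 11440) / 4),
            (8, 13, 5, Fraction(1, 20)),
            (1, 1, 1, Fraction(1, 4)),
        ],
    )
    def test_exact_values(self, n, m, x, expected):
        assert homozygote_acquisition_prob(n, m, x) == expected

    def test_forced_heterozygote_saturates_at_quarter(self):
        for n in range(2, 10):
            assert homozygote_acquisition_prob(n, 2 * n - 1, n - 1) == Fraction(1, 4)

    def test_even_m_homozygous_t0_contributes_fully(self):
        # at m = 2x the (x, x) genotype breeds true, so acquisition can top 1/4
        p = homozygote_acquisition_prob(2, 2, 1)
        dist = genotype_distribution(2, 2)
        expected = dist[(1, 1)] + dist[(2, 0)] * 0  # (2,0) lacks a 1-homolog
        assert p == expected
        assert p > Fraction(1, 4)

    def test_absent_target_gives_zero(self):
        assert homozygote_acquisition_prob(3, 6, 2) == 0  # m=6 forces (3,3)


class TestSelectionTable:
    def test_default_m_values_bracket_fas(self):
        table = selection_table(8, 5)
        assert sorted({r.m for r in table.rows}) == [7, 9, 11, 13]
        assert {r.m for r in table.rows if r.is_fas} == {9, 11}

    def test_n2_x1_acquisition(self):
        table = selection_table(2, 1, m_values=[1, 3])
        acq = table.acquisition_by_m()
        assert acq[1] == Fraction(1, 4)
        assert acq[3] == Fraction(1, 4)  # m=3 forces genotype (2,1)

    def test_n3_x2_forced_top_row(self):
        table = selection_table(3, 2)
        assert table.fas_values == (3, 5)
        assert table.acquisition_by_m()[5] == Fraction(1, 4)

    def test_even_m_rows_flagged_phase_ambiguous(self):
        table = selection_table(4, 2, m_values=[3, 4, 5])
        flags = {r.m: r.phase_ambiguous for r in table.rows}
        assert flags == {3: False, 4: True, 5: False}

    def test_rendered_acquisition_follows_published_rounding(self):
        # the displayed acquisition quarters the *rounded* genotype percent
        table = selection_table(8, 5)
        by_m = table.acquisition_by_m(rendered=True)
        assert by_m == {7: 6.9, 9: 17.1, 11: 18.0, 13: 5.0}
        # the exact fraction at m=11 rounds to 17.9 instead — both available
        exact = table.acquisition_by_m()[11]
        assert round_half_up_percent(exact) == 17.9


class TestRounding:
    @pytest.mark.parametrize(
        "value, expected",
        [
            (Fraction(7840, 11440), 68.5),
            (Fraction(16, 11440), 0.1),
            (Fraction(1795, 10000), 18.0),  # .x5 tie rounds up
            (Fraction(1, 2), 50.0),
        ],
    )
    def test_half_up(self, value, expected):
        assert round_half_up_percent(value) == expected
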