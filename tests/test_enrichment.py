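"""Value-class binning, hypergeometric tails and motif detection."""

import math

import numpy as np
import pandas as pd
import pytest

from kinmotif.enrichment import (
    EPS_P,
    KineticMotif,
    assign_value_class,
    decade_scheme,
    detect_motifs,
    enrichment_pvalue,
    enrichment_table,
    format_pvalue,
    scheme_for,
    tabulate_counts,
)
from kinmotif.fixtures import FixtureSpec, PlantedEffect, generate_fixture


def brute_force_tail(x: int, y: int, M: int, N: int) -> float:
    """Strict upper tail P(X > x) by direct pmf summation with exact combinatorics."""
    total = math.comb(N, M)
    return sum(
        math.comb(y, k) * math.comb(N - y, M - k)
        for k in range(x + 1, min(y, M) + 1)
    ) / total


class TestValueClasses:
    def test_mm_constant_scheme_has_five_decades(self):
        scheme = scheme_for("K_BA")
        assert scheme.class_indices == (1, 2, 3, 4, 5)
        assert scheme.interval(1) == pytest.approx((1e-3, 1e-2))
        assert scheme.interval(5) == pytest.approx((1e1, 1e2))

    def test_rate_constant_scheme_occupies_middle_classes(self):
        scheme = scheme_for("k_BA")
        assert scheme.class_indices == (3, 4)
        assert scheme.interval(3) == pytest.approx((1e-1, 1e0))

    @pytest.mark.parametrize(
        "value,expected",
        [(10 ** -2.5, 1), (1e-2, 2), (0.5, 3), (1.0, 4), (1e2, 5), (10 ** 1.999, 5)],
    )
    def test_assignment_half_open_with_closed_top(self, value, expected):
        assert assign_value_class(value, scheme_for("K_BA")) == expected

    def test_out_of_range_value_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            assign_value_class(5e-4, scheme_for("K_BA"))

    def test_doubled_resolution_scheme(self):
        scheme = scheme_for("K_BA", per_decade=2)
        assert scheme.n_classes == 10
        assert assign_value_class(10 ** -2.75, scheme) == 1
        assert assign_value_class(10 ** -2.25, scheme) == 2


class TestCounts:
    def test_conservation(self, planted_fixture):
        x, y, M, N = tabulate_counts(planted_fixture, "K_BA", scheme_for("K_BA"))
        assert x.sum() == M == 74
        assert y.sum() == N == 20_000

    def test_fully_planted_class_collects_all_solutions(self):
        spec = FixtureSpec(
            M=50, N=2_000,
            effects={"K_AB": PlantedEffect(class_index=3, planting_fraction=1.0)},
            seed=3,
        )
        x, y, M, N = tabulate_counts(generate_fixture(spec), "K_AB", scheme_for("K_AB"))
        assert list(x) == [0, 0, 50, 0, 0]

    def test_no_solutions_is_an_error(self):
        df = generate_fixture(FixtureSpec(M=0, N=100, seed=0))
        with pytest.raises(ValueError, match="solutions"):
            tabulate_counts(df, "K_BA", scheme_for("K_BA"))


class TestHypergeometricTail:
    def test_derived_small_case(self):
        # P(X > 2) = P(X = 3) = C(5,3)/C(10,3) = 10/120
        assert enrichment_pvalue(2, 5, 3, 10) == pytest.approx(10 / 120)

    def test_matches_enumeration_for_small_populations(self, rng):
        # exact-combinatorics oracle across the small-N regime
        for _ in range(300):
            N = int(rng.integers(1, 61))
            M = int(rng.integers(0, N + 1))
            y = int(rng.integers(0, N + 1))
            x = int(rng.integers(0, min(y, M) + 1))
            expected = brute_force_tail(x, y, M, N)
            got = enrichment_pvalue(x, y, M, N)
            if expected > 0:
                assert abs(got - expected) / expected < 1e-10
            else:
                assert got <= 1e-299

    def test_pmf_normalizes(self):
        for N, y, M in [(10, 4, 3), (25, 10, 7), (60, 31, 12)]:
            total = sum(
                math.comb(y, k) * math.comb(N - y, M - k)
                for k in range(max(0, M - (N - y)), min(y, M) + 1)
            )
            assert total == math.comb(N, M)

    def test_tail_strictly_decreases_in_x(self):
        ps = [enrichment_pvalue(x, 300, 40, 1000) for x in range(0, 30)]
        assert all(a > b for a, b in zip(ps, ps[1:]))

    def test_inclusive_tail_option(self):
        strict = enrichment_pvalue(2, 5, 3, 10)
        inclusive = enrichment_pvalue(2, 5, 3, 10, strict_tail=False)
        assert inclusive > strict
        assert inclusive == pytest.approx(brute_force_tail(1, 5, 3, 10))

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            enrichment_pvalue(5, 3, 4, 10)   # x > y
        with pytest.raises(ValueError):
            enrichment_pvalue(1, 3, 11, 10)  # M > N

    def test_formatting_sentinel(self):
        assert format_pvalue(7.55e-4) == "7.6E-04"
        assert format_pvalue(1e-17) == "<2.2E-16"
        assert format_pvalue(0.9999) == "1.0E+00"


class TestMotifDetection:
    def test_planted_motif_recovered(self, planted_fixture):
        table = enrichment_table(planted_fixture, ["K_BA", "K_AB"])
        motifs = detect_motifs(table)
        assert "K_BA" in motifs
        assert motifs["K_BA"].classes == (1,)
        assert motifs["K_BA"].interval == pytest.approx((1e-3, 1e-2))
        assert "K_AB" not in motifs

    def test_adjacent_significant_classes_merge(self):
        # published-style counts: classes 1 and 2 significant for one parameter
        rows = []
        for cls, x, y in [(1, 33, 19_994), (2, 28, 20_000), (3, 11, 20_000),
                          (4, 2, 20_000), (5, 0, 20_000)]:
            p = enrichment_pvalue(x, y, 74, 100_000)
            rows.append(dict(parameter="K_BA", class_index=cls, lower=10.0 ** (cls - 4),
                             upper=10.0 ** (cls - 3), x=x, y=y, M=74, N=100_000,
                             p=p, p_str=format_pvalue(p), significant=p < 1e-3))
        motifs = detect_motifs(pd.DataFrame(rows))
        assert motifs["K_BA"].classes == (1, 2)
        assert motifs["K_BA"].interval == pytest.approx((1e-3, 1e-1))

    def test_uniform_counts_give_no_motif(self):
        df = generate_fixture(FixtureSpec(M=74, N=20_000, seed=5))
        table = enrichment_table(df, ["K_BA", "k_BA", "K_FCC"])
        assert detect_motifs(table) == {}

    def test_motif_membership_mask(self):
        motif = KineticMotif("K_BA", (1, 2), scheme_for("K_BA"))
        values = np.array([5e-3, 5e-2, 5e-1, 1e-1])
        np.testing.assert_array_equal(
            motif.contains(values), [True, True, False, False]
        )
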