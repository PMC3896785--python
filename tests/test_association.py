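"""Mann-Whitney association, function labels, bipartite network, cooperation."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import mannwhitneyu, pearsonr

from kinmotif.association import (
    build_bipartite_network,
    classify_function,
    mann_whitney_z,
    pairwise_cooperation,
    partition_by_motif,
    associate_motifs,
)
from kinmotif.enrichment import KineticMotif, scheme_for
from kinmotif.fixtures import FixtureSpec, PlantedEffect, generate_fixture
from kinmotif.profiler import MotifProfiler


class TestMannWhitney:
    def test_identical_groups_score_zero(self):
        assert mann_whitney_z([1, 2, 3], [1, 2, 3]) == pytest.approx(0.0)

    def test_derived_no_tie_case(self):
        # a = {3,4,5}, b = {1,2}: U = 6, var = 3 -> z = sqrt(3)
        assert mann_whitney_z([3, 4, 5], [1, 2]) == pytest.approx(np.sqrt(3))

    def test_antisymmetric_under_group_swap(self, rng):
        a, b = rng.normal(0.3, 1, 40), rng.normal(0, 1, 55)
        assert mann_whitney_z(a, b) == pytest.approx(-mann_whitney_z(b, a))

    def test_degenerate_all_equal_data(self):
        assert mann_whitney_z([2, 2, 2], [2, 2]) == 0.0

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_z([], [1.0])

    def test_agrees_with_scipy_normal_approximation(self, rng):
        a = rng.normal(0.5, 1, 200)
        b = rng.normal(0.0, 1, 150)
        z = mann_whitney_z(a, b)
        res = mannwhitneyu(a, b, alternative="greater", method="asymptotic",
                           use_continuity=False)
        from scipy.stats import norm
        assert z == pytest.approx(norm.isf(res.pvalue), rel=1e-9)

    def test_tie_correction_matches_scipy(self, rng):
        a = rng.integers(0, 4, 120).astype(float)
        b = rng.integers(0, 4, 140).astype(float)
        z = mann_whitney_z(a, b)
        res = mannwhitneyu(a, b, alternative="greater", method="asymptotic",
                           use_continuity=False)
        from scipy.stats import norm
        assert z == pytest.approx(norm.isf(res.pvalue), rel=1e-9, abs=1e-12)

    def test_infinite_scores_rank_highest(self):
        z_inf = mann_whitney_z([np.inf, np.inf, 5.0], [1.0, 2.0, 3.0])
        z_big = mann_whitney_z([1e12, 1e12, 5.0], [1.0, 2.0, 3.0])
        assert z_inf == pytest.approx(z_big)


class TestFunctionLabels:
    @pytest.mark.parametrize(
        "z_sens,z_prec,expected",
        [
            (-8.75, 30.88, ("PR",)),
            (26.57, 9.23, ("PR", "SN")),
            (2.0, 2.0, ()),
            (3.30, -34.32, ("SN",)),
            (3.29, 3.29, ()),          # strictly greater than the critical value
        ],
    )
    def test_label_assignment(self, z_sens, z_prec, expected):
        assert classify_function(z_sens, z_prec) == expected


class TestPartition:
    def test_groups_partition_screened_rows(self, planted_fixture):
        motif = KineticMotif("K_BA", (1,), scheme_for("K_BA"))
        part = partition_by_motif(planted_fixture, motif)
        assert sum(part.sizes) == (planted_fixture["outcome"] == "OK").sum()

    def test_interior_value_lands_in_motif_group(self, planted_fixture):
        motif = KineticMotif("K_BA", (1, 2), scheme_for("K_BA"))
        part = partition_by_motif(planted_fixture, motif)
        assert np.all(part.motif_rows["K_BA"] < 1e-1)
        assert np.all(part.non_motif_rows["K_BA"] >= 1e-1)

    def test_interior_motif_has_two_sided_complement(self, planted_fixture):
        # a middle-class motif splits the complement into both flanks
        motif = KineticMotif("K_FCC", (3,), scheme_for("K_FCC"))
        part = partition_by_motif(planted_fixture, motif)
        non = part.non_motif_rows["K_FCC"]
        assert (non < 1e-1).any() and (non >= 1e0).any()
        assert not ((part.motif_rows["K_FCC"] < 1e-1) | (part.motif_rows["K_FCC"] >= 1e0)).any()


class TestBipartiteNetwork:
    def test_structure_and_isolated_functions(self):
        g = build_bipartite_network([])
        assert set(g.nodes) == {"sensitivity", "precision"}
        assert g.number_of_edges() == 0

    def test_edges_only_between_sides(self, planted_fixture):
        profile = MotifProfiler(planted_fixture).fit()
        g = profile.network
        side = {n: d["bipartite"] for n, d in g.nodes(data=True)}
        for u, v in g.edges:
            assert side[u] != side[v]

    def test_planted_precision_shift_yields_pr_edge(self, planted_fixture):
        profile = MotifProfiler(planted_fixture).fit()
        assert ("K_BA", "precision") in profile.network.edges
        assert ("K_BA", "sensitivity") not in profile.network.edges


class TestCooperation:
    def test_identical_columns_fully_correlated(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0, 4.0], "b": [1.0, 2.0, 3.0, 4.0]})
        out = pairwise_cooperation(df, ["a", "b"], log_scale=False)
        assert out.loc[0, "r"] == pytest.approx(1.0)

    def test_exact_linearity_is_significant(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0, 4.0], "b": [2.0, 4.0, 6.0, 8.0]})
        out = pairwise_cooperation(df, ["a", "b"], log_scale=False)
        assert out.loc[0, "r"] == pytest.approx(1.0)
        assert bool(out.loc[0, "correlated"])

    def test_too_few_solutions_rejected(self):
        df = pd.DataFrame({"a": [1.0, 2.0], "b": [2.0, 1.0]})
        with pytest.raises(ValueError, match="at least 3"):
            pairwise_cooperation(df, ["a", "b"])

    def test_pvalue_matches_permutation_oracle(self, rng):
        n = 24
        x = 10 ** rng.uniform(-3, 2, n)
        y = x ** 0.6 * 10 ** rng.normal(0, 1.2, n)
        df = pd.DataFrame({"x": x, "y": y})
        out = pairwise_cooperation(df, ["x", "y"])
        r_obs = out.loc[0, "r"]
        lx, ly = np.log10(x), np.log10(y)
        perm_hits = 0
        n_perm = 1000
        for _ in range(n_perm):
            r_perm = pearsonr(lx, rng.permutation(ly))[0]
            if abs(r_perm) >= abs(r_obs):
                perm_hits += 1
        p_perm = perm_hits / n_perm
        p_param = out.loc[0, "p"]
        # agreement within Monte-Carlo error (3 sigma of the permutation estimate)
        mc_sigma = np.sqrt(max(p_param * (1 - p_param), 1e-4) / n_perm)
        assert abs(p_perm - p_param) < 3.5 * mc_sigma + 0.01


class TestAssociationPipeline:
    def test_medians_reported_per_group(self, planted_fixture):
        motif = KineticMotif("K_BA", (1,), scheme_for("K_BA"))
        results = associate_motifs(planted_fixture, {"K_BA": motif})
        r = results[0]
        part = partition_by_motif(planted_fixture, motif)
        assert r.precision_median_motif == pytest.approx(
            float(np.median(part.motif_rows["precision"]))
        )
        assert r.n_motif + r.n_non_motif == sum(part.sizes)
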