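"""Permutation module-preservation statistics and weak-module selection."""

import numpy as np
import pytest

from coexdiff.modules import ModulePartition
from coexdiff.network import CoexpressionNetwork, build_network
from coexdiff.preservation import (
    ModulePreservation,
    PreservationReport,
    classify_preservation,
    connectivity_statistics,
    density_statistics,
    module_preservation,
    permutation_null,
    select_weak_modules,
    z_scores,
    z_summary,
)
from coexdiff.simulate import SimulationConfig, simulate_two_condition

from conftest import make_expr


def toy_network(adjacency, correlation=None, gene_ids=None):
    n = adjacency.shape[0]
    gene_ids = gene_ids or [f"g{i}" for i in range(n)]
    if correlation is None:
        correlation = 2 * adjacency ** (1 / 3) - 1  # any valid companion matrix
        np.fill_diagonal(correlation, 1.0)
    return CoexpressionNetwork(
        gene_ids=gene_ids,
        correlation=correlation,
        adjacency=adjacency,
        tom=adjacency,
        beta=3,
    )


class TestDensityStatistics:
    def test_saturated_and_empty_modules(self, rng):
        n = 5
        expr = make_expr(rng.normal(size=(n, 8)))
        ones = np.ones((n, n))
        net = toy_network(ones)
        stats = density_statistics(list(expr.index), net, expr)
        assert stats["meanAdj"] == pytest.approx(1.0)
        zero = np.eye(n)
        stats0 = density_statistics(list(expr.index), toy_network(zero), expr)
        assert stats0["meanAdj"] == pytest.approx(0.0)

    def test_matches_loop_oracle(self, rng):
        n = 5
        a = rng.uniform(0, 1, size=(n, n))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 1.0)
        c = rng.uniform(-1, 1, size=(n, n))
        c = (c + c.T) / 2
        np.fill_diagonal(c, 1.0)
        expr = make_expr(rng.normal(size=(n, 10)))
        stats = density_statistics(list(expr.index), toy_network(a, c), expr)
        mean_adj = np.mean([a[i, j] for i in range(n) for j in range(n) if i != j])
        mean_cor = np.mean([c[i, j] for i in range(n) for j in range(n) if i != j])
        assert stats["meanAdj"] == pytest.approx(mean_adj, abs=1e-12)
        assert stats["meanCor"] == pytest.approx(mean_cor, abs=1e-12)

    def test_small_module_rejected(self, rng):
        expr = make_expr(rng.normal(size=(2, 5)))
        with pytest.raises(ValueError, match=">= 3"):
            density_statistics(list(expr.index), toy_network(np.eye(2)), expr)


class TestConnectivityStatistics:
    def test_identical_networks_give_unity(self, rng):
        n = 6
        a = rng.uniform(0, 1, size=(n, n))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 1.0)
        net = toy_network(a)
        stats = connectivity_statistics([f"g{i}" for i in range(n)], net, net)
        for v in stats.values():
            assert v == pytest.approx(1.0)

    def test_shuffled_adjacency_kills_correlation(self, rng):
        n = 50
        a = rng.uniform(0, 1, size=(n, n))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 1.0)
        iu = np.triu_indices(n, k=1)
        vals = a[iu].copy()
        rng.shuffle(vals)
        b = np.eye(n)
        b[iu] = vals
        b = b + b.T - np.eye(n)
        np.fill_diagonal(b, 1.0)
        stats = connectivity_statistics(
            [f"g{i}" for i in range(n)], toy_network(a), toy_network(b)
        )
        assert abs(stats["cor_adj"]) < 0.15

    def test_hand_set_three_gene_module(self):
        a_ref = np.array([[1.0, 0.9, 0.1], [0.9, 1.0, 0.3], [0.1, 0.3, 1.0]])
        a_test = np.array([[1.0, 0.8, 0.2], [0.8, 1.0, 0.2], [0.2, 0.2, 1.0]])
        stats = connectivity_statistics(
            ["g0", "g1", "g2"], toy_network(a_ref), toy_network(a_test)
        )
        k_ref = [1.0, 1.2, 0.4]
        k_test = [1.0, 1.0, 0.4]
        assert stats["cor_kIM"] == pytest.approx(np.corrcoef(k_ref, k_test)[0, 1], abs=1e-12)
        assert stats["cor_adj"] == pytest.approx(
            np.corrcoef([0.9, 0.1, 0.3], [0.8, 0.2, 0.2])[0, 1], abs=1e-12
        )


class TestPermutationNull:
    def test_seed_reproducibility(self):
        u = [f"g{i}" for i in range(40)]
        assert permutation_null(5, u, 10, seed=3) == permutation_null(5, u, 10, seed=3)

    def test_full_universe_draw(self):
        u = [f"g{i}" for i in range(8)]
        draws = permutation_null(8, u, 5, seed=0)
        for d in draws:
            assert sorted(d) == sorted(u)

    def test_inclusion_frequency_binomial(self):
        u = [f"g{i}" for i in range(100)]
        draws = permutation_null(10, u, 1000, seed=1)
        freq = {g: 0 for g in u}
        for d in draws:
            for g in d:
                freq[g] += 1
        p = 0.1
        sd = np.sqrt(p * (1 - p) / 1000)
        for g, f in freq.items():
            assert abs(f / 1000 - p) < 3 * sd + 1e-9 or abs(f / 1000 - p) < 0.04

    def test_oversized_module_rejected(self):
        with pytest.raises(ValueError):
            permutation_null(5, ["a", "b"], 10, seed=0)


class TestZScores:
    def test_trivial_cases(self):
        null = {"s": np.array([0.0, 1.0, 2.0, 3.0, 4.0] * 5)}
        zs, flags = z_scores({"s": null["s"].mean()}, null)
        assert zs["s"] == pytest.approx(0.0)
        sd = null["s"].std(ddof=1)
        zs2, _ = z_scores({"s": null["s"].mean() + 2 * sd}, null)
        assert zs2["s"] == pytest.approx(2.0)

    def test_toy_null_oracle(self, rng):
        null_vals = rng.uniform(0, 1, size=25)
        zs, _ = z_scores({"s": 0.9}, {"s": null_vals})
        expected = (0.9 - null_vals.mean()) / null_vals.std(ddof=1)
        assert zs["s"] == pytest.approx(expected, abs=1e-12)

    def test_degenerate_null_sentinels(self):
        null = {"s": np.ones(30)}
        zs, flags = z_scores({"s": 2.0}, null)
        assert zs["s"] == np.inf and flags["s"]
        zs0, flags0 = z_scores({"s": 1.0}, null)
        assert np.isnan(zs0["s"]) and flags0["s"]

    def test_empty_null_rejected(self):
        with pytest.raises(ValueError):
            z_scores({"s": 1.0}, {"s": np.array([])})


class TestZSummary:
    def test_direct_arithmetic(self):
        zd, zc, zs = z_summary([4.0], [6.0])
        assert (zd, zc, zs) == (4.0, 6.0, 5.0)

    def test_constant_lists(self):
        zd, zc, zs = z_summary([3.0, 3.0, 3.0], [3.0, 3.0])
        assert zs == 3.0

    def test_median_combination(self):
        zd, zc, zs = z_summary([1.0, 3.0, 10.0], [2.0, 4.0])
        assert zd == 3.0 and zc == 3.0 and zs == 3.0

    def test_exact_mean_of_medians(self, rng):
        for _ in range(20):
            d = rng.normal(size=rng.integers(1, 6))
            c = rng.normal(size=rng.integers(1, 6))
            zd, zc, zs = z_summary(d, c)
            assert zs == (zd + zc) / 2  # bitwise


class TestClassifyPreservation:
    @pytest.mark.parametrize(
        "z,expected",
        [
            (1.12, "none"),
            (36.80, "strong"),
            (5.0, "weak-to-moderate"),
            (2.0, "none"),        # boundary assigned to the lower category
            (10.0, "weak-to-moderate"),
        ],
    )
    def test_thresholds(self, z, expected):
        assert classify_preservation(z) == expected


def report_from(z_values, artificial=()):
    rows = [
        ModulePreservation(
            module=i + 1,
            color=f"c{i}",
            size=30,
            z_density=z,
            z_connectivity=z,
            z_summary=z,
            category=classify_preservation(z),
            artificial=(i + 1) in artificial,
        )
        for i, z in enumerate(z_values)
    ]
    return PreservationReport(rows=rows, n_perm=100, seed=0)


class TestSelectWeakModules:
    def test_table_like_selection(self):
        report = report_from([1.12, 2.62, 3.91, 4.97, 5.10])
        assert select_weak_modules(report, cutoff=5.0) == [1, 2, 3, 4]

    def test_zero_cutoff_empty(self):
        report = report_from([1.0, 2.0])
        assert select_weak_modules(report, cutoff=0.0) == []

    def test_infinite_cutoff_all_non_artificial(self):
        report = report_from([1.0, 50.0, 3.0], artificial={3})
        assert set(select_weak_modules(report, cutoff=np.inf)) == {1, 2}

    def test_sorted_ascending(self):
        report = report_from([4.0, 1.0, 3.0])
        assert select_weak_modules(report, cutoff=5.0) == [2, 3, 1]


def small_scenario(seed, destroyed=frozenset({1})):
    return SimulationConfig(
        n_samples_ref=30,
        n_samples_test=30,
        module_sizes=[40, 35, 30],
        module_loadings=[0.85, 0.8, 0.75],
        destroyed_modules=set(destroyed),
        n_background_genes=60,
        seed=seed,
    )


class TestModulePreservation:
    def test_self_preservation(self):
        """Every planted module scores strong when test == reference."""
        er, _, _, truth = simulate_two_condition(small_scenario(5, destroyed=frozenset()))
        net, _ = build_network(er, beta=6)
        part = ModulePartition(list(er.index), truth.module_of.to_numpy())
        rep = module_preservation(net, net, er, part, n_perm=100, seed=5)
        for r in rep.rows:
            if not r.artificial:
                assert r.z_summary > 10

    def test_destroyed_module_scores_low_intact_high(self):
        er, et, _, truth = simulate_two_condition(small_scenario(6))
        net_ref, _ = build_network(er, beta=6)
        net_test, _ = build_network(et, beta=6)
        part = ModulePartition(list(er.index), truth.module_of.to_numpy())
        rep = module_preservation(net_ref, net_test, et, part, n_perm=100, seed=6)
        zs = {r.module: r.z_summary for r in rep.rows if not r.artificial}
        assert zs[2] < 5  # destroyed
        assert zs[2] < min(zs[1], zs[3]) - 5  # clearly below intact modules

    def test_gold_module_near_null(self):
        er, et, _, truth = simulate_two_condition(small_scenario(7))
        net_ref, _ = build_network(er, beta=6)
        net_test, _ = build_network(et, beta=6)
        part = ModulePartition(list(er.index), truth.module_of.to_numpy())
        rep = module_preservation(net_ref, net_test, et, part, n_perm=100, seed=7)
        gold = next(r for r in rep.rows if r.color == "gold")
        assert abs(gold.z_summary) < 4
        assert gold.artificial

    def test_z_calibration_under_own_null(self):
        """Observed drawn from the null: Z is near standard normal in mean.

        The mean of R replicate Zs has standard error ~1/sqrt(R); 150
        replicates with 60-draw nulls keep the check comfortably inside
        the 0.2 band.
        """
        er, et, _, truth = simulate_two_condition(small_scenario(8))
        net_ref, _ = build_network(er, beta=6)
        net_test, _ = build_network(et, beta=6)
        universe = net_ref.gene_ids
        zs = []
        for rep in range(150):
            draws = permutation_null(20, universe, 61, seed=1000 + rep)
            observed = density_statistics(draws[0], net_test, et)
            null = {k: np.empty(60) for k in observed}
            for p, d in enumerate(draws[1:]):
                for k, v in density_statistics(d, net_test, et).items():
                    null[k][p] = v
            z, _ = z_scores(observed, null)
            zs.append(z["meanAdj"])
        assert abs(np.mean(zs)) < 0.2
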