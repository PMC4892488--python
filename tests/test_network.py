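"""Signed adjacency, scale-free criterion and topological overlap."""

import numpy as np
import pytest
from scipy import stats

from coexdiff.network import (
    correlation_matrix,
    pick_soft_threshold,
    scale_free_fit,
    signed_adjacency,
    tom_dissimilarity,
    topological_overlap,
)

from conftest import make_expr, random_symmetric_adjacency


class TestCorrelationMatrix:
    def test_identical_and_negated_profiles(self):
        v = np.array([1.0, 2.0, 4.0, 3.0])
        expr = make_expr([v, v, -v])
        c = correlation_matrix(expr)
        assert c[0, 1] == pytest.approx(1.0)
        assert c[0, 2] == pytest.approx(-1.0)
        np.testing.assert_array_equal(np.diag(c), 1.0)

    def test_matches_pearson_formula(self, rng):
        x = rng.normal(size=(4, 7))
        c = correlation_matrix(make_expr(x))
        for i in range(4):
            for j in range(4):
                expected = stats.pearsonr(x[i], x[j]).statistic if i != j else 1.0
                assert c[i, j] == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_gene_listed(self):
        expr = make_expr([[1.0, 1.0, 1.0], [1.0, 2.0, 3.0]], genes=["flat", "ok"])
        with pytest.raises(ValueError, match="flat"):
            correlation_matrix(expr)

    def test_too_few_samples(self):
        with pytest.raises(ValueError, match="3 samples"):
            correlation_matrix(make_expr([[1.0, 2.0], [2.0, 1.0]]))


class TestSignedAdjacency:
    def test_analytic_corners(self):
        cor = np.array([[1.0, 1.0], [1.0, 1.0]])
        assert signed_adjacency(cor, 9)[0, 1] == 1.0
        cor = np.array([[1.0, -1.0], [-1.0, 1.0]])
        assert signed_adjacency(cor, 5)[0, 1] == 0.0
        cor = np.array([[1.0, 0.0], [0.0, 1.0]])
        assert signed_adjacency(cor, 9)[0, 1] == pytest.approx(0.5**9)
        assert signed_adjacency(cor, 9)[0, 1] == pytest.approx(0.001953125)

    @pytest.mark.parametrize("bad", [0, -1, 2.5])
    def test_invalid_beta(self, bad):
        cor = np.eye(2)
        with pytest.raises(ValueError):
            signed_adjacency(cor, bad)

    def test_monotone_in_correlation_and_beta(self):
        cors = np.linspace(-1, 1, 21)
        a6 = ((1 + cors) / 2) ** 6
        assert (np.diff(a6) > 0).all()
        # for cor < 1 adjacency decreases as beta grows
        cor = np.array([[1.0, 0.4], [0.4, 1.0]])
        vals = [signed_adjacency(cor, b)[0, 1] for b in range(1, 10)]
        assert all(v1 > v2 for v1, v2 in zip(vals, vals[1:]))


def pairs_adjacency(degree_counts):
    """Block-diagonal adjacency of gene pairs with a_12 = k, so both genes
    have connectivity exactly k."""
    blocks = []
    for k, count in degree_counts:
        assert count % 2 == 0
        for _ in range(count // 2):
            blocks.append(k)
    n = 2 * len(blocks)
    a = np.zeros((n, n))
    np.fill_diagonal(a, 1.0)
    for b, k in enumerate(blocks):
        a[2 * b, 2 * b + 1] = a[2 * b + 1, 2 * b] = k
    return a


class TestScaleFreeFit:
    def test_exact_power_law_bins(self):
        # counts proportional to k^-2 at geometrically spaced k: the binned
        # log-log points are perfectly collinear with slope -2
        a = pairs_adjacency([(0.08, 128), (0.16, 32), (0.32, 8), (0.64, 2)])
        r2, slope = scale_free_fit(a, n_bins=10)
        assert r2 == pytest.approx(1.0, abs=1e-12)
        assert slope == pytest.approx(-2.0, abs=1e-10)

    def test_constant_connectivity_error(self):
        a = pairs_adjacency([(0.3, 10)])
        with pytest.raises(ValueError, match="degenerate"):
            scale_free_fit(a)

    def test_matches_independent_regression_oracle(self, rng):
        # module-structured synthetic adjacency; regress the same binned
        # points with an independently coded two-pass least squares
        x = rng.normal(size=(200, 30))
        x[:100] += rng.normal(size=30) * 0.8  # one broad module
        cor = correlation_matrix(make_expr(x))
        a = signed_adjacency(cor, 9)
        r2, slope = scale_free_fit(a, n_bins=10)

        k = a.sum(axis=1) - 1.0
        edges = np.linspace(k.min(), k.max(), 11)
        which = np.clip(np.digitize(k, edges[1:-1]), 0, 9)
        pts = []
        for b in range(10):
            m = which == b
            if m.sum() and k[m].mean() > 0:
                pts.append((np.log10(k[m].mean()), np.log10(m.sum() / len(k))))
        xs = np.array([p[0] for p in pts])
        ys = np.array([p[1] for p in pts])
        xm, ym = xs.mean(), ys.mean()
        beta_hat = ((xs - xm) * (ys - ym)).sum() / ((xs - xm) ** 2).sum()
        ss_res = ((ys - (ym + beta_hat * (xs - xm))) ** 2).sum()
        ss_tot = ((ys - ym) ** 2).sum()
        assert r2 == pytest.approx(1 - ss_res / ss_tot, abs=1e-10)
        assert slope == pytest.approx(beta_hat, abs=1e-10)


class TestPickSoftThreshold:
    def _module_correlation(self, seed=0, n=300, n_samples=40):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=(n, n_samples))
        for lo, hi, load in [(0, 80, 0.8), (80, 140, 0.7), (140, 180, 0.6)]:
            f = rng.normal(size=n_samples)
            x[lo:hi] = load * f + np.sqrt(1 - load**2) * x[lo:hi]
        return correlation_matrix(make_expr(x))

    def test_cut_crossing_selects_first_qualifying_power(self):
        """A cutoff placed between two adjacent fits picks the higher power
        (the smallest beta whose R^2 clears the cut with negative slope)."""
        cor = self._module_correlation()
        fits = {}
        for b in range(1, 13):
            fits[b] = scale_free_fit(signed_adjacency(cor, b))
        negative = {b: r2 for b, (r2, slope) in fits.items() if slope < 0}
        target = max(negative, key=negative.get)
        runner_up = max(v for b, v in negative.items() if b != target)
        cut = (negative[target] + runner_up) / 2
        beta, scan = pick_soft_threshold(cor, range(1, 13), r2_cut=cut)
        assert beta == target
        assert scan.criterion_met

    def test_zero_cut_returns_smallest_negative_slope_beta(self):
        cor = self._module_correlation()
        beta, scan = pick_soft_threshold(cor, range(1, 13), r2_cut=0.0)
        qualifying = [
            b for b, r2, s in zip(scan.betas, scan.r_squared, scan.slopes)
            if np.isfinite(r2) and r2 > 0 and s < 0
        ]
        assert beta == min(qualifying)

    def test_fallback_to_argmax_with_flag(self):
        cor = self._module_correlation()
        beta, scan = pick_soft_threshold(cor, range(1, 13), r2_cut=0.9999)
        assert not scan.criterion_met
        best = int(np.nanargmax(np.array(scan.r_squared)))
        assert beta == scan.betas[best]


def tom_oracle(a):
    """O(n^3) literal evaluation of the overlap formula."""
    n = a.shape[0]
    a0 = a.copy()
    np.fill_diagonal(a0, 0.0)
    k = a0.sum(axis=1)
    t = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            l_ij = sum(a0[i, u] * a0[u, j] for u in range(n) if u != i and u != j)
            t[i, j] = (l_ij + a0[i, j]) / (min(k[i], k[j]) + 1 - a0[i, j])
    return t


class TestTopologicalOverlap:
    def test_two_gene_maximal_adjacency(self):
        a = np.array([[1.0, 1.0], [1.0, 1.0]])
        t = topological_overlap(a)
        assert t[0, 1] == pytest.approx(1.0)

    def test_empty_network(self):
        a = np.eye(4)
        t = topological_overlap(a)
        off = t[~np.eye(4, dtype=bool)]
        np.testing.assert_array_equal(off, 0.0)

    def test_matches_brute_force(self, rng):
        for _ in range(5):
            a = random_symmetric_adjacency(rng, 6)
            t = topological_overlap(a)
            np.testing.assert_allclose(t, tom_oracle(a), atol=1e-12)

    def test_range_and_symmetry_on_random_instances(self, rng):
        for _ in range(10):
            a = random_symmetric_adjacency(rng, 15)
            t = topological_overlap(a)
            assert (t >= 0).all() and (t <= 1).all()
            np.testing.assert_allclose(t, t.T, atol=1e-14)

    def test_permutation_equivariance(self, rng):
        a = random_symmetric_adjacency(rng, 8)
        perm = rng.permutation(8)
        t1 = topological_overlap(a)[np.ix_(perm, perm)]
        t2 = topological_overlap(a[np.ix_(perm, perm)])
        np.testing.assert_allclose(t1, t2, atol=1e-12)

    def test_asymmetric_input_rejected(self):
        a = np.eye(3)
        a[0, 1] = 0.5
        with pytest.raises(ValueError, match="symmetric"):
            topological_overlap(a)


from hypothesis import given, settings
from hypothesis import strategies as st


@settings(deadline=None, max_examples=60, derandomize=True)
@given(c=st.floats(min_value=-1.0, max_value=1.0), beta=st.integers(1, 20))
def test_signed_adjacency_stays_in_unit_interval(c, beta):
    cor = np.array([[1.0, c], [c, 1.0]])
    a = signed_adjacency(cor, beta)
    assert 0.0 <= a[0, 1] <= 1.0
    assert a[0, 0] == a[1, 1] == 1.0


@settings(deadline=None, max_examples=25, derandomize=True)
@given(seed=st.integers(0, 10**6), n=st.integers(3, 8))
def test_tom_bounded_and_matches_oracle_on_random_instances(seed, n):
    rng = np.random.default_rng(seed)
    a = random_symmetric_adjacency(rng, n)
    t = topological_overlap(a)
    assert (t >= 0).all() and (t <= 1).all()
    np.testing.assert_allclose(t, tom_oracle(a), atol=1e-12)


def test_tom_dissimilarity_involution(rng):
    a = random_symmetric_adjacency(rng, 6)
    t = topological_overlap(a)
    d = tom_dissimilarity(t)
    np.testing.assert_array_equal(np.diag(d), 0.0)
    back = 1.0 - d
    np.fill_diagonal(back, 1.0)
    np.testing.assert_allclose(back, t, atol=1e-14)
    # identity-like TOM gives unit dissimilarity off the diagonal
    d_id = tom_dissimilarity(np.eye(4))
    assert (d_id[~np.eye(4, dtype=bool)] == 1.0).all()
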