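import numpy as np
import pytest
from scipy import stats

from dualnet.core import ExpressionMatrix, standardize_genes
from dualnet.ggm import (
    edge_pvalue,
    estimate_kappa,
    estimate_lambda,
    infer_network,
    partial_correlations,
    shrunk_correlation,
)


def lambda_oracle(x):
    """Direct double-loop evaluation of the optimal shrinkage intensity."""
    n, p = x.shape
    num = den = 0.0
    for i in range(p):
        for j in range(p):
            if i == j:
                continue
            w = x[:, i] * x[:, j]
            r = w.sum() / (n - 1)
            num += n / (n - 1) ** 3 * np.sum((w - w.mean()) ** 2)
            den += r * r
    return min(max(num / den, 0.0), 1.0)


def standardized(rng, n, p):
    x = rng.normal(size=(n, p))
    x -= x.mean(axis=0)
    x /= x.std(axis=0, ddof=1)
    return x


class TestEstimateLambda:
    def test_perfect_correlation_with_zero_sampling_variance(self):
        # a two-level pattern makes every product term constant, so the
        # estimated Var(r) is exactly zero and no shrinkage is needed
        col = np.array([-1.0, -1.0, 1.0, 1.0])
        col = col / col.std(ddof=1)
        x = np.column_stack([col, col])
        assert estimate_lambda(x) == 0.0

    def test_zero_correlation_maps_to_full_shrinkage(self):
        a = np.array([1.0, 1.0, -1.0, -1.0])
        b = np.array([1.0, -1.0, 1.0, -1.0])
        x = np.column_stack([a / a.std(ddof=1), b / b.std(ddof=1)])
        assert estimate_lambda(x) == 1.0

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(0)
        x = standardized(rng, 20, 10)
        assert estimate_lambda(x) == pytest.approx(lambda_oracle(x), abs=1e-12)

    def test_requires_three_samples(self):
        with pytest.raises(ValueError):
            estimate_lambda(np.ones((2, 5)))

    def test_decreases_with_sample_size(self):
        """More data means less need for regularization (n = 20, 80, 320)."""
        rng = np.random.default_rng(1)
        p = 15
        a = rng.normal(size=(p, p)) / np.sqrt(p)
        cov = a @ a.T + 0.5 * np.eye(p)
        lams = []
        for n in (20, 80, 320):
            x = rng.multivariate_normal(np.zeros(p), cov, size=n)
            x -= x.mean(axis=0)
            x /= x.std(axis=0, ddof=1)
            lams.append(estimate_lambda(x))
        assert lams[0] > lams[1] > lams[2]


class TestShrunkCorrelation:
    def test_limits(self):
        rng = np.random.default_rng(2)
        x = standardized(rng, 30, 5)
        r = x.T @ x / 29
        np.fill_diagonal(r, 1.0)
        np.testing.assert_allclose(shrunk_correlation(r, 1.0), np.eye(5))
        np.testing.assert_allclose(shrunk_correlation(r, 0.0), r)

    def test_spectral_floor(self):
        rng = np.random.default_rng(3)
        x = standardized(rng, 10, 20)  # rank-deficient correlation
        r = x.T @ x / 9
        np.fill_diagonal(r, 1.0)
        eig = np.linalg.eigvalsh(shrunk_correlation(r, 0.2)).min()
        assert eig >= 0.2 - 1e-10

    def test_domain_error(self):
        with pytest.raises(ValueError):
            shrunk_correlation(np.eye(3), 1.5)


class TestPartialCorrelations:
    def test_identity_input_gives_zero(self):
        pcor = partial_correlations(np.eye(4))
        assert np.allclose(pcor - np.eye(4), 0)

    def test_three_variable_closed_form(self):
        r = np.array([[1, 0.6, 0.4], [0.6, 1, 0.5], [0.4, 0.5, 1.0]])
        pcor = partial_correlations(r)
        expected = (0.6 - 0.4 * 0.5) / np.sqrt((1 - 0.4**2) * (1 - 0.5**2))
        assert pcor[0, 1] == pytest.approx(expected, abs=1e-10)
        e02 = (0.4 - 0.6 * 0.5) / np.sqrt((1 - 0.6**2) * (1 - 0.5**2))
        e12 = (0.5 - 0.6 * 0.4) / np.sqrt((1 - 0.6**2) * (1 - 0.4**2))
        assert pcor[0, 2] == pytest.approx(e02, abs=1e-10)
        assert pcor[1, 2] == pytest.approx(e12, abs=1e-10)

    def test_two_gene_shrinkage_reduction(self):
        r12, lam = 0.7, 0.3
        r = np.array([[1.0, r12], [r12, 1.0]])
        pcor = partial_correlations(shrunk_correlation(r, lam))
        assert pcor[0, 1] == pytest.approx((1 - lam) * r12, abs=1e-12)

    def test_non_positive_definite_raises_helpful_error(self):
        rng = np.random.default_rng(4)
        x = standardized(rng, 5, 10)
        r = x.T @ x / 4
        np.fill_diagonal(r, 1.0)
        with pytest.raises(np.linalg.LinAlgError, match="lambda"):
            partial_correlations(r)

    def test_symmetry_and_compression_bound(self):
        rng = np.random.default_rng(5)
        x = standardized(rng, 25, 40)
        lam = estimate_lambda(x)
        r = x.T @ x / 24
        np.fill_diagonal(r, 1.0)
        pcor = partial_correlations(shrunk_correlation(r, lam))
        np.testing.assert_allclose(pcor, pcor.T, atol=1e-10)
        off = pcor[~np.eye(40, dtype=bool)]
        assert np.all(np.abs(off) <= 1 - lam + 1e-8)


class TestEstimateKappa:
    def test_fixed_mode_is_passthrough(self):
        assert estimate_kappa(np.zeros(50), 0.2, mode=20) == 20.0

    def test_fit_matches_grid_search_oracle(self):
        rng = np.random.default_rng(6)
        n, p = 50, 10
        x = standardized(rng, n, p)
        r = x.T @ x / (n - 1)
        np.fill_diagonal(r, 1.0)
        pcor = partial_correlations(r)
        off = pcor[np.triu_indices(p, 1)]
        fit = estimate_kappa(off, 0.0, mode="fit", n_samples=n)
        # brute-force grid over the same likelihood
        from scipy.special import betaln

        grid = np.linspace(3.01, 10 * n, 4000)
        u2 = np.clip(off**2, 0, 1 - 1e-12)
        ll = [
            (k - 3) / 2 * np.sum(np.log1p(-u2)) - off.size * betaln(0.5, (k - 1) / 2)
            for k in grid
        ]
        oracle = grid[int(np.argmax(ll))]
        assert fit == pytest.approx(oracle, rel=0.15)

    def test_degenerate_all_zero_hits_bound_with_warning(self):
        with pytest.warns(UserWarning, match="upper bound"):
            k = estimate_kappa(np.zeros(100), 0.1, mode="fit", n_samples=20)
        assert k == pytest.approx(200, rel=0.01)

    def test_requires_enough_edges(self):
        with pytest.raises(ValueError, match="30"):
            estimate_kappa(np.zeros(10), 0.1, mode="fit", n_samples=20)


class TestEdgePvalue:
    def test_null_center_and_support_boundary(self):
        assert edge_pvalue(0.0, 0.2, 40.0) == pytest.approx(1.0)
        assert edge_pvalue(0.8, 0.2, 40.0) == pytest.approx(0.0, abs=1e-12)
        assert edge_pvalue(-0.8, 0.2, 40.0) == pytest.approx(0.0, abs=1e-12)

    def test_domain_error_beyond_support(self):
        with pytest.raises(ValueError):
            edge_pvalue(0.95, 0.2, 40.0)

    def test_unshrunk_case_reduces_to_classical_t_test(self):
        """With lambda = 0 the Beta tail equals the classical correlation test:
        the null density exponent (kappa - 3)/2 corresponds to the t transform
        r * sqrt((kappa - 1)/(1 - r^2)) with kappa - 1 degrees of freedom."""
        kappa = 30.0
        for r in (0.05, 0.2, 0.45, 0.7):
            t = r * np.sqrt((kappa - 1) / (1 - r**2))
            classical = 2 * stats.t.sf(t, df=kappa - 1)
            assert edge_pvalue(r, 0.0, kappa) == pytest.approx(classical, rel=1e-10)

    def test_monte_carlo_null_agreement(self):
        lam, kappa, r_obs = 0.1, 40.0, 0.3
        rng = np.random.default_rng(7)
        s = rng.beta(0.5, (kappa - 1) / 2, size=200_000)
        r_null = (1 - lam) * np.sqrt(s)  # sign is irrelevant for |r| >= r_obs
        p_mc = float(np.mean(r_null >= r_obs))
        se = np.sqrt(p_mc * (1 - p_mc) / r_null.size)
        assert abs(edge_pvalue(r_obs, lam, kappa) - p_mc) <= 3 * se


class TestInferNetwork:
    def test_two_gene_minimal_case(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=(2, 40))
        x[1] = 0.9 * x[0] + 0.3 * rng.normal(size=40)
        m = ExpressionMatrix(["GA", "GB"], [f"S{j}" for j in range(40)], x)
        ggm, net = infer_network(m, threshold=0.05, kappa=30.0)
        assert len(ggm.edge_table) == 1
        edge_q = ggm.edge_table["q"][0]
        assert (len(net.edges) == 1) == (edge_q <= 0.05)

    def test_edge_table_covers_all_pairs_sorted(self):
        rng = np.random.default_rng(9)
        m = ExpressionMatrix(
            [f"G{i:02d}" for i in range(10)],
            [f"S{j}" for j in range(25)],
            rng.normal(size=(10, 25)),
        )
        ggm, _ = infer_network(m, threshold=0.05)
        assert len(ggm.edge_table) == 45
        pairs = list(zip(ggm.edge_table["gene_a"], ggm.edge_table["gene_b"]))
        assert pairs == sorted(pairs)
        assert all(a < b for a, b in pairs)

    def test_standardization_is_applied_internally(self):
        rng = np.random.default_rng(10)
        raw = rng.normal(loc=7, scale=2, size=(12, 30))
        m = ExpressionMatrix(
            [f"G{i:02d}" for i in range(12)], [f"S{j}" for j in range(30)], raw
        )
        g1, _ = infer_network(m, threshold=0.05)
        g2, _ = infer_network(standardize_genes(m), threshold=0.05)
        np.testing.assert_allclose(g1.pcor, g2.pcor, atol=1e-10)

    def test_networkx_export(self):
        rng = np.random.default_rng(11)
        x = rng.normal(size=(6, 50))
        x[1] = x[0] + 0.1 * rng.normal(size=50)
        m = ExpressionMatrix(
            [f"G{i}" for i in range(6)], [f"S{j}" for j in range(50)], x
        )
        _, net = infer_network(m, threshold=0.05, kappa=25.0)
        g = net.to_networkx()
        assert set(g.nodes) == set(m.gene_ids)
        assert g.number_of_edges() == len(net.edges)
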