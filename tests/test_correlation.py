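"""Correlation estimators against independent brute-force oracles."""

import numpy as np
import pytest

from gutnet.correlation import (
    FractionEstimate,
    basis_correlations,
    basis_variances,
    bootstrap_pvalues,
    clr_pearson,
    clr_transform,
    estimate_fractions,
    sparcc,
    variation_matrix,
)
from gutnet.data import AbundanceTable
from gutnet.simulate import SimulationConfig, simulate_counts


def table_from(counts, prefix="T"):
    counts = np.asarray(counts)
    return AbundanceTable(
        [f"{prefix}{i}" for i in range(counts.shape[0])],
        [f"S{j}" for j in range(counts.shape[1])],
        counts,
    )


class TestEstimateFractions:
    def test_pseudocount_arithmetic(self):
        t = table_from([[0], [3], [7]])
        f = estimate_fractions(t, pseudocount=1.0).fractions[:, 0]
        assert np.allclose(f, [1 / 13, 4 / 13, 8 / 13])

    def test_uniform_counts(self):
        t = table_from([[1], [1], [1], [1]])
        f = estimate_fractions(t, pseudocount=1.0).fractions[:, 0]
        assert np.allclose(f, 0.25)

    def test_dirichlet_converges_to_raw_proportions_at_depth(self):
        rng = np.random.default_rng(0)
        raw = np.array([0.5, 0.3, 0.2])
        t = table_from((raw * 1_000_000).astype(int)[:, None])
        f = estimate_fractions(t, method="dirichlet", rng=rng).fractions[:, 0]
        assert np.max(np.abs(f - raw)) < 1e-3

    def test_nonpositive_pseudocount_rejected(self, tiny_table):
        with pytest.raises(ValueError):
            estimate_fractions(tiny_table, pseudocount=0.0)


class TestClrTransform:
    def test_equal_fractions_zero(self):
        z = clr_transform(np.full((4, 3), 0.25))
        assert np.allclose(z, 0.0)

    def test_known_values(self):
        z = clr_transform(np.array([[0.5], [0.25], [0.25]]))
        assert np.allclose(z[:, 0], [0.4621, -0.2310, -0.2310], atol=1e-4)

    def test_columns_sum_to_zero(self):
        rng = np.random.default_rng(1)
        f = rng.dirichlet(np.ones(8), size=10).T
        assert np.allclose(clr_transform(f).sum(axis=0), 0.0, atol=1e-12)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            clr_transform(np.array([[0.0], [1.0]]))


def pearson_oracle(x):
    """Double-loop textbook Pearson over rows, independent of the estimator."""
    d = x.shape[0]
    r = np.eye(d)
    for i in range(d):
        for j in range(d):
            xi, xj = x[i] - x[i].mean(), x[j] - x[j].mean()
            r[i, j] = (xi * xj).sum() / np.sqrt((xi**2).sum() * (xj**2).sum())
    return r


class TestClrPearson:
    def test_matches_double_loop_oracle(self, random_table):
        res = clr_pearson(random_table)
        f = estimate_fractions(random_table, pseudocount=1.0)
        expected = pearson_oracle(clr_transform(f))
        assert np.max(np.abs(res.rho - expected)) <= 1e-10

    def test_identical_clr_profiles_give_unit_rho(self):
        # two taxa with proportional counts -> identical CLR rows
        t = table_from([[10, 20, 40], [10, 20, 40], [80, 60, 20], [100, 100, 100]])
        res = clr_pearson(t, pseudocount=1e-9)
        assert res.rho[0, 1] == pytest.approx(1.0, abs=1e-9)

    def test_sample_permutation_invariance(self, random_table):
        res = clr_pearson(random_table)
        perm = np.random.default_rng(2).permutation(random_table.n_samples)
        shuffled = AbundanceTable(
            list(random_table.taxa),
            [random_table.samples[i] for i in perm],
            random_table.counts[:, perm],
        )
        assert np.allclose(clr_pearson(shuffled).rho, res.rho, atol=1e-12)

    def test_requires_three_samples(self):
        with pytest.raises(ValueError):
            clr_pearson(table_from([[1, 2], [3, 4], [5, 6]]))


class TestVariationMatrix:
    def test_proportional_taxa_zero_variation(self):
        f = np.array([[0.1, 0.2, 0.3], [0.2, 0.4, 0.6]])
        f = np.vstack([f, 1 - f.sum(axis=0, keepdims=True)])
        t = variation_matrix(f / f.sum(axis=0, keepdims=True))
        assert t[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_known_log_ratio_variance(self):
        # two taxa with log-ratios (0, 1, 2): unbiased variance 1
        r = np.exp([0.0, 1.0, 2.0])
        f = np.vstack([r / (1 + r), 1 / (1 + r)])
        t = variation_matrix(f)
        assert t[0, 1] == pytest.approx(1.0, abs=1e-10)

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(3)
        f = rng.dirichlet(np.ones(8), size=15).T
        t = variation_matrix(f)
        for i in range(8):
            for j in range(8):
                lr = np.log(f[i] / f[j])
                assert t[i, j] == pytest.approx(np.var(lr, ddof=1), abs=1e-10)


def gaussian_elimination(a, b):
    """Hand-rolled elimination solve, independent of numpy.linalg."""
    a = [row[:] for row in a]
    b = list(b)
    n = len(b)
    for col in range(n):
        piv = max(range(col, n), key=lambda r: abs(a[r][col]))
        a[col], a[piv] = a[piv], a[col]
        b[col], b[piv] = b[piv], b[col]
        for r in range(col + 1, n):
            m = a[r][col] / a[col][col]
            for c in range(col, n):
                a[r][c] -= m * a[col][c]
            b[r] -= m * b[col]
    x = [0.0] * n
    for r in range(n - 1, -1, -1):
        x[r] = (b[r] - sum(a[r][c] * x[c] for c in range(r + 1, n))) / a[r][r]
    return x


class TestBasisVariances:
    def test_constant_variation_matrix(self):
        t = np.full((4, 4), 2.0)
        np.fill_diagonal(t, 0.0)
        assert np.allclose(basis_variances(t), 1.0)

    def test_linearity(self):
        v = 3.7
        t = np.full((4, 4), 2.0 * v)
        np.fill_diagonal(t, 0.0)
        assert np.allclose(basis_variances(t), v)

    def test_exact_recovery_when_all_rho_zero(self):
        """T[i,j] = w_i + w_j (uncorrelated basis) must return w exactly."""
        w = np.array([0.5, 1.0, 2.0, 4.0, 0.25])
        t = w[:, None] + w[None, :]
        np.fill_diagonal(t, 0.0)
        assert np.max(np.abs(basis_variances(t) - w)) <= 1e-9

    def test_matches_elimination_oracle(self):
        rng = np.random.default_rng(4)
        t = rng.uniform(0.5, 3.0, size=(5, 5))
        t = (t + t.T) / 2
        np.fill_diagonal(t, 0.0)
        d = 5
        m = [[1.0 + (d - 2) * (i == j) for j in range(d)] for i in range(d)]
        rhs = [t[i].sum() for i in range(d)]
        expected = gaussian_elimination(m, rhs)
        assert np.allclose(basis_variances(t), expected, atol=1e-9)

    def test_too_few_taxa_rejected(self):
        with pytest.raises(ValueError):
            basis_variances(np.zeros((3, 3)))


class TestBasisCorrelations:
    def test_zero_when_t_equals_sum(self):
        w = np.array([1.0, 2.0, 3.0, 4.0])
        t = w[:, None] + w[None, :]
        np.fill_diagonal(t, 0.0)
        rho = basis_correlations(t, w)
        off = rho[~np.eye(4, dtype=bool)]
        assert np.allclose(off, 0.0)

    def test_unit_when_t_zero_equal_omega(self):
        w = np.array([2.0, 2.0, 1.0, 1.0])
        t = np.zeros((4, 4))
        rho = basis_correlations(t, w)
        assert rho[0, 1] == pytest.approx(1.0)

    def test_clip_boundary_arithmetic(self):
        w = np.array([1.0, 4.0])
        t = np.array([[0.0, 1.0], [1.0, 0.0]])
        rho = basis_correlations(t, w)
        assert rho[0, 1] == pytest.approx((1 + 4 - 1) / (2 * 2))

    def test_nonpositive_omega_rejected(self):
        with pytest.raises(ValueError):
            basis_correlations(np.zeros((2, 2)), np.array([1.0, 0.0]))


class TestSparcc:
    def test_null_data_stays_below_gate(self):
        cfg = SimulationConfig(n_taxa=20, n_samples_per_group=500, seed=10)
        table, _, _, _ = simulate_counts(cfg)
        res = sparcc(table, seed=10)
        off = np.abs(res.rho[np.triu_indices(20, k=1)])
        assert off.max() < 0.3

    def test_planted_pair_is_largest(self):
        cfg = SimulationConfig(
            n_taxa=20, n_samples_per_group=200, planted_edges=[(0, 1, 0.8)], seed=1
        )
        table, _, _, _ = simulate_counts(cfg)
        res = sparcc(table, seed=1)
        iu = np.triu_indices(20, k=1)
        off = np.abs(res.rho[iu])
        k = off.argmax()
        assert res.rho[0, 1] >= 0.5
        assert (iu[0][k], iu[1][k]) == (0, 1)

    def test_symmetric_unit_diagonal(self, random_table):
        res = sparcc(random_table, seed=0)
        assert np.allclose(res.rho, res.rho.T)
        assert np.allclose(np.diag(res.rho), 1.0)
        assert res.rho.min() >= -1.0 and res.rho.max() <= 1.0

    def test_sign_agreement_with_clr_pearson(self):
        """Strong planted edges get the same sign from both estimators."""
        agree = 0
        seeds = range(6)
        for seed in seeds:
            cfg = SimulationConfig(
                n_taxa=20, n_samples_per_group=200,
                planted_edges=[(0, 1, 0.8), (2, 3, -0.8)], seed=seed,
            )
            table, _, _, _ = simulate_counts(cfg)
            sp = sparcc(table, seed=seed).rho
            cp = clr_pearson(table).rho
            if np.sign(sp[0, 1]) == np.sign(cp[0, 1]) == 1 and np.sign(sp[2, 3]) == np.sign(cp[2, 3]) == -1:
                agree += 1
        assert agree >= 0.95 * len(list(seeds)) - 1  # allow one disagreement in 6

    def test_too_few_taxa_rejected(self):
        with pytest.raises(ValueError):
            sparcc(table_from([[1, 2, 3], [4, 5, 6], [7, 8, 9]]))


class TestBootstrap:
    def test_identical_columns_minimal_p(self):
        """A perfectly correlated pair at 99 bootstraps: p = 1/100."""
        rng = np.random.default_rng(5)
        base = rng.integers(10, 1000, size=30)
        other = rng.integers(10, 1000, size=(2, 30))
        t = table_from(np.vstack([base, base, other]))
        obs = clr_pearson(t, pseudocount=1e-6)
        assert obs.rho[0, 1] == pytest.approx(1.0, abs=1e-9)
        res = bootstrap_pvalues(t, obs, n_bootstrap=99, seed=5)
        assert res.pvalues[0, 1] == pytest.approx(1 / 100)

    def test_pvalues_in_unit_interval_and_symmetric(self, random_table):
        obs = clr_pearson(random_table)
        res = bootstrap_pvalues(random_table, obs, n_bootstrap=49, seed=6)
        p = res.pvalues
        assert np.all(p > 0) and np.all(p <= 1)
        assert np.allclose(p, p.T)
        assert np.allclose(np.diag(p), 1.0)

    def test_monotone_in_observed_magnitude(self, random_table):
        """For a fixed null sample, a larger |rho_obs| cannot raise p."""
        obs = clr_pearson(random_table)
        res = bootstrap_pvalues(random_table, obs, n_bootstrap=99, seed=7)
        iu = np.triu_indices(random_table.n_taxa, k=1)
        order = np.argsort(np.abs(obs.rho[iu]))
        # p-values sorted by |rho_obs| need not be strictly monotone pair-to-pair
        # (each pair has its own null), but the rank correlation must be negative
        from scipy.stats import spearmanr

        r, _ = spearmanr(np.abs(obs.rho[iu]), res.pvalues[iu])
        assert r < 0

    def test_invalid_bootstrap_count(self, random_table):
        with pytest.raises(ValueError):
            bootstrap_pvalues(random_table, clr_pearson(random_table), n_bootstrap=0)
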