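import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import multivariate_normal, norm

from ipvalign import (
    GenerationSpec,
    PipelineConfig,
    adequacy_gate,
    estimate_thresholds,
    fit_indices,
    fit_one_factor,
    generate,
)
from ipvalign.binary_factor import (
    DegenerateItemError,
    FitResult,
    fit_one_factor_from_corr,
    tetrachoric_from_counts,
)
from ipvalign import tetrachoric
from tests.conftest import make_table


def grid_search_tetrachoric(n11, n10, n01, n00, coarse=2e-3, fine=1e-4):
    """Independent brute-force oracle: maximize the 2x2 bivariate-normal
    likelihood over rho on a grid, using scipy's multivariate normal CDF."""
    counts = np.array([n11, n10, n01, n00], dtype=float)
    if np.any(counts == 0):
        counts = counts + 0.5
    n = counts.sum()
    t1 = norm.ppf(1 - (counts[0] + counts[1]) / n)
    t2 = norm.ppf(1 - (counts[0] + counts[2]) / n)

    def ll(rho):
        p11 = multivariate_normal([0, 0], [[1, rho], [rho, 1]]).cdf([-t1, -t2])
        p1, p2 = norm.cdf(-t1), norm.cdf(-t2)
        probs = np.clip([p11, p1 - p11, p2 - p11, 1 - p1 - p2 + p11], 1e-12, 1)
        return float(np.dot(counts, np.log(probs)))

    grid = np.arange(-0.999, 0.999, coarse)
    best = grid[int(np.argmax([ll(r) for r in grid]))]
    fine_grid = np.arange(best - coarse, best + coarse, fine)
    fine_grid = fine_grid[(fine_grid > -0.9995) & (fine_grid < 0.9995)]
    return fine_grid[int(np.argmax([ll(r) for r in fine_grid]))]


class TestThresholds:
    def test_half_prevalence_zero_threshold(self):
        y = np.r_[np.ones(50), np.zeros(50)].reshape(-1, 1)
        t = make_table(y, ["A"] * 100)
        assert estimate_thresholds(t, "A")[0] == pytest.approx(0.0)

    def test_phi_inverse(self):
        # prevalence 0.1587 = Phi(-1) corresponds to threshold ~ 1
        y = np.r_[np.ones(1587), np.zeros(8413)].reshape(-1, 1)
        t = make_table(y, ["A"] * 10000)
        assert estimate_thresholds(t, "A")[0] == pytest.approx(1.0, abs=1e-3)

    def test_recovery_from_generator(self):
        spec = GenerationSpec(
            group_labels=["A"], items=["x1", "x2"], n_per_group=[10**4],
            loadings=np.full((2, 1), 0.8), thresholds=np.array([[0.7], [1.2]]),
            factor_means=[0.0], factor_vars=[1.0], missing_rate=0.0,
            weight_dist="ones", seed=8,
        )
        table, _ = generate(spec)
        tau_hat = estimate_thresholds(table, "A")
        # univariate threshold of the marginal: tau / sqrt(lam^2 + 1)
        tau_marg = np.array([0.7, 1.2]) / np.sqrt(1 + 0.64)
        for j, tm in enumerate(tau_marg):
            p = norm.cdf(-tm)
            se_tau = np.sqrt(p * (1 - p) / 10**4) / norm.pdf(tm)
            assert abs(tau_hat[j] - tm) < 3 * se_tau

    def test_degenerate_item_error_names_item(self):
        y = np.ones((20, 1))
        t = make_table(y, ["A"] * 20)
        with pytest.raises(DegenerateItemError, match="x1"):
            estimate_thresholds(t, "A")


class TestTetrachoric:
    def test_independence_table_zero(self):
        rho, _ = tetrachoric_from_counts(25, 25, 25, 25)
        assert rho == pytest.approx(0.0, abs=1e-6)

    def test_strong_agreement_table(self):
        # frozen from the grid-search oracle (step 1e-4)
        rho, _ = tetrachoric_from_counts(40, 10, 10, 40)
        assert rho == pytest.approx(0.8090, abs=1e-3)

    def test_symmetry_in_item_labels(self):
        rng = np.random.default_rng(5)
        y = (rng.random((300, 2)) < [0.4, 0.6]).astype(float)
        y[:100, 1] = y[:100, 0]
        t = make_table(y, ["A"] * 300)
        r12, _ = tetrachoric(t, "x1", "x2")
        r21, _ = tetrachoric(t, "x2", "x1")
        assert r12 == pytest.approx(r21, abs=1e-9)

    def test_empty_cell_continuity_correction(self):
        rho, _ = tetrachoric_from_counts(30, 0, 12, 25)
        assert -1 < rho < 1

    @settings(max_examples=12, deadline=None, derandomize=True)
    @given(
        st.tuples(
            st.integers(1, 50), st.integers(1, 50),
            st.integers(1, 50), st.integers(1, 50),
        )
    )
    def test_matches_grid_search_oracle(self, cells):
        rho, _ = tetrachoric_from_counts(*cells)
        oracle = grid_search_tetrachoric(*cells)
        assert abs(rho - oracle) <= 1e-3


class TestFitOneFactor:
    @pytest.mark.parametrize("lam", [0.4, 0.6, 0.8, 0.95])
    @pytest.mark.parametrize("n", [1000, 5000])
    def test_slope_recovery_sweep(self, lam, n):
        spec = GenerationSpec(
            group_labels=["A"], items=[f"x{j}" for j in range(5)],
            n_per_group=[n], loadings=np.full((5, 1), lam),
            thresholds=np.linspace(-0.3, 0.8, 5).reshape(-1, 1),
            factor_means=[0.0], factor_vars=[1.0], missing_rate=0.0,
            weight_dist="ones", seed=int(100 * lam + n),
        )
        table, _ = generate(spec)
        fit = fit_one_factor(table, "A")
        assert fit.converged
        z = (fit.slopes - lam) / fit.slope_se
        assert np.all(np.abs(z) < 3.0)

    def test_perfect_fit_of_model_implied_matrix(self):
        lam = np.array([0.5, 0.6, 0.7, 0.8])
        R = np.outer(lam, lam)
        np.fill_diagonal(R, 1.0)
        fit = fit_one_factor_from_corr(R, n=1000)
        assert fit.chi2 == pytest.approx(0.0, abs=1e-6)
        assert fit.rmsea == pytest.approx(0.0, abs=1e-6)
        assert fit.cfi == pytest.approx(1.0)
        assert np.allclose(fit.loadings, lam, atol=1e-5)

    def test_three_items_saturated(self):
        lam = np.array([0.5, 0.6, 0.7])
        R = np.outer(lam, lam)
        np.fill_diagonal(R, 1.0)
        fit = fit_one_factor_from_corr(R, n=500)
        assert fit.df == 0
        assert np.isnan(fit.rmsea) and np.isnan(fit.cfi) and np.isnan(fit.tli)

    def test_df_formula(self):
        lam = np.full(7, 0.7)
        R = np.outer(lam, lam)
        np.fill_diagonal(R, 1.0)
        fit = fit_one_factor_from_corr(R, n=500)
        assert fit.df == 7 * 6 // 2 - 7 == 14


class TestFitIndices:
    def test_chi2_equal_df_limits(self):
        rmsea, cfi, tli = fit_indices(14.0, 14, 1000, 300.0, 21)
        assert rmsea == 0.0 and cfi == 1.0 and tli == pytest.approx(1.0)

    def test_rmsea_arithmetic(self):
        rmsea, _, _ = fit_indices(28.0, 14, 1000, 300.0, 21)
        # sqrt((28-14)/(14*999)) checked by independent calculator
        assert rmsea == pytest.approx(0.0316386, abs=1e-6)

    def test_monotonicity_in_chi2(self):
        vals = [fit_indices(c, 14, 500, 400.0, 21) for c in (14.0, 30.0, 60.0, 120.0)]
        rmseas = [v[0] for v in vals]
        cfis = [v[1] for v in vals]
        assert rmseas == sorted(rmseas)
        assert cfis == sorted(cfis, reverse=True)
        assert all(0.0 <= c <= 1.0 for c in cfis)

    def test_df_zero_undefined(self):
        assert all(np.isnan(v) for v in fit_indices(0.0, 0, 100, 10.0, 3))


def _fit(loadings_min, rmsea, cfi, tli, converged=True):
    J = 4
    lam = np.full(J, 0.8)
    lam[0] = loadings_min
    return FitResult(
        group="A", items=[f"x{j}" for j in range(J)], loadings=lam,
        loading_se=np.full(J, 0.05), slopes=lam, slope_se=np.full(J, 0.05),
        thresholds=np.zeros(J), chi2=10.0, df=2, n=500, rmsea=rmsea, cfi=cfi,
        tli=tli, baseline_chi2=500.0, baseline_df=6, converged=converged,
    )


class TestAdequacyGate:
    def test_pass(self):
        d = adequacy_gate(_fit(0.36, 0.02, 1.0, 1.0), PipelineConfig())
        assert d.passed

    def test_fail_on_loading_boundary(self):
        d = adequacy_gate(_fit(0.34, 0.02, 1.0, 1.0), PipelineConfig())
        assert not d.passed and not d.loading_ok and d.rmsea_ok

    def test_fail_on_rmsea_boundary(self):
        d = adequacy_gate(_fit(0.5, 0.081, 1.0, 1.0), PipelineConfig())
        assert not d.passed and not d.rmsea_ok

    def test_nonconverged_fails_with_reason(self):
        d = adequacy_gate(_fit(0.5, 0.02, 1.0, 1.0, converged=False))
        assert not d.passed and "non-converged" in d.reason
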