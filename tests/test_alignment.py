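import math

import numpy as np
import pytest
from scipy.stats import norm

from ipvalign import (
    align,
    component_loss,
    fit_multigroup,
    flag_invariance,
    generate,
    inject_noninvariance,
    invariance_r2,
    monte_carlo_quality,
    pct_noninvariant,
    total_loss,
)
from ipvalign.exact_invariance import GroupParams, MultiGroupFit
from ipvalign.synthetic_data import invariance_benchmark_spec


def noise_free_configural(alpha, psi, lam_j=None, tau_j=None, n=500, J=7):
    """Configural parameters implied exactly by an invariant model."""
    G = len(alpha)
    lam_j = np.linspace(0.65, 0.95, J) if lam_j is None else np.asarray(lam_j)
    tau_j = np.linspace(-0.5, 1.5, J) if tau_j is None else np.asarray(tau_j)
    lam0 = lam_j[:, None] * np.sqrt(psi)[None, :]
    tau0 = tau_j[:, None] - lam_j[:, None] * np.asarray(alpha)[None, :]
    groups = [
        GroupParams(
            label=f"G{g:02d}", loadings=lam0[:, g], thresholds=tau0[:, g], n=n,
            cov=np.eye(2 * J) * 1e-4,
        )
        for g in range(G)
    ]
    return MultiGroupFit(
        level="configural", items=[f"i{j}" for j in range(J)], groups=groups,
        loglik=0.0, n_params=2 * J * G, converged=True,
    )


@pytest.fixture(scope="module")
def fitted_small(benchmark_small):
    table, truth = benchmark_small
    conf = fit_multigroup(table, "configural", compute_se=True)
    sol = align(conf)
    return conf, sol, truth


class TestComponentLoss:
    def test_eps_value_at_zero(self):
        assert component_loss(0.0, 1e-4) == pytest.approx(0.1)

    def test_unit_argument(self):
        # (1 + 0.01)^(1/4), checked by independent arithmetic
        assert component_loss(1.0, 0.01) == pytest.approx(1.01**0.25)
        assert component_loss(1.0, 0.01) == pytest.approx(1.0024907, abs=1e-6)

    @pytest.mark.parametrize("x", [-3.0, -0.5, 0.1, 2.0])
    def test_even_and_increasing_in_abs(self, x):
        assert component_loss(x) == pytest.approx(component_loss(-x))
        assert component_loss(2 * x) > component_loss(x)

    def test_nonpositive_epsilon_rejected(self):
        with pytest.raises(ValueError):
            component_loss(1.0, 0.0)


class TestTotalLoss:
    def test_identical_groups_closed_form(self):
        G, J, n, eps = 5, 4, 300, 0.01
        conf = noise_free_configural(np.zeros(G), np.ones(G), J=J, n=n)
        got = total_loss(conf, np.zeros(G), np.ones(G), eps)
        n_pairs = G * (G - 1) // 2
        expected = J * n_pairs * n * 2 * eps**0.25  # all weights sqrt(n*n) = n
        assert got == pytest.approx(expected)

    def test_hand_computed_two_group_toy(self):
        conf = MultiGroupFit(
            level="configural", items=["i0"],
            groups=[
                GroupParams("A", np.array([0.8]), np.array([0.5]), n=100),
                GroupParams("B", np.array([0.9]), np.array([0.3]), n=400),
            ],
            loglik=0.0, n_params=4, converged=True,
        )
        # by hand: psi_B = 1.21 -> lam_B = 0.9/1.1, tau_B = 0.3 + 0.9*0.2/1.1
        lam_b = 0.9 / 1.1
        tau_b = 0.3 + 0.9 * 0.2 / 1.1
        w = math.sqrt(100 * 400)
        expected = w * (
            ((0.8 - lam_b) ** 2 + 0.01) ** 0.25 + ((0.5 - tau_b) ** 2 + 0.01) ** 0.25
        )
        got = total_loss(conf, np.array([0.0, 0.2]), np.array([1.0, 1.21]), 0.01)
        assert got == pytest.approx(expected)

    def test_nonpositive_variance_rejected(self):
        conf = noise_free_configural(np.zeros(3), np.ones(3))
        with pytest.raises(ValueError):
            total_loss(conf, np.zeros(3), np.array([1.0, -1.0, 1.0]))


class TestAlign:
    def test_noise_free_exact_recovery(self):
        rng = np.random.default_rng(3)
        alpha = rng.normal(0, 0.5, 8)
        alpha[0] = 0.0
        psi = rng.uniform(0.7, 1.4, 8)
        psi[0] = 1.0
        conf = noise_free_configural(alpha, psi)
        sol = align(conf)
        assert np.allclose(sol.factor_means, alpha, atol=1e-5)
        assert np.allclose(sol.factor_vars, psi, atol=1e-5)

    def test_two_identical_groups(self):
        conf = noise_free_configural(np.zeros(2), np.ones(2), n=200)
        sol = align(conf)
        assert sol.factor_means[1] == pytest.approx(0.0, abs=1e-6)
        assert sol.factor_vars[1] == pytest.approx(1.0, abs=1e-6)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(4)
        alpha = np.r_[0.0, rng.normal(0, 0.5, 4)]
        psi = np.r_[1.0, rng.uniform(0.8, 1.3, 4)]
        conf = noise_free_configural(alpha, psi, n=500)
        perm = [2, 0, 4, 1, 3]
        conf_perm = MultiGroupFit(
            level="configural", items=conf.items,
            groups=[conf.groups[p] for p in perm], loglik=0.0,
            n_params=conf.n_params, converged=True,
        )
        sol = align(conf, reference="G00")
        sol_p = align(conf_perm, reference="G00")
        by_label = dict(zip(sol_p.group_labels, sol_p.factor_means))
        for lbl, a in zip(sol.group_labels, sol.factor_means):
            assert by_label[lbl] == pytest.approx(a, abs=1e-5)

    def test_loss_at_optimum_not_worse_than_identity(self, fitted_small):
        conf, sol, _ = fitted_small
        G = len(conf.groups)
        identity = total_loss(conf, np.zeros(G), np.ones(G), sol.epsilon)
        assert sol.total_loss <= identity + 1e-8

    def test_reference_pinned(self, fitted_small):
        _, sol, _ = fitted_small
        ref = sol.group_labels.index(sol.reference)
        assert sol.factor_means[ref] == 0.0
        assert sol.factor_vars[ref] == pytest.approx(1.0)

    def test_transform_preserves_response_probabilities(self, fitted_small):
        conf, sol, _ = fitted_small
        eta_star = np.linspace(-3, 3, 41)
        for g in range(len(conf.groups)):
            p_conf = norm.cdf(
                conf.loading_matrix()[:, [g]] * eta_star[None, :]
                - conf.threshold_matrix()[:, [g]]
            )
            eta = sol.factor_means[g] + np.sqrt(sol.factor_vars[g]) * eta_star
            p_aligned = norm.cdf(
                sol.loadings[:, [g]] * eta[None, :] - sol.thresholds[:, [g]]
            )
            assert np.max(np.abs(p_conf - p_aligned)) < 1e-8

    def test_factor_mean_recovery_from_data(self, fitted_small):
        conf, sol, truth = fitted_small
        r = np.corrcoef(truth.factor_means, sol.factor_means)[0, 1]
        assert r > 0.98


class TestFlagging:
    def test_two_groups_with_overlapping_cis_unflagged(self):
        conf = noise_free_configural(np.zeros(2), np.ones(2), n=200)
        sol = flag_invariance(align(conf), conf, alpha_level=0.01)
        assert sol.n_flagged_loadings == 0 and sol.n_flagged_thresholds == 0

    def test_invariant_data_flag_rate_near_alpha(self):
        spec = invariance_benchmark_spec(G=10, n_g=1000, seed=23)
        table, _ = generate(spec)
        conf = fit_multigroup(table, "configural", compute_se=True)
        sol = flag_invariance(align(conf), conf, alpha_level=0.01)
        assert sol.pct_all < 10.0  # well below the 25% trustworthiness limit

    def test_injected_threshold_shift_flagged(self):
        spec = invariance_benchmark_spec(G=6, n_g=2000, seed=31)
        spec = inject_noninvariance(spec, [2], [3], threshold_delta=1.0)
        table, truth = generate(spec)
        conf = fit_multigroup(table, "configural", compute_se=True)
        sol = flag_invariance(align(conf), conf, alpha_level=0.01)
        assert sol.threshold_flags[2, 3]

    def test_detection_precision_and_recall(self):
        # pooled over seeded runs; 16 of 112 cells perturbed (14%)
        tau_cells = [(0, 1), (1, 2), (2, 3), (3, 4), (4, 5), (5, 6), (6, 7), (0, 4), (3, 6)]
        lam_cells = [(1, 1), (2, 5), (4, 2), (5, 3), (6, 4), (0, 6), (3, 7)]
        TP = FP = FN = 0
        for seed in range(300, 310):
            spec = invariance_benchmark_spec(G=8, n_g=2000, seed=seed)
            for k, (j, g) in enumerate(tau_cells):
                spec = inject_noninvariance(
                    spec, [j], [g], threshold_delta=0.8 if k % 2 else -0.8
                )
            for k, (j, g) in enumerate(lam_cells):
                spec = inject_noninvariance(
                    spec, [j], [g], loading_delta=0.6 if k % 2 else -0.35
                )
            table, truth = generate(spec)
            conf = fit_multigroup(table, "configural", compute_se=True)
            sol = flag_invariance(align(conf), conf, alpha_level=0.01)
            ft = {(int(j), int(g)) for j, g in zip(*np.nonzero(sol.threshold_flags))}
            fl = {(int(j), int(g)) for j, g in zip(*np.nonzero(sol.loading_flags))}
            TP += len(ft & truth.noninvariant_thresholds) + len(
                fl & truth.noninvariant_loadings
            )
            FP += len(ft - truth.noninvariant_thresholds) + len(
                fl - truth.noninvariant_loadings
            )
            FN += len(truth.noninvariant_thresholds - ft) + len(
                truth.noninvariant_loadings - fl
            )
        assert TP / (TP + FP) >= 0.8
        assert TP / (TP + FN) >= 0.8


class TestPctNoninvariant:
    def test_controlling_behaviour_counts(self):
        assert pct_noninvariant((21, 3), 5, 36) == (11.7, 1.7, 6.7)

    def test_physical_threshold_count(self):
        assert pct_noninvariant((55, 0), 7, 36)[0] == 21.8

    def test_zero_counts(self):
        assert pct_noninvariant((0, 0), 4, 10) == (0.0, 0.0, 0.0)

    def test_counts_exceeding_cells_rejected(self):
        with pytest.raises(ValueError):
            pct_noninvariant((200, 0), 5, 36)

    def test_exact_rational_rounding(self):
        # 1/3 of cells -> 33.3, not a float artifact
        assert pct_noninvariant((12, 0), 6, 6)[0] == 33.3


class TestInvarianceR2:
    def test_perfectly_invariant_r2_one(self):
        rng = np.random.default_rng(6)
        alpha = np.r_[0.0, rng.normal(0, 0.6, 7)]
        psi = np.r_[1.0, rng.uniform(0.7, 1.4, 7)]
        conf = noise_free_configural(alpha, psi)
        sol = flag_invariance(align(conf), conf, alpha_level=0.01)
        r2 = invariance_r2(sol)
        assert np.all(r2["r2_loading"] > 0.999)
        assert np.all(r2["r2_threshold"] > 0.999)

    def test_noise_only_variation_r2_low(self):
        rng = np.random.default_rng(7)
        G, J = 10, 7
        conf = noise_free_configural(np.zeros(G), np.ones(G), J=J)
        for g, gp in enumerate(conf.groups):
            gp.loadings = gp.loadings + rng.normal(0, 0.08, J)
            gp.thresholds = gp.thresholds + rng.normal(0, 0.08, J)
            gp.cov = np.eye(2 * J) * 0.08**2
        sol = flag_invariance(align(conf), conf, alpha_level=0.01)
        r2 = invariance_r2(sol)
        assert np.nanmean(r2.to_numpy()) < 0.4

    def test_bounds(self, fitted_small):
        conf, sol, _ = fitted_small
        sol = flag_invariance(sol, conf, alpha_level=0.01)
        r2 = invariance_r2(sol).to_numpy()
        ok = np.isnan(r2) | ((r2 >= 0.0) & (r2 <= 1.0))
        assert ok.all()


class TestMonteCarlo:
    def test_deterministic_given_seed(self, fitted_small):
        conf, sol, _ = fitted_small
        a = monte_carlo_quality(sol, replications=2, n_g=300, seed=9)
        b = monte_carlo_quality(sol, replications=2, n_g=300, seed=9)
        assert a.correlations == b.correlations

    def test_degenerate_equal_means_undefined(self):
        conf = noise_free_configural(np.zeros(4), np.ones(4), n=400)
        sol = align(conf)
        rep = monte_carlo_quality(sol, replications=1, n_g=400, seed=2)
        assert np.isnan(rep.mean_correlation)

    def test_requires_replications(self, fitted_small):
        _, sol, _ = fitted_small
        with pytest.raises(ValueError):
            monte_carlo_quality(sol, replications=0, n_g=100, seed=1)
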