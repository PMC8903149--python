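"""Group-specific one-factor analysis for dichotomous items.

Estimation is limited-information in two stages, the standard route for
binary factor analysis:

1. univariate probit thresholds ``tau_j = Phi^{-1}(1 - p_j)`` from weighted
   endorsement shares;
2. pairwise tetrachoric correlations by two-stage maximum likelihood
   (thresholds fixed, bivariate-normal likelihood maximized over rho, with
   pairwise deletion for missing data and a 0.5 continuity correction when a
   2x2 cell is empty);
3. unweighted least squares on the tetrachoric matrix for the one-factor
   structure ``R = lambda lambda' + diag(1 - lambda^2)``, with a mean-scaled
   chi-square: the ULS discrepancy is rescaled by the trace of the residual
   projection against the asymptotic variances of the tetrachoric estimates,
   so that the statistic has the right expectation under the model.

Fit indices (RMSEA, CFI, TLI) use the independence model (all correlations
zero) as baseline.  Loadings are standardized; the equivalent item-response
slopes ``a_j = lambda_j / sqrt(1 - lambda_j^2)`` are reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize, minimize_scalar
from scipy.special import owens_t
from scipy.stats import norm

from .io_survey import ItemResponseTable, PipelineConfig


class DegenerateItemError(ValueError):
    """An item with 0% or 100% endorsement cannot be threshold-scaled."""


@dataclass
class FitResult:
    """One-factor fit for a single group.

    ``loadings`` are standardized (correlation-metric) loadings in (-1, 1);
    ``slopes`` are the equivalent probit item-response discriminations.
    ``chi2`` is the mean-scaled ULS discrepancy statistic with ``df =
    J(J-1)/2 - J``; indices are ``None``-like (NaN) when ``df = 0``.
    """

    group: str
    items: list[str]
    loadings: np.ndarray
    loading_se: np.ndarray
    slopes: np.ndarray
    slope_se: np.ndarray
    thresholds: np.ndarray
    chi2: float
    df: int
    n: int
    rmsea: float
    cfi: float
    tli: float
    baseline_chi2: float
    baseline_df: int
    converged: bool
    heywood: bool = False

    @property
    def min_loading(self) -> float:
        return float(np.min(np.abs(self.loadings)))


@dataclass
class AdequacyDecision:
    """Benchmark screen on a converged fit; pass iff every criterion holds."""

    group: str
    passed: bool
    loading_ok: bool
    rmsea_ok: bool
    cfi_ok: bool
    tli_ok: bool
    reason: str = ""


# -- bivariate normal orthant probability --------------------------------------


def _phi2(h: float, k: float, rho: float) -> float:
    """P(X <= h, Y <= k) for standard bivariate normal via Owen's T."""
    rho = float(np.clip(rho, -0.999999, 0.999999))
    # nudge exact zeros so the Owen's T arguments stay finite
    if h == 0.0:
        h = 1e-12
    if k == 0.0:
        k = 1e-12
    denom = np.sqrt(1.0 - rho * rho)
    a_h = (k - rho * h) / (h * denom)
    a_k = (h - rho * k) / (k * denom)
    beta = 0.5 if h * k < 0 else 0.0
    return float(
        0.5 * (norm.cdf(h) + norm.cdf(k)) - owens_t(h, a_h) - owens_t(k, a_k) - beta
    )


def _orthant_11(t1: float, t2: float, rho: float) -> float:
    """P(Y1* > t1, Y2* > t2) = probability of the (1, 1) cell."""
    return 1.0 - norm.cdf(t1) - norm.cdf(t2) + _phi2(t1, t2, rho)


def _cell_probs(t1: float, t2: float, rho: float) -> np.ndarray:
    p11 = _orthant_11(t1, t2, rho)
    p1 = 1.0 - norm.cdf(t1)
    p2 = 1.0 - norm.cdf(t2)
    p10 = p1 - p11
    p01 = p2 - p11
    p00 = 1.0 - p11 - p10 - p01
    return np.clip(np.array([p11, p10, p01, p00]), 1e-12, 1.0)


def tetrachoric_from_counts(
    n11: float, n10: float, n01: float, n00: float
) -> tuple[float, float]:
    """Two-stage tetrachoric correlation and SE from a 2x2 table.

    Thresholds are fixed at the univariate margins; the multinomial likelihood
    of the four cells is maximized over rho.  An empty cell triggers a 0.5
    continuity correction on all cells.  The SE comes from the curvature of
    the profile log-likelihood at the optimum (thresholds treated as fixed).
    """
    counts = np.array([n11, n10, n01, n00], dtype=float)
    if np.any(counts < 0):
        raise ValueError("negative cell counts")
    if counts.sum() <= 0:
        raise ValueError("empty 2x2 table")
    if np.any(counts == 0):
        counts = counts + 0.5
    n = counts.sum()
    p1 = (counts[0] + counts[1]) / n
    p2 = (counts[0] + counts[2]) / n
    if not (0 < p1 < 1 and 0 < p2 < 1):
        raise DegenerateItemError("degenerate margin in 2x2 table")
    t1 = float(norm.ppf(1.0 - p1))
    t2 = float(norm.ppf(1.0 - p2))

    def nll(rho: float) -> float:
        return -float(np.dot(counts, np.log(_cell_probs(t1, t2, rho))))

    res = minimize_scalar(nll, bounds=(-0.999, 0.999), method="bounded",
                          options={"xatol": 1e-10})
    if not res.success:
        raise RuntimeError(f"tetrachoric optimization failed on cells {counts.tolist()}")
    rho = float(res.x)
    h = 1e-4
    d2 = (nll(min(rho + h, 0.9995)) - 2.0 * nll(rho) + nll(max(rho - h, -0.9995))) / h**2
    se = float(1.0 / np.sqrt(d2)) if d2 > 0 else float("nan")
    return rho, se


def _pair_counts(
    y_i: np.ndarray, y_j: np.ndarray, w: np.ndarray
) -> tuple[float, float, float, float]:
    obs = ~np.isnan(y_i) & ~np.isnan(y_j)
    yi, yj, ww = y_i[obs], y_j[obs], w[obs]
    n11 = float(ww[(yi == 1) & (yj == 1)].sum())
    n10 = float(ww[(yi == 1) & (yj == 0)].sum())
    n01 = float(ww[(yi == 0) & (yj == 1)].sum())
    n00 = float(ww[(yi == 0) & (yj == 0)].sum())
    return n11, n10, n01, n00


def tetrachoric(
    table: ItemResponseTable, item_i: str, item_j: str, group: str | None = None
) -> tuple[float, float]:
    """Tetrachoric correlation between two items (weighted, pairwise deletion)."""
    df = table.data if group is None else table.group_data(group)
    y_i = df[item_i].to_numpy(dtype=float)
    y_j = df[item_j].to_numpy(dtype=float)
    w = df["weight"].to_numpy(dtype=float)
    return tetrachoric_from_counts(*_pair_counts(y_i, y_j, w))


def estimate_thresholds(table: ItemResponseTable, group: str) -> np.ndarray:
    """Weighted univariate probit thresholds ``Phi^{-1}(1 - p_hat_j)``."""
    df = table.group_data(group)
    w = df["weight"].to_numpy(dtype=float)
    taus = np.empty(len(table.items))
    for j, item in enumerate(table.items):
        y = df[item].to_numpy(dtype=float)
        obs = ~np.isnan(y)
        if not obs.any():
            raise DegenerateItemError(f"item {item!r} entirely missing in group {group!r}")
        p = float(np.sum(w[obs] * y[obs]) / np.sum(w[obs]))
        if p <= 0.0 or p >= 1.0:
            raise DegenerateItemError(
                f"item {item!r} has degenerate prevalence {p:.3f} in group {group!r}"
            )
        taus[j] = norm.ppf(1.0 - p)
    return taus


def tetrachoric_matrix(
    table: ItemResponseTable, group: str
) -> tuple[np.ndarray, np.ndarray]:
    """Full tetrachoric matrix and matching matrix of squared SEs."""
    df = table.group_data(group)
    J = len(table.items)
    R = np.eye(J)
    V = np.zeros((J, J))
    w = df["weight"].to_numpy(dtype=float)
    Y = df[table.items].to_numpy(dtype=float)
    for i in range(J):
        for j in range(i + 1, J):
            rho, se = tetrachoric_from_counts(*_pair_counts(Y[:, i], Y[:, j], w))
            R[i, j] = R[j, i] = rho
            V[i, j] = V[j, i] = se**2
    return R, V


# -- one-factor ULS fit --------------------------------------------------------


def _vecl(M: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(M.shape[0], k=1)
    return M[iu]


def _delta_matrix(lam: np.ndarray) -> np.ndarray:
    """Jacobian of the model-implied correlations w.r.t. the loadings."""
    J = lam.size
    pairs = [(i, j) for i in range(J) for j in range(i + 1, J)]
    D = np.zeros((len(pairs), J))
    for p, (i, j) in enumerate(pairs):
        D[p, i] = lam[j]
        D[p, j] = lam[i]
    return D


def fit_one_factor_from_corr(
    R: np.ndarray,
    n: int,
    rho_var: np.ndarray | None = None,
    items: list[str] | None = None,
    group: str = "",
    thresholds: np.ndarray | None = None,
) -> FitResult:
    """ULS one-factor fit to a correlation matrix with mean-scaled chi-square.

    ``rho_var`` holds the squared SEs of the off-diagonal estimates (matrix
    form); when absent the generic Pearson approximation ``(1 - r^2)^2 / n``
    is used for the scaling weights.
    """
    R = np.asarray(R, dtype=float)
    J = R.shape[0]
    if J < 3:
        raise ValueError("one-factor model needs at least 3 items")
    r = _vecl(R)
    P = r.size
    df = P - J

    def objective(lam: np.ndarray) -> float:
        resid = r - _vecl(np.outer(lam, lam))
        return float(np.dot(resid, resid))

    def grad(lam: np.ndarray) -> np.ndarray:
        E = R - np.outer(lam, lam)
        np.fill_diagonal(E, 0.0)
        return -2.0 * E @ lam

    # first principal component of R as start
    evals, evecs = np.linalg.eigh(R)
    v = evecs[:, -1] * np.sqrt(max(evals[-1], 0.1))
    if v.sum() < 0:
        v = -v
    start = np.clip(v, -0.9, 0.9)
    res = minimize(objective, start, jac=grad, method="L-BFGS-B",
                   bounds=[(-0.999, 0.999)] * J, options={"ftol": 1e-14, "gtol": 1e-10})
    lam = res.x
    if lam.sum() < 0:  # reflection indeterminacy: fix the factor's sign
        lam = -lam
    heywood = bool(np.any(np.abs(lam) >= 0.995))
    converged = bool(res.success) and not heywood
    F_hat = objective(lam)

    if rho_var is None:
        gamma_diag = (1.0 - r**2) ** 2  # n * Var(r_hat), Pearson-style default
    else:
        gamma_diag = n * _vecl(np.asarray(rho_var, dtype=float))
    gamma_diag = np.maximum(gamma_diag, 1e-10)

    D = _delta_matrix(lam)
    DtD_inv = np.linalg.pinv(D.T @ D)
    H = D @ DtD_inv @ D.T  # projection onto the model tangent space
    U = np.eye(P) - H
    tr_ug = float(np.sum(np.diag(U) * gamma_diag))
    chi2 = n * F_hat * df / tr_ug if df > 0 and tr_ug > 0 else 0.0

    # baseline (independence) model: all correlations zero, nothing estimated
    F_base = float(np.dot(r, r))
    baseline_df = P
    tr_g = float(np.sum(gamma_diag))
    baseline_chi2 = n * F_base * baseline_df / tr_g if tr_g > 0 else 0.0

    rmsea, cfi, tli = fit_indices(chi2, df, n, baseline_chi2, baseline_df)

    # delta-method SEs: lam_hat is (approximately) a smooth map of r_hat
    A = DtD_inv @ D.T
    cov_lam = A @ np.diag(gamma_diag / n) @ A.T
    loading_se = np.sqrt(np.maximum(np.diag(cov_lam), 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        slopes = lam / np.sqrt(1.0 - lam**2)
        slope_se = loading_se * (1.0 - lam**2) ** (-1.5)

    return FitResult(
        group=group,
        items=list(items) if items is not None else [f"item{j}" for j in range(J)],
        loadings=lam,
        loading_se=loading_se,
        slopes=slopes,
        slope_se=slope_se,
        thresholds=thresholds if thresholds is not None else np.full(J, np.nan),
        chi2=float(chi2),
        df=int(df),
        n=int(n),
        rmsea=rmsea,
        cfi=cfi,
        tli=tli,
        baseline_chi2=float(baseline_chi2),
        baseline_df=int(baseline_df),
        converged=converged,
        heywood=heywood,
    )


def fit_one_factor(
    table: ItemResponseTable, group: str, weighting: str = "uls"
) -> FitResult:
    """Group-specific one-factor fit on estimated tetrachoric correlations."""
    if weighting not in ("uls", "dwls"):
        raise ValueError("weighting must be 'uls' or 'dwls'")
    thresholds = estimate_thresholds(table, group)
    R, V = tetrachoric_matrix(table, group)
    n = len(table.group_data(group))
    return fit_one_factor_from_corr(
        R, n, rho_var=V, items=table.items, group=group, thresholds=thresholds
    )


def fit_indices(
    chi2: float, df: int, n: int, baseline_chi2: float, baseline_df: int
) -> tuple[float, float, float]:
    """RMSEA, CFI and TLI from fitted and baseline discrepancy statistics.

    With ``df = 0`` the model is saturated and all three are undefined (NaN).
    """
    if df < 0 or n <= 1:
        raise ValueError("need df >= 0 and n > 1")
    if df == 0:
        return float("nan"), float("nan"), float("nan")
    rmsea = float(np.sqrt(max(0.0, (chi2 - df) / (df * (n - 1)))))
    num = max(0.0, chi2 - df)
    den = max(chi2 - df, baseline_chi2 - baseline_df, 0.0)
    cfi = 1.0 if den == 0.0 else float(1.0 - num / den)
    if baseline_df <= 0 or baseline_chi2 / baseline_df == 1.0:
        tli = float("nan")
    else:
        tli = float(
            ((baseline_chi2 / baseline_df) - (chi2 / df))
            / ((baseline_chi2 / baseline_df) - 1.0)
        )
    return rmsea, cfi, tli


def adequacy_gate(fit: FitResult, config: PipelineConfig | None = None) -> AdequacyDecision:
    """Benchmark screen: minimum loading and RMSEA/CFI/TLI thresholds.

    Undefined indices (saturated model) vacuously satisfy their criteria; a
    non-converged fit fails outright.
    """
    config = config or PipelineConfig()
    if not fit.converged:
        return AdequacyDecision(
            group=fit.group, passed=False, loading_ok=False, rmsea_ok=False,
            cfi_ok=False, tli_ok=False,
            reason="non-converged fit" + (" (Heywood case)" if fit.heywood else ""),
        )
    loading_ok = bool(np.min(fit.loadings) >= config.min_loading)
    rmsea_ok = bool(np.isnan(fit.rmsea) or fit.rmsea <= config.max_rmsea)
    cfi_ok = bool(np.isnan(fit.cfi) or fit.cfi >= config.min_cfi)
    tli_ok = bool(np.isnan(fit.tli) or fit.tli >= config.min_tli)
    passed = loading_ok and rmsea_ok and cfi_ok and tli_ok
    failed = [
        name
        for name, ok in [
            ("loading", loading_ok), ("RMSEA", rmsea_ok), ("CFI", cfi_ok), ("TLI", tli_ok)
        ]
        if not ok
    ]
    return AdequacyDecision(
        group=fit.group, passed=passed, loading_ok=loading_ok, rmsea_ok=rmsea_ok,
        cfi_ok=cfi_ok, tli_ok=tli_ok,
        reason="" if passed else "failed: " + ", ".join(failed),
    )
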