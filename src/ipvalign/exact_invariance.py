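"""Exact measurement invariance: multiple-group factor models for binary items.

The measurement model is a unidimensional two-parameter item-response model.
With latent trait ``eta ~ Normal(alpha_g, psi_g)`` in group g,

    P(y_j = 1 | eta) = F(lambda_jg * eta - tau_jg)

where F is the probit (default) or logistic link.  The marginal likelihood
integrates over the trait with Gauss-Hermite quadrature (21 nodes default);
respondents are collapsed to unique response patterns per group, missing
items simply drop out of the pattern likelihood (missing-at-random), and
sampling weights multiply log-likelihood contributions (pseudo-ML).

Invariance levels and their identification:

- configural: all ``lambda_jg``, ``tau_jg`` free; ``alpha_g = 0``,
  ``psi_g = 1`` in every group (the model separates into per-group fits);
- metric: ``lambda_j`` shared; thresholds free; ``alpha_g = 0`` everywhere,
  ``psi_g`` free except the reference group (fixed at 1);
- scalar: ``lambda_j`` and ``tau_j`` shared; ``alpha_g`` and ``psi_g`` free
  except the reference group (fixed at 0 and 1).

Each level is nested in the one before, so log-likelihoods are ordered and
likelihood-ratio tests apply, with degrees of freedom equal to the
parameter-count difference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import log_expit, log_ndtr, expit
from scipy.stats import chi2 as chi2_dist
from scipy.stats import norm

from .binary_factor import fit_one_factor
from .io_survey import ItemResponseTable, PipelineConfig

LEVELS = ("configural", "metric", "scalar")

_BOUND_LAM = (1e-3, 15.0)
_BOUND_TAU = (-10.0, 10.0)
_BOUND_ALPHA = (-5.0, 5.0)
_BOUND_LOGPSI = (np.log(0.05), np.log(20.0))


class FitError(RuntimeError):
    """Multi-group fit failed to converge after restarts."""


@dataclass
class GroupParams:
    """Measurement and structural parameters of one group."""

    label: str
    loadings: np.ndarray
    thresholds: np.ndarray
    factor_mean: float = 0.0
    factor_var: float = 1.0
    loading_se: np.ndarray | None = None
    threshold_se: np.ndarray | None = None
    cov: np.ndarray | None = None  # covariance of (loadings, thresholds)
    n: int = 0


@dataclass
class MultiGroupFit:
    """One fitted invariance level across groups."""

    level: str
    items: list[str]
    groups: list[GroupParams]
    loglik: float
    n_params: int
    converged: bool
    link: str = "probit"
    n_quad: int = 21

    @property
    def group_labels(self) -> list[str]:
        return [g.label for g in self.groups]

    @property
    def n_per_group(self) -> np.ndarray:
        return np.array([g.n for g in self.groups])

    def loading_matrix(self) -> np.ndarray:
        """(J, G) loadings."""
        return np.column_stack([g.loadings for g in self.groups])

    def threshold_matrix(self) -> np.ndarray:
        return np.column_stack([g.thresholds for g in self.groups])


@dataclass
class LRTestResult:
    """Chi-square difference test between nested invariance levels."""

    comparison: str
    chi2: float
    df: int
    p_value: float


# -- pattern collapsing and likelihood kernels ---------------------------------


class _GroupData:
    """Unique response patterns with summed weights for one group."""

    def __init__(self, Y: np.ndarray, w: np.ndarray, label: str):
        enc = np.where(np.isnan(Y), 2, Y).astype(np.int8)
        uniq, inv = np.unique(enc, axis=0, return_inverse=True)
        self.label = label
        self.n = len(w)
        self.c = np.bincount(inv, weights=w, minlength=len(uniq))
        self.c2 = np.bincount(inv, weights=w**2, minlength=len(uniq))
        self.Y1 = (uniq == 1).astype(float)  # (L, J)
        self.Y0 = (uniq == 0).astype(float)


def _gh_nodes(n_quad: int) -> tuple[np.ndarray, np.ndarray]:
    """Gauss-Hermite nodes/weights rescaled for a standard normal density."""
    x, w = np.polynomial.hermite.hermgauss(n_quad)
    return x * np.sqrt(2.0), w / np.sqrt(np.pi)


def _link_terms(z: np.ndarray, link: str):
    """log P, log(1-P) and the score factors dlogP/dz, dlog(1-P)/dz."""
    if link == "probit":
        logp = log_ndtr(z)
        log1mp = log_ndtr(-z)
        logphi = -0.5 * z**2 - 0.5 * np.log(2.0 * np.pi)
        g1 = np.exp(logphi - logp)
        g0 = -np.exp(logphi - log1mp)
    else:  # logit
        logp = log_expit(z)
        log1mp = log_expit(-z)
        p = expit(z)
        g1 = 1.0 - p
        g0 = -p
    return logp, log1mp, g1, g0


def _group_ll(
    gdata: _GroupData,
    lam: np.ndarray,
    tau: np.ndarray,
    alpha: float,
    psi: float,
    link: str,
    xi: np.ndarray,
    wq: np.ndarray,
    want_grad: bool = True,
    want_scores: bool = False,
):
    """Weighted log-likelihood of one group, with analytic gradients.

    Returns ``(ll, d_lam, d_tau, d_alpha, d_logpsi, scores)``; gradient parts
    are ``None`` when not requested.  ``scores`` are per-pattern score vectors
    w.r.t. (lam, tau) used for sandwich standard errors.
    """
    s = np.sqrt(psi)
    eta = alpha + s * xi  # (Q,)
    z = lam[:, None] * eta[None, :] - tau[:, None]  # (J, Q)
    logp, log1mp, g1, g0 = _link_terms(z, link)
    A = gdata.Y1 @ logp + gdata.Y0 @ log1mp  # (L, Q)
    B = A + np.log(wq)[None, :]
    Bmax = B.max(axis=1, keepdims=True)
    logP = (Bmax + np.log(np.exp(B - Bmax).sum(axis=1, keepdims=True)))[:, 0]  # (L,)
    ll = float(np.dot(gdata.c, logP))
    if not (want_grad or want_scores):
        return ll, None, None, None, None, None
    r = np.exp(B - logP[:, None])  # (L, Q), rows sum to 1
    cr = gdata.c[:, None] * r
    T = g1 * (gdata.Y1.T @ cr) + g0 * (gdata.Y0.T @ cr)  # (J, Q)
    d_lam = T @ eta
    d_tau = -T.sum(axis=1)
    d_alpha = float(np.sum((T.sum(axis=1)) * lam))
    d_logpsi = float(np.sum((T @ (xi * s / 2.0)) * lam))
    scores = None
    if want_scores:
        # per-pattern scores w.r.t. (lam, tau): (L, 2J)
        S = (
            gdata.Y1[:, :, None] * g1[None, :, :] + gdata.Y0[:, :, None] * g0[None, :, :]
        )  # (L, J, Q)
        RS = S * r[:, None, :]
        sc_lam = RS @ eta
        sc_tau = -RS.sum(axis=2)
        scores = np.concatenate([sc_lam, sc_tau], axis=1)
    return ll, d_lam, d_tau, d_alpha, d_logpsi, scores


# -- parameter packing per invariance level ------------------------------------


def _n_params(level: str, J: int, G: int) -> int:
    if level == "configural":
        return 2 * J * G
    if level == "metric":
        return J + J * G + (G - 1)
    if level == "scalar":
        return 2 * J + 2 * (G - 1)
    raise ValueError(f"unknown level {level!r}")


def _unpack(theta: np.ndarray, level: str, J: int, G: int):
    """Yield (lam_g, tau_g, alpha_g, psi_g) per group from the flat vector."""
    out = []
    if level == "configural":
        for g in range(G):
            seg = theta[2 * J * g : 2 * J * (g + 1)]
            out.append((seg[:J], seg[J:], 0.0, 1.0))
    elif level == "metric":
        lam = theta[:J]
        taus = theta[J : J + J * G].reshape(G, J)
        logpsi = theta[J + J * G :]
        for g in range(G):
            psi = 1.0 if g == 0 else float(np.exp(logpsi[g - 1]))
            out.append((lam, taus[g], 0.0, psi))
    else:  # scalar
        lam, tau = theta[:J], theta[J : 2 * J]
        alpha = theta[2 * J : 2 * J + (G - 1)]
        logpsi = theta[2 * J + (G - 1) :]
        for g in range(G):
            a = 0.0 if g == 0 else float(alpha[g - 1])
            psi = 1.0 if g == 0 else float(np.exp(logpsi[g - 1]))
            out.append((lam, tau, a, psi))
    return out


def _nll_grad(theta, level, J, G, gdatas, link, xi, wq):
    parts = _unpack(theta, level, J, G)
    ll = 0.0
    grad = np.zeros_like(theta)
    for g, (gd, (lam, tau, alpha, psi)) in enumerate(zip(gdatas, parts)):
        l, d_lam, d_tau, d_alpha, d_logpsi, _ = _group_ll(
            gd, lam, tau, alpha, psi, link, xi, wq
        )
        ll += l
        if level == "configural":
            grad[2 * J * g : 2 * J * g + J] += d_lam
            grad[2 * J * g + J : 2 * J * (g + 1)] += d_tau
        elif level == "metric":
            grad[:J] += d_lam
            grad[J + J * g : J + J * (g + 1)] += d_tau
            if g > 0:
                grad[J + J * G + (g - 1)] += d_logpsi
        else:
            grad[:J] += d_lam
            grad[J : 2 * J] += d_tau
            if g > 0:
                grad[2 * J + (g - 1)] += d_alpha
                grad[2 * J + (G - 1) + (g - 1)] += d_logpsi
    return -ll, -grad


def _bounds(level: str, J: int, G: int):
    if level == "configural":
        return ([_BOUND_LAM] * J + [_BOUND_TAU] * J) * G
    if level == "metric":
        return [_BOUND_LAM] * J + [_BOUND_TAU] * (J * G) + [_BOUND_LOGPSI] * (G - 1)
    return (
        [_BOUND_LAM] * J + [_BOUND_TAU] * J + [_BOUND_ALPHA] * (G - 1)
        + [_BOUND_LOGPSI] * (G - 1)
    )


def _limited_info_start(table: ItemResponseTable, group: str, J: int) -> np.ndarray:
    """Configural start from the limited-information (tetrachoric) fit."""
    try:
        fr = fit_one_factor(table, group)
        lam = np.clip(np.abs(fr.slopes), 0.1, 5.0)
        tau = np.clip(fr.thresholds * np.sqrt(lam**2 + 1.0), -6.0, 6.0)
        if np.all(np.isfinite(lam)) and np.all(np.isfinite(tau)):
            return np.concatenate([lam, tau])
    except Exception:
        pass
    return np.concatenate([np.ones(J), np.zeros(J)])


def _minimize(theta0, level, J, G, gdatas, link, xi, wq, bounds):
    best = None
    starts = [theta0]
    # documented restarts: neutral start, then a damped version of it
    neutral = theta0.copy()
    if level == "configural":
        neutral = np.tile(np.concatenate([np.ones(J), np.zeros(J)]), G)
    starts.append(neutral)
    starts.append(0.5 * (theta0 + neutral))
    for s in starts:
        res = minimize(
            _nll_grad, s, args=(level, J, G, gdatas, link, xi, wq), jac=True,
            method="L-BFGS-B", bounds=bounds,
            options={"maxiter": 2000, "ftol": 1e-11, "gtol": 1e-7},
        )
        if best is None or res.fun < best.fun:
            best = res
        if res.success:
            return res, True
    return best, bool(best.success)


def _numerical_hessian(fun_grad, theta, args, h=1e-5):
    """Central finite differences of the analytic gradient."""
    k = theta.size
    H = np.zeros((k, k))
    for i in range(k):
        tp = theta.copy(); tp[i] += h
        tm = theta.copy(); tm[i] -= h
        _, gp = fun_grad(tp, *args)
        _, gm = fun_grad(tm, *args)
        H[i] = (gp - gm) / (2.0 * h)
    return 0.5 * (H + H.T)


def _group_sandwich_cov(gd: _GroupData, lam, tau, link, xi, wq) -> np.ndarray:
    """Pseudo-ML sandwich covariance of (lam, tau) for one group."""
    J = lam.size

    def fg(theta, *_):
        l, d_lam, d_tau, _, _, _ = _group_ll(
            gd, theta[:J], theta[J:], 0.0, 1.0, link, xi, wq
        )
        return -l, -np.concatenate([d_lam, d_tau])

    theta = np.concatenate([lam, tau])
    A = _numerical_hessian(fg, theta, ())
    _, _, _, _, _, scores = _group_ll(
        gd, lam, tau, 0.0, 1.0, link, xi, wq, want_grad=False, want_scores=True
    )
    B = (scores * gd.c2[:, None]).T @ scores
    A_inv = np.linalg.pinv(A)
    return A_inv @ B @ A_inv


# -- public API ----------------------------------------------------------------


def _prepare_groups(table: ItemResponseTable) -> list[_GroupData]:
    gdatas = []
    for g in table.groups:
        sub = table.group_data(g)
        Y = sub[table.items].to_numpy(dtype=float)
        w = sub["weight"].to_numpy(dtype=float)
        present = ~np.isnan(Y)
        for j, item in enumerate(table.items):
            vals = Y[present[:, j], j]
            if vals.size == 0 or vals.min() == vals.max():
                raise FitError(f"item {item!r} degenerate in group {g!r}")
        gdatas.append(_GroupData(Y, w, g))
    return gdatas


def fit_multigroup(
    table: ItemResponseTable,
    level: str,
    config: PipelineConfig | None = None,
    compute_se: bool = False,
    warm_start: "MultiGroupFit | None" = None,
) -> MultiGroupFit:
    """Fit one invariance level by marginal maximum likelihood.

    ``compute_se`` adds per-group sandwich covariances of (loadings,
    thresholds) for the configural level, or a naive inverse-Hessian
    covariance for constrained levels; the configural covariances feed the
    alignment flagging step downstream.
    """
    if level not in LEVELS:
        raise ValueError(f"level must be one of {LEVELS}")
    config = config or PipelineConfig()
    if level != "configural":
        table.require_multigroup()
    gdatas = _prepare_groups(table)
    J, G = len(table.items), len(gdatas)
    xi, wq = _gh_nodes(int(config.quadrature_points))
    link = config.link

    if level == "configural":
        # separates into independent per-group fits
        groups: list[GroupParams] = []
        total_ll = 0.0
        all_ok = True
        for gi, (glabel, gd) in enumerate(zip(table.groups, gdatas)):
            if warm_start is not None and warm_start.level == "configural":
                wsg = warm_start.groups[gi]
                theta0 = np.concatenate([wsg.loadings, wsg.thresholds])
            else:
                theta0 = _limited_info_start(table, glabel, J)
            res, ok = _minimize(
                theta0, "configural", J, 1, [gd], link, xi, wq, _bounds("configural", J, 1)
            )
            all_ok &= ok
            lam, tau = res.x[:J], res.x[J:]
            gp = GroupParams(label=glabel, loadings=lam, thresholds=tau, n=gd.n)
            if compute_se:
                cov = _group_sandwich_cov(gd, lam, tau, link, xi, wq)
                gp.cov = cov
                se = np.sqrt(np.maximum(np.diag(cov), 0.0))
                gp.loading_se, gp.threshold_se = se[:J], se[J:]
            groups.append(gp)
            total_ll += -res.fun
        return MultiGroupFit(
            level="configural", items=list(table.items), groups=groups,
            loglik=total_ll, n_params=_n_params("configural", J, G),
            converged=all_ok, link=link, n_quad=int(config.quadrature_points),
        )

    # constrained levels: joint fit with warm start from the previous rung
    if warm_start is None:
        warm_start = fit_multigroup(table, "configural", config)
    lam_conf = warm_start.loading_matrix()  # (J, G)
    tau_conf = warm_start.threshold_matrix()
    lam_bar = lam_conf.mean(axis=1)
    if level == "metric":
        psi0 = np.clip((lam_conf / lam_bar[:, None]).mean(axis=0) ** 2, 0.1, 10.0)
        theta0 = np.concatenate([lam_bar, tau_conf.T.ravel(), np.log(psi0[1:])])
    else:
        tau_bar = tau_conf.mean(axis=1)
        alpha0 = np.clip(
            ((tau_conf - tau_bar[:, None]) / lam_bar[:, None]).mean(axis=0), -3.0, 3.0
        )
        psi0 = np.clip((lam_conf / lam_bar[:, None]).mean(axis=0) ** 2, 0.1, 10.0)
        theta0 = np.concatenate([lam_bar, tau_bar, alpha0[1:], np.log(psi0[1:])])
    res, ok = _minimize(theta0, level, J, G, gdatas, link, xi, wq, _bounds(level, J, G))
    parts = _unpack(res.x, level, J, G)

    se_lam = se_tau = None
    if compute_se:
        H = _numerical_hessian(_nll_grad, res.x, (level, J, G, gdatas, link, xi, wq))
        cov = np.linalg.pinv(H)
        se = np.sqrt(np.maximum(np.diag(cov), 0.0))
        se_lam, se_tau = se[:J], (se[J : 2 * J] if level == "scalar" else None)

    groups = []
    for gi, (glabel, gd, (lam, tau, alpha, psi)) in enumerate(
        zip(table.groups, gdatas, parts)
    ):
        groups.append(
            GroupParams(
                label=glabel, loadings=np.array(lam), thresholds=np.array(tau),
                factor_mean=alpha, factor_var=psi, n=gd.n,
                loading_se=se_lam, threshold_se=se_tau,
            )
        )
    return MultiGroupFit(
        level=level, items=list(table.items), groups=groups, loglik=-res.fun,
        n_params=_n_params(level, J, G), converged=ok, link=link,
        n_quad=int(config.quadrature_points),
    )


def multigroup_loglik(
    fit: MultiGroupFit, table: ItemResponseTable, n_quad: int | None = None
) -> float:
    """Recompute the fit's log-likelihood, optionally at a finer quadrature."""
    gdatas = _prepare_groups(table)
    xi, wq = _gh_nodes(n_quad or fit.n_quad)
    ll = 0.0
    for gd, gp in zip(gdatas, fit.groups):
        l, *_ = _group_ll(
            gd, gp.loadings, gp.thresholds, gp.factor_mean, gp.factor_var,
            fit.link, xi, wq, want_grad=False,
        )
        ll += l
    return ll


def lr_test(less_constrained: MultiGroupFit, more_constrained: MultiGroupFit) -> LRTestResult:
    """Likelihood-ratio (chi-square difference) test of nested levels."""
    order = {lvl: i for i, lvl in enumerate(LEVELS)}
    if order[more_constrained.level] <= order[less_constrained.level]:
        raise ValueError(
            f"{more_constrained.level!r} is not nested within {less_constrained.level!r}"
        )
    df = less_constrained.n_params - more_constrained.n_params
    if df < 1:
        raise ValueError("parameter counts do not decrease across the comparison")
    stat = max(0.0, 2.0 * (less_constrained.loglik - more_constrained.loglik))
    p = float(chi2_dist.sf(stat, df)) if stat > 0 else 1.0
    return LRTestResult(
        comparison=f"{more_constrained.level} against {less_constrained.level}",
        chi2=float(stat), df=int(df), p_value=p,
    )


@dataclass
class LadderReport:
    """Sequential invariance testing outcome."""

    fits: dict
    tests: list[LRTestResult]
    highest_level: str
    alpha: float


def invariance_ladder(
    table: ItemResponseTable, config: PipelineConfig | None = None
) -> LadderReport:
    """Fit configural, metric and scalar models sequentially and test.

    The highest level attained is the last rung whose test against the
    previous rung is non-significant at ``config.ladder_alpha`` (configural is
    attained whenever it converges).
    """
    config = config or PipelineConfig()
    table.require_multigroup()
    configural = fit_multigroup(table, "configural", config)
    if not configural.converged:
        raise FitError("configural model did not converge; ladder aborted")
    metric = fit_multigroup(table, "metric", config, warm_start=configural)
    scalar = fit_multigroup(table, "scalar", config, warm_start=configural)
    t_metric = lr_test(configural, metric)
    t_scalar = lr_test(metric, scalar)
    highest = "configural"
    if t_metric.p_value > config.ladder_alpha:
        highest = "metric"
        if t_scalar.p_value > config.ladder_alpha:
            highest = "scalar"
    return LadderReport(
        fits={"configural": configural, "metric": metric, "scalar": scalar},
        tests=[t_metric, t_scalar],
        highest_level=highest,
        alpha=config.ladder_alpha,
    )
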