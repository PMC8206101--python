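"""Mixed-effects logistic regression via the Laplace approximation.

Fits logit(P(y=1)) = X beta + Z b_i with per-group random effects
b_i ~ N(0, diag(sigma^2)) — independent (diagonal) random effects, as in a
``(r1 + r2 + ... || group)`` formula.  Estimation mirrors the structure of
lme4's glmer at nAGQ=1:

* inner loop: for fixed variance parameters, the joint penalized
  log-likelihood in (beta, b) is maximized by Newton's method, using the
  block-arrow structure of the Hessian (one small block per group plus a
  Schur complement for beta);
* outer loop: the Laplace-approximated marginal log-likelihood, profiled
  over (beta, b), is maximized over log random-effect SDs by a
  box-constrained quasi-Newton optimizer (L-BFGS-B, finite-difference
  gradients).

Fixed-effect standard errors come from the Schur complement of the joint
Hessian at the optimum (the usual Wald covariance).  Columns are
standardized internally for optimizer conditioning and results mapped back;
the Laplace objective itself is invariant to that scaling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit, log_expit
from scipy.stats import norm

__all__ = ["MixedLogitFit", "fit_mixed_logit", "ConvergenceError"]

_LOG_SIGMA_MIN, _LOG_SIGMA_MAX = -8.0, 3.0


class ConvergenceError(RuntimeError):
    """Optimization failed; ``diagnostics`` carries the trail."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


@dataclass
class MixedLogitFit:
    """Result of one mixed (or plain, if m=0) logistic fit.

    All quantities are on the original predictor scale.  ``b_hat`` rows are
    the posterior modes of the per-group deviations (the BLUP analogues);
    composite per-group coefficients are ``beta[j] + b_hat[:, j']`` for the
    matching columns.
    """

    beta: np.ndarray            # (l,)
    se: np.ndarray              # (l,)
    wald_z: np.ndarray
    wald_p: np.ndarray
    cov_beta: np.ndarray        # (l, l)
    b_hat: np.ndarray           # (n_groups, m)
    sigma: np.ndarray           # (m,) random-effect SDs
    loglik: float               # Laplace-approximated marginal log-likelihood
    bic: float
    n_obs: int
    n_groups: int
    n_fixed: int
    n_vc: int                   # free variance components
    converged: bool
    diagnostics: dict = field(default_factory=dict)


def _segment_sums(Z, X, w, r, groups, n_groups, balanced_shape):
    """Per-group Z'WZ (S,m,m), X'WZ (S,l,m) and Z'r (S,m)."""
    if balanced_shape is not None:
        S, T = balanced_shape
        Z3 = Z.reshape(S, T, -1)
        X3 = X.reshape(S, T, -1)
        w2 = w.reshape(S, T)
        r2 = r.reshape(S, T)
        ZWZ = np.einsum("stj,stk,st->sjk", Z3, Z3, w2)
        XWZ = np.einsum("stj,stk,st->sjk", X3, Z3, w2)
        Zr = np.einsum("stj,st->sj", Z3, r2)
        return ZWZ, XWZ, Zr
    m = Z.shape[1]
    l = X.shape[1]
    ZWZ = np.zeros((n_groups, m, m))
    XWZ = np.zeros((n_groups, l, m))
    Zr = np.zeros((n_groups, m))
    np.add.at(ZWZ, groups, Z[:, :, None] * Z[:, None, :] * w[:, None, None])
    np.add.at(XWZ, groups, X[:, :, None] * Z[:, None, :] * w[:, None, None])
    np.add.at(Zr, groups, Z * r[:, None])
    return ZWZ, XWZ, Zr


def _penalized_newton(y, X, Z, groups, n_groups, inv_s2, beta, b,
                      balanced_shape, ridge=0.0, tol=1e-8, max_iter=60):
    """Maximize the joint penalized log-likelihood in (beta, b).

    Returns (beta, b, info) where info carries the final weighted blocks
    needed by the Laplace objective and the Wald covariance.
    """
    l = X.shape[1]
    m = Z.shape[1] if Z is not None else 0

    def eta_of(beta, b):
        eta = X @ beta
        if m:
            eta = eta + np.einsum("nm,nm->n", Z, b[groups])
        return eta

    def pen_ll(beta, b):
        eta = eta_of(beta, b)
        ll = float(np.sum(np.where(y == 1, log_expit(eta), log_expit(-eta))))
        if m:
            ll -= 0.5 * float(np.sum(b * b * inv_s2))
        ll -= 0.5 * ridge * float(beta @ beta)
        return ll

    f_old = pen_ll(beta, b)
    info = {}
    converged = False
    for it in range(max_iter):
        eta = eta_of(beta, b)
        mu = expit(eta)
        w = np.maximum(mu * (1.0 - mu), 1e-12)
        r = y - mu
        g_beta = X.T @ r - ridge * beta
        Hxx = (X * w[:, None]).T @ X + ridge * np.eye(l)
        if m:
            ZWZ, XWZ, Zr = _segment_sums(Z, X, w, r, groups, n_groups, balanced_shape)
            Hb = ZWZ + np.diag(inv_s2)[None, :, :]
            g_b = Zr - b * inv_s2
            # Schur complement for the beta step
            sol_g = np.linalg.solve(Hb, g_b[:, :, None])[:, :, 0]          # H_i^-1 g_bi
            sol_A = np.linalg.solve(Hb, XWZ.transpose(0, 2, 1))            # H_i^-1 A_i'
            schur = Hxx - np.einsum("sim,smj->ij", XWZ, sol_A)
            rhs = g_beta - np.einsum("sim,sm->i", XWZ, sol_g)
            d_beta = np.linalg.solve(schur, rhs)
            d_b = sol_g - np.einsum("smj,j->sm", sol_A, d_beta)
            gnorm = max(np.abs(g_beta).max(), np.abs(g_b).max())
        else:
            d_beta = np.linalg.solve(Hxx, g_beta)
            d_b = None
            schur = Hxx
            ZWZ = None
            gnorm = np.abs(g_beta).max()

        step = 1.0
        for _ in range(30):
            beta_new = beta + step * d_beta
            b_new = b + step * d_b if m else b
            f_new = pen_ll(beta_new, b_new)
            if f_new >= f_old - 1e-12:
                break
            step *= 0.5
        beta, b, improve, f_old = beta_new, b_new, f_new - f_old, f_new
        if gnorm < tol or (it > 0 and abs(improve) < 1e-10):
            converged = True
            break

    # blocks at the optimum (recomputed so they match beta, b exactly)
    eta = eta_of(beta, b)
    mu = expit(eta)
    w = np.maximum(mu * (1.0 - mu), 1e-12)
    Hxx = (X * w[:, None]).T @ X + ridge * np.eye(l)
    if m:
        ZWZ, XWZ, _ = _segment_sums(Z, X, w, y - mu, groups, n_groups, balanced_shape)
        Hb = ZWZ + np.diag(inv_s2)[None, :, :]
        sol_A = np.linalg.solve(Hb, XWZ.transpose(0, 2, 1))
        schur = Hxx - np.einsum("sim,smj->ij", XWZ, sol_A)
    else:
        schur = Hxx
    ll = float(np.sum(np.where(y == 1, log_expit(eta), log_expit(-eta))))
    info.update(ZWZ=ZWZ, schur=schur, ll=ll, newton_converged=converged, n_iter=it + 1)
    return beta, b, info


def _b_only_newton(y, X, Z, groups, n_groups, inv_s2, beta, b, balanced_shape,
                   tol=1e-9, max_iter=40):
    """Conditional modes of b at fixed beta (independent per-group Newton)."""
    eta_fixed = X @ beta

    def pen_ll(b):
        eta = eta_fixed + np.einsum("nm,nm->n", Z, b[groups])
        ll = float(np.sum(np.where(y == 1, log_expit(eta), log_expit(-eta))))
        return ll - 0.5 * float(np.sum(b * b * inv_s2)), eta

    f_old, eta = pen_ll(b)
    for _ in range(max_iter):
        mu = expit(eta)
        w = np.maximum(mu * (1.0 - mu), 1e-12)
        r = y - mu
        ZWZ, _, Zr = _segment_sums(Z, Z[:, :1], w, r, groups, n_groups, balanced_shape)
        g_b = Zr - b * inv_s2
        Hb = ZWZ + np.diag(inv_s2)[None, :, :]
        d_b = np.linalg.solve(Hb, g_b[:, :, None])[:, :, 0]
        step = 1.0
        for _ in range(25):
            b_new = b + step * d_b
            f_new, eta_new = pen_ll(b_new)
            if f_new >= f_old - 1e-12:
                break
            step *= 0.5
        improve = f_new - f_old
        b, f_old, eta = b_new, f_new, eta_new
        if np.abs(g_b).max() < tol or abs(improve) < 1e-11:
            break
    mu = expit(eta)
    w = np.maximum(mu * (1.0 - mu), 1e-12)
    ZWZ, _, _ = _segment_sums(Z, Z[:, :1], w, y - mu, groups, n_groups, balanced_shape)
    ll = float(np.sum(np.where(y == 1, log_expit(eta), log_expit(-eta))))
    return b, ZWZ, ll


def _marginal_objective(params, state):
    """Negative Laplace marginal log-likelihood as a function of (beta, log sigma).

    Only the conditional modes of b are profiled, so the objective sees the
    full dependence on beta, including through the log-determinant — the
    same surface glmer's outer optimizer walks at nAGQ=1.
    """
    l = state["X"].shape[1]
    beta = params[:l]
    log_sigma = np.clip(params[l:], _LOG_SIGMA_MIN, _LOG_SIGMA_MAX)
    sigma = np.exp(log_sigma)
    inv_s2 = 1.0 / sigma**2
    b, ZWZ, ll_data = _b_only_newton(
        state["y"], state["X"], state["Z"], state["groups"], state["n_groups"],
        inv_s2, beta, state["b"].copy(), state["balanced_shape"],
    )
    state["b"] = b
    pen = 0.5 * float(np.sum(b * b * inv_s2))
    M = np.eye(len(sigma))[None, :, :] + sigma[None, :, None] * ZWZ * sigma[None, None, :]
    _, logdet = np.linalg.slogdet(M)
    return -(ll_data - pen - 0.5 * float(logdet.sum()))


def _laplace_objective(log_sigma, state):
    """Negative Laplace marginal log-likelihood, profiled over (beta, b)."""
    log_sigma = np.clip(log_sigma, _LOG_SIGMA_MIN, _LOG_SIGMA_MAX)
    sigma = np.exp(log_sigma)
    inv_s2 = 1.0 / sigma**2
    beta, b, info = _penalized_newton(
        state["y"], state["X"], state["Z"], state["groups"], state["n_groups"],
        inv_s2, state["beta"].copy(), state["b"].copy(),
        state["balanced_shape"], ridge=state["ridge"],
    )
    state["beta"], state["b"] = beta, b          # warm start for the next call
    pen = 0.5 * float(np.sum(b * b * inv_s2))
    # -0.5 sum_i logdet(I + D^1/2 Z'WZ D^1/2): scaling-invariant form
    M = np.eye(len(sigma))[None, :, :] + sigma[None, :, None] * info["ZWZ"] * sigma[None, None, :]
    _, logdet = np.linalg.slogdet(M)
    ll = info["ll"] - pen - 0.5 * float(logdet.sum())
    state["last"] = (beta.copy(), b.copy(), info)
    return -ll


def fit_mixed_logit(
    y,
    X,
    Z=None,
    groups=None,
    theta_zero: bool = False,
    ridge: float = 0.0,
    maxfev: int = 200,
    log_sigma0: float = -1.2,
) -> MixedLogitFit:
    """Fit the mixed logistic model; ``Z=None`` or ``theta_zero`` gives a
    plain pooled logistic MLE.

    ``y`` in {0,1}; ``X`` (n, l); ``Z`` (n, m) random-effect columns;
    ``groups`` integer codes 0..S-1.  Columns are standardized internally.
    Separation (runaway coefficients) triggers one ridge-stabilised refit,
    flagged in ``diagnostics['ridge_stabilised']``.
    """
    y = np.ascontiguousarray(np.asarray(y, dtype=float))
    X = np.asarray(X, dtype=float)
    n, l = X.shape
    m = 0 if (Z is None or theta_zero) else Z.shape[1]

    # standardize (constant columns keep scale 1)
    sx = X.std(axis=0)
    sx[sx == 0] = 1.0
    Xs = X / sx
    if m:
        Z = np.asarray(Z, dtype=float)
        sz = Z.std(axis=0)
        sz[sz == 0] = 1.0
        Zs = Z / sz
        groups = np.asarray(groups)
        n_groups = int(groups.max()) + 1
        counts = np.bincount(groups, minlength=n_groups)
        balanced = (
            counts.min() == counts.max()
            and bool((groups == np.repeat(np.arange(n_groups), counts[0])).all())
        )
        balanced_shape = (n_groups, counts[0]) if balanced else None
    else:
        Zs, sz, n_groups, balanced_shape = None, None, 1, None
        groups = np.zeros(n, dtype=int)

    state = dict(
        y=y, X=Xs, Z=Zs, groups=groups, n_groups=n_groups,
        balanced_shape=balanced_shape, ridge=ridge,
        beta=np.zeros(l), b=np.zeros((n_groups, m)) if m else np.zeros((n_groups, 0)),
    )

    diagnostics: dict = {}
    if m == 0:
        inv_s2 = np.zeros(0)
        beta, b, info = _penalized_newton(
            y, Xs, None, groups, 1, inv_s2, np.zeros(l), state["b"], None, ridge=ridge
        )
        loglik = info["ll"]
        sigma_s = np.zeros(0)
        schur = info["schur"]
        converged = info["newton_converged"]
        diagnostics["inner_iterations"] = info["n_iter"]
    else:
        # stage A: variance parameters only, beta profiled at the joint
        # penalized mode (fast, gets close)
        res = minimize(
            _laplace_objective, np.full(m, log_sigma0), args=(state,),
            method="L-BFGS-B",
            bounds=[(_LOG_SIGMA_MIN, _LOG_SIGMA_MAX)] * m,
            options=dict(eps=1e-3, ftol=1e-8, gtol=5e-3, maxfun=min(maxfev, 80)),
        )
        log_sig = np.clip(res.x, _LOG_SIGMA_MIN, _LOG_SIGMA_MAX)
        _laplace_objective(log_sig, state)            # re-solve at the optimum
        beta, b, _ = state["last"]
        # stage B: quasi-Newton over (beta, log sigma) jointly with only b
        # profiled — the full Laplace surface, matching glmer at nAGQ=1
        res2 = minimize(
            _marginal_objective, np.concatenate([beta, log_sig]), args=(state,),
            method="L-BFGS-B",
            bounds=[(None, None)] * l + [(_LOG_SIGMA_MIN, _LOG_SIGMA_MAX)] * m,
            options=dict(eps=1e-4, ftol=1e-8, gtol=8e-4, maxfun=2 * maxfev),
        )
        beta = res2.x[:l]
        log_sig = np.clip(res2.x[l:], _LOG_SIGMA_MIN, _LOG_SIGMA_MAX)
        loglik = -float(_marginal_objective(res2.x, state))
        sigma_s = np.exp(log_sig)
        inv_s2 = 1.0 / sigma_s**2
        b = state["b"]
        # Wald covariance: Schur complement of the joint Hessian at the optimum
        eta = Xs @ beta + np.einsum("nm,nm->n", Zs, b[groups])
        mu = expit(eta)
        w = np.maximum(mu * (1.0 - mu), 1e-12)
        Hxx = (Xs * w[:, None]).T @ Xs + ridge * np.eye(l)
        ZWZ, XWZ, _ = _segment_sums(Zs, Xs, w, y - mu, groups, n_groups, balanced_shape)
        Hb = ZWZ + np.diag(inv_s2)[None, :, :]
        sol_A = np.linalg.solve(Hb, XWZ.transpose(0, 2, 1))
        schur = Hxx - np.einsum("sim,smj->ij", XWZ, sol_A)
        converged = bool(res2.success)
        diagnostics.update(
            outer_nfev=int(res.nfev), refine_nfev=int(res2.nfev),
            outer_message=str(res2.message),
        )

    if np.abs(beta).max() > 15.0 and ridge == 0.0:
        # separation: a standardized logit slope of 15 is far beyond anything
        # a bounded-probability process can identify
        fit = fit_mixed_logit(
            y, X, None if m == 0 else Z, None if m == 0 else groups,
            theta_zero=theta_zero, ridge=1e-3, maxfev=maxfev, log_sigma0=log_sigma0,
        )
        fit.diagnostics["ridge_stabilised"] = True
        return fit

    cov_s = np.linalg.inv(schur)
    beta_o = beta / sx
    cov_o = cov_s / np.outer(sx, sx)
    se = np.sqrt(np.diag(cov_o))
    z = np.divide(beta_o, se, out=np.zeros_like(beta_o), where=se > 0)
    p = 2.0 * norm.sf(np.abs(z))
    b_o = b / sz if m else np.zeros((n_groups, 0))
    sigma_o = sigma_s / sz if m else np.zeros(0)
    k = l + m
    bic = -2.0 * loglik + k * np.log(n)
    return MixedLogitFit(
        beta=beta_o, se=se, wald_z=z, wald_p=p, cov_beta=cov_o,
        b_hat=b_o, sigma=sigma_o, loglik=loglik, bic=bic,
        n_obs=n, n_groups=n_groups if m else int(np.unique(groups).size),
        n_fixed=l, n_vc=m, converged=converged, diagnostics=diagnostics,
    )
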