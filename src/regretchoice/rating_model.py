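"""Stage 1 for emotional ratings: per-condition linear mixed regression.

Trial ratings are regressed on the two experienced-emotion factors —
regret (counterfactual − obtained) and disappointment (unobtained −
obtained, within the chosen wheel) — with a random intercept and
independent random slopes per subject (diagonal covariance, mirroring the
choice model) under REML.  Ratings are treated as continuous despite the
bounded integer response axis; no censoring model is applied.

Fixed-effect tests use Satterthwaite-approximated denominator degrees of
freedom, computed from the REML information of the variance parameters
(statsmodels provides the fit; the df approximation is computed here).
The module also reports the within-condition correlation between the two
factors, which the full-feedback task leaves substantial and which bounds
how separable their effects can be.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import t as t_dist

from .dataset import Dataset, derive_trial_statistics
from .mixedlogit import ConvergenceError

__all__ = ["FittedRatingModel", "fit_rating_condition", "extract_rating_coefficients"]

FACTORS = ("regret", "disappointment")


@dataclass
class FittedRatingModel:
    condition: tuple[str, str]
    fixed: pd.Series                    # (Intercept, regret, disappointment)
    se: pd.Series
    df: pd.Series                       # Satterthwaite denominator df
    p: pd.Series
    subject_coefficients: pd.DataFrame  # subject x (b_reg, b_dis) composites
    resid_sd: float
    random_sd: pd.Series                # SDs of (intercept, regret, disappointment) deviations
    factor_correlation: float           # corr(regret, disappointment) in this cell
    converged: bool
    degenerate: bool = False            # constant response / zero residual
    diagnostics: dict = field(default_factory=dict)

    def report(self) -> dict:
        return {
            "condition": list(self.condition),
            "fixed_effects": {
                k: {"estimate": float(self.fixed[k]), "se": float(self.se[k]),
                    "df": float(self.df[k]), "p": float(self.p[k])}
                for k in self.fixed.index
            },
            "random_effect_sd": {k: float(v) for k, v in self.random_sd.items()},
            "residual_sd": float(self.resid_sd),
            "factor_correlation": float(self.factor_correlation),
            "convergence": {"converged": self.converged, "degenerate": self.degenerate,
                            **{k: str(v) for k, v in self.diagnostics.items()}},
        }


def _reml_quantities(psi, y_blocks, X_blocks, Z_blocks):
    """REML log-likelihood and fixed-effect covariance at variance params psi.

    psi = (v_intercept, v_regret, v_disappointment, residual variance);
    V_i = Z_i diag(psi[:3]) Z_i' + psi[3] I per subject.
    """
    v = np.maximum(np.asarray(psi, float), 1e-10)
    G = np.diag(v[:3])
    XtVX = 0.0
    XtVy = 0.0
    logdet = 0.0
    quads = []
    pieces = []
    for yi, Xi, Zi in zip(y_blocks, X_blocks, Z_blocks):
        Vi = Zi @ G @ Zi.T + v[3] * np.eye(len(yi))
        L = np.linalg.cholesky(Vi)
        logdet += 2.0 * float(np.log(np.diag(L)).sum())
        Wy = np.linalg.solve(L, yi)
        WX = np.linalg.solve(L, Xi)
        XtVX = XtVX + WX.T @ WX
        XtVy = XtVy + WX.T @ Wy
        pieces.append((Wy, WX))
    cov_beta = np.linalg.inv(XtVX)
    beta = cov_beta @ XtVy
    rss = sum(float((Wy - WX @ beta) @ (Wy - WX @ beta)) for Wy, WX in pieces)
    sign, logdet_xvx = np.linalg.slogdet(XtVX)
    ll = -0.5 * (logdet + logdet_xvx + rss)
    return ll, beta, cov_beta


def _satterthwaite_df(psi_hat, y_blocks, X_blocks, Z_blocks):
    """df_j = 2 Var(beta_j)^2 / (g_j' C g_j), C = REML info^-1 of psi."""
    psi_hat = np.asarray(psi_hat, float)
    k = len(psi_hat)
    h = np.maximum(1e-4 * np.abs(psi_hat), 1e-8)

    def varbeta(psi):
        _, _, cov = _reml_quantities(psi, y_blocks, X_blocks, Z_blocks)
        return np.diag(cov)

    def loglik(psi):
        ll, _, _ = _reml_quantities(psi, y_blocks, X_blocks, Z_blocks)
        return ll

    grads = np.empty((k, X_blocks[0].shape[1]))
    for j in range(k):
        up, dn = psi_hat.copy(), psi_hat.copy()
        up[j] += h[j]
        dn[j] = max(dn[j] - h[j], 1e-10)
        grads[j] = (varbeta(up) - varbeta(dn)) / (up[j] - dn[j])
    H = np.empty((k, k))
    f0 = loglik(psi_hat)
    for j in range(k):
        for l in range(j, k):
            pj, pl = psi_hat.copy(), psi_hat.copy()
            pj[j] += h[j]; pl[l] += h[l]
            pjl = psi_hat.copy(); pjl[j] += h[j]; pjl[l] += h[l]
            H[j, l] = H[l, j] = (loglik(pjl) - loglik(pj) - loglik(pl) + f0) / (h[j] * h[l])
    C = np.linalg.pinv(-H)
    v0 = varbeta(psi_hat)
    denom = np.einsum("jp,jk,kp->p", grads, C, grads)
    with np.errstate(divide="ignore", invalid="ignore"):
        df = 2.0 * v0**2 / denom
    n_obs = sum(len(y) for y in y_blocks)
    # accept the approximation only on its plausible range; a df below ~2
    # signals a near-singular variance information (boundary psi), where the
    # subject-count fallback is the honest answer
    df = np.where(np.isfinite(df) & (df > 2.0), np.minimum(df, n_obs), float(len(y_blocks) - 1))
    return df


def fit_rating_condition(dataset: Dataset, condition) -> FittedRatingModel:
    """Fit the rating model for one 2x2 cell.

    Requires ratings on at least 80% of the cell's trials; rows without a
    rating are dropped.  If the random-slopes model fails to converge the
    documented fallback — random intercept only — is fitted and flagged.
    """
    if isinstance(condition, str):
        condition = tuple(condition.split("/"))
    cell = dataset.condition(*condition)
    if len(cell) == 0:
        raise ValueError(f"no rows for condition {condition}")
    have = cell["rating"].notna()
    if have.mean() < 0.8:
        raise ValueError(
            f"condition {condition}: ratings present for only {have.mean():.0%} of trials (< 80%)"
        )
    df = derive_trial_statistics(cell.loc[have].copy())
    df = df.sort_values(["subject_id", "trial_index"], kind="stable")
    y = df["rating"].to_numpy(float)

    degenerate = float(np.std(y)) == 0.0
    corr = (
        float(np.corrcoef(df["regret"], df["disappointment"])[0, 1])
        if df["regret"].std() > 0 and df["disappointment"].std() > 0 else np.nan
    )
    subjects = np.unique(df["subject_id"])
    names = ["Intercept", "regret", "disappointment"]
    if degenerate:
        # constant response: slopes are exactly zero, nothing to estimate
        zero = pd.Series(0.0, index=names)
        const = pd.Series({"Intercept": float(y[0]), "regret": 0.0, "disappointment": 0.0})
        coefs = pd.DataFrame(0.0, index=pd.Index(subjects, name="subject_id"),
                             columns=["b_reg", "b_dis"])
        return FittedRatingModel(
            condition=condition, fixed=const, se=zero, df=zero, p=pd.Series(np.nan, index=names),
            subject_coefficients=coefs, resid_sd=0.0,
            random_sd=pd.Series(0.0, index=names), factor_correlation=corr,
            converged=True, degenerate=True,
        )

    # fit on factors per 100 points: slope variance components are then of
    # the same order as the intercept's, which the optimizer needs
    FS = 100.0
    df["regret_s"] = df["regret"] / FS
    df["disappointment_s"] = df["disappointment"] / FS
    vc = {"regret": "0 + regret_s", "disappointment": "0 + disappointment_s"}
    diagnostics: dict = {}
    fallback = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM.from_formula(
            "rating ~ regret_s + disappointment_s", groups="subject_id",
            re_formula="~1", vc_formula=vc, data=df,
        )
        try:
            res = model.fit(reml=True, method="lbfgs", maxiter=200)
            ok = bool(res.converged)
        except Exception as exc:             # singular fits and the like
            diagnostics["random_slopes_error"] = repr(exc)
            ok = False
        if not ok:
            fallback = True
            diagnostics["fallback"] = "random intercept only"
            try:
                model = sm.MixedLM.from_formula(
                    "rating ~ regret_s + disappointment_s", groups="subject_id",
                    re_formula="~1", data=df,
                )
                res = model.fit(reml=True, method="lbfgs", maxiter=200)
                ok = bool(res.converged)
            except Exception as exc:
                diagnostics["random_intercept_error"] = repr(exc)
                ok = False
            if not ok:
                # last resort when even the intercept variance is degenerate:
                # pooled least squares (zero random effects)
                diagnostics["fallback"] = "pooled OLS (no random effects)"
                res = None

    back = np.array([1.0, 1.0 / FS, 1.0 / FS])      # scaled -> per-point units
    if res is None:
        X = np.column_stack([np.ones(len(df)), df["regret_s"], df["disappointment_s"]])
        ols = sm.OLS(df["rating"].to_numpy(float), X).fit()
        fixed = pd.Series(ols.params * back, index=names)
        se = pd.Series(ols.bse * back, index=names)
    else:
        fixed = pd.Series(res.fe_params.values * back, index=names)
        se = pd.Series(res.bse_fe.values * back, index=names)

    # Satterthwaite df from our own REML evaluation at the fitted psi
    y_blocks, X_blocks, Z_blocks = [], [], []
    for sid in subjects:
        sub = df[df["subject_id"] == sid]
        Xi = np.column_stack([np.ones(len(sub)), sub["regret"], sub["disappointment"]])
        y_blocks.append(sub["rating"].to_numpy(float))
        X_blocks.append(Xi)
        Z_blocks.append(Xi)
    if res is None:
        psi = np.array([1e-10, 1e-10, 1e-10, float(ols.scale)])
    elif fallback:
        v_int = float(res.cov_re.iloc[0, 0])
        psi = np.array([v_int, 1e-10, 1e-10, float(res.scale)])
    else:
        v_int = float(res.cov_re.iloc[0, 0])
        # vcomp order follows the vc_formula dict: regret, disappointment
        psi = np.array([v_int, float(res.vcomp[0]) / FS**2,
                        float(res.vcomp[1]) / FS**2, float(res.scale)])
    try:
        dfs = _satterthwaite_df(psi, y_blocks, X_blocks, Z_blocks)
    except np.linalg.LinAlgError:
        dfs = np.full(3, float(len(subjects) - 1))
        diagnostics["satterthwaite"] = "information singular; fell back to n_subjects - 1"
    df_s = pd.Series(dfs, index=names)
    p = pd.Series(2.0 * t_dist.sf(np.abs(fixed / se), df_s), index=names)

    # BLUPs computed directly: dev_i = G Z_i' V_i^{-1} (y_i - X_i beta).
    # (robust where the fitted covariance is singular, e.g. a zero variance
    # component, and exactly zero for a dropped random slope)
    G = np.diag(np.maximum(psi[:3], 0.0))
    resid_v = max(float(psi[3]), 1e-10)
    rows = []
    for yi, Xi, Zi in zip(y_blocks, X_blocks, Z_blocks):
        Vi = Zi @ G @ Zi.T + resid_v * np.eye(len(yi))
        dev = G @ Zi.T @ np.linalg.solve(Vi, yi - Xi @ fixed.to_numpy())
        rows.append({"b_reg": fixed["regret"] + dev[1],
                     "b_dis": fixed["disappointment"] + dev[2]})
    coefs = pd.DataFrame(rows, index=pd.Index(subjects, name="subject_id"))

    random_sd = pd.Series(np.sqrt(np.maximum(psi[:3], 0.0)), index=names)
    return FittedRatingModel(
        condition=condition, fixed=fixed, se=se, df=df_s, p=p,
        subject_coefficients=coefs, resid_sd=float(np.sqrt(psi[3])),
        random_sd=random_sd, factor_correlation=corr,
        converged=True, degenerate=False, diagnostics=diagnostics,
    )


def extract_rating_coefficients(model: FittedRatingModel) -> pd.DataFrame:
    """Per-subject composite (b_reg, b_dis) for stage 2."""
    if not model.converged:
        raise ConvergenceError("refusing to extract coefficients from an unconverged model",
                               diagnostics=model.diagnostics)
    return model.subject_coefficients.copy()
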