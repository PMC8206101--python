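"""Stage 2: 2x2 repeated-measures ANOVA on per-subject stage-1 coefficients.

With two levels per within-subject factor every F(1, n-1) equals the
squared paired t of the corresponding contrast, so no sphericity correction
arises.  Effect size is partial eta-squared, SSn/(SSn + SSd), with
confidence intervals from inversion of the noncentral-F distribution.
The module also houses the calibration harnesses: empirical type-I error
and power of the full simulate -> stage-1 -> stage-2 chain.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import f as f_dist, ncf
from statsmodels.stats.proportion import proportion_confint

from .choice_model import ModelSpec, extract_subject_coefficients, fit_condition
from .dataset import CONDITIONS, Dataset
from .mixedlogit import ConvergenceError
from .simulate import SimulationConfig, simulate_dataset

logger = logging.getLogger(__name__)

__all__ = [
    "AnovaResult",
    "rm_anova_2x2",
    "f_and_eta_from_ss",
    "eta_sq_ci",
    "posthoc_contrast",
    "coefficient_table",
    "anova_by_coefficient",
    "type1_simulation",
    "power_simulation",
]

EFFECTS = ("(Intercept)", "beneficiary", "audience", "beneficiary × audience")


@dataclass
class AnovaResult:
    """One 2x2 within-subject ANOVA table (rows: the four effects)."""

    table: pd.DataFrame  # DFn, DFd, SSn, SSd, F, p, eta_sq, eta_ci_low, eta_ci_high
    n_subjects: int

    def __getitem__(self, effect: str) -> pd.Series:
        return self.table.loc[effect]

    def to_text(self) -> str:
        """Plain-text rendering with the published table's columns."""
        out = self.table.copy()
        out["η² [95% CI]"] = [
            f"{r.eta_sq:.3f} [{r.eta_ci_low:.3f}, {r.eta_ci_high:.3f}]"
            for r in out.itertuples()
        ]
        cols = ["DFn", "DFd", "SSn", "SSd", "F", "p", "η² [95% CI]"]
        return out[cols].to_string(float_format=lambda v: f"{v:.4g}")

    def to_dict(self) -> dict:
        return {
            effect: {k: (None if pd.isna(v) else float(v)) for k, v in row.items()}
            for effect, row in self.table.iterrows()
        }


def _pivot_2x2(table: pd.DataFrame, value: str = "value") -> np.ndarray:
    """(n_subjects, beneficiary[self, partner], audience[absent, present])."""
    required = {"subject_id", "beneficiary", "audience", value}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"coefficient table lacks columns: {sorted(missing)}")
    wide = table.pivot_table(index="subject_id", columns=["beneficiary", "audience"],
                             values=value, aggfunc="mean")
    want = [(b, a) for b in ("self", "partner") for a in ("absent", "present")]
    missing_cells = [c for c in want if c not in wide.columns]
    if missing_cells:
        raise ValueError(f"incomplete 2x2 design; missing cells: {missing_cells}")
    if wide[want].isna().any().any():
        bad = wide[want].isna().any(axis=1)
        raise ValueError(f"subjects missing cells: {list(wide.index[bad])}")
    n = len(wide)
    if n < 3:
        raise ValueError(f"need >= 3 subjects, got {n}")
    return wide[want].to_numpy(float).reshape(n, 2, 2)


def f_and_eta_from_ss(ssn: float, ssd: float, dfn: int, dfd: int) -> tuple[float, float, float]:
    """(F, p, partial eta-squared) from an effect's sums of squares.

    F = (SSn/DFn)/(SSd/DFd); eta² = SSn/(SSn + SSd).  The identities every
    row of a within-subject ANOVA table satisfies.
    """
    if ssn < 0 or ssd < 0:
        raise ValueError("sums of squares must be >= 0")
    F = (ssn / dfn) / (ssd / dfd) if ssd > 0 else (np.inf if ssn > 0 else 0.0)
    p = float(f_dist.sf(F, dfn, dfd)) if np.isfinite(F) else 0.0
    eta = ssn / (ssn + ssd) if (ssn + ssd) > 0 else 0.0
    return F, p, eta


def rm_anova_2x2(table: pd.DataFrame, value: str = "value", ci_level: float = 0.95) -> AnovaResult:
    """Two-way (beneficiary x audience) within-subject ANOVA.

    ``table`` is long-format with columns subject_id, beneficiary, audience
    and ``value`` — one number per subject per cell.  Returns all four
    effect rows (intercept tested against the between-subject variation, as
    in the published table).
    """
    Y = _pivot_2x2(table, value)
    n = Y.shape[0]
    grand = Y.mean()
    subj = Y.mean(axis=(1, 2))
    ben = Y.mean(axis=(0, 2))
    aud = Y.mean(axis=(0, 1))
    cell = Y.mean(axis=0)

    rows = {}
    rows["(Intercept)"] = (4 * n * grand**2, 4 * np.sum((subj - grand) ** 2))
    sb = Y.mean(axis=2)  # subject x beneficiary
    rows["beneficiary"] = (
        2 * n * np.sum((ben - grand) ** 2),
        2 * np.sum((sb - subj[:, None] - ben[None, :] + grand) ** 2),
    )
    sa = Y.mean(axis=1)
    rows["audience"] = (
        2 * n * np.sum((aud - grand) ** 2),
        2 * np.sum((sa - subj[:, None] - aud[None, :] + grand) ** 2),
    )
    inter = cell - ben[:, None] - aud[None, :] + grand
    resid = (
        Y
        - sb[:, :, None] - sa[:, None, :] - cell[None, :, :]
        + subj[:, None, None] + ben[None, :, None] + aud[None, None, :]
        - grand
    )
    rows["beneficiary × audience"] = (n * np.sum(inter**2), np.sum(resid**2))

    records = []
    dfn, dfd = 1, n - 1
    for effect in EFFECTS:
        ssn, ssd = rows[effect]
        F, p, eta = f_and_eta_from_ss(ssn, ssd, dfn, dfd)
        lo, hi = eta_sq_ci(F, dfn, dfd, ci_level) if np.isfinite(F) else (eta, eta)
        records.append(dict(DFn=dfn, DFd=dfd, SSn=ssn, SSd=ssd, F=F, p=p,
                            eta_sq=eta, eta_ci_low=lo, eta_ci_high=hi))
    return AnovaResult(pd.DataFrame(records, index=pd.Index(EFFECTS, name="effect")), n)


def eta_sq_ci(F: float, dfn: int, dfd: int, level: float = 0.95) -> tuple[float, float]:
    """CI for partial eta-squared by noncentral-F inversion.

    The bounds are the noncentralities whose F distribution places the
    observed F at the (1±level)/2 quantiles, mapped via
    eta² = ncp / (ncp + dfn + dfd + 1); the lower bound is floored at 0.
    """
    if F < 0:
        raise ValueError("F must be >= 0")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    if dfn < 1 or dfd < 1:
        raise ValueError("degrees of freedom must be >= 1")
    alpha = (1.0 - level) / 2.0

    def cdf(lam: float) -> float:
        v = ncf.cdf(F, dfn, dfd, lam)
        return float(v) if np.isfinite(v) else 0.0   # cdf -> 0 for extreme ncp

    def ncp_for(prob: float) -> float:
        # the ncp with P(F' <= F | ncp) = prob (0 if even ncp=0 is below it)
        if cdf(0.0) < prob:
            return 0.0
        hi = max(10.0, 4.0 * F * dfn + 20.0)
        while cdf(hi) > prob and hi < 1e8:
            hi *= 2.0
        if cdf(hi) > prob:
            return hi
        return brentq(lambda l: cdf(l) - prob, 0.0, hi)

    lam_lo = ncp_for(1.0 - alpha)
    lam_hi = ncp_for(alpha)
    to_eta = lambda lam: lam / (lam + dfn + dfd + 1)
    return to_eta(lam_lo), to_eta(lam_hi)


def posthoc_contrast(
    table: pd.DataFrame,
    fix_factor: str,
    fix_level: str,
    value: str = "value",
) -> pd.Series:
    """Paired contrast on the non-fixed factor within one level of the other.

    E.g. ``fix_factor='audience', fix_level='absent'`` compares self vs
    partner among audience-absent cells.  F = t², DFd = n − 1.
    """
    if fix_factor not in ("beneficiary", "audience"):
        raise ValueError("fix_factor must be 'beneficiary' or 'audience'")
    sub = table[table[fix_factor] == fix_level]
    if len(sub) == 0:
        raise ValueError(f"no rows with {fix_factor} == {fix_level!r}")
    other = "audience" if fix_factor == "beneficiary" else "beneficiary"
    levels = ("absent", "present") if other == "audience" else ("self", "partner")
    wide = sub.pivot_table(index="subject_id", columns=other, values=value, aggfunc="mean")
    if any(l not in wide.columns for l in levels) or wide[list(levels)].isna().any().any():
        raise ValueError(f"incomplete paired data for {other} within {fix_factor}={fix_level}")
    d = (wide[levels[1]] - wide[levels[0]]).to_numpy(float)
    n = len(d)
    sd = d.std(ddof=1)
    t = 0.0 if sd == 0 else d.mean() / (sd / np.sqrt(n))
    F = t * t
    p = float(f_dist.sf(F, 1, n - 1))
    eta = F / (F + (n - 1)) if np.isfinite(F) else 1.0
    lo, hi = eta_sq_ci(F, 1, n - 1)
    return pd.Series({"F": F, "DFn": 1, "DFd": n - 1, "p": p,
                      "eta_sq": eta, "eta_ci_low": lo, "eta_ci_high": hi})


def coefficient_table(dataset: Dataset, spec: ModelSpec = ModelSpec()) -> pd.DataFrame:
    """Fit all four cells and stack the per-subject choice coefficients.

    Long format: subject_id, beneficiary, audience, coefficient, value.
    """
    rows = []
    for ben, aud in CONDITIONS:
        model = fit_condition(dataset, (ben, aud), spec)
        coefs = extract_subject_coefficients(model)
        for name in coefs.columns:
            rows.append(pd.DataFrame({
                "subject_id": coefs.index,
                "beneficiary": ben,
                "audience": aud,
                "coefficient": name,
                "value": coefs[name].to_numpy(),
            }))
    return pd.concat(rows, ignore_index=True)


def anova_by_coefficient(coef_table: pd.DataFrame) -> dict[str, AnovaResult]:
    """One 2x2 ANOVA per coefficient name in a long coefficient table."""
    return {
        name: rm_anova_2x2(sub)
        for name, sub in coef_table.groupby("coefficient", sort=False)
    }


def _replicate_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(n)]


def _pipeline_pvalues(config: SimulationConfig, spec: ModelSpec):
    """simulate -> per-cell fits -> ANOVA; p-values per (coefficient, effect)."""
    dataset = simulate_dataset(config)
    table = coefficient_table(dataset, spec)
    out = {}
    for name, res in anova_by_coefficient(table).items():
        for effect in ("beneficiary", "audience", "beneficiary × audience"):
            out[(name, effect)] = float(res[effect]["p"])
    return out


def type1_simulation(
    config: SimulationConfig,
    n_replicates: int = 500,
    alpha: float = 0.05,
    spec: ModelSpec = ModelSpec(),
) -> pd.DataFrame:
    """Empirical false-positive rate of the two-stage chain under the null.

    ``config.population`` must be a null spec (identical parameters in all
    cells).  Each replicate simulates a fresh dataset, runs stage 1 and
    stage 2, and records which effects reject at ``alpha``.  Returns one
    row per (coefficient, effect) with the rejection rate and a 95% Wilson
    interval; replicates whose stage-1 fit fails are excluded and counted.
    """
    cells = list(config.population.cells.values())
    if any(c != cells[0] for c in cells[1:]):
        raise ValueError("type-I simulation requires identical parameters in all four cells")
    return _rejection_rates(config, n_replicates, alpha, spec)


def _rejection_rates(config, n_replicates, alpha, spec) -> pd.DataFrame:
    rejections: dict[tuple[str, str], int] = {}
    n_ok, n_failed = 0, 0
    for seed in _replicate_seeds(config.seed, n_replicates):
        try:
            pvals = _pipeline_pvalues(replace(config, seed=seed), spec)
        except (ConvergenceError, np.linalg.LinAlgError) as exc:
            n_failed += 1
            logger.warning("replicate (seed %d) failed in stage 1: %s", seed, exc)
            continue
        n_ok += 1
        for key, p in pvals.items():
            rejections[key] = rejections.get(key, 0) + (p < alpha)
    if n_ok == 0:
        raise RuntimeError("all replicates failed")
    records = []
    for (coef, effect), k in sorted(rejections.items()):
        lo, hi = proportion_confint(k, n_ok, alpha=0.05, method="wilson")
        records.append(dict(coefficient=coef, effect=effect, alpha=alpha,
                            n_replicates=n_ok, n_failed=n_failed,
                            rejection_rate=k / n_ok, ci_low=lo, ci_high=hi))
    return pd.DataFrame(records)


def power_simulation(
    config: SimulationConfig,
    effect: tuple[str, str] = ("AR", "audience"),
    n_subjects=(10, 25, 50),
    alpha: float = 0.05,
    n_replicates: int = 60,
    spec: ModelSpec = ModelSpec(),
) -> pd.DataFrame:
    """Empirical power of the two-stage chain for one ANOVA effect.

    ``config.population`` encodes the alternative (e.g. the default
    audience offset on the AR coefficient).  Power is estimated on a grid
    of sample sizes for sample-size curves; everything else follows
    :func:`type1_simulation`.
    """
    coef_name, effect_name = effect
    records = []
    for i, n in enumerate(np.atleast_1d(n_subjects)):
        sub = replace(config, n_subjects=int(n), seed=config.seed + 1000 * i)
        rates = _rejection_rates(sub, n_replicates, alpha, spec)
        row = rates[(rates.coefficient == coef_name) & (rates.effect == effect_name)]
        if len(row) == 0:
            raise ValueError(f"effect {effect} not present in stage-2 output")
        r = row.iloc[0]
        records.append(dict(n_subjects=int(n), coefficient=coef_name, effect=effect_name,
                            alpha=alpha, n_replicates=int(r.n_replicates),
                            n_failed=int(r.n_failed), power=r.rejection_rate,
                            ci_low=r.ci_low, ci_high=r.ci_high))
    return pd.DataFrame(records)
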