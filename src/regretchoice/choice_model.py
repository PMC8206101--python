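"""Stage 1 for choices: per-condition mixed-effects logistic regression.

Each 2x2 cell is fitted separately with fixed effects (the population-level
BLUEs) and per-subject random deviations (BLUPs) on intercept, dEV, dSD and
AR.  The per-subject composite coefficients (fixed + deviation) are the
summary statistics carried into stage 2.  A combined model with condition
dummies interacting with each gamble statistic, and BIC comparison against
a model augmented with the anticipated-disappointment regressor, are also
provided.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataset import CONDITIONS, Dataset, derive_trial_statistics
from .mixedlogit import ConvergenceError, MixedLogitFit, fit_mixed_logit

__all__ = [
    "ModelSpec",
    "FittedChoiceModel",
    "fit_condition",
    "extract_subject_coefficients",
    "compare_models_bic",
    "fit_combined",
    "ConvergenceError",
]

GAMBLE_STATISTICS = ("dEV", "dSD", "AR")


@dataclass(frozen=True)
class ModelSpec:
    """Which regressors enter the fixed and random parts.

    Defaults: intercept plus the three gamble statistics in both parts
    (identical fixed and random design, diagonal random-effect covariance).
    ``random=()`` constrains all random-effect variances to zero, reducing
    the fit to a pooled logistic MLE.  No interactions among the gamble
    statistics are allowed in a per-condition model.
    """

    fixed: tuple[str, ...] = ("const",) + GAMBLE_STATISTICS
    random: tuple[str, ...] = ("const",) + GAMBLE_STATISTICS

    def __post_init__(self) -> None:
        if len(self.fixed) < 1:
            raise ValueError("at least one fixed regressor is required")
        unknown = set(self.random) - set(self.fixed)
        if unknown:
            raise ValueError(f"random regressors must be a subset of fixed; extra: {unknown}")

    def augmented_with(self, name: str) -> "ModelSpec":
        return ModelSpec(fixed=self.fixed + (name,), random=self.random)

    def nests(self, other: "ModelSpec") -> bool:
        return set(other.fixed) <= set(self.fixed) and set(other.random) <= set(self.random)


@dataclass
class FittedChoiceModel:
    """One fitted mixed logistic model, indexed by regressor name."""

    condition: tuple[str, str] | str
    spec: ModelSpec
    subjects: np.ndarray                 # subject ids, aligned with b_hat rows
    fit: MixedLogitFit
    term_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.term_names:
            self.term_names = self.spec.fixed

    @property
    def beta(self) -> pd.Series:
        return pd.Series(self.fit.beta, index=list(self.term_names))

    @property
    def wald(self) -> pd.DataFrame:
        """Per fixed effect: estimate, SE, Wald z and two-tailed p."""
        return pd.DataFrame(
            {"estimate": self.fit.beta, "se": self.fit.se,
             "z": self.fit.wald_z, "p": self.fit.wald_p},
            index=list(self.term_names),
        )

    @property
    def theta(self) -> pd.Series:
        return pd.Series(self.fit.sigma, index=list(self.spec.random))

    @property
    def bic(self) -> float:
        return self.fit.bic

    @property
    def loglik(self) -> float:
        return self.fit.loglik

    @property
    def converged(self) -> bool:
        return self.fit.converged

    def report(self) -> dict:
        """JSON-ready model report."""
        return {
            "condition": list(self.condition) if isinstance(self.condition, tuple) else self.condition,
            "fixed_effects": {
                name: {"estimate": float(b), "se": float(s), "z": float(z), "p": float(p)}
                for name, b, s, z, p in zip(
                    self.term_names, self.fit.beta, self.fit.se,
                    self.fit.wald_z, self.fit.wald_p)
            },
            "random_effect_sd": {n: float(s) for n, s in self.theta.items()},
            "loglik": float(self.loglik),
            "bic": float(self.bic),
            "n_obs": int(self.fit.n_obs),
            "n_subjects": int(self.fit.n_groups),
            "convergence": {"converged": bool(self.converged), **{
                k: (int(v) if isinstance(v, (int, np.integer)) else str(v) if not isinstance(v, bool) else v)
                for k, v in self.fit.diagnostics.items()}},
        }


def _normalize_condition(condition) -> tuple[str, str]:
    if isinstance(condition, str):
        ben, aud = condition.split("/")
        return ben, aud
    return tuple(condition)


def _design(df: pd.DataFrame, names: tuple[str, ...]) -> np.ndarray:
    cols = []
    for name in names:
        cols.append(np.ones(len(df)) if name == "const" else df[name].to_numpy(float))
    return np.column_stack(cols)


def _prepare(df: pd.DataFrame):
    df = df.loc[df["choice"].isin([0, 1])].copy()
    df = derive_trial_statistics(df)
    df = df.sort_values(["subject_id", "trial_index"], kind="stable").reset_index(drop=True)
    subjects, groups = np.unique(df["subject_id"].to_numpy(), return_inverse=True)
    return df, subjects, groups


def fit_condition(
    dataset: Dataset,
    condition,
    spec: ModelSpec = ModelSpec(),
) -> FittedChoiceModel:
    """Fit one 2x2 cell.

    On outer-optimizer failure the fit is retried once from the
    zero-variance corner with a larger evaluation budget; if that also
    fails a :class:`ConvergenceError` with diagnostics is raised.
    """
    condition = _normalize_condition(condition)
    cell = dataset.condition(*condition)
    if len(cell) == 0:
        raise ValueError(f"no rows for condition {condition}")
    df, subjects, groups = _prepare(cell)
    trials_per_subject = np.bincount(groups)
    if len(subjects) < 2 or trials_per_subject.min() < 8:
        raise ValueError(
            f"condition {condition} needs >= 2 subjects with >= 8 trials each "
            f"(got {len(subjects)} subjects, min {trials_per_subject.min()} trials)"
        )
    y = df["choice"].to_numpy(float)
    X = _design(df, spec.fixed)
    Z = _design(df, spec.random) if spec.random else None
    fit = fit_mixed_logit(y, X, Z=Z, groups=groups if spec.random else None)
    if not fit.converged and spec.random:
        fit = fit_mixed_logit(y, X, Z=Z, groups=groups, maxfev=1000)
        fit.diagnostics["restarted_with_larger_budget"] = True
    if not fit.converged:
        raise ConvergenceError(
            f"mixed logistic fit did not converge for condition {condition}",
            diagnostics=fit.diagnostics,
        )
    return FittedChoiceModel(condition=condition, spec=spec, subjects=subjects, fit=fit)


def extract_subject_coefficients(model: FittedChoiceModel) -> pd.DataFrame:
    """Per-subject composite coefficients for the three gamble statistics.

    Row i = fixed effect + subject i's BLUP deviation (zero deviation for a
    statistic absent from the random part).  These are the quantities the
    second stage compares across conditions.
    """
    if not model.converged:
        raise ConvergenceError(
            "refusing to extract coefficients from an unconverged model",
            diagnostics=model.fit.diagnostics,
        )
    out = {}
    for name in GAMBLE_STATISTICS:
        j = model.term_names.index(name)
        value = np.full(len(model.subjects), model.fit.beta[j])
        if name in model.spec.random:
            value = value + model.fit.b_hat[:, model.spec.random.index(name)]
        out[name] = value
    return pd.DataFrame(out, index=pd.Index(model.subjects, name="subject_id"))


def compare_models_bic(
    dataset: Dataset,
    condition,
    base: ModelSpec = ModelSpec(),
    augmented: ModelSpec | None = None,
) -> float:
    """BIC(augmented) − BIC(base); positive disfavours the augmentation.

    The default augmentation adds the anticipated-disappointment regressor
    ``AD`` to the fixed part, the comparison the study used to decide
    against a disappointment term in the choice model.
    """
    if augmented is None:
        augmented = base.augmented_with("AD")
    if not augmented.nests(base):
        raise ValueError("augmented spec must nest the base spec")
    fit_base = fit_condition(dataset, condition, base)
    fit_aug = fit_condition(dataset, condition, augmented)
    return float(fit_aug.bic - fit_base.bic)


def fit_combined(dataset: Dataset, spec: ModelSpec = ModelSpec()) -> FittedChoiceModel:
    """One model over all four cells with condition-dummy interactions.

    Fixed part: the regressors of ``spec``, beneficiary/audience dummies
    (partner = 1, present = 1), their product, and each dummy's interaction
    with each gamble statistic.  Random part: per-subject, as in ``spec``.
    Non-convergence here is reported via ``converged=False`` rather than an
    exception — a combined interaction model legitimately may not converge.
    """
    present = {(b, a) for b, a in dataset.df[["beneficiary", "audience"]].drop_duplicates().itertuples(index=False)}
    missing = [c for c in CONDITIONS if c not in present]
    if missing:
        raise ValueError(f"combined model requires all four cells; missing: {missing}")
    df, subjects, groups = _prepare(dataset.df)
    ben = (df["beneficiary"] == "partner").to_numpy(float)
    aud = (df["audience"] == "present").to_numpy(float)
    X = _design(df, spec.fixed)
    names = list(spec.fixed)
    extra = [("beneficiary[partner]", ben), ("audience[present]", aud),
             ("beneficiary:audience", ben * aud)]
    for stat in GAMBLE_STATISTICS:
        if stat in spec.fixed:
            v = df[stat].to_numpy(float)
            extra += [(f"beneficiary[partner]:{stat}", ben * v),
                      (f"audience[present]:{stat}", aud * v),
                      (f"beneficiary:audience:{stat}", ben * aud * v)]
    X = np.column_stack([X] + [col for _, col in extra])
    names += [n for n, _ in extra]
    Z = _design(df, spec.random) if spec.random else None
    # ~20 outer parameters: give the quasi-Newton a proportionally larger budget
    fit = fit_mixed_logit(y=df["choice"].to_numpy(float), X=X, Z=Z,
                          groups=groups if spec.random else None, maxfev=1200)
    return FittedChoiceModel(
        condition="combined", spec=spec, subjects=subjects, fit=fit,
        term_names=tuple(names),
    )
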