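"""Generative model of the 2x2 social-context Wheel-of-Fortune experiment.

Simulates the full study — stimulus list, subjects, choices, wheel outcomes
and emotional ratings — with the hierarchical structure the two-stage
analysis assumes:

* each 2x2 cell (beneficiary x audience) has population-level choice
  coefficients ``beta = (intercept, b_e on dEV, b_sd on dSD, b_r on AR)``
  in logit units per point;
* each subject's coefficients deviate from the population by a diagonal
  Gaussian random effect with SDs ``tau`` (redrawn per cell by default,
  matching per-condition independent fits);
* choices are Bernoulli with P(left) = logistic(eta); both wheels then spin,
  yielding factual and counterfactual outcomes;
* ratings are linear in experienced regret and disappointment plus Gaussian
  noise, rounded and clamped to the [-50, 50] response axis.

Defaults encode the study conditions: 50 subjects, 48 trials per cell,
outcomes from {-200, -50, 50, 200}, probabilities on a 0.05 grid in
[0.2, 0.8].
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.special import expit

from .dataset import CONDITIONS, Dataset, derive_trial_statistics
from .task import (
    OUTCOME_ALPHABET,
    Lottery,
    TrialPair,
    TrialRecord,
    decision_variables,
    anticipated_disappointment,
)

__all__ = [
    "CellParams",
    "PopulationSpec",
    "SimulationConfig",
    "GenerationError",
    "generate_gamble_list",
    "simulate_choice",
    "simulate_rating",
    "simulate_dataset",
    "DEFAULT_PROBABILITY_GRID",
]

#: Wheel probabilities: multiples of 0.05 in [0.2, 0.8] — visibly distinct
#: segments, non-degenerate outcome spreads.
DEFAULT_PROBABILITY_GRID = tuple(np.round(np.arange(0.20, 0.8001, 0.05), 2))

COEF_NAMES = ("const", "dEV", "dSD", "AR")


class GenerationError(RuntimeError):
    """Stimulus-generation constraints could not be satisfied."""


@dataclass(frozen=True)
class CellParams:
    """Population parameters of one 2x2 cell.

    ``beta``/``tau``: fixed-effect values and random-effect SDs for
    (intercept, dEV, dSD, AR), logit units per point.  ``rating`` holds
    (intercept, b_regret, b_disappointment, residual SD) in rating units per
    point; ``rating_tau`` the random-effect SDs of (intercept, b_regret,
    b_disappointment).  ``beta_ad`` adds an anticipated-disappointment term
    to the choice logit (0 by default; used only for model-comparison
    simulations).
    """

    beta: tuple[float, float, float, float]
    tau: tuple[float, float, float, float]
    rating: tuple[float, float, float, float] = (0.0, -0.06, -0.10, 10.0)
    rating_tau: tuple[float, float, float] = (5.0, 0.015, 0.025)
    beta_ad: float = 0.0

    def __post_init__(self) -> None:
        if any(t < 0 for t in self.tau) or any(t < 0 for t in self.rating_tau):
            raise ValueError("random-effect SDs must be >= 0")
        if self.rating[3] <= 0:
            raise ValueError("rating residual SD must be > 0")


def _default_cells() -> dict[tuple[str, str], CellParams]:
    """Control cell (self, absent): beta = (0, 0.010, -0.002, 0.010).

    Offsets reproduce the qualitative ordering the 2x2 design is built to
    detect: an audience raises regret aversion (b_r) and damps the drive of
    expected value; choosing for the partner lowers regret aversion and risk
    aversion.  tau is half of each |beta| component of the control cell.
    """
    base = np.array([0.0, 0.010, -0.002, 0.010])
    tau = tuple(np.abs(base) / 2.0)
    cells = {}
    for ben, aud in CONDITIONS:
        beta = base.copy()
        if aud == "present":
            beta[3] += 0.004
            beta[1] -= 0.002
        if ben == "partner":
            beta[3] -= 0.002
            beta[2] += 0.001
        rating = np.array([0.0, -0.06, -0.10, 10.0])
        if aud == "present":
            rating[1] -= 0.02   # stronger expressed regret under an audience
        if (ben, aud) != ("self", "absent"):
            rating[2] += 0.02   # disappointment expressed most strongly alone, for self
        cells[(ben, aud)] = CellParams(beta=tuple(beta), tau=tau, rating=tuple(rating))
    return cells


@dataclass(frozen=True)
class PopulationSpec:
    """Per-cell population parameters of the generative model."""

    cells: dict[tuple[str, str], CellParams] = field(default_factory=_default_cells)

    def __post_init__(self) -> None:
        missing = [c for c in CONDITIONS if c not in self.cells]
        if missing:
            raise ValueError(f"PopulationSpec lacks cells: {missing}")

    @classmethod
    def default(cls) -> "PopulationSpec":
        return cls()

    @classmethod
    def null(cls, beta=(0.0, 0.010, -0.002, 0.010), tau=None, **kwargs) -> "PopulationSpec":
        """Identical parameters in all four cells (no condition effects)."""
        if tau is None:
            tau = tuple(abs(b) / 2.0 for b in beta)
        cell = CellParams(beta=tuple(beta), tau=tuple(tau), **kwargs)
        return cls(cells={c: cell for c in CONDITIONS})

    def with_audience_effect(self, delta_r: float) -> "PopulationSpec":
        """Copy with an audience-present offset ``delta_r`` added to b_r."""
        cells = {}
        for cond, cp in self.cells.items():
            beta = list(cp.beta)
            if cond[1] == "present":
                beta[3] += delta_r
            cells[cond] = CellParams(tuple(beta), cp.tau, cp.rating, cp.rating_tau, cp.beta_ad)
        return PopulationSpec(cells=cells)


@dataclass(frozen=True)
class SimulationConfig:
    """Everything needed to regenerate a dataset byte-identically."""

    seed: int
    n_subjects: int = 50
    n_trials_per_condition: int = 48
    population: PopulationSpec = field(default_factory=PopulationSpec)
    alphabet: tuple[float, ...] = OUTCOME_ALPHABET
    probability_grid: tuple[float, ...] = DEFAULT_PROBABILITY_GRID
    shared_random_effects: bool = False  # True: one subject draw reused across cells
    clamp_ratings: bool = True
    integer_ratings: bool = True         # False: keep the latent continuous rating

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        if self.n_trials_per_condition < 4:
            raise ValueError("n_trials_per_condition must be >= 4")


def _draw_lottery_arrays(n, alphabet, grid, rng):
    alph = np.asarray(sorted(set(alphabet)), dtype=float)
    pair_idx = rng.integers(0, len(alph), size=(n, 2))
    # resample until the two outcomes differ
    while True:
        same = pair_idx[:, 0] == pair_idx[:, 1]
        if not same.any():
            break
        pair_idx[same] = rng.integers(0, len(alph), size=(int(same.sum()), 2))
    x = alph[pair_idx.max(axis=1)]
    y = alph[pair_idx.min(axis=1)]
    p = np.asarray(grid, dtype=float)[rng.integers(0, len(grid), size=n)]
    return x, y, p


def generate_gamble_list(
    n_trials: int,
    alphabet=OUTCOME_ALPHABET,
    probability_grid=DEFAULT_PROBABILITY_GRID,
    rng: np.random.Generator | None = None,
    max_attempts: int = 200,
) -> list[TrialPair]:
    """Draw a stimulus list of ``n_trials`` two-wheel gambles.

    Within each wheel x > y; identical left/right wheels are rejected.  The
    list is resampled until each of dEV, dSD, AR takes both positive and
    negative values and |corr(dEV, AR)| < 0.95, so the three regressors are
    identifiable rather than confounded.
    """
    if rng is None:
        raise ValueError("an explicitly seeded rng is required")
    if len(set(alphabet)) < 2:
        raise GenerationError("outcome alphabet needs >= 2 distinct values")
    if len(probability_grid) == 0 or not all(0 < p < 1 for p in probability_grid):
        raise GenerationError("probability grid must be a non-empty subset of (0, 1)")
    for _ in range(max_attempts):
        xL, yL, pL = _draw_lottery_arrays(n_trials, alphabet, probability_grid, rng)
        xR, yR, pR = _draw_lottery_arrays(n_trials, alphabet, probability_grid, rng)
        identical = (xL == xR) & (yL == yR) & (pL == pR)
        if identical.any():
            continue
        pairs = [
            TrialPair(Lottery(xL[t], yL[t], pL[t]), Lottery(xR[t], yR[t], pR[t]),
                      trial_index=t + 1)
            for t in range(n_trials)
        ]
        dv = np.array([[d.dEV, d.dSD, d.AR] for d in map(decision_variables, pairs)])
        if not ((dv > 0).any(axis=0) & (dv < 0).any(axis=0)).all():
            continue
        sd = dv.std(axis=0)
        if (sd == 0).any():
            continue
        r = np.corrcoef(dv[:, 0], dv[:, 2])[0, 1]
        if abs(r) >= 0.95:
            continue
        return pairs
    raise GenerationError(
        f"could not satisfy stimulus constraints in {max_attempts} attempts "
        "(alphabet/grid too restrictive, e.g. a 2-value alphabet makes AR identically 0)"
    )


def simulate_choice(pair: TrialPair, coefs, rng: np.random.Generator) -> int:
    """One Bernoulli choice from the logistic model.

    ``coefs`` are the subject-level composite coefficients (population +
    subject deviation) ordered (intercept, b_e, b_sd, b_r[, b_ad]).  Returns
    1 (left) or 0 (right).
    """
    coefs = np.asarray(coefs, dtype=float)
    d = decision_variables(pair)
    x = [1.0, d.dEV, d.dSD, d.AR]
    if coefs.size == 5:
        x.append(anticipated_disappointment(pair))
    p_left = expit(float(np.dot(coefs, x)))
    return int(rng.random() < p_left)


def simulate_rating(
    record: TrialRecord, rating_coefs, rng: np.random.Generator, clamp: bool = True
) -> int:
    """One emotional rating: linear in the experienced emotion factors.

    rating = round(a + b_reg * regret + b_dis * disappointment + noise),
    clamped to the [-50, 50] response axis unless ``clamp`` is False.
    """
    a, b_reg, b_dis, resid_sd = rating_coefs
    value = (
        a
        + b_reg * record.experienced_regret
        + b_dis * record.experienced_disappointment
        + (resid_sd * rng.standard_normal() if resid_sd > 0 else 0.0)
    )
    value = round(value)
    if clamp:
        value = min(50, max(-50, value))
    return int(value)


def simulate_dataset(config: SimulationConfig) -> Dataset:
    """Simulate the full 2x2 experiment.

    One stimulus list is generated and presented to every subject in every
    cell in per-subject pseudorandom order (each item once), mirroring the
    task.  Per cell, each subject's coefficients are population beta plus a
    diagonal Gaussian deviation; choices, both wheel spins, the experienced
    emotion factors and the rating follow.  The true per-subject composite
    coefficients are kept in ``provenance['truth']`` for recovery studies.
    """
    rng = np.random.default_rng(config.seed)
    S, T = config.n_subjects, config.n_trials_per_condition
    pairs = generate_gamble_list(T, config.alphabet, config.probability_grid, rng)
    xL = np.array([p.left.x for p in pairs]);  yL = np.array([p.left.y for p in pairs])
    pL = np.array([p.left.p for p in pairs])
    xR = np.array([p.right.x for p in pairs]); yR = np.array([p.right.y for p in pairs])
    pR = np.array([p.right.p for p in pairs])
    stim = pd.DataFrame(dict(xL=xL, yL=yL, pL=pL, xR=xR, yR=yR, pR=pR))
    dv = derive_trial_statistics(stim.assign(choice=1, obtained=xL, counterfactual=xR))
    X = dv[["dEV", "dSD", "AR"]].to_numpy()          # (T, 3)
    AD = dv["AD"].to_numpy()

    shared_z = rng.standard_normal((S, 4)) if config.shared_random_effects else None
    shared_zr = rng.standard_normal((S, 3)) if config.shared_random_effects else None

    frames, truth_rows = [], []
    for ben, aud in CONDITIONS:
        cp = config.population.cells[(ben, aud)]
        z = shared_z if shared_z is not None else rng.standard_normal((S, 4))
        comp = np.asarray(cp.beta) + z * np.asarray(cp.tau)          # (S, 4)
        zr = shared_zr if shared_zr is not None else rng.standard_normal((S, 3))
        rat = np.asarray(cp.rating[:3]) + zr * np.asarray(cp.rating_tau)  # (S, 3)

        order = np.argsort(rng.random((S, T)), axis=1)               # per-subject shuffle
        Xo = X[order]                                                # (S, T, 3)
        eta = comp[:, [0]] + np.einsum("stk,sk->st", Xo, comp[:, 1:])
        if cp.beta_ad != 0.0:
            eta = eta + cp.beta_ad * AD[order]
        p_left = expit(eta)
        choice = (rng.random((S, T)) < p_left).astype(int)
        lo = np.where(rng.random((S, T)) < pL[order], xL[order], yL[order])
        ro = np.where(rng.random((S, T)) < pR[order], xR[order], yR[order])
        obtained = np.where(choice == 1, lo, ro)
        counterfactual = np.where(choice == 1, ro, lo)
        cx = np.where(choice == 1, xL[order], xR[order])
        cy = np.where(choice == 1, yL[order], yR[order])
        unobtained = np.where(obtained == cx, cy, cx)
        regret = counterfactual - obtained
        disappointment = unobtained - obtained
        value = (
            rat[:, [0]] + rat[:, [1]] * regret + rat[:, [2]] * disappointment
            + cp.rating[3] * rng.standard_normal((S, T))
        )
        rating = np.rint(value) if config.integer_ratings else value
        if config.clamp_ratings:
            rating = np.clip(rating, -50, 50)

        subj = np.repeat(np.arange(1, S + 1), T)
        frames.append(pd.DataFrame({
            "subject_id": subj,
            "pair_id": subj,
            "subject_role": "player",
            "beneficiary": ben,
            "audience": aud,
            "trial_index": np.tile(np.arange(1, T + 1), S),
            "xL": xL[order].ravel(), "yL": yL[order].ravel(), "pL": pL[order].ravel(),
            "xR": xR[order].ravel(), "yR": yR[order].ravel(), "pR": pR[order].ravel(),
            "choice": choice.ravel(),
            "obtained": obtained.ravel(),
            "counterfactual": counterfactual.ravel(),
            "rating": (rating.astype(int) if config.integer_ratings else rating).ravel(),
        }))
        for i in range(S):
            truth_rows.append({
                "subject_id": i + 1, "beneficiary": ben, "audience": aud,
                "const": comp[i, 0], "dEV": comp[i, 1], "dSD": comp[i, 2], "AR": comp[i, 3],
                "rating_const": rat[i, 0], "b_reg": rat[i, 1], "b_dis": rat[i, 2],
            })

    df = pd.concat(frames, ignore_index=True)
    provenance = {
        "generator": "regretchoice.simulate.simulate_dataset",
        "version": 1,
        "seed": config.seed,
        "config": _config_echo(config),
        "truth": pd.DataFrame(truth_rows),
    }
    return Dataset(df, provenance)


def _config_echo(config: SimulationConfig) -> dict:
    echo = asdict(config)
    echo["population"] = {
        f"{ben}/{aud}": asdict(config.population.cells[(ben, aud)])
        for ben, aud in CONDITIONS
    }
    return echo
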