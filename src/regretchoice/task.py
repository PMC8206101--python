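"""Wheel-of-Fortune gamble calculus.

A trial presents two lotteries ("wheels"), each with a better outcome ``x``,
a worse outcome ``y`` (``x > y``) and probability ``p`` of the better one.
Choice behaviour is modelled on three trial-level statistics:

* ``dEV``  — difference in expected value, ``EV_L - EV_R``;
* ``dSD``  — difference in outcome spread (risk), ``SD_R - SD_L``
  (note the orientation is reversed relative to ``dEV``);
* ``AR``   — anticipated regret, ``|y_R - x_L| - |y_L - x_R|``, contrasting
  the maximum possible regret of each option.

After both wheels stop, the post-outcome emotion factors are

* experienced regret          = counterfactual outcome − obtained outcome,
* experienced disappointment  = unobtained outcome of the *chosen* wheel
  − obtained outcome.

All quantities are in task points; the payoff rule converts points to GBP.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np

__all__ = [
    "Lottery",
    "TrialPair",
    "DecisionVariables",
    "TrialRecord",
    "expected_value",
    "lottery_sd",
    "decision_variables",
    "anticipated_disappointment",
    "spin",
    "experienced_regret",
    "experienced_disappointment",
    "points_to_gbp",
    "OUTCOME_ALPHABET",
    "PAYOFF_ANCHORS",
]

#: Outcome values used by the default stimulus generator (points).
OUTCOME_ALPHABET = (-200.0, -50.0, 50.0, 200.0)

#: Points -> GBP conversion anchors of the bonus payment rule.
PAYOFF_ANCHORS = ((-200.0, 0.0), (-50.0, 1.0), (50.0, 1.5), (200.0, 2.5))


class LotteryError(ValueError):
    """A lottery violates its invariants (x > y, 0 < p < 1)."""


@dataclass(frozen=True)
class Lottery:
    """One wheel: better outcome ``x``, worse outcome ``y``, P(x) = ``p``."""

    x: float
    y: float
    p: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.y) and math.isfinite(self.p)):
            raise LotteryError("lottery fields must be finite")
        if not self.x > self.y:
            raise LotteryError(f"invariant x > y violated: x={self.x}, y={self.y}")
        if not 0.0 < self.p < 1.0:
            raise LotteryError(f"invariant 0 < p < 1 violated: p={self.p}")

    @property
    def ev(self) -> float:
        return expected_value(self)

    @property
    def sd(self) -> float:
        return lottery_sd(self)

    def other(self, obtained: float) -> float:
        """The unobtained outcome, given that ``obtained`` came up."""
        if obtained == self.x:
            return self.y
        if obtained == self.y:
            return self.x
        raise LotteryError(f"{obtained} is not an outcome of {self}")


@dataclass(frozen=True)
class TrialPair:
    """Two lotteries plus the 2x2 social-context labels of a trial."""

    left: Lottery
    right: Lottery
    beneficiary: Literal["self", "partner"] = "self"
    audience: Literal["present", "absent"] = "absent"
    trial_index: int = 1

    def __post_init__(self) -> None:
        if self.beneficiary not in ("self", "partner"):
            raise ValueError(f"beneficiary must be 'self' or 'partner', got {self.beneficiary!r}")
        if self.audience not in ("present", "absent"):
            raise ValueError(f"audience must be 'present' or 'absent', got {self.audience!r}")
        if self.trial_index < 1:
            raise ValueError("trial_index must be >= 1")

    def swapped(self) -> "TrialPair":
        """The same trial with left and right wheels exchanged."""
        return TrialPair(self.right, self.left, self.beneficiary, self.audience, self.trial_index)


@dataclass(frozen=True)
class DecisionVariables:
    """The three pre-choice regressors of a trial (points)."""

    dEV: float
    dSD: float
    AR: float


@dataclass(frozen=True)
class TrialRecord:
    """A completed trial: choice, both realised outcomes, emotion factors, rating.

    ``choice`` is 1 for the left wheel and 0 for the right wheel.  ``rating``
    is the post-outcome feeling report on the [-50, 50] axis, or ``None`` if
    the response window lapsed.
    """

    pair: TrialPair
    choice: int
    obtained: float
    counterfactual: float
    rating: int | None = None

    def __post_init__(self) -> None:
        if self.choice not in (0, 1):
            raise ValueError("choice must be 1 (left) or 0 (right)")
        chosen = self.chosen
        if self.obtained not in (chosen.x, chosen.y):
            raise ValueError("obtained outcome is not an outcome of the chosen lottery")
        unchosen = self.unchosen
        if self.counterfactual not in (unchosen.x, unchosen.y):
            raise ValueError("counterfactual outcome is not an outcome of the unchosen lottery")
        if self.rating is not None and not -50 <= self.rating <= 50:
            raise ValueError("rating must lie in [-50, 50]")

    @property
    def chosen(self) -> Lottery:
        return self.pair.left if self.choice == 1 else self.pair.right

    @property
    def unchosen(self) -> Lottery:
        return self.pair.right if self.choice == 1 else self.pair.left

    @property
    def experienced_regret(self) -> float:
        return experienced_regret(self.obtained, self.counterfactual)

    @property
    def experienced_disappointment(self) -> float:
        return experienced_disappointment(self.chosen, self.obtained)


def expected_value(lottery: Lottery) -> float:
    """EV = p·x + (1 − p)·y."""
    return lottery.p * lottery.x + (1.0 - lottery.p) * lottery.y


def lottery_sd(lottery: Lottery) -> float:
    """Probability-weighted outcome standard deviation of one wheel.

    SD = sqrt(p (x − EV)² + (1 − p) (y − EV)²); strictly positive because
    x > y and 0 < p < 1.
    """
    ev = expected_value(lottery)
    return math.sqrt(
        lottery.p * (lottery.x - ev) ** 2 + (1.0 - lottery.p) * (lottery.y - ev) ** 2
    )


def decision_variables(pair: TrialPair) -> DecisionVariables:
    """Compute (dEV, dSD, AR) for a trial.

    dEV = EV_L − EV_R;  dSD = SD_R − SD_L;  AR = |y_R − x_L| − |y_L − x_R|.
    All three are exactly 0 for identical wheels and are negated when the
    wheels are swapped.
    """
    left, right = pair.left, pair.right
    dev = expected_value(left) - expected_value(right)
    dsd = lottery_sd(right) - lottery_sd(left)
    ar = abs(right.y - left.x) - abs(left.y - right.x)
    return DecisionVariables(dEV=dev, dSD=dsd, AR=ar)


def anticipated_disappointment(pair: TrialPair) -> float:
    """Difference in each wheel's maximum possible experienced disappointment.

    AD = (x_L − y_L) − (x_R − y_R).  Used only as the optional extra choice
    regressor in BIC model comparison; it is not part of the default model.
    """
    return (pair.left.x - pair.left.y) - (pair.right.x - pair.right.y)


def spin(lottery: Lottery, rng: np.random.Generator) -> float:
    """Spin one wheel: returns ``x`` with probability ``p``, else ``y``."""
    return lottery.x if rng.random() < lottery.p else lottery.y


def experienced_regret(obtained: float, counterfactual: float) -> float:
    """Counterfactual outcome minus obtained outcome.

    Positive values are regret (the other wheel did better), negative values
    rejoicing.
    """
    if not (math.isfinite(obtained) and math.isfinite(counterfactual)):
        raise ValueError("outcomes must be finite")
    return counterfactual - obtained


def experienced_disappointment(chosen: Lottery, obtained: float) -> float:
    """Unobtained minus obtained outcome of the *chosen* wheel."""
    return chosen.other(obtained) - obtained


def points_to_gbp(points: float) -> float:
    """Convert a trial outcome in points to GBP under the bonus payment rule.

    Exact at the four anchor outcomes (−200 → 0, −50 → 1.0, 50 → 1.5,
    200 → 2.5); piecewise-linear between adjacent anchors, hence monotone
    non-decreasing on [−200, 200].  The anchors are not collinear, so a
    single global line cannot reproduce all four printed conversions.
    """
    pts = np.asarray([a for a, _ in PAYOFF_ANCHORS])
    gbp = np.asarray([g for _, g in PAYOFF_ANCHORS])
    if not pts[0] <= points <= pts[-1]:
        raise ValueError(f"points {points} outside the payable range [{pts[0]}, {pts[-1]}]")
    return float(np.interp(points, pts, gbp))
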