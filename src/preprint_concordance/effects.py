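"""Risk-ratio effect estimates reconstructed from per-arm 2x2 counts.

The effect measure is the risk ratio RR = (a/n1) / (c/n2), where a and c are
event counts and n1, n2 the numbers analyzed in the intervention and control
arms. The confidence interval is the Wald interval on the log scale,

    log RR  +/-  z_{1-alpha/2} * sqrt(1/a - 1/n1 + 1/c - 1/n2).

When exactly one of a, c is zero, 0.5 is added to all four cells of the 2x2
table (so each denominator becomes n + 1) before computing the estimate — the
conventional continuity correction of meta-analysis tooling. When both event
counts are zero the risk ratio is not estimable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Optional

from scipy.stats import norm

from .data_model import Outcome, OutcomeReport

__all__ = [
    "EffectEstimate",
    "Direction",
    "NotEstimableError",
    "risk_ratio",
    "direction",
    "is_significant",
]


class NotEstimableError(ValueError):
    """Direction/significance requested on an inestimable effect."""


class Direction(str, Enum):
    FAVORS_INTERVENTION = "favors_intervention"
    FAVORS_CONTROL = "favors_control"
    NULL = "null"


@dataclass(frozen=True)
class EffectEstimate:
    """A ratio-scale effect with its confidence interval.

    ``corrected`` records whether the 0.5 continuity correction was applied;
    for double-zero tables ``estimable`` is False and the numeric fields are
    absent (None).
    """

    outcome: Outcome
    measure: str = "risk_ratio"
    point: Optional[float] = None
    ci_low: Optional[float] = None
    ci_high: Optional[float] = None
    log_se: Optional[float] = None
    estimable: bool = True
    corrected: bool = False

    def __post_init__(self) -> None:
        if self.estimable:
            if self.point is None or self.ci_low is None or self.ci_high is None:
                raise ValueError("estimable effect requires point and interval")
            if not (0 < self.ci_low <= self.point <= self.ci_high):
                raise ValueError(
                    f"interval ({self.ci_low}, {self.ci_high}) does not bracket "
                    f"point {self.point}"
                )
        else:
            if any(v is not None for v in (self.point, self.ci_low, self.ci_high, self.log_se)):
                raise ValueError("inestimable effect must carry no point or interval")


def risk_ratio(report: OutcomeReport, alpha: float = 0.05) -> EffectEstimate:
    """Risk ratio with a two-sided (1 - alpha) Wald log-scale interval."""
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    a = float(report.events_intervention)
    n1 = float(report.n_intervention)
    c = float(report.events_control)
    n2 = float(report.n_control)

    if a == 0 and c == 0:
        return EffectEstimate(outcome=report.outcome, estimable=False,
                              point=None, ci_low=None, ci_high=None, log_se=None)

    corrected = False
    if a == 0 or c == 0:
        # add 0.5 to all four cells: a, n1-a, c, n2-c
        a += 0.5
        c += 0.5
        n1 += 1.0
        n2 += 1.0
        corrected = True

    point = (a / n1) / (c / n2)
    log_se = math.sqrt(1.0 / a - 1.0 / n1 + 1.0 / c - 1.0 / n2)
    z = norm.ppf(1.0 - alpha / 2.0)
    log_point = math.log(point)
    ci_low = math.exp(log_point - z * log_se)
    ci_high = math.exp(log_point + z * log_se)
    # guard against floating error leaving the point a hair outside the interval
    ci_low = min(ci_low, point)
    ci_high = max(ci_high, point)
    return EffectEstimate(
        outcome=report.outcome,
        point=point,
        ci_low=ci_low,
        ci_high=ci_high,
        log_se=log_se,
        estimable=True,
        corrected=corrected,
    )


def direction(est: EffectEstimate) -> Direction:
    """Which arm the point estimate favors, given the outcome's polarity.

    For benefit-type outcomes (clinical improvement) a point above 1 favors
    the intervention; for harm-type outcomes (the other four) a point below 1
    does. A point of exactly 1 is directionless.
    """
    if not est.estimable:
        raise NotEstimableError("direction undefined for an inestimable effect")
    if est.point == 1.0:
        return Direction.NULL
    above = est.point > 1.0
    if est.outcome.is_benefit:
        return Direction.FAVORS_INTERVENTION if above else Direction.FAVORS_CONTROL
    return Direction.FAVORS_CONTROL if above else Direction.FAVORS_INTERVENTION


def is_significant(est: EffectEstimate) -> bool:
    """True iff the confidence interval excludes 1.

    An endpoint exactly equal to 1 counts as not significant (the closed
    interval contains 1) — a conservative boundary convention.
    """
    if not est.estimable:
        raise NotEstimableError("significance undefined for an inestimable effect")
    return est.ci_low > 1.0 or est.ci_high < 1.0
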