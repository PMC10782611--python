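"""Synthetic preprint-article cohorts with ground-truth injection logs.

The generator emulates the statistical structure the concordance analysis
assumes: each trial draws Table-1-like categorical characteristics, a subset
of the five critical outcomes, per-outcome arm sizes, a control-arm risk and
a true risk ratio, and binomial event counts per arm. The article report
starts as a verbatim copy of the preprint, then at most one injection per
outcome is applied with configured probabilities:

* event-count perturbation — one arm's event count is shifted by a strictly
  positive amount (Poisson(1) + 1), clamped to [0, n];
* denominator perturbation — one arm's number analyzed is shifted by a small
  integer, events re-clamped;
* deletion — the outcome is dropped from the article;
* addition — an outcome absent from the preprint is drawn fresh for the
  article;
* direction flip — the article's counts are resampled from the same binomial
  laws until the point estimate crosses 1 (bounded attempt budget; failures
  are logged and skipped so generation always terminates).

Every applied (or skipped) injection is recorded in an :class:`InjectionLog`
whose per-trial ground-truth flags let downstream classification be checked
trial by trial without any external data.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from datetime import date, timedelta
from fractions import Fraction
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .concordance import TrialConcordance
from .data_model import (
    Centers,
    DocType,
    DocumentReport,
    Funding,
    Income,
    Outcome,
    OutcomeReport,
    Registration,
    RiskOfBias,
    Setting,
    TrialPair,
)
from .effects import Direction, direction, risk_ratio

__all__ = [
    "SyntheticConfig",
    "InjectionRecord",
    "InjectionLog",
    "RecoveryReport",
    "generate_cohort",
    "recover_injection_rates",
    "expected_addition_rate",
    "make_discrepancy_cohort",
    "DEFAULT_CHARACTERISTIC_PROBS",
]


# Cohort characteristic distributions: proportions of a 109-trial reference
# cohort, so a default draw resembles a real preprint-article RCT cohort.
DEFAULT_CHARACTERISTIC_PROBS: dict[str, dict[str, float]] = {
    "registration": {
        Registration.PROSPECTIVE.value: 83 / 109,
        Registration.RETROSPECTIVE.value: 25 / 109,
        Registration.NOT_REPORTED.value: 1 / 109,
    },
    "funding": {
        Funding.INDUSTRY_MIXED.value: 65 / 109,
        Funding.PUBLIC.value: 34 / 109,
        Funding.OTHER.value: 10 / 109,
    },
    "centers": {
        Centers.SINGLE.value: 30 / 109,
        Centers.MULTICENTER.value: 79 / 109,
    },
    "setting": {
        Setting.HOSPITAL.value: 93 / 109,
        Setting.OUTPATIENT.value: 16 / 109,
    },
    "income": {
        Income.HIGH.value: 42 / 109,
        Income.LOW_MIDDLE.value: 49 / 109,
        Income.MIXED_LEVELS.value: 18 / 109,
    },
    "overall_rob": {
        RiskOfBias.LOW.value: 13 / 109,
        RiskOfBias.SOME_CONCERNS.value: 87 / 109,
        RiskOfBias.HIGH.value: 9 / 109,
    },
}

# How often each critical outcome tends to be reported in a treatment RCT:
# mortality and safety outcomes are near-ubiquitous, the clinical-progression
# scale less so.
DEFAULT_OUTCOME_INCLUSION_PROBS: dict[str, float] = {
    Outcome.MORTALITY_D28.value: 0.85,
    Outcome.SERIOUS_ADVERSE_EVENTS.value: 0.65,
    Outcome.ANY_ADVERSE_EVENTS.value: 0.60,
    Outcome.CLINICAL_IMPROVEMENT_D28.value: 0.55,
    Outcome.WHO_CPS_GE7_D28.value: 0.40,
}


@dataclass(frozen=True)
class SyntheticConfig:
    """Cohort size, outcome risks, and discrepancy-injection rates.

    Injection probabilities are per outcome. The defaults are calibrated so
    a default-size draw carries per-trial discrepancy rates near those of a
    real preprint-article RCT cohort (roughly 13% of trials with an outcome
    added, 6% deleted, 8% with a count change, ~1% with a direction flip)
    given the default outcome-inclusion probabilities.
    """

    n_trials: int = 109
    seed: int = 0
    characteristic_probs: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_CHARACTERISTIC_PROBS.items()}
    )
    outcome_inclusion_probs: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_OUTCOME_INCLUSION_PROBS)
    )
    control_risk_range: tuple[float, float] = (0.05, 0.40)
    true_rr_range: tuple[float, float] = (0.5, 1.6)
    arm_size_range: tuple[int, int] = (25, 250)
    p_perturb_events: float = 0.018
    p_perturb_n: float = 0.010
    p_add: float = 0.066
    p_delete: float = 0.0185
    p_flip: float = 0.003
    flip_attempts: int = 100

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        for name in ("p_perturb_events", "p_perturb_n", "p_add", "p_delete", "p_flip"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name}={p} outside [0, 1]")
        if self.p_perturb_events + self.p_perturb_n + self.p_delete + self.p_flip > 1.0:
            raise ValueError("per-outcome injection probabilities must sum to <= 1")
        lo, hi = self.control_risk_range
        if not (0.0 < lo <= hi < 1.0):
            raise ValueError("control_risk_range must lie within (0, 1)")
        lo, hi = self.true_rr_range
        if not (0.0 < lo <= hi):
            raise ValueError("true_rr_range must be positive and nonempty")
        lo, hi = self.arm_size_range
        if not (1 <= lo <= hi):
            raise ValueError("arm_size_range must be nonempty with lower bound >= 1")
        for char, probs in self.characteristic_probs.items():
            total = sum(probs.values())
            if not math.isclose(total, 1.0, rel_tol=0, abs_tol=1e-9):
                raise ValueError(f"characteristic_probs[{char!r}] sums to {total}, not 1")
        for code, p in self.outcome_inclusion_probs.items():
            Outcome(code)  # vocabulary check
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"outcome_inclusion_probs[{code!r}]={p} outside [0, 1]")

    @classmethod
    def from_json(cls, path) -> "SyntheticConfig":
        with open(path) as fh:
            raw = json.load(fh)
        for key in ("control_risk_range", "true_rr_range", "arm_size_range"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass(frozen=True)
class InjectionRecord:
    """What happened to one trial x outcome slot during generation."""

    trial_id: str
    outcome: str
    in_preprint: bool
    in_article: bool
    kind: str  # none | perturb_events | perturb_n | delete | add | flip | flip_failed


@dataclass(frozen=True)
class InjectionLog:
    """Complete per-trial, per-outcome record of applied perturbations."""

    records: tuple[InjectionRecord, ...]

    def trial_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.records:
            seen.setdefault(r.trial_id, None)
        return list(seen)

    def trial_flags(self) -> dict[str, dict[str, bool]]:
        """Ground-truth discrepancy flags per trial, recomputed from the log."""
        flags: dict[str, dict[str, bool]] = {}
        for r in self.records:
            f = flags.setdefault(r.trial_id, {
                "any_added": False, "any_deleted": False,
                "any_count_change": False, "any_flip": False,
            })
            if r.kind == "add":
                f["any_added"] = True
            elif r.kind == "delete":
                f["any_deleted"] = True
            elif r.kind in ("perturb_events", "perturb_n"):
                f["any_count_change"] = True
            elif r.kind == "flip":
                f["any_count_change"] = True  # a flip resamples counts
                f["any_flip"] = True
        for f in flags.values():
            f["consistent"] = not (f["any_added"] or f["any_deleted"] or f["any_count_change"])
        return flags

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([r.__dict__ for r in self.records])

    def to_csv(self, path) -> Path:
        path = Path(path)
        self.to_frame().to_csv(path, index=False)
        return path


_OUTCOME_ORDER = tuple(Outcome)


def _draw_level(rng: np.random.Generator, probs: Mapping[str, float]) -> str:
    levels = sorted(probs)
    weights = np.array([probs[lv] for lv in levels], dtype=float)
    weights = weights / weights.sum()
    return str(rng.choice(levels, p=weights))


def _draw_arm_size(rng: np.random.Generator, lo: int, hi: int) -> int:
    # log-uniform arm sizes: small trials common, a right tail of large ones
    return int(round(math.exp(rng.uniform(math.log(lo), math.log(hi)))))


def _draw_outcome_report(rng: np.random.Generator, outcome: Outcome,
                         config: SyntheticConfig) -> tuple[OutcomeReport, float, float]:
    lo, hi = config.arm_size_range
    n1 = _draw_arm_size(rng, lo, hi)
    n2 = _draw_arm_size(rng, lo, hi)
    p_ctrl = rng.uniform(*config.control_risk_range)
    rr = math.exp(rng.uniform(math.log(config.true_rr_range[0]),
                              math.log(config.true_rr_range[1])))
    p_int = min(rr * p_ctrl, 1.0)
    report = OutcomeReport(
        outcome=outcome,
        events_intervention=int(rng.binomial(n1, p_int)),
        n_intervention=n1,
        events_control=int(rng.binomial(n2, p_ctrl)),
        n_control=n2,
    )
    return report, p_int, p_ctrl


def _perturb_events(rng: np.random.Generator, rep: OutcomeReport) -> OutcomeReport:
    arm = "intervention" if rng.uniform() < 0.5 else "control"
    e = getattr(rep, f"events_{arm}")
    n = getattr(rep, f"n_{arm}")
    delta = int(rng.poisson(1.0)) + 1
    sign = 1 if rng.uniform() < 0.5 else -1
    new = min(max(e + sign * delta, 0), n)
    if new == e:  # clamped back onto the original value; push the other way
        new = min(max(e - sign * delta, 0), n)
    kwargs = {f"events_{arm}": new}
    from dataclasses import replace
    return replace(rep, **kwargs)


def _perturb_n(rng: np.random.Generator, rep: OutcomeReport) -> OutcomeReport:
    arm = "intervention" if rng.uniform() < 0.5 else "control"
    n = getattr(rep, f"n_{arm}")
    e = getattr(rep, f"events_{arm}")
    delta = int(rng.integers(1, 6))
    sign = 1 if rng.uniform() < 0.5 else -1
    new_n = n + sign * delta
    if new_n < 1:
        new_n = n + delta
    from dataclasses import replace
    return replace(rep, **{f"n_{arm}": new_n, f"events_{arm}": min(e, new_n)})


def _attempt_flip(rng: np.random.Generator, rep: OutcomeReport,
                  p_int: float, p_ctrl: float,
                  attempts: int) -> Optional[OutcomeReport]:
    """Resample article counts until the point estimate crosses 1, or give up."""
    base_est = risk_ratio(rep)
    if not base_est.estimable or base_est.point == 1.0:
        return None
    base_dir = direction(base_est)
    from dataclasses import replace
    for _ in range(attempts):
        candidate = replace(
            rep,
            events_intervention=int(rng.binomial(rep.n_intervention, p_int)),
            events_control=int(rng.binomial(rep.n_control, p_ctrl)),
        )
        est = risk_ratio(candidate)
        if not est.estimable or est.point == 1.0:
            continue
        if direction(est) is not base_dir and direction(est) is not Direction.NULL:
            return candidate
    return None


def generate_cohort(config: SyntheticConfig) -> tuple[list[TrialPair], InjectionLog]:
    """Generate a cohort of trial pairs plus its ground-truth injection log.

    All randomness flows from ``config.seed``; the same config yields a
    byte-identical cohort and log.
    """
    rng = np.random.default_rng(config.seed)
    pandemic_start = date(2020, 3, 1)
    pairs: list[TrialPair] = []
    records: list[InjectionRecord] = []

    for i in range(config.n_trials):
        trial_id = f"T{i:04d}"
        characteristics = {
            char: _draw_level(rng, probs)
            for char, probs in sorted(config.characteristic_probs.items())
        }
        preprint_date = pandemic_start + timedelta(days=int(rng.integers(0, 760)))
        delay = max(0, int(round(rng.lognormal(math.log(121.0), 0.65))))
        article_date = preprint_date + timedelta(days=delay)

        # reported outcome set; redraw if empty (a trial reports >= 1 outcome)
        included: list[Outcome] = []
        for _ in range(1000):
            included = [
                o for o in _OUTCOME_ORDER
                if rng.uniform() < config.outcome_inclusion_probs.get(o.value, 0.0)
            ]
            if included:
                break
        if not included:
            included = [Outcome.MORTALITY_D28]

        preprint_outcomes: dict[Outcome, OutcomeReport] = {}
        binomial_params: dict[Outcome, tuple[float, float]] = {}
        for outcome in included:
            rep, p_int, p_ctrl = _draw_outcome_report(rng, outcome, config)
            preprint_outcomes[outcome] = rep
            binomial_params[outcome] = (p_int, p_ctrl)

        article_outcomes: dict[Outcome, OutcomeReport] = dict(preprint_outcomes)

        # at most one injection per outcome slot
        thresholds = np.cumsum([
            config.p_perturb_events, config.p_perturb_n,
            config.p_delete, config.p_flip,
        ])
        for outcome in _OUTCOME_ORDER:
            if outcome in preprint_outcomes:
                u = rng.uniform()
                kind = "none"
                if u < thresholds[0]:
                    article_outcomes[outcome] = _perturb_events(rng, preprint_outcomes[outcome])
                    kind = "perturb_events"
                elif u < thresholds[1]:
                    article_outcomes[outcome] = _perturb_n(rng, preprint_outcomes[outcome])
                    kind = "perturb_n"
                elif u < thresholds[2]:
                    del article_outcomes[outcome]
                    kind = "delete"
                elif u < thresholds[3]:
                    p_int, p_ctrl = binomial_params[outcome]
                    flipped = _attempt_flip(rng, preprint_outcomes[outcome],
                                            p_int, p_ctrl, config.flip_attempts)
                    if flipped is not None:
                        article_outcomes[outcome] = flipped
                        kind = "flip"
                    else:
                        kind = "flip_failed"
                records.append(InjectionRecord(
                    trial_id=trial_id, outcome=outcome.value,
                    in_preprint=True, in_article=kind != "delete", kind=kind,
                ))
            else:
                if rng.uniform() < config.p_add:
                    rep, _, _ = _draw_outcome_report(rng, outcome, config)
                    article_outcomes[outcome] = rep
                    records.append(InjectionRecord(
                        trial_id=trial_id, outcome=outcome.value,
                        in_preprint=False, in_article=True, kind="add",
                    ))
                else:
                    records.append(InjectionRecord(
                        trial_id=trial_id, outcome=outcome.value,
                        in_preprint=False, in_article=False, kind="none",
                    ))

        sample_size = max(r.n_intervention + r.n_control for r in preprint_outcomes.values())
        pairs.append(TrialPair(
            trial_id=trial_id,
            preprint=DocumentReport(DocType.PREPRINT, date_online=preprint_date,
                                    outcomes=preprint_outcomes),
            article=DocumentReport(DocType.ARTICLE, date_online=article_date,
                                   outcomes=article_outcomes),
            sample_size=sample_size,
            registration=characteristics["registration"],
            funding=characteristics["funding"],
            centers=characteristics["centers"],
            setting=characteristics["setting"],
            income=characteristics["income"],
            overall_rob=characteristics["overall_rob"],
        ))

    return pairs, InjectionLog(records=tuple(records))


# ---------------------------------------------------------------------------
# Parameter recovery
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RecoveryReport:
    """Detected vs ground-truth discrepancy rates on a generated cohort."""

    n_trials: int
    detected_rates: Mapping[str, float]
    truth_rates: Mapping[str, float]
    agreement: Mapping[str, float]  # fraction of trials where flags agree

    @property
    def exact_agreement(self) -> bool:
        return all(v == 1.0 for v in self.agreement.values())


def recover_injection_rates(
    classifications: Sequence[TrialConcordance], log: InjectionLog
) -> RecoveryReport:
    """Compare pipeline-detected flags with the generator's ground truth.

    Exact trial-by-trial agreement is expected for count perturbations,
    additions, and deletions; direction flips are detected whenever both
    estimates are estimable (the generator only logs a flip after verifying
    both sides, so agreement should also be exact there).
    """
    truth = log.trial_flags()
    by_id = {c.trial_id: c for c in classifications}
    if set(by_id) != set(truth):
        raise ValueError("classification trial ids do not match the injection log")

    flag_pairs = {
        "any_added": lambda c, t: (c.any_added, t["any_added"]),
        "any_deleted": lambda c, t: (c.any_deleted, t["any_deleted"]),
        "any_count_change": lambda c, t: (c.any_estimate_change, t["any_count_change"]),
        "direction_change": lambda c, t: (c.any_direction_change, t["any_flip"]),
        "consistent": lambda c, t: (c.consistent, t["consistent"]),
    }
    n = len(truth)
    detected: dict[str, float] = {}
    truth_rates: dict[str, float] = {}
    agreement: dict[str, float] = {}
    for name, get in flag_pairs.items():
        pairs = [get(by_id[tid], t) for tid, t in truth.items()]
        detected[name] = sum(d for d, _ in pairs) / n
        truth_rates[name] = sum(t for _, t in pairs) / n
        agreement[name] = sum(d == t for d, t in pairs) / n
    return RecoveryReport(
        n_trials=n,
        detected_rates=detected,
        truth_rates=truth_rates,
        agreement=agreement,
    )


def expected_addition_rate(log: InjectionLog, p_add: float) -> float:
    """Exact per-trial probability of >= 1 added outcome, given the drawn
    preprint outcome sets: mean over trials of 1 - (1-p_add)^k where k is
    the number of vocabulary outcomes absent from that trial's preprint."""
    absent: dict[str, int] = {}
    for r in log.records:
        absent.setdefault(r.trial_id, 0)
        if not r.in_preprint:
            absent[r.trial_id] += 1
    probs = [1.0 - (1.0 - p_add) ** k for k in absent.values()]
    return float(np.mean(probs))


# ---------------------------------------------------------------------------
# Deterministic fixture cohort with an exact discrepancy composition
# ---------------------------------------------------------------------------

def _exact_level_assignment(n: int, proportions: Mapping[str, float]) -> list[str]:
    """Level labels for n trials hitting the proportions exactly (largest
    remainder apportionment)."""
    fracs = {lv: Fraction(p).limit_denominator(10**6) * n for lv, p in proportions.items()}
    base = {lv: int(f) for lv, f in fracs.items()}
    remainder = n - sum(base.values())
    by_frac = sorted(fracs, key=lambda lv: (fracs[lv] - base[lv], lv), reverse=True)
    for lv in by_frac[:remainder]:
        base[lv] += 1
    out: list[str] = []
    for lv in sorted(base):
        out.extend([lv] * base[lv])
    return out


def make_discrepancy_cohort(
    n_consistent: int = 81,
    n_added_only: int = 13,
    n_deleted_only: int = 6,
    n_estimate_only: int = 7,
    n_direction_change: int = 1,
    n_added_and_estimate: int = 1,
) -> list[TrialPair]:
    """Hand-specified cohort with an exact discrepancy composition.

    The defaults build a 109-trial cohort in which 14 trials have an outcome
    added in the article, 6 have one deleted, 9 carry a count change in a
    matched outcome (one of which is also among the added trials, and one of
    which flips the direction of effect), and the remaining 81 are consistent
    for all outcomes. No significance or conclusion changes are present.
    Characteristic levels are apportioned to match a realistic cohort's
    marginal frequencies exactly. Fully deterministic; no randomness.
    """
    n_total = (n_consistent + n_added_only + n_deleted_only
               + n_estimate_only + n_direction_change + n_added_and_estimate)

    levels = {
        char: _exact_level_assignment(n_total, probs)
        for char, probs in DEFAULT_CHARACTERISTIC_PROBS.items()
    }

    base_mortality = OutcomeReport(Outcome.MORTALITY_D28, 10, 100, 12, 100)
    base_sae = OutcomeReport(Outcome.SERIOUS_ADVERSE_EVENTS, 5, 80, 6, 80)
    added_ae = OutcomeReport(Outcome.ANY_ADVERSE_EVENTS, 20, 100, 18, 100)
    # one event more in the intervention arm: a count change that moves the
    # point estimate (0.83 -> 0.92) without changing direction or significance
    bumped_mortality = OutcomeReport(Outcome.MORTALITY_D28, 11, 100, 12, 100)
    # a sign-crossing pair: RR 0.8 in the preprint, RR 1.2 in the article,
    # both with wide CIs containing 1 (so significance does not change)
    flip_pre = OutcomeReport(Outcome.MORTALITY_D28, 8, 100, 10, 100)
    flip_art = OutcomeReport(Outcome.MORTALITY_D28, 12, 100, 10, 100)

    kinds = (
        ["consistent"] * n_consistent
        + ["added"] * n_added_only
        + ["deleted"] * n_deleted_only
        + ["estimate"] * n_estimate_only
        + ["direction"] * n_direction_change
        + ["added_and_estimate"] * n_added_and_estimate
    )

    pairs: list[TrialPair] = []
    for i, kind in enumerate(kinds):
        pre_outcomes = {
            Outcome.MORTALITY_D28: base_mortality,
            Outcome.SERIOUS_ADVERSE_EVENTS: base_sae,
        }
        art_outcomes = dict(pre_outcomes)
        if kind == "added":
            art_outcomes[Outcome.ANY_ADVERSE_EVENTS] = added_ae
        elif kind == "deleted":
            del art_outcomes[Outcome.SERIOUS_ADVERSE_EVENTS]
        elif kind == "estimate":
            art_outcomes[Outcome.MORTALITY_D28] = bumped_mortality
        elif kind == "direction":
            pre_outcomes = dict(pre_outcomes)
            pre_outcomes[Outcome.MORTALITY_D28] = flip_pre
            art_outcomes = dict(pre_outcomes)
            art_outcomes[Outcome.MORTALITY_D28] = flip_art
        elif kind == "added_and_estimate":
            art_outcomes[Outcome.MORTALITY_D28] = bumped_mortality
            art_outcomes[Outcome.ANY_ADVERSE_EVENTS] = added_ae

        preprint_date = date(2020, 4, 1) + timedelta(days=(i * 11) % 700)
        article_date = preprint_date + timedelta(days=60 + (i * 13) % 200)
        pairs.append(TrialPair(
            trial_id=f"F{i:04d}",
            preprint=DocumentReport(DocType.PREPRINT, date_online=preprint_date,
                                    outcomes=pre_outcomes),
            article=DocumentReport(DocType.ARTICLE, date_online=article_date,
                                   outcomes=art_outcomes),
            sample_size=60 + (i * 17) % 500,
            registration=levels["registration"][i],
            funding=levels["funding"][i],
            centers=levels["centers"][i],
            setting=levels["setting"][i],
            income=levels["income"][i],
            overall_rob=levels["overall_rob"][i],
        ))
    return pairs
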