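"""Outcome matching and discrepancy classification between document versions.

For each trial, outcomes reported in the preprint and in the article are
matched by the closed five-outcome vocabulary. Matched outcomes are compared
on event counts, numbers analyzed, and the reconstructed risk ratios;
unmatched outcomes are classified as added in, or deleted from, the journal
article. Trial-level discrepancies follow a four-class taxonomy:

1. change in the effect estimate of at least one outcome — operationalized as
   any change in the per-arm event counts or numbers analyzed of a matched
   outcome (the continuous article/preprint point-estimate ratio is reported
   alongside for magnitude inspection but does not gate the flag);
2. change in the direction of the effect;
3. change in statistical significance (the CI crossing 1 or not);
4. change in the overall conclusion — an extracted annotation when present,
   otherwise a documented heuristic (direction AND significance both changed).

A trial is *consistent* when no outcome was added or deleted and every
matched outcome has identical counts in both documents.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Optional, Sequence

import pandas as pd

from .data_model import DocumentReport, Outcome, OutcomeReport, TrialPair
from .effects import EffectEstimate, direction, is_significant, risk_ratio

__all__ = [
    "MatchStatus",
    "OutcomePairComparison",
    "TrialConcordance",
    "match_outcomes",
    "compare_outcome",
    "classify_trial",
    "tally",
    "classification_frame",
    "concordance_report",
    "TALLY_KEYS",
]


class MatchStatus(str, Enum):
    MATCHED = "matched"
    ADDED_IN_ARTICLE = "added_in_article"
    DELETED_IN_ARTICLE = "deleted_in_article"


@dataclass(frozen=True)
class OutcomePairComparison:
    """Comparison of one outcome across the two documents of a trial."""

    outcome: Outcome
    status: MatchStatus
    events_changed: bool = False
    n_changed: bool = False
    preprint_estimate: Optional[EffectEstimate] = None
    article_estimate: Optional[EffectEstimate] = None
    estimate_ratio: Optional[float] = None
    direction_changed: bool = False
    significance_changed: bool = False


@dataclass(frozen=True)
class TrialConcordance:
    """Trial-level discrepancy flags aggregated over outcome comparisons."""

    trial_id: str
    comparisons: tuple[OutcomePairComparison, ...]
    consistent: bool
    any_estimate_change: bool
    any_direction_change: bool
    any_significance_change: bool
    conclusion_change: bool
    any_added: bool
    any_deleted: bool


def compare_outcome(pre: OutcomeReport, art: OutcomeReport,
                    alpha: float = 0.05) -> OutcomePairComparison:
    """Compare one matched outcome's counts and estimates across documents.

    Direction and significance changes are only assessed when both sides are
    estimable; a double-zero table on either side suppresses those flags
    (count discrepancies remain detectable).
    """
    if pre.outcome is not art.outcome:
        raise ValueError(
            f"cannot compare different outcomes: {pre.outcome.value} vs {art.outcome.value}"
        )
    events_changed = (pre.events_intervention != art.events_intervention
                      or pre.events_control != art.events_control)
    n_changed = (pre.n_intervention != art.n_intervention
                 or pre.n_control != art.n_control)
    pre_est = risk_ratio(pre, alpha)
    art_est = risk_ratio(art, alpha)
    if pre_est.estimable and art_est.estimable:
        estimate_ratio = art_est.point / pre_est.point
        direction_changed = direction(pre_est) is not direction(art_est)
        significance_changed = is_significant(pre_est) != is_significant(art_est)
    else:
        estimate_ratio = None
        direction_changed = False
        significance_changed = False
    return OutcomePairComparison(
        outcome=pre.outcome,
        status=MatchStatus.MATCHED,
        events_changed=events_changed,
        n_changed=n_changed,
        preprint_estimate=pre_est,
        article_estimate=art_est,
        estimate_ratio=estimate_ratio,
        direction_changed=direction_changed,
        significance_changed=significance_changed,
    )


def match_outcomes(preprint: DocumentReport, article: DocumentReport,
                   alpha: float = 0.05) -> list[OutcomePairComparison]:
    """One comparison per outcome present in either document.

    Set membership decides the status: present in both -> matched; article
    only -> added; preprint only -> deleted. Conservation holds by
    construction: |matched| + |deleted| = |preprint| and
    |matched| + |added| = |article|.
    """
    pre_set = set(preprint.outcomes)
    art_set = set(article.outcomes)
    comparisons: list[OutcomePairComparison] = []
    for outcome in sorted(pre_set | art_set, key=lambda o: o.value):
        if outcome in pre_set and outcome in art_set:
            comparisons.append(
                compare_outcome(preprint.outcomes[outcome], article.outcomes[outcome], alpha)
            )
        elif outcome in art_set:
            comparisons.append(OutcomePairComparison(
                outcome=outcome,
                status=MatchStatus.ADDED_IN_ARTICLE,
                article_estimate=risk_ratio(article.outcomes[outcome], alpha),
            ))
        else:
            comparisons.append(OutcomePairComparison(
                outcome=outcome,
                status=MatchStatus.DELETED_IN_ARTICLE,
                preprint_estimate=risk_ratio(preprint.outcomes[outcome], alpha),
            ))
    return comparisons


def classify_trial(pair: TrialPair, alpha: float = 0.05) -> TrialConcordance:
    """Aggregate outcome comparisons into the trial-level taxonomy flags."""
    comparisons = match_outcomes(pair.preprint, pair.article, alpha)
    matched = [c for c in comparisons if c.status is MatchStatus.MATCHED]
    any_added = any(c.status is MatchStatus.ADDED_IN_ARTICLE for c in comparisons)
    any_deleted = any(c.status is MatchStatus.DELETED_IN_ARTICLE for c in comparisons)
    any_estimate_change = any(c.events_changed or c.n_changed for c in matched)
    any_direction_change = any(c.direction_changed for c in matched)
    any_significance_change = any(c.significance_changed for c in matched)
    consistent = not (any_added or any_deleted or any_estimate_change)
    if pair.conclusion_change_annotation is not None:
        conclusion_change = pair.conclusion_change_annotation
    else:
        conclusion_change = any_direction_change and any_significance_change
    return TrialConcordance(
        trial_id=pair.trial_id,
        comparisons=tuple(comparisons),
        consistent=consistent,
        any_estimate_change=any_estimate_change,
        any_direction_change=any_direction_change,
        any_significance_change=any_significance_change,
        conclusion_change=conclusion_change,
        any_added=any_added,
        any_deleted=any_deleted,
    )


TALLY_KEYS = (
    "total", "consistent", "estimate_change", "direction_change",
    "significance_change", "conclusion_change", "any_added", "any_deleted",
    "added_or_deleted",
)


def tally(classifications: Sequence[TrialConcordance]) -> dict[str, int]:
    """Cohort-level counts of trials carrying each discrepancy flag.

    Strata overlap (a trial may carry several flags); ``consistent`` equals
    the total minus the size of the union of the non-consistent flags.
    """
    return {
        "total": len(classifications),
        "consistent": sum(c.consistent for c in classifications),
        "estimate_change": sum(c.any_estimate_change for c in classifications),
        "direction_change": sum(c.any_direction_change for c in classifications),
        "significance_change": sum(c.any_significance_change for c in classifications),
        "conclusion_change": sum(c.conclusion_change for c in classifications),
        "any_added": sum(c.any_added for c in classifications),
        "any_deleted": sum(c.any_deleted for c in classifications),
        "added_or_deleted": sum(c.any_added or c.any_deleted for c in classifications),
    }


def classification_frame(classifications: Sequence[TrialConcordance]) -> pd.DataFrame:
    """Flat per-trial classification table (one row per trial)."""
    return pd.DataFrame([
        {
            "trial_id": c.trial_id,
            "consistent": c.consistent,
            "any_estimate_change": c.any_estimate_change,
            "any_direction_change": c.any_direction_change,
            "any_significance_change": c.any_significance_change,
            "conclusion_change": c.conclusion_change,
            "any_added": c.any_added,
            "any_deleted": c.any_deleted,
            "n_outcomes_compared": len(c.comparisons),
        }
        for c in classifications
    ])


def concordance_report(
    trials: Sequence[TrialPair], alpha: float = 0.05
) -> tuple[list[TrialConcordance], pd.DataFrame, dict[str, int]]:
    """Classify a cohort: per-trial records, a flat table, and cohort tallies."""
    if not trials:
        raise ValueError("concordance_report requires at least one trial")
    classifications = [classify_trial(t, alpha) for t in trials]
    return classifications, classification_frame(classifications), tally(classifications)
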