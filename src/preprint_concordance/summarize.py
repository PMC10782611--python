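"""Flow accounting and Table-1-style cohort characteristics summaries.

Categorical characteristics are summarized as frequencies with integer
percentages (half-up rounding); continuous ones (sample size, preprint-to-
publication delay) as medians with interquartile ranges, using linear
interpolation between order statistics at fractional position (n-1)*p.

The characteristics table is reported for four (non-exclusive) strata: the
whole cohort, trials consistent for all outcomes, trials with at least one
outcome added or deleted in the article, and trials with a change in the
effect estimate. A trial may appear in both of the last two strata, so the
summary never forces a partition.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from datetime import date
from typing import Callable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .concordance import TrialConcordance
from .data_model import (
    Centers,
    FlowCounts,
    Funding,
    Income,
    Registration,
    RiskOfBias,
    Setting,
    TrialPair,
    VocabularyError,
    publication_delay_days,
)

__all__ = [
    "CohortSummary",
    "median_iqr",
    "frequency_table",
    "characteristics_table",
    "flow_account",
    "render_flow",
    "preprint_period",
    "PERIOD_LEVELS",
    "CHARACTERISTIC_VOCABULARIES",
]

# Pandemic start used as the origin for the preprint-post period buckets.
PANDEMIC_START = date(2020, 3, 1)
_PERIOD_6MO = date(2020, 9, 1)
_PERIOD_12MO = date(2021, 3, 1)
PERIOD_LEVELS = ("lt_6_months", "6_to_12_months", "gt_12_months")


def preprint_period(pair: TrialPair) -> str:
    """Bucket the preprint post date relative to March 2020.

    Buckets close at the exact 6- and 12-month calendar boundaries
    (2020-09-01 and 2021-03-01), left-inclusive.
    """
    d = pair.preprint.best_date
    if d < _PERIOD_6MO:
        return PERIOD_LEVELS[0]
    if d < _PERIOD_12MO:
        return PERIOD_LEVELS[1]
    return PERIOD_LEVELS[2]


CHARACTERISTIC_VOCABULARIES: dict[str, tuple[str, ...]] = {
    "registration": tuple(m.value for m in Registration),
    "funding": tuple(m.value for m in Funding),
    "centers": tuple(m.value for m in Centers),
    "overall_rob": tuple(m.value for m in RiskOfBias),
    "setting": tuple(m.value for m in Setting),
    "income": tuple(m.value for m in Income),
    "preprint_period": PERIOD_LEVELS,
}

_SELECTORS: dict[str, Callable[[TrialPair], str]] = {
    "registration": lambda t: t.registration.value,
    "funding": lambda t: t.funding.value,
    "centers": lambda t: t.centers.value,
    "overall_rob": lambda t: t.overall_rob.value,
    "setting": lambda t: t.setting.value,
    "income": lambda t: t.income.value,
    "preprint_period": preprint_period,
}


def round_half_up(x: float) -> int:
    """Round a nonnegative value to the nearest integer, ties away from zero."""
    return int(math.floor(x + 0.5))


def median_iqr(values: Sequence[float]) -> tuple[float, float, float]:
    """Median and quartiles (q1, q3) by linear interpolation at (n-1)*p."""
    if len(values) == 0:
        raise ValueError("median_iqr requires at least one value")
    arr = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("median_iqr requires finite values")
    med, q1, q3 = np.quantile(arr, [0.5, 0.25, 0.75], method="linear")
    return float(med), float(q1), float(q3)


def frequency_table(
    trials: Sequence[TrialPair], characteristic: str
) -> dict[str, tuple[int, int]]:
    """Per-level (count, integer percent) over a characteristic's vocabulary.

    Percent = count / total * 100, rounded half-up — the convention that
    reproduces integer percentage columns of cohort tables.
    """
    if not trials:
        raise ValueError("frequency_table requires at least one trial")
    if characteristic not in CHARACTERISTIC_VOCABULARIES:
        raise VocabularyError(
            f"unknown characteristic {characteristic!r}; expected one of "
            f"{sorted(CHARACTERISTIC_VOCABULARIES)}"
        )
    vocab = CHARACTERISTIC_VOCABULARIES[characteristic]
    select = _SELECTORS[characteristic]
    counts = {level: 0 for level in vocab}
    for trial in trials:
        level = select(trial)
        if level not in counts:
            raise VocabularyError(
                f"trial {trial.trial_id}: {characteristic} value {level!r} "
                f"outside vocabulary {vocab}"
            )
        counts[level] += 1
    total = len(trials)
    return {
        level: (count, round_half_up(count / total * 100.0))
        for level, count in counts.items()
    }


STRATA = ("all", "consistent", "added_or_deleted", "estimate_change")


@dataclass(frozen=True)
class CohortSummary:
    """Characteristics summary across the (possibly overlapping) strata.

    ``rows`` maps a row key (e.g. ``"registration:prospective"`` or
    ``"sample_size"``) to a per-stratum cell: ``(count, percent)`` for
    categorical rows, ``(median, q1, q3)`` for continuous ones, or None for
    an empty stratum.
    """

    strata_sizes: Mapping[str, int]
    rows: Mapping[str, Mapping[str, Optional[tuple]]]

    def to_frame(self) -> pd.DataFrame:
        def fmt(cell) -> str:
            if cell is None:
                return ""
            if len(cell) == 2:
                return f"{cell[0]} ({cell[1]})"
            med, q1, q3 = cell
            return f"{med:g} ({q1:g}-{q3:g})"

        data = {"characteristic": list(self.rows)}
        for stratum in STRATA:
            header = f"{stratum} (n={self.strata_sizes[stratum]})"
            data[header] = [fmt(cells[stratum]) for cells in self.rows.values()]
        return pd.DataFrame(data)

    def to_text(self) -> str:
        return self.to_frame().to_string(index=False)

    def to_json(self) -> str:
        return json.dumps(
            {
                "strata_sizes": dict(self.strata_sizes),
                "rows": {k: {s: (list(c) if c is not None else None)
                             for s, c in cells.items()}
                         for k, cells in self.rows.items()},
            },
            indent=2,
        )


def characteristics_table(
    trials: Sequence[TrialPair], classifications: Sequence[TrialConcordance]
) -> CohortSummary:
    """Build the stratified cohort characteristics summary.

    ``classifications`` must cover exactly the trial set (same ids, same
    order not required).
    """
    trial_ids = {t.trial_id for t in trials}
    class_ids = {c.trial_id for c in classifications}
    if trial_ids != class_ids or len(trials) != len(classifications):
        raise ValueError("classifications must cover exactly the trial set")
    by_id = {c.trial_id: c for c in classifications}

    strata_members: dict[str, list[TrialPair]] = {
        "all": list(trials),
        "consistent": [t for t in trials if by_id[t.trial_id].consistent],
        "added_or_deleted": [
            t for t in trials
            if by_id[t.trial_id].any_added or by_id[t.trial_id].any_deleted
        ],
        "estimate_change": [t for t in trials if by_id[t.trial_id].any_estimate_change],
    }
    strata_sizes = {s: len(members) for s, members in strata_members.items()}

    rows: dict[str, dict[str, Optional[tuple]]] = {}

    def continuous_row(key: str, getter: Callable[[TrialPair], float]) -> None:
        cells: dict[str, Optional[tuple]] = {}
        for stratum, members in strata_members.items():
            if members:
                cells[stratum] = median_iqr([getter(t) for t in members])
            else:
                cells[stratum] = None
        rows[key] = cells

    continuous_row("sample_size", lambda t: float(t.sample_size))
    continuous_row("delay_days", lambda t: float(publication_delay_days(t)))

    for characteristic, vocab in CHARACTERISTIC_VOCABULARIES.items():
        per_stratum: dict[str, Optional[dict]] = {}
        for stratum, members in strata_members.items():
            per_stratum[stratum] = (
                frequency_table(members, characteristic) if members else None
            )
        for level in vocab:
            cells = {
                stratum: (table[level] if table is not None else None)
                for stratum, table in per_stratum.items()
            }
            rows[f"{characteristic}:{level}"] = cells

    return CohortSummary(strata_sizes=strata_sizes, rows=rows)


def flow_account(identified: int, exclusions: Mapping[str, int]) -> FlowCounts:
    """Cohort flow accounting: included = identified - sum of exclusions."""
    return FlowCounts(identified=identified, exclusions=exclusions)


def render_flow(flow: FlowCounts) -> str:
    """Plain-text flow summary listing each exclusion reason."""
    lines = [f"identified: {flow.identified}"]
    for reason, count in flow.exclusions.items():
        lines.append(f"  excluded ({reason}): {count}")
    lines.append(f"total excluded: {flow.total_excluded}")
    lines.append(f"included: {flow.included}")
    return "\n".join(lines)
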