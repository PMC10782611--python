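"""Domain types and tabular IO for preprint-article trial pairs.

A *trial pair* is one randomized controlled trial (RCT) together with two
document reports of its results: the first preprint and the subsequent
peer-reviewed journal article. Each document reports, for a closed vocabulary
of five critical outcomes, the number of participants with outcome events and
the number analyzed, per arm (intervention vs. control). Trial-level
characteristics (registration timing, funding, centers, setting, income
classification of the trial countries, overall risk of bias, sample size,
publication dates) are carried alongside for cohort summaries.

Records round-trip through two plain CSV tables inside a directory:

* ``trials.csv`` — one row per trial with its characteristics and dates;
* ``outcomes.csv`` — long format, one row per trial x document x outcome with
  the per-arm 2x2 counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from datetime import date
from enum import Enum
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd

__all__ = [
    "Outcome",
    "DocType",
    "Registration",
    "Funding",
    "Centers",
    "Setting",
    "Income",
    "RiskOfBias",
    "OutcomeReport",
    "DocumentReport",
    "TrialPair",
    "FlowCounts",
    "ValidationError",
    "SchemaError",
    "DomainError",
    "VocabularyError",
    "MissingDateError",
    "NegativeDelayWarning",
    "SCHEMA_VERSION",
    "read_trial_pairs",
    "write_trial_pairs",
    "publication_delay_days",
]

SCHEMA_VERSION = "v1"


# ---------------------------------------------------------------------------
# Errors
# ---------------------------------------------------------------------------

class ValidationError(ValueError):
    """Base class for record validation failures."""


class SchemaError(ValidationError):
    """The file does not conform to the documented tabular schema."""


class DomainError(ValidationError):
    """A value violates a domain invariant (e.g. events > n)."""


class VocabularyError(ValidationError):
    """A categorical value is outside its closed vocabulary."""


class MissingDateError(DomainError):
    """A document carries no usable publication date."""


class NegativeDelayWarning(UserWarning):
    """The article predates the preprint; the record is retained as-is."""


# ---------------------------------------------------------------------------
# Closed vocabularies
# ---------------------------------------------------------------------------

class Outcome(str, Enum):
    """The five critical binary outcomes tracked across both documents.

    ``benefit`` outcomes are ones where more events are better (a risk ratio
    above 1 favors the intervention); for the remaining harm-type outcomes a
    risk ratio below 1 favors the intervention.
    """

    CLINICAL_IMPROVEMENT_D28 = "clinical_improvement_d28"
    WHO_CPS_GE7_D28 = "who_cps_ge7_d28"
    MORTALITY_D28 = "mortality_d28"
    ANY_ADVERSE_EVENTS = "any_adverse_events"
    SERIOUS_ADVERSE_EVENTS = "serious_adverse_events"

    @property
    def label(self) -> str:
        return _OUTCOME_LABELS[self]

    @property
    def is_benefit(self) -> bool:
        return self is Outcome.CLINICAL_IMPROVEMENT_D28


_OUTCOME_LABELS: dict[Outcome, str] = {
    Outcome.CLINICAL_IMPROVEMENT_D28: "Clinical improvement (D28)",
    Outcome.WHO_CPS_GE7_D28: "WHO-CPS level 7 or above (D28)",
    Outcome.MORTALITY_D28: "All-cause mortality (D28)",
    Outcome.ANY_ADVERSE_EVENTS: "Any adverse events",
    Outcome.SERIOUS_ADVERSE_EVENTS: "Serious adverse events",
}


class DocType(str, Enum):
    PREPRINT = "preprint"
    ARTICLE = "article"


class Registration(str, Enum):
    PROSPECTIVE = "prospective"
    RETROSPECTIVE = "retrospective"
    NOT_REPORTED = "not_reported"


class Funding(str, Enum):
    INDUSTRY_MIXED = "industry_mixed"
    PUBLIC = "public"
    OTHER = "other"


class Centers(str, Enum):
    SINGLE = "single"
    MULTICENTER = "multicenter"


class Setting(str, Enum):
    HOSPITAL = "hospital"
    OUTPATIENT = "outpatient"


class Income(str, Enum):
    HIGH = "high"
    LOW_MIDDLE = "low_middle"
    MIXED_LEVELS = "mixed_levels"


class RiskOfBias(str, Enum):
    LOW = "low"
    SOME_CONCERNS = "some_concerns"
    HIGH = "high"


def _coerce_enum(enum_cls, value, context: str):
    try:
        return enum_cls(value)
    except ValueError:
        allowed = ", ".join(m.value for m in enum_cls)
        raise VocabularyError(
            f"{context}: {value!r} not in {{{allowed}}}"
        ) from None


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OutcomeReport:
    """Per-document 2x2 counts for one critical outcome.

    ``events_*`` is the number of participants with the outcome event and
    ``n_*`` the number analyzed in that arm.
    """

    outcome: Outcome
    events_intervention: int
    n_intervention: int
    events_control: int
    n_control: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "outcome", _coerce_enum(Outcome, self.outcome, "outcome"))
        for arm in ("intervention", "control"):
            e = getattr(self, f"events_{arm}")
            n = getattr(self, f"n_{arm}")
            if n < 1:
                raise DomainError(
                    f"{self.outcome.value}: n_{arm}={n} must be >= 1"
                )
            if not 0 <= e <= n:
                raise DomainError(
                    f"{self.outcome.value}: events_{arm}={e} outside [0, n_{arm}={n}]"
                )


@dataclass(frozen=True)
class DocumentReport:
    """One document's report: its type, dates, and reported outcomes."""

    doc_type: DocType
    date_online: Optional[date] = None
    date_print: Optional[date] = None
    outcomes: Mapping[Outcome, OutcomeReport] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "doc_type", _coerce_enum(DocType, self.doc_type, "doc_type"))
        if self.date_online is None and self.date_print is None:
            raise DomainError(f"{self.doc_type.value}: at least one publication date required")
        outcomes = dict(self.outcomes)
        for key, rep in outcomes.items():
            if Outcome(key) is not rep.outcome:
                raise DomainError(
                    f"{self.doc_type.value}: outcome key {key!r} does not match report "
                    f"outcome {rep.outcome.value!r}"
                )
        object.__setattr__(self, "outcomes", outcomes)

    @property
    def best_date(self) -> date:
        """Online publication date when available, otherwise print date."""
        d = self.date_online if self.date_online is not None else self.date_print
        assert d is not None  # enforced by __post_init__
        return d


@dataclass(frozen=True)
class TrialPair:
    """One RCT with its preprint and article reports plus characteristics."""

    trial_id: str
    preprint: DocumentReport
    article: DocumentReport
    sample_size: int
    registration: Registration
    funding: Funding
    centers: Centers
    setting: Setting
    income: Income
    overall_rob: RiskOfBias
    conclusion_change_annotation: Optional[bool] = None

    def __post_init__(self) -> None:
        if self.preprint.doc_type is not DocType.PREPRINT:
            raise DomainError(f"trial {self.trial_id}: preprint report has doc_type "
                              f"{self.preprint.doc_type.value}")
        if self.article.doc_type is not DocType.ARTICLE:
            raise DomainError(f"trial {self.trial_id}: article report has doc_type "
                              f"{self.article.doc_type.value}")
        if self.sample_size < 1:
            raise DomainError(f"trial {self.trial_id}: sample_size must be >= 1")
        for name, cls in (
            ("registration", Registration),
            ("funding", Funding),
            ("centers", Centers),
            ("setting", Setting),
            ("income", Income),
            ("overall_rob", RiskOfBias),
        ):
            object.__setattr__(
                self, name, _coerce_enum(cls, getattr(self, name), f"trial {self.trial_id}: {name}")
            )


@dataclass(frozen=True)
class FlowCounts:
    """Identification/exclusion accounting for the cohort flow diagram."""

    identified: int
    exclusions: Mapping[str, int]
    included: int = field(init=False)

    def __post_init__(self) -> None:
        if self.identified < 0:
            raise DomainError("identified must be >= 0")
        exclusions = dict(self.exclusions)
        for reason, count in exclusions.items():
            if count < 0:
                raise DomainError(f"exclusion {reason!r} has negative count {count}")
        total_excluded = sum(exclusions.values())
        if total_excluded > self.identified:
            raise DomainError(
                f"exclusions total {total_excluded} exceeds identified {self.identified}"
            )
        object.__setattr__(self, "exclusions", exclusions)
        object.__setattr__(self, "included", self.identified - total_excluded)

    @property
    def total_excluded(self) -> int:
        return sum(self.exclusions.values())


# ---------------------------------------------------------------------------
# Publication delay
# ---------------------------------------------------------------------------

def publication_delay_days(pair: TrialPair) -> int:
    """Delay from preprint post to journal publication in whole civil days.

    For each document independently, the online publication date is preferred
    and the print date is the fallback. A negative delay (article predating
    the preprint) is unusual but retained and reported as-is with a
    :class:`NegativeDelayWarning`.
    """
    try:
        pre_date = pair.preprint.best_date
        art_date = pair.article.best_date
    except AssertionError:  # pragma: no cover - unreachable on valid records
        raise MissingDateError(f"trial {pair.trial_id}: document without a date")
    delay = (art_date - pre_date).days
    if delay < 0:
        warnings.warn(
            f"trial {pair.trial_id}: article date {art_date} precedes preprint "
            f"date {pre_date} (delay {delay} days)",
            NegativeDelayWarning,
            stacklevel=2,
        )
    return delay


# ---------------------------------------------------------------------------
# Tabular IO
# ---------------------------------------------------------------------------

_TRIAL_COLUMNS = [
    "trial_id", "sample_size", "registration", "funding", "centers",
    "setting", "income", "overall_rob",
    "preprint_date_online", "preprint_date_print",
    "article_date_online", "article_date_print",
    "conclusion_change",
]
_OUTCOME_COLUMNS = [
    "trial_id", "doc_type", "outcome_code",
    "events_intervention", "n_intervention", "events_control", "n_control",
]

TRIALS_FILE = "trials.csv"
OUTCOMES_FILE = "outcomes.csv"


def _parse_date(value, context: str) -> Optional[date]:
    if value is None or (isinstance(value, float) and pd.isna(value)) or value == "":
        return None
    try:
        return date.fromisoformat(str(value))
    except ValueError:
        raise SchemaError(f"{context}: {value!r} is not an ISO-8601 date") from None


def _parse_count(value, context: str) -> int:
    try:
        out = int(value)
    except (TypeError, ValueError):
        raise SchemaError(f"{context}: {value!r} is not an integer count") from None
    return out


def _parse_optional_bool(value) -> Optional[bool]:
    if value is None or value == "" or (isinstance(value, float) and pd.isna(value)):
        return None
    text = str(value).strip().lower()
    if text in {"true", "1", "yes"}:
        return True
    if text in {"false", "0", "no"}:
        return False
    raise SchemaError(f"conclusion_change: {value!r} is not a boolean")


def read_trial_pairs(path, schema_version: str = SCHEMA_VERSION) -> list[TrialPair]:
    """Read a cohort from ``<path>/trials.csv`` and ``<path>/outcomes.csv``.

    Every validation failure is reported with its file and row coordinates.
    """
    if schema_version != SCHEMA_VERSION:
        raise SchemaError(f"unsupported schema version {schema_version!r}")
    base = Path(path)
    trials_path = base / TRIALS_FILE
    outcomes_path = base / OUTCOMES_FILE
    for p in (trials_path, outcomes_path):
        if not p.exists():
            raise SchemaError(f"missing input file: {p}")

    trials_df = pd.read_csv(trials_path, dtype=str, keep_default_na=False)
    outcomes_df = pd.read_csv(outcomes_path, dtype=str, keep_default_na=False)
    for df, cols, name in (
        (trials_df, _TRIAL_COLUMNS, TRIALS_FILE),
        (outcomes_df, _OUTCOME_COLUMNS, OUTCOMES_FILE),
    ):
        missing = [c for c in cols if c not in df.columns]
        if missing:
            raise SchemaError(f"{name}: missing required columns {missing}")

    # Group outcome rows per trial and document.
    outcome_reports: dict[str, dict[DocType, dict[Outcome, OutcomeReport]]] = {}
    for i, row in enumerate(outcomes_df.itertuples(index=False), start=2):
        where = f"{OUTCOMES_FILE} row {i}"
        trial_id = row.trial_id
        doc_type = _coerce_enum(DocType, row.doc_type, where)
        outcome = _coerce_enum(Outcome, row.outcome_code, where)
        try:
            report = OutcomeReport(
                outcome=outcome,
                events_intervention=_parse_count(row.events_intervention, where),
                n_intervention=_parse_count(row.n_intervention, where),
                events_control=_parse_count(row.events_control, where),
                n_control=_parse_count(row.n_control, where),
            )
        except DomainError as exc:
            raise DomainError(f"{where} (trial {trial_id}): {exc}") from None
        by_doc = outcome_reports.setdefault(trial_id, {DocType.PREPRINT: {}, DocType.ARTICLE: {}})
        if outcome in by_doc[doc_type]:
            raise SchemaError(f"{where}: duplicate outcome {outcome.value} for trial "
                              f"{trial_id} {doc_type.value}")
        by_doc[doc_type][outcome] = report

    pairs: list[TrialPair] = []
    seen: set[str] = set()
    for i, row in enumerate(trials_df.itertuples(index=False), start=2):
        where = f"{TRIALS_FILE} row {i}"
        trial_id = row.trial_id
        if trial_id in seen:
            raise SchemaError(f"{where}: duplicate trial_id {trial_id!r}")
        seen.add(trial_id)
        docs = outcome_reports.get(trial_id, {DocType.PREPRINT: {}, DocType.ARTICLE: {}})
        try:
            preprint = DocumentReport(
                doc_type=DocType.PREPRINT,
                date_online=_parse_date(row.preprint_date_online, where),
                date_print=_parse_date(row.preprint_date_print, where),
                outcomes=docs[DocType.PREPRINT],
            )
            article = DocumentReport(
                doc_type=DocType.ARTICLE,
                date_online=_parse_date(row.article_date_online, where),
                date_print=_parse_date(row.article_date_print, where),
                outcomes=docs[DocType.ARTICLE],
            )
            pairs.append(TrialPair(
                trial_id=trial_id,
                preprint=preprint,
                article=article,
                sample_size=_parse_count(row.sample_size, where),
                registration=row.registration,
                funding=row.funding,
                centers=row.centers,
                setting=row.setting,
                income=row.income,
                overall_rob=row.overall_rob,
                conclusion_change_annotation=_parse_optional_bool(row.conclusion_change),
            ))
        except ValidationError as exc:
            raise type(exc)(f"{where}: {exc}") from None

    unmatched = set(outcome_reports) - seen
    if unmatched:
        raise SchemaError(
            f"{OUTCOMES_FILE}: outcome rows for trials absent from {TRIALS_FILE}: "
            f"{sorted(unmatched)}"
        )
    return pairs


def _date_str(d: Optional[date]) -> str:
    return d.isoformat() if d is not None else ""


def write_trial_pairs(pairs: Sequence[TrialPair], path) -> Path:
    """Write a cohort to ``<path>/trials.csv`` + ``<path>/outcomes.csv``.

    Emits the same schema accepted by :func:`read_trial_pairs`, so that
    read-after-write reproduces the records field by field.
    """
    base = Path(path)
    base.mkdir(parents=True, exist_ok=True)
    trial_rows = []
    outcome_rows = []
    for pair in pairs:
        cc = pair.conclusion_change_annotation
        trial_rows.append({
            "trial_id": pair.trial_id,
            "sample_size": pair.sample_size,
            "registration": pair.registration.value,
            "funding": pair.funding.value,
            "centers": pair.centers.value,
            "setting": pair.setting.value,
            "income": pair.income.value,
            "overall_rob": pair.overall_rob.value,
            "preprint_date_online": _date_str(pair.preprint.date_online),
            "preprint_date_print": _date_str(pair.preprint.date_print),
            "article_date_online": _date_str(pair.article.date_online),
            "article_date_print": _date_str(pair.article.date_print),
            "conclusion_change": "" if cc is None else str(cc).lower(),
        })
        for doc in (pair.preprint, pair.article):
            for outcome in sorted(doc.outcomes, key=lambda o: o.value):
                rep = doc.outcomes[outcome]
                outcome_rows.append({
                    "trial_id": pair.trial_id,
                    "doc_type": doc.doc_type.value,
                    "outcome_code": outcome.value,
                    "events_intervention": rep.events_intervention,
                    "n_intervention": rep.n_intervention,
                    "events_control": rep.events_control,
                    "n_control": rep.n_control,
                })
    pd.DataFrame(trial_rows, columns=_TRIAL_COLUMNS).to_csv(base / TRIALS_FILE, index=False)
    pd.DataFrame(outcome_rows, columns=_OUTCOME_COLUMNS).to_csv(base / OUTCOMES_FILE, index=False)
    return base


def with_article_outcomes(pair: TrialPair, outcomes: Mapping[Outcome, OutcomeReport]) -> TrialPair:
    """Return a copy of ``pair`` whose article reports ``outcomes``."""
    return replace(pair, article=replace(pair.article, outcomes=dict(outcomes)))
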