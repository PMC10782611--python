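"""Shared fixtures and hypothesis strategies for cohort records."""

from __future__ import annotations

from datetime import date, timedelta

import pytest
from hypothesis import strategies as st

from preprint_concordance import (
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


@st.composite
def outcome_reports(draw, outcome=None):
    if outcome is None:
        outcome = draw(st.sampled_from(list(Outcome)))
    n1 = draw(st.integers(min_value=1, max_value=500))
    n2 = draw(st.integers(min_value=1, max_value=500))
    e1 = draw(st.integers(min_value=0, max_value=n1))
    e2 = draw(st.integers(min_value=0, max_value=n2))
    return OutcomeReport(outcome, e1, n1, e2, n2)


@st.composite
def document_reports(draw, doc_type: DocType):
    outcomes = draw(st.sets(st.sampled_from(list(Outcome)), min_size=0, max_size=5))
    reports = {o: draw(outcome_reports(outcome=o)) for o in outcomes}
    base = date(2020, 3, 1) + timedelta(days=draw(st.integers(0, 900)))
    has_online = draw(st.booleans())
    return DocumentReport(
        doc_type=doc_type,
        date_online=base if has_online else None,
        date_print=base + timedelta(days=draw(st.integers(0, 30)))
        if (not has_online or draw(st.booleans())) else None,
        outcomes=reports,
    )


@st.composite
def trial_pairs(draw, trial_id="T0"):
    return TrialPair(
        trial_id=trial_id,
        preprint=draw(document_reports(DocType.PREPRINT)),
        article=draw(document_reports(DocType.ARTICLE)),
        sample_size=draw(st.integers(1, 5000)),
        registration=draw(st.sampled_from(list(Registration))),
        funding=draw(st.sampled_from(list(Funding))),
        centers=draw(st.sampled_from(list(Centers))),
        setting=draw(st.sampled_from(list(Setting))),
        income=draw(st.sampled_from(list(Income))),
        overall_rob=draw(st.sampled_from(list(RiskOfBias))),
        conclusion_change_annotation=draw(st.sampled_from([None, True, False])),
    )


@st.composite
def cohorts(draw, max_size=8):
    n = draw(st.integers(min_value=1, max_value=max_size))
    return [draw(trial_pairs(trial_id=f"T{i:03d}")) for i in range(n)]


def simple_pair(trial_id="T0", pre_outcomes=None, art_outcomes=None, **overrides):
    """Hand-built trial pair with sensible defaults for unit tests."""
    if pre_outcomes is None:
        pre_outcomes = {
            Outcome.MORTALITY_D28: OutcomeReport(Outcome.MORTALITY_D28, 10, 100, 12, 100),
        }
    if art_outcomes is None:
        art_outcomes = dict(pre_outcomes)
    defaults = dict(
        trial_id=trial_id,
        preprint=DocumentReport(DocType.PREPRINT, date_online=date(2020, 6, 1),
                                outcomes=pre_outcomes),
        article=DocumentReport(DocType.ARTICLE, date_online=date(2020, 9, 30),
                               outcomes=art_outcomes),
        sample_size=200,
        registration=Registration.PROSPECTIVE,
        funding=Funding.PUBLIC,
        centers=Centers.MULTICENTER,
        setting=Setting.HOSPITAL,
        income=Income.HIGH,
        overall_rob=RiskOfBias.SOME_CONCERNS,
    )
    defaults.update(overrides)
    return TrialPair(**defaults)


@pytest.fixture
def two_trial_cohort():
    sae = {Outcome.SERIOUS_ADVERSE_EVENTS: OutcomeReport(
        Outcome.SERIOUS_ADVERSE_EVENTS, 3, 50, 4, 50)}
    return [
        simple_pair("T000"),
        simple_pair("T001", pre_outcomes=sae, art_outcomes=dict(sae)),
    ]
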