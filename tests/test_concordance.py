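"""Outcome matching, discrepancy flags, and cohort classification."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from preprint_concordance import (
    DocType,
    DocumentReport,
    MatchStatus,
    Outcome,
    OutcomeReport,
    classify_trial,
    compare_outcome,
    concordance_report,
    make_discrepancy_cohort,
    match_outcomes,
)
from conftest import simple_pair, trial_pairs
from datetime import date


def doc(doc_type, outcomes):
    return DocumentReport(doc_type, date_online=date(2020, 6, 1),
                          outcomes={o.outcome: o for o in outcomes})


def rep(outcome, e1=5, n1=50, e2=6, n2=50):
    return OutcomeReport(outcome, e1, n1, e2, n2)


class TestMatchOutcomes:
    def test_identical_sets_all_matched(self):
        reports = [rep(Outcome.MORTALITY_D28), rep(Outcome.SERIOUS_ADVERSE_EVENTS)]
        comps = match_outcomes(doc(DocType.PREPRINT, reports), doc(DocType.ARTICLE, reports))
        assert len(comps) == 2
        assert all(c.status is MatchStatus.MATCHED for c in comps)

    def test_article_only_outcome_is_added(self):
        pre = doc(DocType.PREPRINT, [rep(Outcome.MORTALITY_D28)])
        art = doc(DocType.ARTICLE, [rep(Outcome.MORTALITY_D28), rep(Outcome.ANY_ADVERSE_EVENTS)])
        comps = match_outcomes(pre, art)
        statuses = {c.outcome: c.status for c in comps}
        assert statuses[Outcome.MORTALITY_D28] is MatchStatus.MATCHED
        assert statuses[Outcome.ANY_ADVERSE_EVENTS] is MatchStatus.ADDED_IN_ARTICLE

    def test_empty_documents_give_empty_list(self):
        assert match_outcomes(doc(DocType.PREPRINT, []), doc(DocType.ARTICLE, [])) == []

    @settings(max_examples=100, deadline=None)
    @given(
        pre_set=st.sets(st.sampled_from(list(Outcome))),
        art_set=st.sets(st.sampled_from(list(Outcome))),
    )
    def test_conservation_under_matching(self, pre_set, art_set):
        pre = doc(DocType.PREPRINT, [rep(o) for o in pre_set])
        art = doc(DocType.ARTICLE, [rep(o) for o in art_set])
        comps = match_outcomes(pre, art)
        matched = sum(c.status is MatchStatus.MATCHED for c in comps)
        added = sum(c.status is MatchStatus.ADDED_IN_ARTICLE for c in comps)
        deleted = sum(c.status is MatchStatus.DELETED_IN_ARTICLE for c in comps)
        assert matched + deleted == len(pre_set)
        assert matched + added == len(art_set)
        assert len(comps) == len(pre_set | art_set)


class TestCompareOutcome:
    def test_identical_counts_no_flags(self):
        r = rep(Outcome.MORTALITY_D28, 10, 100, 10, 100)
        comp = compare_outcome(r, r)
        assert not comp.events_changed and not comp.n_changed
        assert not comp.direction_changed and not comp.significance_changed
        assert comp.estimate_ratio == pytest.approx(1.0)

    def test_event_bump_changes_ratio(self):
        pre = rep(Outcome.MORTALITY_D28, 10, 100, 10, 100)
        art = rep(Outcome.MORTALITY_D28, 11, 100, 10, 100)
        comp = compare_outcome(pre, art)
        assert comp.events_changed and not comp.n_changed
        assert comp.estimate_ratio == pytest.approx(1.1)

    def test_sign_crossing_points_flag_direction_change(self):
        pre = rep(Outcome.MORTALITY_D28, 8, 100, 10, 100)   # RR 0.8
        art = rep(Outcome.MORTALITY_D28, 12, 100, 10, 100)  # RR 1.2
        comp = compare_outcome(pre, art)
        assert comp.direction_changed
        assert not comp.significance_changed

    def test_inestimable_side_suppresses_predicates(self):
        pre = rep(Outcome.MORTALITY_D28, 0, 100, 0, 100)
        art = rep(Outcome.MORTALITY_D28, 3, 100, 1, 100)
        comp = compare_outcome(pre, art)
        assert comp.events_changed
        assert not comp.direction_changed and not comp.significance_changed
        assert comp.estimate_ratio is None

    def test_mismatched_outcomes_rejected(self):
        with pytest.raises(ValueError):
            compare_outcome(rep(Outcome.MORTALITY_D28), rep(Outcome.ANY_ADVERSE_EVENTS))


class TestClassifyTrial:
    def test_verbatim_copy_is_consistent(self):
        c = classify_trial(simple_pair())
        assert c.consistent
        assert not any([c.any_estimate_change, c.any_direction_change,
                        c.any_significance_change, c.conclusion_change,
                        c.any_added, c.any_deleted])

    def test_added_outcome_breaks_consistency_without_estimate_change(self):
        pre = {Outcome.MORTALITY_D28: rep(Outcome.MORTALITY_D28)}
        art = dict(pre)
        art[Outcome.ANY_ADVERSE_EVENTS] = rep(Outcome.ANY_ADVERSE_EVENTS)
        c = classify_trial(simple_pair(pre_outcomes=pre, art_outcomes=art))
        assert not c.consistent
        assert c.any_added and not c.any_estimate_change

    def test_annotation_overrides_conclusion_heuristic(self):
        c = classify_trial(simple_pair(conclusion_change_annotation=True))
        assert c.conclusion_change
        assert c.consistent  # annotation does not affect count consistency

    def test_flag_hierarchy(self):
        """Direction or significance changes imply an estimate change."""
        pre = {Outcome.MORTALITY_D28: rep(Outcome.MORTALITY_D28, 8, 100, 10, 100)}
        art = {Outcome.MORTALITY_D28: rep(Outcome.MORTALITY_D28, 12, 100, 10, 100)}
        c = classify_trial(simple_pair(pre_outcomes=pre, art_outcomes=art))
        assert c.any_direction_change
        assert c.any_estimate_change

    @settings(max_examples=50, deadline=None)
    @given(pair=trial_pairs())
    def test_self_comparison_idempotence(self, pair):
        """A trial whose article verbatim-copies its preprint is consistent."""
        from preprint_concordance.data_model import with_article_outcomes
        cloned = with_article_outcomes(pair, pair.preprint.outcomes)
        c = classify_trial(cloned)
        assert c.consistent
        assert not c.any_estimate_change

    @settings(max_examples=25, deadline=None)
    @given(pair=trial_pairs())
    def test_classification_deterministic(self, pair):
        assert classify_trial(pair) == classify_trial(pair)


class TestConcordanceReport:
    def test_identical_cohort_all_consistent(self):
        trials = [simple_pair(f"T{i}") for i in range(3)]
        _, table, tallies = concordance_report(trials)
        assert tallies["consistent"] == 3
        assert all(tallies[k] == 0 for k in
                   ("estimate_change", "direction_change", "significance_change",
                    "conclusion_change", "any_added", "any_deleted"))
        assert len(table) == 3

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            concordance_report([])

    def test_tallies_satisfy_inclusion_exclusion(self):
        trials = make_discrepancy_cohort()
        classifications, _, tallies = concordance_report(trials)
        union = sum(
            1 for c in classifications
            if c.any_added or c.any_deleted or c.any_estimate_change
        )
        assert tallies["consistent"] == tallies["total"] - union
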