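import random

import pytest

from trace_oracle import interleavings, oracle_verdict, random_small_db
from medlsc.engine import (
    DeadlockReport,
    Status,
    UnknownEvent,
    event_matches,
    init_states,
    monitor_trace,
    playout,
    step,
)
from medlsc.model import WILDCARD, Category, Chart, EntityRef, EventInstance, Role


def _pat(name, source, target, *args):
    return EventInstance(name, source, target, args)


class TestEventMatches:
    def test_wildcard_argument_matches_any_value(self, px_db):
        surgery = px_db.records[0].chart("Surgeries").body[0]
        pattern = EventInstance(
            "ReportSurgery", surgery.source, surgery.target, (WILDCARD, 1997)
        )
        assert event_matches(pattern, surgery, px_db.vocabulary)
        assert surgery.args == ("appendix Removal", 1997)

    def test_reflexive_on_identical_instances(self, px_db):
        ev = px_db.records[0].chart("Diseases").body[0]
        assert event_matches(ev, ev, px_db.vocabulary)

    def test_differing_target_role_does_not_match(self, px_db):
        ev = px_db.records[0].chart("Diseases").body[0]
        redirected = EventInstance(
            ev.name, ev.source, EntityRef(Role.RECORD, "patientX"), ev.args
        )
        assert not event_matches(ev, redirected, px_db.vocabulary)

    def test_ids_are_not_compared_across_patients(self, merged_db):
        # a pattern written against one patient matches another's record
        px_ev = merged_db.record("patientX").chart("Diseases").body[0]
        other = EventInstance(
            px_ev.name,
            EntityRef(Role.PATIENT, "someoneElse"),
            EntityRef(Role.DOCTOR, "drB"),
            px_ev.args,
        )
        assert event_matches(other, px_ev)

    def test_unknown_event_raises(self, px_db):
        ev = px_db.records[0].chart("Diseases").body[0]
        ghost = EventInstance("NoSuchEvent", ev.source, ev.target, ())
        with pytest.raises(UnknownEvent):
            event_matches(ghost, ev, px_db.vocabulary)


class TestStep:
    def test_development_completion_activates_treatment(self, syn_db):
        record = syn_db.records[0]
        states = init_states(record)
        assert states["Treatment"].status is Status.INACTIVE
        for ev in record.chart("Development").body:
            step(states, record, ev, syn_db.vocabulary)
        assert states["Development"].status is Status.COMPLETED
        # the diagnosis event switched execution to the Treatment chart
        assert states["Treatment"].status is Status.ACTIVE

    def test_out_of_order_body_violates_at_second_event(self, syn_db):
        record = syn_db.records[0]
        body = record.chart("Development").body
        swapped = (body[1], body[0]) + body[2:]
        verdict = monitor_trace(record, swapped, syn_db.vocabulary)
        assert verdict.states["Development"].status is Status.VIOLATED
        # flagged at the first out-of-order event (zero-based trace index 0)
        assert verdict.violations[0][:2] == (0, "Development")

    def test_foreign_event_leaves_all_states_unchanged(self, merged_db):
        record = merged_db.record("syntheticGutSurgeryCase")
        states = init_states(record)
        foreign = EventInstance(
            "Aleve",  # resolvable in the merged vocabulary, alien to both charts
            EntityRef(Role.DOCTOR, "doctor"),
            EntityRef(Role.RECORD, "syntheticGutSurgeryCase"),
        )
        before = {n: (s.status, s.cut) for n, s in states.items()}
        step(states, record, foreign, merged_db.vocabulary)
        assert {n: (s.status, s.cut) for n, s in states.items()} == before


class TestMonitorTrace:
    def test_playout_feeds_back_to_full_completion(self, px_db):
        record = px_db.records[0]
        trace = playout(record, px_db.vocabulary)
        verdict = monitor_trace(record, trace, px_db.vocabulary)
        assert verdict.violations == []
        assert all(s.status is Status.COMPLETED for s in verdict.states.values())

    def test_empty_trace_leaves_roots_active_at_cut_zero(self, px_db):
        record = px_db.records[0]
        verdict = monitor_trace(record, (), px_db.vocabulary)
        for name, st in verdict.states.items():
            if name == "DoctorInquiry":
                assert st.status is Status.ACTIVE and st.cut == 0
            else:
                assert st.status is Status.INACTIVE

    def test_missing_outcome_event_leaves_chart_active_at_cut_three(self, px_db):
        record = px_db.records[0]
        trace = playout(record, px_db.vocabulary)
        ineffective = record.chart("PastTreatmentIneffective").body[3]
        pruned = tuple(ev for ev in trace if ev != ineffective)
        assert len(pruned) == len(trace) - 1
        verdict = monitor_trace(record, pruned, px_db.vocabulary)
        state = verdict.states["PastTreatmentIneffective"]
        assert state.status is Status.ACTIVE and state.cut == 3
        # the treatment chain past the missing event never activates
        assert verdict.states["PastTreatmentNegativeEffect"].status is Status.INACTIVE

    def test_unknown_trace_event_raises_with_step_index(self, px_db):
        record = px_db.records[0]
        ghost = EventInstance(
            "Mystery",
            EntityRef(Role.PATIENT, "patientX"),
            EntityRef(Role.DOCTOR, "doctor"),
        )
        with pytest.raises(UnknownEvent, match="step 0"):
            monitor_trace(record, (ghost,), px_db.vocabulary)

    def test_cut_monotone_and_status_order_along_prefixes(self, px_db):
        record = px_db.records[0]
        trace = playout(record, px_db.vocabulary)
        rank = {
            Status.INACTIVE: 0,
            Status.ACTIVE: 1,
            Status.COMPLETED: 2,
            Status.VIOLATED: 2,
        }
        states = init_states(record)
        prev = {n: (s.status, s.cut) for n, s in states.items()}
        for ev in trace:
            step(states, record, ev, px_db.vocabulary)
            for name, st in states.items():
                p_status, p_cut = prev[name]
                assert st.cut >= p_cut
                assert rank[st.status] >= rank[p_status]
                if p_status in (Status.COMPLETED, Status.VIOLATED):
                    assert st.status is p_status
            prev = {n: (s.status, s.cut) for n, s in states.items()}


class TestPlayout:
    def test_synthetic_case_completes_development_before_treatment(self, syn_db):
        record = syn_db.records[0]
        trace = playout(record, syn_db.vocabulary)
        names = [ev.name for ev in trace]
        assert names.index("CFS") < names.index("DietModification")
        assert names[-1] == "reportImprovement"

    def test_single_one_event_chart(self):
        doctor = EntityRef(Role.DOCTOR, "d")
        patient = EntityRef(Role.PATIENT, "p")
        chart = Chart(
            "Solo",
            Category.DEVELOPMENT,
            frozenset({doctor, patient}),
            (_pat("EvA", doctor, patient, "x"),),
        )
        from medlsc.model import PatientRecord

        record = PatientRecord(patient, (chart,))
        assert len(playout(record)) == 1

    def test_trace_length_is_sum_of_reachable_bodies(self, px_db):
        from medlsc.model import chart_stats

        record = px_db.records[0]
        expected = int(chart_stats(record)["events"].sum())
        assert len(playout(record, px_db.vocabulary)) == expected

    def test_playout_is_deterministic(self, px_db, small_cohort):
        for db in (px_db, small_cohort):
            for record in db.records:
                assert playout(record, db.vocabulary) == playout(record, db.vocabulary)

    def test_conflicting_concurrent_charts_report_deadlock(self):
        # two simultaneously active charts demanding each other's later events
        doctor = EntityRef(Role.DOCTOR, "d")
        patient = EntityRef(Role.PATIENT, "p")
        lifelines = frozenset({doctor, patient})
        a = _pat("EvA", doctor, patient, "x")
        b = _pat("EvB", doctor, patient, "x")
        from medlsc.model import PatientRecord

        record = PatientRecord(
            patient,
            (
                Chart("C0", Category.DEVELOPMENT, lifelines, (a, b), activates=((0, "C1"),)),
                Chart("C1", Category.OTHER, lifelines, (b, a), standalone=True),
            ),
        )
        with pytest.raises(DeadlockReport):
            playout(record)


class TestOracleEquivalence:
    def test_engine_agrees_with_brute_force_on_small_records(self):
        rng = random.Random(2024)
        for _ in range(60):
            db = random_small_db(rng)
            record = db.records[0]
            for trace in interleavings(tuple(c.body for c in record.charts)):
                verdict = monitor_trace(record, trace, db.vocabulary)
                got = {n: (s.status.value, s.cut) for n, s in verdict.states.items()}
                assert got == oracle_verdict(record, trace)

    def test_generated_records_selfconsistent(self, small_cohort):
        for record in small_cohort.records:
            trace = playout(record, small_cohort.vocabulary)
            verdict = monitor_trace(record, trace, small_cohort.vocabulary)
            assert verdict.violations == []
            active = {
                n
                for n, s in verdict.states.items()
                if s.status in (Status.ACTIVE, Status.VIOLATED)
            }
            assert active == set()
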