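import dataclasses

import pytest
from hypothesis import given, settings, strategies as st

from medlsc.model import (
    ArityConflict,
    Category,
    Chart,
    EntityRef,
    EventDecl,
    EventInstance,
    EventKind,
    ParamSpec,
    PatientRecord,
    PType,
    Role,
    ScenarioDB,
    Vocabulary,
    chart_stats,
    ensure_event_decl,
    validate_record,
)


def test_entity_equality_is_role_and_id():
    a = EntityRef(Role.PATIENT, "patientX")
    assert a == EntityRef(Role.PATIENT, "patientX")
    assert a != EntityRef(Role.RECORD, "patientX")
    assert a != EntityRef(Role.PATIENT, "patientY")
    with pytest.raises(ValueError):
        EntityRef(Role.PATIENT, "")


def test_generic_event_requires_parameters():
    with pytest.raises(ValueError):
        EventDecl("Fatigue", EventKind.GENERIC, ())
    # names are closed identifiers; free text belongs in TEXT arguments
    with pytest.raises(ValueError):
        EventDecl("Shoulder Dislocation", EventKind.SPECIFIC, ())


class TestEnsureEventDecl:
    def test_first_report_registers_the_event(self):
        vocab = Vocabulary({})
        decl = EventDecl(
            "painInLeftArm", EventKind.GENERIC, (ParamSpec("year", PType.YEAR),)
        )
        vocab = ensure_event_decl(vocab, decl)
        assert len(vocab) == 1
        assert vocab.resolve("painInLeftArm") is decl

    def test_idempotent_for_identical_signature(self):
        decl = EventDecl(
            "ReportSurgery",
            EventKind.GENERIC,
            (ParamSpec("type", PType.TEXT), ParamSpec("year", PType.YEAR)),
        )
        vocab = ensure_event_decl(Vocabulary({}), decl)
        again = ensure_event_decl(vocab, decl)
        assert len(again) == 1
        assert again.decls == vocab.decls

    def test_signature_conflict_raises(self):
        vocab = ensure_event_decl(
            Vocabulary({}), EventDecl("Advair", EventKind.SPECIFIC, ())
        )
        with pytest.raises(ArityConflict):
            ensure_event_decl(
                vocab,
                EventDecl("Advair", EventKind.SPECIFIC, (ParamSpec("year", PType.YEAR),)),
            )

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.sampled_from("ABCD"), max_size=8))
    def test_growth_is_monotone(self, order):
        # every previously resolvable name keeps resolving to the same decl
        decls = {
            c: EventDecl(f"Ev{c}", EventKind.GENERIC, (ParamSpec("v", PType.TEXT),))
            for c in "ABCD"
        }
        vocab = Vocabulary({})
        seen: dict[str, EventDecl] = {}
        for c in order:
            vocab = ensure_event_decl(vocab, decls[c])
            seen[decls[c].name] = decls[c]
            for name, decl in seen.items():
                assert vocab.resolve(name) == decl


@pytest.fixture()
def px_record(px_db):
    return px_db.records[0]


class TestValidateRecord:
    def test_packaged_case_is_clean(self, px_db, px_record):
        assert validate_record(px_db, px_record) == []

    @staticmethod
    def _swap_chart(record, name, **changes):
        charts = []
        for c in record.charts:
            if c.name == name:
                c = dataclasses.replace(c, **changes)
            charts.append(c)
        return dataclasses.replace(record, charts=tuple(charts))

    def test_duration_below_ongoing_sentinel_is_flagged(self, px_db, px_record):
        diseases = px_record.chart("Diseases")
        bad = diseases.body[:1] + (
            dataclasses.replace(diseases.body[1], args=("Allergy", 6, -2)),
        )
        record = self._swap_chart(px_record, "Diseases", body=bad)
        issues = validate_record(px_db, record)
        assert [i.code for i in issues] == ["bad-arg-type"]
        assert issues[0].chart == "Diseases" and issues[0].event_index == 1

    def test_dangling_activation_is_flagged(self, px_db, px_record):
        inquiry = px_record.chart("DoctorInquiry")
        record = self._swap_chart(
            px_record,
            "DoctorInquiry",
            activates=inquiry.activates[:-1] + ((6, "NoSuchChart"),),
        )
        codes = {i.code for i in validate_record(px_db, record)}
        # the treatment chain also becomes unreachable from the root
        assert "dangling-activation" in codes

    @pytest.mark.parametrize(
        "corrupt, expected_code",
        [
            (lambda r: TestValidateRecord._swap_chart(r, "Surgeries", body=()), "empty-body"),
            (
                lambda r: TestValidateRecord._swap_chart(
                    r,
                    "Surgeries",
                    body=(
                        EventInstance(
                            "UndeclaredEvent",
                            next(iter(r.chart("Surgeries").body)).source,
                            next(iter(r.chart("Surgeries").body)).target,
                        ),
                    )
                    + r.chart("Surgeries").body[1:],
                ),
                "unknown-event",
            ),
            (
                lambda r: TestValidateRecord._swap_chart(
                    r,
                    "Surgeries",
                    body=(
                        dataclasses.replace(
                            r.chart("Surgeries").body[0], args=("appendix Removal",)
                        ),
                    )
                    + r.chart("Surgeries").body[1:],
                ),
                "arity-conflict",
            ),
            (
                lambda r: TestValidateRecord._swap_chart(
                    r, "Surgeries", activates=((5, "Diseases"),)
                ),
                "bad-activation-index",
            ),
            (
                lambda r: TestValidateRecord._swap_chart(
                    r, "Surgeries", category=Category.INQUIRY
                ),
                "root-count",
            ),
            (
                lambda r: TestValidateRecord._swap_chart(
                    r, "SuggestedTreatment", activates=((0, "DoctorInquiry"),)
                ),
                "activation-cycle",
            ),
            (
                lambda r: dataclasses.replace(
                    r, patient=EntityRef(Role.DOCTOR, "patientX")
                ),
                "bad-patient-role",
            ),
        ],
        ids=[
            "empty-body",
            "unknown-event",
            "arity-conflict",
            "bad-activation-index",
            "root-count",
            "activation-cycle",
            "bad-patient-role",
        ],
    )
    def test_single_field_corruptions_are_detected(
        self, px_db, px_record, corrupt, expected_code
    ):
        issues = validate_record(px_db, corrupt(px_record))
        assert expected_code in {i.code for i in issues}


class TestChartStats:
    def test_printed_event_counts(self, px_record):
        table = chart_stats(px_record).set_index("chart")
        assert table.loc["GeneralPersonalBackground", "events"] == 5
        assert table.loc["PsychiatryBackground", "events"] == 3
        assert table.loc["PsychiatryBackground", "distinct_decls"] == 1

    def test_totals_match_record(self, px_record):
        table = chart_stats(px_record)
        assert len(table) == len(px_record.charts)
        assert table["events"].sum() == sum(len(c.body) for c in px_record.charts)

    def test_empty_record_gives_empty_table(self):
        empty = PatientRecord(EntityRef(Role.PATIENT, "nobody"), ())
        table = chart_stats(empty)
        assert len(table) == 0
        assert list(table.columns) == ["chart", "category", "events", "distinct_decls"]
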