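"""Packaged interview cases and a seeded synthetic-cohort generator.

The two worked cases (the synthetic gut-surgery case and the patientX
admission interview) ship as `medlsc/1` documents under ``data/`` so the
codec is exercised on every load; :func:`patientx_db`, :func:`synthetic_db`
and :func:`paper_db` read them.  :func:`generate_cohort` produces arbitrary
numbers of additional records with configurable background-event rates and
treatment-outcome probabilities, as a scale surrogate for a future database
of interview narratives.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Optional

import numpy as np

from ..codec import parse_db
from ..model import (
    Category,
    Chart,
    EntityRef,
    EventDecl,
    EventInstance,
    PatientRecord,
    Role,
    ScenarioDB,
    Tag,
    Vocabulary,
    merge_vocabularies,
)
from ._sources import DOCTOR, patientx_vocabulary, synthetic_vocabulary

__all__ = [
    "CohortConfig",
    "ConfigError",
    "build_patientx",
    "build_synthetic_case",
    "default_pool",
    "generate_cohort",
    "paper_db",
    "patientx_db",
    "synthetic_db",
]


def _load_packaged(name: str) -> ScenarioDB:
    text = (resources.files(__package__) / "data" / name).read_text(encoding="utf-8")
    return parse_db(text, strict=True)


def patientx_db() -> ScenarioDB:
    """The packaged patientX admission-interview case."""
    return _load_packaged("patientx.medlsc.json")


def synthetic_db() -> ScenarioDB:
    """The packaged two-chart synthetic gut-surgery case."""
    return _load_packaged("synthetic_case.medlsc.json")


def paper_db() -> ScenarioDB:
    """Both packaged cases over a merged vocabulary."""
    x, s = patientx_db(), synthetic_db()
    return ScenarioDB(
        merge_vocabularies(x.vocabulary, s.vocabulary), x.records + s.records
    )


def build_patientx() -> PatientRecord:
    """The patientX admission interview, loaded from the packaged document
    so every access exercises the codec."""
    return patientx_db().records[0]


def build_synthetic_case() -> PatientRecord:
    """The two-chart synthetic gut-surgery case, loaded from the packaged
    document."""
    return synthetic_db().records[0]


class ConfigError(Exception):
    """Invalid cohort configuration."""


def default_pool() -> list[EventDecl]:
    """Default vocabulary pool for generated cohorts: the patientX
    vocabulary plus a few extra zero-parameter medicine events."""
    from ..model import EventKind

    extra = [
        EventDecl(n, EventKind.SPECIFIC, (), Tag.MEDICINE)
        for n in ("Probiotics", "Ibuprofen", "Melatonin")
    ]
    extra.append(EventDecl("reportImprovement", EventKind.SPECIFIC, (), Tag.OTHER))
    return list(patientx_vocabulary()) + extra


@dataclass
class CohortConfig:
    """Conditions of a generated cohort.

    Rates are per-record means of Poisson-distributed background counts;
    the three outcome probabilities select, per record, whether its one
    treatment chart records an ineffective, negative or improving course
    (any remainder: no treatment chart).
    """

    n_patients: int = 50
    seed: int = 0
    mean_diseases: float = 1.5
    mean_injuries: float = 1.0
    mean_surgeries: float = 0.8
    year_range: tuple[int, int] = (1980, 2010)
    p_ineffective: float = 0.25
    p_negative: float = 0.15
    p_improvement: float = 0.4
    pool: Optional[list[EventDecl]] = None

    def validate(self) -> None:
        probs = (self.p_ineffective, self.p_negative, self.p_improvement)
        if self.n_patients < 0:
            raise ConfigError("n_patients must be >= 0")
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ConfigError("outcome probabilities must lie in [0, 1]")
        if sum(probs) > 1.0 + 1e-12:
            raise ConfigError("outcome probabilities must sum to <= 1")
        if any(m < 0 for m in (self.mean_diseases, self.mean_injuries, self.mean_surgeries)):
            raise ConfigError("rates must be nonnegative")
        lo, hi = self.year_range
        if not (1900 <= lo <= hi <= 2100):
            raise ConfigError("year_range must satisfy 1900 <= min <= max <= 2100")


_DISEASES = ["Rinderpest", "Allergy", "Asthma", "Mononucleosis", "Migraine"]
_INJURY_CASES = ["Fall off bike", "Car accident", "Sports injury", "Fall downstairs"]
_INJURY_EFFECTS = ["Concussion", "Shoulder Dislocation", "Sprained Ankle", "Whiplash"]
_SURGERIES = ["appendix Removal", "Hemorrhoids", "Tonsillectomy", "Gallbladder Removal"]
_NEG_EFFECTS = ["Excessive Shaking", "Sweating", "Nausea", "Dizziness"]


def _duration(rng: np.random.Generator) -> int:
    # ~20% ongoing conditions; otherwise a short count of weeks
    return -1 if rng.random() < 0.2 else int(rng.integers(0, 52))


def _generate_record(
    idx: int, cfg: CohortConfig, rng: np.random.Generator, medicines: list[EventDecl]
) -> PatientRecord:
    pat = EntityRef(Role.PATIENT, f"synth{idx:04d}")
    rec = EntityRef(Role.RECORD, pat.id)
    lifelines = frozenset({DOCTOR, pat, rec})

    def dr(name: str, *args) -> EventInstance:
        return EventInstance(name, DOCTOR, rec, args)

    def pd_(name: str, *args) -> EventInstance:
        return EventInstance(name, pat, DOCTOR, args)

    def dp(name: str, *args) -> EventInstance:
        return EventInstance(name, DOCTOR, pat, args)

    lo, hi = cfg.year_range
    n_dis = int(rng.poisson(cfg.mean_diseases))
    n_inj = int(rng.poisson(cfg.mean_injuries))
    n_sur = int(rng.poisson(cfg.mean_surgeries))

    charts: list[Chart] = []
    sub: list[Chart] = []
    if n_dis:
        sub.append(
            Chart(
                "Diseases",
                Category.DISEASES,
                lifelines,
                tuple(
                    pd_(
                        "Disease",
                        str(rng.choice(_DISEASES)),
                        int(rng.integers(0, 60)),
                        _duration(rng),
                    )
                    for _ in range(n_dis)
                ),
            )
        )
    if n_inj:
        body: list[EventInstance] = []
        for _ in range(n_inj):
            body.append(pd_("ReportCase", str(rng.choice(_INJURY_CASES)), int(rng.integers(0, 60))))
            body.append(pd_("Injury", str(rng.choice(_INJURY_EFFECTS)), _duration(rng)))
        sub.append(Chart("Injuries", Category.INJURIES, lifelines, tuple(body)))
    if n_sur:
        sub.append(
            Chart(
                "Surgeries",
                Category.SURGERIES,
                lifelines,
                tuple(
                    pd_("ReportSurgery", str(rng.choice(_SURGERIES)), int(rng.integers(lo, hi + 1)))
                    for _ in range(n_sur)
                ),
            )
        )

    # treatment outcome: ineffective / negative / improvement / none
    outcome = rng.choice(
        4,
        p=[
            cfg.p_ineffective,
            cfg.p_negative,
            cfg.p_improvement,
            max(0.0, 1.0 - cfg.p_ineffective - cfg.p_negative - cfg.p_improvement),
        ],
    )
    treatment: Optional[Chart] = None
    if outcome < 3:
        med = dr(str(rng.choice([m.name for m in medicines])))
        if outcome == 0:
            treatment = Chart(
                "Treatment",
                Category.TREATMENT_PAST_INEFFECTIVE,
                lifelines,
                (med, dp("Prescription"), pd_("NoChange"), dr("Ineffective")),
            )
        elif outcome == 1:
            treatment = Chart(
                "Treatment",
                Category.TREATMENT_PAST_NEGATIVE,
                lifelines,
                (
                    med,
                    dp("Prescription"),
                    pd_("reportNegativeEffect"),
                    dr("NegativeEffect", str(rng.choice(_NEG_EFFECTS)), -1),
                ),
            )
        else:
            treatment = Chart(
                "Treatment",
                Category.TREATMENT,
                lifelines,
                (med, dp("Prescription"), pd_("reportImprovement")),
            )

    root_body = [dr("reportCase"), pd_("DoctorVisit"), dr("medicalBackground"), dr("CFS")]
    activates: list[tuple[int, str]] = []
    if sub:
        medical = Chart(
            "MedicalBackground",
            Category.MEDICAL_BACKGROUND,
            lifelines,
            tuple(dr(f"report{c.name}") for c in sub),
            activates=tuple((i, c.name) for i, c in enumerate(sub)),
        )
        activates.append((2, "MedicalBackground"))
        charts_after_root: list[Chart] = [medical, *sub]
    else:
        charts_after_root = []
    if treatment is not None:
        activates.append((3, "Treatment"))
        charts_after_root.append(treatment)

    root = Chart(
        "Inquiry",
        Category.INQUIRY,
        lifelines,
        tuple(root_body),
        activates=tuple(activates),
    )
    charts = [root, *charts_after_root]
    return PatientRecord(patient=pat, charts=tuple(charts), meta={"synthetic": "true"})


def generate_cohort(config: CohortConfig) -> ScenarioDB:
    """Generate a seeded synthetic cohort; identical config means an
    identical (byte-identical once serialized) database."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    pool = list(config.pool) if config.pool is not None else default_pool()
    vocab = Vocabulary({})
    from ..model import ensure_event_decl

    for decl in pool:
        vocab = ensure_event_decl(vocab, decl)
    medicines = [d for d in pool if d.tag is Tag.MEDICINE and d.arity == 0]
    if not medicines:
        raise ConfigError("vocabulary pool contains no zero-parameter MEDICINE event")
    records = tuple(
        _generate_record(i, config, rng, medicines) for i in range(config.n_patients)
    )
    return ScenarioDB(vocab, records)
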