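"""Cohort symptom-table ingestion, descriptive statistics and exclusions.

The cohort table has one row per patient with sex, enrollment age and
the age at onset (or a not-diagnosed marker) for the four cardinal
Wolfram-syndrome symptoms: diabetes mellitus (DM), diabetes insipidus
(DI), sensorineural hearing loss (HL) and optic atrophy (OA).  The
packaged ``wolfram_cohort.csv`` fixture transcribes the 40-patient
natural-history cohort this package's defaults are calibrated to.

Status tokens (case-insensitive): a number is the onset age in years;
``Normal`` means hearing confirmed normal by testing (HL only);
``Not Diagnosed`` / ``No dx`` mean the symptom has not been diagnosed.
All three exclude the patient from onset means; only ``Normal`` marks a
confirmed-normal denominator entry.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from importlib.resources import files

import numpy as np
import pandas as pd
from scipy import stats

from .audiometry import AudiogramSession, ValidationError

logger = logging.getLogger(__name__)

SYMPTOMS: tuple[str, ...] = ("DM", "DI", "HL", "OA")

_SYMPTOM_COLUMNS = {"DM": "dm_onset", "DI": "di_onset", "HL": "hl_onset", "OA": "oa_onset"}
_MISSING_TOKENS = {"normal": "normal", "not diagnosed": "not_diagnosed", "no dx": "no_dx"}

#: Mixed-model input is truncated at this session index (later visits are
#: too sparse to support inference).
MAX_ANALYZED_SESSION: int = 5


@dataclass(frozen=True)
class SymptomStatus:
    """Diagnosis status of one symptom for one patient."""

    symptom: str
    status: str  # "diagnosed" | "normal" | "not_diagnosed" | "no_dx"
    onset_age: float | None = None

    def __post_init__(self) -> None:
        if self.symptom not in SYMPTOMS:
            raise ValidationError(f"unknown symptom {self.symptom!r}")
        if (self.status == "diagnosed") != (self.onset_age is not None):
            raise ValidationError("onset_age present iff status is 'diagnosed'")
        if self.onset_age is not None and self.onset_age < 0:
            raise ValidationError("onset_age must be non-negative")

    @property
    def diagnosed(self) -> bool:
        return self.status == "diagnosed"


@dataclass
class PatientRecord:
    """One patient's demographic and symptom-onset summary."""

    patient_id: str
    sex: str
    enrollment_age: float
    statuses: dict[str, SymptomStatus]
    sibship_id: str | None = None
    cochlear_implant: bool = False
    n_sessions: int = 0

    def __post_init__(self) -> None:
        if self.sex not in ("M", "F"):
            raise ValidationError(f"{self.patient_id}: sex must be M or F")
        if self.cochlear_implant and self.n_sessions > 0:
            raise ValidationError(
                f"{self.patient_id}: cochlear-implant patients have no analyzable sessions"
            )

    def status(self, symptom: str) -> SymptomStatus:
        return self.statuses[symptom]

    @property
    def has_snhl(self) -> bool:
        """Diagnosed sensorineural hearing loss (implant users count)."""
        return self.statuses["HL"].diagnosed


@dataclass
class CohortSummary:
    """Descriptive statistics mirroring the cohort table's summary row."""

    n_patients: int
    sex_counts: dict[str, int]
    enrollment_mean: float
    enrollment_sd: float
    symptom_stats: dict[str, tuple[int, float, float | None]]  # n, mean, sd
    prevalence: dict[str, float]
    first_symptom_counts: dict[str, int]
    n_cochlear_implant: int
    chi_square_sex_snhl: tuple[float, float] | None = None


def _parse_status(symptom: str, raw, row_label: str) -> SymptomStatus:
    text = "" if raw is None else str(raw).strip()
    if text == "" or text.lower() == "nan":
        raise ValidationError(f"{row_label}: empty status for {symptom}")
    token = _MISSING_TOKENS.get(text.lower())
    if token is not None:
        if token == "normal" and symptom != "HL":
            raise ValidationError(
                f"{row_label}: 'Normal' status is only meaningful for HL, got {symptom}"
            )
        return SymptomStatus(symptom, token)
    try:
        age = float(text)
    except ValueError:
        raise ValidationError(
            f"{row_label}: unknown status token {text!r} for {symptom}"
        ) from None
    return SymptomStatus(symptom, "diagnosed", age)


def load_cohort(path) -> list[PatientRecord]:
    """Read a cohort CSV into validated :class:`PatientRecord` objects."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = {"patient_id", "sex", "enrollment_age", "cochlear_implant", "n_sessions"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"cohort CSV missing columns {sorted(missing)}")
    records: list[PatientRecord] = []
    seen: set[str] = set()
    for idx, row in df.iterrows():
        label = f"row {idx + 2} ({row['patient_id']})"
        pid = row["patient_id"].strip()
        if pid in seen:
            raise ValidationError(f"{label}: duplicate patient_id")
        seen.add(pid)
        statuses = {
            sym: _parse_status(sym, row.get(col, ""), label)
            for sym, col in _SYMPTOM_COLUMNS.items()
        }
        sib = row.get("sibship", "").strip() or None
        records.append(
            PatientRecord(
                patient_id=pid,
                sex=row["sex"].strip().upper(),
                enrollment_age=float(row["enrollment_age"]),
                statuses=statuses,
                sibship_id=sib,
                cochlear_implant=row["cochlear_implant"].strip() in ("1", "true", "True"),
                n_sessions=int(row["n_sessions"]),
            )
        )
    return records


def packaged_cohort() -> list[PatientRecord]:
    """The shipped 40-patient Wolfram-syndrome cohort fixture."""
    return load_cohort(files("wfs_hearing.data") / "wolfram_cohort.csv")


def symptom_summary(cohort: list[PatientRecord], symptom: str) -> tuple[int, float | None, float | None]:
    """``(n, mean, sd)`` of onset ages over diagnosed patients.

    SD uses the n-1 denominator; undefined (None) for n < 2, and the
    mean is None for n = 0.
    """
    ages = [
        r.statuses[symptom].onset_age for r in cohort if r.statuses[symptom].diagnosed
    ]
    n = len(ages)
    if n == 0:
        return 0, None, None
    mean = float(np.mean(ages))
    sd = float(np.std(ages, ddof=1)) if n > 1 else None
    return n, mean, sd


def prevalence(cohort: list[PatientRecord], symptom: str) -> float:
    """Proportion of the cohort diagnosed with ``symptom``."""
    if not cohort:
        raise ValidationError("prevalence undefined for an empty cohort")
    n_dx = sum(1 for r in cohort if r.statuses[symptom].diagnosed)
    return n_dx / len(cohort)


def first_symptom_counts(
    cohort: list[PatientRecord],
) -> tuple[dict[str, int], set[str]]:
    """Count, per symptom, the patients for whom it appeared first.

    A symptom is first when its onset age is strictly below every other
    diagnosed onset for that patient.  Exact ties make all tied symptoms
    co-first (each counted); such patients are returned in the tie set.
    """
    counts = {s: 0 for s in SYMPTOMS}
    tied: set[str] = set()
    for rec in cohort:
        onsets = {
            s: st.onset_age for s, st in rec.statuses.items() if st.diagnosed
        }
        if not onsets:
            continue
        earliest = min(onsets.values())
        firsts = [s for s, a in onsets.items() if a == earliest]
        if len(firsts) > 1:
            tied.add(rec.patient_id)
            logger.info(
                "%s: tied first symptoms %s at %.1f years", rec.patient_id, firsts, earliest
            )
        for s in firsts:
            counts[s] += 1
    return counts, tied


def nth_symptom_counts(cohort: list[PatientRecord], n: int) -> dict[str, int]:
    """Count patients for whom each symptom was the ``n``-th diagnosed (1-based).

    Uses the same strict age ordering as :func:`first_symptom_counts`;
    ties share a rank and each tied symptom is counted at that rank.
    """
    counts = {s: 0 for s in SYMPTOMS}
    for rec in cohort:
        onsets = sorted(
            ((st.onset_age, s) for s, st in rec.statuses.items() if st.diagnosed)
        )
        if len(onsets) < n:
            continue
        distinct_ages = sorted({a for a, _ in onsets})
        # rank of a symptom = 1 + number of strictly earlier distinct ages
        for age, sym in onsets:
            if distinct_ages.index(age) + 1 == n:
                counts[sym] += 1
    return counts


def early_onset_count(
    cohort: list[PatientRecord], symptom: str = "HL", age_limit: float = 3.0
) -> int:
    """Patients whose ``symptom`` onset was at or before ``age_limit`` years."""
    return sum(
        1
        for r in cohort
        if r.statuses[symptom].diagnosed and r.statuses[symptom].onset_age <= age_limit
    )


def sex_association(cohort: list[PatientRecord]) -> tuple[float | None, float | None]:
    """Pearson chi-square (no continuity correction) of sex x SNHL status.

    Returns ``(chi_square, p)``; ``(None, None)`` when a margin is zero.
    """
    table = np.zeros((2, 2))
    for rec in cohort:
        i = 0 if rec.sex == "M" else 1
        j = 0 if rec.has_snhl else 1
        table[i, j] += 1
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        logger.warning("sex x SNHL table has a zero margin; chi-square undefined")
        return None, None
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), float(p)


def hearing_category_counts(cohort: list[PatientRecord]) -> dict[str, int]:
    """Patients by hearing status: confirmed normal vs. diagnosed SNHL."""
    n_loss = sum(1 for r in cohort if r.has_snhl)
    return {"normal": len(cohort) - n_loss, "hearing_loss": n_loss}


def summarize_cohort(cohort: list[PatientRecord]) -> CohortSummary:
    """Full descriptive summary (mirrors the cohort table's summary row)."""
    firsts, _ = first_symptom_counts(cohort)
    enroll = np.array([r.enrollment_age for r in cohort], dtype=float)
    chi = sex_association(cohort)
    return CohortSummary(
        n_patients=len(cohort),
        sex_counts={
            "M": sum(1 for r in cohort if r.sex == "M"),
            "F": sum(1 for r in cohort if r.sex == "F"),
        },
        enrollment_mean=float(enroll.mean()),
        enrollment_sd=float(enroll.std(ddof=1)) if len(cohort) > 1 else math.nan,
        symptom_stats={s: symptom_summary(cohort, s) for s in SYMPTOMS},
        prevalence={s: prevalence(cohort, s) for s in SYMPTOMS},
        first_symptom_counts=firsts,
        n_cochlear_implant=sum(1 for r in cohort if r.cochlear_implant),
        chi_square_sex_snhl=None if chi[0] is None else chi,
    )


@dataclass
class Exclusion:
    """One dropped record with the rule that dropped it."""

    patient_id: str
    session_index: int
    ear: str | None
    reason: str


@dataclass
class ExclusionResult:
    """Sessions kept for analysis plus the full exclusion log."""

    kept: list[AudiogramSession]
    excluded: list[Exclusion] = field(default_factory=list)


def apply_exclusions(
    sessions: list[AudiogramSession],
    cohort: list[PatientRecord] | None = None,
    max_session: int = MAX_ANALYZED_SESSION,
) -> ExclusionResult:
    """Drop QC-flagged ears/sessions and late visits from modelling input.

    Rules: ears flagged conductive are dropped (per ear); sessions with an
    invalid ear are dropped; cochlear-implant patients (from ``cohort``)
    are dropped; visits beyond ``max_session`` are dropped.  A session
    that loses one ear to a conductive flag is kept with that ear's
    flag preserved; downstream ear-role assembly skips the flagged ear.
    Every drop is logged with its reason.
    """
    implanted = {
        r.patient_id for r in (cohort or []) if r.cochlear_implant
    }
    kept: list[AudiogramSession] = []
    log: list[Exclusion] = []
    for s in sessions:
        if s.patient_id in implanted:
            log.append(Exclusion(s.patient_id, s.session_index, None, "cochlear implant"))
            continue
        if s.session_index > max_session:
            log.append(
                Exclusion(
                    s.patient_id, s.session_index, None,
                    f"session index beyond analysis window ({max_session})",
                )
            )
            continue
        if s.left.invalid_flag or s.right.invalid_flag:
            bad = "left" if s.left.invalid_flag else "right"
            log.append(Exclusion(s.patient_id, s.session_index, bad, "invalid audiogram"))
            continue
        for ear in (s.left, s.right):
            if ear.conductive_flag:
                log.append(
                    Exclusion(s.patient_id, s.session_index, ear.ear, "conductive component")
                )
        kept.append(s)
    for e in log:
        logger.info(
            "excluded %s session %d%s: %s",
            e.patient_id, e.session_index, f" ({e.ear})" if e.ear else "", e.reason,
        )
    return ExclusionResult(kept=kept, excluded=log)
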