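"""Domain records, calendar arithmetic and cohort eligibility.

Every downstream endpoint (steroid, report NLP, volumetric) works on the
four record types defined here.  All dates are whole calendar days
(:class:`datetime.date`); progression-free survival (PFS) is expressed in
months from the end of chemoirradiation (CRT), using a fixed mean Gregorian
month of 30.4375 days so that a 404-day interval prints as 13.3 months.
"""

from __future__ import annotations

import datetime as dt
import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

#: Mean Gregorian month length in days; the single day<->month convention
#: used throughout the package.
DAYS_PER_MONTH = 30.4375


class Method(str, enum.Enum):
    """Progression-determination method."""

    CLINICAL = "clinical"
    STEROID = "steroid"
    NLP = "nlp"
    VOLUMETRIC = "volumetric"


def months_between(start: dt.date, end: dt.date) -> float:
    """Signed interval from *start* to *end* in months.

    Uses the fixed 30.4375-day month.  Antisymmetric:
    ``months_between(a, b) == -months_between(b, a)``.
    """
    if not isinstance(start, dt.date) or not isinstance(end, dt.date):
        raise TypeError("months_between expects datetime.date arguments")
    return (end - start).days / DAYS_PER_MONTH


@dataclass(frozen=True)
class PatientRecord:
    """Anchor dates for one patient.

    ``clinical_progression_date`` is the manually-determined (RANO-style)
    progression date, or the synthetic ground truth; ``None`` for a
    non-progressor.  ``clinical_determined`` is False when no clinical
    determination could be made at all (lost to follow-up), which excludes
    the patient from the cohort.
    """

    patient_id: str
    diagnosis_date: dt.date
    crt_end_date: dt.date
    surgery_date: Optional[dt.date] = None
    clinical_progression_date: Optional[dt.date] = None
    treatment_year: int = 0
    clinical_determined: bool = True

    def __post_init__(self) -> None:
        if self.surgery_date is not None:
            if not (self.diagnosis_date <= self.surgery_date <= self.crt_end_date):
                raise ValueError(
                    f"{self.patient_id}: expected diagnosis <= surgery <= CRT end"
                )
        elif self.diagnosis_date > self.crt_end_date:
            raise ValueError(f"{self.patient_id}: diagnosis after CRT end")
        if (
            self.clinical_progression_date is not None
            and self.clinical_progression_date < self.crt_end_date
        ):
            raise ValueError(
                f"{self.patient_id}: clinical progression before CRT end"
            )


@dataclass(frozen=True)
class PrescriptionRecord:
    patient_id: str
    drug_name: str
    dose_mg: float
    route: str  # "oral" | "intravenous" | "other"
    order_date: dt.date
    brand_name: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.dose_mg > 0:
            raise ValueError(
                f"{self.patient_id}: dose_mg must be positive, got {self.dose_mg}"
            )


@dataclass(frozen=True)
class RadiologyReport:
    patient_id: str
    report_date: dt.date
    document_type: str
    body_text: str


@dataclass(frozen=True)
class ScanVolumeRecord:
    """One segmented brain-MRI scan.

    Contrast-enhancing (CE) tumor drives the volumetric progression rule;
    non-enhancing (NE) tumor and edema are carried for reporting.
    """

    patient_id: str
    scan_date: dt.date
    ce_tumor_cm3: float
    ne_tumor_cm3: float
    edema_cm3: float

    def __post_init__(self) -> None:
        for name in ("ce_tumor_cm3", "ne_tumor_cm3", "edema_cm3"):
            if getattr(self, name) < 0:
                raise ValueError(f"{self.patient_id}: {name} must be >= 0")

    @property
    def total_tumor_cm3(self) -> float:
        return self.ce_tumor_cm3 + self.ne_tumor_cm3

    @property
    def total_burden_cm3(self) -> float:
        return self.total_tumor_cm3 + self.edema_cm3


@dataclass(frozen=True)
class EndpointResult:
    """One (patient, method) PFS determination.

    ``evaluable`` is False when the method could not be applied at all
    (e.g. no usable volumetric baseline) — distinct from "evaluated and
    found no progression".
    """

    patient_id: str
    method: Method
    progressed: bool
    progression_date: Optional[dt.date] = None
    pfs_months: Optional[float] = None
    evaluable: bool = True
    evidence: object = None

    def __post_init__(self) -> None:
        if self.progressed:
            if self.progression_date is None or self.pfs_months is None:
                raise ValueError(
                    f"{self.patient_id}/{self.method}: progressed result "
                    "requires progression_date and pfs_months"
                )
            if self.pfs_months < 0:
                raise ValueError(
                    f"{self.patient_id}/{self.method}: negative pfs_months"
                )
        else:
            if self.progression_date is not None or self.pfs_months is not None:
                raise ValueError(
                    f"{self.patient_id}/{self.method}: non-progressed result "
                    "must not carry a date"
                )


@dataclass
class CohortBundle:
    """The four per-patient EHR tables."""

    patients: list[PatientRecord] = field(default_factory=list)
    prescriptions: list[PrescriptionRecord] = field(default_factory=list)
    reports: list[RadiologyReport] = field(default_factory=list)
    volumes: list[ScanVolumeRecord] = field(default_factory=list)

    def patient_ids(self) -> set[str]:
        return {p.patient_id for p in self.patients}

    def for_patient(self, patient_id: str) -> tuple[
        list[PrescriptionRecord], list[RadiologyReport], list[ScanVolumeRecord]
    ]:
        return (
            [r for r in self.prescriptions if r.patient_id == patient_id],
            [r for r in self.reports if r.patient_id == patient_id],
            [r for r in self.volumes if r.patient_id == patient_id],
        )


class CohortIntegrityError(ValueError):
    """A modality row references a patient absent from the patient table."""


def apply_eligibility(bundle: CohortBundle) -> set[str]:
    """Eligible patient ids: >=1 report, >=1 prescription, >=2 brain-MRI
    scans dated after CRT end, and a resolvable clinical determination.

    Idempotent and monotone (removing datapoints never adds a patient).
    Raises :class:`CohortIntegrityError` on orphan modality rows.
    """
    known = bundle.patient_ids()
    for table in (bundle.prescriptions, bundle.reports, bundle.volumes):
        for row in table:
            if row.patient_id not in known:
                raise CohortIntegrityError(
                    f"modality row references unknown patient {row.patient_id!r}"
                )

    by_patient = {p.patient_id: p for p in bundle.patients}
    eligible: set[str] = set()
    for pid, patient in by_patient.items():
        if not patient.clinical_determined:
            continue
        rxs, reports, scans = bundle.for_patient(pid)
        post_crt_scans = [s for s in scans if s.scan_date > patient.crt_end_date]
        if len(reports) >= 1 and len(rxs) >= 1 and len(post_crt_scans) >= 2:
            eligible.add(pid)
    return eligible


def clinical_pfs(patient: PatientRecord) -> EndpointResult:
    """Clinical-standard endpoint straight from the patient record."""
    if patient.clinical_progression_date is None:
        return EndpointResult(patient.patient_id, Method.CLINICAL, progressed=False)
    return EndpointResult(
        patient.patient_id,
        Method.CLINICAL,
        progressed=True,
        progression_date=patient.clinical_progression_date,
        pfs_months=months_between(
            patient.crt_end_date, patient.clinical_progression_date
        ),
    )
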