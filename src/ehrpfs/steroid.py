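"""Steroid-prescription progression endpoint.

Dexamethasone is the corticosteroid of choice for symptomatic brain-tumor
management and is prescribed on a decreasing ("taper") schedule.  Because
steroids are also routinely given right after surgery and chemoirradiation
(CRT), only prescriptions dated at least one month after CRT end are
considered progression-related.  All post-CRT dexamethasone orders are
treated as a single taper course running from the first date of the
largest dose to the last date of the smallest dose; the course start is
the steroid-derived progression date.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .records import (
    DAYS_PER_MONTH,
    EndpointResult,
    Method,
    PatientRecord,
    PrescriptionRecord,
    months_between,
)

#: Editable brand-name synonym set for generic dexamethasone.
DEFAULT_SYNONYMS = frozenset(
    {
        "dexamethasone",
        "dexamethasone intensol",
        "decadron",
        "dexpak",
        "hexadrol",
        "baycadron",
    }
)


@dataclass(frozen=True)
class TaperCourse:
    """A single post-CRT dexamethasone course."""

    patient_id: str
    course_start: dt.date
    course_end: dt.date
    max_dose_mg: float
    min_dose_mg: float
    n_orders: int

    def __post_init__(self) -> None:
        if self.course_start > self.course_end:
            raise ValueError("course_start after course_end")
        if self.max_dose_mg < self.min_dose_mg:
            raise ValueError("max dose below min dose")
        if self.n_orders < 1:
            raise ValueError("empty course")


def select_dexamethasone(
    prescriptions: Iterable[PrescriptionRecord],
    synonyms: frozenset[str] | set[str] = DEFAULT_SYNONYMS,
) -> list[PrescriptionRecord]:
    """Keep dexamethasone orders of any dose and any route.

    A record matches when its generic or brand name equals (or contains,
    for the generic keyword) 'dexamethasone' or a configured brand
    synonym, case-insensitively.
    """
    lowered = {s.lower() for s in synonyms}
    kept = []
    for rx in prescriptions:
        names = [rx.drug_name.lower()]
        if rx.brand_name:
            names.append(rx.brand_name.lower())
        if any("dexamethasone" in n or n.strip() in lowered for n in names):
            kept.append(rx)
    return kept


def filter_post_crt(
    records: Iterable[PrescriptionRecord], crt_end_date: dt.date
) -> list[PrescriptionRecord]:
    """Keep orders dated >= 1 month (30.4375 days, boundary inclusive)
    after CRT end; earlier orders reflect routine post-surgical/CRT use."""
    if crt_end_date is None:
        raise ValueError("patient has no CRT end date")
    return [
        r for r in records if (r.order_date - crt_end_date).days >= DAYS_PER_MONTH
    ]


def derive_taper_course(
    records: Sequence[PrescriptionRecord],
) -> Optional[TaperCourse]:
    """Collapse post-CRT dexamethasone orders into one taper course.

    course_start = earliest order date among the records carrying the
    maximal dose; course_end = latest order date among those carrying the
    minimal dose.  Returns None on empty input.  If the raw end precedes
    the start (largest dose ordered last — never the case on a true
    taper), the course is clamped to a degenerate window at the start.
    """
    records = list(records)
    if not records:
        return None
    max_dose = max(r.dose_mg for r in records)
    min_dose = min(r.dose_mg for r in records)
    start = min(r.order_date for r in records if r.dose_mg == max_dose)
    end = max(r.order_date for r in records if r.dose_mg == min_dose)
    return TaperCourse(
        patient_id=records[0].patient_id,
        course_start=start,
        course_end=max(end, start),
        max_dose_mg=max_dose,
        min_dose_mg=min_dose,
        n_orders=len(records),
    )


def steroid_pfs(
    patient: PatientRecord,
    prescriptions: Iterable[PrescriptionRecord],
    synonyms: frozenset[str] | set[str] = DEFAULT_SYNONYMS,
) -> EndpointResult:
    """Steroid-derived endpoint: progression at the start of the post-CRT
    dexamethasone taper course, if one exists."""
    dex = select_dexamethasone(prescriptions, synonyms)
    post = filter_post_crt(dex, patient.crt_end_date)
    course = derive_taper_course(post)
    if course is None:
        return EndpointResult(patient.patient_id, Method.STEROID, progressed=False)
    return EndpointResult(
        patient.patient_id,
        Method.STEROID,
        progressed=True,
        progression_date=course.course_start,
        pfs_months=months_between(patient.crt_end_date, course.course_start),
        evidence=course,
    )
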