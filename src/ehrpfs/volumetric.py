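"""Volumetric (computer-vision-derived) progression endpoint.

Works on longitudinal contrast-enhancing (CE) tumor volumes produced by an
upstream MRI segmentation pipeline.  Each post-CRT scan is compared to the
fixed post-surgery / pre-CRT baseline scan by the relative volumetric
change ratio

    relative_change = scan CE volume / baseline CE volume

and a ratio >= 1.05 (a 5% increase, boundary inclusive) flags progression.
The earliest flagged scan dates the endpoint; later shrinkage never
un-calls it.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .records import (
    EndpointResult,
    Method,
    PatientRecord,
    ScanVolumeRecord,
    months_between,
)

#: Default progression threshold on the CE volume ratio (>= 5% increase).
DEFAULT_THRESHOLD = 1.05


@dataclass(frozen=True)
class VolumetricAssessment:
    scan_date: dt.date
    baseline_ce_cm3: float
    scan_ce_cm3: float
    relative_change: float
    progression_flag: bool


class DegenerateBaselineError(ValueError):
    """Baseline CE volume is zero (e.g. complete resection)."""


def select_baseline(
    scans: Iterable[ScanVolumeRecord],
    surgery_date: dt.date,
    crt_bound_date: dt.date,
) -> Optional[ScanVolumeRecord]:
    """Earliest scan in the post-surgery, pre-CRT window, or None.

    *crt_bound_date* is the upper bound of the baseline window (CRT start
    when known, otherwise CRT end).
    """
    window = [
        s
        for s in scans
        if surgery_date <= s.scan_date < crt_bound_date
    ]
    if not window:
        return None
    return min(window, key=lambda s: s.scan_date)


def relative_change(baseline_ce: float, scan_ce: float) -> float:
    """Eponymous ratio of a follow-up CE volume over the baseline CE volume."""
    if baseline_ce < 0 or scan_ce < 0:
        raise ValueError("volumes must be non-negative")
    if baseline_ce == 0:
        raise DegenerateBaselineError("baseline CE volume is zero")
    return scan_ce / baseline_ce


def classify_scan(ratio: float, threshold: float = DEFAULT_THRESHOLD) -> bool:
    """True iff the ratio meets the progression threshold (inclusive)."""
    if ratio < 0:
        raise ValueError("ratio must be non-negative")
    return ratio >= threshold


def volumetric_pfs(
    patient: PatientRecord,
    scans: Sequence[ScanVolumeRecord],
    threshold: float = DEFAULT_THRESHOLD,
) -> EndpointResult:
    """Volumetric endpoint for one patient.

    Not-evaluable (``evaluable=False``) when no baseline scan exists in
    the post-surgery/pre-CRT window, or the baseline CE volume is zero —
    distinguished from an evaluated non-progression.
    """
    if patient.surgery_date is None:
        return EndpointResult(
            patient.patient_id, Method.VOLUMETRIC, progressed=False, evaluable=False
        )
    baseline = select_baseline(scans, patient.surgery_date, patient.crt_end_date)
    if baseline is None or baseline.ce_tumor_cm3 == 0:
        return EndpointResult(
            patient.patient_id, Method.VOLUMETRIC, progressed=False, evaluable=False
        )
    followups = sorted(
        (s for s in scans if s.scan_date > patient.crt_end_date),
        key=lambda s: s.scan_date,
    )
    assessments = []
    first_flagged: Optional[ScanVolumeRecord] = None
    for scan in followups:
        ratio = relative_change(baseline.ce_tumor_cm3, scan.ce_tumor_cm3)
        flag = classify_scan(ratio, threshold)
        assessments.append(
            VolumetricAssessment(
                scan_date=scan.scan_date,
                baseline_ce_cm3=baseline.ce_tumor_cm3,
                scan_ce_cm3=scan.ce_tumor_cm3,
                relative_change=ratio,
                progression_flag=flag,
            )
        )
        if flag and first_flagged is None:
            first_flagged = scan
    if first_flagged is None:
        return EndpointResult(
            patient.patient_id,
            Method.VOLUMETRIC,
            progressed=False,
            evidence=assessments,
        )
    return EndpointResult(
        patient.patient_id,
        Method.VOLUMETRIC,
        progressed=True,
        progression_date=first_flagged.scan_date,
        pfs_months=months_between(patient.crt_end_date, first_flagged.scan_date),
        evidence=assessments,
    )
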