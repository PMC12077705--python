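"""Flat-file I/O for cohort bundles and endpoint results.

Formats (all plain text, dates ISO-8601, empty field = missing):

* ``patients.csv`` — patient_id, diagnosis_date, surgery_date, crt_end_date,
  clinical_progression_date, treatment_year [, clinical_determined]
* ``prescriptions.csv`` — patient_id, drug_name, brand_name, dose_mg, route,
  order_date
* ``reports.jsonl`` — one JSON object per report: patient_id, report_date,
  document_type, text
* ``volumes.csv`` — patient_id, scan_date, ce_tumor_cm3, ne_tumor_cm3,
  edema_cm3
* ``results.csv`` — patient_id, method, progressed, progression_date,
  pfs_months [, evaluable]
"""

from __future__ import annotations

import datetime as dt
import json
from pathlib import Path
from typing import Optional

import pandas as pd

from .records import (
    CohortBundle,
    EndpointResult,
    Method,
    PatientRecord,
    PrescriptionRecord,
    RadiologyReport,
    ScanVolumeRecord,
)


class ParseError(ValueError):
    """Malformed row in a cohort file; message names the file and row."""


def _parse_date(value, where: str) -> Optional[dt.date]:
    if value is None or (isinstance(value, float) and pd.isna(value)) or value == "":
        return None
    try:
        return dt.date.fromisoformat(str(value))
    except ValueError as exc:
        raise ParseError(f"{where}: malformed date {value!r}") from exc


def _require_date(value, where: str) -> dt.date:
    parsed = _parse_date(value, where)
    if parsed is None:
        raise ParseError(f"{where}: missing required date")
    return parsed


def read_patients(path: Path) -> list[PatientRecord]:
    frame = pd.read_csv(path, dtype={"patient_id": str}, float_precision="round_trip")
    records = []
    for i, row in frame.iterrows():
        where = f"{path.name} row {i}"
        determined = True
        if "clinical_determined" in frame.columns and not pd.isna(
            row["clinical_determined"]
        ):
            determined = str(row["clinical_determined"]).strip().lower() in (
                "true",
                "1",
                "yes",
            )
        try:
            records.append(
                PatientRecord(
                    patient_id=row["patient_id"],
                    diagnosis_date=_require_date(row["diagnosis_date"], where),
                    surgery_date=_parse_date(row.get("surgery_date"), where),
                    crt_end_date=_require_date(row["crt_end_date"], where),
                    clinical_progression_date=_parse_date(
                        row.get("clinical_progression_date"), where
                    ),
                    treatment_year=int(row["treatment_year"]),
                    clinical_determined=determined,
                )
            )
        except ValueError as exc:
            raise ParseError(f"{where}: {exc}") from exc
    return records


def read_prescriptions(path: Path) -> list[PrescriptionRecord]:
    frame = pd.read_csv(path, dtype={"patient_id": str}, float_precision="round_trip")
    records = []
    for i, row in frame.iterrows():
        where = f"{path.name} row {i}"
        try:
            dose = float(row["dose_mg"])
        except (TypeError, ValueError) as exc:
            raise ParseError(f"{where}: malformed dose_mg {row['dose_mg']!r}") from exc
        if not dose > 0:
            raise ParseError(f"{where}: dose_mg must be positive, got {dose}")
        brand = row.get("brand_name")
        if pd.isna(brand) or brand == "":
            brand = None
        records.append(
            PrescriptionRecord(
                patient_id=row["patient_id"],
                drug_name=str(row["drug_name"]),
                brand_name=brand,
                dose_mg=dose,
                route=str(row["route"]),
                order_date=_require_date(row["order_date"], where),
            )
        )
    return records


def read_reports(path: Path) -> list[RadiologyReport]:
    records = []
    with open(path, encoding="utf-8") as handle:
        for i, line in enumerate(handle):
            if not line.strip():
                continue
            where = f"{path.name} line {i}"
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise ParseError(f"{where}: malformed JSON") from exc
            records.append(
                RadiologyReport(
                    patient_id=str(obj["patient_id"]),
                    report_date=_require_date(obj["report_date"], where),
                    document_type=str(obj["document_type"]),
                    body_text=str(obj["text"]),
                )
            )
    return records


def read_volumes(path: Path) -> list[ScanVolumeRecord]:
    frame = pd.read_csv(path, dtype={"patient_id": str}, float_precision="round_trip")
    records = []
    for i, row in frame.iterrows():
        where = f"{path.name} row {i}"
        try:
            records.append(
                ScanVolumeRecord(
                    patient_id=row["patient_id"],
                    scan_date=_require_date(row["scan_date"], where),
                    ce_tumor_cm3=float(row["ce_tumor_cm3"]),
                    ne_tumor_cm3=float(row["ne_tumor_cm3"]),
                    edema_cm3=float(row["edema_cm3"]),
                )
            )
        except ValueError as exc:
            raise ParseError(f"{where}: {exc}") from exc
    return records


def read_cohort(directory: Path | str) -> CohortBundle:
    """Read the four cohort files from *directory*.

    A missing prescriptions/reports/volumes file yields an empty
    collection; patients.csv is required.
    """
    directory = Path(directory)
    bundle = CohortBundle(patients=read_patients(directory / "patients.csv"))
    rx = directory / "prescriptions.csv"
    if rx.exists() and rx.stat().st_size > 0:
        try:
            bundle.prescriptions = read_prescriptions(rx)
        except pd.errors.EmptyDataError:
            pass
    rp = directory / "reports.jsonl"
    if rp.exists():
        bundle.reports = read_reports(rp)
    vol = directory / "volumes.csv"
    if vol.exists() and vol.stat().st_size > 0:
        try:
            bundle.volumes = read_volumes(vol)
        except pd.errors.EmptyDataError:
            pass
    return bundle


def _date_str(d: Optional[dt.date]) -> str:
    return "" if d is None else d.isoformat()


def write_cohort(bundle: CohortBundle, directory: Path | str) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        [
            {
                "patient_id": p.patient_id,
                "diagnosis_date": _date_str(p.diagnosis_date),
                "surgery_date": _date_str(p.surgery_date),
                "crt_end_date": _date_str(p.crt_end_date),
                "clinical_progression_date": _date_str(p.clinical_progression_date),
                "treatment_year": p.treatment_year,
                "clinical_determined": p.clinical_determined,
            }
            for p in bundle.patients
        ]
    ).to_csv(directory / "patients.csv", index=False)
    pd.DataFrame(
        [
            {
                "patient_id": r.patient_id,
                "drug_name": r.drug_name,
                "brand_name": r.brand_name or "",
                "dose_mg": r.dose_mg,
                "route": r.route,
                "order_date": _date_str(r.order_date),
            }
            for r in bundle.prescriptions
        ],
        columns=[
            "patient_id",
            "drug_name",
            "brand_name",
            "dose_mg",
            "route",
            "order_date",
        ],
        # %.17g keeps doubles exactly round-trippable through text
    ).to_csv(directory / "prescriptions.csv", index=False, float_format="%.17g")
    with open(directory / "reports.jsonl", "w", encoding="utf-8") as handle:
        for r in bundle.reports:
            handle.write(
                json.dumps(
                    {
                        "patient_id": r.patient_id,
                        "report_date": r.report_date.isoformat(),
                        "document_type": r.document_type,
                        "text": r.body_text,
                    }
                )
                + "\n"
            )
    pd.DataFrame(
        [
            {
                "patient_id": s.patient_id,
                "scan_date": _date_str(s.scan_date),
                "ce_tumor_cm3": s.ce_tumor_cm3,
                "ne_tumor_cm3": s.ne_tumor_cm3,
                "edema_cm3": s.edema_cm3,
            }
            for s in bundle.volumes
        ],
        columns=["patient_id", "scan_date", "ce_tumor_cm3", "ne_tumor_cm3", "edema_cm3"],
    ).to_csv(directory / "volumes.csv", index=False, float_format="%.17g")


def write_results(results: list[EndpointResult], path: Path | str) -> None:
    pd.DataFrame(
        [
            {
                "patient_id": r.patient_id,
                "method": r.method.value,
                "progressed": r.progressed,
                "progression_date": _date_str(r.progression_date),
                "pfs_months": "" if r.pfs_months is None else f"{r.pfs_months:.6f}",
                "evaluable": r.evaluable,
            }
            for r in results
        ],
        columns=[
            "patient_id",
            "method",
            "progressed",
            "progression_date",
            "pfs_months",
            "evaluable",
        ],
    ).to_csv(path, index=False)


def read_results(path: Path | str) -> list[EndpointResult]:
    frame = pd.read_csv(path, dtype={"patient_id": str}, float_precision="round_trip")
    results = []
    for i, row in frame.iterrows():
        where = f"{Path(path).name} row {i}"
        progressed = str(row["progressed"]).strip().lower() in ("true", "1", "yes")
        pfs = row.get("pfs_months")
        pfs = None if pd.isna(pfs) or pfs == "" else float(pfs)
        evaluable = True
        if "evaluable" in frame.columns and not pd.isna(row["evaluable"]):
            evaluable = str(row["evaluable"]).strip().lower() in ("true", "1", "yes")
        results.append(
            EndpointResult(
                patient_id=row["patient_id"],
                method=Method(row["method"]),
                progressed=progressed,
                progression_date=_parse_date(row.get("progression_date"), where),
                pfs_months=pfs,
                evaluable=evaluable,
            )
        )
    return results
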