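"""Seeded synthetic EHR cohort generator with known ground truth.

The real study data are private institutional records, so every pipeline
stage is exercised against a generated glioblastoma cohort whose design
emulates the published cohort's observable behavior:

* right-skewed clinical PFS — lognormal truth with defaults hitting a
  6.5-month median and 13.3-month mean in closed form;
* a dexamethasone taper course lagging the clinical progression date by a
  normal draw (default mean 4.5, sd 8.3 months), plus a routine
  post-surgical course and distractor prescriptions;
* brain-MRI surveillance reports every 2-4 months built from stability /
  negation / surgical / progression sentence templates whose stems come
  from the shipped default lexicon, so each report carries an exact gold
  status;
* contrast-enhancing volume trajectories that grow multiplicatively after
  a radiographic onset, with a configurable fraction of progressors whose
  ratio never reaches the 5% threshold ("volume-silent", default 0.46);
* per-modality evidence leads: textual and radiographic evidence may
  precede the clinical declaration (defaults 6.9 and 2.6 months).

All template text is synthetic; no distributional form here is taken from
the study, which reports only summary statistics.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .records import (
    DAYS_PER_MONTH,
    CohortBundle,
    PatientRecord,
    PrescriptionRecord,
    RadiologyReport,
    ScanVolumeRecord,
)

BRAIN_MRI_TYPE = "MRI BRAIN-Perfusion (IP)"


class ConfigError(ValueError):
    """Invalid generator configuration."""


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for the synthetic cohort.

    Defaults are calibrated a priori to the published cohort's summary
    behavior; see docs/methods.md for each choice.
    """

    n_patients: int = 92
    seed: int = 0
    p_progression: float = 91.0 / 92.0
    # lognormal truth PFS: median exp(mu), mean exp(mu + sigma^2/2)
    truth_pfs_log_mu: float = math.log(6.5)
    truth_pfs_log_sigma: float = math.sqrt(2.0 * math.log(13.3 / 6.5))
    # steroid taper lag after clinical truth (months)
    steroid_lag_mean_months: float = 4.5
    steroid_lag_sd_months: float = 8.3
    steroid_lag_min_months: Optional[float] = None
    # evidence leads, months before the clinical truth date: for reports,
    # when progression phrasing starts appearing; for volumes, when the CE
    # ratio crosses the 5% threshold
    report_lead_mean_months: float = 6.9
    report_lead_sd_months: float = 19.2
    volume_lead_mean_months: float = 2.6
    volume_lead_sd_months: float = 5.8
    # surveillance spacing
    report_interval_months_min: float = 2.0
    report_interval_months_max: float = 4.0
    p_report_detect: float = 0.9
    # dexamethasone taper
    taper_doses_mg: tuple[float, ...] = (8.0, 4.0, 2.0, 1.0)
    taper_spacing_days: int = 10  # ~30-day taper across the four doses
    # contrast-enhancing volume model
    baseline_ce_log_mu: float = math.log(2.0)
    baseline_ce_log_sigma: float = 0.8
    ce_growth_rate_per_month: float = 0.10
    ce_pre_onset_drift_per_month: float = 0.0
    ce_noise_cv: float = 0.02
    frac_volume_silent: float = 0.46
    # per-patient modality missingness
    p_steroid_missing: float = 0.25
    p_report_missing: float = 0.0
    p_volume_missing: float = 0.0
    # follow-up horizons
    followup_margin_months: float = 12.0
    nonprogressor_followup_months: float = 36.0
    treatment_year_min: int = 2004
    treatment_year_max: int = 2023

    def __post_init__(self) -> None:
        if self.n_patients <= 0:
            raise ConfigError("n_patients must be positive")
        for name in (
            "p_progression",
            "p_report_detect",
            "frac_volume_silent",
            "p_steroid_missing",
            "p_report_missing",
            "p_volume_missing",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        if self.truth_pfs_log_sigma < 0:
            raise ConfigError("truth_pfs_log_sigma must be >= 0")
        if self.report_interval_months_min > self.report_interval_months_max:
            raise ConfigError("report interval min > max")
        if self.report_interval_months_min <= 0:
            raise ConfigError("report interval must be positive")
        doses = self.taper_doses_mg
        if not doses or any(
            doses[i] <= doses[i + 1] for i in range(len(doses) - 1)
        ):
            raise ConfigError("taper_doses_mg must be strictly decreasing")
        if self.ce_growth_rate_per_month <= 0:
            raise ConfigError("ce_growth_rate_per_month must be positive")

    @classmethod
    def perfect_information(cls, **overrides) -> "GeneratorConfig":
        """Idealized conditions: every modality reflects the truth
        immediately and noiselessly.

        Detection certain, no evidence leads or steroid lag, no
        measurement noise, no volume-silent fraction, no missingness, and
        CE growth fast enough (doubling per month) that the first scan
        after progression crosses the 5% threshold.
        """
        base = dict(
            p_report_detect=1.0,
            steroid_lag_mean_months=0.0,
            steroid_lag_sd_months=0.0,
            report_lead_mean_months=0.0,
            report_lead_sd_months=0.0,
            volume_lead_mean_months=0.0,
            volume_lead_sd_months=0.0,
            ce_noise_cv=0.0,
            ce_pre_onset_drift_per_month=0.0,
            ce_growth_rate_per_month=1.0,
            frac_volume_silent=0.0,
            p_steroid_missing=0.0,
            p_report_missing=0.0,
            p_volume_missing=0.0,
        )
        base.update(overrides)
        return cls(**base)


def sample_truth_pfs(config: GeneratorConfig, rng: np.random.Generator) -> float:
    """One lognormal truth-PFS draw in months."""
    if config.truth_pfs_log_sigma == 0.0:
        return math.exp(config.truth_pfs_log_mu)
    return float(
        rng.lognormal(config.truth_pfs_log_mu, config.truth_pfs_log_sigma)
    )


def make_surveillance_schedule(
    config: GeneratorConfig, rng: np.random.Generator, horizon_months: float
) -> list[float]:
    """Post-CRT visit times (months), consecutive gaps uniform in the
    configured [min, max] interval, out to the horizon."""
    times: list[float] = []
    t = 0.0
    while True:
        t += float(
            rng.uniform(
                config.report_interval_months_min, config.report_interval_months_max
            )
        )
        if t > horizon_months:
            break
        times.append(t)
    return times


def _months_to_date(anchor: dt.date, months: float) -> dt.date:
    return anchor + dt.timedelta(days=round(months * DAYS_PER_MONTH))


# --- report templates -------------------------------------------------------
# Sentences are annotated with the (progression, stability, surgical) counts
# the document pipeline assigns them under the shipped default lexicon; the
# gold status of an assembled report follows from these counts by
# construction and is never re-derived.

_NEUTRAL = [
    "MRI brain with and without contrast was performed.",
    "The ventricles are midline and of normal caliber.",
    "There is no acute intracranial hemorrhage.",
    "Major intracranial flow voids are preserved.",
]

# (sentence, progression_count, stability_count, surgical_count)
_STABILITY = [
    ("The ventricles and sulci are stable in appearance.", 0, 1, 0),
    ("No evidence of tumor progression.", 0, 1, 0),
    ("Signal abnormality is unchanged from the prior examination.", 0, 1, 0),
    ("Enhancement within the surgical bed has decreased.", 0, 1, 0),
    ("Findings are improved compared with the previous study.", 0, 1, 0),
    ("Expected postoperative changes surround the resection cavity.", 0, 0, 0),
    (
        "Increased enhancement along the margin of the resection cavity "
        "reflects postoperative change.",
        0,
        0,
        1,
    ),
]

_PROGRESSION = [
    ("There is increased enhancement in the left frontal region.", 1, 0, 0),
    ("Findings are consistent with tumor progression.", 1, 0, 0),
    ("The enhancing mass has enlarged in the interval.", 1, 0, 0),
    ("Worsening mass effect with interval growth of the lesion.", 2, 0, 0),
    ("Progressive enlargement of the enhancing component is seen.", 2, 0, 0),
    ("New nodular enhancement has increased in size.", 1, 0, 0),
]


def _compose_report(
    rng: np.random.Generator, progression: bool
) -> tuple[str, str]:
    """Assemble one template-pure report body; returns (text, gold_status).

    Progression reports carry two progression sentences (>= 2 unmodified
    progression mentions) and at most one stability sentence, so the
    one-to-one rule calls progression.  Stability reports carry no
    unmodified progression mention at all.
    """
    sentences = [_NEUTRAL[0]]
    if progression:
        picks = rng.choice(len(_PROGRESSION), size=2, replace=False)
        sentences += [_PROGRESSION[i][0] for i in picks]
        if rng.random() < 0.5:
            sentences.append(_STABILITY[int(rng.integers(0, 5))][0])
        gold = "progression"
    else:
        n_stab = int(rng.integers(2, 4))
        picks = rng.choice(len(_STABILITY), size=n_stab, replace=False)
        chosen = [int(i) for i in picks]
        if not any(_STABILITY[i][1] > 0 for i in chosen):
            # guarantee at least one stability-counted mention
            chosen[0] = int(rng.integers(0, 5))
        sentences += [_STABILITY[i][0] for i in chosen]
        gold = "no_progression"
    if rng.random() < 0.5:
        sentences.append(_NEUTRAL[int(rng.integers(1, len(_NEUTRAL)))])
    return "\n".join(sentences), gold


@dataclass(frozen=True)
class ReportGold:
    patient_id: str
    report_date: dt.date
    status: str


@dataclass(frozen=True)
class ScanGold:
    patient_id: str
    scan_date: dt.date
    ratio: float
    progression_flag: bool


@dataclass
class SyntheticTruth:
    """Ground truth emitted at generation time."""

    truth_months: dict[str, Optional[float]] = field(default_factory=dict)
    steroid_lag_months: dict[str, Optional[float]] = field(default_factory=dict)
    volume_silent: dict[str, bool] = field(default_factory=dict)
    report_gold: list[ReportGold] = field(default_factory=list)
    scan_gold: list[ScanGold] = field(default_factory=list)


def generate_prescriptions(
    patient: PatientRecord,
    truth_date: Optional[dt.date],
    config: GeneratorConfig,
    rng: np.random.Generator,
    steroid_missing: bool = False,
    horizon_date: Optional[dt.date] = None,
) -> tuple[list[PrescriptionRecord], Optional[float]]:
    """Prescription table for one patient.

    Emits a routine post-surgical dexamethasone course (dated well before
    CRT end + 1 month, exercising the downstream filter), a
    progression-triggered taper course starting at truth + lag, and
    distractor non-steroid orders.  Returns the records and the drawn lag
    in months (None when no taper course was emitted).
    """
    pid = patient.patient_id
    records: list[PrescriptionRecord] = []
    horizon_date = horizon_date or patient.crt_end_date + dt.timedelta(days=365)

    # routine post-surgical course
    if patient.surgery_date is not None and not steroid_missing:
        start = patient.surgery_date + dt.timedelta(days=int(rng.integers(1, 4)))
        for k, dose in enumerate((4.0, 2.0)):
            records.append(
                PrescriptionRecord(
                    patient_id=pid,
                    drug_name="dexamethasone",
                    dose_mg=dose,
                    route="oral",
                    order_date=start + dt.timedelta(days=3 * k),
                )
            )

    # distractor orders
    span_days = max((horizon_date - patient.diagnosis_date).days, 1)
    for _ in range(int(rng.integers(2, 6))):
        drug, dose = [
            ("temozolomide", 140.0),
            ("levetiracetam", 500.0),
            ("ondansetron", 8.0),
            ("famotidine", 20.0),
        ][int(rng.integers(0, 4))]
        records.append(
            PrescriptionRecord(
                patient_id=pid,
                drug_name=drug,
                dose_mg=dose,
                route="oral",
                order_date=patient.diagnosis_date
                + dt.timedelta(days=int(rng.integers(0, span_days))),
            )
        )

    # progression-triggered taper course
    lag: Optional[float] = None
    if truth_date is not None and not steroid_missing:
        lag = float(
            rng.normal(config.steroid_lag_mean_months, config.steroid_lag_sd_months)
        ) if config.steroid_lag_sd_months > 0 else config.steroid_lag_mean_months
        if config.steroid_lag_min_months is not None:
            lag = max(lag, config.steroid_lag_min_months)
        start = truth_date + dt.timedelta(days=round(lag * DAYS_PER_MONTH))
        route = "intravenous" if rng.random() < 0.1 else "oral"
        for k, dose in enumerate(config.taper_doses_mg):
            records.append(
                PrescriptionRecord(
                    patient_id=pid,
                    drug_name="dexamethasone",
                    brand_name="Decadron" if rng.random() < 0.2 else None,
                    dose_mg=float(dose),
                    route=route if k == 0 else "oral",
                    order_date=start + dt.timedelta(days=k * config.taper_spacing_days),
                )
            )
    return records, lag


def generate_reports(
    patient: PatientRecord,
    schedule_months: Sequence[float],
    onset_months: Optional[float],
    config: GeneratorConfig,
    rng: np.random.Generator,
) -> tuple[list[RadiologyReport], list[ReportGold]]:
    """Surveillance brain-MRI reports on the visit schedule.

    Reports before the textual-evidence onset use stability templates;
    reports at/after it use progression templates with probability
    ``p_report_detect``.  Occasional non-brain distractor documents are
    emitted to exercise the document-type filter.
    """
    reports: list[RadiologyReport] = []
    gold: list[ReportGold] = []
    for t in schedule_months:
        date = _months_to_date(patient.crt_end_date, t)
        progressing = (
            onset_months is not None
            and t >= onset_months
            and rng.random() < config.p_report_detect
        )
        text, status = _compose_report(rng, progressing)
        reports.append(
            RadiologyReport(
                patient_id=patient.patient_id,
                report_date=date,
                document_type=BRAIN_MRI_TYPE,
                body_text=text,
            )
        )
        gold.append(ReportGold(patient.patient_id, date, status))
        if rng.random() < 0.1:
            dtype = ("DX Chest - PA + Lat", "CT Cerebrum")[int(rng.integers(0, 2))]
            reports.append(
                RadiologyReport(
                    patient_id=patient.patient_id,
                    report_date=date + dt.timedelta(days=1),
                    document_type=dtype,
                    body_text="Lungs are clear. No acute abnormality.",
                )
            )
    return reports, gold


def generate_volumes(
    patient: PatientRecord,
    baseline_date: dt.date,
    schedule_months: Sequence[float],
    onset_months: Optional[float],
    silent: bool,
    config: GeneratorConfig,
    rng: np.random.Generator,
) -> tuple[list[ScanVolumeRecord], list[ScanGold]]:
    """Baseline plus follow-up scans with gold CE ratios.

    CE volume drifts multiplicatively before the radiographic onset and
    grows at ``ce_growth_rate_per_month`` after it, with lognormal
    multiplicative noise.  Volume-silent progressors are clamped so every
    ratio stays below 1.05.
    """
    pid = patient.patient_id
    baseline_ce = float(
        rng.lognormal(config.baseline_ce_log_mu, config.baseline_ce_log_sigma)
    )
    ne_ratio = float(rng.uniform(0.5, 2.0))
    edema_ratio = float(rng.uniform(1.0, 3.0))

    def _noise() -> float:
        if config.ce_noise_cv <= 0:
            return 1.0
        return float(np.exp(rng.normal(0.0, config.ce_noise_cv)))

    def _companions(ce: float) -> tuple[float, float]:
        ne = ce * ne_ratio * _noise()
        edema = (ce + ne) * edema_ratio * _noise()
        return ne, edema

    scans = []
    gold = []
    ne0, ed0 = _companions(baseline_ce)
    scans.append(
        ScanVolumeRecord(pid, baseline_date, baseline_ce, ne0, ed0)
    )
    drift = 1.0 + config.ce_pre_onset_drift_per_month
    growth = 1.0 + config.ce_growth_rate_per_month
    onset = onset_months  # may precede CRT end (negative months)
    for t in schedule_months:
        if onset is None or t < onset:
            ce = baseline_ce * drift**t * _noise()
        else:
            stable = baseline_ce * drift ** max(onset, 0.0)
            # cap runaway exponential growth at a gross tumor burden
            ce = stable * min(growth ** (t - onset), 50.0) * _noise()
        if silent:
            ce = min(ce, baseline_ce * 1.049)
        ne, edema = _companions(ce)
        date = _months_to_date(patient.crt_end_date, t)
        scans.append(ScanVolumeRecord(pid, date, ce, ne, edema))
        ratio = ce / baseline_ce
        gold.append(ScanGold(pid, date, ratio, ratio >= 1.05))
    return scans, gold


def generate_cohort(
    config: GeneratorConfig,
) -> tuple[CohortBundle, SyntheticTruth]:
    """Deterministic function of (config, seed): the full cohort bundle
    plus its ground truth."""
    rng = np.random.default_rng(config.seed)
    bundle = CohortBundle()
    truth = SyntheticTruth()

    for i in range(config.n_patients):
        pid = f"P{i + 1:03d}"
        year = int(
            rng.integers(config.treatment_year_min, config.treatment_year_max + 1)
        )
        diagnosis = dt.date(year, int(rng.integers(1, 13)), int(rng.integers(1, 29)))
        surgery = diagnosis + dt.timedelta(days=int(rng.integers(7, 22)))
        crt_start = surgery + dt.timedelta(days=int(rng.integers(21, 36)))
        crt_end = crt_start + dt.timedelta(days=42)
        baseline_scan_date = surgery + dt.timedelta(
            days=int(rng.integers(5, max(6, (crt_start - surgery).days)))
        )

        progressor = rng.random() < config.p_progression
        truth_months = sample_truth_pfs(config, rng) if progressor else None
        truth_date = (
            None if truth_months is None else _months_to_date(crt_end, truth_months)
        )

        patient = PatientRecord(
            patient_id=pid,
            diagnosis_date=diagnosis,
            surgery_date=surgery,
            crt_end_date=crt_end,
            clinical_progression_date=truth_date,
            treatment_year=year,
        )
        bundle.patients.append(patient)
        truth.truth_months[pid] = truth_months

        horizon = (
            truth_months + config.followup_margin_months
            if truth_months is not None
            else config.nonprogressor_followup_months
        )
        schedule = make_surveillance_schedule(config, rng, horizon)

        steroid_missing = rng.random() < config.p_steroid_missing
        report_missing = rng.random() < config.p_report_missing
        volume_missing = rng.random() < config.p_volume_missing

        # evidence onsets relative to CRT end (months)
        report_onset = volume_onset = None
        if truth_months is not None:
            report_lead = (
                float(
                    rng.normal(
                        config.report_lead_mean_months, config.report_lead_sd_months
                    )
                )
                if config.report_lead_sd_months > 0
                else config.report_lead_mean_months
            )
            volume_lead = (
                float(
                    rng.normal(
                        config.volume_lead_mean_months, config.volume_lead_sd_months
                    )
                )
                if config.volume_lead_sd_months > 0
                else config.volume_lead_mean_months
            )
            report_onset = truth_months - report_lead
            # place the growth start so the CE ratio crosses the 5%
            # threshold at truth - volume_lead
            t_star = math.log(1.05) / math.log(1.0 + config.ce_growth_rate_per_month)
            volume_onset = truth_months - volume_lead - t_star

        rxs, lag = generate_prescriptions(
            patient,
            truth_date,
            config,
            rng,
            steroid_missing=steroid_missing,
            horizon_date=_months_to_date(crt_end, horizon),
        )
        bundle.prescriptions.extend(rxs)
        truth.steroid_lag_months[pid] = lag

        if not report_missing:
            reports, rgold = generate_reports(
                patient, schedule, report_onset, config, rng
            )
            bundle.reports.extend(reports)
            truth.report_gold.extend(rgold)

        silent = bool(
            truth_months is not None and rng.random() < config.frac_volume_silent
        )
        truth.volume_silent[pid] = silent
        if not volume_missing:
            scans, sgold = generate_volumes(
                patient,
                baseline_scan_date,
                schedule,
                volume_onset,
                silent,
                config,
                rng,
            )
            bundle.volumes.extend(scans)
            truth.scan_gold.extend(sgold)

    return bundle, truth


def write_truth(truth: SyntheticTruth, directory) -> None:
    """Serialize ground truth next to the cohort files (truth.csv,
    report_gold.csv, scan_gold.csv)."""
    import pandas as pd
    from pathlib import Path

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        [
            {
                "patient_id": pid,
                "truth_pfs_months": "" if m is None else f"{m:.6f}",
                "steroid_lag_months": (
                    ""
                    if truth.steroid_lag_months.get(pid) is None
                    else f"{truth.steroid_lag_months[pid]:.6f}"
                ),
                "volume_silent": truth.volume_silent.get(pid, False),
            }
            for pid, m in truth.truth_months.items()
        ]
    ).to_csv(directory / "truth.csv", index=False)
    pd.DataFrame(
        [
            {
                "patient_id": g.patient_id,
                "report_date": g.report_date.isoformat(),
                "gold_status": g.status,
            }
            for g in truth.report_gold
        ]
    ).to_csv(directory / "report_gold.csv", index=False)
    pd.DataFrame(
        [
            {
                "patient_id": g.patient_id,
                "scan_date": g.scan_date.isoformat(),
                "gold_ratio": f"{g.ratio:.8f}",
                "gold_flag": g.progression_flag,
            }
            for g in truth.scan_gold
        ]
    ).to_csv(directory / "scan_gold.csv", index=False)
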