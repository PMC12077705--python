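"""End-to-end orchestration: all four endpoints over a cohort bundle,
plus the standard comparison battery."""

from __future__ import annotations

from dataclasses import asdict
from typing import Optional

from . import compare
from .lexicon import TermLexicon, default_lexicon
from .records import (
    CohortBundle,
    EndpointResult,
    Method,
    apply_eligibility,
    clinical_pfs,
)
from .steroid import steroid_pfs
from .nlp import nlp_pfs
from .volumetric import volumetric_pfs

#: The six pairwise comparisons reported by default: each automated method
#: against the clinical standard, then the automated methods against each
#: other.
DEFAULT_PAIRS = (
    (Method.STEROID, Method.CLINICAL),
    (Method.NLP, Method.CLINICAL),
    (Method.VOLUMETRIC, Method.CLINICAL),
    (Method.NLP, Method.STEROID),
    (Method.NLP, Method.VOLUMETRIC),
    (Method.VOLUMETRIC, Method.STEROID),
)


def derive_all_endpoints(
    bundle: CohortBundle,
    lexicon: Optional[TermLexicon] = None,
    eligible_only: bool = True,
) -> list[EndpointResult]:
    """One EndpointResult per (eligible patient, method)."""
    lexicon = lexicon or default_lexicon()
    ids = apply_eligibility(bundle) if eligible_only else bundle.patient_ids()
    results = []
    for patient in bundle.patients:
        if patient.patient_id not in ids:
            continue
        rxs, reports, scans = bundle.for_patient(patient.patient_id)
        results.append(clinical_pfs(patient))
        results.append(steroid_pfs(patient, rxs))
        results.append(nlp_pfs(patient, reports, lexicon))
        results.append(volumetric_pfs(patient, scans))
    return results


def _by_method(results: list[EndpointResult]) -> dict[Method, list[EndpointResult]]:
    grouped: dict[Method, list[EndpointResult]] = {m: [] for m in Method}
    for r in results:
        grouped[r.method].append(r)
    return grouped


def comparison_battery(
    results: list[EndpointResult],
    cohort_n: int,
    window_months: float = 2.0,
    bonferroni_m: int = compare.DEFAULT_BONFERRONI_M,
) -> dict:
    """Descriptive summaries, paired differences, agreement fractions,
    Kruskal-Wallis omnibus on the all-methods complete cases, and the six
    Bonferroni-adjusted Wilcoxon pairwise tests."""
    grouped = _by_method(results)
    wide = compare.aggregate(results)

    summaries = {
        m.value: compare.summarize(grouped[m], cohort_n) for m in Method if grouped[m]
    }
    differences = {}
    agreement = {}
    for m in (Method.STEROID, Method.NLP, Method.VOLUMETRIC):
        diff = compare.difference_stats(grouped[m], grouped[Method.CLINICAL])
        if diff is not None:
            differences[m.value] = diff
        frac = compare.agreement_within(
            grouped[m], grouped[Method.CLINICAL], window_months
        )
        if frac is not None:
            agreement[m.value] = frac

    # omnibus on patients progressing under all four methods
    complete = wide.dropna()
    omnibus = None
    if len(complete) >= 2 and complete.shape[1] >= 2:
        omnibus = compare.kruskal_wallis(
            [complete[c].to_numpy() for c in complete.columns]
        )

    pairs = {}
    for a, b in DEFAULT_PAIRS:
        sub = wide[[a.value, b.value]].dropna()
        if len(sub):
            pairs[(a.value, b.value)] = (
                sub[a.value].to_numpy(),
                sub[b.value].to_numpy(),
            )
    pairwise = compare.wilcoxon_pairwise(pairs, m=bonferroni_m)

    return {
        "summaries": summaries,
        "differences": differences,
        "agreement_within_window": agreement,
        "window_months": window_months,
        "omnibus": omnibus,
        "pairwise": pairwise,
        "n_complete_cases": int(len(complete)),
    }


def battery_to_jsonable(battery: dict) -> dict:
    """JSON-serializable view of :func:`comparison_battery` output."""
    out = {
        "window_months": battery["window_months"],
        "n_complete_cases": battery["n_complete_cases"],
        "summaries": {
            k: {**asdict(v), "method": v.method.value}
            for k, v in battery["summaries"].items()
        },
        "differences": {
            k: {**asdict(v), "method": v.method.value}
            for k, v in battery["differences"].items()
        },
        "agreement_within_window": battery["agreement_within_window"],
        "pairwise": [asdict(t) for t in battery["pairwise"]],
    }
    out["omnibus"] = (
        None if battery["omnibus"] is None else asdict(battery["omnibus"])
    )
    return out
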