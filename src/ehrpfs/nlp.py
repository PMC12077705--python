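"""Rule-based NLP progression endpoint for brain-MRI radiology reports.

The pipeline mirrors how a clinician skims a surveillance report: find
mentions of progression-flavored language (growth, recurrence, increased
enhancement) and stability-flavored language (stable, unchanged,
decreased), attribute each mention to its sentence context via
ConText-style directional triggers (negation — expanded with no-change
phrasing —, historical, hypothetical, family, and a custom surgical
modifier for post-operative/pseudoprogression changes), re-categorize
accordingly, and call the document by a one-to-one frequency rule:
progression iff unmodified progression mentions outnumber stability
mentions.  The first progression-positive report after radiotherapy dates
the endpoint.

Everything is deterministic: identical text and lexicon give identical
assessments.
"""

from __future__ import annotations

import datetime as dt
import re
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .lexicon import TermLexicon, Trigger
from .records import (
    EndpointResult,
    Method,
    PatientRecord,
    RadiologyReport,
    months_between,
)

STATUS_PROGRESSION = "progression"
STATUS_NO_PROGRESSION = "no_progression"

#: document_type patterns (case-insensitive regex) identifying brain MRI.
DEFAULT_BRAIN_MRI_PATTERNS = (r"mri.*brain", r"brain.*mri")

_TOKEN_RE = re.compile(r"[A-Za-z][A-Za-z\-']*")
_SENTENCE_RE = re.compile(r"[^.!?;\n]+[.!?;]?")


def normalize_text(text: str) -> str:
    """Standardize paragraph formatting and spacing.  Idempotent."""
    text = text.replace("\r\n", "\n").replace("\r", "\n")
    text = re.sub(r"[ \t]+", " ", text)
    text = re.sub(r" ?\n ?", "\n", text)
    text = re.sub(r"\n{2,}", "\n", text)
    return text.strip()


@dataclass(frozen=True)
class TermMatch:
    """One matched lexicon term with its sentence context."""

    surface_text: str
    matched_stem: str
    base_category: str  # "progression" | "stability"
    modifiers: frozenset[str]
    sentence_index: int
    span: tuple[int, int]  # 0-based, half-open, document coordinates


def _sentence_spans(text: str) -> list[tuple[int, int]]:
    spans = []
    for m in _SENTENCE_RE.finditer(text):
        if m.group().strip():
            spans.append((m.start(), m.end()))
    return spans


def _match_stem(token: str, stems: frozenset[str]) -> Optional[str]:
    for stem in stems:
        if token.startswith(stem):
            return stem
    return None


def _trigger_scopes(
    tokens: list[str], triggers: Sequence[Trigger], terminators: frozenset[str]
) -> list[tuple[Trigger, set[int]]]:
    """Token-index scope of every trigger occurrence in one sentence.

    Scope runs from the trigger to the sentence boundary in the trigger's
    direction, cut at the nearest terminator token; the trigger's own
    tokens are excluded.
    """
    term_positions = [i for i, tok in enumerate(tokens) if tok in terminators]
    scopes: list[tuple[Trigger, set[int]]] = []
    n = len(tokens)
    for trig in triggers:
        phrase = trig.phrase.split()
        plen = len(phrase)
        for i in range(n - plen + 1):
            if tokens[i : i + plen] != phrase:
                continue
            scope: set[int] = set()
            if trig.direction in ("forward", "bidirectional"):
                stop = n
                for t in term_positions:
                    if t >= i + plen:
                        stop = t
                        break
                scope.update(range(i + plen, stop))
            if trig.direction in ("backward", "bidirectional"):
                start = 0
                for t in reversed(term_positions):
                    if t < i:
                        start = t + 1
                        break
                scope.update(range(start, i))
            if scope:
                scopes.append((trig, scope))
    return scopes


def extract_matches(text: str, lexicon: TermLexicon) -> list[TermMatch]:
    """Sentence-segment *text* and match category stems with modifiers.

    Expects normalized text.  A match receives every modifier whose
    trigger occurs in the same sentence with a directional scope covering
    the matched token.
    """
    matches: list[TermMatch] = []
    for s_idx, (s_start, s_end) in enumerate(_sentence_spans(text)):
        sentence = text[s_start:s_end]
        token_spans = [(m.group(), m.start(), m.end()) for m in _TOKEN_RE.finditer(sentence)]
        tokens = [t[0].lower() for t in token_spans]
        scopes = _trigger_scopes(tokens, lexicon.triggers, lexicon.terminators)
        for i, (surface, t_start, t_end) in enumerate(token_spans):
            token = tokens[i]
            stem = _match_stem(token, lexicon.progression_stems)
            category = "progression"
            if stem is None:
                stem = _match_stem(token, lexicon.stability_stems)
                category = "stability"
            if stem is None:
                continue
            modifiers = frozenset(
                trig.modifier for trig, scope in scopes if i in scope
            )
            matches.append(
                TermMatch(
                    surface_text=surface,
                    matched_stem=stem,
                    base_category=category,
                    modifiers=modifiers,
                    sentence_index=s_idx,
                    span=(s_start + t_start, s_start + t_end),
                )
            )
    return matches


def categorize_match(base_category: str, modifiers: frozenset[str]) -> Optional[str]:
    """Re-categorization rule for one match.

    Returns the bucket the match counts toward ("progression",
    "stability", "surgical") or None if dropped.  Modifier precedence:
    NEGATED > HISTORICAL > SURGICAL > HYPOTHETICAL/FAMILY.

    Progression terms negated or historical count as stability (a negated
    progression statement is an assertion of stability); surgical-context
    progression terms go to their own bucket (likely pseudoprogression);
    purely hypothetical/familial mentions are dropped.  Negated stability
    terms are dropped rather than inverted.
    """
    if base_category == "progression":
        if "NEGATED" in modifiers or "HISTORICAL" in modifiers:
            return "stability"
        if "SURGICAL" in modifiers:
            return "surgical"
        if "HYPOTHETICAL" in modifiers or "FAMILY" in modifiers:
            return None
        return "progression"
    if base_category == "stability":
        if "NEGATED" in modifiers:
            return None
        if "HISTORICAL" in modifiers or "SURGICAL" in modifiers:
            return "stability"
        if "HYPOTHETICAL" in modifiers or "FAMILY" in modifiers:
            return None
        return "stability"
    raise ValueError(f"unknown base category {base_category!r}")


def recategorize(matches: Iterable[TermMatch]) -> tuple[int, int, int]:
    """Tally matches into (progression_count, stability_count,
    surgical_count) after context re-categorization."""
    prog = stab = surg = 0
    for m in matches:
        bucket = categorize_match(m.base_category, m.modifiers)
        if bucket == "progression":
            prog += 1
        elif bucket == "stability":
            stab += 1
        elif bucket == "surgical":
            surg += 1
    return prog, stab, surg


def determine_status(
    progression_count: int, stability_count: int, surgical_count: int
) -> str:
    """One-to-one document rule.

    Progression iff unmodified progression mentions strictly outnumber
    stability mentions.  On a tie the surgical bucket (post-operative
    change, read as stability) joins the stability side, so ties — and
    documents with no evidence at all — resolve to no_progression.
    """
    if min(progression_count, stability_count, surgical_count) < 0:
        raise ValueError("negative category count")
    if progression_count > stability_count:
        return STATUS_PROGRESSION
    # tie or deficit: surgical joins stability, which can only confirm
    # no_progression since stability_count + surgical_count >= progression_count
    return STATUS_NO_PROGRESSION


@dataclass(frozen=True)
class DocumentAssessment:
    """Per-report audit record: counts, status, and the matches behind them."""

    report_date: dt.date
    progression_count: int
    stability_count: int
    surgical_count: int
    status: str
    matches: tuple[TermMatch, ...]


def assess_document(report: RadiologyReport, lexicon: TermLexicon) -> DocumentAssessment:
    text = normalize_text(report.body_text)
    matches = extract_matches(text, lexicon)
    prog, stab, surg = recategorize(matches)
    return DocumentAssessment(
        report_date=report.report_date,
        progression_count=prog,
        stability_count=stab,
        surgical_count=surg,
        status=determine_status(prog, stab, surg),
        matches=tuple(matches),
    )


def select_brain_mri_reports(
    reports: Iterable[RadiologyReport],
    rt_end_date: dt.date,
    patterns: Sequence[str] = DEFAULT_BRAIN_MRI_PATTERNS,
) -> list[RadiologyReport]:
    """Keep brain-MRI reports dated strictly after the end of radiotherapy."""
    compiled = [re.compile(p, re.IGNORECASE) for p in patterns]
    return [
        r
        for r in reports
        if r.report_date > rt_end_date
        and any(c.search(r.document_type) for c in compiled)
    ]


def nlp_pfs(
    patient: PatientRecord,
    reports: Sequence[RadiologyReport],
    lexicon: TermLexicon,
) -> EndpointResult:
    """Report-derived endpoint: date of the earliest post-RT brain-MRI
    report whose document status is progression.  Evidence carries the
    full per-report assessment sequence as an audit trail."""
    selected = sorted(
        select_brain_mri_reports(reports, patient.crt_end_date),
        key=lambda r: r.report_date,
    )
    assessments = [assess_document(r, lexicon) for r in selected]
    for assessment in assessments:
        if assessment.status == STATUS_PROGRESSION:
            return EndpointResult(
                patient.patient_id,
                Method.NLP,
                progressed=True,
                progression_date=assessment.report_date,
                pfs_months=months_between(
                    patient.crt_end_date, assessment.report_date
                ),
                evidence=assessments,
            )
    return EndpointResult(
        patient.patient_id, Method.NLP, progressed=False, evidence=assessments
    )
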