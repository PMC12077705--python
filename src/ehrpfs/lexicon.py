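"""Term lexicon for rule-based report analysis.

A :class:`TermLexicon` carries progression / stability stem sets plus five
trigger families (negation, historical, hypothetical, family, surgical),
each trigger a whole-token phrase with a directional, sentence-bounded
scope.  The packaged default lexicon is a reconstruction from RANO
response language and is meant to be edited per site.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Literal

import yaml

Direction = Literal["forward", "backward", "bidirectional"]

MODIFIERS = ("NEGATED", "HISTORICAL", "HYPOTHETICAL", "FAMILY", "SURGICAL")

_TRIGGER_FIELDS = {
    "negation_triggers": "NEGATED",
    "historical_triggers": "HISTORICAL",
    "hypothetical_triggers": "HYPOTHETICAL",
    "family_triggers": "FAMILY",
    "surgical_triggers": "SURGICAL",
}


@dataclass(frozen=True)
class Trigger:
    phrase: str
    direction: Direction
    modifier: str

    def __post_init__(self) -> None:
        if self.direction not in ("forward", "backward", "bidirectional"):
            raise ValueError(f"bad trigger direction {self.direction!r}")
        if self.modifier not in MODIFIERS:
            raise ValueError(f"bad trigger modifier {self.modifier!r}")
        if not self.phrase.strip():
            raise ValueError("empty trigger phrase")


@dataclass(frozen=True)
class TermLexicon:
    progression_stems: frozenset[str]
    stability_stems: frozenset[str]
    triggers: tuple[Trigger, ...]
    terminators: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        overlap = self.progression_stems & self.stability_stems
        if overlap:
            raise ValueError(
                f"progression and stability stems must be disjoint: {sorted(overlap)}"
            )
        if not self.progression_stems or not self.stability_stems:
            raise ValueError("both stem sets must be non-empty")


def _normalize_stems(stems: Iterable[str]) -> frozenset[str]:
    return frozenset(s.strip().lower() for s in stems if s.strip())


def lexicon_from_dict(data: dict) -> TermLexicon:
    triggers = []
    for field_name, modifier in _TRIGGER_FIELDS.items():
        for entry in data.get(field_name, []):
            triggers.append(
                Trigger(
                    phrase=str(entry["phrase"]).strip().lower(),
                    direction=entry.get("direction", "forward"),
                    modifier=modifier,
                )
            )
    return TermLexicon(
        progression_stems=_normalize_stems(data.get("progression_stems", [])),
        stability_stems=_normalize_stems(data.get("stability_stems", [])),
        triggers=tuple(triggers),
        terminators=_normalize_stems(data.get("terminators", [])),
    )


def load_lexicon(path: Path | str) -> TermLexicon:
    """Load a lexicon from a YAML file."""
    with open(path, encoding="utf-8") as handle:
        return lexicon_from_dict(yaml.safe_load(handle))


def default_lexicon() -> TermLexicon:
    """The packaged default (reconstructed) lexicon."""
    text = (
        resources.files("ehrpfs").joinpath("data/default_lexicon.yaml").read_text()
    )
    return lexicon_from_dict(yaml.safe_load(text))
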