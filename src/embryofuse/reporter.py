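"""Consensus-grounded stage reports with a hallucination guardrail.

The predicted class acts as an exact retrieval key into a structured
knowledge base of per-stage consensus criteria; a report is synthesized from
templates parameterized *only* by the prediction and the retrieved entry's
fields, so every stage-specific morphological term in the output is
traceable to the knowledge base (closed-vocabulary guarantee).  A validator
re-checks any report — templated or rewritten by a pluggable generator hook
— against the stage's forbidden terms, e.g. an "inner cell mass" can never
be described in a 2-cell embryo report.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

from embryofuse.phantom import CLASSES

__all__ = [
    "KnowledgeBaseError", "IncompleteKBError", "DuplicateEntryError",
    "KnowledgeEntry", "StageReport",
    "default_kb_path", "load_knowledge", "retrieve",
    "generate_report", "validate_report",
]


class KnowledgeBaseError(ValueError):
    pass


class IncompleteKBError(KnowledgeBaseError):
    pass


class DuplicateEntryError(KnowledgeBaseError):
    pass


@dataclass(frozen=True)
class KnowledgeEntry:
    stage_key: str
    stage_name: str
    consensus_criteria: tuple[str, ...]
    typical_features: tuple[str, ...]
    forbidden_terms: tuple[str, ...]
    source_tag: str

    def validate(self) -> None:
        if not self.consensus_criteria:
            raise KnowledgeBaseError(f"entry {self.stage_key!r} has no criteria")
        typical = {t.lower() for t in self.typical_features}
        overlap = typical & {t.lower() for t in self.forbidden_terms}
        if overlap:
            raise KnowledgeBaseError(
                f"entry {self.stage_key!r} lists terms as both typical and "
                f"forbidden: {sorted(overlap)}"
            )


@dataclass
class StageReport:
    label: str
    observation: str
    confidence: str
    confidence_tier: str
    probability: float
    consensus_alignment: str
    source_tag: str
    grade: str | None = None

    def sections(self) -> dict[str, str]:
        return {
            "observation": self.observation,
            "confidence": self.confidence,
            "consensus_alignment": self.consensus_alignment,
        }

    def to_text(self) -> str:
        lines = [
            f"Stage assessment: {self.label}",
            f"Observation: {self.observation}",
            f"Confidence: {self.confidence}",
            f"Consensus alignment: {self.consensus_alignment}",
        ]
        if self.grade is not None:
            lines.append(f"Grade: {self.grade}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "observation": self.observation,
            "confidence": self.confidence,
            "confidence_tier": self.confidence_tier,
            "probability": self.probability,
            "consensus_alignment": self.consensus_alignment,
            "source_tag": self.source_tag,
            "grade": self.grade,
        }


def default_kb_path() -> Path:
    return Path(resources.files("embryofuse") / "data" / "knowledge_base.yaml")


def load_knowledge(path=None) -> dict[str, KnowledgeEntry]:
    """Load and validate the structured knowledge base (bundled by default).

    Requires exactly one entry for each of the seven stage classes; duplicate
    stage keys and typical/forbidden overlaps are rejected.
    """
    path = Path(path) if path is not None else default_kb_path()
    raw = yaml.safe_load(path.read_text())
    if not isinstance(raw, dict) or "entries" not in raw:
        raise KnowledgeBaseError("knowledge base must be a mapping with an 'entries' list")
    kb: dict[str, KnowledgeEntry] = {}
    for item in raw["entries"]:
        entry = KnowledgeEntry(
            stage_key=item["stage_key"],
            stage_name=item["stage_name"],
            consensus_criteria=tuple(item["consensus_criteria"]),
            typical_features=tuple(item["typical_features"]),
            forbidden_terms=tuple(item.get("forbidden_terms", ())),
            source_tag=item["source_tag"],
        )
        if entry.stage_key in kb:
            raise DuplicateEntryError(f"duplicate entry for stage {entry.stage_key!r}")
        entry.validate()
        kb[entry.stage_key] = entry
    missing = [c for c in CLASSES if c not in kb]
    if missing:
        raise IncompleteKBError(f"knowledge base is missing stages: {missing}")
    return kb


def retrieve(kb: dict[str, KnowledgeEntry], label: str, top_k: int = 1,
             similarity_hook=None) -> list[KnowledgeEntry]:
    """Exact-key retrieval; a similarity hook may append up to ``top_k - 1``
    related entries, otherwise only the exact entry is returned (no fabricated
    neighbors)."""
    if label not in kb:
        raise KeyError(f"unknown stage label {label!r}")
    entries = [kb[label]]
    if similarity_hook is not None and top_k > 1:
        extra = [e for e in similarity_hook(kb, label, top_k - 1)
                 if e.stage_key != label]
        entries.extend(extra[: top_k - 1])
    return entries


def _confidence_tier(probability: float, thresholds: tuple[float, float]) -> str:
    high, moderate = thresholds
    if probability >= high:
        return "High"
    if probability >= moderate:
        return "Moderate"
    return "Low"


def generate_report(prediction: dict, entries: list[KnowledgeEntry],
                    thresholds: tuple[float, float] = (0.9, 0.7),
                    grade_map=None, generator_hook=None) -> StageReport:
    """Synthesize the three-section stage report from the retrieved entry.

    ``prediction`` carries ``label`` and ``probability``.  The templates draw
    exclusively on the entry's fields; ``grade_map`` (probability -> tier) adds
    an optional quality grade; ``generator_hook`` may rephrase the drafted
    report but its output must still pass :func:`validate_report`.
    """
    if not entries:
        raise ValueError("report generation requires at least one retrieved entry")
    label = prediction["label"]
    probability = float(prediction["probability"])
    if not 0.0 <= probability <= 1.0:
        raise ValueError(f"probability must lie in [0, 1], got {probability}")
    entry = entries[0]
    tier = _confidence_tier(probability, thresholds)

    features = ", ".join(entry.typical_features[:3])
    observation = (
        f"Detected features typical of the {entry.stage_name}: {features}."
    )
    confidence = (
        f"{tier} confidence in the {entry.stage_name} assessment "
        f"(probability {probability:.2f})."
    )
    alignment = (
        f"Aligns with consensus criteria for the {entry.stage_name} "
        f"[{entry.source_tag}]: {entry.consensus_criteria[0]}"
    )
    report = StageReport(
        label=label,
        observation=observation,
        confidence=confidence,
        confidence_tier=tier,
        probability=probability,
        consensus_alignment=alignment,
        source_tag=entry.source_tag,
        grade=grade_map(probability) if grade_map is not None else None,
    )
    if generator_hook is not None:
        report = generator_hook(report, entry)
    return report


def validate_report(report: StageReport, label: str,
                    kb: dict[str, KnowledgeEntry]) -> list[str]:
    """Return every guardrail violation in ``report`` (empty list = pass).

    Violations are: a stage-forbidden term present anywhere in the report text
    (case-insensitive, word-boundary match) or a missing/empty section.
    """
    if label not in kb:
        raise KeyError(f"unknown stage label {label!r}")
    entry = kb[label]
    violations = []
    text = " ".join(report.sections().values())
    for term in entry.forbidden_terms:
        if re.search(rf"\b{re.escape(term)}\b", text, flags=re.IGNORECASE):
            violations.append(f"forbidden term: {term}")
    for name, value in report.sections().items():
        if not value or not value.strip():
            violations.append(f"missing section: {name}")
    return violations
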