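"""Core record type for SOAP-structured emergency-department notes.

A record is one ED encounter documented in the SOAP framework: four
free-text paragraphs (Subjective, Objective, Assessment, Plan) plus the
disposition label observed 24 h after first evaluation — ``inpatient``
(a ward bed was required) or ``discharged``.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

INPATIENT = "inpatient"
DISCHARGED = "discharged"
UNKNOWN = "unknown"
LABELS = (INPATIENT, DISCHARGED, UNKNOWN)

#: Section key order used everywhere (Subjective, Objective, Assessment, Plan).
SECTION_KEYS = ("S", "O", "A", "P")


@dataclass(frozen=True)
class SoapRecord:
    """One ED encounter: four SOAP sections and an optional disposition."""

    record_id: str
    subjective: str = ""
    objective: str = ""
    assessment: str = ""
    plan: str = ""
    label: str = UNKNOWN

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValueError(
                f"label must be one of {LABELS}, got {self.label!r}"
            )

    @property
    def sections(self) -> tuple[str, str, str, str]:
        return (self.subjective, self.objective, self.assessment, self.plan)

    def is_complete(self) -> bool:
        """True iff all four sections are non-empty after whitespace stripping."""
        return all(s.strip() for s in self.sections)

    @property
    def text(self) -> str:
        """All four sections joined in S-O-A-P order (paragraph concatenation)."""
        return " ".join(self.sections)

    def duplicate_key(self) -> str:
        """Identity key for duplicate detection.

        Lowercased raw section texts joined with a non-printing separator;
        whitespace is deliberately *not* collapsed so byte-level copies are
        duplicates while distinct blank records are not.
        """
        return "\x1f".join(s.lower() for s in self.sections)

    def with_label(self, label: str) -> "SoapRecord":
        return replace(self, label=label)


def labels_of(records: Sequence[SoapRecord]) -> list[str]:
    return [r.label for r in records]


# ---------------------------------------------------------------------------
# Corpus I/O: JSON-lines and CSV with columns id, S, O, A, P, label.
# ---------------------------------------------------------------------------

def _to_row(record: SoapRecord) -> dict[str, str]:
    return {
        "id": record.record_id,
        "S": record.subjective,
        "O": record.objective,
        "A": record.assessment,
        "P": record.plan,
        "label": record.label,
    }


def _from_row(row: dict) -> SoapRecord:
    label = row.get("label") or UNKNOWN
    return SoapRecord(
        record_id=str(row["id"]),
        subjective=str(row.get("S", "") or ""),
        objective=str(row.get("O", "") or ""),
        assessment=str(row.get("A", "") or ""),
        plan=str(row.get("P", "") or ""),
        label=label,
    )


def write_jsonl(records: Iterable[SoapRecord], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for rec in records:
            fh.write(json.dumps(_to_row(rec), ensure_ascii=False) + "\n")


def read_jsonl(path: str | Path) -> list[SoapRecord]:
    out: list[SoapRecord] = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip("\n")
            if line:
                out.append(_from_row(json.loads(line)))
    return out


def write_csv(records: Iterable[SoapRecord], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=["id", "S", "O", "A", "P", "label"])
        writer.writeheader()
        for rec in records:
            writer.writerow(_to_row(rec))


def read_csv(path: str | Path) -> list[SoapRecord]:
    with open(path, encoding="utf-8", newline="") as fh:
        return [_from_row(row) for row in csv.DictReader(fh)]
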