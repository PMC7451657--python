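"""Exclusion rules for raw SOAP-note corpora, with per-class accounting.

Four rules are applied, in a fixed precedence, before any modelling:

1. **duplicates** — byte-identical copies (lowercased section texts; the
   first occurrence is kept);
2. **explicit status** — the final disposition leaks into the note itself
   (e.g. "HAA" for hospital admission authorized, "PD" for patient
   discharged, "patient left");
3. **empty** — all four sections blank after whitespace stripping;
4. **incomplete** — at least one, but not all, sections blank.

Each record is removed by at most one rule (first match), so the report is
a partition: initial = removed + final, per class and in total. Precedence
matters — an exact copy of an empty record counts as a duplicate, not as
empty.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .records import DISCHARGED, INPATIENT, SoapRecord

__all__ = [
    "FilterReport",
    "is_explicit_status",
    "is_empty",
    "is_incomplete",
    "filter_corpus",
    "load_phrase_list",
    "save_phrase_list",
]

#: Abbreviations this short are matched on word boundaries; longer phrases
#: by substring (after whitespace normalization, case-insensitive).
_BOUNDARY_MAX_LEN = 3


@dataclass(frozen=True)
class ClassCounts:
    inpatient: int
    discharged: int

    @property
    def total(self) -> int:
        return self.inpatient + self.discharged


@dataclass(frozen=True)
class FilterReport:
    """Per-class removal bookkeeping (the study's selection table layout)."""

    initial: ClassCounts
    duplicates: ClassCounts
    explicit_status: ClassCounts
    empty: ClassCounts
    incomplete: ClassCounts
    final: ClassCounts

    _ROWS = (
        ("initial", "Number of reports in the original database", +1),
        ("duplicates", "Duplicated reports", -1),
        ("explicit_status", "Information on final status explicit in reports", -1),
        ("empty", "Empty reports", -1),
        ("incomplete", "Incomplete SOAP reports", -1),
        ("final", "Number of reports used in the study", +1),
    )

    @classmethod
    def from_counts(
        cls,
        initial: tuple[int, int],
        duplicates: tuple[int, int] = (0, 0),
        explicit_status: tuple[int, int] = (0, 0),
        empty: tuple[int, int] = (0, 0),
        incomplete: tuple[int, int] = (0, 0),
    ) -> "FilterReport":
        """Build a report from (inpatient, discharged) tuples; final is derived."""
        rows = {
            "initial": ClassCounts(*initial),
            "duplicates": ClassCounts(*duplicates),
            "explicit_status": ClassCounts(*explicit_status),
            "empty": ClassCounts(*empty),
            "incomplete": ClassCounts(*incomplete),
        }
        final = ClassCounts(
            rows["initial"].inpatient
            - sum(rows[k].inpatient for k in ("duplicates", "explicit_status", "empty", "incomplete")),
            rows["initial"].discharged
            - sum(rows[k].discharged for k in ("duplicates", "explicit_status", "empty", "incomplete")),
        )
        report = cls(final=final, **rows)
        report.validate()
        return report

    def validate(self) -> None:
        removed_inp = sum(
            getattr(self, k).inpatient
            for k in ("duplicates", "explicit_status", "empty", "incomplete")
        )
        removed_dis = sum(
            getattr(self, k).discharged
            for k in ("duplicates", "explicit_status", "empty", "incomplete")
        )
        if self.final.inpatient != self.initial.inpatient - removed_inp:
            raise ValueError("inpatient column does not balance")
        if self.final.discharged != self.initial.discharged - removed_dis:
            raise ValueError("discharged column does not balance")
        for key, _, _ in self._ROWS:
            counts = getattr(self, key)
            if counts.inpatient < 0 or counts.discharged < 0:
                raise ValueError(f"negative count in row {key!r}")

    def to_tsv(self) -> str:
        """Mirror of the study's selection table (removals printed negative)."""
        lines = ["Description\tInpatient\tDischarged\tTotal"]
        for key, desc, sign in self._ROWS:
            c = getattr(self, key)
            lines.append(
                f"{desc}\t{sign * c.inpatient}\t{sign * c.discharged}\t{sign * c.total}"
            )
        return "\n".join(lines) + "\n"

    @classmethod
    def from_tsv(cls, text: str) -> "FilterReport":
        by_desc = {}
        for line in text.strip().splitlines()[1:]:
            desc, inp, dis, _tot = line.split("\t")
            by_desc[desc] = (abs(int(inp)), abs(int(dis)))
        kwargs = {key: ClassCounts(*by_desc[desc]) for key, desc, _ in cls._ROWS}
        report = cls(**kwargs)
        report.validate()
        return report


def _normalize_ws(text: str) -> str:
    return " ".join(text.split())


def _phrase_matcher(phrases: Sequence[str]) -> re.Pattern:
    if not phrases:
        raise ValueError("phrase list must be non-empty")
    parts = []
    for p in phrases:
        p = _normalize_ws(p)
        esc = re.escape(p)
        if len(p) <= _BOUNDARY_MAX_LEN:
            parts.append(rf"\b{esc}\b")  # avoid e.g. "pd" inside "copd"
        else:
            parts.append(esc)
    return re.compile("|".join(parts), flags=re.IGNORECASE)


def is_explicit_status(record: SoapRecord, phrases: Sequence[str]) -> bool:
    """True iff any leak phrase occurs in any of the four sections."""
    pattern = _phrase_matcher(phrases)
    return any(pattern.search(_normalize_ws(s)) for s in record.sections)


def is_empty(record: SoapRecord) -> bool:
    """True iff all four sections are blank after whitespace stripping."""
    return not any(s.strip() for s in record.sections)


def is_incomplete(record: SoapRecord) -> bool:
    """True iff at least one but not all sections are blank."""
    blanks = sum(1 for s in record.sections if not s.strip())
    return 1 <= blanks <= 3


def filter_corpus(
    records: Sequence[SoapRecord], phrases: Sequence[str]
) -> tuple[list[SoapRecord], FilterReport]:
    """Apply the four exclusion rules and account for every removal.

    Rules are applied per record in precedence order duplicate → explicit
    status → empty → incomplete; the first matching rule claims the record.
    All records must carry a known disposition label (needed for per-class
    accounting).
    """
    unlabeled = [r.record_id for r in records if r.label not in (INPATIENT, DISCHARGED)]
    if unlabeled:
        raise ValueError(
            f"per-class accounting requires labeled records; unlabeled ids: "
            f"{unlabeled[:20]}"
        )
    pattern = _phrase_matcher(phrases)

    counts = {
        key: {INPATIENT: 0, DISCHARGED: 0}
        for key in ("initial", "duplicates", "explicit_status", "empty", "incomplete")
    }
    clean: list[SoapRecord] = []
    seen: set[str] = set()
    for rec in records:
        counts["initial"][rec.label] += 1
        key = rec.duplicate_key()
        if key in seen:
            counts["duplicates"][rec.label] += 1
            continue
        seen.add(key)
        if any(pattern.search(_normalize_ws(s)) for s in rec.sections):
            counts["explicit_status"][rec.label] += 1
        elif is_empty(rec):
            counts["empty"][rec.label] += 1
        elif is_incomplete(rec):
            counts["incomplete"][rec.label] += 1
        else:
            clean.append(rec)

    def pair(key: str) -> tuple[int, int]:
        return (counts[key][INPATIENT], counts[key][DISCHARGED])

    report = FilterReport.from_counts(
        initial=pair("initial"),
        duplicates=pair("duplicates"),
        explicit_status=pair("explicit_status"),
        empty=pair("empty"),
        incomplete=pair("incomplete"),
    )
    return clean, report


def load_phrase_list(path: str | Path) -> list[str]:
    """One phrase per line; blank lines and leading/trailing space ignored."""
    with open(path, encoding="utf-8") as fh:
        return [line.strip() for line in fh if line.strip()]


def save_phrase_list(phrases: Iterable[str], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for p in phrases:
            fh.write(p + "\n")
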