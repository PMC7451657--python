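"""Synthetic SOAP-note corpus generator.

Real first-encounter ED notes are private, so every downstream stage is
exercised on generated corpora that emulate the *structure* of the study
data: four free-text sections per record, two roughly balanced disposition
classes, class-indicative multiword phrases (symptom phrases for
admissions, normal-exam phrases for discharges), plus stopwords, numerals
and punctuation noise. Contamination artifacts (duplicates, explicit
final-status leaks, empty and incomplete records) are injected with known
ground truth so filter bookkeeping can be verified exactly.

Text is assembled from banks of 1–3-token phrases so that bigram and
trigram features carry the class signal; tokens are lowercase ASCII
pseudo-words with a handful of real clinical anchor phrases. No attempt is
made to model actual Portuguese clinical language.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .filtering import FilterReport, is_explicit_status
from .records import DISCHARGED, INPATIENT, SoapRecord

__all__ = [
    "CorpusConfig",
    "ContaminationSpec",
    "RaterModel",
    "PhraseBanks",
    "build_phrase_banks",
    "generate_corpus",
    "inject_contamination",
    "simulate_rater",
    "DEFAULT_EXPLICIT_PHRASES",
    "DEFAULT_STOPWORDS",
]

#: Final-status leak phrases shipped by default (English translations of the
#: kinds of annotations found in real notes; short abbreviations are matched
#: on word boundaries by the filter).
DEFAULT_EXPLICIT_PHRASES = (
    "HAA",
    "patient left",
    "PD",
    "patient not located",
    "patient did not answer when called",
)

#: Function-word noise emitted between phrases.
DEFAULT_STOPWORDS = (
    "de", "da", "do", "em", "um", "uma", "para", "com", "os", "as",
    "que", "por", "ao", "dos", "das",
)

# Real clinical anchor phrases: symptoms for admissions, normal-exam /
# absence-of-symptom phrases for discharges.
_ADMISSION_ANCHORS = (
    "edema",
    "paroxysmal nocturnal dyspnea",
    "non measured fev",
)
_DISCHARGE_ANCHORS = (
    "well perfused extrem",
    "normal breath sound",
    "no history dysuria",
)

_PUNCT = (",", ".", ";", ":")


@dataclass(frozen=True)
class CorpusConfig:
    """Parameters of the synthetic corpus generator.

    ``class_balance`` is the fraction of inpatient records;
    ``signal_strength`` is the per-slot probability that a class-indicative
    phrase (rather than a neutral one) is emitted. The defaults mirror the
    study corpus shape: 9,030 usable records with 4,357 admissions.
    """

    n_records: int = 9030
    class_balance: float = 4357 / 9030
    signal_strength: float = 0.9
    vocab_sizes: tuple[int, int, int] = (40, 40, 120)  # admission, discharge, neutral
    phrases_per_section: int = 6
    stopword_rate: float = 0.3
    numeral_rate: float = 0.1
    punctuation_rate: float = 0.2
    seed: int = 0

    def validate(self) -> None:
        if self.n_records < 2:
            raise ValueError(f"n_records must be >= 2, got {self.n_records}")
        if not 0.0 < self.class_balance < 1.0:
            raise ValueError(
                f"class_balance must be in (0, 1), got {self.class_balance}"
            )
        if not 0.0 <= self.signal_strength <= 1.0:
            raise ValueError(
                f"signal_strength must be in [0, 1], got {self.signal_strength}"
            )
        for name in ("stopword_rate", "numeral_rate", "punctuation_rate"):
            rate = getattr(self, name)
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {rate}")
        if self.phrases_per_section < 1:
            raise ValueError(
                f"phrases_per_section must be >= 1, got {self.phrases_per_section}"
            )
        if any(v < 1 for v in self.vocab_sizes):
            raise ValueError(f"vocab_sizes must be positive, got {self.vocab_sizes}")


@dataclass(frozen=True)
class ContaminationSpec:
    """Counts of artifacts to inject, per class (inpatient, discharged)."""

    n_duplicates: tuple[int, int] = (0, 0)
    n_explicit_status: tuple[int, int] = (0, 0)
    n_empty: tuple[int, int] = (0, 0)
    n_incomplete: tuple[int, int] = (0, 0)
    explicit_phrases: tuple[str, ...] = DEFAULT_EXPLICIT_PHRASES
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_duplicates", "n_explicit_status", "n_empty", "n_incomplete"):
            pair = getattr(self, name)
            if any(v < 0 for v in pair):
                raise ValueError(f"{name} counts must be non-negative, got {pair}")
        if sum(self.n_explicit_status) > 0 and not self.explicit_phrases:
            raise ValueError(
                "explicit_phrases must be non-empty when n_explicit_status > 0"
            )


@dataclass(frozen=True)
class RaterModel:
    """Operating point of a simulated human grader.

    ``sensitivity`` is the probability a true inpatient is rated inpatient;
    ``specificity`` the probability a true discharged is rated discharged.
    """

    sensitivity: float
    specificity: float
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 <= self.sensitivity <= 1.0:
            raise ValueError(f"sensitivity must be in [0, 1], got {self.sensitivity}")
        if not 0.0 <= self.specificity <= 1.0:
            raise ValueError(f"specificity must be in [0, 1], got {self.specificity}")


@dataclass(frozen=True)
class PhraseBanks:
    admission: tuple[str, ...]
    discharge: tuple[str, ...]
    neutral: tuple[str, ...]
    stopwords: tuple[str, ...] = DEFAULT_STOPWORDS


def _pseudo_words(rng: np.random.Generator, n: int, taken: set[str]) -> list[str]:
    """Pronounceable lowercase ASCII pseudo-words, unique and >= 4 chars."""
    onsets = list("bcdfglmnprstvz")
    vowels = list("aeiou")
    words: list[str] = []
    while len(words) < n:
        k = rng.integers(2, 4)  # 2-3 syllables -> 4-6 chars
        w = "".join(
            onsets[rng.integers(len(onsets))] + vowels[rng.integers(len(vowels))]
            for _ in range(k)
        )
        if w not in taken:
            taken.add(w)
            words.append(w)
    return words


def build_phrase_banks(
    vocab_sizes: tuple[int, int, int] = (40, 40, 120)
) -> PhraseBanks:
    """Deterministic phrase banks: anchors plus 1–3-token pseudo-word phrases.

    Banks depend only on ``vocab_sizes`` (fixed internal seed) so that the
    informative feature set is stable across corpus seeds.
    """
    rng = np.random.default_rng(20140101)
    taken = set(DEFAULT_STOPWORDS)
    taken.update(w for p in DEFAULT_EXPLICIT_PHRASES for w in p.lower().split())

    def make_bank(size: int, anchors: tuple[str, ...]) -> tuple[str, ...]:
        bank = list(anchors[:size])
        n_extra = max(0, size - len(bank))
        words = _pseudo_words(rng, 3 * n_extra, taken)
        for i in range(n_extra):
            n_tok = int(rng.integers(1, 4))
            bank.append(" ".join(words[3 * i : 3 * i + n_tok]))
        return tuple(bank)

    n_adm, n_dis, n_neu = vocab_sizes
    return PhraseBanks(
        admission=make_bank(n_adm, _ADMISSION_ANCHORS),
        discharge=make_bank(n_dis, _DISCHARGE_ANCHORS),
        neutral=make_bank(n_neu, ()),
    )


def round_half_away(x: float) -> int:
    """Round half away from zero (deterministic and symmetric)."""
    return int(np.floor(abs(x) + 0.5) * np.sign(x)) if x else 0


def _decorate(tokens: list[str], rng: np.random.Generator, cfg: CorpusConfig) -> None:
    if tokens and rng.random() < cfg.punctuation_rate:
        tokens[-1] = tokens[-1] + _PUNCT[rng.integers(len(_PUNCT))]
    if rng.random() < cfg.stopword_rate:
        tokens.append(DEFAULT_STOPWORDS[rng.integers(len(DEFAULT_STOPWORDS))])
    if rng.random() < cfg.numeral_rate:
        tokens.append(str(rng.integers(1, 1000)))


def _section_text(
    label: str, banks: PhraseBanks, rng: np.random.Generator, cfg: CorpusConfig
) -> str:
    own = banks.admission if label == INPATIENT else banks.discharge
    tokens: list[str] = []
    for _ in range(cfg.phrases_per_section):
        use_signal = cfg.signal_strength > 0 and rng.random() < cfg.signal_strength
        bank = own if use_signal else banks.neutral
        tokens.extend(bank[rng.integers(len(bank))].split())
        _decorate(tokens, rng, cfg)
    return " ".join(tokens)


def _fresh_record(
    record_id: str,
    label: str,
    banks: PhraseBanks,
    rng: np.random.Generator,
    cfg: CorpusConfig,
) -> SoapRecord:
    s, o, a, p = (_section_text(label, banks, rng, cfg) for _ in range(4))
    return SoapRecord(record_id, s, o, a, p, label)


def generate_corpus(config: CorpusConfig) -> list[SoapRecord]:
    """Generate exactly ``n_records`` complete, duplicate-free labeled records.

    Class counts follow round-half-away-from-zero of ``n × class_balance``
    (clamped so both classes appear); the per-record class sequence is a
    seeded permutation. Identical config (including seed) gives a
    byte-identical corpus.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    banks = build_phrase_banks(config.vocab_sizes)

    n = config.n_records
    n_inp = min(max(round_half_away(n * config.class_balance), 1), n - 1)
    labels = np.array([INPATIENT] * n_inp + [DISCHARGED] * (n - n_inp))
    labels = labels[rng.permutation(n)]

    width = len(str(n))
    records: list[SoapRecord] = []
    seen: set[str] = set()
    for i, label in enumerate(labels):
        rec = _fresh_record(f"rec-{i:0{width}d}", str(label), banks, rng, config)
        # regenerate on the (vanishingly rare) exact text collision so the
        # clean corpus is guaranteed duplicate-free
        while rec.duplicate_key() in seen:
            rec = _fresh_record(f"rec-{i:0{width}d}", str(label), banks, rng, config)
        seen.add(rec.duplicate_key())
        records.append(rec)
    return records


def _sample_without_replacement(
    rng: np.random.Generator, pool: list[SoapRecord], k: int, what: str
) -> list[SoapRecord]:
    if k > len(pool):
        raise ValueError(
            f"cannot draw {k} {what} artifacts from a class pool of {len(pool)}"
        )
    idx = rng.choice(len(pool), size=k, replace=False)
    return [pool[i] for i in idx]


def inject_contamination(
    records: list[SoapRecord], spec: ContaminationSpec
) -> tuple[list[SoapRecord], FilterReport]:
    """Append known artifacts and return the corpus plus removal ground truth.

    Duplicates are exact copies of existing records under fresh ids;
    explicit-status artifacts are copies with a leak phrase appended to one
    section; empty artifacts have whitespace-only sections (each with a
    distinct amount of padding, so empties are not mutual duplicates);
    incomplete artifacts are copies with 1–3 randomly chosen sections
    blanked. The returned report counts exactly what was injected and equals
    the filter's accounting on the contaminated corpus.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    contaminated = list(records)
    seen = {r.duplicate_key() for r in records}
    pools = {
        INPATIENT: [r for r in records if r.label == INPATIENT],
        DISCHARGED: [r for r in records if r.label == DISCHARGED],
    }
    counter = 0

    def next_id(kind: str) -> str:
        nonlocal counter
        counter += 1
        return f"cont-{kind}-{counter:06d}"

    empty_pad = 0
    for ci, label in enumerate((INPATIENT, DISCHARGED)):
        pool = pools[label]

        for base in _sample_without_replacement(
            rng, pool, spec.n_duplicates[ci], "duplicate"
        ):
            contaminated.append(
                SoapRecord(next_id("dup"), *base.sections, label=label)
            )

        for base in _sample_without_replacement(
            rng, pool, spec.n_explicit_status[ci], "explicit-status"
        ):
            phrase = spec.explicit_phrases[rng.integers(len(spec.explicit_phrases))]
            sections = list(base.sections)
            j = int(rng.integers(4))
            sections[j] = f"{sections[j]} {phrase}"
            rec = SoapRecord(next_id("leak"), *sections, label=label)
            while rec.duplicate_key() in seen:  # two leaks on the same base
                sections[j] += " "
                rec = SoapRecord(next_id("leak"), *sections, label=label)
            seen.add(rec.duplicate_key())
            contaminated.append(rec)

        for _ in range(spec.n_empty[ci]):
            pad = " " * empty_pad
            empty_pad += 1
            contaminated.append(
                SoapRecord(next_id("empty"), pad, "", "", "", label=label)
            )

        for base in _sample_without_replacement(
            rng, pool, spec.n_incomplete[ci], "incomplete"
        ):
            sections = list(base.sections)
            n_blank = int(rng.integers(1, 4))
            for j in rng.choice(4, size=n_blank, replace=False):
                sections[j] = ""
            rec = SoapRecord(next_id("inc"), *sections, label=label)
            while rec.duplicate_key() in seen:
                k = next(i for i, s in enumerate(sections) if s.strip())
                sections[k] += " "
                rec = SoapRecord(next_id("inc"), *sections, label=label)
            seen.add(rec.duplicate_key())
            contaminated.append(rec)

        # leak-free guarantee for the base pool is by construction (phrase
        # banks exclude the leak vocabulary); assert on a sample for safety
        if pool and is_explicit_status(pool[0], list(spec.explicit_phrases)):
            raise ValueError("base corpus already contains explicit-status phrases")

    n_inp = len(pools[INPATIENT])
    n_dis = len(pools[DISCHARGED])
    report = FilterReport.from_counts(
        initial=(
            n_inp
            + spec.n_duplicates[0]
            + spec.n_explicit_status[0]
            + spec.n_empty[0]
            + spec.n_incomplete[0],
            n_dis
            + spec.n_duplicates[1]
            + spec.n_explicit_status[1]
            + spec.n_empty[1]
            + spec.n_incomplete[1],
        ),
        duplicates=spec.n_duplicates,
        explicit_status=spec.n_explicit_status,
        empty=spec.n_empty,
        incomplete=spec.n_incomplete,
    )
    return contaminated, report


def simulate_rater(records, model: RaterModel) -> list[str]:
    """Draw one binary rating per record from a fixed operating point.

    Accepts SoapRecords or bare label strings; every element must carry a
    known disposition. A true inpatient is rated inpatient with probability
    ``sensitivity``; a true discharged is rated discharged with probability
    ``specificity``. Draws are independent and seeded.
    """
    model.validate()
    truths = [r.label if isinstance(r, SoapRecord) else str(r) for r in records]
    bad = [i for i, t in enumerate(truths) if t not in (INPATIENT, DISCHARGED)]
    if bad:
        raise ValueError(f"records without a known label at positions {bad[:10]}")
    rng = np.random.default_rng(model.seed)
    u = rng.random(len(truths))
    out = []
    for t, ui in zip(truths, u):
        if t == INPATIENT:
            out.append(INPATIENT if ui < model.sensitivity else DISCHARGED)
        else:
            out.append(DISCHARGED if ui < model.specificity else INPATIENT)
    return out
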