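"""Text normalization: lowercasing, punctuation/digit removal, stopwords,
stemming, and n-gram extraction.

Tokens are delimited by blank spaces. Normalization lowercases, strips
punctuation marks and numerical characters, drops stopwords, then reduces
each surviving token to its radical form through a named stemming contract
(a deterministic token → token map). Features are the union of all
contiguous unigrams, bigrams and trigrams.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field
from typing import Callable

__all__ = [
    "TokenizerConfig",
    "normalize_text",
    "extract_ngrams",
    "identity_stem",
    "portuguese_suffix_stem",
    "STEMMERS",
    "NGRAM_JOINER",
]

NGRAM_JOINER = "_"

_STRIP = str.maketrans("", "", string.punctuation + string.digits)


def identity_stem(token: str) -> str:
    return token


# Plural / feminine / adverb / diminutive suffix reductions for Portuguese,
# in the minimal suffix-stripping (RSLP-S) style: rules are
# (suffix, minimum-stem-length, replacement), first match wins within each
# pass. Accented and ASCII-folded variants are both listed because source
# notes may or may not carry diacritics.
_PLURAL_RULES = (
    ("ões", 3, "ão"), ("oes", 3, "ao"),
    ("ães", 3, "ão"), ("aes", 3, "ao"),
    ("ais", 1, "al"), ("éis", 2, "el"), ("eis", 2, "el"),
    ("óis", 2, "ol"), ("ois", 2, "ol"),
    ("les", 3, "l"), ("res", 3, "r"), ("ns", 1, "m"),
    ("es", 3, ""), ("is", 2, "il"), ("s", 2, ""),
)
_FEMININE_RULES = (
    ("ona", 3, "ão"), ("ora", 3, "or"),
    ("na", 4, "no"), ("inha", 3, "inho"), ("esa", 3, "ês"),
    ("osa", 3, "oso"), ("íaca", 3, "íaco"), ("ica", 3, "ico"),
    ("ada", 2, "ado"), ("ida", 3, "ido"), ("ída", 3, "ido"),
    ("ima", 3, "imo"), ("iva", 3, "ivo"), ("eira", 3, "eiro"),
)
_ADVERB_RULES = (("mente", 4, ""),)
_DIMINUTIVE_RULES = (
    ("zinho", 2, ""), ("zinha", 2, ""), ("inho", 3, ""), ("inha", 3, ""),
)


def _apply_rules(token: str, rules) -> str:
    for suffix, min_stem, repl in rules:
        if token.endswith(suffix) and len(token) - len(suffix) >= min_stem:
            return token[: len(token) - len(suffix)] + repl
    return token


def portuguese_suffix_stem(token: str) -> str:
    """Light Portuguese suffix-stripping stemmer.

    Reduces plural, feminine, adverbial and diminutive forms to a common
    radical; deliberately conservative (suffix stripping only, no
    dictionary), so distinct words are rarely conflated.
    """
    token = _apply_rules(token, _PLURAL_RULES)
    token = _apply_rules(token, _ADVERB_RULES)
    token = _apply_rules(token, _FEMININE_RULES)
    token = _apply_rules(token, _DIMINUTIVE_RULES)
    return token


STEMMERS: dict[str, Callable[[str], str]] = {
    "identity": identity_stem,
    "portuguese": portuguese_suffix_stem,
}


@dataclass(frozen=True)
class TokenizerConfig:
    """Normalization settings: stopword list, stemming contract, casing.

    The default stemmer is the identity map (appropriate for synthetic
    pseudo-word corpora); ``"portuguese"`` selects the suffix-stripping
    stemmer.
    """

    stopwords: frozenset[str] = frozenset()
    stemmer: str = "identity"
    lowercase: bool = True

    def __post_init__(self) -> None:
        if self.stemmer not in STEMMERS:
            raise ValueError(
                f"unknown stemmer {self.stemmer!r}; available: {sorted(STEMMERS)}"
            )
        lowered = frozenset(w.lower() for w in self.stopwords)
        object.__setattr__(self, "stopwords", lowered)

    @property
    def stem(self) -> Callable[[str], str]:
        return STEMMERS[self.stemmer]


def normalize_text(text: str, config: TokenizerConfig | None = None) -> list[str]:
    """Tokenize on whitespace, then lowercase, strip punctuation and digits,
    drop stopwords, and stem. Tokens emptied by stripping are discarded."""
    config = config or TokenizerConfig()
    stem = config.stem
    out: list[str] = []
    for raw in text.split():
        tok = raw.lower() if config.lowercase else raw
        tok = tok.translate(_STRIP)
        if not tok or tok in config.stopwords:
            continue
        out.append(stem(tok))
    return out


def extract_ngrams(tokens: list[str], joiner: str = NGRAM_JOINER) -> list[str]:
    """All contiguous 1-, 2- and 3-grams, in positional order.

    ``m`` tokens yield ``m + max(m-1, 0) + max(m-2, 0)`` features.
    """
    grams = list(tokens)
    grams.extend(joiner.join(tokens[i : i + 2]) for i in range(len(tokens) - 1))
    grams.extend(joiner.join(tokens[i : i + 3]) for i in range(len(tokens) - 2))
    return grams
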