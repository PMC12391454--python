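"""Three-level clinical free-text preprocessing.

Levels are strictly cumulative:

* ``MINIMAL`` — lowercase, strip punctuation (commas between digits are deleted
  so numeric identifiers like ``27,447`` survive as ``27447``), collapse
  whitespace, drop stop words, and spell out standalone integers 1–10.
* ``SPELL`` — ``MINIMAL`` plus conservative spell correction against a
  reference word list: a token absent from the list is replaced by its
  misspelling-dictionary entry if present, else by the *unique* reference word
  within one edit (substitution, insertion, deletion, or adjacent
  transposition), else left unchanged.
* ``MAXIMAL`` — ``SPELL`` plus acronym expansion from an abbreviation table.

All lexicon inputs are plain TSV files so domain-specific tables (e.g. tables
derived from a medical lexicon) can be swapped in.
"""
from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "PreprocessLevel",
    "Lexicons",
    "Vocabulary",
    "default_lexicons",
    "load_lexicons",
    "preprocess_minimal",
    "preprocess_spell",
    "preprocess_maximal",
    "preprocess",
    "institution_vocabulary",
    "TextPreprocessor",
]

_NUMBER_WORDS = {str(i + 1): w for i, w in enumerate(
    "one two three four five six seven eight nine ten".split())}
_DIGIT_COMMA = re.compile(r"(?<=\d),(?=\d)")
_NON_ALNUM = re.compile(r"[^0-9a-z]+")
_ALPHABET = "abcdefghijklmnopqrstuvwxyz"


class PreprocessLevel(str, enum.Enum):
    MINIMAL = "minimal"
    SPELL = "spell"
    MAXIMAL = "maximal"

    @classmethod
    def parse(cls, value: "PreprocessLevel | str") -> "PreprocessLevel":
        if isinstance(value, cls):
            return value
        return cls(str(value).lower())


@dataclass
class Lexicons:
    """Lexical resources: stop words, spell references, abbreviations."""

    stopwords: frozenset[str]
    misspelling_dictionary: dict[str, str]
    reference_words: frozenset[str]
    abbreviation_map: dict[str, tuple[str, ...]]
    _spell_cache: dict[str, str] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        for acro, expansion in self.abbreviation_map.items():
            joined = " ".join(expansion)
            if joined != joined.lower() or _NON_ALNUM.search(joined.replace(" ", "")):
                raise ValueError(f"abbreviation expansion not normalized: {acro!r}")

    def with_reference(self, extra_words: Iterable[str]) -> "Lexicons":
        """A copy whose reference word list is extended by ``extra_words``."""
        return Lexicons(
            stopwords=self.stopwords,
            misspelling_dictionary=dict(self.misspelling_dictionary),
            reference_words=self.reference_words | frozenset(extra_words),
            abbreviation_map=dict(self.abbreviation_map),
        )


@dataclass(frozen=True)
class Vocabulary:
    """Unique word tokens used in one institution's texts at a given level."""

    institution_id: str
    tokens: frozenset[str]
    level: PreprocessLevel

    def __len__(self) -> int:
        return len(self.tokens)


def load_lexicons(directory: str | Path) -> Lexicons:
    """Load ``stopwords.tsv``, ``misspellings.tsv``, ``abbreviations.tsv``,
    ``wordlist.tsv`` from a directory."""
    directory = Path(directory)
    stopwords = frozenset(
        w.strip() for w in (directory / "stopwords.tsv").read_text().split()
        if w.strip())
    misspellings: dict[str, str] = {}
    for line in (directory / "misspellings.tsv").read_text().splitlines():
        if line.strip():
            wrong, right = line.split("\t")
            misspellings[wrong.strip()] = right.strip()
    abbreviations: dict[str, tuple[str, ...]] = {}
    for line in (directory / "abbreviations.tsv").read_text().splitlines():
        if line.strip():
            acro, expansion = line.split("\t")
            abbreviations[acro.strip()] = tuple(expansion.split())
    reference = frozenset(
        w.strip() for w in (directory / "wordlist.tsv").read_text().split()
        if w.strip())
    return Lexicons(stopwords=stopwords, misspelling_dictionary=misspellings,
                    reference_words=reference, abbreviation_map=abbreviations)


def default_lexicons() -> Lexicons:
    """The packaged lexicons (built to cover the synthetic templates)."""
    return load_lexicons(resources.files("genshift") / "data")


# ---------------------------------------------------------------------------
# level transforms


def preprocess_minimal(text: str, lexicons: Lexicons) -> list[str]:
    text = _DIGIT_COMMA.sub("", text.lower())
    text = _NON_ALNUM.sub(" ", text)
    out = []
    for tok in text.split():
        if tok in lexicons.stopwords:
            continue
        out.append(_NUMBER_WORDS.get(tok, tok))
    return out


def _edits1(token: str) -> set[str]:
    """All strings within one edit (OSA distance 1) of ``token``."""
    splits = [(token[:i], token[i:]) for i in range(len(token) + 1)]
    deletes = {a + b[1:] for a, b in splits if b}
    transposes = {a + b[1] + b[0] + b[2:] for a, b in splits if len(b) > 1}
    replaces = {a + c + b[1:] for a, b in splits if b for c in _ALPHABET}
    inserts = {a + c + b for a, b in splits for c in _ALPHABET}
    return deletes | transposes | replaces | inserts


def _correct_token(token: str, lexicons: Lexicons) -> str:
    if token in lexicons.reference_words or any(ch.isdigit() for ch in token):
        return token
    cached = lexicons._spell_cache.get(token)
    if cached is not None:
        return cached
    if token in lexicons.misspelling_dictionary:
        corrected = lexicons.misspelling_dictionary[token]
    else:
        candidates = _edits1(token) & lexicons.reference_words
        corrected = next(iter(candidates)) if len(candidates) == 1 else token
    lexicons._spell_cache[token] = corrected
    return corrected


def preprocess_spell(text: str, lexicons: Lexicons) -> list[str]:
    return [_correct_token(t, lexicons) for t in preprocess_minimal(text, lexicons)]


def preprocess_maximal(text: str, lexicons: Lexicons) -> list[str]:
    out: list[str] = []
    for tok in preprocess_spell(text, lexicons):
        out.extend(lexicons.abbreviation_map.get(tok, (tok,)))
    return out


_LEVEL_FN = {
    PreprocessLevel.MINIMAL: preprocess_minimal,
    PreprocessLevel.SPELL: preprocess_spell,
    PreprocessLevel.MAXIMAL: preprocess_maximal,
}


def preprocess(text: str, level: PreprocessLevel | str,
               lexicons: Lexicons) -> list[str]:
    """Apply one preprocessing level to a single text."""
    return _LEVEL_FN[PreprocessLevel.parse(level)](text, lexicons)


def institution_vocabulary(corpus, institution_id: str,
                           level: PreprocessLevel | str,
                           lexicons: Lexicons) -> Vocabulary:
    """All unique word tokens in one institution's preprocessed texts."""
    level = PreprocessLevel.parse(level)
    fn = _LEVEL_FN[level]
    tokens: set[str] = set()
    for text in corpus.records_for(institution_id)["text"]:
        tokens.update(fn(text, lexicons))
    return Vocabulary(institution_id=institution_id,
                      tokens=frozenset(tokens), level=level)


class TextPreprocessor(TransformerMixin, BaseEstimator):
    """Stateless transformer applying one preprocessing level to raw texts.

    ``transform`` returns whitespace-joined token strings so the output can
    feed a downstream ``TfidfVectorizer(tokenizer=str.split)`` inside an
    sklearn pipeline.
    """

    def __init__(self, level: PreprocessLevel | str = PreprocessLevel.MINIMAL,
                 lexicons: Lexicons | None = None):
        self.level = level
        self.lexicons = lexicons

    def fit(self, X: Sequence[str], y=None) -> "TextPreprocessor":
        self.lexicons_ = self.lexicons if self.lexicons is not None else default_lexicons()
        self.level_ = PreprocessLevel.parse(self.level)
        return self

    def transform(self, X: Sequence[str]) -> list[str]:
        if not hasattr(self, "lexicons_"):
            self.fit(X)
        fn = _LEVEL_FN[self.level_]
        return [" ".join(fn(text, self.lexicons_)) for text in X]
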