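"""Dictionary-based psycholinguistic features and structural text measures.

Implements LIWC-style category counting: a lexicon maps category names to
word lists whose entries are either literal lowercase words or prefix
patterns ending in ``*`` (``hate*`` matches ``hate``, ``hates``, ``hated``).
A token may match several categories; each category's feature value is the
proportion of the period's tokens matching it.

The genuine LIWC dictionary is proprietary, so the package ships a small
open mini-lexicon in the same plain-text format and accepts a user-supplied
full dictionary anywhere a lexicon path is taken.

Structural measures: Flesch Reading Ease (with a vowel-group syllable
heuristic), word repeatability ``1 - distinct/total tokens``, and mean word
length in characters.  Word usage is captured as top-k unigram proportions
over a training-defined vocabulary.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

__all__ = [
    "Lexicon",
    "LexiconParseError",
    "tokenize",
    "load_lexicon",
    "builtin_lexicon",
    "category_proportions",
    "structural_features",
    "flesch_reading_ease",
    "build_vocabulary",
    "unigram_features",
]


class LexiconParseError(ValueError):
    pass


_URL_RE = re.compile(r"(?:https?://\S+|www\.\S+)", re.IGNORECASE)
_HANDLE_RE = re.compile(r"@\w+")
_TOKEN_RE = re.compile(r"[a-z0-9']+")


def tokenize(text: str) -> list[str]:
    """Lowercase and split into maximal runs of letters/digits/apostrophes.

    URLs and @-handles are dropped before tokenization; punctuation and
    emoji never form tokens.
    """
    text = _URL_RE.sub(" ", text)
    text = _HANDLE_RE.sub(" ", text)
    return _TOKEN_RE.findall(text.lower())


@dataclass
class Lexicon:
    """Category → entry-set map with prefix-wildcard matching."""

    categories: dict[str, frozenset[str]]
    _literal_map: dict = field(init=False, repr=False)
    _prefixes: list = field(init=False, repr=False)
    _token_cache: dict = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.categories = {
            name: frozenset(entries) for name, entries in self.categories.items()
        }
        for name, entries in self.categories.items():
            if not entries:
                raise LexiconParseError(f"category {name!r} is empty")
        self._names = sorted(self.categories)
        index = {name: i for i, name in enumerate(self._names)}
        self._literal_map = {}
        self._prefixes = []
        for name, entries in self.categories.items():
            i = index[name]
            for entry in entries:
                if entry.endswith("*"):
                    self._prefixes.append((entry[:-1], i))
                else:
                    self._literal_map.setdefault(entry, []).append(i)
        self._token_cache = {}

    @property
    def names(self) -> list[str]:
        return list(self._names)

    def categories_for(self, token: str) -> tuple[int, ...]:
        """Indices (into sorted category names) the token matches; cached."""
        hit = self._token_cache.get(token)
        if hit is None:
            cats = set(self._literal_map.get(token, ()))
            for prefix, i in self._prefixes:
                if token.startswith(prefix):
                    cats.add(i)
            hit = tuple(sorted(cats))
            self._token_cache[token] = hit
        return hit

    def matches(self, token: str, category: str) -> bool:
        return self._names.index(category) in self.categories_for(token)


def load_lexicon(path: str | Path) -> Lexicon:
    """Parse the dic-like plain-text lexicon format.

    One category per line, ``name: entry, entry, ...``; ``#`` starts a
    comment; ``*`` is allowed only entry-final.  Duplicate entries are
    deduplicated; an empty category or a malformed line is a parse error
    naming the line number.
    """
    return _parse_lexicon(Path(path).read_text(encoding="utf-8"), str(path))


def _parse_lexicon(content: str, source: str) -> Lexicon:
    categories: dict[str, set[str]] = {}
    for lineno, raw in enumerate(content.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if ":" not in line:
            raise LexiconParseError(f"{source}:{lineno}: expected 'name: entries'")
        name, _, rest = line.partition(":")
        name = name.strip()
        if not name:
            raise LexiconParseError(f"{source}:{lineno}: missing category name")
        entries = {e.strip().lower() for e in rest.split(",") if e.strip()}
        if not entries:
            raise LexiconParseError(f"{source}:{lineno}: empty category {name!r}")
        for entry in entries:
            if "*" in entry[:-1]:
                raise LexiconParseError(
                    f"{source}:{lineno}: '*' must be entry-final in {entry!r}"
                )
        if name in categories:
            categories[name] |= entries
        else:
            categories[name] = entries
    if not categories:
        raise LexiconParseError(f"{source}: no categories found")
    return Lexicon({k: frozenset(v) for k, v in categories.items()})


@lru_cache(maxsize=1)
def builtin_lexicon() -> Lexicon:
    """The bundled open mini-lexicon (36 psycholinguistic categories)."""
    content = (
        resources.files("relapsekit.data").joinpath("mini_lexicon.dic").read_text("utf-8")
    )
    return _parse_lexicon(content, "mini_lexicon.dic")


def category_proportions(
    tokens: Sequence[str], lexicon: Lexicon
) -> dict[str, float]:
    """Per-category proportion of tokens matching the category's entries.

    A token may count toward several categories.  All proportions are zero
    when the token list is empty.
    """
    names = lexicon.names
    counts = [0] * len(names)
    for token in tokens:
        for i in lexicon.categories_for(token):
            counts[i] += 1
    n = len(tokens)
    if n == 0:
        return {name: 0.0 for name in names}
    return {name: counts[i] / n for i, name in enumerate(names)}


# ---------------------------------------------------------------------------
# Structural features

_VOWEL_GROUP_RE = re.compile(r"[aeiouy]+")
_SENTENCE_RE = re.compile(r"[.!?]+")


def _count_syllables(word: str) -> int:
    word = word.lower().strip("'")
    if not word:
        return 0
    groups = len(_VOWEL_GROUP_RE.findall(word))
    # silent trailing 'e' ("make"), but not a lone vowel group ("the")
    if word.endswith("e") and not word.endswith(("le", "ee")) and groups > 1:
        groups -= 1
    return max(groups, 1)


def flesch_reading_ease(text: str) -> float:
    """206.835 − 1.015·(words/sentences) − 84.6·(syllables/word).

    Returns 0.0 when the text has no sentences or no words.
    """
    sentences = [s for s in _SENTENCE_RE.split(text) if s.strip()]
    words = tokenize(text)
    if not sentences or not words:
        return 0.0
    syllables = sum(_count_syllables(w) for w in words)
    return (
        206.835
        - 1.015 * (len(words) / len(sentences))
        - 84.6 * (syllables / len(words))
    )


def repeatability(tokens: Sequence[str]) -> float:
    """1 − distinct/total tokens; 0 for one token or none."""
    n = len(tokens)
    if n <= 1:
        return 0.0
    return 1.0 - len(set(tokens)) / n


def mean_word_length(tokens: Sequence[str]) -> float:
    if not tokens:
        return 0.0
    return sum(len(t) for t in tokens) / len(tokens)


def structural_features(period_texts: Iterable[str]) -> tuple[float, float, float]:
    """(readability, repeatability, mean_word_length) of the pooled text."""
    pooled = " ".join(period_texts)
    tokens = tokenize(pooled)
    return (
        flesch_reading_ease(pooled),
        repeatability(tokens),
        mean_word_length(tokens),
    )


# ---------------------------------------------------------------------------
# Unigram usage


def _grams(tokens: Sequence[str], n: int) -> list[str]:
    if n == 1:
        return list(tokens)
    return [" ".join(tokens[i : i + n]) for i in range(len(tokens) - n + 1)]


def build_vocabulary(
    training_texts: Iterable[str], k: int, ngram: int = 1
) -> list[str]:
    """Top-k n-grams by training-corpus frequency, ties lexicographic.

    Must be built from training-split text only, so held-out periods never
    leak vocabulary into the features.  ``ngram=2`` switches to bigrams
    (space-joined token pairs); unigrams are the default.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if ngram not in (1, 2):
        raise ValueError("only unigrams and bigrams are supported")
    counts: Counter[str] = Counter()
    for text in training_texts:
        counts.update(_grams(tokenize(text), ngram))
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return [word for word, _ in ranked[:k]]


def unigram_features(
    tokens: Sequence[str], vocabulary: Sequence[str]
) -> dict[str, float]:
    """Per-vocabulary-gram proportion of the period's tokens.

    Out-of-vocabulary tokens contribute to the denominator only.  Bigram
    vocabularies (space-joined entries) are counted over adjacent pairs.
    """
    n = len(tokens)
    if n == 0:
        return {w: 0.0 for w in vocabulary}
    ngram = 2 if any(" " in w for w in vocabulary) else 1
    counts = Counter(_grams(tokens, ngram)) if ngram == 2 else Counter(tokens)
    return {w: counts.get(w, 0) / n for w in vocabulary}
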