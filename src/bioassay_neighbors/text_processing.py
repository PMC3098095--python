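"""Turning free assay-description text into stemmed, stop-word-free tokens.

The processing chain is: lowercase and tokenize (dropping punctuation and
parentheses, preserving internal hyphens), remove stop words, then Porter-stem
every surviving token. Hyphenated tokens are never split, so chemical names
and formulas such as "luciferin-h" or "vcam-1" stay single terms; tokens
containing digits are kept (protein and chemical nomenclature needs them) but
pure-digit tokens are dropped as carrying no conceptual content.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from .corpus_io import RawDocument
from .porter import porter_stem

__all__ = [
    "TokenizedDocument",
    "PreprocessConfig",
    "load_stopwords",
    "default_stopwords",
    "normalize_and_tokenize",
    "filter_stopwords",
    "porter_stem",
    "preprocess_document",
    "preprocess_corpus",
]

logger = logging.getLogger(__name__)

# parenthesis-like characters removed outright before splitting
_PARENS = str.maketrans("", "", "()[]{}")
# leading / trailing characters stripped from each whitespace token: anything
# that is not a letter or digit (covers punctuation incl. hyphens at the edges)
_EDGE = re.compile(r"^[^a-z0-9]+|[^a-z0-9]+$")
_PURE_DIGIT = re.compile(r"^[0-9]+$")


@dataclass(frozen=True)
class TokenizedDocument:
    """A document reduced to its ordered processed tokens (duplicates kept)."""

    id: str
    tokens: tuple[str, ...]


def default_stopwords() -> frozenset[str]:
    """The packaged SMART-style English stop-word list."""
    text = resources.files("bioassay_neighbors").joinpath("data/stopwords_en.txt").read_text(
        encoding="utf-8"
    )
    return frozenset(_parse_stopword_lines(text.splitlines()))


def load_stopwords(path: str | Path) -> frozenset[str]:
    """Load a stop-word file: one lowercase word per line, '#' comments allowed."""
    return frozenset(_parse_stopword_lines(Path(path).read_text(encoding="utf-8").splitlines()))


def _parse_stopword_lines(lines) -> list[str]:
    words = []
    for line in lines:
        word = line.split("#", 1)[0].strip()
        if word:
            words.append(word.lower())
    return words


@dataclass(frozen=True)
class PreprocessConfig:
    """Tokenization settings.

    ``include_title`` prepends the assay name to the description before
    tokenization (off by default: the method mines the description text, but
    titles are often informative and can be opted in). ``min_token_length``
    drops tokens shorter than the given number of characters.
    """

    stopword_list: frozenset[str] = field(default_factory=default_stopwords)
    include_title: bool = False
    min_token_length: int = 1

    def __post_init__(self) -> None:
        if self.min_token_length < 1:
            raise ValueError("min_token_length must be >= 1")
        for word in self.stopword_list:
            if not word or word != word.lower():
                raise ValueError(f"stop words must be lowercase and non-empty: {word!r}")


def normalize_and_tokenize(text: str, min_token_length: int = 1) -> list[str]:
    """Lowercase, strip parentheses and punctuation, and split into raw tokens.

    Internal hyphens are preserved ("cell-based" stays one token); leading and
    trailing punctuation, including edge hyphens, is stripped. Pure-digit
    tokens and tokens shorter than ``min_token_length`` are dropped.
    """
    tokens: list[str] = []
    for raw in text.lower().translate(_PARENS).split():
        token = _EDGE.sub("", raw)
        if not token or len(token) < min_token_length:
            continue
        if _PURE_DIGIT.match(token):
            continue
        tokens.append(token)
    return tokens


def filter_stopwords(tokens: list[str], stopword_list: frozenset[str]) -> list[str]:
    """Drop stop words, preserving token order."""
    return [t for t in tokens if t not in stopword_list]


def preprocess_document(doc: RawDocument, config: PreprocessConfig | None = None) -> TokenizedDocument:
    """Tokenize, stop-word filter, and Porter-stem one document.

    The stop-word filter is applied both before and after stemming: a stem can
    coincide with a stop word even when the surface form does not (e.g.
    "doing" -> "do"), and the output must be stop-word free.
    """
    config = config or PreprocessConfig()
    text = doc.description
    if config.include_title and doc.name:
        text = doc.name + "\n" + text
    raw = normalize_and_tokenize(text, config.min_token_length)
    kept = filter_stopwords(raw, config.stopword_list)
    stemmed = filter_stopwords([porter_stem(t) for t in kept], config.stopword_list)
    if not stemmed:
        logger.warning("document %r has no tokens after preprocessing", doc.id)
    return TokenizedDocument(id=doc.id, tokens=tuple(stemmed))


def preprocess_corpus(
    docs: list[RawDocument], config: PreprocessConfig | None = None
) -> list[TokenizedDocument]:
    """Preprocess every document, preserving corpus order."""
    config = config or PreprocessConfig()
    return [preprocess_document(doc, config) for doc in docs]
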