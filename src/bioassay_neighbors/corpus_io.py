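"""Reading and writing corpus, annotation, and pair-list files.

Formats
-------
Corpus CSV
    RFC 4180, UTF-8, header required, columns ``id,name,description``.
Corpus JSONL
    One UTF-8 JSON object per line with keys ``id``, ``name``, ``description``.
Corpus text directory
    Every ``*.txt`` file is one document; the filename stem is the id.
Annotation TSV
    Two tab-separated columns: a query assay id and a comma-separated list of
    related assay ids (the second column may be empty).
Pair TSV
    Columns ``id_a``, ``id_b`` and an optional score in [0, 1]; pairs are
    stored canonically with the lexicographically smaller id first.

Assay identifiers are opaque strings. PubChem AIDs happen to be numeric, but
nothing in the neighboring method does arithmetic on them, so the tool stays
generic over any id scheme.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

logger = logging.getLogger(__name__)

CORPUS_FORMATS = ("csv", "jsonl", "textdir")


@dataclass(frozen=True)
class RawDocument:
    """One assay record: an id, a short title, and free description text."""

    id: str
    name: str = ""
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("RawDocument id must be non-empty")


@dataclass
class AnnotationMap:
    """Curated neighbor annotations: query assay id -> related assay ids.

    Self-references are dropped (with a warning) at load time; curated files
    in the wild do contain them.
    """

    entries: dict[str, list[str]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.entries)

    def iter_pairs(self) -> Iterator[tuple[str, str]]:
        """Yield each annotation as a canonical (smaller, larger) id pair."""
        for query, related in self.entries.items():
            for other in related:
                yield canonical_pair(query, other)


def canonical_pair(a: str, b: str) -> tuple[str, str]:
    """Order an unordered id pair lexicographically; reject self pairs."""
    if a == b:
        raise ValueError(f"self pair not allowed: {a!r}")
    return (a, b) if a < b else (b, a)


class PairList:
    """A set of unordered assay-id pairs, each with an optional score in [0, 1].

    Pairs are held canonically (lexicographically smaller id first). Used both
    for predicted neighbor pairs and for reference (curated) pairs.
    """

    def __init__(
        self, pairs: Iterable[tuple[str, str]] | Mapping[tuple[str, str], float | None] = ()
    ) -> None:
        self._pairs: dict[tuple[str, str], float | None] = {}
        if isinstance(pairs, Mapping):
            for (a, b), score in pairs.items():
                self.add(a, b, score)
        else:
            for a, b in pairs:
                self.add(a, b)

    def add(self, a: str, b: str, score: float | None = None) -> None:
        if score is not None and not 0.0 <= score <= 1.0:
            raise ValueError(f"pair score outside [0, 1]: {score}")
        key = canonical_pair(a, b)
        if key in self._pairs:
            raise ValueError(f"duplicate pair after canonicalization: {key}")
        self._pairs[key] = score

    def __contains__(self, pair: tuple[str, str]) -> bool:
        a, b = pair
        return canonical_pair(a, b) in self._pairs

    def __len__(self) -> int:
        return len(self._pairs)

    def __iter__(self) -> Iterator[tuple[str, str]]:
        return iter(self._pairs)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PairList):
            return NotImplemented
        return self._pairs == other._pairs

    def score(self, a: str, b: str) -> float | None:
        return self._pairs[canonical_pair(a, b)]

    def keys(self) -> set[tuple[str, str]]:
        return set(self._pairs)

    def items(self) -> Iterator[tuple[tuple[str, str], float | None]]:
        return iter(self._pairs.items())

    def ids(self) -> set[str]:
        """All assay ids that appear in at least one pair."""
        out: set[str] = set()
        for a, b in self._pairs:
            out.add(a)
            out.add(b)
        return out

    def __repr__(self) -> str:  # pragma: no cover
        return f"PairList({len(self)} pairs)"


def read_corpus(path: str | Path, format: str = "csv") -> list[RawDocument]:
    """Read a description corpus in one of the supported formats.

    Parameters
    ----------
    path
        File path (csv, jsonl) or directory path (textdir).
    format
        One of ``csv``, ``jsonl``, ``textdir``.

    Returns
    -------
    Documents in input order (row order, line order, or sorted filename order
    for a directory). Ids must be unique; a duplicate is a hard error.
    """
    path = Path(path)
    if format not in CORPUS_FORMATS:
        raise ValueError(f"unknown corpus format {format!r}; expected one of {CORPUS_FORMATS}")
    if format == "csv":
        docs = list(_read_corpus_csv(path))
    elif format == "jsonl":
        docs = list(_read_corpus_jsonl(path))
    else:
        docs = list(_read_corpus_textdir(path))
    seen: set[str] = set()
    for doc in docs:
        if doc.id in seen:
            raise ValueError(f"duplicate document id {doc.id!r} in {path}")
        seen.add(doc.id)
    return docs


def _read_corpus_csv(path: Path) -> Iterator[RawDocument]:
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or "id" not in reader.fieldnames:
            raise ValueError(f"corpus CSV {path} lacks an 'id' header column")
        if "description" not in reader.fieldnames:
            raise ValueError(f"corpus CSV {path} lacks a 'description' header column")
        for row in reader:
            yield RawDocument(
                id=row["id"], name=row.get("name") or "", description=row["description"] or ""
            )


def _read_corpus_jsonl(path: Path) -> Iterator[RawDocument]:
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise ValueError(f"{path}:{lineno}: invalid JSON: {exc}") from exc
            if "description" not in obj:
                raise ValueError(f"{path}:{lineno}: missing 'description' key")
            yield RawDocument(
                id=str(obj["id"]), name=str(obj.get("name", "")), description=str(obj["description"])
            )


def _read_corpus_textdir(path: Path) -> Iterator[RawDocument]:
    if not path.is_dir():
        raise NotADirectoryError(f"{path} is not a directory")
    for txt in sorted(path.glob("*.txt")):
        yield RawDocument(id=txt.stem, name="", description=txt.read_text(encoding="utf-8"))


def write_corpus_csv(documents: Iterable[RawDocument], path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id", "name", "description"])
        for doc in documents:
            writer.writerow([doc.id, doc.name, doc.description])


def write_corpus_jsonl(documents: Iterable[RawDocument], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for doc in documents:
            fh.write(
                json.dumps(
                    {"id": doc.id, "name": doc.name, "description": doc.description},
                    ensure_ascii=False,
                )
                + "\n"
            )


def read_annotations(path: str | Path) -> AnnotationMap:
    """Read a curated-neighbor TSV: ``query_id<TAB>related_id1,related_id2,...``.

    The second column may be empty (an assay with no annotated neighbors).
    Self-references are dropped with a warning rather than raised, matching
    what curated files in the wild actually contain.
    """
    entries: dict[str, list[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields_ = line.split("\t")
            if len(fields_) != 2:
                raise ValueError(
                    f"{path}:{lineno}: expected 2 tab-separated fields, got {len(fields_)}"
                )
            query, related_raw = fields_
            related = [r for r in related_raw.split(",") if r]
            kept = []
            for r in related:
                if r == query:
                    logger.warning("%s:%d: dropping self-reference %r", path, lineno, query)
                else:
                    kept.append(r)
            entries[query] = kept
    return AnnotationMap(entries=entries)


def write_annotations(annotations: AnnotationMap, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for query in sorted(annotations.entries):
            fh.write(f"{query}\t{','.join(annotations.entries[query])}\n")


def read_pairs(path: str | Path) -> PairList:
    """Read a pair TSV (``id_a<TAB>id_b[<TAB>score]``) into a canonical PairList."""
    pairs = PairList()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields_ = line.split("\t")
            if len(fields_) not in (2, 3):
                raise ValueError(
                    f"{path}:{lineno}: expected 2 or 3 tab-separated fields, got {len(fields_)}"
                )
            score = float(fields_[2]) if len(fields_) == 3 else None
            try:
                pairs.add(fields_[0], fields_[1], score)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return pairs


def write_pairs(pairs: PairList, path: str | Path) -> None:
    """Write a PairList as TSV in sorted canonical order; read(write(x)) == x."""
    with open(path, "w", encoding="utf-8") as fh:
        for (a, b), score in sorted(pairs.items()):
            if score is None:
                fh.write(f"{a}\t{b}\n")
            else:
                fh.write(f"{a}\t{b}\t{score!r}\n")
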