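"""Seeded synthetic corpora with planted cluster structure.

Stands in for a real assay-description corpus: documents fall into known
clusters, each cluster owning a private topic vocabulary on top of a shared
background vocabulary. Every token of a document in cluster c is drawn from
c's topic vocabulary with probability rho (the topic fraction), otherwise
uniformly from the background. At rho = 1 different clusters share no terms
at all; at rho = 0 there is no planted signal and within- and between-cluster
similarities are statistically indistinguishable.

Vocabulary words are consonant-vowel syllable strings (e.g. "bakodu")
verified to be fixed points of the Porter stemmer and absent from the default
stop-word list, so the token stream survives preprocessing unchanged. This
isolates the vector/similarity machinery from stemmer behavior. A second
mode (``morphology=True``) appends English-style inflections ("-s", "-ed",
"-ing") to content words and interleaves stop words, exercising the full
text-processing chain: the inflected forms stem back to their base words, so
the planted structure is unchanged.

What this generator does NOT emulate: real biomedical language, named
entities, shared protocol boilerplate between unrelated assays, or documents
of wildly varying length. Recovery on this corpus demonstrates the pipeline
machinery, not performance on real descriptions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .corpus_io import (
    AnnotationMap,
    PairList,
    RawDocument,
    write_annotations,
    write_corpus_csv,
    write_pairs,
)
from .evaluation import BenchmarkSet, build_benchmark_pairs
from .neighboring import ClusterSet, clusters_to_pairs
from .porter import porter_stem
from .text_processing import default_stopwords

_CONSONANTS = "bdfgklmnprtvz"
_VOWELS = "aiou"  # no 'e': avoids the stemmer's final-e rules by construction
_STOPWORD_FILLER = ("the", "of", "is", "this", "and", "in", "a", "for", "with", "that")
_INFLECTIONS = ("", "", "s", "ed", "ing")
_SENTENCE_LEN = 15  # a period is appended every ~15 tokens


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of a planted-cluster corpus.

    Defaults are the fixture used throughout the test suite: 4 clusters of 5
    documents, 20 topic terms per cluster over a 100-term background, 200
    tokens per document, topic fraction 0.9, seed 1.
    """

    n_clusters: int = 4
    docs_per_cluster: int = 5
    topic_vocab_size: int = 20
    background_vocab_size: int = 100
    doc_length: int | tuple[int, int] = 200
    topic_fraction: float = 0.9
    seed: int = 1
    morphology: bool = False

    def __post_init__(self) -> None:
        if min(self.n_clusters, self.docs_per_cluster, self.topic_vocab_size,
               self.background_vocab_size) < 1:
            raise ValueError("all sizes must be positive")
        lo, hi = self._length_range()
        if lo < 1 or hi < lo:
            raise ValueError(f"invalid doc_length {self.doc_length}")
        if not 0.0 <= self.topic_fraction <= 1.0:
            raise ValueError(f"topic_fraction outside [0, 1]: {self.topic_fraction}")

    def _length_range(self) -> tuple[int, int]:
        if isinstance(self.doc_length, int):
            return self.doc_length, self.doc_length
        lo, hi = self.doc_length
        return lo, hi


@dataclass
class SyntheticCorpus:
    """Generated documents plus their ground-truth cluster structure."""

    documents: list[RawDocument]
    truth_clusters: ClusterSet
    truth_pairs: PairList
    spec: SyntheticSpec
    topic_vocabularies: list[tuple[str, ...]] = field(default_factory=list)
    background_vocabulary: tuple[str, ...] = ()


def _generate_words(rng: np.random.Generator, count: int, taken: set[str]) -> list[str]:
    """Unique CV-syllable words that are Porter fixed points, not stop words."""
    stop = default_stopwords()
    words: list[str] = []
    while len(words) < count:
        n_syll = int(rng.integers(2, 4))  # 2-3 syllables, 4-6 letters
        word = "".join(
            _CONSONANTS[rng.integers(len(_CONSONANTS))] + _VOWELS[rng.integers(len(_VOWELS))]
            for _ in range(n_syll)
        )
        if word in taken or word in stop or porter_stem(word) != word:
            continue
        taken.add(word)
        words.append(word)
    return words


def generate_corpus(spec: SyntheticSpec) -> SyntheticCorpus:
    """Generate a corpus deterministically from the spec's seed.

    The same spec (same seed) always produces byte-identical documents; a
    single RNG stream is used, with no global state.
    """
    rng = np.random.default_rng(spec.seed)
    taken: set[str] = set()
    topics = [
        tuple(_generate_words(rng, spec.topic_vocab_size, taken))
        for _ in range(spec.n_clusters)
    ]
    background = tuple(_generate_words(rng, spec.background_vocab_size, taken))
    lo, hi = spec._length_range()

    documents: list[RawDocument] = []
    cluster_members: list[frozenset[str]] = []
    k = 0
    for c in range(spec.n_clusters):
        members = []
        for _ in range(spec.docs_per_cluster):
            doc_id = f"A{k:04d}"
            k += 1
            members.append(doc_id)
            length = int(rng.integers(lo, hi + 1)) if hi > lo else lo
            tokens = []
            for _ in range(length):
                if rng.random() < spec.topic_fraction:
                    word = topics[c][rng.integers(spec.topic_vocab_size)]
                else:
                    word = background[rng.integers(spec.background_vocab_size)]
                if spec.morphology:
                    word += _INFLECTIONS[rng.integers(len(_INFLECTIONS))]
                    if rng.random() < 0.3:
                        tokens.append(_STOPWORD_FILLER[rng.integers(len(_STOPWORD_FILLER))])
                tokens.append(word)
            documents.append(
                RawDocument(id=doc_id, name=f"synthetic assay {doc_id}",
                            description=_render_text(tokens))
            )
        cluster_members.append(frozenset(members))

    truth_clusters = ClusterSet(clusters=cluster_members, threshold=None)
    return SyntheticCorpus(
        documents=documents,
        truth_clusters=truth_clusters,
        truth_pairs=clusters_to_pairs(truth_clusters),
        spec=spec,
        topic_vocabularies=topics,
        background_vocabulary=background,
    )


def _render_text(tokens: list[str]) -> str:
    """Join tokens into sentence-like text with a period every ~15 tokens."""
    out = []
    for n, tok in enumerate(tokens, 1):
        out.append(tok + "." if n % _SENTENCE_LEN == 0 else tok)
    return " ".join(out)


def ground_truth_pairs(corpus: SyntheticCorpus) -> BenchmarkSet:
    """Ground truth as a BenchmarkSet, via annotation-style chaining.

    Each multi-member cluster is rendered as one annotation record (first
    member lists the rest) and run through the same closure-and-expand
    benchmark construction applied to curated data, so end-to-end evaluation
    exercises identical code paths. Size-1 clusters contribute no pairs.
    """
    entries: dict[str, list[str]] = {}
    for cluster in corpus.truth_clusters.clusters:
        members = sorted(cluster)
        if len(members) >= 2:
            entries[members[0]] = members[1:]
    return build_benchmark_pairs(AnnotationMap(entries=entries))


def write_fixture(corpus: SyntheticCorpus, out_dir: str | Path) -> dict[str, Path]:
    """Write corpus CSV, ground-truth annotation TSV, and truth-pair TSV.

    Files mirror the real-data input formats exactly, so the CLI pipeline can
    consume the fixture like a downloaded corpus.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "corpus": out_dir / "corpus.csv",
        "annotations": out_dir / "annotations.tsv",
        "truth_pairs": out_dir / "truth_pairs.tsv",
    }
    write_corpus_csv(corpus.documents, paths["corpus"])
    entries: dict[str, list[str]] = {}
    for cluster in corpus.truth_clusters.clusters:
        members = sorted(cluster)
        if len(members) >= 2:
            entries[members[0]] = members[1:]
    write_annotations(AnnotationMap(entries=entries), paths["annotations"])
    write_pairs(corpus.truth_pairs, paths["truth_pairs"])
    return paths
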