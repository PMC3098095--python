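"""Weighted bag-of-words document vectors from term-document statistics.

Each assay description becomes a sparse non-negative vector over the stemmed
corpus vocabulary. A term's weight combines an augmented term-frequency factor
with an inverse-document-frequency factor:

    weight(i, j) = 0.5 * (1 + m_ij / max_tf_j) * IDF

where ``m_ij`` is the occurrence count of term i in document j and
``max_tf_j`` is the largest count of any term in document j. The augmented-TF
factor lies in (0.5, 1] for present terms, bounding the influence of raw
within-document frequency.

Two IDF variants are provided:

``standard``  (default)
    IDF_i = log2(N / df_i) with N documents and df_i the number of documents
    containing term i. Down-weights terms spread over many documents.
``paper``
    IDF_ij = log2(M_i / m_ij) with M_i the corpus-wide occurrence total of
    term i. A per-document variant that instead *rewards* corpus-wide
    frequency relative to local frequency; kept selectable because some
    published bioassay-neighboring results were produced with this form.
    Note its ranking behavior is roughly opposite to standard IDF.

Both variants are non-negative (M_i >= m_ij and N >= df_i always hold), so
cosine scores between vectors stay in [0, 1].
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import sparse
from scipy.io import mmwrite

from .text_processing import TokenizedDocument

logger = logging.getLogger(__name__)

IDF_MODES = ("standard", "paper")


@dataclass
class TermDocumentCounts:
    """Sparse occurrence counts of stemmed terms over a corpus.

    ``matrix`` is documents-by-terms CSR; ``term_totals[i]`` (M_i) sums
    occurrences of term i over the corpus; ``doc_freq[i]`` (df_i) counts the
    documents containing term i.
    """

    vocabulary: tuple[str, ...]
    doc_ids: tuple[str, ...]
    matrix: sparse.csr_matrix
    term_totals: np.ndarray
    doc_freq: np.ndarray

    @property
    def n_docs(self) -> int:
        return len(self.doc_ids)

    def term_index(self, term: str) -> int:
        try:
            return self.vocabulary.index(term)
        except ValueError:
            raise KeyError(f"term {term!r} not in vocabulary") from None

    def occurrences(self, term_i: int, doc_j: int) -> int:
        return int(self.matrix[doc_j, term_i])


@dataclass(frozen=True)
class WeightingConfig:
    """Vector-weighting settings: the IDF variant and an optional min_df prune.

    ``min_df`` (document-frequency floor, default 1 = keep everything) exists
    purely for scalability on very large corpora; the method itself applies no
    pruning.
    """

    idf_mode: str = "standard"
    min_df: int = 1
    log_base: int = field(default=2, init=False)  # fixed; all IDFs are log2

    def __post_init__(self) -> None:
        if self.idf_mode not in IDF_MODES:
            raise ValueError(f"idf_mode must be one of {IDF_MODES}, got {self.idf_mode!r}")
        if self.min_df < 1:
            raise ValueError("min_df must be >= 1")


@dataclass
class DocumentVector:
    """Sparse weighted term vector for one assay.

    ``weights`` maps term index -> positive weight; exact zeros are dropped.
    ``dim`` is the shared vocabulary size; vectors from different vocabulary
    spaces must not be compared.
    """

    doc_id: str
    weights: dict[int, float]
    dim: int

    def norm(self) -> float:
        return math.sqrt(sum(w * w for w in self.weights.values()))

    def is_zero(self) -> bool:
        return not self.weights


def build_counts(corpus: list[TokenizedDocument]) -> TermDocumentCounts:
    """Accumulate term-document occurrence counts over a tokenized corpus.

    Vocabulary order is first-appearance order. Documents with zero tokens
    are allowed (they become all-zero rows) but are logged.
    """
    if not corpus:
        raise ValueError("cannot build counts from an empty corpus")
    ids = [doc.id for doc in corpus]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate document ids in corpus")

    vocab_index: dict[str, int] = {}
    rows: list[int] = []
    cols: list[int] = []
    vals: list[int] = []
    for j, doc in enumerate(corpus):
        if not doc.tokens:
            logger.warning("document %r is empty; it will have a zero vector", doc.id)
            continue
        counts: dict[int, int] = {}
        for tok in doc.tokens:
            i = vocab_index.setdefault(tok, len(vocab_index))
            counts[i] = counts.get(i, 0) + 1
        for i, c in counts.items():
            rows.append(j)
            cols.append(i)
            vals.append(c)

    n_terms = len(vocab_index)
    matrix = sparse.csr_matrix(
        (vals, (rows, cols)), shape=(len(corpus), n_terms), dtype=np.int64
    )
    term_totals = np.asarray(matrix.sum(axis=0)).ravel()
    doc_freq = np.asarray((matrix > 0).sum(axis=0)).ravel()
    return TermDocumentCounts(
        vocabulary=tuple(vocab_index),
        doc_ids=tuple(ids),
        matrix=matrix,
        term_totals=term_totals,
        doc_freq=doc_freq,
    )


def inverse_document_frequency(
    term_i: int, doc_j: int, counts: TermDocumentCounts, config: WeightingConfig | None = None
) -> float:
    """IDF of one term (for one document in ``paper`` mode).

    standard: log2(N / df_i), independent of the document.
    paper:    log2(M_i / m_ij), defined only where the term occurs.
    """
    config = config or WeightingConfig()
    if not 0 <= term_i < len(counts.vocabulary):
        raise KeyError(f"term index {term_i} outside vocabulary")
    if config.idf_mode == "standard":
        return math.log2(counts.n_docs / counts.doc_freq[term_i])
    m_ij = counts.occurrences(term_i, doc_j)
    if m_ij == 0:
        raise ValueError(
            f"paper-mode IDF undefined: term {counts.vocabulary[term_i]!r} "
            f"absent from document {counts.doc_ids[doc_j]!r}"
        )
    return math.log2(counts.term_totals[term_i] / m_ij)


def term_weight(m_ij: int, max_tf_j: int, idf: float) -> float:
    """Augmented-TF x IDF weight: 0.5 * (1 + m_ij/max_tf_j) * idf; 0 if absent."""
    if m_ij == 0:
        return 0.0
    if max_tf_j == 0:
        raise ValueError("max_tf_j = 0 with a present term")
    if not 0 <= m_ij <= max_tf_j:
        raise ValueError(f"m_ij={m_ij} outside [0, max_tf_j={max_tf_j}]")
    if idf < 0:
        raise ValueError(f"negative idf {idf}")
    return 0.5 * (1.0 + m_ij / max_tf_j) * idf


def vectorize_counts(
    counts: TermDocumentCounts, config: WeightingConfig | None = None
) -> list[DocumentVector]:
    """Weight every (term, document) occurrence into sparse document vectors.

    Exact-zero weights (zero IDF) are dropped; a document whose every term has
    zero IDF yields a zero vector and is logged.
    """
    config = config or WeightingConfig()
    dim = len(counts.vocabulary)
    keep = counts.doc_freq >= config.min_df
    vectors: list[DocumentVector] = []
    csr = counts.matrix
    for j, doc_id in enumerate(counts.doc_ids):
        start, end = csr.indptr[j], csr.indptr[j + 1]
        term_idx = csr.indices[start:end]
        m = csr.data[start:end]
        weights: dict[int, float] = {}
        if len(m):
            max_tf = int(m.max())
            for i, m_ij in zip(term_idx, m):
                if not keep[i]:
                    continue
                if config.idf_mode == "standard":
                    idf = math.log2(counts.n_docs / counts.doc_freq[i])
                else:
                    idf = math.log2(counts.term_totals[i] / m_ij)
                w = term_weight(int(m_ij), max_tf, idf)
                if w > 0.0:
                    weights[int(i)] = w
        if not weights:
            logger.warning("document %r has a zero vector", doc_id)
        vectors.append(DocumentVector(doc_id=doc_id, weights=weights, dim=dim))
    return vectors


def vectorize_corpus(
    corpus: list[TokenizedDocument], config: WeightingConfig | None = None
) -> list[DocumentVector]:
    """build_counts followed by vectorize_counts, one vector per input document."""
    return vectorize_counts(build_counts(corpus), config)


def export_matrixmarket(counts: TermDocumentCounts, prefix: str | Path) -> None:
    """Write the term-by-document count matrix as MTX plus sidecar lists.

    Produces ``<prefix>.mtx`` (coordinate format, terms as rows), and
    ``<prefix>.terms.txt`` / ``<prefix>.docs.txt`` with one term or document
    id per line, for inspection and interoperability.
    """
    prefix = Path(prefix)
    mmwrite(str(prefix.with_suffix(".mtx")), counts.matrix.T.tocoo())
    prefix.with_suffix(".terms.txt").write_text(
        "".join(t + "\n" for t in counts.vocabulary), encoding="utf-8"
    )
    prefix.with_suffix(".docs.txt").write_text(
        "".join(d + "\n" for d in counts.doc_ids), encoding="utf-8"
    )
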