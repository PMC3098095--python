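"""Cosine scoring of document-vector pairs, thresholding, and clustering.

Similarity between two assays is the cosine of the angle between their
weighted term vectors: dot(u, v) / (|u| |v|). With non-negative weights the
score lies in [0, 1] — 1 for token-identical descriptions, 0 for descriptions
sharing no terms. All C(n, 2) pairs are scored exactly (sparse dot products
over shared terms); neighbors are the pairs at or above a cosine threshold,
and single-linkage clusters are the connected components of that threshold
graph.

Zero vectors (descriptions emptied by preprocessing) get cosine 0 against
everything, by convention rather than NaN, so they simply have no neighbors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy import sparse

from .corpus_io import PairList
from .vector_model import DocumentVector

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SimilarityEdge:
    """An unordered assay pair (id_a < id_b) with its cosine score."""

    id_a: str
    id_b: str
    score: float

    def __post_init__(self) -> None:
        if self.id_a >= self.id_b:
            raise ValueError(f"edge ids must satisfy id_a < id_b: {self.id_a!r}, {self.id_b!r}")
        if not 0.0 <= self.score <= 1.0:
            raise ValueError(f"edge score outside [0, 1]: {self.score}")


@dataclass
class ScoreHistogram:
    """Binned cosine-score distribution over all scored pairs.

    Bins are half-open [lo, hi) except the last, which is closed at 1.0 so a
    perfect score is counted.
    """

    bin_edges: np.ndarray
    counts: np.ndarray

    @property
    def fractions(self) -> np.ndarray:
        total = self.counts.sum()
        return self.counts / total if total else self.counts.astype(float)


@dataclass
class ClusterSet:
    """A partition of a universe of assay ids, tagged with the cosine cutoff."""

    clusters: list[frozenset[str]]
    threshold: float | None

    def universe(self) -> set[str]:
        out: set[str] = set()
        for c in self.clusters:
            out |= c
        return out

    def __len__(self) -> int:
        return len(self.clusters)


def cosine_similarity(u: DocumentVector, v: DocumentVector) -> float:
    """Cosine of the angle between two document vectors, clipped to [0, 1].

    Vectors must come from the same vocabulary space. If either vector is
    all-zero the score is 0 by convention (logged).
    """
    if u.dim != v.dim:
        raise ValueError(f"vectors from different vocabulary spaces: dim {u.dim} vs {v.dim}")
    if u.is_zero() or v.is_zero():
        logger.warning(
            "cosine with zero vector (%r, %r) defined as 0", u.doc_id, v.doc_id
        )
        return 0.0
    if u.weights == v.weights:
        return 1.0  # identical descriptions: exactly 1 by definition, no float noise
    small, large = (u.weights, v.weights) if len(u.weights) <= len(v.weights) else (v.weights, u.weights)
    dot = sum(w * large[i] for i, w in small.items() if i in large)
    score = dot / (u.norm() * v.norm())
    return min(max(score, 0.0), 1.0)


def all_pairs_similarity(vectors: list[DocumentVector]) -> list[SimilarityEdge]:
    """Score every unordered pair of vectors: exactly C(n, 2) edges.

    Computed as a row-normalized sparse matrix product, which is the same
    sparse shared-term dot product applied to all pairs at once. Zero vectors
    score 0 against everything.
    """
    n = len(vectors)
    if n < 2:
        raise ValueError("need at least 2 vectors to score pairs")
    dims = {v.dim for v in vectors}
    if len(dims) != 1:
        raise ValueError("vectors from different vocabulary spaces")
    dim = dims.pop()

    rows, cols, vals = [], [], []
    for j, vec in enumerate(vectors):
        for i, w in vec.weights.items():
            rows.append(j)
            cols.append(i)
            vals.append(w)
    x = sparse.csr_matrix((vals, (rows, cols)), shape=(n, max(dim, 1)))
    norms = np.sqrt(np.asarray(x.multiply(x).sum(axis=1)).ravel())
    nz = norms > 0
    if not nz.all():
        logger.warning("%d zero vector(s); their pairs score 0", int((~nz).sum()))
    inv = np.where(nz, 1.0 / np.where(nz, norms, 1.0), 0.0)
    xn = sparse.diags(inv) @ x
    sim = (xn @ xn.T).toarray()
    np.clip(sim, 0.0, 1.0, out=sim)

    edges = []
    for j in range(n):
        for k in range(j + 1, n):
            a, b = vectors[j].doc_id, vectors[k].doc_id
            if a > b:
                a, b = b, a
            edges.append(SimilarityEdge(id_a=a, id_b=b, score=float(sim[j, k])))
    return edges


def neighbor_pairs_at_threshold(edges: list[SimilarityEdge], threshold: float) -> PairList:
    """Pairs with cosine >= threshold (inclusive), scores retained."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold outside [0, 1]: {threshold}")
    pairs = PairList()
    for e in edges:
        if e.score >= threshold:
            pairs.add(e.id_a, e.id_b, e.score)
    return pairs


def score_histogram(edges: list[SimilarityEdge], bin_width: float = 0.05) -> ScoreHistogram:
    """Histogram of cosine scores over [0, 1] with the given bin width."""
    if not edges:
        raise ValueError("no edges to histogram")
    if not 0.0 < bin_width <= 1.0:
        raise ValueError(f"bin_width outside (0, 1]: {bin_width}")
    n_bins = int(np.ceil(round(1.0 / bin_width, 12)))
    bin_edges = np.minimum(np.arange(n_bins + 1) * bin_width, 1.0)
    bin_edges[-1] = 1.0
    scores = np.array([e.score for e in edges])
    counts, _ = np.histogram(scores, bins=bin_edges)  # np closes the last bin
    return ScoreHistogram(bin_edges=bin_edges, counts=counts)


def single_linkage_clusters(
    edges: list[SimilarityEdge], threshold: float, universe: set[str]
) -> ClusterSet:
    """Connected components of the graph on ``universe`` with edges >= threshold.

    Single-linkage at a cutoff is exactly component-finding: any qualifying
    link merges two groups. Ids touched by no qualifying edge are singletons.
    """
    for e in edges:
        if e.id_a not in universe or e.id_b not in universe:
            raise ValueError(f"edge endpoint outside universe: ({e.id_a}, {e.id_b})")
    g: nx.Graph = nx.Graph()
    g.add_nodes_from(universe)
    g.add_edges_from((e.id_a, e.id_b) for e in edges if e.score >= threshold)
    clusters = sorted((frozenset(c) for c in nx.connected_components(g)), key=min)
    return ClusterSet(clusters=clusters, threshold=threshold)


def clusters_to_pairs(cluster_set: ClusterSet) -> PairList:
    """All within-cluster pairs: the union over clusters of their C(s, 2) pairs."""
    pairs = PairList()
    for cluster in cluster_set.clusters:
        members = sorted(cluster)
        for j in range(len(members)):
            for k in range(j + 1, len(members)):
                pairs.add(members[j], members[k])
    return pairs


def multi_threshold_clusters(
    edges: list[SimilarityEdge], thresholds: list[float], universe: set[str]
) -> list[ClusterSet]:
    """Cluster at a strictly descending sequence of cutoffs.

    Each higher-threshold clustering refines every lower-threshold one:
    lowering the cutoff can only merge components, never split them. Used to
    connect tight cores first and then attach looser members (e.g. a cutoff
    of 0.90 followed by 0.88).
    """
    if any(t2 >= t1 for t1, t2 in zip(thresholds, thresholds[1:])):
        raise ValueError(f"thresholds must be strictly descending: {thresholds}")
    return [single_linkage_clusters(edges, t, universe) for t in thresholds]


def write_edges(edges: list[SimilarityEdge], path) -> None:
    """Write all scored pairs as a sorted pair TSV with scores."""
    with open(path, "w", encoding="utf-8") as fh:
        for e in sorted(edges, key=lambda e: (e.id_a, e.id_b)):
            fh.write(f"{e.id_a}\t{e.id_b}\t{e.score!r}\n")


def read_edges(path) -> list[SimilarityEdge]:
    """Read a scored pair TSV back into edges."""
    edges = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip():
                continue
            a, b, s = line.split("\t")
            edges.append(SimilarityEdge(id_a=a, id_b=b, score=float(s)))
    return edges


def write_histogram(hist: ScoreHistogram, path) -> None:
    """Write histogram bins as TSV: bin_start, bin_end, count, fraction."""
    fractions = hist.fractions
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("bin_start\tbin_end\tcount\tfraction\n")
        for lo, hi, c, f in zip(hist.bin_edges[:-1], hist.bin_edges[1:], hist.counts, fractions):
            fh.write(f"{lo:.6g}\t{hi:.6g}\t{int(c)}\t{f!r}\n")


def plot_histogram(hist: ScoreHistogram, path) -> None:
    """Render the score distribution as a bar plot (PNG/SVG by extension)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    widths = np.diff(hist.bin_edges)
    fig, ax = plt.subplots(figsize=(7, 4))
    ax.bar(hist.bin_edges[:-1], hist.fractions, width=widths, align="edge", edgecolor="black")
    ax.set_xlabel("cosine score")
    ax.set_ylabel("fraction of assay pairs")
    ax.set_xlim(0, 1)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
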