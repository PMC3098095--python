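"""Benchmark construction and precision/recall scoring of predicted neighbors.

The curated benchmark is built from depositor-style annotations by extracting
every annotated (query, related) pair, closing the pairs under single linkage
into connected components, and expanding each component into all of its
within-component pairs. Closure means an assay annotated as related to B,
with B related to C, contributes the pair (A, C) even though never directly
annotated; a ``closure=False`` mode keeps only the directly annotated pairs
for comparison.

Precision is the fraction of predicted pairs found in the benchmark; recall
is the fraction of benchmark pairs predicted; F1 is their harmonic mean.
Benchmark pairs whose assays are absent from the scored corpus still count in
the recall denominator (they depress recall) unless ``strict`` filtering is
requested by the caller beforehand.
"""

from __future__ import annotations

import logging
import statistics
from dataclasses import dataclass

import networkx as nx

from .corpus_io import AnnotationMap, PairList
from .neighboring import ClusterSet, SimilarityEdge, clusters_to_pairs, neighbor_pairs_at_threshold

logger = logging.getLogger(__name__)


@dataclass
class BenchmarkSet:
    """Reference pair set with closure-cluster summary statistics."""

    pairs: PairList
    n_source_records: int
    n_clusters: int
    cluster_sizes: list[int]

    @property
    def median_cluster_size(self) -> float:
        return statistics.median(self.cluster_sizes) if self.cluster_sizes else 0.0

    @property
    def n_single_pair_clusters(self) -> int:
        """Clusters of exactly two assays, contributing a single pair each."""
        return sum(1 for s in self.cluster_sizes if s == 2)


@dataclass
class EvalReport:
    """Precision/recall/F1 of one predicted pair set against a reference."""

    threshold: float | None
    n_predicted: int
    n_reference: int
    n_true: int
    precision: float
    recall: float
    f1: float
    precision_defined: bool = True


@dataclass
class OverlapRecord:
    """Agreement between two pair sets: |a|, |b|, |a ∩ b|, |a ∩ b| / |a|."""

    size_a: int
    size_b: int
    common: int
    fraction_a_confirmed: float


def build_benchmark_pairs(annotations: AnnotationMap, closure: bool = True) -> BenchmarkSet:
    """Extract annotated pairs, single-linkage close, expand within components.

    With ``closure=False`` the direct annotated pairs are returned without
    transitive expansion (clusters are still reported from the closure graph,
    since that is what the pairs connect).
    """
    g: nx.Graph = nx.Graph()
    n_source = 0
    for query, related in annotations.entries.items():
        if related:
            n_source += 1
        for other in related:
            g.add_edge(query, other)
    components = sorted((frozenset(c) for c in nx.connected_components(g)), key=min)
    cluster_sizes = sorted((len(c) for c in components), reverse=True)

    if closure:
        pairs = clusters_to_pairs(ClusterSet(clusters=list(components), threshold=None))
    else:
        pairs = PairList(set(annotations.iter_pairs()))
    return BenchmarkSet(
        pairs=pairs,
        n_source_records=n_source,
        n_clusters=len(components),
        cluster_sizes=cluster_sizes,
    )


def precision_recall(
    predicted: PairList, reference: PairList, threshold: float | None = None
) -> EvalReport:
    """Score predicted pairs against reference pairs.

    True predictions are the set intersection. With zero predictions,
    precision is undefined; it is reported as 0 with ``precision_defined``
    False so sweeps serialize cleanly.
    """
    if len(reference) == 0:
        raise ValueError("empty reference pair set: nothing to evaluate against")
    n_pred = len(predicted)
    n_ref = len(reference)
    n_true = len(predicted.keys() & reference.keys())
    defined = n_pred > 0
    precision = n_true / n_pred if defined else 0.0
    recall = n_true / n_ref
    return EvalReport(
        threshold=threshold,
        n_predicted=n_pred,
        n_reference=n_ref,
        n_true=n_true,
        precision=precision,
        recall=recall,
        f1=f1_score(precision, recall),
        precision_defined=defined,
    )


def f1_score(precision: float, recall: float) -> float:
    """Harmonic mean 2pr/(p+r); 0 by convention when both are 0."""
    if not 0.0 <= precision <= 1.0 or not 0.0 <= recall <= 1.0:
        raise ValueError(f"precision/recall outside [0, 1]: {precision}, {recall}")
    if precision + recall == 0.0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def threshold_sweep(
    edges: list[SimilarityEdge], reference: BenchmarkSet, thresholds: list[float]
) -> list[EvalReport]:
    """Evaluate neighbor prediction at each cosine cutoff.

    The predicted set shrinks (weakly) as the cutoff rises, so recall is
    non-increasing in threshold; this theorem is asserted on every run.
    """
    reports = []
    for t in thresholds:
        predicted = neighbor_pairs_at_threshold(edges, t)
        reports.append(precision_recall(predicted, reference.pairs, threshold=t))
    order = sorted(range(len(thresholds)), key=lambda i: thresholds[i])
    recalls = [reports[i].recall for i in order]
    assert all(r1 >= r2 for r1, r2 in zip(recalls, recalls[1:])), (
        "recall must be non-increasing in threshold"
    )
    return reports


def pair_overlap(a: PairList, b: PairList) -> OverlapRecord:
    """How much of pair set a is confirmed by pair set b."""
    common = len(a.keys() & b.keys())
    if len(a) == 0:
        logger.warning("overlap against an empty pair set; fraction reported as 0")
        fraction = 0.0
    else:
        fraction = common / len(a)
    return OverlapRecord(size_a=len(a), size_b=len(b), common=common, fraction_a_confirmed=fraction)


def write_reports(reports: list[EvalReport], path) -> None:
    """Write evaluation reports as TSV (threshold-sweep table shape).

    Precision/recall/F1 are rendered as percentages to two decimals;
    the underlying values stay unrounded in memory.
    """
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("threshold\tn_predicted\tn_reference\tn_true\tprecision\trecall\tf1\n")
        for r in reports:
            t = "" if r.threshold is None else f"{r.threshold:g}"
            fh.write(
                f"{t}\t{r.n_predicted}\t{r.n_reference}\t{r.n_true}\t"
                f"{100 * r.precision:.2f}\t{100 * r.recall:.2f}\t{100 * r.f1:.2f}\n"
            )


def write_overlap(records: list[tuple[str, str, OverlapRecord]], path) -> None:
    """Write overlap records as TSV: method_a, method_b, sizes, common, fraction."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("method_a\tmethod_b\tsize_a\tsize_b\tcommon\tfraction\n")
        for name_a, name_b, rec in records:
            fh.write(
                f"{name_a}\t{name_b}\t{rec.size_a}\t{rec.size_b}\t{rec.common}\t"
                f"{rec.fraction_a_confirmed:.4f}\n"
            )
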