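"""Benchmark construction and precision/recall/F1 scoring."""

import itertools
import random

import pytest

from bioassay_neighbors import (
    AnnotationMap,
    PairList,
    SimilarityEdge,
    build_benchmark_pairs,
    f1_score,
    pair_overlap,
    precision_recall,
    threshold_sweep,
)


def pairs_of(*items):
    return PairList(list(items))


class TestBuildBenchmark:
    def test_closure_expands_transitive_relations(self):
        ann = AnnotationMap(entries={"A": ["B"], "B": ["C"]})
        bench = build_benchmark_pairs(ann)
        assert bench.pairs.keys() == {("A", "B"), ("A", "C"), ("B", "C")}
        assert bench.n_clusters == 1 and bench.cluster_sizes == [3]

    def test_disjoint_single_pair_clusters(self):
        bench = build_benchmark_pairs(AnnotationMap(entries={"A": ["B"], "C": ["D"]}))
        assert bench.pairs.keys() == {("A", "B"), ("C", "D")}
        assert bench.n_clusters == 2
        assert bench.n_single_pair_clusters == 2
        assert bench.median_cluster_size == 2

    def test_empty_annotations_empty_benchmark(self):
        bench = build_benchmark_pairs(AnnotationMap())
        assert len(bench.pairs) == 0 and bench.n_clusters == 0

    def test_no_closure_mode_keeps_direct_pairs_only(self):
        ann = AnnotationMap(entries={"A": ["B"], "B": ["C"]})
        bench = build_benchmark_pairs(ann, closure=False)
        assert bench.pairs.keys() == {("A", "B"), ("B", "C")}

    def test_closure_is_idempotent(self):
        """Rebuilding from the benchmark's own pairs reproduces the same pairs."""
        rng = random.Random(11)
        for _ in range(30):
            entries = {}
            ids = [f"x{j}" for j in range(rng.randint(2, 15))]
            for q in rng.sample(ids, rng.randint(1, len(ids))):
                k = rng.randint(0, min(3, len(ids)))
                entries[q] = [r for r in rng.sample(ids, k) if r != q]
            first = build_benchmark_pairs(AnnotationMap(entries=entries))
            rebuilt: dict[str, list[str]] = {}
            for a, b in first.pairs:
                rebuilt.setdefault(a, []).append(b)
            second = build_benchmark_pairs(AnnotationMap(entries=rebuilt))
            assert second.pairs.keys() == first.pairs.keys()
            assert second.n_clusters == first.n_clusters


class TestPrecisionRecall:
    def test_identity(self):
        report = precision_recall(pairs_of(("A", "B")), pairs_of(("A", "B")))
        assert report.precision == 1.0 and report.recall == 1.0 and report.f1 == 1.0

    def test_half_overlap(self):
        report = precision_recall(
            pairs_of(("A", "B"), ("C", "D")), pairs_of(("A", "B"), ("E", "F"))
        )
        assert report.precision == 0.5 and report.recall == 0.5
        assert report.n_true == 1

    def test_empty_predictions_precision_undefined(self):
        report = precision_recall(PairList(), pairs_of(("A", "B")))
        assert report.recall == 0.0
        assert report.precision == 0.0 and not report.precision_defined

    def test_empty_reference_errors(self):
        with pytest.raises(ValueError):
            precision_recall(pairs_of(("A", "B")), PairList())

    def test_counts_match_brute_force_set_operations(self):
        rng = random.Random(5)
        universe = list(itertools.combinations("abcdefgh", 2))
        for _ in range(50):
            pred = set(rng.sample(universe, rng.randint(0, len(universe))))
            ref = set(rng.sample(universe, rng.randint(1, len(universe))))
            report = precision_recall(PairList(pred), PairList(ref))
            assert report.n_true == len(pred & ref)
            assert report.n_true <= min(report.n_predicted, report.n_reference)
            if pred:
                assert report.precision == len(pred & ref) / len(pred)
            assert report.recall == len(pred & ref) / len(ref)


class TestF1:
    def test_published_comparison_rows(self):
        # harmonic means of rounded (precision, recall) percentages as printed
        assert round(100 * f1_score(0.005, 0.41), 2) == 0.99
        assert round(100 * f1_score(0.006, 0.46), 2) == 1.18

    def test_degenerate_and_symmetry(self):
        assert f1_score(0.0, 0.0) == 0.0
        for p, r in [(0.2, 0.8), (0.31, 0.62), (1.0, 0.5)]:
            assert f1_score(p, r) == f1_score(r, p)
            assert f1_score(p, r) <= 2 * min(p, r)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            f1_score(1.2, 0.5)


class TestThresholdSweep:
    def test_recall_non_increasing(self, fixture_corpus, fixture_edges):
        import bioassay_neighbors as bn

        reference = bn.ground_truth_pairs(fixture_corpus)
        thresholds = [round(0.1 * k, 1) for k in range(1, 10)]
        reports = threshold_sweep(fixture_edges, reference, thresholds)
        recalls = [r.recall for r in reports]
        assert all(r1 >= r2 for r1, r2 in zip(recalls, recalls[1:]))

    def test_zero_threshold_gives_full_recall_with_nonzero_vectors(self, fixture_corpus,
                                                                   fixture_edges):
        import bioassay_neighbors as bn

        reference = bn.ground_truth_pairs(fixture_corpus)
        [report] = threshold_sweep(fixture_edges, reference, [0.0])
        assert report.recall == 1.0

    def test_planted_structure_recovered_at_default_threshold(self, fixture_corpus,
                                                              fixture_edges):
        import bioassay_neighbors as bn

        reference = bn.ground_truth_pairs(fixture_corpus)
        [report] = threshold_sweep(fixture_edges, reference, [0.4])
        assert report.precision >= 0.95 and report.recall >= 0.95


class TestPairOverlap:
    def test_fraction_of_a_confirmed_by_b(self):
        rec = pair_overlap(pairs_of(("A", "B"), ("C", "D")), pairs_of(("A", "B")))
        assert rec.common == 1 and rec.fraction_a_confirmed == 0.5

    def test_identity_and_disjoint(self):
        a = pairs_of(("A", "B"), ("C", "D"))
        assert pair_overlap(a, a).fraction_a_confirmed == 1.0
        assert pair_overlap(a, pairs_of(("E", "F"))).fraction_a_confirmed == 0.0

    def test_empty_a_flagged(self, caplog):
        with caplog.at_level("WARNING"):
            rec = pair_overlap(PairList(), pairs_of(("A", "B")))
        assert rec.fraction_a_confirmed == 0.0
        assert any("empty" in r.message for r in caplog.records)
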