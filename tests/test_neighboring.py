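"""Cosine scoring, thresholding, histograms, and single-linkage clustering."""

import itertools
import math
import random

import numpy as np
import pytest

from bioassay_neighbors import (
    DocumentVector,
    SimilarityEdge,
    all_pairs_similarity,
    clusters_to_pairs,
    cosine_similarity,
    multi_threshold_clusters,
    neighbor_pairs_at_threshold,
    score_histogram,
    single_linkage_clusters,
)
from bioassay_neighbors.neighboring import ClusterSet, read_edges, write_edges


def vec(doc_id, *entries, dim=8):
    return DocumentVector(doc_id=doc_id, weights=dict(entries), dim=dim)


def dense_cosine_oracle(u: DocumentVector, v: DocumentVector) -> float:
    """Brute-force dense cosine over the full vocabulary, for cross-checking."""
    a = np.zeros(u.dim)
    b = np.zeros(v.dim)
    for i, w in u.weights.items():
        a[i] = w
    for i, w in v.weights.items():
        b[i] = w
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    return float(a @ b / (na * nb))


def dfs_components_oracle(nodes, edge_pairs):
    """Connected components by explicit depth-first search."""
    adjacency = {n: set() for n in nodes}
    for a, b in edge_pairs:
        adjacency[a].add(b)
        adjacency[b].add(a)
    seen, components = set(), []
    for start in nodes:
        if start in seen:
            continue
        stack, comp = [start], set()
        while stack:
            node = stack.pop()
            if node in comp:
                continue
            comp.add(node)
            stack.extend(adjacency[node] - comp)
        seen |= comp
        components.append(frozenset(comp))
    return set(components)


class TestCosine:
    def test_identical_vectors_score_exactly_one(self):
        u = vec("a", (0, 1.3), (3, 0.7))
        v = vec("b", (0, 1.3), (3, 0.7))
        assert cosine_similarity(u, v) == 1.0

    def test_disjoint_supports_score_exactly_zero(self):
        assert cosine_similarity(vec("a", (0, 2.0)), vec("b", (1, 3.0))) == 0.0

    def test_hand_worked_value(self):
        # u=(1,0,1), v=(1,1,0): dot=1, norms sqrt(2) -> 0.5
        u = vec("a", (0, 1.0), (2, 1.0), dim=3)
        v = vec("b", (0, 1.0), (1, 1.0), dim=3)
        assert cosine_similarity(u, v) == pytest.approx(0.5, abs=1e-15)

    def test_zero_vector_convention(self, caplog):
        with caplog.at_level("WARNING"):
            assert cosine_similarity(vec("a"), vec("b", (0, 1.0))) == 0.0
        assert any("zero vector" in r.message for r in caplog.records)

    def test_mismatched_spaces_error(self):
        with pytest.raises(ValueError):
            cosine_similarity(vec("a", dim=3), vec("b", dim=4))

    def test_symmetry_and_scale_invariance(self):
        rng = random.Random(7)
        for _ in range(20):
            u = vec("a", *((i, rng.uniform(0.1, 3)) for i in rng.sample(range(8), 3)))
            v = vec("b", *((i, rng.uniform(0.1, 3)) for i in rng.sample(range(8), 3)))
            s = cosine_similarity(u, v)
            assert cosine_similarity(v, u) == s
            scaled = DocumentVector("a2", {i: 7.5 * w for i, w in u.weights.items()}, 8)
            assert cosine_similarity(scaled, v) == pytest.approx(s, abs=1e-12)
            assert 0.0 <= s <= 1.0


class TestAllPairs:
    def test_pair_count(self):
        vectors = [vec(f"d{j}", (j, 1.0)) for j in range(4)]
        assert len(all_pairs_similarity(vectors)) == 6

    def test_single_vector_errors(self):
        with pytest.raises(ValueError):
            all_pairs_similarity([vec("a", (0, 1.0))])

    def test_matches_dense_oracle_on_random_corpora(self):
        """Sparse all-pairs equals the dense double loop to 1e-12 (200 corpora)."""
        rng = random.Random(42)
        for _ in range(200):
            n = rng.randint(2, 30)
            dim = rng.randint(1, 12)
            vectors = []
            for j in range(n):
                support = rng.sample(range(dim), rng.randint(0, dim))
                vectors.append(
                    vec(f"d{j:02d}", *((i, rng.uniform(0.01, 5)) for i in support), dim=dim)
                )
            got = {(e.id_a, e.id_b): e.score for e in all_pairs_similarity(vectors)}
            assert len(got) == n * (n - 1) // 2
            for u, v in itertools.combinations(vectors, 2):
                expected = dense_cosine_oracle(u, v)
                assert got[(u.doc_id, v.doc_id)] == pytest.approx(expected, abs=1e-12)


class TestThreshold:
    def edges(self):
        return [SimilarityEdge("A", "B", 0.94), SimilarityEdge("C", "D", 0.30)]

    def test_inclusive_cutoff(self):
        assert len(neighbor_pairs_at_threshold(self.edges(), 0.4)) == 1
        assert len(neighbor_pairs_at_threshold(self.edges(), 0.94)) == 1  # >= is inclusive
        assert len(neighbor_pairs_at_threshold(self.edges(), 0.0)) == 2
        assert len(neighbor_pairs_at_threshold(self.edges(), 1.0)) == 0

    def test_threshold_out_of_range(self):
        with pytest.raises(ValueError):
            neighbor_pairs_at_threshold(self.edges(), 1.5)

    def test_antitone_in_threshold(self, fixture_edges):
        previous = None
        for t in np.linspace(0, 1, 11):
            current = neighbor_pairs_at_threshold(fixture_edges, float(t)).keys()
            if previous is not None:
                assert current <= previous
            previous = current


class TestHistogram:
    def test_binning_example(self):
        edges = [SimilarityEdge("A", "B", 0.05), SimilarityEdge("C", "D", 0.45),
                 SimilarityEdge("E", "F", 0.90)]
        hist = score_histogram(edges, bin_width=0.1)
        assert hist.counts.sum() == 3
        assert hist.counts[0] == 1 and hist.counts[4] == 1 and hist.counts[9] == 1

    def test_fractions_sum_to_one(self, fixture_edges):
        hist = score_histogram(fixture_edges, bin_width=0.05)
        assert hist.counts.sum() == len(fixture_edges)
        assert math.isclose(hist.fractions.sum(), 1.0, abs_tol=1e-12)

    def test_score_exactly_one_lands_in_final_bin(self):
        hist = score_histogram([SimilarityEdge("A", "B", 1.0)], bin_width=0.1)
        assert hist.counts[-1] == 1

    def test_no_edges_errors(self):
        with pytest.raises(ValueError):
            score_histogram([], 0.1)


class TestClustering:
    def chain_edges(self):
        return [SimilarityEdge("A", "B", 0.9), SimilarityEdge("B", "C", 0.85)]

    def test_transitive_chaining(self):
        cs = single_linkage_clusters(self.chain_edges(), 0.8, {"A", "B", "C", "D"})
        assert set(cs.clusters) == {frozenset("ABC"), frozenset("D")}

    def test_high_threshold_gives_singletons(self):
        cs = single_linkage_clusters(self.chain_edges(), 0.95, {"A", "B", "C", "D"})
        assert all(len(c) == 1 for c in cs.clusters) and len(cs) == 4

    def test_endpoint_outside_universe_errors(self):
        with pytest.raises(ValueError):
            single_linkage_clusters(self.chain_edges(), 0.5, {"A", "B"})

    def test_matches_dfs_oracle_on_random_graphs(self):
        """Clusters equal DFS connected components on 200 random threshold graphs."""
        rng = random.Random(7)
        for _ in range(200):
            n = rng.randint(1, 50)
            nodes = {f"n{j:02d}" for j in range(n)}
            edges = []
            for a, b in itertools.combinations(sorted(nodes), 2):
                if rng.random() < 3.0 / max(n, 1):
                    edges.append(SimilarityEdge(a, b, rng.random()))
            t = rng.random()
            got = set(single_linkage_clusters(edges, t, nodes).clusters)
            expected = dfs_components_oracle(
                nodes, [(e.id_a, e.id_b) for e in edges if e.score >= t]
            )
            assert got == expected

    def test_clusters_to_pairs(self):
        cs = ClusterSet(clusters=[frozenset("ABC"), frozenset("D"), frozenset("EFGH")],
                        threshold=0.5)
        pairs = clusters_to_pairs(cs)
        assert len(pairs) == 3 + 0 + 6
        assert ("A", "C") in pairs and ("E", "H") in pairs


class TestMultiThreshold:
    def test_example_chaining_at_lower_cutoff(self):
        edges = [SimilarityEdge("A", "B", 0.92), SimilarityEdge("B", "C", 0.89)]
        high, low = multi_threshold_clusters(edges, [0.90, 0.88], {"A", "B", "C"})
        assert set(high.clusters) == {frozenset("AB"), frozenset("C")}
        assert set(low.clusters) == {frozenset("ABC")}

    def test_single_threshold_degenerates(self, fixture_edges):
        universe = {e.id_a for e in fixture_edges} | {e.id_b for e in fixture_edges}
        [multi] = multi_threshold_clusters(fixture_edges, [0.4], universe)
        single = single_linkage_clusters(fixture_edges, 0.4, universe)
        assert set(multi.clusters) == set(single.clusters)

    def test_non_descending_thresholds_error(self):
        with pytest.raises(ValueError):
            multi_threshold_clusters([], [0.5, 0.5], set())

    def test_refinement_property_on_random_inputs(self):
        """Every higher-threshold cluster is contained in one lower-threshold cluster."""
        rng = random.Random(3)
        for _ in range(50):
            n = rng.randint(2, 25)
            nodes = {f"n{j}" for j in range(n)}
            edges = [
                SimilarityEdge(a, b, rng.random())
                for a, b in itertools.combinations(sorted(nodes), 2)
                if rng.random() < 0.3
            ]
            ts = sorted({round(rng.random(), 3) for _ in range(4)}, reverse=True)
            if len(ts) < 2:
                continue
            sets = multi_threshold_clusters(edges, ts, nodes)
            for higher, lower in zip(sets, sets[1:]):
                for cluster in higher.clusters:
                    assert any(cluster <= low for low in lower.clusters)


def test_edges_tsv_roundtrip(tmp_path, fixture_edges):
    path = tmp_path / "edges.tsv"
    write_edges(fixture_edges, path)
    back = read_edges(path)
    assert {(e.id_a, e.id_b, e.score) for e in back} == {
        (e.id_a, e.id_b, e.score) for e in fixture_edges
    }
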