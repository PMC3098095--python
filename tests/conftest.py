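import pytest

import bioassay_neighbors as bn


@pytest.fixture(scope="session")
def fixture_corpus():
    """The default planted-cluster corpus: 4 clusters x 5 docs, rho=0.9, seed 1."""
    return bn.generate_corpus(bn.SyntheticSpec())


@pytest.fixture(scope="session")
def fixture_edges(fixture_corpus):
    """All-pairs cosine edges of the default fixture (standard IDF)."""
    vectors = bn.vectorize_corpus(bn.preprocess_corpus(fixture_corpus.documents))
    return bn.all_pairs_similarity(vectors)


@pytest.fixture
def tiny_corpus():
    """Three hand-written assay descriptions: two near-duplicates, one unrelated."""
    return [
        bn.RawDocument(id="1663", name="qHTS primary",
                       description="Inhibition of luciferase activity in cells."),
        bn.RawDocument(id="1664", name="qHTS confirmatory",
                       description="Inhibition of luciferase activity in cells."),
        bn.RawDocument(id="2551", name="binding assay",
                       description="Radioligand binding displacement at the dopamine receptor."),
    ]
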