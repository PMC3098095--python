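"""Score a handful of assay descriptions against each other.

Builds a three-document corpus in memory, runs the preprocess -> vectorize ->
cosine chain, and prints every pairwise score. Two of the descriptions are
identical (score 1.0); the third shares almost nothing with them (score near
0). Scores in between would indicate partial vocabulary overlap.
"""

import bioassay_neighbors as bn

docs = [
    bn.RawDocument(id="1663", description="Inhibition of firefly luciferase activity in cells."),
    bn.RawDocument(id="1664", description="Inhibition of firefly luciferase activity in cells."),
    bn.RawDocument(id="2551", description="Radioligand binding displacement at dopamine receptors."),
]

tokenized = bn.preprocess_corpus(docs)
for doc in tokenized:
    print(f"{doc.id}: tokens after stemming/stop-word removal -> {list(doc.tokens)}")

vectors = bn.vectorize_corpus(tokenized)
for edge in bn.all_pairs_similarity(vectors):
    print(f"cosine({edge.id_a}, {edge.id_b}) = {edge.score:.4f}")

print("\n1.0 = identical descriptions; 0.0 = no shared terms; "
      ">= 0.4 would be called a neighbor at the default threshold.")
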