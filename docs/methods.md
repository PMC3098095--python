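# Methods

## The model

An assay description is treated as a bag of words: word order is discarded
and only term occurrence counts matter. This is deliberately conservative —
no named-entity recognition, topic models, or embeddings — because assay
descriptions are long, repetitive, protocol-heavy documents where shared
vocabulary alone carries a strong relatedness signal, and because a
bag-of-words pipeline is fully auditable: every similarity score can be
traced to the specific shared terms that produced it.

### Text processing

Processing order is: lowercase → remove parenthesis characters → split on
whitespace → strip leading/trailing non-alphanumerics from each token → drop
pure-digit tokens → remove stop words → Porter-stem → remove stop words
again. Choices worth recording:

- **Hyphens.** Internal hyphens are preserved so chemical names and
  formulas ("luciferin-h", "vcam-1", "cell-based") remain single terms;
  edge hyphens are stripped with other punctuation.
- **Digits.** Tokens containing digits are kept ("p450"); tokens that are
  *only* digits are dropped — a bare number carries no assay concept.
- **Stemmer.** The original Porter (1980) algorithm, implemented in
  `porter.py` and validated against hand-verified reference stems. The later
  Porter2/Snowball revision stems some words differently; the 1980 rules are
  used throughout so vocabularies are stable and reproducible.
- **Stop words.** The packaged list (`data/stopwords_en.txt`) is a
  SMART-style English IR list of ~400 function words, overridable by file.
  The filter runs again after stemming because a stem can coincide with a
  stop word even when its surface form does not ("doing" → "do").
- **Titles.** `include_title=False` by default — the method mines the
  description body — but assay titles are often informative, so prepending
  them is one flag away.
- Lowercasing happens before hyphen handling, and numerals are kept inside
  mixed tokens; where the processing order was genuinely open these defaults
  are documented rather than claimed canonical.

### Weighting

For term *i* in document *j* with count `m_ij`:

    weight = 0.5 * (1 + m_ij / max_tf_j) * IDF

The augmented-TF factor `0.5·(1 + m/max_tf)` lies in (0.5, 1] for present
terms, which stops long repetitive protocol sections from dominating a
vector. Maximum-term-frequency normalization is the standard choice that
pairs with the `0.5·(1+·)` form; the normalization function was an open
design point and this is the documented default.

Two IDF variants exist because the per-document form

    IDF_ij = log2(M_i / m_ij)        (idf_mode="paper")

(with `M_i` the corpus-wide occurrence total of term *i*) actually gives
*higher* weight to terms that are widespread in the corpus relative to their
local count — opposite to the usual intent that widely co-occurring terms be
down-weighted. The default is therefore the standard form

    IDF_i = log2(N / df_i)           (idf_mode="standard")

which matches that intent; the per-document variant is kept selectable for
comparability with results produced under it. Both are non-negative
(`M_i ≥ m_ij`, `N ≥ df_i`), so all weights are non-negative and cosine
scores stay in [0, 1]. Exact-zero weights are dropped from the sparse
vectors; all arithmetic is double precision. No document-frequency pruning
is applied by default (`min_df=1`); the option exists only for scalability.

### Similarity, thresholding, clustering

Similarity is the cosine of the angle between two document vectors, chosen
over Euclidean distance for its naturally normalized range. Numerical
conventions:

- A pair of *token-identical* documents short-circuits to exactly 1.0,
  avoiding float noise in the norm product.
- Cosine with an all-zero vector (a description emptied by preprocessing) is
  defined as 0 with a warning, not NaN — empty descriptions simply have no
  neighbors.
- Thresholding is inclusive (`score ≥ t`); scores are never rounded before
  comparison.
- All C(n, 2) pairs are scored exactly via a row-normalized sparse matrix
  product (sparse dot products over shared terms). Corpora of a few thousand
  documents are trivial at O(n²); no approximate nearest-neighbor indexing
  is used or wanted.

Single-linkage clustering at a cutoff is exactly connected-components of the
threshold graph, computed with networkx; ids touched by no qualifying edge
are singletons. `multi_threshold_clusters` evaluates a strictly descending
cutoff sequence (e.g. 0.90 then 0.88) and guarantees each higher-threshold
clustering refines every lower one, since lowering the cutoff only adds
edges. Score histograms use half-open bins with the final bin closed at 1.0
(default width 0.05, configurable).

### Evaluation

The curated benchmark is built from depositor-style annotations by
extract → close → expand: every annotated (query, related) pair becomes an
edge, the edges are closed into connected components (single linkage), and
each component contributes all of its within-component pairs. Closure means
A–B plus B–C yields the pair A–C even though never directly annotated; a
`closure=False` mode keeps direct pairs only, for comparison. The
construction is idempotent.

Precision = true/predicted, recall = true/reference, F1 = harmonic mean,
with conventions chosen for clean serialization: zero predictions give
precision 0 with a `precision_defined=False` flag rather than NaN, and
F1(0, 0) = 0. Reference pairs whose assays never appear in the scored corpus
still count in the recall denominator — missing descriptions depress recall
rather than silently shrinking the benchmark. Reports render percentages to
two decimals; in-memory values are unrounded. In threshold sweeps, recall is
non-increasing in the threshold (the predicted set is antitone); this
theorem is asserted on every run.

### Default threshold

The default neighbor cutoff is 0.4. Over real assay-description corpora the
all-pairs cosine distribution is bimodal — the overwhelming mass of
unrelated pairs lies below ~0.5 and a small strong-relevance mass above
~0.8 — and 0.4 sits at the lower edge of the gap, balancing precision
against recall in benchmark sweeps. It is a config field everywhere it is
used.

## The synthetic generator

`SyntheticSpec` plants cluster structure: each of `n_clusters` clusters owns
a private topic vocabulary of `topic_vocab_size` words, disjoint from the
other clusters and from a shared `background_vocab_size`-word background.
Each token of a document in cluster *c* is drawn from *c*'s topic vocabulary
with probability `topic_fraction` (ρ), else uniformly from the background.
One RNG stream seeded from `spec.seed` drives everything; the same spec is
byte-reproducible.

Defaults — 4 clusters × 5 documents, 20 topic words, 100 background words,
200 tokens per document, ρ = 0.9, seed 1 — are the fixture used across the
test suite. The document count is deliberately small (all-pairs work is
O(n²) and the signal is per-pair, not per-corpus), the 200-token length is
in the range of a short real assay description, and ρ = 0.9 encodes a corpus
whose related assays share most of their vocabulary.

Vocabulary words are consonant–vowel syllable strings verified at generation
time to be Porter fixed points and absent from the stop list, so the token
stream survives preprocessing unchanged — end-to-end tests then isolate the
vector/similarity machinery from stemmer behavior. A `morphology=True` mode
appends English-style inflections ("-s", "-ed", "-ing") and interleaves stop
words; the inflected forms provably stem back to their base words, so the
planted structure is preserved while the full text-processing chain is
exercised. Text is emitted as space-joined tokens with a period every ~15
tokens so normalization has punctuation to strip.

What the generator does *not* emulate: real biomedical language, named
entities, boilerplate shared between unrelated depositors, heavily skewed
document lengths, or partially overlapping topics. Passing the recovery
tests shows the pipeline machinery is correct; it does not certify
performance on real corpora, where vocabulary sharing between unrelated
assays is far messier.

One property worth knowing: the *mean within-cluster cosine* is not monotone
in ρ. At ρ = 0 every document is drawn from the same background, so all
pairs — within and between — score high (~0.76 under the defaults); as ρ
grows, rare background words acquire high IDF and add uncorrelated noise to
within-cluster pairs. The planted signal is the *separation* between within-
and between-cluster scores, which is ~0 at ρ = 0 and large (> 0.3) for any
ρ ≥ 0.3 under the defaults; the property tests assert exactly that.

## Problem sizes

The test suite and acceptance script run entirely on generated data: the
20-document fixture for end-to-end recovery, random corpora of up to 30
documents (200 replicates) for the dense-cosine oracle cross-check, and
random graphs of up to 50 nodes (200 replicates) for the
connected-components oracle. These sizes make every check exact or
near-exact while keeping the whole suite in seconds.

## Known limitations

- Bag-of-words cannot distinguish assays that share protocol boilerplate but
  differ in target, nor connect assays described with disjoint synonyms.
- The per-document `paper` IDF mode is provided for comparability, not
  recommended; its weighting runs against the stated down-weighting intent.
- Benchmark closure inflates the reference set when annotation chains are
  long; the no-closure mode bounds that effect but breaks comparability with
  cluster-expanded reference counts.
- No statistical significance testing of precision differences between
  methods is implemented.
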