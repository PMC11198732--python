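# Methods

## Scope and data model

`textnetsum` operates on *corpora*: ordered collections of documents, one
per queried biological entity, each holding free text and its
sentence-segmented tokens.  Entity ids are unique within a corpus and
insertion order is preserved through file round-trips, so rankings always
cover the queried list in a reproducible order.  Documents with empty text
are retained (they simply score 0 and contribute no terms) rather than
dropped: downstream reports must account for every queried entity.  Files
are UTF-8 and undecodable bytes raise an error instead of being replaced —
silent mojibake in a token would corrupt every downstream count.  The corpus
carries a creation timestamp as provenance metadata only; no computation
reads it.

Multi-source text for one entity (e.g. a curated summary plus an
enrichment-result description) is deliberately *not* concatenated: each
source is a separate corpus producing its own network, and integration
happens at the network level by union/intersection.  This keeps per-source
statistics honest and makes the provenance of every edge explicit.

## Tokenization

Sentences split on `[.!?]` followed by whitespace; tokens are lowercased,
punctuation is stripped from token edges only, and tokens containing no
alphabetic character are dropped.  Consequences of these rules:

- hyphenated biomedical compounds ("ubiquitin-protein", "hect-type") stay
  whole — splitting them destroys meaning;
- bare numerals, percentages and stranded punctuation ("42", "3.5", "--")
  are removed, but alphanumeric identifiers ("e3", "p53") survive;
- no abbreviation dictionary is used, so "E. coli" splits into two
  sentences.  This is accepted noise: the splitter is deterministic and
  dependency-free, and sentence-level co-occurrence counts are robust to
  occasional over-splitting.

No stemming or lemmatization is applied: curated functional descriptions
use controlled vocabulary where inflection carries little signal, and
stemmed forms make networks harder to read.

## Vocabulary filtering

Filters form a conjunction — a term survives only if it passes every
enabled filter — so their application order is immaterial.  Available
filters: stopword list (a packaged English function-word list is the
default), minimum token length (default 1 in the library, 2 in the CLI,
where single characters are rarely wanted), minimum document frequency,
maximum document-frequency fraction (removes ubiquitous boilerplate such as
"protein"), minimum TF-IDF, and a whitelist (e.g. an ontology-derived
vocabulary; supplying an *empty* whitelist is an error because it could
only produce an empty vocabulary).

The frequency thresholds are document-frequency based; total term
frequency was the plausible alternative, and document frequency was chosen
because it is what distinguishes "describes many entities" from "repeated
within one entity".  When a background-statistics table is supplied
(pre-computed over a large reference corpus), document-frequency and
TF-IDF thresholds are evaluated against it instead of the query corpus,
since a 20-gene query corpus cannot estimate which words are generically
common.

Vocabulary ordering is descending corpus frequency with lexicographic
tie-break, everywhere (filtering, important words, wordcloud data), so
top-k truncation is deterministic.

TF-IDF is `tf · ln(N/df)`: natural log, no within-document normalization.
This is the simplest standard form; anyone can regenerate a shipped
background table from it.  Terms in every document weigh exactly 0, and a
single-document corpus has an all-zero TF-IDF matrix — correlation networks
are therefore only meaningful on frequency matrices or multi-document
corpora.

## Networks

**Correlation.**  Pearson correlation between term rows of the
term-document matrix (Spearman by flag, for corpora with heavy-tailed
counts).  Pairs below the threshold are *omitted as edges* rather than
stored with zero weight — identical semantics, sparse representation.
Zero-variance terms have undefined correlation; they are kept as isolated
nodes so frequency displays still show them.  At least 2 documents and 2
terms are required; fewer documents is an error, not a NaN.

**Co-occurrence.**  Weight = number of sentences (pooled over the whole
corpus) containing both terms at least once; within-sentence multiplicity
counts once.  Pooling across the corpus is the default because the quantity
of interest is "how often do these words co-describe entities overall"; a
per-document variant (`unit="document"`, counting each document at most
once per pair) is exposed for corpora with highly repetitive descriptions.

**Community detection.**  Greedy modularity maximization by default —
deterministic for a fixed graph, which matters for reproducible reports —
with asynchronous label propagation as the seeded alternative.
Negative-weight edges (possible in correlation networks with a negative
threshold) are excluded from the modularity computation; isolated nodes
become singleton clusters.  Cluster labels are integers numbered by
decreasing community size with ties broken by smallest member, so the
labelling itself is deterministic.

## Bootstrap cluster tagging

Base tree: average-linkage hierarchical clustering on `d(t,u) = 1 − r(t,u)`
with Pearson `r` — common defaults for correlation-distance word
clustering; linkage method is configurable.  Documents (matrix columns) are
the resampling unit, matching the statistical role of observations.  For
each of `n_boot` resamples (with replacement, same size) the tree is
rebuilt and each internal node of the *base* tree is checked for exact
leaf-set reappearance; the bootstrap probability (BP) is the fraction of
resamples containing it.  The root trivially has BP 1.

Plain BP is reported, not a multiscale approximately-unbiased (AU)
correction.  BP is known to be conservative for large clusters under small
`n_boot`; for the desk-scale tagging use case ("is this word group stable
under document resampling?") BP preserves the semantics at a fraction of
the complexity.  Adding AU would require the multiscale resample-size
sequence and is a known limitation, not an oversight.

Degenerate resamples can leave a term with zero variance; its pairwise
distances are then set to the maximum (2.0), keeping the linkage defined
without biasing stable clusters.

Defaults: `n_boot=100` (BP resolution 0.01, sufficient to separate "almost
always recovered" from "unstable"), `support_threshold=0.9`.

## Entity scoring

`score(e) = Σ_w count(w in e's tokens) · ω(w)` over the important words,
where `ω` is the criterion value (corpus frequency or weighted degree) of
the word — so a word's influence on entity ranking mirrors its prominence
in the network.  Counting is over post-tokenization tokens per document,
for consistency with every other count in the package.  Length
normalization (`by_length`) is available for entity lists with very uneven
description lengths; it is off by default because raw content is the
quantity the score is defined on, and entities with zero tokens score 0
under either setting.

## Merging and comparison

Union: node/edge set unions; edge weight by `max` (a strong relation in any
source survives).  Intersection: node/edge sets present in all inputs;
weight by `min` (conservative).  `mean` is available for both.  Node
frequencies sum across the sources containing the node, because the
underlying corpora are disjoint bodies of text.  Mixing correlation and
co-occurrence networks is rejected — their weights are not commensurable.
The merged network records each input's threshold in metadata and each
edge's contributing sources as provenance.  Note that `mean`-merged
co-occurrence weights need not be integers; integer weights are a property
of freshly built co-occurrence networks, not an invariant of the class.

Comparison reports shared-node/edge counts and Jaccard indices of the node
and edge sets.  The Jaccard of two empty sets is defined as 1.0 (two empty
networks are identical), which keeps self-comparison at exactly 1.0.

## Exports

GraphML carries node frequency/cluster, edge weight/provenance, and the
network-level metadata (metric, threshold, sources, meta as a JSON string
attribute); reading it back reconstructs the network losslessly, with
integer-valued attributes restored to `int`.  Cytoscape.js JSON uses the
`elements.nodes/edges` structure with `data.id`, `data.source/target/
weight` and adds styling fields: node `size` linear in frequency into
[10, 50] px, edge `width` linear in |weight| into [1, 10] px.  Newick
dendrograms label internal nodes with BP at 2 decimals and use
merge-height differences as branch lengths.  All exports write nodes and
edges in sorted order with sorted JSON keys, so identical inputs give
byte-identical files; no images are rendered — plotting is downstream of
the exported data.

## Synthetic corpora

The generator emulates the statistical skeleton of curated description
corpora: entities grouped by hidden function ("themes"), each theme owning
a marker vocabulary, descriptions mixing theme words with shared background
boilerplate.  Each token is drawn independently — uniformly within its
vocabulary (a Zipf option exists for stress tests) — with probability
`noise_fraction` from the background.  Theme vocabularies are pairwise
disjoint unless `shared_theme_overlap` moves a fraction of each into a
common pool.  Generated text survives the package tokenizer unchanged, and
generation is deterministic given the seed.

Defaults (3 themes × 15 words × 10 entities, 5 sentences × 8 words, noise
0.2, background vocabulary 20) describe a desk-scale corpus in which theme
structure is clearly present but ~20% of tokens are cross-theme noise.
A feasibility check rejects specs whose theme vocabulary cannot cover a
sentence's expected theme-word content.

What the generator does **not** emulate: real grammar and phrase structure
(tokens are i.i.d., so n-gram statistics are unrealistic), Zipfian corpus
frequencies (unless enabled), polysemy, and the long tail of rare
biomedical terms.  Passing the planted-theme recovery tests therefore shows
that the pipeline's counting, correlation, clustering and bootstrap
machinery is correct and stable — not that real gene-summary corpora will
separate this cleanly; real vocabularies overlap far more than disjoint
planted themes.

## Numerical and degenerate-input choices

- Correlation edge weights are clipped to [−1, 1] to absorb floating-point
  excess; oracle tests agree to 1e−9, TF-IDF to 1e−12, GraphML weight
  round-trips to 1e−12.
- All ties (vocabulary order, important words, wordcloud sizes, cluster
  label numbering) break lexicographically.
- Empty corpora, empty vocabularies, sub-minimum matrix shapes, unknown
  enum values and empty whitelists raise `ValueError` with the offending
  name; missing files raise `FileNotFoundError`.
- Every stochastic step (label propagation, bootstrap resampling, synthetic
  generation) takes an explicit seed; `numpy.random.default_rng` is the
  only RNG used.

## Problem sizes

The test suite and the acceptance script run entirely on synthetic corpora
of ≤ 30 documents, ≤ 50 terms, with 100 bootstrap resamples and 50-corpus
oracle sweeps — sizes chosen so the full validation suite completes in
seconds while still exercising every code path; the algorithms themselves
are O(T²·D) or better and handle corpora orders of magnitude larger.

## Known limitations

- No AU-corrected bootstrap p-values (plain BP only, see above).
- The sentence splitter has no abbreviation handling.
- No statistical significance testing of edges, scores or network overlap
  — thresholds are the only selection mechanism, by design.
- No live database fetching; corpora arrive as local TSV/JSON through the
  `read_corpus` seam where fetch adapters would plug in.
- vis.js export is not provided; Cytoscape.js JSON covers the
  interactive-viewer contract.
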