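# Methods

## Sentence co-occurrence mining

The unit of evidence is a single sentence containing a queried gene
symbol and at least one ontology keyword. Matching is case-insensitive
whole-word matching for both genes and keywords, with word boundaries
defined as transitions to non-alphanumeric characters. Two consequences
are deliberate: hyphens and slashes are boundaries, so "stress-induced"
contains the word *stress*; and a symbol never matches inside a longer
token, so the gene `CNR` does not match "CNRs" or "CNR1". Short gene
symbols are ambiguous in both directions (`CNR` is also an imaging
acronym), and the boundary rule minimizes false hits without any
named-entity recognition. Gene synonyms are not searched by default —
short synonyms have too many other meanings — but a synonym table
(2-column TSV, `symbol<TAB>syn1|syn2`) can be supplied for secondary
searches.

The title is treated as the first sentence-bearing text block of each
record and is searched like the abstract. Multi-word keywords match with
flexible internal whitespace.

Evidence is tallied per abstract, not per sentence: the count for a
(gene, concept) pair is the number of distinct PMIDs contributing at
least one matching sentence. These counts are the edge weights of the
result graph, and each edge carries the contributing PMIDs so a weight is
always the size of its evidence set. A sentence matching several
concepts counts independently toward each.

### Sentence splitting

The splitter is rule-based and pinned in the repository rather than
delegated to a toolkit model, so segmentation is identical everywhere the
package runs. A run of `.!?` followed by whitespace ends a sentence
unless (a) the next character is lowercase, (b) the token before a period
is in a fixed biomedical abbreviation list (`et al.`, `Fig.`, `e.g.`,
`approx.`, ...), or (c) the token is a single uppercase initial
("J. Smith"). Decimal numbers never split because no whitespace follows
the period. The abbreviation list is part of the source and covered by a
hand-segmented fixture in the tests; unlisted abbreviations before an
uppercase word will over-split, which costs a candidate sentence but
never produces a false co-occurrence.

### Queries and the remote adapter

Each gene is paired with each concept at the concept (level-2) grouping,
mirroring how results are displayed: `GENE AND (kw1 OR kw2 ...)`, with
multi-word keywords double-quoted. Concept display names are not
themselves search terms — only the level-3 keywords are. Remote search
backends implement a one-method adapter contract (`search(query) ->
pmids`) and can only narrow the candidate abstract set; matching
semantics live entirely in the local miner, and a fake adapter returning
every PMID reproduces pure-local results exactly (property-tested). At
most 200 gene symbols are accepted per search; gene–gene relationships
are out of scope, so larger lists can simply be split across searches.

### GWAS catalog matching

Rows of the "all associations v1.0.2" TSV are parsed keeping every data
row; `REPORTED GENE(S)` splits on commas and `MAPPED_GENE` additionally
on `" - "` (the catalog's intergenic flanking-gene separator). A row is
returned for a gene when the gene equals an entry of either gene list
(case-insensitive) *and* a keyword under the reserved `GWAS` ontology
branch occurs as a whole word in `DISEASE/TRAIT` or `MAPPED_TRAIT`. The
trait-keyword requirement is a design choice — the catalog's trait text
is the field the ontology can meaningfully filter — and can be disabled
(`require_trait_keyword=False` / `--no-trait-filter`) to list every
phenotypic association of a gene. P-values are never thresholded; they
are carried as raw catalog text for display because the column mixes
exponent notation with annotations.

## The stress classifier

### Preprocessing and encoding

Sentences are lowercased; any non-alphanumeric character is a token
boundary; stopwords are removed against a 153-word English list pinned
in-repo; remaining tokens are stemmed with the classic Porter algorithm
(implemented in the package; verified against the algorithm's published
example pairs). Stopword filtering precedes stemming because the list
contains surface forms. The preprocessing configuration is
content-addressed (SHA-256 of list + flags) and recorded in every saved
model manifest, so a model refuses to load under different preprocessing.

The vocabulary maps tokens to indices 2..V-1 in order of descending
corpus frequency, ties lexicographic; 0 is padding and 1 is
out-of-vocabulary, making the mapping a deterministic function of the
corpus. Sequences are pre-padded/pre-truncated to 64 tokens (longer
sentences keep their last 64 tokens), matching the common default of the
embedding-layer tooling this architecture comes from.

### Architecture and training

    embedding V×32 → conv1d (16 filters, kernel 4, valid, ReLU)
    → max-pool (window 2, floor on odd lengths: 61→30)
    → flatten (480) → dense 10 (ReLU) → dense 1 (sigmoid)

The flatten width is `floor((64-4+1)/2) × 16 = 480`; the floor-division
pooling is required for that width and is asserted against the running
network. The loss is binary cross-entropy (systemic = 1), optimized by
Adamax with learning rate 0.002, β₁ = 0.9, β₂ = 0.999, batch size 32.
The labeled corpus is split 80/20 into training and validation
(unstratified uniform at the caller's seed; the vocabulary is fitted on
the full corpus before splitting). Training runs a fixed number of
epochs and returns the weights of the epoch with the highest validation
accuracy, earliest on ties — validation loss starts rising once the
model overfits, and the pre-overfitting peak is the model worth keeping.

Both passes of the network are written directly in numpy (the max-pool
backward routes gradients through argmax positions; the embedding
gradient scatter-adds over token indices). With one CPU and a fixed
seed, two runs produce bit-identical weights — a property the
deep-learning frameworks only offer conditionally — at the cost of GPU
support, which this model does not need.

Weight initialization: embeddings uniform(−0.05, 0.05), conv and dense
Glorot-uniform, biases zero. Probabilities are clipped to 1e−12 inside
the loss only; predictions are raw sigmoid outputs.

### Decision rule and evaluation

A sentence is labeled systemic iff p > 0.5; the tie at exactly 0.5 goes
to cellular. The confusion matrix uses systemic as the positive class.
Metrics with a zero denominator are reported as undefined (`None`) with
a warning, never as 0. AUC uses the rank (Mann–Whitney) formulation with
average ranks for ties, which equals the threshold-sweep trapezoid exactly;
the tests cross-check it against scikit-learn's independent implementation.

### Weak labeling

The two boolean queries that define the training classes are shipped as
constants, byte-for-byte as published, including the original's lowercase
"or" before ACTH — they are data, not code to normalize. The systemic
query ANDs an HPA-axis OR-group with *stress* and NOTs out the cellular
OR-group; the cellular query ANDs the oxidative/ROS OR-group with
*stress*. From the abstracts each query returns, only sentences
containing the whole word *stress* are kept ("stress-induced" counts,
"stressed" does not). Sentences appearing verbatim in both classes carry
contradictory labels and are dropped from both (with a logged count);
the seed-term discovery step that produced the queries (word2vec cosine
similarity) is outside this package's scope — the queries are the
reproducible artifact.

### Synthetic corpus generator

Because the real weakly-labeled corpus requires a PubMed bulk download,
the generator emulates its structure: balanced classes, every sentence
containing *stress*, sentence lengths uniform on 8–30 tokens (bracketing
typical abstract sentences so both padding and truncation paths are
exercised), and class signal carried by marker vocabularies — a
restraint/corticosterone-like list for systemic, an oxidative/ROS-like
list for cellular, 1–3 markers per sentence over shared scientific
filler. `marker_overlap` replaces a fraction of each class's
`n_markers`-word pool with markers common to both classes: at 0 the
classes are separable by vocabulary alone (a bag-of-words linear
classifier reaches 100% training accuracy), and held-out separability
declines monotonically as overlap grows. Generation is deterministic
given (seed, parameters).

What passing on this corpus shows — and does not show. The synthetic
corpus makes the *machinery* testable end to end: encoding, training,
epoch selection, thresholding, evaluation, determinism. It is easier
than real text (no polysemy, no syntax, markers never appear in the
filler), so accuracy here does not predict accuracy on real abstracts,
and the published corpus-dependent figures (≈0.99 validation accuracy,
AUC ≈ 0.99, 23k-token vocabulary) are not reproducible without the real
corpus. Conversely, a failure here would be a genuine defect.

## Problem sizes

The test suite and the acceptance script train on 1,000 sentences per
class for up to 10 epochs (plus a label-shuffle control at the same
size), and smaller corpora (≈400/class) for unit-level properties; these
sizes sit well past the point where the learnability properties
stabilize while keeping a full run in tens of seconds on one CPU.

## Known limitations

* No gene named-entity normalization: a symbol that is also an English
  word will match that word (whole-word matching only bounds, not
  resolves, the ambiguity).
* The sentence splitter's abbreviation list is finite; exotic
  abbreviations before uppercase words over-split.
* The classifier is binary by construction; sentences where "stress"
  means mechanical or materials stress fall outside both classes.
* The GWAS matcher filters on trait text only, not on the underlying
  study abstracts.
* `p_value_float()` returns None for the catalog's annotated p-value
  strings (e.g. "6E-8 (male)"); the raw text is always preserved.
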