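# Methods

This note documents the models and procedures the package implements, the
parameters that matter, what the synthetic-data generator does and does not
emulate, and the numerical and design choices made where the design was
genuinely open.

## Data model

A corpus is a sequence of documents; a document is a title, an abstract, a
list of entity mentions and a set of document-level relations. Character
offsets are 0-based and end-exclusive over `title + " " + abstract` (one
separator character, the convention of released PubTator corpora), and every
mention must slice back to its surface text — this invariant is validated on
read and is the anchor for all downstream offset arithmetic. Composite
concept annotations (several MeSH ids on one mention) are kept as sequences
and expanded wherever identifiers are counted or paired; the input sentinel
`-1` becomes the explicit `unmapped` marker and is excluded from pairing and
evaluation.

## Disease recognition

The recognizer is dictionary-based. Terms and text are tokenized by
splitting on non-alphanumeric characters with case folding (digits kept);
this is the simplest reproducible rule and is deliberately not configurable.
Stopwords (the PubMed list shipped as package data) are removed from
dictionary terms and skipped inside document text during matching (the skip
can be disabled). Tokens are normalized by a pluggable stemmer; the default
is a small rule-based suffix stripper (plural, participle and adverb
endings) iterated to a fixed point, which makes it idempotent by
construction. The original system used the NLM Lexical Variant Generator,
which is not redistributable; any consistent normalizer preserves the
mechanism, and `identity` is available when no stemming is wanted.

Matching is greedy leftmost-longest: at each position the longest indexed
token sequence wins and matching resumes after it; ties cannot arise because
keys of equal length at one position are identical. A brute-force
enumeration oracle (try every key at every position) checks this on random
dictionaries and texts.

Post-processing order is fixed: abbreviation propagation, adjacent-span
merging, exclusion filtering, MeSH mapping. Abbreviation pairs are detected
with the Schwartz–Hearst parenthesis pattern validated by right-to-left
character alignment, within one sentence; propagation of the concept to all
occurrences of either form is document-wide, and on conflict the long form's
concept wins. Merging joins same-concept spans separated only by
non-alphanumeric characters; a consequence is that a defining occurrence
"long form (SF)" merges into a single span. The exclusion list maps a
normalized term to (TP, FP) counts tallied on a training corpus; a span is
removed when `FP > 0` and `TP/FP < 0.3`. The threshold is *strict*: a ratio
of exactly 0.3 is kept. Setting the threshold to `+inf` reproduces the
harsher mode that removes every term ever seen as a false positive;
threshold 0 disables the filter. Exclusion keys are stemmed-lowercased terms
(the same normalization as matching), so inflectional variants share
counts. MeSH mapping translates source concept ids through a supplied
table; spans whose concepts all lack a mapping are dropped by default
(`unmapped_policy="sentinel"` keeps them).

## Knowledge-graph features

The graph store holds multi-edges with a predicate, a directionality flag
(one-directional/causal vs two-directional/non-causal) and per-source
provenance counts. An edge's total provenance is the **sum** across sources
(the alternative, a per-source maximum, is a documented open choice; the sum
is used because record counts from different sources are disjoint evidence).

Paths between two concepts are direct (one edge, in either role — the
orientation of a causal edge is recorded but does not disqualify it) or
indirect (one intermediate x; each one-directional edge must be oriented
a → x or x → b). If any direct path exists, indirect paths are ignored. Per
pair the features are: path type (direct/indirect/none), confidence score,
number of paths, set of predicates, provenance count. Aggregation over
same-kind paths takes the maximum of scores and provenance counts and the
union of predicates; an indirect path's own provenance is the minimum over
its two edges. "Same length" is read as same kind, the literal reading of
the source semantics.

The provenance-based confidence formula of the original commercial graph
platform is unpublished, so the scorer is pluggable:
`log-provenance` (default, `sum over edges of log(1 + total provenance)`),
`raw-provenance`, and `constant-1`. The default preserves "score grows with
evidence, with diminishing returns" while being fully reproducible.

The knowledge-base baseline predicts a relation iff the pair is directly
connected by a predicate outside the configured treatment set (default
`{treats, prevents}`): therapeutic links are explicitly not
chemical-induced-disease evidence.

## Statistical features

Per pair and document: mention counts of the chemical and disease, their
product (possible pairs), ratios of each against the document totals,
minimal sentence distance (title = sentence 0) and minimal word distance
(tokens strictly between the closest mention boundaries; overlapping
mentions give 0 — "word distance" is token count, not characters), and
title flags (chemical in title, disease in title, both). Sentence
segmentation and token positions come from the dependency parses — a single
source of truth, no separate sentence splitter. MeSH identifiers enter as
nominal features, one-hot encoded against the training vocabulary; unseen
ids at test time map to an all-zero block.

## Linguistic features

Parses are an input artifact (CoNLL-U with `# doc_id = …` comments and
MISC-column character offsets); trees are validated (single root, acyclic)
on read. "Verb" means a Penn tag starting with `VB` (or UPOS `VERB` via
configuration). The governing verb of a token is the first verb on the head
chain starting at the token's *head* — a verb is never its own governing
verb. The relating word of a pair is the lowest common ancestor with
self-inclusive ancestor sets — if one token dominates the other, the
dominating token itself; it is undefined for cross-sentence pairs. These two
conventions together make the worked-example tree and the "chemical is the
relating word" identity feature jointly coherent. Multi-token mentions are
represented by their syntactic head (the mention token whose head lies
outside the mention). Negation of a token is the presence of a dependent
with a negation label (`neg`) or an adverbial-modifier dependent whose word
is in the lexicon `{not, no, never, without}`.

The first feature set describes one representative mention pair per
identifier pair, ranked by: same-sentence before cross-sentence; then pairs
with no other chemical–disease mention pair strictly *lower* in the tree
(operationalized as: no other pair's relating word is a proper descendant
of this pair's relating word); remaining ties by earliest document order.
With only cross-sentence candidates, the last chemical-before-disease pair
by document position is taken, else the first chemical and first disease
mentions. Features: the two governing verbs, the relating word and its
governing verb (as nominal word features), word order, lower-pair flag,
four negation flags, and three identity flags comparing token indices. The
paper-level phrase "whether the chemical is the same as the relating word"
is implemented literally (chemical head token vs relating word); comparing
the chemical's governing verb instead is possible behind the identity-flag
semantics but was not chosen.

The second set aggregates over *all* mention pairs of the document: for
each vocabulary word (every word observed as a governing verb or relating
word in the training pass), how often it occurs in either role. Each role
occurrence counts once, so a word serving as both governing verb and
relating word of one pair contributes twice.

## Classifier

One instance per document per unique chemical–disease identifier
combination; pairs may span the title/abstract border; the label is
positive iff the pair is in the document's gold relations. Feature kinds are
inferred from training values (string → nominal one-hot, boolean → binary,
numeric → min-max scaled by training bounds with test-time clipping to
[0, 1]; constant features scale to 0).

The SVM is C-support vector classification with an RBF kernel and class
weight 5:1 in favour of the positive (minority) class. Cost and gamma are
chosen by grid search — default grid `cost ∈ 2^-2..2^6`, `gamma ∈ 2^-6..2^2`
in powers of two — scored by pooled (micro) F over stratified k-fold
cross-validation (default 10 folds, capped at the minority class size) at
the fixed 0.5 decision boundary; ties keep the earliest grid point. The
refitted model's decision values are sigmoid-calibrated (Platt scaling via
cross-validated decision values, then a single refit on all data). The
decision threshold is subsequently tuned: out-of-fold calibrated
probabilities are swept over a 0.01-step grid and the threshold maximizing
micro F is kept, lowest threshold on ties; degenerate sets (fewer than four
instances in either class) fall back to 0.5 with a warning. Folds are
stratified by label; per-document grouping was considered and left to the
caller (documents contribute several instances, but on the synthetic data
label leakage across folds is controlled by the pair-level truth).

The sentence co-occurrence baseline predicts a pair iff some chemical and
disease mention of the pair share a sentence.

## Evaluation

Micro-averaged precision, recall and F over (document, chemical, disease)
triples for relations; for disease normalization either strict-span
matching (offsets equal and at least one shared concept id, with one-to-one
matching against gold) or per-document id-set comparison. Zero denominators
yield 0 and set a `degenerate` flag. Error listings (FP/FN) are
deterministically ordered with optional seeded sampling.

## Synthetic data generator

The generator emits six mutually consistent artifacts (corpus, dictionary,
concept→MeSH map, knowledge-graph edge list, CoNLL-U parses, ground-truth
table) from a seeded configuration. Documents are built from sentence
templates with hand-authored dependency trees — parses are authored, not
produced by a parser, keeping tests hermetic. Chemical mentions are included
as gold annotations (the chemical recognizer is an upstream system whose
output this pipeline consumes).

Whether a chemical causes a disease is decided **once per concept pair**
(probability `p_relation = 0.25`, chosen near the ~0.19 positive rate of
real CID corpora) the first time the pair is co-mentioned; every document
co-mentioning a related pair asserts the relation. In a document, a related
pair is realized in one sentence with `p_same_sentence = 0.7` (matching the
observation that roughly a quarter of true relations span sentence
boundaries) — using either an "induced" sentence or a neutral "was
associated with" sentence (`p_neutral_given_rel = 0.4`) — or in two separate
sentences (administration, then disease development). Unrelated pairs get a
negated, a therapeutic, or the same neutral sentence
(`p_neutral_given_unrel = 0.4`). The shared neutral template is the point of
the design: for those pairs the text is uninformative and only the planted
knowledge-graph edge separates the classes, so ablating the knowledge
features must reduce performance. Edges are planted once per pair: a
directed `causes` edge with `p_kg_edge_given_rel = 0.9` for related pairs
(`1.0` in the clean "KG-linked" study condition) and
`p_kg_edge_given_unrel = 0.05` for unrelated ones (`0.0` when clean), a
`treats` edge for unrelated pairs with `p_treat_edge = 0.3`, and an
indirect chemical→gene→disease chain for 10% of related pairs. Provenance
counts are uniform on 1..20.

What the generator does **not** emulate: natural English (templates only),
Medline vocabulary distributions, nested or overlapping mentions,
normalization ambiguity (mentions carry a single correct id), parser errors,
and annotation noise. Tests passing on this data therefore demonstrate that
the machinery is correct and that the classifier recovers plantable signal;
they say nothing about performance on real abstracts, where entity
recognition quality and terminology coverage dominate.

## Problem sizes and runtime choices

The end-to-end study uses a 300-document fixture split 200/100 with a 3×3
grid (`cost ∈ {1, 4, 16}`, `gamma ∈ {2^-4, 2^-2, 1}`); the full 9×9 default
grid changes the selected parameters only marginally on this data and the
coarse grid keeps the whole study in the tens of seconds. Oracle-equivalence
checks run 500 random cases per component. The brute-force oracles
(exhaustive key enumeration for matching, exhaustive length-≤2 chain
enumeration for paths, ancestor-chain scans for tree traversals, exhaustive
threshold sweeps) are implemented independently of the code paths they
check and live with the tests.

## Known limitations

- The confidence scorer is a stand-in family, not the original proprietary
  formula; rankings by score are comparable within a scorer only.
- The built-in stemmer is intentionally mild; heavily inflected or Greek or
  Latin medical variants will not always conflate.
- Representative-pair selection breaks exotic ties (identical offsets) by
  construction order; such mention sets do not occur in validated corpora.
- Relation evaluation is identifier-based: a correct prediction with a
  wrong-but-plausible MeSH id counts as both a false positive and a false
  negative, as in the source evaluation protocol.
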