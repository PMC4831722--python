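"""End-to-end relation extraction on a synthetic corpus.

Generates a seeded fixture world (corpus, knowledge graph, parses), trains
the class-weighted SVM on 2/3 of the documents, and evaluates on the rest,
alongside the sentence co-occurrence baseline.
"""

from religator import (
    FixtureConfig,
    RelationExtractor,
    cooccurrence_baseline,
    evaluate_cid,
    generate,
)

fx = generate(FixtureConfig(seed=8, n_docs=90))
train_corpus, test_corpus = fx.split(60)

extractor = RelationExtractor.fit(
    train_corpus,
    fx.parses,
    fx.graph,
    seed=0,
    cost_grid=(1.0, 4.0, 16.0),
    gamma_grid=(2.0**-4, 2.0**-2, 1.0),
)
print(
    f"selected cost={extractor.model.cost:g}, gamma={extractor.model.gamma:g}, "
    f"tuned threshold={extractor.model.threshold:.2f}"
)

result = extractor.evaluate(test_corpus, fx.parses, fx.graph)
print(f"SVM          P={result.precision:.3f} R={result.recall:.3f} F={result.f_score:.3f}")

cooc = evaluate_cid(test_corpus, cooccurrence_baseline(test_corpus, fx.parses))
print(f"co-occurrence P={cooc.precision:.3f} R={cooc.recall:.3f} F={cooc.f_score:.3f}")
# The SVM combines knowledge-graph, statistical and linguistic features and
# clearly beats sentence co-occurrence, whose recall is bounded by the share
# of relations expressed within a single sentence (~0.7 in this generator).
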