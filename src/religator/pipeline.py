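"""End-to-end orchestration: corpus -> NER -> features -> model -> evaluation.

The :class:`RelationExtractor` bundles everything prediction needs beyond the
corpus itself: the trained SVM with its feature space, the aggregate-word
vocabulary collected on the training pass, and the feature configuration.
:func:`run_pipeline` drives the artifact-to-artifact flow used by the CLI,
stamping outputs with the configuration hash and seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import pickle
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from . import classifier as clf
from .classifier import FeatureConfig, TrainedModel
from .corpus import Corpus, read_pubtator, write_pubtator
from .evaluation import EvalResult, evaluate_cid, write_report
from .kg import KnowledgeGraph, load_graph
from .linguistic import collect_vocabulary
from .ner import (
    NerConfig,
    build_index,
    default_stopwords,
    load_dictionary,
    load_exclusion_list,
    load_mesh_map,
    load_stopwords,
    recognize_diseases,
)
from .parses import SentenceParse, read_conllu

logger = logging.getLogger(__name__)


@dataclass
class RelationExtractor:
    """A trained relation-extraction model plus its feature resources."""

    model: TrainedModel
    vocabulary: list[str]
    feature_config: FeatureConfig

    @classmethod
    def fit(
        cls,
        corpus: Corpus,
        parses: Mapping[str, Sequence[SentenceParse]],
        graph: KnowledgeGraph | None,
        feature_config: FeatureConfig = FeatureConfig(),
        seed: int = 0,
        cost_grid: Sequence[float] = clf.DEFAULT_COST_GRID,
        gamma_grid: Sequence[float] = clf.DEFAULT_GAMMA_GRID,
        folds: int = 10,
        class_weight: float = 5.0,
        tune: bool = True,
    ) -> "RelationExtractor":
        vocabulary = (
            collect_vocabulary(
                [(doc, parses.get(doc.doc_id, ())) for doc in corpus],
                feature_config.verb_tagset,
            )
            if feature_config.include_linguistic
            else []
        )
        instances = clf.generate_instances(corpus, use_gold_labels=True)
        instances = clf.assemble_features(
            instances, corpus, parses, graph, vocabulary, feature_config
        )
        model = clf.train(
            instances,
            cost_grid=cost_grid,
            gamma_grid=gamma_grid,
            folds=folds,
            class_weight=class_weight,
            seed=seed,
        )
        if tune:
            clf.tune_threshold(model, instances, folds=folds)
        return cls(model=model, vocabulary=vocabulary, feature_config=feature_config)

    def predict(
        self,
        corpus: Corpus,
        parses: Mapping[str, Sequence[SentenceParse]],
        graph: KnowledgeGraph | None,
        threshold: float | None = None,
    ) -> dict[str, set[tuple[str, str]]]:
        instances = clf.generate_instances(corpus, use_gold_labels=False)
        instances = clf.assemble_features(
            instances, corpus, parses, graph, self.vocabulary, self.feature_config
        )
        return clf.predict(self.model, instances, threshold)

    def evaluate(
        self,
        corpus: Corpus,
        parses: Mapping[str, Sequence[SentenceParse]],
        graph: KnowledgeGraph | None,
        threshold: float | None = None,
    ) -> EvalResult:
        return evaluate_cid(corpus, self.predict(corpus, parses, graph, threshold))

    def save(self, path) -> None:
        with open(path, "wb") as handle:
            pickle.dump(self, handle)

    @classmethod
    def load(cls, path) -> "RelationExtractor":
        with open(path, "rb") as handle:
            extractor = pickle.load(handle)
        if not isinstance(extractor, cls):
            raise TypeError(f"{path} does not contain a RelationExtractor")
        return extractor


class PipelineConfigError(ValueError):
    """Raised when the run configuration is missing a required key."""


DEFAULT_STAGES = ("ner", "train", "predict", "evaluate")


def _config_hash(config: Mapping) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:12]


def _require(config: Mapping, key: str, stage: str) -> str:
    paths = config.get("paths", {})
    if key not in paths:
        raise PipelineConfigError(
            f"stage {stage!r} requires config key paths.{key}"
        )
    path = Path(paths[key])
    if not path.exists():
        raise FileNotFoundError(f"paths.{key}: {path} does not exist")
    return str(path)


def run_ner_stage(config: Mapping, corpus: Corpus) -> Corpus:
    """Replace disease mentions by recognizer output, document by document."""
    ner_cfg = config.get("ner", {})
    dictionary = load_dictionary(_require(config, "dictionary", "ner"))
    mesh_map = load_mesh_map(_require(config, "mesh_map", "ner"))
    stopwords = (
        load_stopwords(config["paths"]["stopwords"])
        if "stopwords" in config.get("paths", {})
        else default_stopwords()
    )
    exclusion = (
        load_exclusion_list(config["paths"]["exclusion"])
        if "exclusion" in config.get("paths", {})
        else {}
    )
    index = build_index(
        dictionary, stopwords, ner_cfg.get("normalizer", "builtin-suffix-stemmer")
    )
    ner_config = NerConfig(
        normalizer=ner_cfg.get("normalizer", "builtin-suffix-stemmer"),
        ratio_threshold=float(ner_cfg.get("ratio_threshold", 0.3)),
        unmapped_policy=ner_cfg.get("unmapped_policy", "drop"),
    )
    documents = [
        recognize_diseases(doc, index, exclusion, mesh_map, ner_config)
        for doc in corpus
    ]
    out = Corpus(documents=documents)
    out.validate()
    return out


def run_pipeline(
    config: Mapping,
    stages: Sequence[str] = DEFAULT_STAGES,
    out_dir=None,
) -> dict[str, object]:
    """Execute the selected stages in workflow order; artifacts on disk.

    Returns a dict with the produced objects ("corpus", "extractor",
    "predictions", "evaluation") and writes, under ``out_dir``, the NER
    corpus, model, predictions table, evaluation report and a ``run.json``
    stamp carrying the configuration hash, seed, and per-stage counts.
    """
    out = Path(out_dir or config.get("out_dir", "."))
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    stamp: dict[str, object] = {"config_hash": _config_hash(config), "seed": seed}
    results: dict[str, object] = {}

    corpus = read_pubtator(_require(config, "corpus", "load"))
    stamp["documents"] = len(corpus)
    results["corpus"] = corpus

    if "ner" in stages:
        corpus = run_ner_stage(config, corpus)
        write_pubtator(corpus, out / "ner_corpus.pubtator")
        stamp["ner_disease_mentions"] = sum(
            len(d.mentions_of_type("disease")) for d in corpus
        )
        results["corpus"] = corpus

    needs_model = {"train", "predict", "evaluate"} & set(stages)
    if needs_model:
        parses = read_conllu(_require(config, "parses", "features"))
        feat_cfg_raw = config.get("features", {})
        feature_config = FeatureConfig(
            include_knowledge=feat_cfg_raw.get("include_knowledge", True),
            include_statistical=feat_cfg_raw.get("include_statistical", True),
            include_linguistic=feat_cfg_raw.get("include_linguistic", True),
            scorer=feat_cfg_raw.get("scorer", "log-provenance"),
        )
        graph = None
        if feature_config.include_knowledge:
            graph = load_graph(_require(config, "kg", "features"))

        train_cfg = config.get("train", {})
        if "train" in stages:
            extractor = RelationExtractor.fit(
                corpus,
                parses,
                graph,
                feature_config,
                seed=seed,
                cost_grid=tuple(train_cfg.get("cost_grid", clf.DEFAULT_COST_GRID)),
                gamma_grid=tuple(train_cfg.get("gamma_grid", clf.DEFAULT_GAMMA_GRID)),
                folds=int(train_cfg.get("folds", 10)),
                class_weight=float(train_cfg.get("class_weight", 5.0)),
            )
            extractor.save(out / "model.pkl")
            stamp["threshold"] = extractor.model.threshold
            stamp["cost"] = extractor.model.cost
            stamp["gamma"] = extractor.model.gamma
        else:
            extractor = RelationExtractor.load(_require(config, "model", "predict"))
        results["extractor"] = extractor

        if "predict" in stages or "evaluate" in stages:
            predictions = extractor.predict(corpus, parses, graph)
            results["predictions"] = predictions
            with open(out / "predictions.tsv", "w", encoding="utf-8") as handle:
                for doc_id in sorted(predictions):
                    for chem, dis in sorted(predictions[doc_id]):
                        handle.write(f"{doc_id}\t{chem}\t{dis}\n")
            stamp["predicted_relations"] = sum(len(v) for v in predictions.values())

        if "evaluate" in stages:
            result = evaluate_cid(corpus, results["predictions"])
            write_report(result, out / "report.tsv")
            stamp["f_score"] = result.f_score
            results["evaluation"] = result

    with open(out / "run.json", "w", encoding="utf-8") as handle:
        json.dump(stamp, handle, indent=2, sort_keys=True)
        handle.write("\n")
    return results
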