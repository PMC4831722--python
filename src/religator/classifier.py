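"""Pair-instance generation, feature assembly, and the relation classifier.

Every (unique chemical id x unique disease id) combination in a document is
one classification instance; the label is positive iff the pair is among the
document's gold relations.  Three feature groups — prior knowledge from the
graph store, document statistics, and dependency-tree linguistics — feed a
class-weighted RBF-kernel SVM.  Numeric features are min-max scaled to [0,1]
by training bounds (test values clipped); nominal features are one-hot
encoded against the training vocabulary with unseen values mapping to an
all-zero block.  The SVM uses a 5:1 cost ratio favouring the positive
(minority) class; cost and gamma are chosen by grid search under stratified
10-fold cross-validation at a fixed 0.5 threshold, after which the decision
threshold itself is tuned on out-of-fold probabilities to maximize the
micro-averaged F-score.
"""

from __future__ import annotations

import logging
import pickle
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from sklearn.calibration import CalibratedClassifierCV
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .corpus import CHEMICAL, DISEASE, Corpus
from .evaluation import EvalResult
from .kg import KnowledgeGraph, path_features
from .linguistic import aggregate_linguistic_features, pair_linguistic_features
from .parses import DEFAULT_NEGATION_LEXICON, SentenceParse
from .statistical import _sentence_index, stat_features

logger = logging.getLogger(__name__)

POSITIVE = "positive"
NEGATIVE = "negative"
UNKNOWN = "unknown"

FeatureValue = float | int | bool | str | None


@dataclass
class PairInstance:
    doc_id: str
    chem_id: str
    dis_id: str
    features: dict[str, FeatureValue] = field(default_factory=dict)
    label: str = UNKNOWN


class TrainingError(RuntimeError):
    """Raised when training preconditions are not met."""


def generate_instances(corpus: Corpus, use_gold_labels: bool = True) -> list[PairInstance]:
    """One instance per document per unique chemical-disease id combination.

    Composite mention ids are expanded; sentinel ids are skipped.  Pairs may
    cross the title-abstract border (mention positions play no role here).
    """
    instances: list[PairInstance] = []
    for doc in corpus:
        chem_ids = sorted(doc.concept_ids_of_type(CHEMICAL))
        dis_ids = sorted(doc.concept_ids_of_type(DISEASE))
        gold = {(r.chemical_id, r.disease_id) for r in doc.relations}
        for chem in chem_ids:
            for dis in dis_ids:
                label = UNKNOWN
                if use_gold_labels:
                    label = POSITIVE if (chem, dis) in gold else NEGATIVE
                instances.append(
                    PairInstance(doc_id=doc.doc_id, chem_id=chem, dis_id=dis, label=label)
                )
    return instances


# ---------------------------------------------------------------------------
# Feature assembly


@dataclass(frozen=True)
class FeatureConfig:
    include_knowledge: bool = True
    include_statistical: bool = True
    include_linguistic: bool = True
    scorer: str = "log-provenance"
    negation_lexicon: frozenset[str] = DEFAULT_NEGATION_LEXICON
    verb_tagset: str = "penn"


def assemble_features(
    instances: Sequence[PairInstance],
    corpus: Corpus,
    parses: Mapping[str, Sequence[SentenceParse]],
    graph: KnowledgeGraph | None,
    vocabulary: Sequence[str] = (),
    config: FeatureConfig = FeatureConfig(),
) -> list[PairInstance]:
    """Populate the feature map of each instance (returns new instances).

    ``vocabulary`` is the training-time list of governing-verb/relating-word
    forms for the aggregate linguistic features.
    """
    docs = {doc.doc_id: doc for doc in corpus}
    agg_cache: dict[str, dict[str, int]] = {}
    out: list[PairInstance] = []
    for inst in instances:
        doc = docs[inst.doc_id]
        doc_parses = parses.get(inst.doc_id, ())
        feats: dict[str, FeatureValue] = {}

        if config.include_knowledge:
            if graph is None:
                raise ValueError("knowledge features requested but no graph given")
            pf = path_features(graph, inst.chem_id, inst.dis_id, config.scorer)
            feats["kg_path_type"] = pf.path_type
            feats["kg_score"] = pf.score
            feats["kg_n_paths"] = pf.n_paths
            feats["kg_provenance"] = pf.provenance_count
            for predicate in pf.predicates:
                feats[f"kg_pred={predicate}"] = True

        if config.include_statistical:
            sf = stat_features(doc, doc_parses, inst.chem_id, inst.dis_id)
            feats.update(
                n_chem_mentions=sf.n_chem_mentions,
                n_dis_mentions=sf.n_dis_mentions,
                n_pairs=sf.n_pairs,
                ratio_chem=sf.ratio_chem,
                ratio_dis=sf.ratio_dis,
                ratio_pairs=sf.ratio_pairs,
                min_sentence_dist=sf.min_sentence_dist,
                min_word_dist=sf.min_word_dist,
                chem_in_title=sf.chem_in_title,
                dis_in_title=sf.dis_in_title,
                both_in_title=sf.both_in_title,
                chem_id=sf.chem_id,
                dis_id=sf.dis_id,
            )

        if config.include_linguistic:
            lf = pair_linguistic_features(
                doc,
                doc_parses,
                inst.chem_id,
                inst.dis_id,
                config.negation_lexicon,
                config.verb_tagset,
            )
            feats.update(
                gov_verb_chem=lf.gov_verb_chem,
                gov_verb_dis=lf.gov_verb_dis,
                relating_word=lf.relating_word,
                gov_verb_relating=lf.gov_verb_relating,
                chem_before_dis=lf.chem_before_dis,
                other_pair_lower=lf.other_pair_lower,
                neg_relating=lf.neg_relating,
                neg_gov_chem=lf.neg_gov_chem,
                neg_gov_dis=lf.neg_gov_dis,
                neg_gov_relating=lf.neg_gov_relating,
                chem_is_relating=lf.chem_is_relating,
                govdis_is_relating=lf.govdis_is_relating,
                both_gov_are_relating=lf.both_gov_are_relating,
            )
            if inst.doc_id not in agg_cache:
                agg_cache[inst.doc_id] = aggregate_linguistic_features(
                    doc, doc_parses, vocabulary, config.verb_tagset
                )
            for word, count in agg_cache[inst.doc_id].items():
                feats[f"ling_agg={word}"] = count

        out.append(replace(inst, features=feats))
    return out


# ---------------------------------------------------------------------------
# Feature space


class FeatureSpaceError(RuntimeError):
    pass


@dataclass
class FeatureSpace:
    """Fixed vectorization layout fitted on training instances."""

    numeric: list[str] = field(default_factory=list)
    bounds: dict[str, tuple[float, float]] = field(default_factory=dict)
    boolean: list[str] = field(default_factory=list)
    nominal: dict[str, list[str]] = field(default_factory=dict)
    fitted: bool = False

    @property
    def dimension(self) -> int:
        return (
            len(self.numeric)
            + len(self.boolean)
            + sum(len(v) for v in self.nominal.values())
        )

    def feature_names(self) -> list[str]:
        names = list(self.numeric) + list(self.boolean)
        for name, vocab in sorted(self.nominal.items()):
            names.extend(f"{name}={value}" for value in vocab)
        return names


def fit_feature_space(instances: Sequence[PairInstance]) -> FeatureSpace:
    """Infer feature kinds and training bounds/vocabularies.

    A feature with any string value is nominal; all-boolean features are
    binary; everything else numeric with min-max bounds from training.
    """
    values: dict[str, list[FeatureValue]] = {}
    for inst in instances:
        for name, value in inst.features.items():
            values.setdefault(name, []).append(value)
    space = FeatureSpace()
    for name in sorted(values):
        vals = [v for v in values[name] if v is not None]
        if any(isinstance(v, str) for v in vals):
            space.nominal[name] = sorted({str(v) for v in vals})
        elif vals and all(isinstance(v, bool) for v in vals):
            space.boolean.append(name)
        else:
            numbers = [float(v) for v in vals] or [0.0]
            space.numeric.append(name)
            space.bounds[name] = (min(numbers), max(numbers))
    space.fitted = True
    return space


def vectorize(instance: PairInstance, space: FeatureSpace) -> np.ndarray:
    """Map one instance to the fixed-dimension numeric vector.

    Numeric features are scaled by training bounds and clipped to [0,1]
    (constant features scale to 0); booleans map to {0,1}; nominals one-hot
    with unseen or absent values as an all-zero block.
    """
    if not space.fitted:
        raise FeatureSpaceError("feature space must be fitted before vectorize")
    vec = np.zeros(space.dimension, dtype=float)
    pos = 0
    for name in space.numeric:
        value = instance.features.get(name)
        lo, hi = space.bounds[name]
        if value is not None and hi > lo:
            vec[pos] = min(max((float(value) - lo) / (hi - lo), 0.0), 1.0)
        pos += 1
    for name in space.boolean:
        vec[pos] = 1.0 if instance.features.get(name) else 0.0
        pos += 1
    for name, vocab in sorted(space.nominal.items()):
        value = instance.features.get(name)
        if value is not None:
            try:
                vec[pos + vocab.index(str(value))] = 1.0
            except ValueError:
                pass  # unseen nominal value: all-zero block
        pos += len(vocab)
    return vec


def vectorize_all(
    instances: Sequence[PairInstance], space: FeatureSpace
) -> np.ndarray:
    return np.vstack([vectorize(inst, space) for inst in instances])


# ---------------------------------------------------------------------------
# Training, threshold tuning, prediction


DEFAULT_COST_GRID = tuple(2.0**k for k in range(-2, 7))
DEFAULT_GAMMA_GRID = tuple(2.0**k for k in range(-6, 3))


@dataclass
class TrainedModel:
    space: FeatureSpace
    svm: CalibratedClassifierCV
    cost: float
    gamma: float
    class_weight: float
    threshold: float = 0.5
    seed: int = 0
    cv_f_score: float = 0.0
    version: str = "1"

    def probabilities(self, instances: Sequence[PairInstance]) -> np.ndarray:
        X = vectorize_all(instances, self.space)
        positive_col = list(self.svm.classes_).index(1)
        return self.svm.predict_proba(X)[:, positive_col]


def _labels(instances: Sequence[PairInstance]) -> np.ndarray:
    unknown = [i for i in instances if i.label == UNKNOWN]
    if unknown:
        raise TrainingError(f"{len(unknown)} instance(s) carry no label")
    return np.array([1 if i.label == POSITIVE else 0 for i in instances])


def _make_svc(cost: float, gamma: float, class_weight: float, seed: int) -> SVC:
    return SVC(
        C=cost,
        gamma=gamma,
        kernel="rbf",
        class_weight={1: class_weight},
        random_state=seed,
    )


def _fit_calibrated(
    X: np.ndarray,
    y: np.ndarray,
    cost: float,
    gamma: float,
    class_weight: float,
    seed: int,
) -> CalibratedClassifierCV:
    """SVM with sigmoid (Platt) calibration of its decision values.

    The calibration map is fitted on cross-validated decision values, then
    the SVM itself is refitted on all data (``ensemble=False``); the inner
    fold count adapts to the minority-class size.
    """
    cv = max(2, min(5, int(np.bincount(y).min())))
    model = CalibratedClassifierCV(
        _make_svc(cost, gamma, class_weight, seed),
        method="sigmoid",
        cv=cv,
        ensemble=False,
    )
    model.fit(X, y)
    return model


def _cv_micro_f(
    X: np.ndarray,
    y: np.ndarray,
    cost: float,
    gamma: float,
    class_weight: float,
    folds: int,
    seed: int,
) -> float:
    """Pooled (micro) F over stratified CV folds at the fixed 0.5 threshold."""
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    tp = fp = fn = 0
    for train_idx, test_idx in skf.split(X, y):
        svc = _make_svc(cost, gamma, class_weight, seed)
        svc.fit(X[train_idx], y[train_idx])
        pred = svc.predict(X[test_idx])
        truth = y[test_idx]
        tp += int(np.sum((pred == 1) & (truth == 1)))
        fp += int(np.sum((pred == 1) & (truth == 0)))
        fn += int(np.sum((pred == 0) & (truth == 1)))
    return EvalResult.from_counts(tp, fp, fn).f_score


def train(
    instances: Sequence[PairInstance],
    space: FeatureSpace | None = None,
    cost_grid: Sequence[float] = DEFAULT_COST_GRID,
    gamma_grid: Sequence[float] = DEFAULT_GAMMA_GRID,
    folds: int = 10,
    class_weight: float = 5.0,
    seed: int = 0,
) -> TrainedModel:
    """Grid-search the SVM's cost and gamma, then refit on all data.

    Each (cost, gamma) is scored by pooled F over stratified k-fold CV at the
    fixed default threshold; ties keep the first grid point in iteration
    order.  The refit model emits sigmoid-calibrated positive-class
    probabilities.
    """
    if space is None:
        space = fit_feature_space(instances)
    X = vectorize_all(instances, space)
    y = _labels(instances)
    n_pos, n_neg = int(y.sum()), int(len(y) - y.sum())
    if n_pos == 0 or n_neg == 0:
        raise TrainingError("training requires both classes to be present")
    folds_eff = max(2, min(folds, n_pos, n_neg))

    best: tuple[float, float, float] | None = None  # (f, cost, gamma)
    for cost in cost_grid:
        for gamma in gamma_grid:
            f = _cv_micro_f(X, y, cost, gamma, class_weight, folds_eff, seed)
            if best is None or f > best[0]:
                best = (f, cost, gamma)
    assert best is not None
    cv_f, cost, gamma = best
    svc = _fit_calibrated(X, y, cost, gamma, class_weight, seed)
    logger.info(
        "selected cost=%g gamma=%g (CV F=%.3f, %d folds)", cost, gamma, cv_f, folds_eff
    )
    return TrainedModel(
        space=space,
        svm=svc,
        cost=cost,
        gamma=gamma,
        class_weight=class_weight,
        seed=seed,
        cv_f_score=cv_f,
    )


def threshold_sweep(
    probabilities: np.ndarray, y: np.ndarray, step: float = 0.01
) -> tuple[float, float]:
    """Best threshold on a probability/label set: max micro F, ties lowest."""
    best_thr, best_f = 0.0, -1.0
    for k in range(int(round(1 / step)) + 1):
        thr = round(k * step, 10)
        pred = probabilities >= thr
        tp = int(np.sum(pred & (y == 1)))
        fp = int(np.sum(pred & (y == 0)))
        fn = int(np.sum(~pred & (y == 1)))
        f = EvalResult.from_counts(tp, fp, fn).f_score
        if f > best_f:
            best_thr, best_f = thr, f
    return best_thr, best_f


def tune_threshold(
    model: TrainedModel,
    instances: Sequence[PairInstance],
    folds: int = 10,
    step: float = 0.01,
) -> float:
    """Decision threshold maximizing micro F on out-of-fold probabilities.

    The model's (cost, gamma) are held fixed; probabilities come from
    stratified CV refits so the sweep never scores in-sample outputs.  Sets
    and returns the threshold; degenerate inputs fall back to 0.5.
    """
    X = vectorize_all(instances, model.space)
    y = _labels(instances)
    n_pos, n_neg = int(y.sum()), int(len(y) - y.sum())
    if min(n_pos, n_neg) < 4:
        logger.warning("degenerate instance set; keeping threshold 0.5")
        model.threshold = 0.5
        return 0.5
    folds_eff = max(2, min(folds, n_pos, n_neg))
    skf = StratifiedKFold(n_splits=folds_eff, shuffle=True, random_state=model.seed)
    probs = np.zeros(len(y))
    for train_idx, test_idx in skf.split(X, y):
        svc = _fit_calibrated(
            X[train_idx],
            y[train_idx],
            model.cost,
            model.gamma,
            model.class_weight,
            model.seed,
        )
        positive_col = list(svc.classes_).index(1)
        probs[test_idx] = svc.predict_proba(X[test_idx])[:, positive_col]
    threshold, _ = threshold_sweep(probs, y, step)
    model.threshold = threshold
    return threshold


def predict(
    model: TrainedModel,
    instances: Sequence[PairInstance],
    threshold: float | None = None,
) -> dict[str, set[tuple[str, str]]]:
    """Predicted relation set per document: probability >= threshold."""
    thr = model.threshold if threshold is None else threshold
    probs = model.probabilities(instances)
    predicted: dict[str, set[tuple[str, str]]] = {}
    for inst, p in zip(instances, probs):
        if p >= thr:
            predicted.setdefault(inst.doc_id, set()).add((inst.chem_id, inst.dis_id))
    return predicted


def save_model(model: TrainedModel, path) -> None:
    """Serialize the model with a metadata header."""
    payload = {
        "metadata": {
            "version": model.version,
            "cost": model.cost,
            "gamma": model.gamma,
            "class_weight": model.class_weight,
            "threshold": model.threshold,
            "seed": model.seed,
            "cv_f_score": model.cv_f_score,
            "dimension": model.space.dimension,
        },
        "model": model,
    }
    with open(path, "wb") as handle:
        pickle.dump(payload, handle)


def load_model(path) -> TrainedModel:
    with open(path, "rb") as handle:
        payload = pickle.load(handle)
    return payload["model"]


# ---------------------------------------------------------------------------
# Sentence co-occurrence baseline


def cooccurrence_baseline(
    corpus: Corpus, parses: Mapping[str, Sequence[SentenceParse]]
) -> dict[str, set[tuple[str, str]]]:
    """Predict a relation iff some chemical and disease mention of the pair
    share a sentence."""
    predicted: dict[str, set[tuple[str, str]]] = {}
    for doc in corpus:
        doc_parses = parses.get(doc.doc_id, ())
        pairs: set[tuple[str, str]] = set()
        chem_sents = [
            (m, _sentence_index(doc_parses, m)) for m in doc.mentions_of_type(CHEMICAL)
        ]
        dis_sents = [
            (m, _sentence_index(doc_parses, m)) for m in doc.mentions_of_type(DISEASE)
        ]
        for cm, cs in chem_sents:
            if cs is None:
                continue
            for dm, ds in dis_sents:
                if ds != cs:
                    continue
                for chem in cm.concept_ids:
                    for dis in dm.concept_ids:
                        if chem != "unmapped" and dis != "unmapped":
                            pairs.add((chem, dis))
        if pairs:
            predicted[doc.doc_id] = pairs
    return predicted
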