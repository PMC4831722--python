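"""Micro-averaged precision/recall/F for entity normalization and relations.

True/false positives and false negatives are pooled over all documents before
computing precision, recall and F-score.  Zero denominators yield 0 and set a
flag on the result.
"""

from __future__ import annotations

import logging
import random
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .corpus import DISEASE, UNMAPPED, Corpus, Document, EntityMention

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EvalResult:
    tp: int
    fp: int
    fn: int
    precision: float
    recall: float
    f_score: float
    degenerate: bool = False  # a zero denominator was hit

    @classmethod
    def from_counts(cls, tp: int, fp: int, fn: int) -> "EvalResult":
        degenerate = False
        if tp + fp:
            precision = tp / (tp + fp)
        else:
            precision, degenerate = 0.0, True
        if tp + fn:
            recall = tp / (tp + fn)
        else:
            recall, degenerate = 0.0, True
        if precision + recall:
            f_score = 2 * precision * recall / (precision + recall)
        else:
            f_score = 0.0
        return cls(tp, fp, fn, precision, recall, f_score, degenerate)


def _gold_relation_triples(corpus: Corpus) -> set[tuple[str, str, str]]:
    return {
        (doc.doc_id, rel.chemical_id, rel.disease_id)
        for doc in corpus
        for rel in doc.relations
    }


def evaluate_cid(
    gold: Corpus, predicted: Mapping[str, Iterable[tuple[str, str]]]
) -> EvalResult:
    """Document-level relation evaluation over (doc, chemical, disease) triples."""
    known_docs = {doc.doc_id for doc in gold}
    pred_triples: set[tuple[str, str, str]] = set()
    for doc_id, pairs in predicted.items():
        if doc_id not in known_docs:
            logger.warning(
                "predictions for unknown document %s counted as false positives",
                doc_id,
            )
        for chem, dis in pairs:
            pred_triples.add((doc_id, chem, dis))
    gold_triples = _gold_relation_triples(gold)
    tp = len(pred_triples & gold_triples)
    fp = len(pred_triples - gold_triples)
    fn = len(gold_triples - pred_triples)
    return EvalResult.from_counts(tp, fp, fn)


STRICT_SPAN = "strict_span"
ID_LEVEL = "id_level"


def _expand_ids(mention: EntityMention) -> set[str]:
    return {c for c in mention.concept_ids if c != UNMAPPED}


def evaluate_dner(
    gold: Corpus,
    predicted: Mapping[str, Sequence[EntityMention]],
    mode: str = STRICT_SPAN,
) -> EvalResult:
    """Disease recognition/normalization evaluation.

    ``strict_span``: a predicted mention is a true positive iff a gold
    disease mention has the same offsets and shares at least one concept id.
    ``id_level``: per-document sets of disease ids are compared.
    """
    tp = fp = fn = 0
    for doc in gold:
        gold_mentions = doc.mentions_of_type(DISEASE)
        preds = list(predicted.get(doc.doc_id, ()))
        if mode == STRICT_SPAN:
            gold_keys = [
                ((m.start, m.end), _expand_ids(m)) for m in gold_mentions
            ]
            matched = [False] * len(gold_keys)
            for p in preds:
                hit = False
                for i, ((start, end), ids) in enumerate(gold_keys):
                    if (
                        not matched[i]
                        and (p.start, p.end) == (start, end)
                        and _expand_ids(p) & ids
                    ):
                        matched[i] = True
                        hit = True
                        break
                if hit:
                    tp += 1
                else:
                    fp += 1
            fn += matched.count(False)
        elif mode == ID_LEVEL:
            gold_ids = set().union(*(_expand_ids(m) for m in gold_mentions), set())
            pred_ids = set().union(*(_expand_ids(m) for m in preds), set())
            tp += len(gold_ids & pred_ids)
            fp += len(pred_ids - gold_ids)
            fn += len(gold_ids - pred_ids)
        else:
            raise ValueError(f"unknown mode {mode!r}")
    return EvalResult.from_counts(tp, fp, fn)


def error_listing(
    gold: Corpus,
    predicted: Mapping[str, Iterable[tuple[str, str]]],
    sample_size: int | None = None,
    seed: int = 0,
) -> list[tuple[str, tuple[str, str], str]]:
    """False-positive / false-negative relation listing for error analysis.

    Deterministically ordered by document id then pair; with ``sample_size``
    a seeded random sample is drawn (the full population, with a warning,
    when the sample size exceeds it).
    """
    gold_triples = _gold_relation_triples(gold)
    pred_triples = {
        (doc_id, chem, dis)
        for doc_id, pairs in predicted.items()
        for chem, dis in pairs
    }
    listing = [
        (doc_id, (chem, dis), "FP")
        for doc_id, chem, dis in sorted(pred_triples - gold_triples)
    ] + [
        (doc_id, (chem, dis), "FN")
        for doc_id, chem, dis in sorted(gold_triples - pred_triples)
    ]
    listing.sort()
    if sample_size is not None:
        if sample_size >= len(listing):
            if sample_size > len(listing):
                logger.warning(
                    "sample size %d exceeds population %d; returning all",
                    sample_size,
                    len(listing),
                )
            return listing
        rng = random.Random(seed)
        listing = sorted(rng.sample(listing, sample_size))
    return listing


def write_report(result: EvalResult, path) -> None:
    """Tab-separated evaluation report."""
    with open(path, "w", encoding="utf-8") as handle:
        handle.write("metric\tvalue\n")
        for name in ("tp", "fp", "fn"):
            handle.write(f"{name}\t{getattr(result, name)}\n")
        for name in ("precision", "recall", "f_score"):
            handle.write(f"{name}\t{getattr(result, name):.4f}\n")
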