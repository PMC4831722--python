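"""Document-level statistical features for a chemical-disease identifier pair.

Counts and ratios of mention frequencies, minimal sentence and word distance
between the pair's mentions, and title co-occurrence flags.  Sentence
segmentation and token positions come from the dependency parses (single
source of truth); the title is sentence 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .corpus import CHEMICAL, DISEASE, Document, EntityMention
from .parses import SentenceParse


@dataclass(frozen=True)
class PairStatFeatures:
    n_chem_mentions: int
    n_dis_mentions: int
    n_pairs: int
    ratio_chem: float
    ratio_dis: float
    ratio_pairs: float
    min_sentence_dist: int
    min_word_dist: int
    chem_in_title: bool
    dis_in_title: bool
    both_in_title: bool
    chem_id: str
    dis_id: str


def _sentence_index(
    parses: Sequence[SentenceParse], mention: EntityMention
) -> int | None:
    for parse in parses:
        if not parse.tokens:
            continue
        if parse.char_start < mention.end and mention.start < parse.char_end:
            return parse.sentence_index
    return None


def _word_distance(
    tokens: Sequence[tuple[int, int]], a: EntityMention, b: EntityMention
) -> int:
    """Tokens strictly between the two mention spans; overlap counts as 0."""
    lo, hi = (a, b) if a.start <= b.start else (b, a)
    if hi.start < lo.end:  # overlapping mentions
        return 0
    return sum(1 for start, end in tokens if start >= lo.end and end <= hi.start)


def stat_features(
    document: Document,
    parses: Sequence[SentenceParse],
    chem_id: str,
    dis_id: str,
) -> PairStatFeatures:
    chem_all = document.mentions_of_type(CHEMICAL)
    dis_all = document.mentions_of_type(DISEASE)
    chems = [m for m in chem_all if chem_id in m.concept_ids]
    diss = [m for m in dis_all if dis_id in m.concept_ids]
    if not chems or not diss:
        raise ValueError(
            f"doc {document.doc_id}: no mention of {chem_id!r} or {dis_id!r}"
        )

    n_chem, n_dis = len(chems), len(diss)
    total_pairs = len(chem_all) * len(dis_all)

    all_tokens = [
        (t.char_start, t.char_end)
        for parse in parses
        for t in parse.tokens
        if t.char_start >= 0
    ]
    sent_of = {id(m): _sentence_index(parses, m) for m in chems + diss}

    sentence_dists = [
        abs(sent_of[id(cm)] - sent_of[id(dm)])
        for cm in chems
        for dm in diss
        if sent_of[id(cm)] is not None and sent_of[id(dm)] is not None
    ]
    word_dists = [_word_distance(all_tokens, cm, dm) for cm in chems for dm in diss]

    title_end = len(document.title)
    chem_in_title = any(m.start < title_end for m in chems)
    dis_in_title = any(m.start < title_end for m in diss)

    return PairStatFeatures(
        n_chem_mentions=n_chem,
        n_dis_mentions=n_dis,
        n_pairs=n_chem * n_dis,
        ratio_chem=n_chem / len(chem_all),
        ratio_dis=n_dis / len(dis_all),
        ratio_pairs=(n_chem * n_dis) / total_pairs,
        min_sentence_dist=min(sentence_dists, default=0),
        min_word_dist=min(word_dists, default=0),
        chem_in_title=chem_in_title,
        dis_in_title=dis_in_title,
        both_in_title=chem_in_title and dis_in_title,
        chem_id=chem_id,
        dis_id=dis_id,
    )
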