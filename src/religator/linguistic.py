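"""Linguistic features for chemical-disease pairs.

Two feature sets are derived from the dependency parses of a document.  The
first describes one *representative* mention pair per (chemical id, disease
id): the governing verbs of the two mentions, the relating word and its
governing verb, word-order and tree-topology flags, negation flags, and
identity flags comparing tokens.  The second aggregates, over *all* mention
pairs in the document, how often each vocabulary word serves as a governing
verb or relating word.

A multi-token mention is represented by its syntactic head: the mention token
whose head lies outside the mention.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .corpus import CHEMICAL, DISEASE, Document, EntityMention
from .parses import (
    DEFAULT_NEGATION_LEXICON,
    SentenceParse,
    governing_verb,
    is_negated,
    relating_word,
)


@dataclass(frozen=True)
class LocatedMention:
    mention: EntityMention
    sentence_index: int
    head_token: int  # 1-based index within the sentence


def locate_mention(
    parses: Sequence[SentenceParse], mention: EntityMention
) -> LocatedMention | None:
    """Map a mention to its sentence and syntactic head token.

    A token belongs to the mention when its character span overlaps the
    mention span.  The head token is the first mention token whose head lies
    outside the mention (the root counts as outside); ``None`` when no parsed
    token overlaps the mention.
    """
    for parse in parses:
        inside = [
            t
            for t in parse.tokens
            if t.char_start >= 0
            and t.char_start < mention.end
            and mention.start < t.char_end
        ]
        if not inside:
            continue
        indices = {t.index for t in inside}
        head = next((t for t in inside if t.head not in indices), inside[-1])
        return LocatedMention(
            mention=mention, sentence_index=parse.sentence_index, head_token=head.index
        )
    return None


def _mentions_with_id(
    document: Document, entity_type: str, concept_id: str
) -> list[EntityMention]:
    return [
        m
        for m in document.mentions_of_type(entity_type)
        if concept_id in m.concept_ids
    ]


def _strictly_lower(
    parse: SentenceParse, candidate_rw: int, other_rw: int | None
) -> bool:
    return (
        other_rw is not None
        and other_rw != candidate_rw
        and candidate_rw in parse.ancestors(other_rw)
    )


def _has_lower_pair(
    parse: SentenceParse,
    rw: int,
    chem_here: Sequence[LocatedMention],
    dis_here: Sequence[LocatedMention],
    this_pair: tuple[LocatedMention, LocatedMention],
) -> bool:
    """Is some other chemical-disease mention pair lower in this tree?

    'Lower' means the other pair's relating word is a strict descendant of
    this pair's relating word.
    """
    cm0, dm0 = this_pair
    for cm in chem_here:
        for dm in dis_here:
            if (
                cm.mention == cm0.mention
                and dm.mention == dm0.mention
            ):
                continue
            other_rw = relating_word(parse, cm.head_token, dm.head_token)
            if _strictly_lower(parse, rw, other_rw):
                return True
    return False


def select_representative_pair(
    document: Document,
    parses: Sequence[SentenceParse],
    chem_id: str,
    dis_id: str,
) -> tuple[EntityMention, EntityMention]:
    """Choose the mention pair the first linguistic feature set describes.

    Ranking: (1) same-sentence pairs precede cross-sentence pairs; (2) among
    same-sentence pairs, those with no other chemical-disease mention pair
    strictly lower in the parse tree precede the rest; remaining ties break
    by earliest document order of the chemical, then the disease.  With only
    cross-sentence pairs: the last pair (by document position) with the
    chemical before the disease; if none, the first chemical and the first
    disease mentions.
    """
    chems = sorted(
        _mentions_with_id(document, CHEMICAL, chem_id), key=lambda m: m.start
    )
    diss = sorted(
        _mentions_with_id(document, DISEASE, dis_id), key=lambda m: m.start
    )
    if not chems or not diss:
        raise ValueError(
            f"doc {document.doc_id}: no mention of {chem_id!r} or {dis_id!r}"
        )

    located_chem = {id(m): locate_mention(parses, m) for m in chems}
    located_dis = {id(m): locate_mention(parses, m) for m in diss}

    # All located chemical/disease mentions per sentence (any concept id),
    # needed for the "no other pair lower in the tree" test.
    all_chem_located = [
        lm
        for m in document.mentions_of_type(CHEMICAL)
        if (lm := locate_mention(parses, m)) is not None
    ]
    all_dis_located = [
        lm
        for m in document.mentions_of_type(DISEASE)
        if (lm := locate_mention(parses, m)) is not None
    ]

    same_sentence: list[tuple[bool, int, int, EntityMention, EntityMention]] = []
    for cm in chems:
        lc = located_chem[id(cm)]
        if lc is None:
            continue
        for dm in diss:
            ld = located_dis[id(dm)]
            if ld is None or ld.sentence_index != lc.sentence_index:
                continue
            parse = parses[lc.sentence_index]
            rw = relating_word(parse, lc.head_token, ld.head_token)
            lower = rw is not None and _has_lower_pair(
                parse,
                rw,
                [x for x in all_chem_located if x.sentence_index == lc.sentence_index],
                [x for x in all_dis_located if x.sentence_index == lc.sentence_index],
                (lc, ld),
            )
            same_sentence.append((lower, cm.start, dm.start, cm, dm))
    if same_sentence:
        _, _, _, cm, dm = min(same_sentence, key=lambda t: (t[0], t[1], t[2]))
        return cm, dm

    ordered = [
        (cm.start, dm.start, cm, dm)
        for cm in chems
        for dm in diss
        if cm.start < dm.start
    ]
    if ordered:
        _, _, cm, dm = max(ordered, key=lambda t: (t[0], t[1]))
        return cm, dm
    return chems[0], diss[0]


@dataclass(frozen=True)
class PairLinguisticFeatures:
    gov_verb_chem: str | None
    gov_verb_dis: str | None
    relating_word: str | None
    gov_verb_relating: str | None
    chem_before_dis: bool
    other_pair_lower: bool
    neg_relating: bool
    neg_gov_chem: bool
    neg_gov_dis: bool
    neg_gov_relating: bool
    chem_is_relating: bool
    govdis_is_relating: bool
    both_gov_are_relating: bool


def pair_linguistic_features(
    document: Document,
    parses: Sequence[SentenceParse],
    chem_id: str,
    dis_id: str,
    negation_lexicon: frozenset[str] = DEFAULT_NEGATION_LEXICON,
    verb_tagset: str = "penn",
) -> PairLinguisticFeatures:
    """First linguistic feature set, on the representative mention pair.

    For a cross-sentence pair the governing verbs come from the two different
    sentence trees and the relating word, its governing verb, and their
    negation flags are undefined/false.  Identity flags compare token indices
    within the shared sentence.
    """
    cm, dm = select_representative_pair(document, parses, chem_id, dis_id)
    lc = locate_mention(parses, cm)
    ld = locate_mention(parses, dm)

    gov_chem_word = gov_dis_word = None
    neg_gov_chem = neg_gov_dis = False
    gov_chem_idx = gov_dis_idx = None
    if lc is not None:
        parse_c = parses[lc.sentence_index]
        gov_chem_idx = governing_verb(parse_c, lc.head_token, verb_tagset)
        if gov_chem_idx is not None:
            gov_chem_word = parse_c.token(gov_chem_idx).word.lower()
            neg_gov_chem = is_negated(parse_c, gov_chem_idx, negation_lexicon)
    if ld is not None:
        parse_d = parses[ld.sentence_index]
        gov_dis_idx = governing_verb(parse_d, ld.head_token, verb_tagset)
        if gov_dis_idx is not None:
            gov_dis_word = parse_d.token(gov_dis_idx).word.lower()
            neg_gov_dis = is_negated(parse_d, gov_dis_idx, negation_lexicon)

    same_sentence = (
        lc is not None and ld is not None and lc.sentence_index == ld.sentence_index
    )
    rw_word = gov_rw_word = None
    neg_relating = neg_gov_relating = False
    chem_is_relating = govdis_is_relating = both_gov_are_relating = False
    other_pair_lower = False
    if same_sentence:
        parse = parses[lc.sentence_index]
        rw = relating_word(parse, lc.head_token, ld.head_token)
        if rw is not None:
            rw_word = parse.token(rw).word.lower()
            neg_relating = is_negated(parse, rw, negation_lexicon)
            gov_rw_idx = governing_verb(parse, rw, verb_tagset)
            if gov_rw_idx is not None:
                gov_rw_word = parse.token(gov_rw_idx).word.lower()
                neg_gov_relating = is_negated(parse, gov_rw_idx, negation_lexicon)
            chem_is_relating = lc.head_token == rw
            govdis_is_relating = gov_dis_idx == rw
            both_gov_are_relating = gov_chem_idx == rw and gov_dis_idx == rw
            chem_here = [
                lm
                for m in document.mentions_of_type(CHEMICAL)
                if (lm := locate_mention(parses, m)) is not None
                and lm.sentence_index == lc.sentence_index
            ]
            dis_here = [
                lm
                for m in document.mentions_of_type(DISEASE)
                if (lm := locate_mention(parses, m)) is not None
                and lm.sentence_index == lc.sentence_index
            ]
            other_pair_lower = _has_lower_pair(parse, rw, chem_here, dis_here, (lc, ld))

    return PairLinguisticFeatures(
        gov_verb_chem=gov_chem_word,
        gov_verb_dis=gov_dis_word,
        relating_word=rw_word,
        gov_verb_relating=gov_rw_word,
        chem_before_dis=cm.start < dm.start,
        other_pair_lower=other_pair_lower,
        neg_relating=neg_relating,
        neg_gov_chem=neg_gov_chem,
        neg_gov_dis=neg_gov_dis,
        neg_gov_relating=neg_gov_relating,
        chem_is_relating=chem_is_relating,
        govdis_is_relating=govdis_is_relating,
        both_gov_are_relating=both_gov_are_relating,
    )


def _pair_role_words(
    parses: Sequence[SentenceParse],
    lc: LocatedMention,
    ld: LocatedMention,
    verb_tagset: str,
) -> list[str]:
    """Governing-verb and relating-word occurrences for one mention pair.

    Each role occurrence counts once: a word serving as both a governing verb
    and the relating word of the same pair contributes twice, once per role.
    """
    words: list[str] = []
    parse_c = parses[lc.sentence_index]
    parse_d = parses[ld.sentence_index]
    gc = governing_verb(parse_c, lc.head_token, verb_tagset)
    if gc is not None:
        words.append(parse_c.token(gc).word.lower())
    gd = governing_verb(parse_d, ld.head_token, verb_tagset)
    if gd is not None:
        words.append(parse_d.token(gd).word.lower())
    if lc.sentence_index == ld.sentence_index:
        rw = relating_word(parse_c, lc.head_token, ld.head_token)
        if rw is not None:
            words.append(parse_c.token(rw).word.lower())
    return words


def aggregate_linguistic_features(
    document: Document,
    parses: Sequence[SentenceParse],
    vocabulary: Sequence[str],
    verb_tagset: str = "penn",
) -> dict[str, int]:
    """Second linguistic feature set: per-vocabulary-word role counts.

    Counts, over all chemical-mention x disease-mention pairs in the
    document, how often each vocabulary word occurs as a governing verb or
    relating word; out-of-vocabulary words are ignored.
    """
    counts = {w: 0 for w in vocabulary}
    vocab = set(vocabulary)
    chem_located = [
        lm
        for m in document.mentions_of_type(CHEMICAL)
        if (lm := locate_mention(parses, m)) is not None
    ]
    dis_located = [
        lm
        for m in document.mentions_of_type(DISEASE)
        if (lm := locate_mention(parses, m)) is not None
    ]
    for lc in chem_located:
        for ld in dis_located:
            for word in _pair_role_words(parses, lc, ld, verb_tagset):
                if word in vocab:
                    counts[word] += 1
    return counts


def collect_vocabulary(
    documents_with_parses: Sequence[tuple[Document, Sequence[SentenceParse]]],
    verb_tagset: str = "penn",
) -> list[str]:
    """Training pass: every word observed as governing verb or relating word."""
    vocab: set[str] = set()
    for document, parses in documents_with_parses:
        chem_located = [
            lm
            for m in document.mentions_of_type(CHEMICAL)
            if (lm := locate_mention(parses, m)) is not None
        ]
        dis_located = [
            lm
            for m in document.mentions_of_type(DISEASE)
            if (lm := locate_mention(parses, m)) is not None
        ]
        for lc in chem_located:
            for ld in dis_located:
                vocab.update(_pair_role_words(parses, lc, ld, verb_tagset))
    return sorted(vocab)
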