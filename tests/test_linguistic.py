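"""Representative-pair selection and the two linguistic feature sets."""

import pytest

from religator.corpus import Document, EntityMention
from religator.fixtures import figure_tree_fixture
from religator.linguistic import (
    aggregate_linguistic_features,
    collect_vocabulary,
    locate_mention,
    pair_linguistic_features,
    select_representative_pair,
)

from .treedocs import CHEM, DIS, build_document

TITLE = [("Study", "NN", 0, "root"), (".", ".", 1, "punct")]


def _induce(chem, dis):
    return [
        (chem, "NN", 2, "nsubj"),
        ("induced", "VBD", 0, "root"),
        (dis, "NN", 2, "dobj"),
        (".", ".", 2, "punct"),
    ]


def _negated(chem, dis):
    return [
        (chem, "NN", 4, "nsubj"),
        ("did", "VBD", 4, "aux"),
        ("not", "RB", 4, "neg"),
        ("cause", "VB", 0, "root"),
        (dis, "NN", 4, "dobj"),
        (".", ".", 4, "punct"),
    ]


def _solo(word, pos="NN"):
    return [(word, pos, 2, "nsubj"), ("appeared", "VBD", 0, "root"), (".", ".", 2, "punct")]


ENTITIES = {
    "c1drug": (CHEM, "D1"),
    "c2drug": (CHEM, "D2"),
    "d1pain": (DIS, "D9"),
    "d2pain": (DIS, "D8"),
}


def test_same_sentence_pair_has_precedence():
    doc, parses = build_document(
        "1",
        [TITLE, _solo("c1drug"), _induce("c1drug", "d1pain")],
        ENTITIES,
    )
    cm, dm = select_representative_pair(doc, parses, "D1", "D9")
    # the chosen chemical mention is the one sharing the sentence, not the
    # earlier solo occurrence
    assert locate_mention(parses, cm).sentence_index == 2
    assert locate_mention(parses, dm).sentence_index == 2


def test_cross_sentence_last_chem_before_dis_pair():
    doc, parses = build_document(
        "2",
        [TITLE, _solo("c1drug"), _solo("d1pain"), _solo("c1drug"), _solo("d1pain")],
        ENTITIES,
    )
    cm, dm = select_representative_pair(doc, parses, "D1", "D9")
    assert locate_mention(parses, cm).sentence_index == 3
    assert locate_mention(parses, dm).sentence_index == 4


def test_cross_sentence_disease_first_falls_back_to_first_mentions():
    doc, parses = build_document(
        "3",
        [TITLE, _solo("d1pain"), _solo("d1pain"), _solo("c1drug")],
        ENTITIES,
    )
    cm, dm = select_representative_pair(doc, parses, "D1", "D9")
    assert locate_mention(parses, cm).sentence_index == 3
    assert locate_mention(parses, dm).sentence_index == 1


def test_pair_without_lower_pair_preferred():
    # Sentence with two chem-dis pairs nested under each other: the pair
    # whose relating word has no other pair strictly below wins.
    nested = [
        ("c1drug", "NN", 2, "nsubj"),
        ("induced", "VBD", 0, "root"),
        ("d1pain", "NN", 2, "dobj"),
        ("because", "IN", 6, "mark"),
        ("c2drug", "NN", 6, "nsubj"),
        ("caused", "VBD", 2, "advcl"),
        ("d2pain", "NN", 6, "dobj"),
        (".", ".", 2, "punct"),
    ]
    doc, parses = build_document("4", [TITLE, nested], ENTITIES)
    # for (c1, d1) the relating word is "induced" and the (c2, d2) pair under
    # "caused" is strictly lower, so (c2, d2) is flagged, (c1, d1) is not
    feats_outer = pair_linguistic_features(doc, parses, "D1", "D9")
    feats_inner = pair_linguistic_features(doc, parses, "D2", "D8")
    assert feats_outer.other_pair_lower is True
    assert feats_inner.other_pair_lower is False


def test_missing_mention_is_contract_violation(small_fixture):
    doc = small_fixture.corpus.documents[0]
    with pytest.raises(ValueError):
        select_representative_pair(doc, small_fixture.parses[doc.doc_id], "DX", "DY")


# ---------------------------------------------------------------------------
# First feature set


def _figure_document():
    parse, chem_tok, dis_tok = figure_tree_fixture()
    text = " ".join(t.word for t in parse.tokens)
    chem = parse.token(chem_tok)
    dis = parse.token(dis_tok)
    doc = Document(
        doc_id="fig",
        title=text,
        abstract="",
        mentions=[
            EntityMention(chem.char_start, chem.char_end, chem.word, CHEM, ("D1",)),
            EntityMention(dis.char_start, dis.char_end, dis.word, DIS, ("D9",)),
        ],
    )
    return doc, [parse]


def test_pair_features_on_worked_example():
    doc, parses = _figure_document()
    feats = pair_linguistic_features(doc, parses, "D1", "D9")
    assert feats.gov_verb_chem == "demonstrated"
    assert feats.gov_verb_dis == "produce"
    assert feats.relating_word == "demonstrated"
    assert feats.chem_before_dis is True
    assert feats.chem_is_relating is False
    assert feats.govdis_is_relating is False


def test_cross_sentence_pair_has_undefined_relating_word():
    doc, parses = build_document(
        "5", [TITLE, _solo("c1drug"), _solo("d1pain")], ENTITIES
    )
    feats = pair_linguistic_features(doc, parses, "D1", "D9")
    assert feats.relating_word is None
    assert feats.gov_verb_relating is None
    assert feats.neg_relating is False and feats.neg_gov_relating is False
    # governing verbs still come from the two different trees
    assert feats.gov_verb_chem == "appeared" and feats.gov_verb_dis == "appeared"


def test_negated_relating_word_and_identity_flags():
    doc, parses = build_document("6", [TITLE, _negated("c1drug", "d1pain")], ENTITIES)
    feats = pair_linguistic_features(doc, parses, "D1", "D9")
    assert feats.relating_word == "cause"
    assert feats.neg_relating is True
    # governing verb of the disease is "cause", which is the relating word
    assert feats.govdis_is_relating is True
    assert feats.both_gov_are_relating is True


def test_chem_dominating_dis_is_its_own_relating_word():
    spec = [
        ("c1drug", "NN", 0, "root"),
        ("of", "IN", 1, "prep"),
        ("d1pain", "NN", 2, "pobj"),
        (".", ".", 1, "punct"),
    ]
    doc, parses = build_document("7", [TITLE, spec], ENTITIES)
    feats = pair_linguistic_features(doc, parses, "D1", "D9")
    assert feats.relating_word == "c1drug"
    assert feats.chem_is_relating is True


# ---------------------------------------------------------------------------
# Aggregate feature set


def test_aggregate_counts_each_role_once():
    doc, parses = build_document("8", [TITLE, _induce("c1drug", "d1pain")], ENTITIES)
    counts = aggregate_linguistic_features(doc, parses, ["induced", "other"])
    # one pair: governing verb of chem, of dis, and relating word are all
    # "induced" -> three role occurrences
    assert counts == {"induced": 3, "other": 0}


def test_aggregate_empty_vocabulary():
    doc, parses = build_document("9", [TITLE, _induce("c1drug", "d1pain")], ENTITIES)
    assert aggregate_linguistic_features(doc, parses, []) == {}


def test_aggregate_no_chemical_mentions_all_zero():
    doc, parses = build_document("10", [TITLE, _solo("d1pain")], ENTITIES)
    assert aggregate_linguistic_features(doc, parses, ["appeared"]) == {"appeared": 0}


def test_collect_vocabulary_covers_observed_roles():
    doc, parses = build_document(
        "11", [TITLE, _induce("c1drug", "d1pain"), _negated("c2drug", "d2pain")], ENTITIES
    )
    vocab = collect_vocabulary([(doc, parses)])
    assert "induced" in vocab and "cause" in vocab
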