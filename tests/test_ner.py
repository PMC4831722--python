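"""Dictionary recognition: tokenization, stemming, matching, post-processing."""

import logging
import math
import random

import pytest

from religator.corpus import Document
from religator.ner import (
    ConceptSpan,
    TermEntry,
    apply_exclusion,
    build_exclusion_list,
    build_index,
    default_stopwords,
    match_longest,
    merge_adjacent,
    normalize_to_mesh,
    propagate_abbreviations,
    recognize_diseases,
    tokenize,
)
from religator.stemming import ConfigurationError, get_normalizer, suffix_stem

from .oracles import brute_force_match


# ---------------------------------------------------------------------------
# Tokenizer


def test_tokenize_empty():
    assert tokenize("") == []


def test_tokenize_drops_punctuation_and_folds_case():
    tokens = tokenize("heart-attack, acute")
    assert [t.text for t in tokens] == ["heart", "attack", "acute"]
    # offsets recover the original surface
    assert "heart-attack, acute"[tokens[0].start : tokens[0].end] == "heart"
    assert [t.text for t in tokenize("Q10 deficiency")] == ["q10", "deficiency"]


def test_tokenize_offsets_nonoverlapping_ordered():
    rng = random.Random(0)
    for _ in range(50):
        text = "".join(rng.choice("ab1 ,.-X") for _ in range(30))
        tokens = tokenize(text)
        for prev, curr in zip(tokens, tokens[1:]):
            assert prev.end <= curr.start
        for t in tokens:
            assert text[t.start : t.end].lower() == t.text


# ---------------------------------------------------------------------------
# Stemmer


def test_identity_normalizer():
    assert get_normalizer("identity")("seizures") == "seizures"


def test_builtin_stemmer_merges_singular_and_plural():
    assert suffix_stem("seizures") == suffix_stem("seizure")


@pytest.mark.parametrize(
    "word", ["seizures", "induced", "carcinomas", "bleeding", "rapidly", "q10"]
)
def test_builtin_stemmer_idempotent(word):
    once = suffix_stem(word)
    assert suffix_stem(once) == once


def test_unknown_normalizer_is_configuration_error():
    with pytest.raises(ConfigurationError):
        get_normalizer("lvg")


# ---------------------------------------------------------------------------
# Index construction


def test_build_index_single_term():
    index = build_index([TermEntry("C1", "fever")])
    assert index.entries == {("fever",): frozenset({"C1"})}


def test_build_index_removes_stopwords():
    index = build_index([TermEntry("C2", "pain in chest")], stopwords={"in"})
    assert ("pain", "chest") in index.entries


def test_build_index_drops_all_stopword_terms(caplog):
    with caplog.at_level(logging.WARNING):
        index = build_index(
            [TermEntry("C1", "the"), TermEntry("C2", "fever")], stopwords={"the"}
        )
    assert ("fever",) in index.entries and len(index.entries) == 1
    assert any("dropped" in rec.message for rec in caplog.records)


# ---------------------------------------------------------------------------
# Longest match


@pytest.fixture()
def liver_index():
    return build_index(
        [TermEntry("C1", "liver failure"), TermEntry("C2", "liver")],
        normalizer="identity",
    )


def test_longest_match_wins(liver_index):
    text = "acute liver failure"
    spans = match_longest(tokenize(text), liver_index)
    assert len(spans) == 1
    assert text[spans[0].start : spans[0].end] == "liver failure"
    assert spans[0].concept_ids == frozenset({"C1"})


def test_shorter_match_when_longer_absent(liver_index):
    text = "liver disease"
    spans = match_longest(tokenize(text), liver_index)
    assert [text[s.start : s.end] for s in spans] == ["liver"]
    assert spans[0].concept_ids == frozenset({"C2"})


def test_match_skips_text_stopwords():
    index = build_index([TermEntry("C3", "pain chest")], stopwords={"in", "the"})
    text = "pain in the chest"
    spans = match_longest(tokenize(text), index)
    assert len(spans) == 1
    assert text[spans[0].start : spans[0].end] == "pain in the chest"


def test_match_agrees_with_brute_force_oracle():
    """Greedy leftmost-longest matching vs exhaustive key enumeration."""
    rng = random.Random(1234)
    vocab = ["liver", "heart", "failure", "acute", "pain", "in", "of", "q10"]
    for _ in range(500):
        entries = [
            TermEntry(
                f"C{k}",
                " ".join(rng.sample(vocab, rng.randint(1, 3))),
            )
            for k in range(rng.randint(1, 8))
        ]
        stop = set(rng.sample(vocab, rng.randint(0, 2)))
        try:
            index = build_index(entries, stop, normalizer="identity")
        except ValueError:
            continue
        if not index.entries:
            continue
        text = " ".join(rng.choice(vocab) for _ in range(rng.randint(0, 20)))
        tokens = tokenize(text)
        got = [
            (s.start, s.end, s.concept_ids) for s in match_longest(tokens, index)
        ]
        expected = brute_force_match(tokens, index)
        assert got == expected


# ---------------------------------------------------------------------------
# Abbreviation propagation


def test_abbreviation_propagates_long_to_short():
    text = (
        "History of non-Hodgkin lymphoma (NHL) was noted. "
        "Treatment of NHL continued."
    )
    lf_start = text.index("non-Hodgkin lymphoma")
    spans = [
        ConceptSpan(
            start=lf_start,
            end=lf_start + len("non-Hodgkin lymphoma"),
            concept_ids=frozenset({"C9"}),
            norm_term="non hodgkin lymphoma",
        )
    ]
    out = propagate_abbreviations(text, spans)
    nhl_spans = [s for s in out if text[s.start : s.end] == "NHL"]
    assert len(nhl_spans) == 2  # the defining "(NHL)" and the later bare "NHL"
    assert all(s.concept_ids == frozenset({"C9"}) for s in nhl_spans)


def test_no_propagation_without_long_form():
    text = "The value (NHL) was measured."
    assert propagate_abbreviations(text, []) == []


def test_short_form_concept_propagates_to_long_form():
    text = "Relapse of non-Hodgkin lymphoma (NHL) occurred."
    sf_start = text.index("NHL")
    spans = [
        ConceptSpan(
            start=sf_start,
            end=sf_start + 3,
            concept_ids=frozenset({"C9"}),
            norm_term="nhl",
        )
    ]
    out = propagate_abbreviations(text, spans)
    lf = [s for s in out if text[s.start : s.end] == "non-Hodgkin lymphoma"]
    assert len(lf) == 1 and lf[0].concept_ids == frozenset({"C9"})


# ---------------------------------------------------------------------------
# Merging, exclusion, MeSH mapping


def _span(start, end, ids, term="t"):
    return ConceptSpan(start=start, end=end, concept_ids=frozenset(ids), norm_term=term)


def test_merge_adjacent_same_concept():
    text = "abcde fghij"
    merged = merge_adjacent(text, [_span(0, 5, {"C1"}), _span(6, 11, {"C1"})])
    assert [(s.start, s.end) for s in merged] == [(0, 11)]


def test_merge_keeps_different_concepts_apart():
    text = "abcde fghij"
    spans = [_span(0, 5, {"C1"}), _span(6, 11, {"C2"})]
    assert merge_adjacent(text, spans) == spans


def test_merge_chain_collapses_and_is_idempotent():
    text = "aa bb cc"
    spans = [_span(0, 2, {"C1"}), _span(3, 5, {"C1"}), _span(6, 8, {"C1"})]
    merged = merge_adjacent(text, spans)
    assert [(s.start, s.end) for s in merged] == [(0, 8)]
    assert merge_adjacent(text, merged) == merged


def test_exclusion_threshold_boundary():
    spans = [_span(0, 4, {"C1"}, term="patch")]
    # ratio 1/9 < 0.3: removed
    assert apply_exclusion(spans, {"patch": (1, 9)}) == []
    # ratio exactly 0.3 is NOT lower than the threshold: kept
    assert apply_exclusion(spans, {"patch": (3, 10)}) == spans
    # unlisted terms and fp-free terms kept
    assert apply_exclusion(spans, {}) == spans
    assert apply_exclusion(spans, {"patch": (0, 0)}) == spans


def test_exclusion_monotone_in_threshold():
    spans = [_span(0, 4, {"C1"}, term="a"), _span(5, 9, {"C2"}, term="b")]
    excl = {"a": (1, 2), "b": (5, 1)}
    assert apply_exclusion(spans, excl, 0.0) == spans  # identity
    kept_mid = apply_exclusion(spans, excl, 0.3)
    kept_inf = apply_exclusion(spans, excl, math.inf)
    assert set(kept_inf) <= set(kept_mid) <= set(spans)
    assert kept_inf == []  # every listed term with fp>0 removed


def test_normalize_to_mesh_mapping_drop_and_dedup():
    text = "abcd efgh"
    spans = [
        _span(0, 4, {"C1"}),
        _span(5, 9, {"C2", "C3"}),  # both map to the same MeSH id
    ]
    mesh = {"C1": "D001", "C2": "D002", "C3": "D002"}
    mentions = normalize_to_mesh(text, spans, mesh)
    assert [m.concept_ids for m in mentions] == [("D001",), ("D002",)]
    # unmapped concept dropped in drop-mode, kept as sentinel otherwise
    assert normalize_to_mesh(text, [_span(0, 4, {"CX"})], mesh) == []
    kept = normalize_to_mesh(text, [_span(0, 4, {"CX"})], mesh, "sentinel")
    assert kept[0].concept_ids == ("unmapped",)


# ---------------------------------------------------------------------------
# Full chain


@pytest.fixture()
def chain_resources():
    entries = [
        TermEntry("C1", "acute liver failure"),
        TermEntry("C2", "liver failure"),
        TermEntry("C3", "rash"),
        TermEntry("C4", "non-Hodgkin lymphoma"),
    ]
    index = build_index(entries, default_stopwords())
    mesh = {"C1": "D100", "C2": "D200", "C3": "D300", "C4": "D400"}
    exclusion = {"rash": (1, 9)}  # ratio 0.11 < 0.3: filtered out
    return index, exclusion, mesh


def test_recognize_diseases_full_chain(chain_resources):
    index, exclusion, mesh = chain_resources
    doc = Document(
        doc_id="42",
        title="Report of acute liver failure",
        abstract=(
            "Patient with non-Hodgkin lymphoma (NHL) developed rash. "
            "NHL history was long. Liver failure followed."
        ),
    )
    out = recognize_diseases(doc, index, exclusion, mesh)
    found = {(doc.text[m.start : m.end], m.concept_ids) for m in out.mentions}
    # longest match beats nested term; exclusion removes "rash";
    # abbreviation propagation tags the bare NHL occurrence, and the merge
    # stage joins the defining long form with its adjacent short form
    assert ("acute liver failure", ("D100",)) in found
    assert ("Liver failure", ("D200",)) in found
    assert ("non-Hodgkin lymphoma (NHL", ("D400",)) in found
    assert ("NHL", ("D400",)) in found  # the later bare occurrence
    assert not any(t == "rash" for t, _ in found)


def test_recognize_diseases_no_hits(chain_resources):
    index, exclusion, mesh = chain_resources
    doc = Document(doc_id="1", title="Plain title", abstract="Nothing here.")
    assert recognize_diseases(doc, index, exclusion, mesh).mentions == []


def test_recognize_diseases_deterministic_and_nonoverlapping(chain_resources):
    index, exclusion, mesh = chain_resources
    doc = Document(
        doc_id="2",
        title="Acute liver failure and rash",
        abstract="Acute liver failure with liver failure and rash.",
    )
    first = recognize_diseases(doc, index, exclusion, mesh)
    second = recognize_diseases(doc, index, exclusion, mesh)
    assert first.mentions == second.mentions
    ordered = sorted(first.mentions, key=lambda m: m.start)
    for a, b in zip(ordered, ordered[1:]):
        assert a.end <= b.start
    for m in first.mentions:
        assert doc.text[m.start : m.end] == m.text


def test_build_exclusion_list_tallies_tp_fp(small_fixture):
    doc = small_fixture.corpus.documents[0]
    gold_disease = doc.mentions_of_type("disease")[0]
    spans = [
        _span(gold_disease.start, gold_disease.end, {"C1"}, term="good"),
        _span(0, 3, {"C2"}, term="bad"),
    ]
    excl = build_exclusion_list([doc], {doc.doc_id: spans})
    assert excl["good"] == (1, 0)
    assert excl["bad"] == (0, 1)
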