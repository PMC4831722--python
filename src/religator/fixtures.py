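"""Seeded generator of synthetic corpora with planted ground truth.

The generator emits the full set of mutually consistent input artifacts the
pipeline consumes — a PubTator corpus, a disease dictionary, a concept-to-MeSH
map, a knowledge-graph edge list, CoNLL-U dependency parses, and a
ground-truth relation table — so that every stage is testable without any
external download.

Documents are built from a small set of sentence templates with hand-authored
dependency trees.  Whether a chemical truly causes a disease is a *global*
property of the concept pair, decided once (with probability ``p_relation``)
the first time the pair is co-mentioned anywhere; every document co-mentioning
a related pair asserts the relation.  In a given document a related pair
shares a sentence with probability ``p_same_sentence`` (an "induced" or a
neutral "associated with" sentence), otherwise it is realized in two separate
sentences; unrelated pairs appear in a negated, a therapeutic, or a neutral
sentence.  The neutral template is deliberately shared between related and
unrelated pairs: for those pairs the text alone is ambiguous and only the
planted knowledge-graph edge (present with probability ``p_kg_edge_given_rel``
vs ``p_kg_edge_given_unrel``, also decided once per pair) separates the
classes.  Therapeutic "treats" edges are planted for unrelated pairs.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from pathlib import Path

from .corpus import (
    CHEMICAL,
    DISEASE,
    Corpus,
    Document,
    EntityMention,
    RelationAnnotation,
    write_pubtator,
)
from .kg import KGEdge, KnowledgeGraph, save_graph
from .ner import TermEntry
from .parses import ParsedToken, SentenceParse, write_conllu


@dataclass(frozen=True)
class FixtureConfig:
    seed: int = 0
    n_docs: int = 50
    n_chemicals: int = 30
    n_diseases: int = 30
    p_relation: float = 0.25
    p_same_sentence: float = 0.7
    p_kg_edge_given_rel: float = 0.9
    p_kg_edge_given_unrel: float = 0.05
    p_treat_edge: float = 0.3
    #: share of same-sentence related / of unrelated pairs realized with the
    #: ambiguous neutral template
    p_neutral_given_rel: float = 0.4
    p_neutral_given_unrel: float = 0.4
    #: chance of an extra indirect chem -> gene -> disease chain for a related pair
    p_indirect_given_rel: float = 0.1
    template_set: str = "v1"

    def __post_init__(self) -> None:
        for name in (
            "p_relation",
            "p_same_sentence",
            "p_kg_edge_given_rel",
            "p_kg_edge_given_unrel",
            "p_treat_edge",
            "p_neutral_given_rel",
            "p_neutral_given_unrel",
            "p_indirect_given_rel",
        ):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        if min(self.n_docs, self.n_chemicals, self.n_diseases) < 1:
            raise ValueError("sizes must be >= 1")


@dataclass(frozen=True)
class PlantedRelation:
    doc_id: str
    chem_id: str  # MeSH
    dis_id: str  # MeSH
    same_sentence: bool


@dataclass
class FixtureSet:
    corpus: Corpus
    dictionary: list[TermEntry]
    mesh_map: dict[str, str]
    graph: KnowledgeGraph
    parses: dict[str, list[SentenceParse]]
    planted: list[PlantedRelation]
    config: FixtureConfig

    def split(self, n_train_docs: int) -> tuple[Corpus, Corpus]:
        """Document-level train/test split sharing the graph and parses."""
        train = Corpus(documents=self.corpus.documents[:n_train_docs])
        test = Corpus(documents=self.corpus.documents[n_train_docs:])
        return train, test

    def write(self, out_dir) -> dict[str, Path]:
        """Write the six artifacts; byte-identical for a fixed config."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "corpus": out / "corpus.pubtator",
            "dictionary": out / "dictionary.tsv",
            "mesh_map": out / "mesh_map.tsv",
            "kg": out / "kg.tsv",
            "parses": out / "parses.conllu",
            "ground_truth": out / "relations_gold.tsv",
        }
        write_pubtator(self.corpus, paths["corpus"])
        with open(paths["dictionary"], "w", encoding="utf-8") as handle:
            for entry in self.dictionary:
                handle.write(f"{entry.concept_id}\t{entry.term}\n")
        with open(paths["mesh_map"], "w", encoding="utf-8") as handle:
            for concept_id in sorted(self.mesh_map):
                handle.write(f"{concept_id}\t{self.mesh_map[concept_id]}\n")
        save_graph(self.graph, paths["kg"])
        write_conllu(self.parses, paths["parses"])
        with open(paths["ground_truth"], "w", encoding="utf-8") as handle:
            for rel in self.planted:
                handle.write(
                    f"{rel.doc_id}\t{rel.chem_id}\t{rel.dis_id}\t"
                    f"{int(rel.same_sentence)}\n"
                )
        return paths


# ---------------------------------------------------------------------------
# Sentence templates: (word, pos, head, dep_label) with 1-based heads.

Spec = list[tuple[str, str, int, str]]


def _t_induce(chem: str, dis: str) -> tuple[Spec, int, int]:
    return (
        [
            (chem, "NN", 2, "nsubj"),
            ("induced", "VBD", 0, "root"),
            (dis, "NN", 2, "dobj"),
            (".", ".", 2, "punct"),
        ],
        1,
        3,
    )


def _t_neutral(chem: str, dis: str) -> tuple[Spec, int, int]:
    return (
        [
            (chem, "NN", 3, "nsubjpass"),
            ("was", "VBD", 3, "auxpass"),
            ("associated", "VBN", 0, "root"),
            ("with", "IN", 3, "prep"),
            (dis, "NN", 4, "pobj"),
            (".", ".", 3, "punct"),
        ],
        1,
        5,
    )


def _t_negated(chem: str, dis: str) -> tuple[Spec, int, int]:
    return (
        [
            (chem, "NN", 4, "nsubj"),
            ("did", "VBD", 4, "aux"),
            ("not", "RB", 4, "neg"),
            ("cause", "VB", 0, "root"),
            (dis, "NN", 4, "dobj"),
            (".", ".", 4, "punct"),
        ],
        1,
        5,
    )


def _t_treat(chem: str, dis: str) -> tuple[Spec, int, int]:
    return (
        [
            (dis, "NN", 3, "nsubjpass"),
            ("was", "VBD", 3, "auxpass"),
            ("treated", "VBN", 0, "root"),
            ("with", "IN", 3, "prep"),
            (chem, "NN", 4, "pobj"),
            (".", ".", 3, "punct"),
        ],
        5,
        1,
    )


def _t_admin(chem: str) -> tuple[Spec, int, int | None]:
    return (
        [
            (chem, "NN", 3, "nsubjpass"),
            ("was", "VBD", 3, "auxpass"),
            ("administered", "VBN", 0, "root"),
            (".", ".", 3, "punct"),
        ],
        1,
        None,
    )


def _t_develop(dis: str) -> tuple[Spec, int | None, int]:
    return (
        [
            ("Later", "RB", 3, "advmod"),
            (dis, "NN", 3, "nsubj"),
            ("developed", "VBD", 0, "root"),
            (".", ".", 3, "punct"),
        ],
        None,
        2,
    )


def _t_title_chem(chem: str) -> tuple[Spec, int, int | None]:
    return (
        [
            ("Effects", "NNS", 0, "root"),
            ("of", "IN", 1, "prep"),
            (chem, "NN", 2, "pobj"),
            (".", ".", 1, "punct"),
        ],
        3,
        None,
    )


def _t_title_dis(dis: str) -> tuple[Spec, int | None, int]:
    return (
        [
            ("Course", "NN", 0, "root"),
            ("of", "IN", 1, "prep"),
            (dis, "NN", 2, "pobj"),
            (".", ".", 1, "punct"),
        ],
        None,
        3,
    )


def _realize(spec: Spec, sentence_index: int, char_offset: int) -> tuple[str, SentenceParse]:
    """Render a template to text and a parse with document-level offsets."""
    words = [w for w, _, _, _ in spec]
    text = " ".join(words)
    tokens = []
    pos = char_offset
    for i, (word, tag, head, dep) in enumerate(spec, start=1):
        tokens.append(
            ParsedToken(
                index=i,
                word=word,
                pos=tag,
                head=head,
                dep_label=dep,
                char_start=pos,
                char_end=pos + len(word),
            )
        )
        pos += len(word) + 1
    return text, SentenceParse(sentence_index=sentence_index, tokens=tokens)


# ---------------------------------------------------------------------------


@dataclass
class _Entity:
    name: str
    concept_id: str | None  # source-vocabulary id (diseases only)
    mesh_id: str
    entity_type: str


def _vocabularies(config: FixtureConfig) -> tuple[list[_Entity], list[_Entity]]:
    chems = [
        _Entity(
            name=f"chem{i}nib",
            concept_id=None,
            mesh_id=f"D{10000 + i}",
            entity_type=CHEMICAL,
        )
        for i in range(config.n_chemicals)
    ]
    diss = [
        _Entity(
            name=f"dis{i}osis",
            concept_id=f"C{i:07d}",
            mesh_id=f"D{20000 + i}",
            entity_type=DISEASE,
        )
        for i in range(config.n_diseases)
    ]
    return chems, diss


def generate(config: FixtureConfig = FixtureConfig()) -> FixtureSet:
    """Generate the six mutually consistent artifacts for one configuration.

    Deterministic for a fixed config: running twice yields identical
    in-memory objects and byte-identical files.
    """
    rng = random.Random(config.seed)
    chems, diss = _vocabularies(config)

    dictionary = []
    mesh_map: dict[str, str] = {}
    for d in diss:
        dictionary.append(TermEntry(concept_id=d.concept_id, term=d.name))
        dictionary.append(TermEntry(concept_id=d.concept_id, term=f"{d.name} syndrome"))
        mesh_map[d.concept_id] = d.mesh_id

    graph = KnowledgeGraph()
    documents: list[Document] = []
    parses: dict[str, list[SentenceParse]] = {}
    planted: list[PlantedRelation] = []
    gene_counter = 0

    # Global per-pair truth: decided once, on first co-mention; the matching
    # knowledge-graph edges are planted at the same moment.
    pair_related: dict[tuple[str, str], bool] = {}

    def decide_pair(chem: _Entity, dis: _Entity) -> bool:
        nonlocal gene_counter
        key = (chem.mesh_id, dis.mesh_id)
        if key in pair_related:
            return pair_related[key]
        related = rng.random() < config.p_relation
        pair_related[key] = related
        if related:
            if rng.random() < config.p_kg_edge_given_rel:
                _add_edge(graph, chem.mesh_id, "causes", dis.mesh_id, rng)
            if rng.random() < config.p_indirect_given_rel:
                gene = f"G{gene_counter}"
                gene_counter += 1
                _add_edge(graph, chem.mesh_id, "affects", gene, rng)
                _add_edge(graph, gene, "associated_with", dis.mesh_id, rng)
        else:
            if rng.random() < config.p_kg_edge_given_unrel:
                _add_edge(graph, chem.mesh_id, "causes", dis.mesh_id, rng)
            if rng.random() < config.p_treat_edge:
                _add_edge(graph, chem.mesh_id, "treats", dis.mesh_id, rng)
        return related

    for doc_index in range(config.n_docs):
        doc_id = str(10000 + doc_index)
        doc_chems = sorted(
            rng.sample(chems, rng.randint(1, min(3, len(chems)))),
            key=lambda e: e.mesh_id,
        )
        doc_diss = sorted(
            rng.sample(diss, rng.randint(1, min(3, len(diss)))),
            key=lambda e: e.mesh_id,
        )

        # Plan sentences: title first, then one or two sentences per pair.
        sentence_plan: list[tuple[Spec, _Entity | None, _Entity | None, int, int | None]] = []
        if doc_index % 2 == 0:
            spec, c_tok, _ = _t_title_chem(doc_chems[0].name)
            sentence_plan.append((spec, doc_chems[0], None, c_tok, None))
        else:
            spec, _, d_tok = _t_title_dis(doc_diss[0].name)
            sentence_plan.append((spec, None, doc_diss[0], None, d_tok))

        pair_truth: list[tuple[_Entity, _Entity, bool, bool]] = []
        for chem in doc_chems:
            for dis in doc_diss:
                related = decide_pair(chem, dis)
                same_sentence = True
                if related:
                    same_sentence = rng.random() < config.p_same_sentence
                    if same_sentence:
                        if rng.random() < config.p_neutral_given_rel:
                            spec, c_tok, d_tok = _t_neutral(chem.name, dis.name)
                        else:
                            spec, c_tok, d_tok = _t_induce(chem.name, dis.name)
                        sentence_plan.append((spec, chem, dis, c_tok, d_tok))
                    else:
                        spec_a, c_tok, _ = _t_admin(chem.name)
                        sentence_plan.append((spec_a, chem, None, c_tok, None))
                        spec_b, _, d_tok = _t_develop(dis.name)
                        sentence_plan.append((spec_b, None, dis, None, d_tok))
                else:
                    roll = rng.random()
                    if roll < config.p_neutral_given_unrel:
                        spec, c_tok, d_tok = _t_neutral(chem.name, dis.name)
                    elif roll < config.p_neutral_given_unrel + 0.5 * (
                        1 - config.p_neutral_given_unrel
                    ):
                        spec, c_tok, d_tok = _t_negated(chem.name, dis.name)
                    else:
                        spec, c_tok, d_tok = _t_treat(chem.name, dis.name)
                    sentence_plan.append((spec, chem, dis, c_tok, d_tok))
                pair_truth.append((chem, dis, related, same_sentence))

        # Realize sentences; sentence 0 is the title.
        doc_parses: list[SentenceParse] = []
        mentions: list[EntityMention] = []
        texts: list[str] = []
        offset = 0
        title = ""
        for s_index, (spec, chem, dis, c_tok, d_tok) in enumerate(sentence_plan):
            text, parse = _realize(spec, s_index, offset)
            doc_parses.append(parse)
            texts.append(text)
            for entity, tok in ((chem, c_tok), (dis, d_tok)):
                if entity is None or tok is None:
                    continue
                token = parse.token(tok)
                mentions.append(
                    EntityMention(
                        start=token.char_start,
                        end=token.char_end,
                        text=entity.name,
                        entity_type=entity.entity_type,
                        concept_ids=(entity.mesh_id,),
                    )
                )
            if s_index == 0:
                title = text
            offset += len(text) + 1  # single separator / space join

        abstract = " ".join(texts[1:])
        relations = set()
        for chem, dis, related, same_sentence in pair_truth:
            if related:
                relations.add(
                    RelationAnnotation(chemical_id=chem.mesh_id, disease_id=dis.mesh_id)
                )
                planted.append(
                    PlantedRelation(
                        doc_id=doc_id,
                        chem_id=chem.mesh_id,
                        dis_id=dis.mesh_id,
                        same_sentence=same_sentence,
                    )
                )

        documents.append(
            Document(
                doc_id=doc_id,
                title=title,
                abstract=abstract,
                mentions=sorted(mentions, key=lambda m: (m.start, m.end)),
                relations=relations,
            )
        )
        parses[doc_id] = doc_parses

    corpus = Corpus(documents=documents)
    corpus.validate()
    return FixtureSet(
        corpus=corpus,
        dictionary=dictionary,
        mesh_map=mesh_map,
        graph=graph,
        parses=parses,
        planted=planted,
        config=config,
    )


def _add_edge(
    graph: KnowledgeGraph, subject: str, predicate: str, obj: str, rng: random.Random
) -> None:
    count = rng.randint(1, 20)
    for edge in graph.edges_between(subject, obj):
        if edge.subject == subject and edge.predicate == predicate:
            edge.provenance["synthetic"] = edge.provenance.get("synthetic", 0) + count
            return
    graph.add_edge(
        KGEdge(
            subject=subject,
            predicate=predicate,
            object=obj,
            directed=True,
            provenance={"synthetic": count},
        )
    )


def figure_tree_fixture() -> tuple[SentenceParse, int, int]:
    """Hand-encoded worked example of the governing-verb/relating-word rules.

    Sentence: "A case of acetaminophen demonstrated that reexposure can
    produce anaphylaxis ."  The disease's governing verb is "produce"; the
    chemical's governing verb is "demonstrated", which is also the relating
    word of the pair.  Returns (parse, chemical token index, disease token
    index).
    """
    spec: Spec = [
        ("A", "DT", 2, "det"),
        ("case", "NN", 5, "nsubj"),
        ("of", "IN", 2, "prep"),
        ("acetaminophen", "NN", 3, "pobj"),
        ("demonstrated", "VBD", 0, "root"),
        ("that", "IN", 9, "mark"),
        ("reexposure", "NN", 9, "nsubj"),
        ("can", "MD", 9, "aux"),
        ("produce", "VB", 5, "ccomp"),
        ("anaphylaxis", "NN", 9, "dobj"),
        (".", ".", 5, "punct"),
    ]
    _, parse = _realize(spec, 0, 0)
    return parse, 4, 10
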