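"""PubTator corpus model and I/O.

The corpus format is line-oriented: a ``PMID|t|<title>`` line, a
``PMID|a|<abstract>`` line, zero or more tab-separated mention lines
(``PMID  start  end  text  Chemical|Disease  MeSH[|MeSH...]``), zero or more
document-level relation lines (``PMID  CID  chemicalMeSH  diseaseMeSH``), and a
blank line between documents.

Character offsets are 0-based, end-exclusive, and index into the concatenation
``title + " " + abstract`` (a single separator character, as in the released
CDR files).  A mention whose ``-1`` identifier marks a failed normalization is
stored with the sentinel :data:`UNMAPPED`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator

logger = logging.getLogger(__name__)

#: Sentinel concept identifier for mentions that could not be normalized.
UNMAPPED = "unmapped"

#: Separator inserted between title and abstract when computing offsets.
TITLE_SEPARATOR = " "

CHEMICAL = "chemical"
DISEASE = "disease"

#: Delimiter joining multiple MeSH identifiers on one annotation line.
COMPOSITE_ID_DELIMITER = "|"


class PubTatorParseError(ValueError):
    """Raised when a PubTator file violates the line grammar."""


class PubTatorValidationError(ValueError):
    """Raised when parsed content violates a document invariant."""


@dataclass(frozen=True)
class EntityMention:
    """A single entity annotation anchored in the document text."""

    start: int
    end: int
    text: str
    entity_type: str  # CHEMICAL or DISEASE
    concept_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise PubTatorValidationError(
                f"invalid mention span ({self.start}, {self.end})"
            )
        if len(self.text) != self.end - self.start:
            raise PubTatorValidationError(
                f"mention text length {len(self.text)} does not match span "
                f"({self.start}, {self.end})"
            )
        if self.entity_type not in (CHEMICAL, DISEASE):
            raise PubTatorValidationError(
                f"unknown entity type {self.entity_type!r}"
            )
        if not self.concept_ids:
            raise PubTatorValidationError("mention must carry >= 1 concept id")

    @property
    def is_unmapped(self) -> bool:
        return all(c == UNMAPPED for c in self.concept_ids)


@dataclass(frozen=True, order=True)
class RelationAnnotation:
    """A document-level chemical-induced-disease assertion (MeSH id pair)."""

    chemical_id: str
    disease_id: str

    def __post_init__(self) -> None:
        if self.chemical_id == UNMAPPED or self.disease_id == UNMAPPED:
            raise PubTatorValidationError("relation ids must be non-sentinel")


@dataclass
class Document:
    doc_id: str
    title: str
    abstract: str
    mentions: list[EntityMention] = field(default_factory=list)
    relations: set[RelationAnnotation] = field(default_factory=set)

    @property
    def text(self) -> str:
        """Title and abstract joined by the single separator character."""
        return self.title + TITLE_SEPARATOR + self.abstract

    def mentions_of_type(self, entity_type: str) -> list[EntityMention]:
        return [m for m in self.mentions if m.entity_type == entity_type]

    def concept_ids_of_type(self, entity_type: str) -> set[str]:
        """Unique non-sentinel ids of one type, composite ids expanded."""
        ids: set[str] = set()
        for m in self.mentions_of_type(entity_type):
            ids.update(c for c in m.concept_ids if c != UNMAPPED)
        return ids

    def validate(self) -> None:
        if not self.doc_id:
            raise PubTatorValidationError("empty doc_id")
        text = self.text
        for m in self.mentions:
            if m.end > len(text) or text[m.start : m.end] != m.text:
                raise PubTatorValidationError(
                    f"doc {self.doc_id}: span ({m.start}, {m.end}) slices to "
                    f"{text[m.start:m.end]!r}, annotation says {m.text!r}"
                )
        chem_ids = self.concept_ids_of_type(CHEMICAL)
        dis_ids = self.concept_ids_of_type(DISEASE)
        for rel in self.relations:
            if rel.chemical_id not in chem_ids or rel.disease_id not in dis_ids:
                logger.warning(
                    "doc %s: relation (%s, %s) references an id absent from "
                    "the mention annotations; kept",
                    self.doc_id,
                    rel.chemical_id,
                    rel.disease_id,
                )


@dataclass
class Corpus:
    documents: list[Document] = field(default_factory=list)

    def __iter__(self) -> Iterator[Document]:
        return iter(self.documents)

    def __len__(self) -> int:
        return len(self.documents)

    def validate(self) -> None:
        seen: set[str] = set()
        for doc in self.documents:
            doc.validate()
            if doc.doc_id in seen:
                raise PubTatorValidationError(f"duplicate doc_id {doc.doc_id}")
            seen.add(doc.doc_id)


_TYPE_IN = {"chemical": CHEMICAL, "disease": DISEASE}
_TYPE_OUT = {CHEMICAL: "Chemical", DISEASE: "Disease"}


def _parse_concept_field(raw: str) -> tuple[str, ...]:
    ids = tuple(
        UNMAPPED if part == "-1" else part
        for part in raw.split(COMPOSITE_ID_DELIMITER)
        if part
    )
    return ids or (UNMAPPED,)


def read_pubtator(path) -> Corpus:
    """Parse a PubTator file into a validated :class:`Corpus`."""
    documents: list[Document] = []
    current: Document | None = None

    with open(path, encoding="utf-8") as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                if current is not None:
                    documents.append(current)
                    current = None
                continue
            if "|t|" in line or "|a|" in line:
                doc_id, kind, payload = line.split("|", 2)
                if kind == "t":
                    if current is not None:
                        documents.append(current)
                    current = Document(doc_id=doc_id, title=payload, abstract="")
                elif kind == "a":
                    if current is None or current.doc_id != doc_id:
                        raise PubTatorParseError(
                            f"line {lineno}: abstract line without a matching "
                            f"title line for {doc_id}"
                        )
                    current.abstract = payload
                else:  # pragma: no cover - unreachable given the guard above
                    raise PubTatorParseError(f"line {lineno}: unknown kind {kind!r}")
                continue
            fields = line.split("\t")
            if current is None or fields[0] != current.doc_id:
                raise PubTatorParseError(
                    f"line {lineno}: annotation for {fields[0]!r} outside its "
                    "document block"
                )
            if len(fields) == 4 and fields[1] == "CID":
                current.relations.add(
                    RelationAnnotation(chemical_id=fields[2], disease_id=fields[3])
                )
            elif len(fields) == 6:
                _, start, end, text, etype, concept = fields
                etype_key = _TYPE_IN.get(etype.lower())
                if etype_key is None:
                    raise PubTatorParseError(
                        f"line {lineno}: unknown entity type {etype!r}"
                    )
                try:
                    mention = EntityMention(
                        start=int(start),
                        end=int(end),
                        text=text,
                        entity_type=etype_key,
                        concept_ids=_parse_concept_field(concept),
                    )
                except (ValueError, PubTatorValidationError) as exc:
                    raise PubTatorParseError(f"line {lineno}: {exc}") from exc
                current.mentions.append(mention)
            else:
                raise PubTatorParseError(
                    f"line {lineno}: malformed annotation line with "
                    f"{len(fields)} fields"
                )
    if current is not None:
        documents.append(current)

    corpus = Corpus(documents=documents)
    corpus.validate()
    return corpus


def write_pubtator(corpus: Corpus, path) -> None:
    """Serialize a corpus; ``read_pubtator`` of the output is the identity."""
    with open(path, "w", encoding="utf-8") as handle:
        for i, doc in enumerate(corpus.documents):
            if i:
                handle.write("\n")
            handle.write(f"{doc.doc_id}|t|{doc.title}\n")
            handle.write(f"{doc.doc_id}|a|{doc.abstract}\n")
            for m in sorted(doc.mentions, key=lambda m: (m.start, m.end)):
                ids = COMPOSITE_ID_DELIMITER.join(
                    "-1" if c == UNMAPPED else c for c in m.concept_ids
                )
                handle.write(
                    f"{doc.doc_id}\t{m.start}\t{m.end}\t{m.text}\t"
                    f"{_TYPE_OUT[m.entity_type]}\t{ids}\n"
                )
            for rel in sorted(doc.relations):
                handle.write(
                    f"{doc.doc_id}\tCID\t{rel.chemical_id}\t{rel.disease_id}\n"
                )


@dataclass(frozen=True)
class CorpusStats:
    documents: int
    chemical_mentions: int
    disease_mentions: int
    unique_chemical_ids: int
    unique_disease_ids: int
    relations: int


def corpus_stats(corpus: Corpus) -> CorpusStats:
    """Summary counts in the style of a corpus characteristics table.

    Mentions are counted per annotation line; unique identifiers are counted
    after expanding composite ids and dropping the unmapped sentinel.
    """
    chem_mentions = dis_mentions = relations = 0
    chem_ids: set[str] = set()
    dis_ids: set[str] = set()
    for doc in corpus:
        chem_mentions += len(doc.mentions_of_type(CHEMICAL))
        dis_mentions += len(doc.mentions_of_type(DISEASE))
        chem_ids.update(doc.concept_ids_of_type(CHEMICAL))
        dis_ids.update(doc.concept_ids_of_type(DISEASE))
        relations += len(doc.relations)
    return CorpusStats(
        documents=len(corpus),
        chemical_mentions=chem_mentions,
        disease_mentions=dis_mentions,
        unique_chemical_ids=len(chem_ids),
        unique_disease_ids=len(dis_ids),
        relations=relations,
    )


def concatenate(corpora: Iterable[Corpus]) -> Corpus:
    merged = Corpus(documents=[d for c in corpora for d in c.documents])
    merged.validate()
    return merged
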