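"""Helpers to build small documents with hand-authored dependency parses."""

from __future__ import annotations

from religator.corpus import CHEMICAL, DISEASE, Document, EntityMention
from religator.fixtures import Spec, _realize
from religator.parses import SentenceParse


def build_document(
    doc_id: str,
    sentence_specs: list[Spec],
    entities: dict[str, tuple[str, str]],
) -> tuple[Document, list[SentenceParse]]:
    """Realize sentences (first one is the title) and annotate entity words.

    ``entities`` maps a surface word to (entity_type, concept_id); every
    occurrence of the word becomes a mention.
    """
    parses: list[SentenceParse] = []
    texts: list[str] = []
    mentions: list[EntityMention] = []
    offset = 0
    for s_index, spec in enumerate(sentence_specs):
        text, parse = _realize(spec, s_index, offset)
        parses.append(parse)
        texts.append(text)
        for token in parse.tokens:
            if token.word in entities:
                etype, concept = entities[token.word]
                mentions.append(
                    EntityMention(
                        start=token.char_start,
                        end=token.char_end,
                        text=token.word,
                        entity_type=etype,
                        concept_ids=(concept,),
                    )
                )
        offset += len(text) + 1
    doc = Document(
        doc_id=doc_id,
        title=texts[0],
        abstract=" ".join(texts[1:]),
        mentions=sorted(mentions, key=lambda m: (m.start, m.end)),
    )
    doc.validate()
    return doc, parses


CHEM = CHEMICAL
DIS = DISEASE
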