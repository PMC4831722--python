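"""Dependency-tree substrate: CoNLL-U I/O and tree traversals.

Parses are consumed as an input artifact: a CoNLL-U file with one
``# doc_id = <id>`` comment per sentence and document-level character offsets
in the MISC column (``start=<n>|end=<n>``).  On top of the trees, this module
defines the two traversals the relation features build on:

* the *governing verb* of a token — the first verb encountered walking the
  head chain from the token towards the root (the token itself never counts);
* the *relating word* of a token pair — the first word the two tokens have in
  common on their (self-inclusive) paths to the root, i.e. the lowest common
  ancestor; undefined across sentences.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable


class ConlluError(ValueError):
    """Raised for malformed CoNLL-U content or an invalid tree."""


@dataclass(frozen=True)
class ParsedToken:
    index: int  # 1-based position within the sentence
    word: str
    pos: str
    head: int  # index of the head token; 0 = root
    dep_label: str
    char_start: int = -1  # document-level offsets; -1 when absent
    char_end: int = -1


@dataclass
class SentenceParse:
    sentence_index: int
    tokens: list[ParsedToken] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        n = len(self.tokens)
        roots = 0
        for tok in self.tokens:
            if tok.head == tok.index:
                raise ConlluError(
                    f"sentence {self.sentence_index}: token {tok.index} is its "
                    "own head"
                )
            if not (0 <= tok.head <= n):
                raise ConlluError(
                    f"sentence {self.sentence_index}: head {tok.head} out of "
                    f"range for {n} tokens"
                )
            if tok.head == 0:
                roots += 1
        if n and roots != 1:
            raise ConlluError(
                f"sentence {self.sentence_index}: {roots} roots (need exactly 1)"
            )
        # Cycle check: every head chain must terminate at the root.
        for tok in self.tokens:
            seen = set()
            current = tok.index
            while current != 0:
                if current in seen:
                    raise ConlluError(
                        f"sentence {self.sentence_index}: cycle through token "
                        f"{current}"
                    )
                seen.add(current)
                current = self.tokens[current - 1].head

    def token(self, index: int) -> ParsedToken:
        return self.tokens[index - 1]

    def ancestors(self, index: int) -> list[int]:
        """Head chain from the token's head up to (excluding) the root."""
        chain = []
        current = self.token(index).head
        while current != 0:
            chain.append(current)
            current = self.token(current).head
        return chain

    def children(self, index: int) -> list[ParsedToken]:
        return [t for t in self.tokens if t.head == index]

    @property
    def char_start(self) -> int:
        return min((t.char_start for t in self.tokens if t.char_start >= 0), default=-1)

    @property
    def char_end(self) -> int:
        return max((t.char_end for t in self.tokens if t.char_end >= 0), default=-1)


_MISC_OFFSET_RE = re.compile(r"start=(\d+)\|end=(\d+)")


def read_conllu(path) -> dict[str, list[SentenceParse]]:
    """Parse a CoNLL-U file into per-document sentence lists.

    Multiword-token and empty-node lines (ids containing ``-`` or ``.``) are
    skipped.  Trees are validated (single root, acyclic) on construction.
    """
    with open(path, encoding="utf-8") as handle:
        return parse_conllu(handle)


def parse_conllu(lines: Iterable[str]) -> dict[str, list[SentenceParse]]:
    docs: dict[str, list[SentenceParse]] = {}
    doc_id: str | None = None
    tokens: list[ParsedToken] = []

    def flush() -> None:
        nonlocal tokens
        if tokens:
            if doc_id is None:
                raise ConlluError("sentence without a preceding '# doc_id =' comment")
            sentences = docs.setdefault(doc_id, [])
            sentences.append(
                SentenceParse(sentence_index=len(sentences), tokens=tokens)
            )
            tokens = []

    for raw in lines:
        line = raw.rstrip("\n")
        if not line.strip():
            flush()
            continue
        if line.startswith("#"):
            m = re.match(r"#\s*doc_id\s*=\s*(\S+)", line)
            if m:
                flush()
                doc_id = m.group(1)
                docs.setdefault(doc_id, [])
            continue
        fields = line.split("\t")
        if len(fields) != 10:
            raise ConlluError(f"expected 10 columns, got {len(fields)}: {line!r}")
        tok_id, form, _lemma, upos, xpos, _feats, head, deprel, _deps, misc = fields
        if "-" in tok_id or "." in tok_id:
            continue
        pos = xpos if xpos not in ("_", "") else upos
        offset = _MISC_OFFSET_RE.search(misc)
        tokens.append(
            ParsedToken(
                index=int(tok_id),
                word=form,
                pos=pos,
                head=int(head),
                dep_label=deprel,
                char_start=int(offset.group(1)) if offset else -1,
                char_end=int(offset.group(2)) if offset else -1,
            )
        )
    flush()
    return docs


def write_conllu(parses: dict[str, list[SentenceParse]], path) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        for doc_id, sentences in parses.items():
            handle.write(f"# doc_id = {doc_id}\n")
            for sent in sentences:
                for tok in sent.tokens:
                    misc = (
                        f"start={tok.char_start}|end={tok.char_end}"
                        if tok.char_start >= 0
                        else "_"
                    )
                    handle.write(
                        "\t".join(
                            [
                                str(tok.index),
                                tok.word,
                                "_",
                                "_",
                                tok.pos,
                                "_",
                                str(tok.head),
                                tok.dep_label,
                                "_",
                                misc,
                            ]
                        )
                        + "\n"
                    )
                handle.write("\n")


def is_verb(token: ParsedToken, verb_tagset: str = "penn") -> bool:
    """Penn tags starting with VB (incl. MD auxiliaries excluded) or UPOS VERB."""
    if verb_tagset == "penn":
        return token.pos.startswith("VB")
    if verb_tagset == "upos":
        return token.pos == "VERB"
    raise ValueError(f"unknown verb_tagset {verb_tagset!r}")


def governing_verb(
    parse: SentenceParse, token_index: int, verb_tagset: str = "penn"
) -> int | None:
    """First verb on the head chain from the token towards the root.

    The walk starts at the token's head, so a verb is never its own governing
    verb.  Returns the verb's token index, or ``None`` if the chain reaches
    the root without meeting a verb.
    """
    for ancestor in parse.ancestors(token_index):
        if is_verb(parse.token(ancestor), verb_tagset):
            return ancestor
    return None


def relating_word(parse: SentenceParse, index_a: int, index_b: int) -> int | None:
    """Lowest common ancestor with self-inclusive ancestor sets.

    The first word the two tokens have in common when each walks towards the
    root; if one token dominates the other, the dominating token itself.
    """
    chain_a = [index_a] + parse.ancestors(index_a)
    set_b = {index_b, *parse.ancestors(index_b)}
    for node in chain_a:
        if node in set_b:
            return node
    return None


DEFAULT_NEGATION_LEXICON = frozenset({"not", "no", "never", "without"})
DEFAULT_NEGATION_LABELS = frozenset({"neg"})
DEFAULT_ADVMOD_LABELS = frozenset({"advmod"})


def is_negated(
    parse: SentenceParse,
    token_index: int,
    negation_lexicon: frozenset[str] = DEFAULT_NEGATION_LEXICON,
    negation_labels: frozenset[str] = DEFAULT_NEGATION_LABELS,
    advmod_labels: frozenset[str] = DEFAULT_ADVMOD_LABELS,
) -> bool:
    """Negation modifier on the token's direct dependents.

    True iff some dependent bears a negation dependency label, or bears an
    adverbial-modifier label and its word is in the negation lexicon.
    """
    for child in parse.children(token_index):
        if child.dep_label in negation_labels:
            return True
        if child.dep_label in advmod_labels and child.word.lower() in negation_lexicon:
            return True
    return False
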