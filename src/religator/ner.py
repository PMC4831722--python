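"""Dictionary-based disease recognition and normalization.

The recognizer follows the Peregrine scheme: dictionary terms are tokenized,
stopwords removed and tokens stemmed; document text is scanned greedily
left-to-right for the longest indexed token sequence.  Post-processing then
(1) propagates concepts between abbreviations and their long forms,
(2) merges adjacent same-concept spans, (3) removes terms on a trained
exclusion list when their true-positive/false-positive ratio is below a
threshold (default 0.3; a ratio of exactly 0.3 is kept), and (4) maps source
concept identifiers to MeSH.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, NamedTuple, Sequence

from .abbreviations import find_abbreviations
from .corpus import DISEASE, UNMAPPED, Document, EntityMention
from .stemming import Normalizer, get_normalizer

logger = logging.getLogger(__name__)

_TOKEN_RE = re.compile(r"[0-9a-z]+")


class Token(NamedTuple):
    text: str  # case-folded surface
    start: int
    end: int


def tokenize(text: str) -> list[Token]:
    """Split on non-alphanumeric characters, case-fold, keep digits.

    Offsets index into the original string, so every token slices back to its
    (case-sensitive) surface form.
    """
    folded = text.lower()
    return [Token(m.group(), m.start(), m.end()) for m in _TOKEN_RE.finditer(folded)]


@dataclass(frozen=True)
class TermEntry:
    concept_id: str
    term: str


@dataclass
class TermIndex:
    """Dictionary terms indexed by normalized token sequence."""

    entries: dict[tuple[str, ...], frozenset[str]]
    stopwords: frozenset[str]
    normalizer_name: str
    max_len: int = 0

    @property
    def normalizer(self) -> Normalizer:
        return get_normalizer(self.normalizer_name)


def normalize_term(
    text: str, stopwords: frozenset[str], normalizer: Normalizer
) -> str:
    """Canonical key for a surface term: stemmed non-stopword tokens joined."""
    return " ".join(
        normalizer(t.text) for t in tokenize(text) if t.text not in stopwords
    )


def build_index(
    entries: Sequence[TermEntry],
    stopwords: Iterable[str] = (),
    normalizer: str = "builtin-suffix-stemmer",
) -> TermIndex:
    if not entries:
        raise ValueError("dictionary must contain at least one entry")
    stop = frozenset(s.lower() for s in stopwords)
    norm = get_normalizer(normalizer)
    index: dict[tuple[str, ...], set[str]] = {}
    for entry in entries:
        key = tuple(
            norm(t.text) for t in tokenize(entry.term) if t.text not in stop
        )
        if not key:
            logger.warning(
                "dictionary term %r (%s) reduces to an empty token sequence; "
                "dropped",
                entry.term,
                entry.concept_id,
            )
            continue
        index.setdefault(key, set()).add(entry.concept_id)
    return TermIndex(
        entries={k: frozenset(v) for k, v in index.items()},
        stopwords=stop,
        normalizer_name=normalizer,
        max_len=max((len(k) for k in index), default=0),
    )


@dataclass(frozen=True)
class ConceptSpan:
    """A recognized term span with its candidate concept identifiers."""

    start: int
    end: int
    concept_ids: frozenset[str]
    norm_term: str


def match_longest(
    tokens: Sequence[Token], index: TermIndex, *, skip_stopwords: bool = True
) -> list[ConceptSpan]:
    """Greedy left-to-right longest match against the term index.

    At each position the longest indexed token sequence wins; stopword tokens
    inside the document text are skipped during matching (configurable);
    matching resumes after the matched span.
    """
    norm = index.normalizer
    normalized = [norm(t.text) for t in tokens]
    spans: list[ConceptSpan] = []
    n = len(tokens)
    i = 0
    while i < n:
        if skip_stopwords and tokens[i].text in index.stopwords:
            i += 1
            continue
        positions: list[int] = []
        j = i
        while j < n and len(positions) < index.max_len:
            if skip_stopwords and tokens[j].text in index.stopwords:
                j += 1
                continue
            positions.append(j)
            j += 1
        matched = False
        for length in range(len(positions), 0, -1):
            key = tuple(normalized[p] for p in positions[:length])
            concepts = index.entries.get(key)
            if concepts:
                last = positions[length - 1]
                spans.append(
                    ConceptSpan(
                        start=tokens[i].start,
                        end=tokens[last].end,
                        concept_ids=concepts,
                        norm_term=" ".join(key),
                    )
                )
                i = last + 1
                matched = True
                break
        if not matched:
            i += 1
    return spans


def _word_occurrences(text: str, phrase: str) -> list[tuple[int, int]]:
    """Case-insensitive occurrences of ``phrase`` at word boundaries."""
    hits = []
    pattern = re.compile(
        r"(?<![0-9A-Za-z])" + re.escape(phrase) + r"(?![0-9A-Za-z])",
        re.IGNORECASE,
    )
    for m in pattern.finditer(text):
        hits.append((m.start(), m.end()))
    return hits


def _overlaps(a_start: int, a_end: int, spans: Iterable[ConceptSpan]) -> bool:
    return any(s.start < a_end and a_start < s.end for s in spans)


def propagate_abbreviations(
    text: str,
    spans: Sequence[ConceptSpan],
    stopwords: frozenset[str] = frozenset(),
    normalizer: Normalizer | None = None,
) -> list[ConceptSpan]:
    """Tag every occurrence of an abbreviation and its long form alike.

    If either form of a detected abbreviation pair carries a concept, all
    document occurrences of both forms receive that concept.  When the two
    forms disagree, the long form's concept wins and a warning is logged.
    """
    norm = normalizer or (lambda t: t)
    result = list(spans)
    for pair in find_abbreviations(text):
        long_concepts = frozenset().union(
            *(
                s.concept_ids
                for s in spans
                if s.start < pair.long_end and pair.long_start < s.end
            ),
            frozenset(),
        )
        short_concepts = frozenset().union(
            *(
                s.concept_ids
                for s in spans
                if s.start < pair.short_end and pair.short_start < s.end
            ),
            frozenset(),
        )
        if long_concepts and short_concepts and long_concepts != short_concepts:
            logger.warning(
                "abbreviation %r / %r carry conflicting concepts; keeping the "
                "long form's",
                pair.short_form,
                pair.long_form,
            )
        concepts = long_concepts or short_concepts
        if not concepts:
            continue
        for form in (pair.short_form, pair.long_form):
            for occ_start, occ_end in _word_occurrences(text, form):
                if _overlaps(occ_start, occ_end, result):
                    continue
                result.append(
                    ConceptSpan(
                        start=occ_start,
                        end=occ_end,
                        concept_ids=concepts,
                        norm_term=normalize_term(form, stopwords, norm),
                    )
                )
    return sorted(result, key=lambda s: (s.start, s.end))


_NO_ALNUM_RE = re.compile(r"^[^0-9A-Za-z]*$")


def merge_adjacent(text: str, spans: Sequence[ConceptSpan]) -> list[ConceptSpan]:
    """Merge same-concept spans separated only by whitespace/punctuation."""
    ordered = sorted(spans, key=lambda s: (s.start, s.end))
    merged: list[ConceptSpan] = []
    for span in ordered:
        if (
            merged
            and merged[-1].concept_ids == span.concept_ids
            and span.start >= merged[-1].end
            and _NO_ALNUM_RE.match(text[merged[-1].end : span.start])
        ):
            prev = merged.pop()
            merged.append(
                ConceptSpan(
                    start=prev.start,
                    end=span.end,
                    concept_ids=prev.concept_ids,
                    norm_term=(prev.norm_term + " " + span.norm_term).strip(),
                )
            )
        else:
            merged.append(span)
    return merged


#: term -> (true-positive count, false-positive count) from a training corpus
ExclusionList = dict[str, tuple[int, int]]


def apply_exclusion(
    spans: Sequence[ConceptSpan],
    exclusion: ExclusionList,
    ratio_threshold: float = 0.3,
) -> list[ConceptSpan]:
    """Drop spans whose term's TP/FP ratio is *lower than* the threshold.

    Terms with no false positives are always kept; a ratio exactly equal to
    the threshold is kept.  ``ratio_threshold=math.inf`` reproduces the
    stricter mode that removes every term ever seen as a false positive.
    """
    if ratio_threshold < 0:
        raise ValueError("ratio_threshold must be >= 0")
    kept = []
    for span in spans:
        counts = exclusion.get(span.norm_term)
        if counts is not None:
            tp, fp = counts
            if fp > 0 and tp / fp < ratio_threshold:
                continue
        kept.append(span)
    return kept


def build_exclusion_list(
    documents: Iterable[Document],
    predicted: dict[str, Sequence[ConceptSpan]],
    stopwords: frozenset[str] = frozenset(),
    normalizer: Normalizer | None = None,
) -> ExclusionList:
    """Term-level TP/FP tally of recognizer output against gold mentions.

    A predicted span counts as a true positive when it overlaps a gold disease
    mention; otherwise as a false positive.  Keys are normalized terms
    (stemmed, lowercased, stopwords removed).
    """
    tally: dict[str, list[int]] = {}
    for doc in documents:
        gold = [
            (m.start, m.end) for m in doc.mentions if m.entity_type == DISEASE
        ]
        for span in predicted.get(doc.doc_id, ()):
            hit = any(span.start < g_end and g_start < span.end for g_start, g_end in gold)
            entry = tally.setdefault(span.norm_term, [0, 0])
            entry[0 if hit else 1] += 1
    return {term: (tp, fp) for term, (tp, fp) in tally.items()}


#: source concept id -> MeSH identifier
MeshMap = dict[str, str]


def normalize_to_mesh(
    text: str,
    spans: Sequence[ConceptSpan],
    mesh_map: MeshMap,
    unmapped_policy: str = "drop",
) -> list[EntityMention]:
    """Translate concept ids to MeSH and emit disease mentions.

    ``unmapped_policy`` is ``"drop"`` (spans whose concepts all lack a mapping
    are removed and counted in a log summary) or ``"sentinel"`` (kept with the
    unmapped sentinel id).  Duplicate MeSH ids at one span are deduplicated.
    """
    if unmapped_policy not in ("drop", "sentinel"):
        raise ValueError(f"unknown unmapped_policy {unmapped_policy!r}")
    mentions: list[EntityMention] = []
    n_dropped = 0
    seen_spans: set[tuple[int, int]] = set()
    for span in spans:
        mesh_ids = sorted({mesh_map[c] for c in span.concept_ids if c in mesh_map})
        if not mesh_ids:
            if unmapped_policy == "drop":
                n_dropped += 1
                continue
            mesh_ids = [UNMAPPED]
        if (span.start, span.end) in seen_spans:
            continue
        seen_spans.add((span.start, span.end))
        mentions.append(
            EntityMention(
                start=span.start,
                end=span.end,
                text=text[span.start : span.end],
                entity_type=DISEASE,
                concept_ids=tuple(mesh_ids),
            )
        )
    if n_dropped:
        logger.info("normalize_to_mesh: dropped %d unmapped span(s)", n_dropped)
    return mentions


def _resolve_overlaps(spans: Sequence[ConceptSpan]) -> list[ConceptSpan]:
    """Longest-first, leftmost-first overlap resolution (final safety pass)."""
    chosen: list[ConceptSpan] = []
    for span in sorted(spans, key=lambda s: (-(s.end - s.start), s.start, s.end)):
        if not _overlaps(span.start, span.end, chosen):
            chosen.append(span)
    return sorted(chosen, key=lambda s: (s.start, s.end))


@dataclass(frozen=True)
class NerConfig:
    normalizer: str = "builtin-suffix-stemmer"
    ratio_threshold: float = 0.3
    unmapped_policy: str = "drop"
    skip_text_stopwords: bool = True


def recognize_diseases(
    document: Document,
    index: TermIndex,
    exclusion: ExclusionList,
    mesh_map: MeshMap,
    config: NerConfig = NerConfig(),
) -> Document:
    """Full recognition chain; returns a copy with disease mentions replaced.

    Stage order is fixed: tokenize, longest match, abbreviation propagation,
    adjacent-span merging, exclusion filtering, MeSH normalization.  Chemical
    mentions and gold relations on the document are preserved untouched.
    """
    text = document.text
    tokens = tokenize(text)
    spans = match_longest(tokens, index, skip_stopwords=config.skip_text_stopwords)
    spans = propagate_abbreviations(
        text, spans, index.stopwords, index.normalizer
    )
    spans = merge_adjacent(text, spans)
    spans = apply_exclusion(spans, exclusion, config.ratio_threshold)
    spans = _resolve_overlaps(spans)
    mentions = normalize_to_mesh(text, spans, mesh_map, config.unmapped_policy)
    kept = [m for m in document.mentions if m.entity_type != DISEASE]
    return Document(
        doc_id=document.doc_id,
        title=document.title,
        abstract=document.abstract,
        mentions=sorted(kept + mentions, key=lambda m: (m.start, m.end)),
        relations=set(document.relations),
    )


# ---------------------------------------------------------------------------
# Resource loaders


def load_dictionary(path, delimiter: str = "\t") -> list[TermEntry]:
    entries = []
    with open(path, encoding="utf-8") as handle:
        for line in handle:
            line = line.rstrip("\n")
            if not line:
                continue
            concept_id, term = line.split(delimiter, 1)
            entries.append(TermEntry(concept_id=concept_id, term=term))
    return entries


def load_mesh_map(path, delimiter: str = "\t") -> MeshMap:
    mapping: MeshMap = {}
    with open(path, encoding="utf-8") as handle:
        for line in handle:
            line = line.rstrip("\n")
            if not line:
                continue
            concept_id, mesh_id = line.split(delimiter, 1)
            mapping[concept_id] = mesh_id
    return mapping


def load_exclusion_list(path, delimiter: str = "\t") -> ExclusionList:
    excl: ExclusionList = {}
    with open(path, encoding="utf-8") as handle:
        for line in handle:
            line = line.rstrip("\n")
            if not line:
                continue
            term, tp, fp = line.split(delimiter)
            excl[term] = (int(tp), int(fp))
    return excl


def save_exclusion_list(exclusion: ExclusionList, path) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        for term in sorted(exclusion):
            tp, fp = exclusion[term]
            handle.write(f"{term}\t{tp}\t{fp}\n")


def default_stopwords() -> frozenset[str]:
    """The PubMed stopword list shipped with the package."""
    data = resources.files("religator").joinpath("data/pubmed_stopwords.txt")
    return frozenset(
        line.strip() for line in data.read_text("utf-8").splitlines() if line.strip()
    )


def load_stopwords(path) -> frozenset[str]:
    with open(path, encoding="utf-8") as handle:
        return frozenset(line.strip() for line in handle if line.strip())
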