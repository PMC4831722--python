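"""Abbreviation / long-form pair detection (Schwartz & Hearst pattern).

Finds ``long form (SF)`` patterns within a sentence and validates the pairing
by right-to-left character alignment: every alphanumeric character of the
short form must appear in the long form, in order, and the short form's first
character must start a word of the long form.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

# Sentence boundary: period/question/exclamation followed by whitespace.
_SENT_RE = re.compile(r"[.!?](?=\s)|\Z")
_PAREN_RE = re.compile(r"\(([^()]{1,40})\)")


@dataclass(frozen=True)
class AbbreviationPair:
    short_form: str
    long_form: str
    short_start: int  # document-level offsets of the defining occurrence
    short_end: int
    long_start: int
    long_end: int


def _valid_short_form(sf: str) -> bool:
    if not (2 <= len(sf) <= 10):
        return False
    if len(sf.split()) > 2:
        return False
    if not any(ch.isalpha() for ch in sf):
        return False
    return sf[0].isalnum()


def _best_long_form(sf: str, candidate: str) -> str | None:
    """Right-to-left alignment of the short form into the candidate text.

    Returns the matched long form (a suffix of ``candidate`` starting at a
    word boundary) or ``None`` if the alignment fails.
    """
    s_index = len(sf) - 1
    l_index = len(candidate) - 1
    while s_index >= 0:
        curr = sf[s_index].lower()
        if not curr.isalnum():
            s_index -= 1
            continue
        # The first short-form character must match the start of a word.
        while l_index >= 0 and (
            candidate[l_index].lower() != curr
            or (s_index == 0 and l_index > 0 and candidate[l_index - 1].isalnum())
        ):
            l_index -= 1
        if l_index < 0:
            return None
        l_index -= 1
        s_index -= 1
    start = candidate.rfind(" ", 0, l_index + 1) + 1
    return candidate[start:]


def _sentences(text: str) -> list[tuple[int, int]]:
    spans: list[tuple[int, int]] = []
    start = 0
    for m in _SENT_RE.finditer(text):
        end = m.end()
        if end > start:
            spans.append((start, end))
        start = end
        while start < len(text) and text[start].isspace():
            start += 1
    return spans


def find_abbreviations(text: str) -> list[AbbreviationPair]:
    """All validated long-form/short-form pairs in the text.

    Detection is restricted to one sentence (the defining parenthesis and its
    long form must not cross a sentence boundary); propagation of concepts to
    other occurrences is the caller's concern.
    """
    pairs: list[AbbreviationPair] = []
    for sent_start, sent_end in _sentences(text):
        sentence = text[sent_start:sent_end]
        for pm in _PAREN_RE.finditer(sentence):
            sf = pm.group(1).strip()
            if not _valid_short_form(sf):
                continue
            before = sentence[: pm.start()].rstrip()
            words = before.split()
            if not words:
                continue
            max_words = min(len(sf) + 5, len(sf) * 2)
            candidate = " ".join(words[-max_words:])
            lf = _best_long_form(sf, candidate)
            if lf is None or not lf.strip():
                continue
            lf = lf.strip()
            long_start = sent_start + before.rfind(lf)
            sf_inner = pm.group(1)
            sf_offset = pm.start(1) + sf_inner.index(sf)
            pairs.append(
                AbbreviationPair(
                    short_form=sf,
                    long_form=lf,
                    short_start=sent_start + sf_offset,
                    short_end=sent_start + sf_offset + len(sf),
                    long_start=long_start,
                    long_end=long_start + len(lf),
                )
            )
    return pairs
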