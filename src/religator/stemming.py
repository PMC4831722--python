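"""Pluggable token normalizers for dictionary matching.

Dictionary recognition matches stems rather than surface tokens so that
``seizure`` and ``seizures`` hit the same dictionary entry.  The original
system used the NLM Lexical Variant Generator; any consistent stemmer
preserves the mechanism, so the default here is a small rule-based suffix
stripper applied to a fixed point (hence idempotent), with ``identity``
available as a fallback and an adapter hook for external normalizers.
"""

from __future__ import annotations

from typing import Callable

Normalizer = Callable[[str], str]


class ConfigurationError(ValueError):
    """Raised for an unknown normalizer or scorer name."""


def identity(token: str) -> str:
    return token


_VOWELS = set("aeiou")


def _strip_once(word: str) -> str:
    # Plural endings
    if word.endswith("ies") and len(word) > 4:
        return word[:-3] + "y"
    if word.endswith("sses"):
        return word[:-2]
    if word.endswith("s") and len(word) > 3 and word[-2] not in "sui":
        return word[:-1]
    # Participle / adverb endings; require a remaining stem with a vowel
    for suffix in ("ing", "ed", "ly"):
        if word.endswith(suffix):
            stem = word[: -len(suffix)]
            if len(stem) >= 3 and any(ch in _VOWELS for ch in stem):
                return stem
    return word


def suffix_stem(token: str) -> str:
    """Builtin suffix stemmer: strip plural/participle endings to a fixed point.

    Iterating to a fixed point makes the function idempotent by construction.
    """
    word = token.lower()
    while True:
        stripped = _strip_once(word)
        if stripped == word:
            return word
        word = stripped


_REGISTRY: dict[str, Normalizer] = {
    "identity": identity,
    "builtin-suffix-stemmer": suffix_stem,
}


def register_normalizer(name: str, func: Normalizer) -> None:
    """Adapter hook: register an external normalizer under a name."""
    _REGISTRY[name] = func


def get_normalizer(name: str) -> Normalizer:
    try:
        return _REGISTRY[name]
    except KeyError:
        raise ConfigurationError(
            f"unknown normalizer {name!r}; known: {sorted(_REGISTRY)}"
        ) from None
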