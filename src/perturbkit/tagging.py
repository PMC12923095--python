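"""Coarse part-of-speech tagging and the medical-term lexicon.

Only four coarse categories gate perturbation eligibility: adjectives,
adverbs, verbs and nouns ("valid words"). Everything else — determiners,
adpositions, pronouns, conjunctions, auxiliaries, numbers — is left alone.

The bundled tagger is deterministic: a lexicon of common English function
and content words, then suffix heuristics, then a default of ``noun``
(the safe choice for out-of-vocabulary clinical vocabulary, which is
overwhelmingly nominal). Any callable ``token -> category`` can be injected
in its place.
"""

from __future__ import annotations

import functools
import importlib.resources
from typing import Callable, FrozenSet, Iterable

#: Coarse POS categories produced by the bundled tagger.
POS_CATEGORIES = frozenset(
    {
        "noun",
        "verb",
        "adjective",
        "adverb",
        "adposition",
        "determiner",
        "pronoun",
        "conjunction",
        "auxiliary",
        "number",
        "other",
    }
)

#: Categories eligible for perturbation by default.
DEFAULT_VALID_POS: FrozenSet[str] = frozenset({"adjective", "adverb", "verb", "noun"})

Tagger = Callable[[str], str]

_SUFFIX_RULES = (
    ("ly", "adverb"),
    ("tion", "noun"),
    ("sion", "noun"),
    ("ment", "noun"),
    ("ness", "noun"),
    ("ity", "noun"),
    ("itis", "noun"),
    ("osis", "noun"),
    ("oma", "noun"),
    ("ful", "adjective"),
    ("ous", "adjective"),
    ("ive", "adjective"),
    ("ic", "adjective"),
    ("able", "adjective"),
    ("ible", "adjective"),
    ("al", "adjective"),
    ("ize", "verb"),
    ("ise", "verb"),
    ("ing", "verb"),
    ("ed", "verb"),
)


def _read_data_text(name: str) -> str:
    return importlib.resources.files("perturbkit.data").joinpath(name).read_text("utf-8")


def _normalise(token: str) -> str:
    t = token.lower()
    for suf in ("’s", "'s"):
        if t.endswith(suf):
            t = t[: -len(suf)]
    return t


class RuleBasedTagger:
    """Deterministic lexicon + suffix tagger over single word tokens."""

    def __init__(self, extra_lexicon: dict[str, str] | None = None):
        self._lexicon: dict[str, str] = {}
        for line in _read_data_text("pos_lexicon.tsv").splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            word, pos = line.split("\t")
            self._lexicon[word] = pos
        if extra_lexicon:
            self._lexicon.update(extra_lexicon)

    def __call__(self, token: str) -> str:
        t = _normalise(token)
        if not t:
            return "other"
        if t in self._lexicon:
            return self._lexicon[t]
        if any(ch.isdigit() for ch in t):
            return "number"
        for suffix, pos in _SUFFIX_RULES:
            # suffix rules need a real stem left over
            if t.endswith(suffix) and len(t) > len(suffix) + 2:
                return pos
        return "noun"


@functools.lru_cache(maxsize=1)
def default_tagger() -> RuleBasedTagger:
    return RuleBasedTagger()


def load_medical_lexicon(path: str | None = None) -> FrozenSet[str]:
    """Load a newline-delimited lowercase medical-term lexicon.

    With no ``path`` the small bundled default lexicon is returned.
    """
    if path is None:
        text = _read_data_text("medical_terms.txt")
    else:
        with open(path, encoding="utf-8") as fh:
            text = fh.read()
    return frozenset(w.strip().lower() for w in text.splitlines() if w.strip())


def is_medical(token: str, lexicon: Iterable[str]) -> bool:
    """Lexicon membership for a token, tolerant of possessives and plurals."""
    lex = lexicon if isinstance(lexicon, (set, frozenset)) else frozenset(lexicon)
    t = _normalise(token)
    if t in lex:
        return True
    if t.endswith("es") and t[:-2] in lex:
        return True
    if t.endswith("s") and t[:-1] in lex:
        return True
    return False
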