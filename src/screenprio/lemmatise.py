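"""Pluggable lemmatisation and lightweight part-of-speech tagging.

Reference text is tokenised into (surface, lemma, pos) triples.  The shipped
default is a deterministic rule-based English lemmatiser: plural stripping
plus a small set of verb-suffix rules.  Anything smarter (a biomedical
tagger, spaCy, ...) can be plugged in by implementing :class:`Lemmatiser`.

Part-of-speech tags follow a coarse Penn-style scheme and are only consumed
by the multiword-term extractor, which needs to recognise runs of
adjectives/nouns.  Tags:

``NN``  noun (the default open-class tag)
``JJ``  adjective (suffix heuristics)
``CD``  numeral
``IN``  function word (from the stop list)
"""

from __future__ import annotations

from importlib import resources
from typing import Protocol

__all__ = [
    "Lemmatiser",
    "RuleLemmatiser",
    "default_lemmatiser",
    "default_stoplist",
]

_ADJ_SUFFIXES = (
    "al", "ous", "ive", "ic", "ary", "able", "ible", "ful",
    "less", "ent", "ant", "ish", "ile",
)


def default_stoplist() -> frozenset[str]:
    """The versioned English stop list shipped with the package."""
    text = resources.files("screenprio").joinpath("data/stopwords.txt").read_text("utf-8")
    return frozenset(w for w in text.split() if w)


class Lemmatiser(Protocol):
    """Maps a lowercased surface token to a ``(lemma, pos)`` pair."""

    def __call__(self, surface: str) -> tuple[str, str]: ...


class RuleLemmatiser:
    """Deterministic rule-based lemmatiser.

    Rules (applied to the lowercased surface, first match wins):

    * ``-ies`` -> ``-y``           (studies -> study)
    * ``-ches/-shes/-sses/-xes/-zes`` -> strip ``es``  (matches -> match)
    * trailing ``-s`` stripped unless the word ends ``-ss``/``-us``/``-is``
      (trials -> trial, analysis stays)
    * ``-ised``/``-ized`` -> strip the ``d`` (randomised -> randomise)

    Deliberately minimal: determinism and transparency are favoured over
    linguistic coverage, and residual inflection only fragments rare
    vocabulary entries below the frequency cut-off anyway.
    """

    def __init__(self, stoplist: frozenset[str] | None = None):
        self._stoplist = default_stoplist() if stoplist is None else stoplist

    def lemma(self, word: str) -> str:
        w = word.lower()
        if len(w) > 3 and w.endswith("ies"):
            return w[:-3] + "y"
        if len(w) > 4 and w.endswith(("ches", "shes", "sses", "xes", "zes")):
            return w[:-2]
        if len(w) > 3 and w.endswith("s") and not w.endswith(("ss", "us", "is")):
            return w[:-1]
        if len(w) > 4 and w.endswith(("ised", "ized")):
            return w[:-1]
        return w

    def pos(self, word: str) -> str:
        w = word.lower()
        if w in self._stoplist:
            return "IN"
        if w.isdigit():
            return "CD"
        if len(w) > 4 and w.endswith(_ADJ_SUFFIXES):
            return "JJ"
        return "NN"

    def __call__(self, surface: str) -> tuple[str, str]:
        return self.lemma(surface), self.pos(surface)


def default_lemmatiser() -> RuleLemmatiser:
    return RuleLemmatiser()
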