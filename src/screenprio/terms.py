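"""Multiword term candidates scored by the C-value method.

Candidate terms are contiguous lemma n-grams drawn from noun-phrase runs —
token sequences tagged adjective/noun and ending in a noun (POS regex
``(JJ|NN)* NN``, length ≥ 2).  Termhood combines the candidate's length,
frequency and nesting:

    C-value(t) = log2|t| · f(t)                                if t is not
                                                               nested,
    C-value(t) = log2|t| · ( f(t) − (1/|T_t|) Σ_{s∈T_t} f(s) ) otherwise,

where f(t) counts every occurrence of the n-gram in the corpus, and T_t is
the set of longer extracted candidates that contain t.  Longer collocations
therefore discount their fragments.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

from .corpus import Collection, TokenisedDocument, tokenise_collection
from .lemmatise import Lemmatiser

__all__ = ["TermCandidate", "extract_terms", "write_terms"]

MAX_NGRAM = 6
_NP_TAGS = {"JJ", "NN"}


@dataclass
class TermCandidate:
    surface: str
    length_words: int
    frequency: int
    nested_in: frozenset[str] = field(default_factory=frozenset)
    c_value: float = 0.0


def _np_runs(doc: TokenisedDocument) -> list[list[str]]:
    """Maximal runs of adjective/noun tokens (lemma form)."""
    runs: list[list[str]] = []
    current: list[tuple[str, str]] = []
    for _, lemma, pos in doc.tokens:
        if pos in _NP_TAGS:
            current.append((lemma, pos))
        else:
            if current:
                runs.append(current)
            current = []
    if current:
        runs.append(current)
    # trim trailing adjectives: a candidate must end in a noun
    out = []
    for run in runs:
        while run and run[-1][1] != "NN":
            run = run[:-1]
        if len(run) >= 2:
            out.append([lemma for lemma, _ in run])
    return out


def extract_terms(
    collection: Collection,
    lemmatiser: Lemmatiser | None = None,
    tokenised: dict[str, tuple[TokenisedDocument, TokenisedDocument]] | None = None,
    max_ngram: int = MAX_NGRAM,
) -> list[TermCandidate]:
    """Extract and score multiword term candidates over the collection.

    Returns candidates sorted by C-value descending (ties by surface form),
    invariant to document order.
    """
    docs = tokenised if tokenised is not None else tokenise_collection(collection, lemmatiser)
    freq: Counter[tuple[str, ...]] = Counter()
    for ref_id in collection.ids:
        for doc in docs[ref_id]:
            for run in _np_runs(doc):
                # noun-final sub-n-grams of each run
                n = len(run)
                for length in range(2, min(max_ngram, n) + 1):
                    for start in range(0, n - length + 1):
                        freq[tuple(run[start : start + length])] += 1
    if not freq:
        return []

    # containment inverted: each candidate registers itself with every
    # strictly shorter contiguous sub-n-gram it contains
    containers: dict[tuple[str, ...], set[tuple[str, ...]]] = {}
    for h in freq:
        n = len(h)
        for length in range(2, n):
            for start in range(0, n - length + 1):
                sub = h[start : start + length]
                if sub in freq:
                    containers.setdefault(sub, set()).add(h)

    out: list[TermCandidate] = []
    for g, f in freq.items():
        longer = containers.get(g, set())
        if longer:
            discount = sum(freq[h] for h in longer) / len(longer)
            c_val = math.log2(len(g)) * (f - discount)
        else:
            c_val = math.log2(len(g)) * f
        out.append(
            TermCandidate(
                surface=" ".join(g),
                length_words=len(g),
                frequency=f,
                nested_in=frozenset(" ".join(h) for h in longer),
                c_value=c_val,
            )
        )
    out.sort(key=lambda t: (-t.c_value, t.surface))
    return out


def write_terms(terms: list[TermCandidate], path: str | Path) -> Path:
    """Serialise the scored term list as TSV (term, length, frequency, c_value)."""
    path = Path(path)
    lines = ["term\tlength\tfrequency\tc_value"]
    lines += [
        f"{t.surface}\t{t.length_words}\t{t.frequency}\t{t.c_value:.6g}" for t in terms
    ]
    path.write_text("\n".join(lines) + "\n", "utf-8")
    return path
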