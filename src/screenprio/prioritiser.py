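"""Relevancy classifier and active-learning screening session.

The relevancy model is a linear support vector classifier with the
L2-regularised squared-hinge loss, solved in the dual by coordinate descent
(liblinear, via scikit-learn) with cost C = 1 and stopping tolerance
ε = 0.1 by default.  Decision values w·x + b are mapped through the
logistic function to inclusion confidences in (0, 1); a user-chosen
threshold turns a confidence into an include/exclude prediction.

A :class:`ScreeningSession` tracks decisions in order, refuses to train
before both classes are present (cold start), re-ranks the unscreened
references by confidence after each retrain, and raises a reminder flag
after ``reminder_interval`` (default 25) decisions without a model update.

A small Boolean query language over indexed lemmas, extracted multiword
terms, topic ids and cluster ids (``AND`` / ``OR`` / ``NOT``, parentheses,
``topic:3``, ``cluster:2``, quoted phrases) provides the in-memory keyword
filter used to restrict rankings.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import scipy.sparse as sp
from sklearn.svm import LinearSVC

from .corpus import Collection, TokenisedDocument, tokenise_collection
from .errors import (
    ColdStartError,
    ConfigurationError,
    DecisionConflictError,
    QueryParseError,
)
from .features import FeatureMatrix
from .lda import TopicModel
from .lemmatise import Lemmatiser, default_lemmatiser

__all__ = [
    "ClassifierConfig",
    "LinearModel",
    "Ranking",
    "ScreeningSession",
    "train",
    "confidence",
    "predict",
    "rank",
    "CollectionIndex",
    "keyword_filter",
]


@dataclass(frozen=True)
class ClassifierConfig:
    cost_C: float = 1.0
    tolerance_eps: float = 0.1
    confidence_threshold: float = 0.5
    reminder_interval: int = 25
    seed: int = 0

    def __post_init__(self):
        if self.cost_C <= 0:
            raise ConfigurationError("cost_C must be positive")
        if self.tolerance_eps <= 0:
            raise ConfigurationError("tolerance_eps must be positive")
        if not 0 < self.confidence_threshold < 1:
            raise ConfigurationError("confidence_threshold must lie in (0, 1)")


@dataclass(frozen=True)
class LinearModel:
    weights: np.ndarray
    bias: float

    def decision_value(self, x) -> np.ndarray:
        x = sp.csr_matrix(x) if not sp.issparse(x) else x
        return np.asarray(x @ self.weights).ravel() + self.bias


def train(
    X: sp.spmatrix | np.ndarray,
    y: np.ndarray,
    config: ClassifierConfig | None = None,
) -> LinearModel:
    """Fit the squared-hinge linear SVM on labelled screening decisions.

    ``y`` holds +1 (include) / −1 or 0 (exclude).  Raises
    :class:`ColdStartError` unless both classes are present.
    """
    config = config or ClassifierConfig()
    y = np.asarray(y).ravel()
    y = np.where(y > 0, 1, -1)
    if len(np.unique(y)) < 2:
        raise ColdStartError(
            "training needs at least one include and one exclude; screen a "
            "random sample or use keyword search to find both classes first"
        )
    clf = LinearSVC(
        loss="squared_hinge",
        penalty="l2",
        dual=True,
        C=config.cost_C,
        tol=config.tolerance_eps,
        fit_intercept=True,
        intercept_scaling=1.0,
        random_state=config.seed,
        max_iter=10000,
    )
    clf.fit(X, y)
    return LinearModel(weights=clf.coef_.ravel().copy(), bias=float(clf.intercept_[0]))


def confidence(model: LinearModel, x) -> np.ndarray | float:
    """Inclusion confidence: logistic of the decision value, in (0, 1)."""
    values = model.decision_value(x)
    out = 1.0 / (1.0 + np.exp(-values))
    return float(out[0]) if out.size == 1 else out


def predict(model: LinearModel, x, threshold: float = 0.5) -> np.ndarray | str:
    """Include iff confidence ≥ threshold (boundary counts as include)."""
    if not 0 < threshold <= 1:
        raise ConfigurationError("threshold must lie in (0, 1]")
    conf = np.atleast_1d(confidence(model, x))
    labels = np.where(conf >= threshold, "include", "exclude")
    return str(labels[0]) if labels.size == 1 else labels


@dataclass(frozen=True)
class Ranking:
    """Unscreened references sorted by confidence descending, ties by id."""

    entries: tuple[tuple[str, float], ...]

    @property
    def ids(self) -> list[str]:
        return [e[0] for e in self.entries]

    def top(self, n: int) -> list[str]:
        return self.ids[:n]

    def __len__(self) -> int:
        return len(self.entries)


def rank(
    ids: list[str], confidences: dict[str, float], screened: set[str]
) -> Ranking:
    unscreened = [i for i in ids if i not in screened]
    ordered = sorted(unscreened, key=lambda i: (-confidences[i], i))
    return Ranking(entries=tuple((i, confidences[i]) for i in ordered))


class ScreeningSession:
    """Decision log + model + confidences for one screening task.

    The topic/TF-IDF features are computed once at ingest and reused across
    retrains; only the classifier is refitted as decisions accumulate.
    """

    def __init__(
        self,
        collection: Collection,
        features: FeatureMatrix,
        config: ClassifierConfig | None = None,
    ):
        if features.doc_ids != collection.ids:
            raise ConfigurationError("feature matrix does not match the collection")
        self.collection = collection
        self.features = features
        self.config = config or ClassifierConfig()
        self.decisions: dict[str, str] = {}  # insertion-ordered
        self.model: LinearModel | None = None
        self.confidences: dict[str, float] = {}
        self.decisions_since_update = 0

    # -- decision log -------------------------------------------------------
    def record_decision(self, ref_id: str, decision: str) -> None:
        if ref_id not in self.collection:
            raise ConfigurationError(f"unknown reference id {ref_id!r}")
        if ref_id in self.decisions:
            raise DecisionConflictError(
                f"{ref_id!r} already screened; use revise_decision to change it"
            )
        if decision not in ("include", "exclude"):
            raise ConfigurationError(f"bad decision {decision!r}")
        self.decisions[ref_id] = decision
        self.decisions_since_update += 1

    def revise_decision(self, ref_id: str, decision: str) -> None:
        if ref_id not in self.decisions:
            raise ConfigurationError(f"{ref_id!r} has not been screened")
        self.decisions[ref_id] = decision
        self.decisions_since_update += 1

    @property
    def reminder_due(self) -> bool:
        return self.decisions_since_update >= self.config.reminder_interval

    def n_included(self) -> int:
        return sum(1 for d in self.decisions.values() if d == "include")

    def can_train(self) -> bool:
        n_inc = self.n_included()
        return 0 < n_inc < len(self.decisions)

    # -- model --------------------------------------------------------------
    def retrain(self) -> LinearModel:
        ids = self.collection.ids
        decided = [i for i in ids if i in self.decisions]
        rows = [ids.index(i) for i in decided]
        y = np.array([1 if self.decisions[i] == "include" else -1 for i in decided])
        self.model = train(self.features.matrix[rows], y, self.config)
        conf = np.atleast_1d(confidence(self.model, self.features.matrix))
        self.confidences = dict(zip(ids, conf.tolist()))
        self.decisions_since_update = 0
        return self.model

    def ranking(self) -> Ranking:
        if self.model is None:
            raise ColdStartError("no model yet: call retrain() after screening both classes")
        return rank(self.collection.ids, self.confidences, set(self.decisions))

    def random_batch(self, n: int, rng: np.random.Generator) -> list[str]:
        """Uniform sample of unscreened references for cold-start screening."""
        pool = [i for i in self.collection.ids if i not in self.decisions]
        n = min(n, len(pool))
        idx = rng.choice(len(pool), size=n, replace=False)
        return [pool[int(j)] for j in idx]

    # -- persistence --------------------------------------------------------
    def save(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {
            "config": {
                "cost_C": self.config.cost_C,
                "tolerance_eps": self.config.tolerance_eps,
                "confidence_threshold": self.config.confidence_threshold,
                "reminder_interval": self.config.reminder_interval,
                "seed": self.config.seed,
            },
            "decisions": list(self.decisions.items()),
            "decisions_since_update": self.decisions_since_update,
            "model": None
            if self.model is None
            else {"weights": self.model.weights.tolist(), "bias": self.model.bias},
        }
        path.write_text(json.dumps(payload), "utf-8")
        return path

    def restore(self, path: str | Path) -> None:
        payload = json.loads(Path(path).read_text("utf-8"))
        self.config = ClassifierConfig(**payload["config"])
        self.decisions = dict(payload["decisions"])
        self.decisions_since_update = payload["decisions_since_update"]
        if payload["model"] is not None:
            self.model = LinearModel(
                weights=np.asarray(payload["model"]["weights"]),
                bias=payload["model"]["bias"],
            )
            conf = np.atleast_1d(confidence(self.model, self.features.matrix))
            self.confidences = dict(zip(self.collection.ids, conf.tolist()))


# ---------------------------------------------------------------------------
# Boolean keyword filter
# ---------------------------------------------------------------------------

_QUERY_TOKEN = re.compile(r'\(|\)|"[^"]*"|[^\s()]+')


class CollectionIndex:
    """In-memory keyword index over lemmas, terms, topics and clusters."""

    def __init__(
        self,
        collection: Collection,
        lemmatiser: Lemmatiser | None = None,
        topic_model: TopicModel | None = None,
        cluster_labels: dict[str, int] | None = None,
        tokenised: dict[str, tuple[TokenisedDocument, TokenisedDocument]] | None = None,
    ):
        self._lem = lemmatiser or default_lemmatiser()
        docs = tokenised if tokenised is not None else tokenise_collection(collection, self._lem)
        self.all_ids = frozenset(collection.ids)
        self._lemma_to_ids: dict[str, set[str]] = {}
        self._sequences: dict[str, list[str]] = {}
        for ref_id, (title_doc, abstract_doc) in docs.items():
            seq = title_doc.lemmas + abstract_doc.lemmas
            self._sequences[ref_id] = seq
            for lem in set(seq):
                self._lemma_to_ids.setdefault(lem, set()).add(ref_id)
        self._argmax_topic: dict[str, int] = {}
        if topic_model is not None:
            am = topic_model.doc_topic.argmax(axis=1)
            self._argmax_topic = dict(zip(topic_model.doc_ids, am.tolist()))
        self._clusters = dict(cluster_labels or {})

    def lemma_ids(self, word: str) -> set[str]:
        lemma, _ = self._lem(word.lower())
        return set(self._lemma_to_ids.get(lemma, set()))

    def phrase_ids(self, phrase: str) -> set[str]:
        lemmas = [self._lem(w.lower())[0] for w in re.findall(r"[A-Za-z0-9]+", phrase)]
        if not lemmas:
            return set()
        if len(lemmas) == 1:
            return self.lemma_ids(lemmas[0])
        m = len(lemmas)
        hits = set()
        for ref_id, seq in self._sequences.items():
            for i in range(len(seq) - m + 1):
                if seq[i : i + m] == lemmas:
                    hits.add(ref_id)
                    break
        return hits

    def topic_ids(self, topic: int) -> set[str]:
        """References whose argmax topic is ``topic``."""
        return {i for i, k in self._argmax_topic.items() if k == topic}

    def topic_member_ids(self, topic: int, topic_model: TopicModel) -> set[str]:
        """Alternative reading: membership in the topic's 45-reference list."""
        return set(topic_model.top_refs[topic])

    def cluster_ids(self, cluster: int) -> set[str]:
        return {i for i, c in self._clusters.items() if c == cluster}


def keyword_filter(index: CollectionIndex, query: str) -> set[str]:
    """Evaluate a Boolean keyword expression against the index.

    Grammar: ``expr := or`` ; ``or := and (OR and)*`` ;
    ``and := unary (AND unary)*`` ; ``unary := NOT unary | atom`` ;
    ``atom := '(' expr ')' | topic:N | cluster:N | "phrase" | word``.
    """
    tokens = []
    for m in _QUERY_TOKEN.finditer(query):
        tokens.append((m.group(0), m.start()))
    pos = 0

    def peek():
        return tokens[pos][0] if pos < len(tokens) else None

    def advance():
        nonlocal pos
        tok = tokens[pos]
        pos += 1
        return tok

    def parse_or() -> set[str]:
        result = parse_and()
        while peek() is not None and peek().upper() == "OR":
            advance()
            result = result | parse_and()
        return result

    def parse_and() -> set[str]:
        result = parse_unary()
        while peek() is not None and peek().upper() == "AND":
            advance()
            result = result & parse_unary()
        return result

    def parse_unary() -> set[str]:
        tok = peek()
        if tok is None:
            raise QueryParseError("unexpected end of query", len(query))
        if tok.upper() == "NOT":
            advance()
            return index.all_ids - parse_unary()
        return parse_atom()

    def parse_atom() -> set[str]:
        if peek() is None:
            raise QueryParseError("unexpected end of query", len(query))
        tok, at = advance()
        if tok == "(":
            inner = parse_or()
            if peek() != ")":
                raise QueryParseError("missing closing parenthesis", at)
            advance()
            return inner
        if tok == ")":
            raise QueryParseError("unmatched closing parenthesis", at)
        if tok.upper() in ("AND", "OR"):
            raise QueryParseError(f"operator {tok!r} needs a left operand", at)
        if tok.startswith('"'):
            return index.phrase_ids(tok.strip('"'))
        if ":" in tok:
            kind, _, value = tok.partition(":")
            if not value.isdigit():
                raise QueryParseError(f"{kind}: requires a numeric id", at)
            if kind.lower() == "topic":
                return index.topic_ids(int(value))
            if kind.lower() == "cluster":
                return index.cluster_ids(int(value))
            raise QueryParseError(f"unknown filter kind {kind!r}", at)
        return index.lemma_ids(tok)

    if not tokens:
        raise QueryParseError("empty query", 0)
    result = parse_or()
    if pos != len(tokens):
        raise QueryParseError(f"trailing tokens starting at {tokens[pos][0]!r}",
                              tokens[pos][1])
    return result
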