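"""Latent Dirichlet allocation by collapsed Gibbs sampling.

Topic proportions serve three purposes in the screening workflow: a
visual-search handle (each topic summarised by its 5 most frequent words and
its 45 most associated references), a similarity measure between references
(cosine of their proportion vectors), and a feature block for the relevancy
classifier.

The sampler is the standard collapsed Gibbs scheme: token-topic assignments
are resampled from

    p(z = k) ∝ (n_dk + α_k) (n_kw + β) / (n_k + Vβ)

and document proportions are estimated as θ_dk = (n_dk + α_k) / (L_d + Σα).
Defaults follow common practice for screening corpora: K = 300 topics,
symmetric α = 1/K, β = 0.01, with the symmetric-α Minka fixed-point update
applied every ``optimise_interval`` sweeps (0 disables it).  The inner loop
is numba-compiled; the fit is deterministic given the seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from numba import njit
from scipy.special import psi

from .corpus import Collection, TokenisedDocument, Vocabulary, tokenise_collection
from .errors import ConfigurationError
from .lemmatise import Lemmatiser

__all__ = ["TopicModelParams", "TopicModel", "fit_lda", "infer_topics", "topic_similarity"]

N_TOP_WORDS = 5
N_TOP_REFS = 45


@dataclass(frozen=True)
class TopicModelParams:
    K: int = 300
    alpha: float | None = None  # None -> 1/K
    beta: float = 0.01
    n_iterations: int = 1000
    optimise_interval: int = 50
    seed: int = 0

    def __post_init__(self):
        if self.K < 2:
            raise ConfigurationError("K must be >= 2")
        if self.alpha is not None and self.alpha <= 0:
            raise ConfigurationError("alpha must be positive")
        if self.beta <= 0:
            raise ConfigurationError("beta must be positive")
        if self.optimise_interval < 0:
            raise ConfigurationError("optimise_interval must be >= 0 (0 disables)")

    @property
    def alpha_value(self) -> float:
        return 1.0 / self.K if self.alpha is None else self.alpha


@dataclass
class TopicModel:
    params: TopicModelParams
    topic_word_counts: np.ndarray  # (K, V) integer counts
    doc_topic: np.ndarray          # (N, K) proportions, rows on the simplex
    alpha: np.ndarray              # (K,) symmetric prior after optimisation
    vocabulary_index: dict[str, int]
    doc_ids: list[str]
    top_words: list[list[str]] = field(default_factory=list)
    top_refs: list[list[str]] = field(default_factory=list)

    @property
    def K(self) -> int:
        return self.topic_word_counts.shape[0]

    def theta(self, ref_id: str) -> np.ndarray:
        return self.doc_topic[self.doc_ids.index(ref_id)]

    def save(self, path: str | Path) -> Path:
        """Serialise parameters and counts as JSON + a dense theta TSV."""
        path = Path(path)
        payload = {
            "params": {
                "K": self.params.K,
                "alpha": self.params.alpha,
                "beta": self.params.beta,
                "n_iterations": self.params.n_iterations,
                "optimise_interval": self.params.optimise_interval,
                "seed": self.params.seed,
            },
            "alpha": self.alpha.tolist(),
            "topic_word_counts": self.topic_word_counts.tolist(),
            "vocabulary_index": self.vocabulary_index,
            "doc_ids": self.doc_ids,
            "top_words": self.top_words,
            "top_refs": self.top_refs,
        }
        path.write_text(json.dumps(payload), "utf-8")
        theta_path = path.with_suffix(".theta.tsv")
        np.savetxt(theta_path, self.doc_topic, delimiter="\t", fmt="%.8g")
        return path

    @classmethod
    def load(cls, path: str | Path) -> "TopicModel":
        path = Path(path)
        payload = json.loads(path.read_text("utf-8"))
        params = TopicModelParams(**payload["params"])
        theta = np.loadtxt(path.with_suffix(".theta.tsv"), delimiter="\t", ndmin=2)
        return cls(
            params=params,
            topic_word_counts=np.asarray(payload["topic_word_counts"], dtype=np.int64),
            doc_topic=theta,
            alpha=np.asarray(payload["alpha"], dtype=np.float64),
            vocabulary_index=payload["vocabulary_index"],
            doc_ids=payload["doc_ids"],
            top_words=payload["top_words"],
            top_refs=payload["top_refs"],
        )


@njit(cache=True)
def _gibbs_sweeps(doc_of, word_of, z, ndk, nkw, nk, alpha, beta, n_sweeps, seed):
    np.random.seed(seed)
    n_tokens = word_of.shape[0]
    K = ndk.shape[1]
    V = nkw.shape[1]
    vbeta = V * beta
    cum = np.empty(K)
    for _ in range(n_sweeps):
        for t in range(n_tokens):
            d = doc_of[t]
            w = word_of[t]
            k = z[t]
            ndk[d, k] -= 1
            nkw[k, w] -= 1
            nk[k] -= 1
            acc = 0.0
            for kk in range(K):
                acc += (ndk[d, kk] + alpha[kk]) * (nkw[kk, w] + beta) / (nk[kk] + vbeta)
                cum[kk] = acc
            u = np.random.random() * acc
            k = np.searchsorted(cum, u)
            if k >= K:
                k = K - 1
            z[t] = k
            ndk[d, k] += 1
            nkw[k, w] += 1
            nk[k] += 1


def _tokens_to_ids(
    docs: list[tuple[TokenisedDocument, TokenisedDocument]], vocab_index: dict[str, int]
) -> list[np.ndarray]:
    out = []
    for title_doc, abstract_doc in docs:
        ids = [
            vocab_index[lem]
            for lem in title_doc.lemmas + abstract_doc.lemmas
            if lem in vocab_index
        ]
        out.append(np.asarray(ids, dtype=np.int64))
    return out


def _optimise_symmetric_alpha(alpha: float, ndk: np.ndarray, K: int) -> float:
    """One Minka fixed-point step for a symmetric Dirichlet concentration."""
    lengths = ndk.sum(axis=1)
    num = psi(ndk + alpha).sum() - ndk.size * psi(alpha)
    den = K * (psi(lengths + K * alpha) - psi(K * alpha)).sum()
    if den <= 0 or not np.isfinite(num) or num <= 0:
        return alpha
    return float(max(alpha * num / den, 1e-8))


def fit_lda(
    collection: Collection,
    vocabulary: Vocabulary,
    params: TopicModelParams | None = None,
    lemmatiser: Lemmatiser | None = None,
    tokenised: dict[str, tuple[TokenisedDocument, TokenisedDocument]] | None = None,
) -> TopicModel:
    """Fit the topic model on titles + abstracts of the whole collection."""
    params = params or TopicModelParams()
    if len(collection) < params.K:
        import warnings

        warnings.warn(
            f"collection has {len(collection)} documents < K={params.K} topics",
            stacklevel=2,
        )
    docs_map = tokenised if tokenised is not None else tokenise_collection(collection, lemmatiser)
    doc_ids = collection.ids
    token_ids = _tokens_to_ids([docs_map[i] for i in doc_ids], vocabulary.entries)
    n_tokens = int(sum(len(t) for t in token_ids))
    if n_tokens == 0:
        raise ConfigurationError("no in-vocabulary tokens: cannot fit a topic model")

    K, V = params.K, len(vocabulary)
    doc_of = np.concatenate(
        [np.full(len(t), d, dtype=np.int64) for d, t in enumerate(token_ids)]
    )
    word_of = np.concatenate(token_ids)
    rng = np.random.default_rng(params.seed)
    z = rng.integers(0, K, size=n_tokens).astype(np.int64)
    ndk = np.zeros((len(doc_ids), K), dtype=np.int64)
    nkw = np.zeros((K, V), dtype=np.int64)
    nk = np.zeros(K, dtype=np.int64)
    np.add.at(ndk, (doc_of, z), 1)
    np.add.at(nkw, (z, word_of), 1)
    np.add.at(nk, z, 1)

    alpha_val = params.alpha_value
    interval = params.optimise_interval or params.n_iterations
    done = 0
    chunk_seed = params.seed
    while done < params.n_iterations:
        sweeps = min(interval, params.n_iterations - done)
        alpha = np.full(K, alpha_val)
        _gibbs_sweeps(doc_of, word_of, z, ndk, nkw, nk, alpha, params.beta,
                      sweeps, (chunk_seed * 2654435761 + done) % (2**31 - 1))
        done += sweeps
        if params.optimise_interval and done < params.n_iterations:
            alpha_val = _optimise_symmetric_alpha(alpha_val, ndk, K)

    alpha = np.full(K, alpha_val)
    lengths = ndk.sum(axis=1, keepdims=True)
    theta = (ndk + alpha) / (lengths + alpha.sum())

    index_to_lemma = vocabulary.index_to_lemma
    top_words = [
        [index_to_lemma[w] for w in _top_indices(nkw[k], N_TOP_WORDS, index_to_lemma)]
        for k in range(K)
    ]
    top_refs = []
    ids_arr = np.asarray(doc_ids)
    for k in range(K):
        # association = theta[d, k]; ties broken by reference id
        order = sorted(range(len(doc_ids)), key=lambda d: (-theta[d, k], doc_ids[d]))
        top_refs.append([str(ids_arr[d]) for d in order[: min(N_TOP_REFS, len(doc_ids))]])

    return TopicModel(
        params=params,
        topic_word_counts=nkw,
        doc_topic=theta,
        alpha=alpha,
        vocabulary_index=dict(vocabulary.entries),
        doc_ids=list(doc_ids),
        top_words=top_words,
        top_refs=top_refs,
    )


def _top_indices(counts: np.ndarray, n: int, names: list[str]) -> list[int]:
    order = sorted(range(len(counts)), key=lambda w: (-counts[w], names[w]))
    return order[:n]


def infer_topics(
    model: TopicModel,
    doc: tuple[TokenisedDocument, TokenisedDocument] | TokenisedDocument,
    n_sweeps: int = 100,
    seed: int = 0,
) -> np.ndarray:
    """Topic proportions for a new document, topic-word counts held fixed.

    Gibbs-samples the document's token assignments against the trained
    counts and averages θ over the second half of the sweeps.  A document
    with no in-vocabulary tokens gets the prior (uniform for symmetric α).
    """
    if isinstance(doc, TokenisedDocument):
        lemmas = doc.lemmas
    else:
        lemmas = doc[0].lemmas + doc[1].lemmas
    words = np.asarray(
        [model.vocabulary_index[lem] for lem in lemmas if lem in model.vocabulary_index],
        dtype=np.int64,
    )
    K = model.K
    alpha = model.alpha
    if words.size == 0:
        return alpha / alpha.sum()
    beta = model.params.beta
    V = model.topic_word_counts.shape[1]
    rng = np.random.default_rng(seed)
    nk_global = model.topic_word_counts.sum(axis=1)
    phi_cols = (model.topic_word_counts[:, words] + beta) / (nk_global + V * beta)[:, None]
    z = rng.integers(0, K, size=words.size)
    n_local = np.bincount(z, minlength=K).astype(np.float64)
    theta_acc = np.zeros(K)
    n_acc = 0
    for sweep in range(n_sweeps):
        for t in range(words.size):
            n_local[z[t]] -= 1
            p = (n_local + alpha) * phi_cols[:, t]
            p /= p.sum()
            z[t] = rng.choice(K, p=p)
            n_local[z[t]] += 1
        if sweep >= n_sweeps // 2:
            theta_acc += (n_local + alpha) / (words.size + alpha.sum())
            n_acc += 1
    return theta_acc / n_acc


def topic_similarity(theta_a: np.ndarray, theta_b: np.ndarray) -> float:
    """Cosine similarity of two topic-proportion vectors, in [0, 1]."""
    a = np.asarray(theta_a, dtype=float)
    b = np.asarray(theta_b, dtype=float)
    if a.shape != b.shape:
        raise ConfigurationError("topic vectors have different K")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ConfigurationError("zero-norm topic vector")
    return float(np.dot(a, b) / (na * nb))
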