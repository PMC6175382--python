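"""Descriptive clustering: spectral embedding, spherical k-means, keywords.

The collection is partitioned by spectral clustering of the cosine
similarities between combined title+abstract TF-IDF rows.  The N×N
similarity matrix S = X Xᵀ is never materialised: the eigensolver only sees
the linear operator v ↦ D^{-1/2} X (Xᵀ (D^{-1/2} v)), where the degrees
d_i = x_i · (Xᵀ 1) are themselves computed by sparse products.  The top-k
eigenvectors of the symmetrically normalised operator are row-normalised to
the unit sphere (Ng–Jordan–Weiss) and clustered by spherical k-means — best
of ``replicates`` runs, each initialised with the scalable k-means++
(k-means‖) oversampling scheme (l = 2k candidates per round, 5 rounds).

Each cluster then receives a human-readable description: candidate keyword
indicators (words, lemmas, extracted multiword terms) are filtered to those
positively correlated with membership, greedily selected by conditional
mutual information maximisation (CMIM) to suppress redundancy, truncated at
the keyword count minimising the BIC of a logistic membership model, and
sorted by fitted coefficient.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import LinearOperator, eigsh
from sklearn.linear_model import LogisticRegression

from .corpus import Collection, TokenisedDocument, Vocabulary, build_vocabulary, tokenise_collection
from .errors import ConfigurationError
from .features import fit_tfidf
from .lemmatise import Lemmatiser
from .terms import extract_terms

__all__ = [
    "ClusteringConfig",
    "SpectralEmbedding",
    "ClusterAssignment",
    "ClusterDescription",
    "spectral_embed",
    "spherical_kmeans",
    "describe_cluster",
    "cluster_collection",
]

CMIM_CAP = 50


@dataclass(frozen=True)
class ClusteringConfig:
    k: int = 10
    replicates: int = 10
    max_iterations: int = 100
    oversampling_factor_l: int | None = None  # None -> 2k
    oversampling_rounds: int = 5
    seed: int = 0

    def __post_init__(self):
        if self.k < 2:
            raise ConfigurationError("k must be >= 2")
        if self.replicates < 1:
            raise ConfigurationError("replicates must be >= 1")

    @property
    def l_value(self) -> int:
        return 2 * self.k if self.oversampling_factor_l is None else self.oversampling_factor_l


@dataclass
class SpectralEmbedding:
    matrix: np.ndarray       # (n, k), rows unit-normalised for k-means
    eigenvectors: np.ndarray  # (n, k), raw eigenvectors of the operator
    eigenvalues: np.ndarray   # length k, descending


@dataclass
class ClusterAssignment:
    labels: dict[str, int]

    def members(self, cluster: int) -> list[str]:
        return [i for i, c in self.labels.items() if c == cluster]

    @property
    def k(self) -> int:
        return max(self.labels.values()) + 1


@dataclass
class ClusterDescription:
    cluster: int
    keywords: list[tuple[str, float]]  # (keyword, coefficient), coef descending

    @property
    def keyword_count_m(self) -> int:
        return len(self.keywords)


# ---------------------------------------------------------------------------
# Spectral embedding via the implicit similarity operator
# ---------------------------------------------------------------------------

def spectral_embed(tfidf_rows: sp.csr_matrix, k: int) -> SpectralEmbedding:
    """Top-k eigenvectors of D^{-1/2} X Xᵀ D^{-1/2}, rows unit-normalised.

    ``tfidf_rows`` must be L2-normalised and contain no all-zero rows (empty
    documents are held out by :func:`cluster_collection` and reattached
    afterwards).
    """
    X = sp.csr_matrix(tfidf_rows)
    n = X.shape[0]
    if n < k:
        raise ConfigurationError(f"need at least k={k} documents, got {n}")
    row_norms = np.asarray(X.multiply(X).sum(axis=1)).ravel()
    if np.any(row_norms <= 1e-12):
        raise ConfigurationError("all-zero TF-IDF rows must be held out before embedding")

    col_sums = np.asarray(X.sum(axis=0)).ravel()
    degrees = X @ col_sums  # d_i = x_i · Σ_j x_j  (includes the self term)
    dinv_sqrt = 1.0 / np.sqrt(degrees)

    def matvec(v):
        u = dinv_sqrt * v
        return dinv_sqrt * (X @ (X.T @ u))

    if n <= max(3 * k, 25):
        # eigsh cannot ask for k close to n; fall back to the dense problem
        S = (X @ X.T).toarray()
        M = S * np.outer(dinv_sqrt, dinv_sqrt)
        vals, vecs = np.linalg.eigh(M)
        vals, vecs = vals[::-1][:k], vecs[:, ::-1][:, :k]
    else:
        op = LinearOperator((n, n), matvec=matvec, dtype=np.float64)
        v0 = np.full(n, 1.0 / np.sqrt(n))
        vals, vecs = eigsh(op, k=k, which="LA", v0=v0)
        order = np.argsort(vals)[::-1]
        vals, vecs = vals[order], vecs[:, order]

    norms = np.linalg.norm(vecs, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    return SpectralEmbedding(matrix=vecs / norms, eigenvectors=vecs, eigenvalues=vals)


# ---------------------------------------------------------------------------
# Spherical k-means with scalable k-means++ initialisation
# ---------------------------------------------------------------------------

def _scalable_kmeanspp(X: np.ndarray, k: int, l: int, rounds: int,
                       rng: np.random.Generator) -> np.ndarray:
    """k-means‖ oversampling, then weighted k-means++ reduction to k seeds."""
    n = X.shape[0]
    first = int(rng.integers(n))
    candidates = [first]
    d = np.maximum(1.0 - X @ X[first], 0.0)  # cosine distance to nearest centre
    for _ in range(rounds):
        phi = float(d.sum())
        if phi <= 0:
            break
        probs = np.minimum(1.0, l * d / phi)
        new = np.nonzero(rng.random(n) < probs)[0]
        if new.size:
            candidates.extend(int(j) for j in new)
            d = np.minimum(d, np.maximum(1.0 - (X @ X[new].T).max(axis=1), 0.0))
    candidates = sorted(set(candidates))
    C = X[candidates]
    # weight each candidate by the number of points nearest to it
    nearest = np.argmax(X @ C.T, axis=1)
    weights = np.bincount(nearest, minlength=len(candidates)).astype(float)

    if len(candidates) <= k:
        seeds = list(range(len(candidates)))
        extra = rng.choice(n, size=k - len(candidates), replace=False)
        return np.vstack([C, X[extra]])[:k] if len(candidates) < k else C

    # classic weighted k-means++ on the candidate set
    seeds = [int(rng.choice(len(candidates), p=weights / weights.sum()))]
    dc = np.maximum(1.0 - C @ C[seeds[0]], 0.0)
    for _ in range(1, k):
        w = weights * dc
        if w.sum() <= 0:
            remaining = [j for j in range(len(candidates)) if j not in seeds]
            seeds.append(int(rng.choice(remaining)))
        else:
            seeds.append(int(rng.choice(len(candidates), p=w / w.sum())))
        dc = np.minimum(dc, np.maximum(1.0 - C @ C[seeds[-1]], 0.0))
    return C[seeds].copy()


def _normalise_rows(M: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(M, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    return M / norms


def spherical_kmeans(
    embedding: SpectralEmbedding | np.ndarray, config: ClusteringConfig
) -> np.ndarray:
    """Cluster unit-norm rows by cosine similarity; returns integer labels.

    Runs ``replicates`` independent restarts and keeps the assignment with
    the largest total cosine similarity to its centroids.  A centroid left
    empty mid-iteration is re-seeded at the point farthest from its own
    centroid.  Deterministic given the seed.
    """
    X = embedding.matrix if isinstance(embedding, SpectralEmbedding) else np.asarray(embedding)
    n = X.shape[0]
    k = config.k
    if k > n:
        raise ConfigurationError(f"k={k} exceeds the number of documents n={n}")
    master = np.random.default_rng(config.seed)
    best_labels, best_obj = None, -np.inf
    for _ in range(config.replicates):
        rng = np.random.default_rng(master.integers(2**31 - 1))
        C = _normalise_rows(
            _scalable_kmeanspp(X, k, config.l_value, config.oversampling_rounds, rng)
        )
        labels = np.zeros(n, dtype=np.int64)
        for _ in range(config.max_iterations):
            sims = X @ C.T
            new_labels = np.argmax(sims, axis=1)
            # re-seed empty clusters at the farthest point from its centroid
            for c in range(k):
                if not np.any(new_labels == c):
                    own = np.argmin(np.max(sims, axis=1))
                    new_labels[own] = c
            if np.array_equal(new_labels, labels) and _ > 0:
                break
            labels = new_labels
            C = np.zeros_like(C)
            for c in range(k):
                C[c] = X[labels == c].sum(axis=0)
            C = _normalise_rows(C)
        obj = float(np.sum((X @ C.T)[np.arange(n), labels]))
        if obj > best_obj:
            best_obj, best_labels = obj, labels.copy()
    return best_labels


# ---------------------------------------------------------------------------
# CMIM + BIC keyword descriptions
# ---------------------------------------------------------------------------

def _mi_binary(F: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Plug-in mutual information I(f; y) per column, add-half smoothing."""
    n = len(y)
    n11 = y @ F
    n1 = F.sum(axis=0)
    ny = y.sum()
    cells = np.stack([
        n11, ny - n11, n1 - n11, n - n1 - ny + n11
    ])  # f=1&y=1, f=0&y=1, f=1&y=0, f=0&y=0
    cells = cells + 0.5
    total = cells.sum(axis=0)
    p = cells / total
    pf1 = p[0] + p[2]
    pf0 = p[1] + p[3]
    py1 = p[0] + p[1]
    py0 = p[2] + p[3]
    marg = np.stack([pf1 * py1, pf0 * py1, pf1 * py0, pf0 * py0])
    return (p * np.log(p / marg)).sum(axis=0)


def _cmi_binary(F: np.ndarray, y: np.ndarray, s: np.ndarray) -> np.ndarray:
    """I(f; y | s) per column for binary indicators, add-half smoothing."""
    out = np.zeros(F.shape[1])
    n = len(y)
    for s_val in (0, 1):
        mask = s == s_val
        ns = int(mask.sum())
        if ns == 0:
            continue
        out += (ns / n) * _mi_binary(F[mask], y[mask])
    return out


def cmim_select(F: np.ndarray, y: np.ndarray, cap: int = CMIM_CAP) -> list[int]:
    """Greedy CMIM forward selection over binary indicator columns.

    At each step adds the feature maximising min over already-selected s of
    Î(f; y | s); stops when no candidate retains a positive score or the cap
    is reached.  Ties broken by lowest column index.
    """
    scores = _mi_binary(F, y)  # min over the empty set = marginal MI
    selected: list[int] = []
    available = np.ones(F.shape[1], dtype=bool)
    for _ in range(min(cap, F.shape[1])):
        masked = np.where(available, scores, -np.inf)
        best = int(np.argmax(masked))
        if masked[best] <= 0:
            break
        selected.append(best)
        available[best] = False
        cmi_new = _cmi_binary(F, y, F[:, best].astype(np.int64))
        scores = np.minimum(scores, cmi_new)
    return selected


def _logistic_bic(F: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """BIC = −2·llf + p·ln(n) of a logistic membership model; returns coefs."""
    n, m = F.shape
    clf = LogisticRegression(C=np.inf, solver="lbfgs", max_iter=200, tol=1e-6)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # separation stops at max_iter; BIC is fine
        clf.fit(F, y)
    p = np.clip(clf.predict_proba(F)[:, 1], 1e-12, 1 - 1e-12)
    llf = float(y @ np.log(p) + (1 - y) @ np.log(1 - p))
    return -2.0 * llf + (m + 1) * np.log(n), clf.coef_.ravel()


def describe_cluster(
    cluster: int,
    labels: np.ndarray,
    candidate_features: np.ndarray,
    feature_names: list[str],
) -> ClusterDescription:
    """Select and order the keyword description of one cluster.

    ``candidate_features`` is a binary (n × p) indicator matrix over words,
    lemmas and multiword terms.  Pipeline: positive-correlation filter →
    greedy CMIM → BIC model-order choice → sort by logistic coefficient.
    """
    y = (np.asarray(labels) == cluster).astype(np.int64)
    if y.sum() == 0:
        raise ConfigurationError(f"cluster {cluster} is empty")
    F = np.asarray(candidate_features, dtype=np.int64)
    in_rate = F[y == 1].mean(axis=0)
    out_rate = F[y == 0].mean(axis=0) if (y == 0).any() else np.zeros(F.shape[1])
    positive = np.nonzero(in_rate > out_rate)[0]
    if positive.size == 0:
        warnings.warn(
            f"cluster {cluster}: no positively correlated keyword; "
            "falling back to the single best-correlated feature",
            stacklevel=2,
        )
        best = int(np.argmax(_mi_binary(F, y)))
        _, coefs = _logistic_bic(F[:, [best]], y)
        return ClusterDescription(cluster=cluster, keywords=[(feature_names[best], float(coefs[0]))])

    Fp = F[:, positive]
    selected_local = cmim_select(Fp, y)
    selected = [int(positive[j]) for j in selected_local]
    if not selected:
        selected = [int(positive[np.argmax(_mi_binary(Fp, y))])]

    best_bic, best_m, best_coefs = np.inf, 1, None
    for m in range(1, len(selected) + 1):
        bic, coefs = _logistic_bic(F[:, selected[:m]], y)
        if bic < best_bic:
            best_bic, best_m, best_coefs = bic, m, coefs
    chosen = selected[:best_m]
    pairs = sorted(
        zip((feature_names[j] for j in chosen), best_coefs.tolist()),
        key=lambda kv: (-kv[1], kv[0]),
    )
    return ClusterDescription(cluster=cluster, keywords=[(k, float(v)) for k, v in pairs])


# ---------------------------------------------------------------------------
# End-to-end
# ---------------------------------------------------------------------------

MAX_TERM_CANDIDATES = 200


def candidate_keyword_matrix(
    collection: Collection,
    vocabulary: Vocabulary,
    tokenised: dict[str, tuple[TokenisedDocument, TokenisedDocument]],
    terms_list=None,
    min_term_frequency: int = 5,
) -> tuple[np.ndarray, list[str]]:
    """Binary presence indicators for lemmas, surface words and terms.

    Multiword terms below ``min_term_frequency`` (the vocabulary cut-off)
    are too rare to describe a cluster and are skipped, as are terms beyond
    the ``MAX_TERM_CANDIDATES`` highest C-values.  Exact-duplicate indicator
    columns are collapsed (first name kept).
    """
    from .features import count_matrix

    n = len(collection)
    columns: dict[str, np.ndarray] = {}
    lemma_names = sorted(vocabulary.entries)
    lemma_set = set(lemma_names)
    counts = count_matrix(collection, vocabulary, None, tokenised)
    presence = (counts > 0).toarray().astype(np.int64)
    for lemma in lemma_names:
        columns[lemma] = presence[:, vocabulary.entries[lemma]]
    surface_map: dict[str, set[int]] = {}
    for i, ref_id in enumerate(collection.ids):
        title_doc, abstract_doc = tokenised[ref_id]
        for surface, lemma, _ in title_doc.tokens + abstract_doc.tokens:
            sl = surface.lower()
            if sl != lemma and lemma in lemma_set and len(sl) > 1:
                surface_map.setdefault(sl, set()).add(i)
    for sl in sorted(surface_map):
        col = np.zeros(n, dtype=np.int64)
        col[sorted(surface_map[sl])] = 1
        columns[sl] = col
    if terms_list:
        kept = [t for t in terms_list if t.frequency >= min_term_frequency]
        kept = kept[:MAX_TERM_CANDIDATES]  # already sorted by C-value
        padded = {
            ref_id: " " + " ".join(
                tokenised[ref_id][0].lemmas + tokenised[ref_id][1].lemmas
            ) + " "
            for ref_id in collection.ids
        }
        for t in kept:
            needle = f" {t.surface} "
            col = np.zeros(n, dtype=np.int64)
            for i, ref_id in enumerate(collection.ids):
                if needle in padded[ref_id]:
                    col[i] = 1
            columns[t.surface] = col
    # collapse duplicate indicator columns, keeping the first (sorted) name
    seen: dict[bytes, str] = {}
    names: list[str] = []
    cols: list[np.ndarray] = []
    for name in columns:
        key = columns[name].tobytes()
        if key in seen:
            continue
        seen[key] = name
        names.append(name)
        cols.append(columns[name])
    return np.column_stack(cols), names


def cluster_collection(
    collection: Collection,
    config: ClusteringConfig,
    vocabulary: Vocabulary | None = None,
    lemmatiser: Lemmatiser | None = None,
    min_count: int = 5,
    with_terms: bool = True,
) -> tuple[ClusterAssignment, list[ClusterDescription]]:
    """Embed → cluster → describe, over combined title+abstract TF-IDF.

    Documents with no in-vocabulary tokens are held out of the eigenproblem
    and assigned afterwards to the cluster whose TF-IDF centroid is nearest
    in cosine (all-zero rows tie at 0 and fall to the lowest cluster index).
    """
    tokenised = tokenise_collection(collection, lemmatiser)
    vocab = vocabulary or build_vocabulary(collection, min_count=min_count,
                                           lemmatiser=lemmatiser, tokenised=tokenised)
    block = fit_tfidf(collection, vocab, None, tokenised=tokenised)
    X = block.matrix
    row_norms = np.asarray(X.multiply(X).sum(axis=1)).ravel()
    nonempty = np.nonzero(row_norms > 1e-12)[0]
    empty = np.nonzero(row_norms <= 1e-12)[0]
    if nonempty.size < config.k:
        raise ConfigurationError(
            f"k={config.k} exceeds the {nonempty.size} non-empty documents"
        )
    embedding = spectral_embed(X[nonempty], config.k)
    sub_labels = spherical_kmeans(embedding, config)
    labels = np.zeros(len(collection), dtype=np.int64)
    labels[nonempty] = sub_labels
    if empty.size:
        centroids = np.vstack([
            np.asarray(X[nonempty][sub_labels == c].mean(axis=0)).ravel()
            for c in range(config.k)
        ])
        sims = X[empty] @ centroids.T  # all zeros for empty docs -> cluster 0
        labels[empty] = np.argmax(np.asarray(sims), axis=1)

    ids = collection.ids
    assignment = ClusterAssignment(labels={ids[i]: int(labels[i]) for i in range(len(ids))})
    terms_list = extract_terms(collection, lemmatiser, tokenised) if with_terms else None
    F, names = candidate_keyword_matrix(collection, vocab, tokenised, terms_list)
    descriptions = [
        describe_cluster(c, labels, F, names) for c in range(config.k)
    ]
    return assignment, descriptions
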