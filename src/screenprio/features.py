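"""Classifier feature representation: TF-IDF blocks + topic proportions.

Each reference is represented by three concatenated blocks, in fixed order:

1. L2-normalised TF-IDF of the title lemmas,
2. L2-normalised TF-IDF of the abstract lemmas,
3. the LDA topic-proportion vector θ.

TF is the raw within-field lemma count; IDF is the smoothed
``ln((1+N)/(1+df)) + 1`` so that a term present in every document still has
positive weight.  The L2 normalisation guarantees that the sum of squared
weights of every non-empty bag-of-words row equals 1.  The topic block is a
probability simplex and is left un-normalised.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from sklearn.feature_extraction.text import TfidfTransformer

from .corpus import Collection, Field, TokenisedDocument, Vocabulary, tokenise_collection
from .errors import ConfigurationError
from .lda import TopicModel
from .lemmatise import Lemmatiser

__all__ = ["TfidfBlock", "fit_tfidf", "count_matrix", "build_features", "FeatureMatrix"]


def count_matrix(
    collection: Collection,
    vocabulary: Vocabulary,
    fld: Field | None,
    tokenised: dict[str, tuple[TokenisedDocument, TokenisedDocument]] | None = None,
    lemmatiser: Lemmatiser | None = None,
) -> sp.csr_matrix:
    """Sparse lemma-count matrix (references × vocabulary).

    ``fld=None`` counts titles and abstracts together (used for clustering).
    """
    docs = tokenised if tokenised is not None else tokenise_collection(collection, lemmatiser)
    rows: list[int] = []
    cols: list[int] = []
    vals: list[int] = []
    for i, ref_id in enumerate(collection.ids):
        title_doc, abstract_doc = docs[ref_id]
        if fld == "title":
            lemmas = title_doc.lemmas
        elif fld == "abstract":
            lemmas = abstract_doc.lemmas
        else:
            lemmas = title_doc.lemmas + abstract_doc.lemmas
        counts: dict[int, int] = {}
        for lem in lemmas:
            j = vocabulary.entries.get(lem)
            if j is not None:
                counts[j] = counts.get(j, 0) + 1
        rows.extend([i] * len(counts))
        cols.extend(counts.keys())
        vals.extend(counts.values())
    return sp.csr_matrix(
        (vals, (rows, cols)), shape=(len(collection), len(vocabulary)), dtype=np.float64
    )


@dataclass
class TfidfBlock:
    """One L2-normalised TF-IDF block (title or abstract or combined)."""

    matrix: sp.csr_matrix
    idf: np.ndarray
    field: Field | None

    @property
    def n_features(self) -> int:
        return self.matrix.shape[1]


def fit_tfidf(
    collection: Collection,
    vocabulary: Vocabulary,
    fld: Field | None,
    tokenised: dict[str, tuple[TokenisedDocument, TokenisedDocument]] | None = None,
    lemmatiser: Lemmatiser | None = None,
) -> TfidfBlock:
    """TF-IDF weights for one field; every non-empty row has unit L2 norm."""
    counts = count_matrix(collection, vocabulary, fld, tokenised, lemmatiser)
    if counts.nnz == 0:
        raise ConfigurationError(
            f"field {fld!r} contains no in-vocabulary tokens in any reference"
        )
    transformer = TfidfTransformer(norm="l2", smooth_idf=True, sublinear_tf=False)
    matrix = transformer.fit_transform(counts)
    return TfidfBlock(matrix=matrix.tocsr(), idf=transformer.idf_, field=fld)


@dataclass
class FeatureMatrix:
    """Concatenated per-reference feature rows: [title | abstract | θ]."""

    matrix: sp.csr_matrix
    doc_ids: list[str]
    n_title: int
    n_abstract: int
    n_topics: int

    def row(self, ref_id: str) -> sp.csr_matrix:
        return self.matrix[self.doc_ids.index(ref_id)]

    @property
    def n_features(self) -> int:
        return self.matrix.shape[1]


def build_features(
    collection: Collection,
    tfidf_title: TfidfBlock,
    tfidf_abstract: TfidfBlock,
    topic_model: TopicModel | None = None,
) -> FeatureMatrix:
    """Concatenate the three feature blocks; dimension = 2·|V| (+ K)."""
    n = len(collection)
    blocks: list[sp.spmatrix] = [tfidf_title.matrix, tfidf_abstract.matrix]
    n_topics = 0
    if topic_model is not None:
        if topic_model.doc_topic.shape[0] != n or topic_model.doc_ids != collection.ids:
            raise ConfigurationError("topic model fitted on a different collection")
        blocks.append(sp.csr_matrix(topic_model.doc_topic))
        n_topics = topic_model.K
    for b in blocks[:2]:
        if b.shape[0] != n:
            raise ConfigurationError("feature block row count mismatch")
    return FeatureMatrix(
        matrix=sp.hstack(blocks, format="csr"),
        doc_ids=collection.ids,
        n_title=tfidf_title.n_features,
        n_abstract=tfidf_abstract.n_features,
        n_topics=n_topics,
    )
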