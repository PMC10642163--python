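"""Shared count-feature space for the trainable CPC predictors.

Referral medical terms are vectorized into unigram + bigram counts, with
document-frequency filtering (a column must appear in at least
``min_doc_count`` referrals and in at most ``max_doc_fraction`` of them) to
drop rare and ubiquitous terms. The same vectorizer embeds CPC seed texts so
clustering centroids live in the referral feature space.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import scipy.sparse as sp
from scipy.io import mmread, mmwrite
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.feature_extraction.text import CountVectorizer

DEFAULT_MIN_DOC_COUNT = 30
DEFAULT_MAX_DOC_FRACTION = 0.8
NGRAM_RANGE = (1, 2)


def _ngrams(tokens: Sequence[str], ngram_range=NGRAM_RANGE) -> list[str]:
    lo, hi = ngram_range
    out: list[str] = []
    for n in range(lo, hi + 1):
        out.extend(
            " ".join(tokens[i : i + n]) for i in range(len(tokens) - n + 1)
        )
    return out


class FeatureBuildError(ValueError):
    pass


@dataclass
class FeatureMatrix:
    """Sparse document-term count matrix with its row ids and vocabulary."""

    ids: list[str]
    vocabulary: list[str]
    matrix: sp.csr_matrix

    def __post_init__(self) -> None:
        if self.matrix.shape != (len(self.ids), len(self.vocabulary)):
            raise FeatureBuildError("matrix shape does not match ids/vocabulary")

    def toarray(self) -> np.ndarray:
        return self.matrix.toarray()

    def save(self, mtx_path, vocab_path) -> None:
        mmwrite(str(mtx_path), self.matrix)
        Path(vocab_path).write_text(
            "\n".join(self.vocabulary) + "\n", encoding="utf-8"
        )

    @classmethod
    def load(cls, mtx_path, vocab_path, ids: list[str]) -> "FeatureMatrix":
        mat = sp.csr_matrix(mmread(str(mtx_path)))
        vocab = Path(vocab_path).read_text(encoding="utf-8").splitlines()
        return cls(ids=ids, vocabulary=vocab, matrix=mat)


class TermCountVectorizer(BaseEstimator, TransformerMixin):
    """CountVectorizer over pre-tokenized medical-term sequences.

    Parameters mirror the count-feature defaults: unigrams and bigrams, a
    column kept only when its document frequency is >= ``min_doc_count``
    documents and <= ``max_doc_fraction`` of all documents. Columns are in
    lexicographic order. For small corpora ``min_doc_count`` must be lowered
    or the vocabulary empties.
    """

    def __init__(
        self,
        min_doc_count: int = DEFAULT_MIN_DOC_COUNT,
        max_doc_fraction: float = DEFAULT_MAX_DOC_FRACTION,
        ngram_range: tuple[int, int] = NGRAM_RANGE,
    ):
        self.min_doc_count = min_doc_count
        self.max_doc_fraction = max_doc_fraction
        self.ngram_range = ngram_range

    def _make_vectorizer(self) -> CountVectorizer:
        rng = self.ngram_range
        return CountVectorizer(
            analyzer=lambda tokens: _ngrams(list(tokens), rng),
            min_df=self.min_doc_count,
            max_df=self.max_doc_fraction,
            lowercase=False,
        )

    def fit(self, X: Sequence[Sequence[str]], y=None):
        if len(X) == 0:
            raise FeatureBuildError("cannot build features from zero referrals")
        self.vectorizer_ = self._make_vectorizer()
        try:
            self.vectorizer_.fit(X)
        except ValueError as exc:
            raise FeatureBuildError(
                "document-frequency filtering removed every column; lower "
                f"min_doc_count (={self.min_doc_count}) or raise "
                f"max_doc_fraction (={self.max_doc_fraction}) for this corpus"
            ) from exc
        self.vocabulary_ = sorted(self.vectorizer_.vocabulary_)
        return self

    def transform(self, X: Sequence[Sequence[str]]) -> sp.csr_matrix:
        if not hasattr(self, "vectorizer_"):
            raise ValueError("vectorizer is not fitted")
        return sp.csr_matrix(self.vectorizer_.transform(X))


def build_features(
    token_sequences: Sequence[Sequence[str]],
    ids: Sequence[str] | None = None,
    min_doc_count: int = DEFAULT_MIN_DOC_COUNT,
    max_doc_fraction: float = DEFAULT_MAX_DOC_FRACTION,
    ngram_range: tuple[int, int] = NGRAM_RANGE,
) -> tuple[FeatureMatrix, TermCountVectorizer]:
    """Fit the vectorizer on a corpus and return its FeatureMatrix."""
    vec = TermCountVectorizer(min_doc_count, max_doc_fraction, ngram_range)
    mat = vec.fit(token_sequences).transform(token_sequences)
    if ids is None:
        ids = [str(i) for i in range(len(token_sequences))]
    return FeatureMatrix(list(ids), vec.vocabulary_, mat), vec
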