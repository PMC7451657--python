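"""N-gram featurization: F-value feature selection and max-normalized TF-IDF.

The pipeline turns filtered SOAP text into a sparse set-of-words matrix in
four steps: normalization, tokenization into 1–3-grams, selection of the
n-grams whose F-value lies strictly above a percentile of the F-value
distribution, and TF-IDF weighting.

For feature i with per-document raw counts X_{k,i}, the F-value is

    F(i) = [ (X̄ᵢ_inp − X̄ᵢ)² + (X̄ᵢ_dis − X̄ᵢ)² ] / [ s²ᵢ_inp + s²ᵢ_dis ]

where X̄ᵢ, X̄ᵢ_inp, X̄ᵢ_dis are the feature's means over all, inpatient
and discharged training documents and s² are the within-class sample
variances (1/(n−1)); a zero denominator defines F = 0. F-values are
computed on raw counts, before any weighting.

Matrix cells use augmented term frequency times inverse document frequency:

    TFIDF(t, d, D) = f(t,d) / max{f(t',d) : t' ∈ d} × log( |D| / df(t) )

with f(t,d) the count of t in document d, the max ranging over the
document's in-vocabulary terms, and df(t) the training document frequency.
The logarithm is natural by default (the base only rescales columns).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import scipy.sparse as sp
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.feature_extraction.text import CountVectorizer
from sklearn.utils.validation import check_is_fitted

from .records import INPATIENT
from .text import NGRAM_JOINER, TokenizerConfig, extract_ngrams, normalize_text

__all__ = [
    "FeatureStats",
    "TermDocumentMatrix",
    "compute_f_values",
    "select_features",
    "fit_tfidf",
    "transform_tfidf",
    "SoapVectorizer",
]


@dataclass(frozen=True)
class FeatureStats:
    """Per-feature class-conditional moments and the resulting F-values."""

    features: tuple[str, ...]
    mean_all: np.ndarray
    mean_inpatient: np.ndarray
    mean_discharged: np.ndarray
    n_inpatient: int
    n_discharged: int
    f_value: np.ndarray


@dataclass(frozen=True)
class TermDocumentMatrix:
    """Documents × selected n-grams, TF-IDF weighted, plus ordered indices."""

    documents: tuple[str, ...]
    features: tuple[str, ...]
    weights: sp.csr_matrix

    def save(self, out_dir: str | Path, stem: str = "matrix") -> None:
        """MatrixMarket coordinate export plus row/column index files."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        from scipy.io import mmwrite

        mmwrite(str(out_dir / f"{stem}.mtx"), self.weights)
        (out_dir / f"{stem}.rows.txt").write_text(
            "\n".join(self.documents) + "\n", encoding="utf-8"
        )
        (out_dir / f"{stem}.cols.txt").write_text(
            "\n".join(self.features) + "\n", encoding="utf-8"
        )

    @classmethod
    def load(cls, out_dir: str | Path, stem: str = "matrix") -> "TermDocumentMatrix":
        from scipy.io import mmread

        out_dir = Path(out_dir)
        weights = sp.csr_matrix(mmread(str(out_dir / f"{stem}.mtx")))
        rows = (out_dir / f"{stem}.rows.txt").read_text(encoding="utf-8").split()
        cols = (out_dir / f"{stem}.cols.txt").read_text(encoding="utf-8").split()
        return cls(tuple(rows), tuple(cols), weights)


def _class_masks(y) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(y)
    if y.dtype.kind in "biu":
        pos = y.astype(int) == 1
    else:
        pos = y == INPATIENT
    return pos, ~pos


def compute_f_values(
    X: sp.spmatrix | np.ndarray, y, features=None
) -> FeatureStats:
    """F-value of every feature from per-document raw count vectors.

    ``y`` holds class labels (strings, or 1 = inpatient / 0 = discharged);
    each class needs at least two documents for the within-class variances
    to exist.
    """
    X = sp.csr_matrix(X, dtype=np.float64)
    pos, neg = _class_masks(y)
    n_pos, n_neg = int(pos.sum()), int(neg.sum())
    if n_pos < 2 or n_neg < 2:
        raise ValueError(
            f"each class needs >= 2 documents (got inpatient={n_pos}, "
            f"discharged={n_neg}); within-class variance is undefined otherwise"
        )
    n = n_pos + n_neg

    sum_all = np.asarray(X.sum(axis=0)).ravel()
    sum_pos = np.asarray(X[pos].sum(axis=0)).ravel()
    sum_neg = sum_all - sum_pos
    X2 = X.multiply(X)
    sq_pos = np.asarray(X2[pos].sum(axis=0)).ravel()
    sq_neg = np.asarray(X2.sum(axis=0)).ravel() - sq_pos

    mean_all = sum_all / n
    mean_pos = sum_pos / n_pos
    mean_neg = sum_neg / n_neg

    var_pos = (sq_pos - n_pos * mean_pos**2) / (n_pos - 1)
    var_neg = (sq_neg - n_neg * mean_neg**2) / (n_neg - 1)
    denom = np.maximum(var_pos, 0.0) + np.maximum(var_neg, 0.0)
    numer = (mean_pos - mean_all) ** 2 + (mean_neg - mean_all) ** 2

    with np.errstate(divide="ignore", invalid="ignore"):
        f = np.where(denom > 0, numer / np.where(denom > 0, denom, 1.0), 0.0)

    if features is None:
        features = tuple(f"f{i}" for i in range(X.shape[1]))
    return FeatureStats(
        features=tuple(features),
        mean_all=mean_all,
        mean_inpatient=mean_pos,
        mean_discharged=mean_neg,
        n_inpatient=n_pos,
        n_discharged=n_neg,
        f_value=f,
    )


def select_features(stats: FeatureStats, percentile: float = 65.0) -> np.ndarray:
    """Indices of features with F-value strictly above the given percentile.

    The percentile is the inclusive linear-interpolation quantile of the
    F-value distribution; ties at the threshold are excluded.
    """
    f = np.asarray(stats.f_value)
    if f.size == 0:
        raise ValueError("no features to select from")
    threshold = np.percentile(f, percentile)
    return np.flatnonzero(f > threshold)


def _augmented_tf(X: sp.csr_matrix) -> sp.csr_matrix:
    """Counts divided by the document's maximum in-vocabulary count.

    Documents with no in-vocabulary term keep an all-zero row.
    """
    X = X.tocsr().astype(np.float64)
    row_max = X.max(axis=1).toarray().ravel()
    scale = np.divide(1.0, row_max, out=np.zeros_like(row_max), where=row_max > 0)
    return sp.diags(scale) @ X


def fit_tfidf(
    X_counts: sp.spmatrix | np.ndarray, log_base: float | None = None
) -> tuple[sp.csr_matrix, np.ndarray]:
    """Weight a training count matrix; return (weights, idf_table).

    idf(t) = log(|D| / df(t)) on the training documents, natural log unless
    ``log_base`` is given. A term present in every document gets idf 0.
    """
    X = sp.csr_matrix(X_counts, dtype=np.float64)
    if X.shape[0] == 0 or X.shape[1] == 0:
        raise ValueError("training matrix must be non-empty")
    df = np.asarray((X > 0).sum(axis=0)).ravel()
    with np.errstate(divide="ignore"):
        idf = np.where(df > 0, np.log(X.shape[0] / np.where(df > 0, df, 1)), 0.0)
    if log_base is not None:
        idf = idf / np.log(log_base)
    return _augmented_tf(X) @ sp.diags(idf), idf


def transform_tfidf(
    X_counts: sp.spmatrix | np.ndarray, idf: np.ndarray
) -> sp.csr_matrix:
    """Apply a frozen training idf table to new count vectors.

    Max-TF normalization uses each new document's own in-vocabulary counts.
    """
    X = sp.csr_matrix(X_counts, dtype=np.float64)
    idf = np.asarray(idf, dtype=np.float64)
    if X.shape[1] != idf.shape[0]:
        raise ValueError(
            f"vocabulary mismatch: matrix has {X.shape[1]} columns, "
            f"idf table has {idf.shape[0]} entries"
        )
    return _augmented_tf(X) @ sp.diags(idf)


class SoapVectorizer(TransformerMixin, BaseEstimator):
    """Supervised text vectorizer: 1–3-gram counts → F-value selection → TF-IDF.

    Fitting computes raw n-gram counts on the training documents, ranks
    every candidate n-gram by F-value, keeps those strictly above
    ``percentile`` of the F-value distribution, and freezes the training
    idf table. ``transform`` weights any documents against that frozen
    vocabulary; unseen n-grams are ignored.

    Parameters
    ----------
    percentile : float, default 65
        F-value percentile; only features strictly above it are kept.
    stopwords : collection of str, optional
    stemmer : {"identity", "portuguese"}, default "identity"
    lowercase : bool, default True
    log_base : float or None, default None
        Base of the idf logarithm; None means natural log.

    Attributes
    ----------
    vocabulary_ : tuple of str — selected n-grams, in column order.
    idf_ : ndarray — frozen training idf per selected n-gram.
    feature_stats_ : FeatureStats over all candidate n-grams.
    n_documents_ : int — training corpus size |D|.
    """

    def __init__(
        self,
        percentile: float = 65.0,
        stopwords=None,
        stemmer: str = "identity",
        lowercase: bool = True,
        log_base: float | None = None,
    ):
        self.percentile = percentile
        self.stopwords = stopwords
        self.stemmer = stemmer
        self.lowercase = lowercase
        self.log_base = log_base

    def _tokenizer_config(self) -> TokenizerConfig:
        return TokenizerConfig(
            stopwords=frozenset(self.stopwords or ()),
            stemmer=self.stemmer,
            lowercase=self.lowercase,
        )

    def build_analyzer(self):
        config = self._tokenizer_config()
        return lambda text: extract_ngrams(normalize_text(text, config), NGRAM_JOINER)

    def fit(self, X, y):
        if not 0.0 <= self.percentile <= 100.0:
            raise ValueError(f"percentile must be in [0, 100], got {self.percentile}")
        docs = list(X)
        if not docs:
            raise ValueError("training corpus is empty")
        counter = CountVectorizer(analyzer=self.build_analyzer(), lowercase=False)
        counts = counter.fit_transform(docs)
        candidates = counter.get_feature_names_out()
        stats = compute_f_values(counts, y, features=candidates)
        keep = select_features(stats, self.percentile)
        if keep.size == 0:
            raise ValueError(
                "feature selection kept nothing (all F-values tied at or below "
                "the percentile threshold)"
            )
        self.feature_stats_ = stats
        self.vocabulary_ = tuple(str(candidates[i]) for i in keep)
        self._counter_ = CountVectorizer(
            analyzer=self.build_analyzer(),
            lowercase=False,
            vocabulary={t: j for j, t in enumerate(self.vocabulary_)},
        )
        selected_counts = counts[:, keep]
        _, self.idf_ = fit_tfidf(selected_counts, log_base=self.log_base)
        self.n_documents_ = counts.shape[0]
        return self

    def transform(self, X) -> sp.csr_matrix:
        check_is_fitted(self, "idf_")
        counts = self._counter_.transform(list(X))
        return transform_tfidf(counts, self.idf_)

    def count_transform(self, X) -> sp.csr_matrix:
        """Raw counts over the selected vocabulary (no weighting)."""
        check_is_fitted(self, "idf_")
        return self._counter_.transform(list(X))

    def get_feature_names_out(self, input_features=None):
        check_is_fitted(self, "vocabulary_")
        return np.asarray(self.vocabulary_, dtype=object)

    def to_matrix(self, X, document_ids) -> TermDocumentMatrix:
        return TermDocumentMatrix(
            documents=tuple(document_ids),
            features=tuple(self.vocabulary_),
            weights=self.transform(X),
        )

    def save_vocabulary(self, path: str | Path) -> None:
        """TSV export: feature, f_value, idf (selected vocabulary only)."""
        check_is_fitted(self, "vocabulary_")
        by_name = {t: i for i, t in enumerate(self.feature_stats_.features)}
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("feature\tf_value\tidf\n")
            for j, term in enumerate(self.vocabulary_):
                fv = self.feature_stats_.f_value[by_name[term]]
                fh.write(f"{term}\t{fv:.12g}\t{self.idf_[j]:.12g}\n")
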