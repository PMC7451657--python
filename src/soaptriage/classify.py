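"""Linear nu-SVC disposition classifier.

The decision rule is an affine score s(x) = w·x + b over the TF-IDF
vocabulary; a document is predicted *inpatient* iff s(x) ≥ 0 (admission is
the positive class, so ROC orientation is unambiguous). Training solves
the nu-parameterized maximum-margin problem with a linear kernel; nu
bounds the fraction of margin errors from above and the fraction of
support vectors from below, i.e.

    (margin errors)/n  ≤  nu  ≤  (support vectors)/n.

The quadratic-programming engine is an interchangeable standard solver
(libsvm via scikit-learn); the contribution here is the pipeline contract
around it, not a novel SVM.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import scipy.sparse as sp
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.svm import NuSVC
from sklearn.utils.validation import check_is_fitted

from .records import DISCHARGED, INPATIENT

__all__ = ["DispositionClassifier", "feasible_nu_upper_bound", "save_model", "load_model"]


def feasible_nu_upper_bound(n_pos: int, n_neg: int) -> float:
    """Largest feasible nu for given class sizes: 2·min(n⁺, n⁻)/n."""
    return 2.0 * min(n_pos, n_neg) / (n_pos + n_neg)


def _encode(y) -> np.ndarray:
    y = np.asarray(y)
    if y.dtype.kind in "biu":
        return y.astype(int)
    out = np.where(y == INPATIENT, 1, 0)
    bad = ~np.isin(y, (INPATIENT, DISCHARGED))
    if bad.any():
        raise ValueError(f"unknown labels: {sorted(set(y[bad]))}")
    return out


class DispositionClassifier(ClassifierMixin, BaseEstimator):
    """nu-SVC with linear kernel predicting admission vs. discharge.

    Parameters
    ----------
    nu : float, default 0.5
        Upper bound on the fraction of margin errors and lower bound on the
        fraction of support vectors; must satisfy 0 < nu ≤ 2·min(n⁺,n⁻)/n.

    Attributes
    ----------
    weights_ : ndarray of shape (n_features,) — hyperplane normal w.
    bias_ : float — intercept b; score is w·x + b.
    classes_ : array([\"discharged\", \"inpatient\"]).
    support_ : ndarray — training indices of the support vectors.
    n_support_ : int — number of support vectors.
    """

    def __init__(self, nu: float = 0.5):
        self.nu = nu

    def fit(self, X, y):
        y_bin = _encode(y)
        n_pos = int((y_bin == 1).sum())
        n_neg = int((y_bin == 0).sum())
        if n_pos == 0 or n_neg == 0:
            raise ValueError("training data must contain both classes")
        if not 0.0 < self.nu <= 1.0:
            raise ValueError(f"nu must be in (0, 1], got {self.nu}")
        bound = feasible_nu_upper_bound(n_pos, n_neg)
        if self.nu > bound:
            raise ValueError(
                f"nu={self.nu} infeasible for class sizes ({n_pos}, {n_neg}); "
                f"feasible bound is nu <= {bound:.6g}"
            )
        X = sp.csr_matrix(X, dtype=np.float64)
        svc = NuSVC(nu=self.nu, kernel="linear")
        try:
            svc.fit(X, y_bin)
        except ValueError as err:  # libsvm's own feasibility guard
            if "nu" in str(err).lower():
                raise ValueError(
                    f"nu={self.nu} rejected by the solver; feasible bound is "
                    f"nu <= {bound:.6g}"
                ) from err
            raise
        # libsvm orders classes [0, 1], so a positive decision value means
        # class 1 == inpatient — the fixed sign convention.
        self.weights_ = np.asarray(svc.coef_.todense()).ravel() if sp.issparse(
            svc.coef_
        ) else np.asarray(svc.coef_).ravel()
        self.bias_ = float(svc.intercept_[0])
        self.support_ = svc.support_.copy()
        self.n_support_ = int(svc.support_.size)
        self.classes_ = np.array([DISCHARGED, INPATIENT])
        self.n_features_in_ = X.shape[1]
        return self

    def decision_function(self, X) -> np.ndarray:
        """Continuous decision scores s(x) = w·x + b, one per document."""
        check_is_fitted(self, "weights_")
        X = sp.csr_matrix(X, dtype=np.float64)
        if X.shape[1] != self.weights_.shape[0]:
            raise ValueError(
                f"dimension mismatch: matrix has {X.shape[1]} columns, model "
                f"has {self.weights_.shape[0]} weights"
            )
        return np.asarray(X @ self.weights_).ravel() + self.bias_

    def predict(self, X) -> np.ndarray:
        """Inpatient iff the decision score is ≥ 0."""
        scores = self.decision_function(X)
        return np.where(scores >= 0, INPATIENT, DISCHARGED)


def save_model(
    clf: DispositionClassifier, features, out_dir: str | Path, stem: str = "model"
) -> None:
    """TSV export: (feature, weight) table plus a small header file."""
    check_is_fitted(clf, "weights_")
    features = list(features)
    if len(features) != clf.weights_.shape[0]:
        raise ValueError("feature list length does not match weight vector")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    with open(out_dir / f"{stem}.weights.tsv", "w", encoding="utf-8") as fh:
        fh.write("feature\tweight\n")
        for feat, w in zip(features, clf.weights_):
            fh.write(f"{feat}\t{w:.17g}\n")
    with open(out_dir / f"{stem}.header.tsv", "w", encoding="utf-8") as fh:
        fh.write("key\tvalue\n")
        fh.write(f"bias\t{clf.bias_:.17g}\n")
        fh.write(f"nu\t{clf.nu:.17g}\n")
        fh.write(f"positive_class\t{INPATIENT}\n")
        fh.write(f"negative_class\t{DISCHARGED}\n")


def load_model(
    out_dir: str | Path, stem: str = "model"
) -> tuple[DispositionClassifier, list[str]]:
    """Rebuild a scoring-ready classifier from the TSV export."""
    out_dir = Path(out_dir)
    features: list[str] = []
    weights: list[float] = []
    with open(out_dir / f"{stem}.weights.tsv", encoding="utf-8") as fh:
        next(fh)
        for line in fh:
            feat, w = line.rstrip("\n").split("\t")
            features.append(feat)
            weights.append(float(w))
    header: dict[str, str] = {}
    with open(out_dir / f"{stem}.header.tsv", encoding="utf-8") as fh:
        next(fh)
        for line in fh:
            key, value = line.rstrip("\n").split("\t")
            header[key] = value
    clf = DispositionClassifier(nu=float(header["nu"]))
    clf.weights_ = np.asarray(weights, dtype=np.float64)
    clf.bias_ = float(header["bias"])
    clf.classes_ = np.array([DISCHARGED, INPATIENT])
    clf.n_features_in_ = len(features)
    return clf, features
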