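"""Evaluation statistics for the human-vs-machine comparison.

Covers everything needed to score a disposition predictor against binary
ground truth and against human graders: stratified splitting, the sampling
margin of error with finite-population correction, ROC/AUROC with DeLong
confidence intervals, the Mann-Whitney (concordance-probability) AUROC
estimator, Youden's J optimal cutoff, Wilson score intervals for
sensitivity/specificity, DeLong's nonparametric test for two correlated
ROC curves, Cohen's kappa with agreement-strength bands, conservative
aggregation of a rater pair (disagreement → "inpatient"), and the
five-category concordance accounting of machine vs. physician successes.

Binary human ratings enter ROC analysis as degenerate {0, 1} score
vectors, which yields the familiar two-segment ROC of a single operating
point.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm, rankdata
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve as _sk_roc_curve
from statsmodels.stats.proportion import proportion_confint

from .records import DISCHARGED, INPATIENT, SoapRecord

__all__ = [
    "SplitSpec",
    "RocAnalysis",
    "DeLongResult",
    "KappaResult",
    "ConcordanceTable",
    "stratified_split",
    "margin_of_error",
    "roc_analysis",
    "auroc_mann_whitney",
    "youden_cutoff",
    "sens_spec_ci",
    "delong_variance",
    "delong_test",
    "cohens_kappa",
    "kappa_band",
    "aggregate_conservative",
    "concordance_table",
    "binary_ratings_as_scores",
]


def _positive_mask(labels) -> np.ndarray:
    """Boolean mask of the positive (inpatient) class; requires both classes."""
    y = np.asarray(labels)
    if y.dtype.kind in "biu":
        pos = y.astype(int) == 1
    else:
        pos = y == INPATIENT
    if not pos.any() or pos.all():
        raise ValueError("both classes must be present")
    return pos


# ---------------------------------------------------------------------------
# Splitting and sampling error
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SplitSpec:
    """Either explicit per-class test counts or a single test fraction."""

    test_counts: dict[str, int] | None = None
    test_fraction: float | None = None
    seed: int = 0

    def validate(self) -> None:
        if (self.test_counts is None) == (self.test_fraction is None):
            raise ValueError("give exactly one of test_counts or test_fraction")
        if self.test_fraction is not None and not 0.0 < self.test_fraction < 1.0:
            raise ValueError(
                f"test_fraction must be in (0, 1), got {self.test_fraction}"
            )
        if self.test_counts is not None and any(
            v < 0 for v in self.test_counts.values()
        ):
            raise ValueError(f"test counts must be non-negative: {self.test_counts}")


def stratified_split(records, spec: SplitSpec):
    """Seeded stratified partition into (train, test).

    Explicit per-class test counts are honored exactly; with a fraction,
    each class contributes round-half-away(fraction × class size) records.
    Test records are sampled without replacement; train is the complement.
    Accepts SoapRecords or bare label strings; input order is preserved
    within each partition.
    """
    spec.validate()
    labels = [r.label if isinstance(r, SoapRecord) else str(r) for r in records]
    rng = np.random.default_rng(spec.seed)
    by_class: dict[str, list[int]] = {}
    for i, lab in enumerate(labels):
        by_class.setdefault(lab, []).append(i)

    test_idx: set[int] = set()
    for lab in sorted(by_class):
        pool = by_class[lab]
        if spec.test_counts is not None:
            k = spec.test_counts.get(lab, 0)
        else:
            k = int(math.floor(abs(spec.test_fraction * len(pool)) + 0.5))
        if k > len(pool):
            raise ValueError(
                f"requested {k} test records for class {lab!r} but only "
                f"{len(pool)} are available"
            )
        if k:
            test_idx.update(pool[j] for j in rng.choice(len(pool), k, replace=False))

    train = [records[i] for i in range(len(records)) if i not in test_idx]
    test = [records[i] for i in range(len(records)) if i in test_idx]
    return train, test


def margin_of_error(n: int, N: float | None, confidence: float = 0.95) -> float:
    """Sampling margin of error for a proportion at worst-case p = 0.5.

    z·sqrt(0.25/n) with the finite-population correction
    sqrt((N−n)/(N−1)); pass ``N=None`` (or inf) for an infinite population.
    Returned as a proportion (0.064 = 6.4%).
    """
    if n <= 0:
        raise ValueError(f"sample size must be positive, got {n}")
    z = norm.ppf(1.0 - (1.0 - confidence) / 2.0)
    moe = z * math.sqrt(0.25 / n)
    if N is not None and not math.isinf(N):
        if n > N:
            raise ValueError(f"sample size {n} exceeds population size {N}")
        moe *= math.sqrt((N - n) / (N - 1))
    return float(moe)


# ---------------------------------------------------------------------------
# ROC / AUROC
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RocAnalysis:
    """ROC curve points (fpr/tpr non-decreasing), AUROC and its 95% CI."""

    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auroc: float
    ci95: tuple[float, float]


def _delong_placements(scores, pos: np.ndarray):
    """Midrank placement values (v01 per positive, v10 per negative) and AUC."""
    scores = np.asarray(scores, dtype=np.float64)
    x, y = scores[pos], scores[~pos]
    m, n = x.size, y.size
    tz = rankdata(np.concatenate([x, y]))
    tx = rankdata(x)
    ty = rankdata(y)
    auc = (tz[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v01 = (tz[:m] - tx) / n
    v10 = 1.0 - (tz[m:] - ty) / m
    return auc, v01, v10


def delong_variance(scores, labels) -> float:
    """DeLong variance of a single AUROC estimate (midrank placements)."""
    pos = _positive_mask(labels)
    _, v01, v10 = _delong_placements(scores, pos)
    m, n = v01.size, v10.size
    var01 = v01.var(ddof=1) if m > 1 else 0.0
    var10 = v10.var(ddof=1) if n > 1 else 0.0
    return float(var01 / m + var10 / n)


def roc_analysis(scores, labels, confidence: float = 0.95) -> RocAnalysis:
    """Full ROC curve with trapezoidal AUROC and a DeLong-variance CI.

    The curve runs over all distinct score thresholds; tied scores produce
    diagonal segments. The CI is the normal approximation
    auroc ± z·sqrt(var), clipped to [0, 1].
    """
    pos = _positive_mask(labels)
    fpr, tpr, thresholds = _sk_roc_curve(
        pos.astype(int), np.asarray(scores, dtype=np.float64),
        drop_intermediate=False,
    )
    auroc = float(_trapezoid_auc(fpr, tpr))
    se = math.sqrt(delong_variance(scores, labels))
    z = norm.ppf(1.0 - (1.0 - confidence) / 2.0)
    lo = float(np.clip(auroc - z * se, 0.0, 1.0))
    hi = float(np.clip(auroc + z * se, 0.0, 1.0))
    return RocAnalysis(
        thresholds=thresholds, tpr=tpr, fpr=fpr, auroc=auroc, ci95=(lo, hi)
    )


def auroc_mann_whitney(scores, labels) -> float:
    """AUROC as the probability of concordance: mean over positive–negative
    pairs of 1[pos > neg] + ½·1[tie]. Equals the trapezoidal estimate."""
    pos = _positive_mask(labels)
    auc, _, _ = _delong_placements(scores, pos)
    return float(auc)


def youden_cutoff(roc: RocAnalysis) -> tuple[float, float, float]:
    """Threshold maximizing J = sensitivity + specificity − 1.

    Ties are broken toward higher sensitivity (the conservative,
    admission-favoring choice), then toward the lower threshold. Returns
    (threshold, sensitivity, specificity); scores ≥ threshold are called
    inpatient.
    """
    j = roc.tpr - roc.fpr
    best = None
    for i in range(len(j)):
        key = (j[i], roc.tpr[i], -roc.thresholds[i])
        if best is None or key > best[0]:
            best = (key, i)
    i = best[1]
    return float(roc.thresholds[i]), float(roc.tpr[i]), float(1.0 - roc.fpr[i])


def sens_spec_ci(
    tp: int, fn: int, tn: int, fp: int, confidence: float = 0.95
) -> tuple[tuple[float, float, float], tuple[float, float, float]]:
    """Sensitivity and specificity with Wilson score intervals.

    Returns ((sens, lo, hi), (spec, lo, hi)).
    """
    if min(tp, fn, tn, fp) < 0:
        raise ValueError("counts must be non-negative")
    if tp + fn == 0 or tn + fp == 0:
        raise ValueError("both tp+fn and tn+fp must be positive")
    alpha = 1.0 - confidence
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    s_lo, s_hi = proportion_confint(tp, tp + fn, alpha=alpha, method="wilson")
    p_lo, p_hi = proportion_confint(tn, tn + fp, alpha=alpha, method="wilson")
    return (sens, float(s_lo), float(s_hi)), (spec, float(p_lo), float(p_hi))


def binary_ratings_as_scores(ratings) -> np.ndarray:
    """Encode binary ratings as {0, 1} scores (inpatient → 1) for ROC use."""
    r = np.asarray(ratings)
    if r.dtype.kind in "biu":
        return r.astype(float)
    return (r == INPATIENT).astype(float)


# ---------------------------------------------------------------------------
# DeLong's test for two correlated ROC curves
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DeLongResult:
    auroc_a: float
    auroc_b: float
    variance_a: float
    variance_b: float
    covariance: float
    z: float
    p: float


def delong_test(scores_a, scores_b, labels) -> DeLongResult:
    """DeLong's nonparametric comparison of two AUROCs on the same cases.

    Placement (structural-component) values are computed per case for each
    curve with midranks for ties; their empirical covariance gives the
    variance of the AUROC difference, z = (A₁ − A₂)/sqrt(v₁ + v₂ − 2c),
    and a two-sided normal p-value. Identical curves give z = 0, p = 1.
    """
    scores_a = np.asarray(scores_a, dtype=np.float64)
    scores_b = np.asarray(scores_b, dtype=np.float64)
    if scores_a.shape != scores_b.shape:
        raise ValueError(
            f"score vectors must cover the same cases: {scores_a.shape} vs "
            f"{scores_b.shape}"
        )
    pos = _positive_mask(labels)
    if pos.shape != scores_a.shape:
        raise ValueError("labels must align with the score vectors")
    auc_a, v01_a, v10_a = _delong_placements(scores_a, pos)
    auc_b, v01_b, v10_b = _delong_placements(scores_b, pos)
    m, n = v01_a.size, v10_a.size

    s01 = np.cov(np.vstack([v01_a, v01_b]), ddof=1) if m > 1 else np.zeros((2, 2))
    s10 = np.cov(np.vstack([v10_a, v10_b]), ddof=1) if n > 1 else np.zeros((2, 2))
    s = s01 / m + s10 / n
    var_a, var_b, cov = float(s[0, 0]), float(s[1, 1]), float(s[0, 1])
    var_diff = var_a + var_b - 2.0 * cov

    if var_diff <= 1e-15:
        if abs(auc_a - auc_b) < 1e-12:
            z, p = 0.0, 1.0
        else:
            raise ValueError(
                "degenerate comparison: zero variance of the AUROC difference "
                "with unequal AUROCs"
            )
    else:
        z = float((auc_a - auc_b) / math.sqrt(var_diff))
        p = float(2.0 * norm.sf(abs(z)))
    return DeLongResult(
        auroc_a=float(auc_a),
        auroc_b=float(auc_b),
        variance_a=var_a,
        variance_b=var_b,
        covariance=cov,
        z=z,
        p=p,
    )


# ---------------------------------------------------------------------------
# Inter-rater agreement
# ---------------------------------------------------------------------------

#: Landis–Koch strength-of-agreement bands; the study's gate for pooling a
#: physician pair is kappa ≥ 0.61 ("substantial" or better).
_KAPPA_BANDS = (
    (0.0, "poor"),
    (0.21, "slight"),
    (0.41, "fair"),
    (0.61, "moderate"),
    (0.81, "substantial"),
    (1.01, "almost perfect"),
)


def kappa_band(kappa: float) -> str:
    for upper, name in _KAPPA_BANDS:
        if kappa < upper:
            return name
    return "almost perfect"


@dataclass(frozen=True)
class KappaResult:
    po: float
    pe: float
    kappa: float
    band: str


def cohens_kappa(ratings_a, ratings_b) -> KappaResult:
    """Cohen's kappa for two equal-length rating vectors.

    po is the observed agreement, pe the chance agreement from the raters'
    marginal frequencies, kappa = (po − pe)/(1 − pe). When pe = 1 (both
    raters constant on the same category) kappa is defined as 1.
    """
    a = np.asarray(ratings_a)
    b = np.asarray(ratings_b)
    if a.shape != b.shape or a.ndim != 1 or a.size == 0:
        raise ValueError("ratings must be equal-length non-empty vectors")
    n = a.size
    po = float(np.mean(a == b))
    cats = np.union1d(a, b)
    pe = float(
        sum(np.mean(a == c) * np.mean(b == c) for c in cats)
    )
    if pe >= 1.0 - 1e-15:
        if po >= 1.0 - 1e-15:
            kappa = 1.0
        else:
            raise ValueError("chance agreement pe = 1 with imperfect agreement")
    else:
        kappa = (po - pe) / (1.0 - pe)
    return KappaResult(po=po, pe=pe, kappa=float(kappa), band=kappa_band(kappa))


def aggregate_conservative(ratings_a, ratings_b) -> np.ndarray:
    """Pool a rater pair: agreement keeps the common answer; disagreement
    resolves to "inpatient" (the patient-safety-maximizing call)."""
    a = np.asarray(ratings_a)
    b = np.asarray(ratings_b)
    if a.shape != b.shape:
        raise ValueError("rating vectors must cover the same cases")
    return np.where(a == b, a, INPATIENT)


# ---------------------------------------------------------------------------
# Concordance accounting (machine vs. physician groups)
# ---------------------------------------------------------------------------

_CATEGORIES = (
    ("all_wrong", "Machine and physicians were wrong"),
    ("machine_only_correct", "Machine was correct and all physicians were wrong"),
    ("physicians_only_correct", "All physicians were correct and machine was wrong"),
    ("physician_groups_diverge", "Divergences between novice and experienced physicians"),
    ("all_correct", "Machine and physicians were correct"),
)


@dataclass(frozen=True)
class ConcordanceTable:
    """Five mutually exclusive outcome categories, per truth class and total.

    ``counts[category]`` is a (discharged, inpatient) pair keyed by the true
    disposition; categories partition the evaluated cases. Divergence
    between the two physician groups takes precedence over the
    machine-correctness categories.
    """

    counts: dict[str, tuple[int, int]]  # category -> (discharged, admitted)
    n_cases: int

    def total(self, category: str) -> int:
        d, a = self.counts[category]
        return d + a

    def percentage(self, category: str, which: str = "total") -> float:
        d, a = self.counts[category]
        value = {"discharged": d, "admitted": a, "total": d + a}[which]
        return 100.0 * value / self.n_cases

    def to_tsv(self) -> str:
        lines = ["Situation\tDischarged Patients\tAdmitted Patients\tTotal"]
        for key, desc in _CATEGORIES:
            d, a = self.counts[key]
            cells = [
                f"{v} ({100.0 * v / self.n_cases:.2f}%)" for v in (d, a, d + a)
            ]
            lines.append(desc + "\t" + "\t".join(cells))
        return "\n".join(lines) + "\n"


def concordance_table(
    machine_preds, group1_preds, group2_preds, truth
) -> ConcordanceTable:
    """Assign every case to exactly one of five outcome categories.

    A case where the two physician groups disagree with each other is a
    divergence regardless of the machine; the remaining cases split by
    machine and (unanimous) physician correctness.
    """
    vectors = [np.asarray(v) for v in (machine_preds, group1_preds, group2_preds, truth)]
    shape = vectors[0].shape
    if any(v.shape != shape for v in vectors) or vectors[0].ndim != 1:
        raise ValueError("all four vectors must be equal-length 1-d")
    machine, g1, g2, y = vectors

    counts = {key: [0, 0] for key, _ in _CATEGORIES}
    for i in range(len(y)):
        cls = 1 if y[i] == INPATIENT else 0
        if g1[i] != g2[i]:
            key = "physician_groups_diverge"
        else:
            m_ok = machine[i] == y[i]
            p_ok = g1[i] == y[i]
            if m_ok and p_ok:
                key = "all_correct"
            elif m_ok:
                key = "machine_only_correct"
            elif p_ok:
                key = "physicians_only_correct"
            else:
                key = "all_wrong"
        counts[key][cls] += 1
    return ConcordanceTable(
        counts={k: (v[0], v[1]) for k, v in counts.items()}, n_cases=len(y)
    )
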