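"""Evaluation statistics: splitting, margin of error, ROC/AUROC estimator
equivalence, Youden cutoff, Wilson intervals, DeLong test, kappa,
conservative aggregation and concordance accounting — each checked against
an independent naive oracle where one exists."""

import math

import numpy as np
import pytest
from scipy.stats import norm, rankdata
from sklearn.metrics import cohen_kappa_score

from soaptriage import (
    DISCHARGED,
    INPATIENT,
    SplitSpec,
    aggregate_conservative,
    auroc_mann_whitney,
    binary_ratings_as_scores,
    cohens_kappa,
    concordance_table,
    delong_test,
    delong_variance,
    kappa_band,
    margin_of_error,
    roc_analysis,
    sens_spec_ci,
    stratified_split,
    youden_cutoff,
)
from conftest import random_scores_labels

# ---------------------------------------------------------------------------
# naive oracles
# ---------------------------------------------------------------------------


def naive_auroc(scores, labels):
    """Exhaustive positive-negative pair count with half credit for ties."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for x in pos:
        for y in neg:
            total += 1.0 if x > y else (0.5 if x == y else 0.0)
    return total / (len(pos) * len(neg))


def naive_delong_variance(scores, labels):
    """Structural components by double loop (midranks implicit in psi)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = len(pos), len(neg)

    def psi(x, y):
        return 1.0 if x > y else (0.5 if x == y else 0.0)

    v10 = np.array([np.mean([psi(x, y) for y in neg]) for x in pos])
    v01 = np.array([np.mean([psi(x, y) for x in pos]) for y in neg])
    return v10.var(ddof=1) / m + v01.var(ddof=1) / n


# ---------------------------------------------------------------------------
# stratified split
# ---------------------------------------------------------------------------


class TestStratifiedSplit:
    def test_study_scale_bookkeeping(self):
        """Explicit per-class test counts (120 discharged, 110 inpatient)
        drawn from 4,673 / 4,357 leave a 4,553 / 4,247 training set."""
        labels = [DISCHARGED] * 4673 + [INPATIENT] * 4357
        spec = SplitSpec(test_counts={DISCHARGED: 120, INPATIENT: 110}, seed=1)
        train, test = stratified_split(labels, spec)
        assert len(test) == 230
        assert len(train) == 8800
        assert train.count(DISCHARGED) == 4553
        assert train.count(INPATIENT) == 4247

    def test_tiny_fraction_rounds_to_empty_test_set(self):
        labels = [INPATIENT] * 3 + [DISCHARGED] * 3
        train, test = stratified_split(labels, SplitSpec(test_fraction=0.05, seed=0))
        assert test == []
        assert len(train) == 6

    def test_same_seed_same_partition(self, small_corpus):
        spec = SplitSpec(test_fraction=0.3, seed=42)
        a = stratified_split(list(small_corpus), spec)
        b = stratified_split(list(small_corpus), spec)
        assert a == b

    def test_fraction_is_stratified_within_rounding(self, small_corpus):
        train, test = stratified_split(
            list(small_corpus), SplitSpec(test_fraction=0.25, seed=9)
        )
        n_inp = sum(r.label == INPATIENT for r in small_corpus)
        got = sum(r.label == INPATIENT for r in test)
        assert got == int(math.floor(0.25 * n_inp + 0.5))

    def test_counts_exceeding_class_size_rejected(self):
        with pytest.raises(ValueError, match="available"):
            stratified_split(
                [INPATIENT, DISCHARGED],
                SplitSpec(test_counts={INPATIENT: 2}, seed=0),
            )


class TestMarginOfError:
    def test_study_sample_gives_6_4_percent(self):
        assert margin_of_error(230, 9030, 0.95) == pytest.approx(0.064, abs=5e-4)

    def test_census_has_zero_margin(self):
        assert margin_of_error(500, 500, 0.95) == 0.0

    def test_infinite_population_closed_form(self):
        # 1.96 * sqrt(0.25/100) = 0.098
        assert margin_of_error(100, None, 0.95) == pytest.approx(0.098, abs=1e-3)

    def test_oversampling_rejected(self):
        with pytest.raises(ValueError):
            margin_of_error(10, 5)


# ---------------------------------------------------------------------------
# ROC / AUROC
# ---------------------------------------------------------------------------


class TestRoc:
    def test_perfect_separation(self):
        roc = roc_analysis([3.0, 2.0, -1.0, -2.0], [1, 1, 0, 0])
        assert roc.auroc == 1.0

    def test_all_tied_scores_give_half(self):
        roc = roc_analysis([1.0] * 6, [1, 1, 1, 0, 0, 0])
        assert roc.auroc == 0.5

    def test_exhaustive_pair_count_example(self):
        # positives {0.9, 0.8}, negatives {0.85, 0.7}: 3 of 4 pairs concordant
        roc = roc_analysis([0.9, 0.8, 0.85, 0.7], [1, 1, 0, 0])
        assert roc.auroc == pytest.approx(0.75)

    def test_curve_is_monotone_with_proper_endpoints(self, rng):
        scores, labels = random_scores_labels(rng, n=60, tie_prob=0.5)
        roc = roc_analysis(scores, labels)
        assert (np.diff(roc.tpr) >= 0).all() and (np.diff(roc.fpr) >= 0).all()
        assert (roc.fpr[0], roc.tpr[0]) == (0.0, 0.0)
        assert (roc.fpr[-1], roc.tpr[-1]) == (1.0, 1.0)
        assert roc.ci95[0] <= roc.auroc <= roc.ci95[1]

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            roc_analysis([1.0, 2.0], [1, 1])

    def test_trapezoid_equals_mann_whitney_including_ties(self, rng):
        for k in range(300):
            scores, labels = random_scores_labels(
                rng, n=30, tie_prob=0.5 if k % 2 else 0.0
            )
            trap = roc_analysis(scores, labels).auroc
            mw = auroc_mann_whitney(scores, labels)
            assert abs(trap - mw) < 1e-12
            assert abs(mw - naive_auroc(scores, labels)) < 1e-12

    def test_reversed_scores_complement_auroc(self, rng):
        scores, labels = random_scores_labels(rng, n=50)
        a = auroc_mann_whitney(scores, labels)
        b = auroc_mann_whitney(-scores, labels)
        assert a + b == pytest.approx(1.0, abs=1e-12)

    def test_single_positive_above_all_negatives(self):
        assert auroc_mann_whitney([5.0, 1.0, 2.0], [1, 0, 0]) == 1.0

    def test_binary_ratings_make_two_segment_curve(self):
        ratings = [INPATIENT, INPATIENT, DISCHARGED, DISCHARGED, INPATIENT]
        truth = [INPATIENT, INPATIENT, INPATIENT, DISCHARGED, DISCHARGED]
        roc = roc_analysis(binary_ratings_as_scores(ratings), truth)
        assert len(roc.thresholds) == 3  # one interior operating point


class TestYouden:
    def test_perfect_classifier_reaches_j_of_one(self):
        roc = roc_analysis([2.0, 1.0, -1.0, -2.0], [1, 1, 0, 0])
        thr, sens, spec = youden_cutoff(roc)
        assert sens + spec - 1 == pytest.approx(1.0)
        assert -1.0 < thr <= 1.0

    def test_uninformative_scores_give_j_zero(self):
        roc = roc_analysis([1.0] * 4, [1, 1, 0, 0])
        thr, sens, spec = youden_cutoff(roc)
        assert sens + spec - 1 == pytest.approx(0.0)
        assert sens == 1.0  # conservative tie-break: favor sensitivity

    def test_argmax_agrees_with_exhaustive_scan(self):
        scores = np.array([0.1, 0.4, 0.35, 0.8, 0.65, 0.05])
        labels = np.array([0, 0, 1, 1, 1, 0])
        roc = roc_analysis(scores, labels)
        thr, sens, spec = youden_cutoff(roc)
        best_j = max(
            np.mean(scores[labels == 1] >= t) - np.mean(scores[labels == 0] >= t)
            for t in scores
        )
        assert sens + spec - 1 == pytest.approx(best_j)
        assert np.mean(scores[labels == 1] >= thr) == pytest.approx(sens)

    def test_thresholding_at_cutoff_reproduces_sens_spec(self, rng):
        scores, labels = random_scores_labels(rng, n=80, tie_prob=0.3)
        roc = roc_analysis(scores, labels)
        thr, sens, spec = youden_cutoff(roc)
        pred = scores >= thr
        assert np.mean(pred[labels == 1]) == pytest.approx(sens)
        assert np.mean(~pred[labels == 0]) == pytest.approx(spec)


class TestSensSpecCi:
    def test_certain_sensitivity_has_unit_upper_bound(self):
        (sens, lo, hi), _ = sens_spec_ci(10, 0, 5, 5)
        assert sens == 1.0 and hi == pytest.approx(1.0, abs=1e-12) and lo < 1.0

    def test_even_split_gives_half(self):
        (sens, _, _), _ = sens_spec_ci(7, 7, 5, 5)
        assert sens == 0.5

    def test_wilson_bounds_match_direct_formula(self):
        tp, fn, tn, fp = 85, 15, 78, 22
        (sens, s_lo, s_hi), (spec, p_lo, p_hi) = sens_spec_ci(tp, fn, tn, fp)
        z = norm.ppf(0.975)

        def wilson(k, n):
            p = k / n
            centre = (p + z**2 / (2 * n)) / (1 + z**2 / n)
            half = (
                z * math.sqrt(p * (1 - p) / n + z**2 / (4 * n**2)) / (1 + z**2 / n)
            )
            return centre - half, centre + half

        assert (s_lo, s_hi) == pytest.approx(wilson(tp, tp + fn), abs=1e-12)
        assert (p_lo, p_hi) == pytest.approx(wilson(tn, tn + fp), abs=1e-12)
        assert sens == 0.85 and spec == 0.78

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValueError):
            sens_spec_ci(0, 0, 5, 5)


# ---------------------------------------------------------------------------
# DeLong
# ---------------------------------------------------------------------------


class TestDeLong:
    def test_identical_curves_give_z_zero_p_one(self, rng):
        scores, labels = random_scores_labels(rng, n=40)
        res = delong_test(scores, scores.copy(), labels)
        assert res.z == 0.0 and res.p == 1.0

    def test_variance_matches_brute_force_on_30_cases(self, rng):
        for k in range(20):
            scores, labels = random_scores_labels(
                rng, n=30, tie_prob=0.4 if k % 2 else 0.0
            )
            fast = delong_variance(scores, labels)
            slow = naive_delong_variance(scores, labels)
            assert abs(fast - slow) < 1e-12

    def test_p_is_two_sided_normal_tail(self, rng):
        scores_a, labels = random_scores_labels(rng, n=60)
        scores_b = scores_a + rng.normal(0, 1.5, 60)
        res = delong_test(scores_a, scores_b, labels)
        assert res.p == pytest.approx(2 * norm.sf(abs(res.z)), abs=1e-15)
        assert res.variance_a > 0 and res.variance_b > 0

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError, match="same cases"):
            delong_test([1.0, 2.0], [1.0], [1, 0])

    def test_variance_tracks_bootstrap_on_100_cases(self, rng):
        """DeLong's analytic variance should sit within 15% of a stratified
        bootstrap estimate of the AUROC sampling variance."""
        n_pos = n_neg = 50
        scores = np.r_[rng.normal(0.8, 1, n_pos), rng.normal(0, 1, n_neg)]
        labels = np.r_[np.ones(n_pos, int), np.zeros(n_neg, int)]
        analytic = delong_variance(scores, labels)

        reps = 10_000
        pos_samples = scores[:n_pos][rng.integers(0, n_pos, (reps, n_pos))]
        neg_samples = scores[n_pos:][rng.integers(0, n_neg, (reps, n_neg))]
        ranks = rankdata(np.hstack([pos_samples, neg_samples]), axis=1)
        aucs = (ranks[:, :n_pos].sum(axis=1) - n_pos * (n_pos + 1) / 2) / (
            n_pos * n_neg
        )
        boot = aucs.var(ddof=1)
        assert abs(analytic - boot) / boot < 0.15


# ---------------------------------------------------------------------------
# kappa, aggregation, concordance
# ---------------------------------------------------------------------------


class TestKappa:
    def test_identical_ratings(self):
        res = cohens_kappa([INPATIENT, DISCHARGED] * 5, [INPATIENT, DISCHARGED] * 5)
        assert res.kappa == 1.0 and res.band == "almost perfect"

    def test_constant_vs_balanced_rater_gives_zero(self):
        a = [INPATIENT] * 10
        b = [INPATIENT] * 5 + [DISCHARGED] * 5
        res = cohens_kappa(a, b)
        assert res.po == 0.5 and res.pe == 0.5 and res.kappa == 0.0

    def test_two_by_two_table_example(self):
        # [[10, 2], [3, 15]]: po = 25/30, pe from marginals, kappa ~ 0.6575
        a = [INPATIENT] * 12 + [DISCHARGED] * 18
        b = (
            [INPATIENT] * 10 + [DISCHARGED] * 2
            + [INPATIENT] * 3 + [DISCHARGED] * 15
        )
        res = cohens_kappa(a, b)
        assert res.kappa == pytest.approx(0.6575, abs=5e-4)
        assert res.band == "substantial"

    def test_agrees_with_sklearn_on_random_vectors(self, rng):
        for _ in range(25):
            a = rng.integers(0, 2, 30)
            b = rng.integers(0, 2, 30)
            if (a == b).all() or len(np.union1d(a, b)) < 2:
                continue
            res = cohens_kappa(a, b)
            assert res.kappa == pytest.approx(
                cohen_kappa_score(a, b), abs=1e-12
            )

    def test_kappa_bounded_by_observed_agreement(self, rng):
        for _ in range(25):
            a = rng.integers(0, 2, 20)
            b = rng.integers(0, 2, 20)
            res = cohens_kappa(a, b)
            assert res.kappa <= res.po + 1e-12 <= 1 + 1e-12
            assert (res.kappa == 1.0) == bool((np.asarray(a) == np.asarray(b)).all())

    def test_band_boundaries(self):
        assert kappa_band(0.61) == "substantial"
        assert kappa_band(0.80) == "substantial"
        assert kappa_band(0.81) == "almost perfect"
        assert kappa_band(-0.2) == "poor"

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            cohens_kappa([1, 0], [1])


class TestAggregateConservative:
    def test_disagreement_resolves_to_inpatient(self):
        out = aggregate_conservative([INPATIENT], [DISCHARGED])
        assert out[0] == INPATIENT

    def test_agreement_keeps_common_answer(self):
        out = aggregate_conservative([DISCHARGED], [DISCHARGED])
        assert out[0] == DISCHARGED

    def test_inpatient_count_never_decreases(self, rng):
        cats = np.array([INPATIENT, DISCHARGED])
        for _ in range(20):
            a = cats[rng.integers(0, 2, 40)]
            b = cats[rng.integers(0, 2, 40)]
            pooled = aggregate_conservative(a, b)
            n_pooled = (pooled == INPATIENT).sum()
            assert n_pooled >= (a == INPATIENT).sum()
            assert n_pooled >= (b == INPATIENT).sum()


def build_concordance_vectors():
    """Construct 230 cases realizing the study's published concordance
    per-class category counts."""
    # (truth, n, machine_ok, phys_ok, diverge) per block
    blocks = [
        (DISCHARGED, 9, False, False, False),   # all wrong
        (INPATIENT, 1, False, False, False),
        (DISCHARGED, 12, True, False, False),   # machine only
        (INPATIENT, 2, True, False, False),
        (DISCHARGED, 10, False, True, False),   # physicians only
        (INPATIENT, 9, False, True, False),
        (DISCHARGED, 23, False, False, True),   # groups diverge
        (INPATIENT, 27, False, False, True),
        (DISCHARGED, 66, True, True, False),    # all correct
        (INPATIENT, 71, True, True, False),
    ]
    flip = {INPATIENT: DISCHARGED, DISCHARGED: INPATIENT}
    machine, g1, g2, truth = [], [], [], []
    for t, n, m_ok, p_ok, div in blocks:
        for _ in range(n):
            truth.append(t)
            machine.append(t if m_ok else flip[t])
            if div:
                g1.append(t)
                g2.append(flip[t])
            else:
                g1.append(t if p_ok else flip[t])
                g2.append(t if p_ok else flip[t])
    return machine, g1, g2, truth


class TestConcordance:
    def test_reproduces_published_accounting(self):
        table = concordance_table(*build_concordance_vectors())
        assert table.n_cases == 230
        assert table.total("all_wrong") == 10
        assert table.total("machine_only_correct") == 14
        assert table.total("physicians_only_correct") == 19
        assert table.total("physician_groups_diverge") == 50
        assert table.total("all_correct") == 137
        assert table.counts["all_correct"] == (66, 71)
        assert table.percentage("all_correct") == pytest.approx(59.56, abs=0.01)

    def test_everyone_correct(self):
        y = [INPATIENT, DISCHARGED] * 4
        table = concordance_table(y, y, y, y)
        assert table.total("all_correct") == 8
        assert all(
            table.total(k) == 0
            for k in table.counts
            if k != "all_correct"
        )

    def test_categories_partition_cases(self, rng):
        cats = np.array([INPATIENT, DISCHARGED])
        for _ in range(10):
            vecs = [cats[rng.integers(0, 2, 35)] for _ in range(4)]
            table = concordance_table(*vecs)
            assert sum(table.total(k) for k in table.counts) == 35

    def test_divergence_takes_precedence(self):
        # machine correct, groups disagree -> divergence, not machine-only
        table = concordance_table(
            [INPATIENT], [INPATIENT], [DISCHARGED], [INPATIENT]
        )
        assert table.total("physician_groups_diverge") == 1

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            concordance_table([INPATIENT], [INPATIENT], [INPATIENT], [])
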