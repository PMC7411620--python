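"""Metric definitions checked against hand tallies and the published
study matrices (where the derivation is orientation-safe)."""

import numpy as np
import pytest

from temsense.evaluation import (
    ConfusionMatrix,
    accuracy,
    cohen_kappa,
    confusion,
    metric_report,
    nominal_error_stats,
    per_class_rates,
    precision_recall_f,
)
from temsense.fusion_classify import ClassifierConfig, CVResult
from temsense.labeling import EMOTIONS
from temsense.reference import load_study_confusion

PERFECT = ConfusionMatrix(np.diag([9, 22, 40, 13]))


def _toy_cv(y_true, y_pred, proba=None, priors=None):
    n = len(y_true)
    if proba is None:
        proba = np.array([
            [1.0 if c == p else 0.0 for c in EMOTIONS] for p in y_pred
        ])
    if priors is None:
        priors = np.tile([0.25, 0.25, 0.25, 0.25], (n, 1))
    return CVResult(
        fold_id=np.zeros(n, dtype=int),
        y_true=np.array(y_true, dtype=object),
        y_pred=np.array(y_pred, dtype=object),
        proba=np.asarray(proba, dtype=float),
        priors=np.asarray(priors, dtype=float),
        config=ClassifierConfig(),
    )


class TestConfusion:
    def test_manual_tally(self):
        cv = _toy_cv(
            ["happy", "happy", "sad", "angry", "relaxed", "sad"],
            ["happy", "sad", "sad", "happy", "relaxed", "sad"],
        )
        cm = confusion(cv)
        expected = np.array([
            [1, 0, 0, 0],  # relaxed
            [0, 2, 0, 0],  # sad
            [0, 1, 1, 0],  # happy
            [0, 0, 1, 0],  # angry
        ])
        assert np.array_equal(cm.counts, expected)

    def test_row_sums_conserve_class_counts(self):
        cv = _toy_cv(["happy"] * 4 + ["sad"] * 2, ["sad"] * 6)
        cm = confusion(cv)
        assert cm.counts.sum(axis=1).tolist() == [0, 2, 4, 0]
        assert cm.n == 6

    def test_all_correct_is_diagonal(self):
        cv = _toy_cv(["happy", "sad"], ["happy", "sad"])
        cm = confusion(cv)
        assert np.trace(cm.counts) == cm.n


class TestAccuracyKappa:
    def test_perfect_matrix(self):
        assert accuracy(PERFECT) == 100.0
        assert cohen_kappa(PERFECT) == pytest.approx(1.0)

    def test_study_accuracies(self):
        expected = {"eeg": 75.00, "gsr": 72.61, "ppg": 78.57, "fusion": 79.76}
        for modality, acc in expected.items():
            cm = load_study_confusion(modality)
            assert accuracy(cm) == pytest.approx(acc, abs=0.01)

    def test_study_kappas(self):
        assert cohen_kappa(load_study_confusion("ppg")) == pytest.approx(0.678, abs=1e-3)
        assert cohen_kappa(load_study_confusion("fusion")) == pytest.approx(0.690, abs=1e-3)

    def test_kappa_transpose_invariance(self):
        for modality in ("eeg", "gsr", "ppg", "fusion"):
            cm = load_study_confusion(modality)
            cm_t = ConfusionMatrix(cm.counts.T)
            assert cohen_kappa(cm_t) == pytest.approx(cohen_kappa(cm))
            assert accuracy(cm_t) == pytest.approx(accuracy(cm))

    def test_permutation_invariance(self):
        rng = np.random.default_rng(30)
        counts = rng.integers(0, 20, size=(4, 4))
        counts[0, 0] += 1  # ensure nonzero total
        cm = ConfusionMatrix(counts)
        perm = rng.permutation(4)
        permuted = ConfusionMatrix(counts[np.ix_(perm, perm)])
        assert accuracy(permuted) == pytest.approx(accuracy(cm))
        assert cohen_kappa(permuted) == pytest.approx(cohen_kappa(cm))


class TestPerClassRates:
    def test_study_eeg_matrix_rates(self):
        """The EEG matrix is row-consistent with the study's class counts;
        happy sensitivity = 33/40 and angry specificity = 69/71 by the
        brute-force definitions."""
        cm = load_study_confusion("eeg")
        rates = per_class_rates(cm)
        assert rates.loc["happy", "sensitivity"] == pytest.approx(33 / 40)
        assert rates.loc["angry", "specificity"] == pytest.approx(69 / 71)
        assert rates.loc["relaxed", "sensitivity"] == pytest.approx(6 / 9)
        assert rates.loc["sad", "sensitivity"] == pytest.approx(15 / 22)

    def test_perfect_matrix_rates(self):
        rates = per_class_rates(PERFECT)
        assert (rates["sensitivity"] == 1.0).all()
        assert (rates["specificity"] == 1.0).all()

    def test_empty_class_row_gives_nan_sensitivity(self):
        counts = np.diag([5, 5, 5, 0])
        counts[3, 0] = 0
        rates = per_class_rates(ConfusionMatrix(counts))
        assert np.isnan(rates.loc["angry", "sensitivity"])


class TestPrecisionRecallF:
    def test_perfect_matrix(self):
        prf = precision_recall_f(PERFECT)
        assert (prf.loc[list(EMOTIONS)] == 1.0).all().all()
        assert (prf.loc["weighted_avg"] == 1.0).all()

    def test_study_eeg_relaxed_precision(self):
        prf = precision_recall_f(load_study_confusion("eeg"))
        assert prf.loc["relaxed", "precision"] == pytest.approx(6 / 11)

    def test_f_equals_precision_when_balanced(self):
        cm = load_study_confusion("eeg")
        prf = precision_recall_f(cm)
        for c in EMOTIONS:
            p, r, f = prf.loc[c]
            if p == r:
                assert f == pytest.approx(p)
            else:
                assert f == pytest.approx(2 * p * r / (p + r))


class TestNominalErrorStats:
    def test_perfect_confident_predictions(self):
        cv = _toy_cv(["happy", "sad"], ["happy", "sad"])
        stats = nominal_error_stats(cv)
        assert stats == {"mae": 0.0, "rmse": 0.0, "rae_pct": 0.0, "rrse_pct": 0.0}

    def test_predicting_priors_gives_100_percent_relative_error(self):
        priors = np.tile([9 / 84, 22 / 84, 40 / 84, 13 / 84], (8, 1))
        y = ["happy", "sad", "angry", "relaxed"] * 2
        cv = _toy_cv(y, y, proba=priors, priors=priors)
        stats = nominal_error_stats(cv)
        assert stats["rae_pct"] == pytest.approx(100.0)
        assert stats["rrse_pct"] == pytest.approx(100.0)

    def test_two_instance_two_class_hand_example(self):
        """p = (.75, .25) vs truth (1, 0) and p = (.5, .5) vs truth (0, 1)
        over two classes: MAE = (0.25 + 0.25 + 0.5 + 0.5) / 4 = 0.375."""
        cv = CVResult(
            fold_id=np.zeros(2, dtype=int),
            y_true=np.array(["relaxed", "sad"], dtype=object),
            y_pred=np.array(["relaxed", "relaxed"], dtype=object),
            proba=np.array([[0.75, 0.25], [0.5, 0.5]]),
            priors=np.tile([0.5, 0.5], (2, 1)),
            classes=("relaxed", "sad"),
            config=ClassifierConfig(),
        )
        stats = nominal_error_stats(cv)
        assert stats["mae"] == pytest.approx(0.375)
        manual_rmse = np.sqrt((0.25**2 + 0.25**2 + 0.5**2 + 0.5**2) / 4)
        assert stats["rmse"] == pytest.approx(manual_rmse)

    def test_rmse_and_relative_errors_nonnegative(self, feature_matrix, dataset_labels):
        from temsense.fusion_classify import cross_validate

        cv = cross_validate(feature_matrix, dataset_labels, ClassifierConfig(seed=2))
        stats = nominal_error_stats(cv)
        assert 0 <= stats["mae"] <= 1
        assert stats["rmse"] >= stats["mae"]  # quadratic mean dominates
        assert stats["rae_pct"] >= 0 and stats["rrse_pct"] >= 0


def test_metric_report_is_complete(feature_matrix, dataset_labels):
    from temsense.fusion_classify import cross_validate

    cv = cross_validate(feature_matrix, dataset_labels, ClassifierConfig(seed=5))
    report = metric_report(cv)
    assert report["n"] == 84
    assert 0 <= report["accuracy_pct"] <= 100
    assert -1 < report["kappa"] < 1
    assert set(report["per_class"]) == set(EMOTIONS)
    for c in EMOTIONS:
        pc = report["per_class"][c]
        if pc["precision"] == pc["recall"] and pc["precision"] > 0:
            assert pc["f_score"] == pytest.approx(pc["precision"])
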