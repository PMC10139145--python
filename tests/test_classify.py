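"""Feature assembly, the four-learner CV harness, and confusion rates."""

import numpy as np
import pytest
from sklearn.preprocessing import StandardScaler

from tfdp import (
    ClassSpec,
    CohortConfig,
    assemble_features,
    confusion_rates,
    generate_cohort,
    run_cv,
)
from tfdp.classify import default_configs
from tfdp.errors import InvalidInputError, StratificationError

ALGOS = ("LR", "SVM", "RF", "ADABOOST")


@pytest.fixture(scope="module")
def separable_cohort():
    """Two classes with biomarker means 8 degC apart and tight spread."""
    cfg = CohortConfig(
        control=ClassSpec(64.0, 78.0, sd_t1m=0.5, sd_t2m=0.5, n=15),
        poag=ClassSpec(56.0, 70.0, sd_t1m=0.5, sd_t2m=0.5, n=15),
        seed=21,
    )
    ds = generate_cohort(cfg)
    X, y = assemble_features(ds.runs, grid_step=2.0)
    return X, y


class TestAssembleFeatures:
    def test_default_grid_726_features(self, small_cohort):
        X, y = assemble_features(small_cohort.runs[:10], grid_step=0.5)
        assert X.shape == (10, 726)
        assert y is not None and set(np.unique(y)) <= {0, 1}

    def test_one_degree_grid_366_features(self, small_cohort):
        X, _ = assemble_features(small_cohort.runs[:10], grid_step=1.0)
        assert X.shape == (10, 366)

    def test_single_run_ok(self, small_cohort):
        X, _ = assemble_features(small_cohort.runs[:1], grid_step=0.5)
        assert X.shape == (1, 726)

    def test_incommensurate_grid_step_rejected(self, small_cohort):
        with pytest.raises(InvalidInputError):
            assemble_features(small_cohort.runs[:2], grid_step=0.13)


class TestRunCV:
    def test_separable_cohort_all_learners_above_95(self, separable_cohort):
        X, y = separable_cohort
        report = run_cv(X, y, seed=0)
        for alg in ALGOS:
            assert report.results[alg].mean_accuracy_pct >= 95.0

    def test_seeded_reports_identical(self, separable_cohort):
        X, y = separable_cohort
        a = run_cv(X, y, seed=3).to_json()
        b = run_cv(X, y, seed=3).to_json()
        assert a == b

    def test_fold_split_invariant_to_sample_order(self, separable_cohort):
        """Accuracies depend on the seed-driven shuffle, not the input order."""
        X, y = separable_cohort
        perm = np.random.default_rng(5).permutation(len(y))
        a = run_cv(X, y, seed=4)
        b = run_cv(X[perm], y[perm], seed=4)
        for alg in ALGOS:
            assert a.results[alg].mean_accuracy_pct == pytest.approx(
                b.results[alg].mean_accuracy_pct, abs=1e-9
            )

    def test_permutation_null_within_binomial_band(self, separable_cohort):
        X, y = separable_cohort
        yp = np.random.default_rng(11).permutation(y)
        report = run_cv(X, yp, seed=11)
        half = 1.96 * np.sqrt(0.25 / len(y)) * 100
        for alg in ALGOS:
            assert 50 - half <= report.results[alg].mean_accuracy_pct <= 50 + half

    def test_global_scaling_does_not_change_null_conclusion(self, separable_cohort):
        """Leakage regression check: z-scoring on the full dataset (instead of
        per training fold) must not lift permutation-null accuracy out of the
        chance band."""
        X, y = separable_cohort
        yp = np.random.default_rng(13).permutation(y)
        X_leaky = StandardScaler().fit_transform(X)
        report = run_cv(X_leaky, yp, seed=13)
        half = 1.96 * np.sqrt(0.25 / len(y)) * 100
        for alg in ALGOS:
            assert 50 - half <= report.results[alg].mean_accuracy_pct <= 50 + half

    def test_null_band_rate_over_20_seeded_permutations(self):
        """Each learner stays inside the 95% binomial chance band in >= 18 of
        20 seeded label permutations of a default-means cohort (coarse 5 degC
        feature grid to keep this fast)."""
        cfg = CohortConfig(
            control=ClassSpec(67.9, 77.7, n=20), poag=ClassSpec(64.6, 79.3, n=20), seed=11
        )
        ds = generate_cohort(cfg)
        X, y = assemble_features(ds.runs, grid_step=5.0)
        half = 1.96 * np.sqrt(0.25 / len(y)) * 100
        within = dict.fromkeys(ALGOS, 0)
        for rep in range(20):
            yp = np.random.default_rng(1000 + rep).permutation(y)
            report = run_cv(X, yp, seed=rep)
            for alg in ALGOS:
                if 50 - half <= report.results[alg].mean_accuracy_pct <= 50 + half:
                    within[alg] += 1
        for alg in ALGOS:
            assert within[alg] >= 18, (alg, within)

    def test_stratification_error_when_class_too_small(self):
        X = np.random.default_rng(0).normal(size=(12, 4))
        y = np.array([0] * 9 + [1] * 3)
        with pytest.raises(StratificationError):
            run_cv(X, y, seed=0)

    def test_report_records_hyperparameters_and_seed(self, separable_cohort):
        X, y = separable_cohort
        report = run_cv(X, y, configs=default_configs(), seed=8)
        assert report.seed == 8
        assert set(report.results) == set(ALGOS)
        assert report.n_samples == len(y)


class TestConfusionRates:
    def test_constructed_table(self):
        rates = confusion_rates({"TP": 57, "FN": 25, "FP": 23, "TN": 148})
        assert rates.sensitivity_pct == 69.5
        assert rates.false_positive_rate_pct == 13.5

    def test_perfect_classifier(self):
        rates = confusion_rates({"TP": 50, "FN": 0, "FP": 0, "TN": 50})
        assert rates.sensitivity_pct == 100.0 and rates.false_positive_rate_pct == 0.0

    def test_all_negative_predictor(self):
        rates = confusion_rates({"TP": 0, "FN": 40, "FP": 0, "TN": 60})
        assert rates.sensitivity_pct == 0.0 and rates.false_positive_rate_pct == 0.0

    def test_zero_denominator_flags_not_raises(self):
        rates = confusion_rates({"TP": 0, "FN": 0, "FP": 3, "TN": 7})
        assert rates.sensitivity_undefined and np.isnan(rates.sensitivity_pct)
        assert not rates.fpr_undefined
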