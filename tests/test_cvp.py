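"""Current-visit prediction: metric arithmetic, the classifier harness,
year-window sweep, age-split analysis and imbalance diagnostics."""

import math

import numpy as np
import pytest

from fldpred.cvp import imbalance_factor, menopause_split, train_eval_cvp, year_window_sweep
from fldpred.metrics import EvalReport
from fldpred.pipeline import preprocess_cohort
from fldpred.simulate import GeneratorParams, generate_cohort
from tests.test_preprocessing import make_table


def test_confusion_metric_closed_form():
    y_true = [1] * 80 + [1] * 30 + [0] * 20 + [0] * 70
    y_pred = [1] * 80 + [0] * 30 + [1] * 20 + [0] * 70
    rep = EvalReport.from_predictions(y_true, y_pred)
    assert (rep.tp, rep.fp, rep.tn, rep.fn) == (80, 20, 70, 30)
    assert rep.precision == pytest.approx(0.8)
    assert rep.recall == pytest.approx(0.727, abs=5e-4)
    assert rep.f1 == pytest.approx(0.762, abs=5e-4)
    assert rep.tp + rep.fp + rep.tn + rep.fn == rep.n


def test_perfectly_separable_knn_is_exact():
    rng = np.random.default_rng(0)
    y = np.repeat([0, 1], 100)
    X = np.column_stack([y * 10.0 + rng.standard_normal(200) * 0.01, rng.standard_normal(200)])
    t = make_table({"a": X[:, 0], "b": X[:, 1]}, {}, labels=list(y))
    train, test = t.select_rows(np.arange(200) % 2 == 0), t.select_rows(np.arange(200) % 2 == 1)
    rep = train_eval_cvp(train, test, "knn")
    assert rep.accuracy == 1.0


def test_uninformative_features_give_chance_accuracy_and_auroc():
    rng = np.random.default_rng(1)
    n = 4000
    y = rng.integers(0, 2, n)
    t = make_table({"a": rng.standard_normal(n), "b": rng.standard_normal(n)}, {}, labels=list(y))
    train, test = t.select_rows(np.arange(n) < n // 2), t.select_rows(np.arange(n) >= n // 2)
    rep = train_eval_cvp(train, test, "gaussian_nb")
    assert rep.accuracy == pytest.approx(0.5, abs=0.03)
    assert rep.auroc == pytest.approx(0.5, abs=0.03)


def test_single_class_training_rejected():
    t = make_table({"a": [1.0, 2.0, 3.0]}, {}, labels=[1, 1, 1])
    with pytest.raises(ValueError):
        train_eval_cvp(t, t, "logistic")


@pytest.mark.parametrize("clf", ["adaboost", "svm", "logistic", "random_forest", "c45_tree", "cart_tree"])
def test_all_classifiers_run_and_report_valid_metrics(small_table, clf):
    years = small_table.meta["visit_year"]
    train = small_table.select_rows((years < 2016).to_numpy())
    test = small_table.select_rows((years == 2016).to_numpy())
    rep = train_eval_cvp(train, test, clf, seed=0)
    assert 0.0 <= rep.accuracy <= 1.0 and 0.0 <= rep.auroc <= 1.0
    assert rep.n == len(test)


def test_accuracy_increases_with_effect_size():
    from scipy.stats import spearmanr

    levels = [0.2, 0.8, 2.0]
    accs = []
    for scale in levels:
        per_seed = []
        for seed in range(3):
            cohort = generate_cohort(
                GeneratorParams(
                    n_subjects=400,
                    effect_sizes=tuple(scale * b for b in (1.0, 0.9, 0.8, 0.7, 0.6)),
                    seed=seed,
                )
            )
            table = preprocess_cohort(cohort)
            years = table.meta["visit_year"]
            train = table.select_rows((years < 2015).to_numpy())
            test = table.select_rows((years >= 2015).to_numpy())
            per_seed.append(train_eval_cvp(train, test, "gaussian_nb").accuracy)
        accs.append(np.mean(per_seed))
    rho, _ = spearmanr(levels, accs)
    assert rho > 0.9
    assert accs[-1] > accs[0] + 0.05


class TestYearWindowSweep:
    @staticmethod
    def tables_by_year(table):
        years = sorted(table.meta["visit_year"].unique())
        return {int(y): table.rows_in_years([int(y)]) for y in years}

    def test_single_window_is_best(self):
        cohort = generate_cohort(GeneratorParams(n_subjects=300, seed=2))
        table = preprocess_cohort(cohort)
        tables = self.tables_by_year(table)
        two = {2016: tables[2016], 2015: tables[2015]}
        res = year_window_sweep(two, 2016, "gaussian_nb")
        assert res.best_window == (2015, 2015)

    def test_shifted_link_excludes_preshift_years(self):
        cohort = generate_cohort(
            GeneratorParams(n_subjects=2500, effect_flip_before_year=2013, seed=3)
        )
        table = preprocess_cohort(cohort)
        res = year_window_sweep(self.tables_by_year(table), 2016, "logistic")
        assert res.best_window[0] >= 2013

    def test_stationary_cohort_windows_are_stable(self):
        spreads = []
        for seed in range(3):
            cohort = generate_cohort(GeneratorParams(n_subjects=1200, seed=40 + seed))
            table = preprocess_cohort(cohort)
            res = year_window_sweep(self.tables_by_year(table), 2016, "gaussian_nb")
            accs = list(res.accuracies().values())
            spreads.append(max(accs) - min(accs))
        assert np.mean(spreads) < 0.05


class TestMenopauseSplit:
    def test_age_attenuated_link_weakens_after_threshold(self):
        cohort = generate_cohort(
            GeneratorParams(n_subjects=3000, attenuation_age=55, attenuation_factor=0.1, seed=4)
        )
        table = preprocess_cohort(cohort)
        res = menopause_split(
            table, [55], train_years=range(2009, 2016), test_year=2016
        )
        before, after = res[55]
        assert before is not None and after is not None
        assert before.accuracy > after.accuracy

    def test_homogeneous_link_shows_no_split_effect(self):
        gaps = []
        for seed in range(3):
            cohort = generate_cohort(GeneratorParams(n_subjects=1500, seed=50 + seed))
            table = preprocess_cohort(cohort)
            res = menopause_split(table, [55], train_years=range(2009, 2016), test_year=2016)
            before, after = res[55]
            gaps.append(before.accuracy - after.accuracy)
        assert abs(np.mean(gaps)) < 0.03

    def test_threshold_below_all_ages_flags_empty_side(self, small_table):
        res = menopause_split(small_table, [1], train_years=range(2009, 2016), test_year=2016)
        before, after = res[1]
        assert before is None and after is not None


class TestImbalance:
    @pytest.mark.parametrize(
        "labels, expected",
        [([0] * 60 + [1] * 40, 1.5), ([0] * 50 + [1] * 50, 1.0)],
    )
    def test_ratios(self, labels, expected):
        assert imbalance_factor(labels) == pytest.approx(expected)

    def test_screening_counts(self):
        assert round(imbalance_factor([0] * 48574 + [1] * 23990), 2) == 2.02

    def test_single_class_is_infinite(self):
        assert math.isinf(imbalance_factor([1, 1, 1]))

    def test_majority_baseline_accuracy_equals_majority_fraction(self):
        rng = np.random.default_rng(7)
        y = (rng.random(500) < 0.7).astype(int)
        maj = int(np.bincount(y).argmax())
        assert (y == maj).mean() == pytest.approx(np.bincount(y).max() / len(y))
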