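import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from thighacc import CLASSES
from thighacc.evaluation import (
    ClassPerformance,
    ConfusionMatrix,
    adjust_p,
    benchmark,
    class_performance,
    compare_algorithms,
    confusion,
    loso_split,
    reliability_cv,
    robustness,
    sum_matrices,
    summarise_cvs,
    training_sample_check,
)
from tests.conftest import PUBLISHED_MATRICES


class TestLosoSplit:
    @pytest.mark.parametrize("n", [2, 5, 40])
    def test_each_participant_held_out_once(self, n):
        ids = [f"P{i}" for i in range(n)]
        folds = loso_split(ids)
        assert len(folds) == n
        assert sorted(test for _, test in folds) == sorted(ids)
        for train, test in folds:
            assert set(train) | {test} == set(ids)
            assert test not in train

    def test_duplicates_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            loso_split(["a", "a", "b"])


class TestConfusion:
    def test_perfect_predictions_are_diagonal(self):
        labels = np.array(list(CLASSES) * 3, dtype=object)
        m = confusion(labels, labels)
        assert np.array_equal(m.counts, np.eye(4, dtype=int) * 3)

    def test_additivity_over_participants(self, rng):
        a_pred = rng.choice(CLASSES, 50).astype(object)
        a_ref = rng.choice(CLASSES, 50).astype(object)
        b_pred = rng.choice(CLASSES, 70).astype(object)
        b_ref = rng.choice(CLASSES, 70).astype(object)
        summed = sum_matrices([confusion(a_pred, a_ref, "A"), confusion(b_pred, b_ref, "B")])
        concat = confusion(
            np.concatenate([a_pred, b_pred]), np.concatenate([a_ref, b_ref])
        )
        assert np.array_equal(summed.counts, concat.counts)

    def test_published_reference_totals_identical_across_algorithms(self):
        """The four published matrices share reference column totals."""
        totals = {
            algo: np.asarray(m).sum(axis=0).tolist()
            for algo, m in PUBLISHED_MATRICES.items()
        }
        assert all(t == [1464, 636, 780, 3012] for t in totals.values())

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError, match="unknown label"):
            confusion(np.array(["Walking"]), np.array(["MVPA"]))


class TestClassPerformance:
    def test_perfect_matrix(self):
        m = ConfusionMatrix(np.eye(4, dtype=int) * 10)
        for cls in CLASSES:
            perf = class_performance(m, cls)
            assert perf.sensitivity == 100.0
            assert perf.specificity == 100.0
            assert perf.balanced_accuracy == 100.0

    def test_published_svm_lipa_row(self):
        m = ConfusionMatrix(PUBLISHED_MATRICES["svm"])
        perf = class_performance(m, "LIPA")
        assert round(perf.sensitivity, 1) == 57.4
        assert round(perf.specificity, 1) == 97.8
        assert round(perf.balanced_accuracy, 1) == 77.6

    def test_published_random_forest_lipa_balanced_accuracy(self):
        m = ConfusionMatrix(PUBLISHED_MATRICES["random_forest"])
        assert round(class_performance(m, "LIPA").balanced_accuracy, 1) == 80.6

    def test_balanced_accuracy_is_mean_of_sens_and_spec(self, rng):
        counts = rng.integers(1, 100, size=(4, 4))
        m = ConfusionMatrix(counts)
        for cls in CLASSES:
            perf = class_performance(m, cls)
            assert perf.balanced_accuracy == pytest.approx(
                (perf.sensitivity + perf.specificity) / 2
            )

    def test_empty_reference_class_raises(self):
        counts = np.eye(4, dtype=int) * 5
        counts[:, 2] = 0  # no LIPA reference windows
        with pytest.raises(ValueError, match="undefined"):
            class_performance(ConfusionMatrix(counts), "LIPA")


class TestBenchmark:
    def _perf(self, ba):
        return ClassPerformance("MVPA", ba, ba, ba, ba >= 80)

    def test_boundary_inclusive(self):
        perfs = [self._perf(v) for v in (85, 75, 90, 80)]
        assert benchmark(perfs) == 75.0

    def test_all_acceptable(self):
        assert benchmark([self._perf(100)] * 5) == 100.0

    def test_monotone_in_threshold(self, rng):
        perfs = [self._perf(v) for v in rng.uniform(50, 100, 30)]
        shares = [benchmark(perfs, th) for th in (60, 70, 80, 90)]
        assert shares == sorted(shares, reverse=True)


class TestAdjustP:
    @pytest.mark.parametrize(
        "p,k,method,expected",
        [
            (0.01, 3, "bonferroni", 0.03),
            (0.5, 3, "bonferroni", 1.0),
            (0.01, 3, "sidak", 0.029701),
            (0.2, 1, "sidak", 0.2),
        ],
    )
    def test_closed_forms(self, p, k, method, expected):
        assert adjust_p(p, k, method) == pytest.approx(expected)

    @given(
        p=st.floats(min_value=0, max_value=1),
        k=st.integers(min_value=1, max_value=50),
    )
    def test_adjusted_never_below_raw(self, p, k):
        for method in ("bonferroni", "sidak"):
            adj = adjust_p(p, k, method)
            assert adj >= p - 1e-12
            assert adj <= 1.0 + 1e-12

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            adjust_p(1.5, 2)


class TestReliabilityCV:
    def test_printed_scale(self):
        # mean 10, sample SD 0.44 -> 4.4%
        values = np.array([10 - 0.44 / np.sqrt(2), 10 + 0.44 / np.sqrt(2)])
        assert reliability_cv(values) == pytest.approx(4.4, rel=1e-6)

    def test_constant_values_zero(self):
        assert reliability_cv(np.full(5, 3.3)) == 0.0

    def test_zero_mean_rejected(self):
        with pytest.raises(ValueError, match="zero mean"):
            reliability_cv(np.array([-1.0, 1.0]))

    def test_summary_flags_acceptability(self, rng):
        cvs = rng.normal(4.4, 1.0, size=40)
        summary = summarise_cvs(cvs)
        assert summary["acceptable"]
        assert summary["ci_low"] <= summary["centre"] <= summary["ci_high"]


class TestRobustness:
    def test_monotone_nonlinear_association_found_by_spearman(self):
        rng = np.random.default_rng(21)
        ids = [f"P{i}" for i in range(30)]
        height = rng.lognormal(0.5, 0.9, size=30)  # strongly skewed, non-normal
        ba = pd.Series(60 + 10 * np.log(height) + rng.normal(0, 0.5, 30), index=ids)
        chars = pd.DataFrame({"body_height": height}, index=ids)
        (res,) = robustness(ba, chars)
        assert res.test == "spearman"
        assert res.p_adjusted < 0.05
        assert res.statistic > 0.8

    def test_independent_characteristic_not_flagged(self):
        hits = 0
        reps = 40
        for rep in range(reps):
            rng = np.random.default_rng(100 + rep)
            ids = [f"P{i}" for i in range(25)]
            ba = pd.Series(rng.normal(90, 3, 25), index=ids)
            chars = pd.DataFrame({"age": rng.normal(73, 6, 25)}, index=ids)
            (res,) = robustness(ba, chars)
            hits += res.p_adjusted < 0.05
        # nominal 5% level: expect ~2 of 40 false positives
        assert hits / reps <= 0.10

    def test_binary_characteristic_uses_group_test(self):
        rng = np.random.default_rng(3)
        ids = [f"P{i}" for i in range(30)]
        ba = pd.Series(rng.normal(90, 3, 30), index=ids)
        chars = pd.DataFrame({"sex": ["female", "male"] * 15}, index=ids)
        (res,) = robustness(ba, chars)
        assert res.test in ("t-test", "mann-whitney")

    def test_too_few_participants_rejected(self):
        ba = pd.Series([90.0, 91.0], index=["a", "b"])
        chars = pd.DataFrame({"age": [70, 75]}, index=["a", "b"])
        with pytest.raises(ValueError, match="at least 3"):
            robustness(ba, chars)


class TestTrainingSampleCheck:
    def test_perfect_labels_give_100(self):
        labels = np.array(list(CLASSES) * 10, dtype=object)
        result = training_sample_check(labels, labels)
        assert all(v == 100.0 for v in result.values())

    def test_compare_algorithms_adjusts_over_pairs(self, rng):
        table = pd.DataFrame(
            {
                "svm": rng.normal(90, 3, 20),
                "ima": rng.normal(90, 3, 20),
                "tm": rng.normal(85, 3, 20),
            }
        )
        results = compare_algorithms(table)
        assert len(results) == 3
        assert all(r.k == 3 and r.p_adjusted >= r.p_raw for r in results)
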