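import numpy as np
import pytest

from thighacc.cutpoint_models import (
    CutpointModel,
    WindowMetrics,
    calibrate,
    classify_cutpoint,
    compute_ima,
    compute_svm,
    compute_tm,
    detect_posture,
)


def _dyn(vec=None, n=600):
    if vec is None:
        return np.zeros((n, 3))
    return np.tile(np.asarray(vec, float), (n, 1))


class TestMetrics:
    def test_svm_constant_magnitudes(self):
        assert compute_svm(_dyn([0.1, 0, 0])) == pytest.approx(60.0)
        assert compute_svm(_dyn()) == 0.0
        assert compute_svm(_dyn([0.3, 0.4, 0.0])) == pytest.approx(300.0)

    def test_ima_rectangle_integral_of_constant(self):
        assert compute_ima(_dyn([0.1, 0.1, 0.1])) == pytest.approx(3.0)
        assert compute_ima(_dyn()) == 0.0

    def test_ima_rectified_sinusoid(self):
        """∫|sin| over 10 s of a 1 Hz sinusoid ≈ 10·(2/π)."""
        t = np.arange(600) / 60.0
        d = np.zeros((600, 3))
        d[:, 0] = np.sin(2 * np.pi * t)
        assert compute_ima(d) == pytest.approx(10 * 2 / np.pi, rel=0.01)
        assert compute_ima(d, method="trapezoid") == pytest.approx(
            10 * 2 / np.pi, rel=0.01
        )

    def test_tm_constant_is_zero_and_alternation_is_amplitude(self):
        assert compute_tm(_dyn([0.5, 0.2, 0.1])) == pytest.approx(0.0, abs=1e-12)
        d = np.zeros((600, 3))
        A = 0.3
        d[:, 1] = A * (-1.0) ** np.arange(600)
        assert compute_tm(d) == pytest.approx(A * np.sqrt(600 / 599), rel=1e-6)

    def test_tm_equals_dynamic_resultant_sd(self, rng):
        from thighacc.feature_extraction import build_feature_matrix
        from thighacc.signal_processing import WindowFrame

        dynamic = rng.normal(0, 0.2, size=(600, 3))
        frame = WindowFrame(0, "P01", 1, 1, np.tile([0, 1.0, 0], (600, 1)), dynamic)
        table = build_feature_matrix([frame])
        assert compute_tm(dynamic) == pytest.approx(
            table["dynamic_resultant_sd"].iloc[0]
        )

    def test_wrong_window_length_rejected(self):
        with pytest.raises(ValueError, match="600"):
            compute_svm(np.zeros((599, 3)))

    def test_axis_permutation_invariance(self, rng):
        d = rng.normal(0, 0.2, size=(600, 3))
        for perm in ([1, 2, 0], [2, 1, 0]):
            assert compute_svm(d[:, perm]) == pytest.approx(compute_svm(d))
            assert compute_ima(d[:, perm]) == pytest.approx(compute_ima(d))
            assert compute_tm(d[:, perm]) == pytest.approx(compute_tm(d))

    def test_positive_scaling(self, rng):
        d = rng.normal(0, 0.2, size=(600, 3))
        c = 2.7
        assert compute_svm(c * d) == pytest.approx(c * compute_svm(d))
        assert compute_ima(c * d) == pytest.approx(c * compute_ima(d))
        assert compute_tm(c * d) == pytest.approx(c * compute_tm(d))


class TestPostureDetection:
    @pytest.mark.parametrize(
        "static_y,expected",
        [(0.98, "upright"), (0.05, "not_upright"), (-0.9, "upright"),
         (0.5, "not_upright")],  # boundary: strict >
    )
    def test_threshold_convention(self, static_y, expected):
        assert detect_posture(static_y) == expected

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            detect_posture(float("nan"))


class TestCalibration:
    def test_noiseless_linear_inversion(self):
        metric = np.linspace(0, 400, 200)
        met = 0.9 + 0.01 * metric
        model = calibrate(metric, met, metric_name="svm")
        assert model.trend_family == "linear"
        assert model.r_squared == pytest.approx(1.0, abs=1e-9)
        assert model.cutoff_lipa == pytest.approx(60.0, abs=1e-6)
        assert model.cutoff_mvpa == pytest.approx(210.0, abs=1e-6)

    def test_noisy_linear_recovery(self):
        rng = np.random.default_rng(7)
        metric = rng.uniform(0, 400, size=4000)
        met = 0.9 + 0.01 * metric + rng.normal(0, 0.1, size=4000)
        model = calibrate(metric, met)
        assert abs(model.cutoff_lipa - 60.0) / 60.0 < 0.05
        assert abs(model.cutoff_mvpa - 210.0) / 210.0 < 0.05

    def test_exponential_family_selected(self):
        metric = np.linspace(100, 2000, 300)
        met = np.exp(0.001 * metric)
        model = calibrate(metric, met)
        assert model.trend_family == "exponential"
        assert model.r_squared == pytest.approx(1.0, abs=1e-9)

    def test_cutoffs_outside_observed_range_rejected(self):
        metric = np.linspace(0, 50, 100)  # MET stays below 1.5
        met = 0.9 + 0.01 * metric
        with pytest.raises(ValueError, match="outside the fitted range"):
            calibrate(metric, met)

    def test_decreasing_relationship_falls_back_with_warning(self):
        metric = np.linspace(0, 400, 100)
        met = 5.0 - 0.01 * metric
        with pytest.warns(RuntimeWarning, match="monotone"), pytest.raises(ValueError):
            calibrate(metric, met)

    def test_json_round_trip(self, tmp_path):
        metric = np.linspace(0, 400, 200)
        model = calibrate(metric, 0.9 + 0.01 * metric, metric_name="ima")
        path = tmp_path / "model.json"
        model.to_json(path)
        restored = CutpointModel.from_json(path)
        assert restored == model


class TestClassification:
    @pytest.fixture
    def model(self):
        metric = np.linspace(0, 400, 200)
        return calibrate(metric, 0.9 + 0.01 * metric, metric_name="svm")

    def _metrics(self, svm, static_y):
        return WindowMetrics(svm=svm, ima=0.0, tm=0.0, static_y_mean=static_y)

    def test_low_metric_splits_by_posture(self, model):
        assert classify_cutpoint(self._metrics(10.0, 0.9), model) == "Standing"
        assert classify_cutpoint(self._metrics(10.0, 0.05), model) == "Sedentary"

    def test_between_cutoffs_is_lipa_regardless_of_posture(self, model):
        assert classify_cutpoint(self._metrics(100.0, 0.9), model) == "LIPA"
        assert classify_cutpoint(self._metrics(100.0, 0.0), model) == "LIPA"

    def test_mvpa_boundary_inclusive(self, model):
        assert classify_cutpoint(self._metrics(model.cutoff_mvpa, 0.0), model) == "MVPA"

    def test_classification_invariant_under_rescaled_units(self, rng):
        """Scaling metric and cut-offs by the same c preserves every label."""
        metric = rng.uniform(0, 400, size=500)
        met = 0.9 + 0.01 * metric + rng.normal(0, 0.05, size=500)
        base = calibrate(metric, met, metric_name="svm")
        c = 3.5
        scaled = calibrate(metric * c, met, metric_name="svm")
        for m in rng.uniform(0, 400, size=50):
            a = classify_cutpoint(self._metrics(m, 0.9), base)
            b = classify_cutpoint(self._metrics(m * c, 0.9), scaled)
            assert a == b
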