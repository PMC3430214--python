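import numpy as np
import pytest

from cellopt import ann
from cellopt.dataset import Dataset, Trial
from cellopt.design import REFERENCE_FACTORS, coded_to_actual, generate_ccd
from cellopt.scaling import ScalerParams


def _net(w_in=None, b_hidden=None, w_out=None, b_out=0.0):
    return ann.NetworkModel(
        w_in=np.zeros((3, 4)) if w_in is None else w_in,
        b_hidden=np.zeros(4) if b_hidden is None else b_hidden,
        w_out=np.zeros(4) if w_out is None else w_out,
        b_out=b_out,
        scaler=ScalerParams.from_factors(REFERENCE_FACTORS),
    )


class TestForward:
    def test_zero_network_outputs_zero(self):
        assert ann.forward(_net(), [0.3, -0.2, 0.9]) == 0.0

    def test_constant_path_through_tanh_zero(self):
        model = _net(w_out=np.array([1.0, 0, 0, 0]), b_out=0.5)
        assert ann.forward(model, [0.7, -0.1, 0.4]) == pytest.approx(0.5)

    def test_single_hidden_unit_manual_arithmetic(self):
        # one active unit: y = 2*tanh(0.5*x1 - 0.25*x2 + 0.1) + 0.3
        w_in = np.zeros((3, 4))
        w_in[0, 0], w_in[1, 0] = 0.5, -0.25
        model = _net(
            w_in=w_in,
            b_hidden=np.array([0.1, 0, 0, 0]),
            w_out=np.array([2.0, 0, 0, 0]),
            b_out=0.3,
        )
        x = np.array([0.4, 0.8, -0.6])
        expected = 2.0 * np.tanh(0.5 * 0.4 - 0.25 * 0.8 + 0.1) + 0.3
        assert ann.forward(model, x) == pytest.approx(expected, rel=1e-12)

    def test_batch_matches_loop(self):
        rng = np.random.default_rng(3)
        model = _net(
            w_in=rng.normal(size=(3, 4)),
            b_hidden=rng.normal(size=4),
            w_out=rng.normal(size=4),
            b_out=0.2,
        )
        xs = rng.normal(size=(5, 3))
        batch = ann.forward(model, xs)
        np.testing.assert_allclose(batch, [ann.forward(model, x) for x in xs])


class TestGradient:
    @pytest.mark.parametrize("seed", range(5))
    def test_backprop_matches_central_finite_differences(self, seed):
        """The analytic gradient agrees with a finite-difference oracle to
        1e-6 relative on random networks and data."""
        rng = np.random.default_rng(seed)
        p = rng.normal(scale=0.8, size=21)
        x = rng.uniform(-1, 1, size=(7, 3))
        t = rng.uniform(0, 1, size=7)
        _, grad = ann.loss_and_grad(p, x, t)
        h = 1e-6
        fd = np.empty(21)
        for k in range(21):
            pp, pm = p.copy(), p.copy()
            pp[k] += h
            pm[k] -= h
            fd[k] = (ann.loss_and_grad(pp, x, t)[0] - ann.loss_and_grad(pm, x, t)[0]) / (2 * h)
        np.testing.assert_allclose(grad, fd, rtol=1e-6, atol=1e-9)


def _constant_dataset(value=60.0):
    points = generate_ccd(REFERENCE_FACTORS, n_center=2)
    trials = [
        Trial(label=p.label, coded=p.coded, actual=p.actual, efficiency=value)
        for p in points
    ]
    return Dataset(factors=REFERENCE_FACTORS, trials=tuple(trials))


class TestTrain:
    def test_reference_dataset_reaches_goal(self, reference_fit):
        meta = reference_fit.network.meta
        assert meta.converged and meta.final_mse <= 1e-4

    def test_training_set_correlation(self, reference_fit):
        assert reference_fit.rsquared >= 0.99

    def test_deterministic_given_seed(self, reference_dataset):
        cfg = ann.TrainConfig(seed=11)
        m1 = ann.train(reference_dataset, cfg)
        m2 = ann.train(reference_dataset, cfg)
        np.testing.assert_array_equal(m1.w_in, m2.w_in)
        np.testing.assert_array_equal(m1.w_out, m2.w_out)
        assert m1.b_out == m2.b_out

    def test_constant_target_converges_fast(self):
        model = ann.train(_constant_dataset(60.0), ann.TrainConfig(seed=0))
        assert model.meta.converged
        assert ann.predict(model, coded_to_actual([0.3, -0.5, 0.8])) == pytest.approx(
            60.0, abs=3.0
        )

    def test_too_few_distinct_points_rejected(self):
        t = Trial("1", [0, 0, 0], [0.4, 0.28, 3.0], efficiency=50.0)
        t2 = Trial("2", [0, 0, 0], [0.4, 0.28, 3.0], efficiency=50.0)
        with pytest.raises(ValueError, match="distinct"):
            ann.train(Dataset(factors=REFERENCE_FACTORS, trials=(t, t2)), ann.TrainConfig())

    def test_unreachable_goal_raises_with_best_model(self, reference_dataset):
        cfg = ann.TrainConfig(goal_mse=1e-12, max_epochs=50, max_restarts=2, seed=0)
        with pytest.raises(ann.ConvergenceError) as exc_info:
            ann.train(reference_dataset, cfg)
        best = exc_info.value.best_model
        assert best.meta.final_mse > 1e-12
        assert np.isfinite(ann.predict(best, [0.4, 0.28, 3.0]))


class TestPredict:
    def test_center_point_matches_published_fit(self, reference_fit):
        """Published centre-point fitted value, within retraining slack."""
        pred = reference_fit.predict(coded=[0.0, 0.0, 0.0])
        assert pred == pytest.approx(76.86, abs=1.5)

    def test_zero_weight_network_predicts_scaled_bias(self):
        model = _net(b_out=0.25)
        assert ann.predict(model, [0.4, 0.28, 3.0]) == pytest.approx(25.0)


class TestModelFile:
    def test_round_trip_predictions_bitwise(self, reference_fit, tmp_path):
        path = tmp_path / "model.txt"
        ann.save_model(reference_fit.network, path)
        back = ann.load_model(path)
        rng = np.random.default_rng(0)
        xs = rng.uniform([0.06, 0.08, 0.5], [0.74, 0.48, 5.5], size=(100, 3))
        np.testing.assert_array_equal(
            ann.predict(reference_fit.network, xs), ann.predict(back, xs)
        )
        assert back.meta.final_mse == reference_fit.network.meta.final_mse

    def test_truncated_file_is_format_error(self, reference_fit, tmp_path):
        path = tmp_path / "model.txt"
        ann.save_model(reference_fit.network, path)
        text = path.read_text().splitlines()
        path.write_text("\n".join(text[:3]))
        with pytest.raises(ann.ModelFormatError):
            ann.load_model(path)

    def test_arbitrary_file_is_format_error(self, tmp_path):
        path = tmp_path / "junk.txt"
        path.write_text("hello\nworld\n")
        with pytest.raises(ann.ModelFormatError):
            ann.load_model(path)
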