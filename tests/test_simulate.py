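"""Artificial test surfaces, replicate sampling, study metrics."""

import numpy as np
import pytest
from scipy.special import erf

import splanova as sp
from splanova.simulate import (
    SimulationSpec,
    StudyResult,
    mean_squared_bias,
    metrics_table,
    run_study,
    sample_dataset,
    trace_variability,
    true_decomposition,
    true_function,
)


class TestTrueFunctions:
    def test_example1_center_and_periodicity(self):
        assert true_function("example1", 0.5, 0.5) == pytest.approx(0.0, abs=1e-12)
        x, y = 0.23, 0.71
        assert true_function("example1", x, y) == pytest.approx(
            true_function("example1", x, y + 1.0), abs=1e-9
        )

    def test_example2_center_value(self):
        assert true_function("example2", 0.5, 0.5) == pytest.approx(1.0)

    def test_unknown_id_rejected(self):
        with pytest.raises(ValueError):
            true_function("example3", 0.0, 0.0)


class TestTrueDecomposition:
    def test_example1_components_have_zero_means_and_marginals(self):
        td = true_decomposition("example1")
        g = np.linspace(0, 1, 2001)
        assert abs(np.trapezoid(td["main_x"](g), g)) < 1e-12
        assert abs(np.trapezoid(td["main_y"](g), g)) < 1e-10
        # interaction marginals vanish (full-period trapezoid is exact
        # for periodic integrands)
        gy = np.linspace(0, 1, 401)
        for x0 in (0.2, 0.7):
            marg = np.trapezoid(td["interaction"](np.full_like(gy, x0), gy), gy)
            assert abs(marg) < 1e-10

    def test_example1_components_sum_to_function(self):
        td = true_decomposition("example1")
        g = np.linspace(0, 1, 11)
        X, Y = np.meshgrid(g, g, indexing="ij")
        total = (td["intercept"] + td["main_x"](X) + td["main_y"](Y)
                 + td["interaction"](X, Y))
        np.testing.assert_allclose(total, true_function("example1", X, Y),
                                   atol=1e-12)

    def test_example2_quadrature_refinement(self):
        g = np.linspace(0, 1, 21)
        lo = true_decomposition("example2", order=64)
        hi = true_decomposition("example2", order=128)
        assert abs(lo["intercept"] - hi["intercept"]) < 1e-9
        assert np.max(np.abs(lo["main_x"](g) - hi["main_x"](g))) < 1e-9

    def test_example2_main_effect_matches_erf_closed_form(self):
        """Independent closed-form oracle: the Gaussian bump factorizes,
        so f_x = 2(x-1/2) + m*(g(x) - m) with m the erf-integral of g."""
        s = np.sqrt(0.08)
        m = 0.5 * np.sqrt(0.08 * np.pi) * (erf(0.5 / s) - erf(-0.5 / s))
        g = lambda t: np.exp(-((t - 0.5) ** 2) / 0.08)
        xs = np.linspace(0, 1, 17)
        expected = 2 * (xs - 0.5) + m * (g(xs) - m)
        got = true_decomposition("example2")["main_x"](xs)
        np.testing.assert_allclose(got, expected, atol=1e-10)


class TestSampleDataset:
    def test_reproducible_and_in_unit_square(self):
        spec = SimulationSpec("example1", n=50, seed=5)
        a = sample_dataset(spec, 3)
        b = sample_dataset(spec, 3)
        np.testing.assert_array_equal(a.x, b.x)
        np.testing.assert_array_equal(a.z, b.z)
        assert a.x.min() >= 0 and a.x.max() <= 1
        c = sample_dataset(spec, 4)
        assert not np.array_equal(a.z, c.z)

    def test_pooled_noise_variance(self):
        """Pooled residual variance over replicates ~ noise_var."""
        spec = SimulationSpec("example1", n=300, noise_var=0.25, seed=6)
        eps = []
        for rep in range(30):
            obs = sample_dataset(spec, rep)
            eps.append(obs.z - true_function("example1", obs.x[:, 0], obs.x[:, 1]))
        eps = np.concatenate(eps)
        mc_sd = 0.25 * np.sqrt(2.0 / (eps.size - 1))
        assert abs(np.var(eps, ddof=1) - 0.25) < 3 * mc_sd

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            SimulationSpec("example1", n=5)
        with pytest.raises(ValueError):
            SimulationSpec("example1", noise_var=0.0)
        with pytest.raises(ValueError):
            SimulationSpec("exampleX")


class TestRunStudy:
    def test_smoke_two_replicates(self):
        spec = SimulationSpec("example1", n=30, reps=2, seed=1)
        res = run_study(spec)
        for method in ("tensor", "posthoc"):
            for comp in ("main_x", "main_y", "interaction"):
                assert res.values[(method, comp)].shape[0] == 2
        # noise is actually drawn: replicates differ
        v = res.values[("posthoc", "main_x")]
        assert not np.allclose(v[0], v[1])

    def test_noiseless_limit_recovers_main_effect(self):
        spec = SimulationSpec("example1", n=300, noise_var=1e-12, reps=1, seed=2)
        res = run_study(spec)
        truth = 2 * (res.xs - 0.5)
        interior = (res.xs >= 0.05) & (res.xs <= 0.95)
        for method in ("tensor", "posthoc"):
            fx = res.values[(method, "main_x")][0]
            # thin-plate interpolants extrapolate poorly in the outermost
            # grid cells, so the tight bound applies to the interior
            assert np.max(np.abs(fx - truth)[interior]) < 0.02, method
            assert np.max(np.abs(fx - truth)) < 0.05, method

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError):
            run_study(SimulationSpec("example1", n=30, reps=1), methods=("svd",))


def _toy_result(values_by_comp):
    spec = SimulationSpec("example1", n=30, reps=2, seed=0)
    xs = np.linspace(0, 1, next(iter(values_by_comp.values())).shape[1])
    return StudyResult(
        spec=spec, methods=("tensor",), xs=xs, ys=xs,
        xy=np.column_stack([xs, xs]),
        values={("tensor", c): v for c, v in values_by_comp.items()},
    )


class TestMetrics:
    def test_trace_of_identical_replicates_is_zero(self):
        v = np.tile(np.array([1.0, 2.0, 3.0]), (4, 1))
        res = _toy_result({"main_x": v})
        assert trace_variability(res, "main_x", "tensor") == 0.0

    def test_trace_scales_quadratically(self):
        rng = np.random.default_rng(0)
        v = rng.normal(size=(6, 5))
        res1 = _toy_result({"main_x": v})
        res2 = _toy_result({"main_x": 2 * v})
        assert trace_variability(res2, "main_x", "tensor") == pytest.approx(
            4 * trace_variability(res1, "main_x", "tensor")
        )

    def test_two_replicate_trace_hand_oracle(self):
        """tr = sum_g (v1g - v2g)^2 / 2 for two replicates."""
        v1 = np.array([1.0, 0.0, 2.0])
        v2 = np.array([0.0, 1.0, 5.0])
        res = _toy_result({"main_x": np.vstack([v1, v2])})
        hand = float(np.sum((v1 - v2) ** 2) / 2.0)
        assert trace_variability(res, "main_x", "tensor") == pytest.approx(hand)

    def test_single_replicate_trace_rejected(self):
        res = _toy_result({"main_x": np.ones((1, 3))})
        with pytest.raises(ValueError):
            trace_variability(res, "main_x", "tensor")

    def test_msb_zero_when_truth_reproduced(self):
        truth = np.array([1.0, -1.0, 0.5])
        res = _toy_result({"main_x": np.tile(truth, (3, 1))})
        assert mean_squared_bias(res, "main_x", "tensor", truth) == 0.0

    def test_msb_constant_offset_closed_form(self):
        truth = np.zeros(4)
        res = _toy_result({"main_x": np.full((5, 4), 0.3)})
        assert mean_squared_bias(res, "main_x", "tensor", truth) == pytest.approx(
            0.09
        )

    def test_msb_grid_mismatch_rejected(self):
        res = _toy_result({"main_x": np.ones((2, 4))})
        with pytest.raises(ValueError, match="grid"):
            mean_squared_bias(res, "main_x", "tensor", np.ones(7))


class TestMetricsTable:
    @pytest.fixture(scope="class")
    def small_result(self):
        return run_study(SimulationSpec("example1", n=30, reps=3, seed=9))

    def test_layout(self, small_result):
        tab = metrics_table(small_result)
        assert list(tab.index) == ["tr_fx", "tr_fy", "tr_fxy",
                                   "msb_fx", "msb_fy", "msb_fxy"]
        assert tab.shape[1] == 2  # two methods x one size

    def test_values_match_individual_metrics(self, small_result):
        tab = metrics_table(small_result)
        assert tab.loc["tr_fx", ("posthoc", 30)] == pytest.approx(
            trace_variability(small_result, "main_x", "posthoc")
        )
        assert tab.loc["msb_fy", ("tensor", 30)] == pytest.approx(
            mean_squared_bias(small_result, "main_y", "tensor")
        )

    def test_csv_round_trip(self, small_result, tmp_path):
        import pandas as pd

        tab = metrics_table(small_result)
        path = tmp_path / "metrics.csv"
        tab.to_csv(path)
        back = pd.read_csv(path, index_col=0, header=[0, 1])
        np.testing.assert_allclose(back.to_numpy(dtype=float), tab.to_numpy())
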