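"""Objective evaluation and the first-order solver."""

import numpy as np
import pytest

import s3reg as s
from oracles import grid_search_objective


def _incidence(ds):
    return s.incidence_matrix(s.build_mst(ds.coords))


class TestObjective:
    def test_hand_worked_two_spot_instance(self, tiny_dataset):
        H = _incidence(tiny_dataset)
        field = s.CoefficientField(np.ones((2, 1)), tiny_dataset.spot_ids, ["x"])
        pen = s.PenaltyConfig(1.0, 1.0, 1.0)
        # data (1/2)(0+1)=0.5, fused 0, l1 2, group sqrt(2)*sqrt(2)=2
        assert s.evaluate_objective(tiny_dataset, field, H, pen) == pytest.approx(4.5)

    def test_perfect_fit_zero_penalties(self, tiny_dataset):
        H = _incidence(tiny_dataset)
        field = s.CoefficientField(np.array([[1.0], [2.0]]), tiny_dataset.spot_ids, ["x"])
        assert s.evaluate_objective(tiny_dataset, field, H, s.PenaltyConfig()) == 0.0

    def test_null_model_is_mean_square_response(self, small_sim):
        ds, _ = small_sim
        H = _incidence(ds)
        field = s.CoefficientField(np.zeros((ds.n_spots, ds.n_predictors)),
                                   ds.spot_ids, ds.predictor_names)
        expected = float((ds.response**2).mean())
        assert s.evaluate_objective(ds, field, H, s.PenaltyConfig(1, 1, 1)) == \
            pytest.approx(expected)

    def test_term_decomposition_conserves_total(self, small_sim):
        ds, _ = small_sim
        H = _incidence(ds)
        rng = np.random.default_rng(0)
        values = rng.normal(size=(ds.n_spots, ds.n_predictors))
        pen = s.PenaltyConfig(0.3, 0.2, 0.1)
        terms = s.objective_terms(ds, values, H, pen)
        assert sum(terms.values()) == pytest.approx(
            s.evaluate_objective(ds, values, H, pen), rel=1e-12
        )

    def test_dimension_mismatch_raises(self, tiny_dataset):
        H = _incidence(tiny_dataset)
        with pytest.raises(s.ValidationError):
            s.objective_terms(tiny_dataset, np.zeros((3, 1)), H, s.PenaltyConfig())


class TestFit:
    def test_objective_never_worse_than_zero_field(self, small_sim):
        ds, _ = small_sim
        g = s.build_mst(ds.coords)
        pen = s.PenaltyConfig(0.01, 0.001, 0.001)
        res = s.fit_s3r(ds, g, pen, s.OptimizerConfig(max_iter=1000, seed=0))
        zero_obj = s.evaluate_objective(
            ds, np.zeros((ds.n_spots, ds.n_predictors)), _incidence(ds), pen
        )
        assert res.objective_trace.min() <= zero_obj

    def test_final_objective_matches_reevaluation(self, small_sim):
        ds, _ = small_sim
        g = s.build_mst(ds.coords)
        pen = s.PenaltyConfig(0.01, 0.001, 0.001)
        res = s.fit_s3r(ds, g, pen, s.OptimizerConfig(max_iter=800, seed=0))
        reevaluated = s.evaluate_objective(ds, res.field, s.incidence_matrix(g), pen)
        best = res.objective_trace.min()
        assert abs(best - reevaluated) <= 1e-9 * max(1.0, abs(best))

    def test_best_so_far_trace_non_increasing(self, small_sim):
        ds, _ = small_sim
        g = s.build_mst(ds.coords)
        res = s.fit_s3r(ds, g, s.PenaltyConfig(0.01, 0.001, 0.001),
                        s.OptimizerConfig(max_iter=600, seed=0))
        incumbent = np.minimum.accumulate(res.objective_trace)
        assert np.all(np.diff(incumbent) <= 0)

    def test_fusion_dominated_limit_is_spatially_constant(self, small_sim):
        ds, _ = small_sim
        g = s.build_mst(ds.coords)
        res = s.fit_s3r(ds, g, s.PenaltyConfig(lambda1=1e4),
                        s.OptimizerConfig(max_iter=4000, seed=0))
        spread = res.field.values.max(axis=0) - res.field.values.min(axis=0)
        assert spread.max() < 1e-3

    def test_sparsity_dominated_limit_is_zero(self, small_sim):
        ds, _ = small_sim
        g = s.build_mst(ds.coords)
        for pen in (s.PenaltyConfig(lambda2=1e4), s.PenaltyConfig(lambda3=1e4)):
            res = s.fit_s3r(ds, g, pen, s.OptimizerConfig(max_iter=2000, seed=0))
            thr = s.hard_threshold(res.field)
            assert np.abs(thr.values).max() < 1e-6
            assert res.objective_trace.min() == pytest.approx(
                float((ds.response**2).mean()), rel=1e-6
            )

    def test_matches_grid_search_oracle_on_path(self):
        ds = s.SpatialDataset(
            ["a", "b", "c"], np.array([[0.0, 0], [1, 0], [2, 0.0]]),
            np.array([0.0, 0.0, 3.0]), np.ones((3, 1)), ["x"],
        )
        g = s.build_mst(ds.coords)
        pen = s.PenaltyConfig(lambda1=0.5)
        res = s.fit_s3r(ds, g, pen, s.OptimizerConfig(max_iter=4000, seed=0))
        H = s.incidence_matrix(g).matrix.toarray()
        axes = [np.round(np.arange(-1.0, 4.0 + 0.005, 0.05), 10)] * 3
        best_pt, _ = grid_search_objective(
            ds.response, ds.predictors, H, (0.5, 0.0, 0.0),
            np.sqrt(3), axes,
        )
        assert np.abs(res.field.values.ravel(order="F") - best_pt).max() < 0.02 + 0.025

    def test_unpenalized_single_predictor_recovers_per_spot_ratio(self):
        rng = np.random.default_rng(4)
        x = rng.uniform(1.0, 2.0, size=40)
        y = rng.normal(size=40)
        ds = s.SpatialDataset([f"s{i}" for i in range(40)], rng.uniform(size=(40, 2)),
                              y, x[:, None], ["x"])
        g = s.build_mst(ds.coords)
        res = s.fit_s3r(ds, g, s.PenaltyConfig(), s.OptimizerConfig(max_iter=6000, seed=0))
        assert np.abs(res.field.values.ravel() - y / x).max() < 1e-4

    def test_scale_equivariance_of_fitted_values(self):
        rng = np.random.default_rng(9)
        x = rng.uniform(1.0, 2.0, size=30)
        y = rng.normal(size=30)
        coords = rng.uniform(size=(30, 2))
        ids = [f"s{i}" for i in range(30)]
        g = s.build_mst(coords)
        opt = s.OptimizerConfig(max_iter=6000, seed=0)
        f1 = s.fit_s3r(s.SpatialDataset(ids, coords, y, x[:, None], ["x"]),
                       g, s.PenaltyConfig(), opt)
        f2 = s.fit_s3r(s.SpatialDataset(ids, coords, 2 * y, x[:, None], ["x"]),
                       g, s.PenaltyConfig(), opt)
        pred1 = x * f1.field.values.ravel()
        pred2 = x * f2.field.values.ravel()
        assert np.abs(pred2 - 2 * pred1).max() < 1e-3

    def test_identical_seed_and_config_bitwise_reproducible(self, small_sim):
        ds, _ = small_sim
        g = s.build_mst(ds.coords)
        pen = s.PenaltyConfig(0.01, 0.001, 0.001)
        opt = s.OptimizerConfig(max_iter=400, seed=3, batch_mode=True, batch_size=30)
        r1 = s.fit_s3r(ds, g, pen, opt)
        r2 = s.fit_s3r(ds, g, pen, opt)
        assert np.array_equal(r1.objective_trace, r2.objective_trace)
        assert np.array_equal(r1.field.values, r2.field.values)

    def test_divergent_learning_rate_raises(self, small_sim):
        ds, _ = small_sim
        g = s.build_mst(ds.coords)
        with pytest.raises(s.DivergenceError):
            s.fit_s3r(ds, g, s.PenaltyConfig(),
                      s.OptimizerConfig(max_iter=500, learning_rate=1e200,
                                        grad_clip_norm=None, seed=0))


class TestHardThreshold:
    def test_zero_threshold_is_identity(self):
        field = s.CoefficientField(np.array([[1e-12, 0.5]]), ["a"], ["g1", "g2"])
        out = s.hard_threshold(field, 0.0)
        assert np.array_equal(out.values, field.values)

    def test_magnitude_rule(self):
        field = s.CoefficientField(np.array([[1e-9, 0.5]]), ["a"], ["g1", "g2"])
        out = s.hard_threshold(field, 1e-6)
        assert np.array_equal(out.values, [[0.0, 0.5]])

    def test_objective_barely_changes(self, small_sim):
        ds, _ = small_sim
        H = _incidence(ds)
        rng = np.random.default_rng(1)
        values = rng.normal(size=(ds.n_spots, ds.n_predictors))
        tiny = rng.uniform(-1e-9, 1e-9, size=values.shape)
        mask = rng.uniform(size=values.shape) < 0.4
        values[mask] = tiny[mask]
        field = s.CoefficientField(values, ds.spot_ids, ds.predictor_names)
        pen = s.PenaltyConfig(0.5, 0.5, 0.5)
        before = s.evaluate_objective(ds, field, H, pen)
        after = s.evaluate_objective(ds, s.hard_threshold(field, 1e-6), H, pen)
        n_zeroed = int(mask.sum())
        assert abs(after - before) < 1e-6 * max(n_zeroed, 1)
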