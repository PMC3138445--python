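import numpy as np
import pytest

import drugcombo as dc
from drugcombo.errors import RankError, ScalerError, UndefinedCorrelationError
from drugcombo.models import ModelSpec, fit_linear_family, fit_network, qrf_regressors


class TestInputScaler:
    def test_scaling_anchors(self, panel3):
        scaler = dc.InputScaler.from_panel(panel3)
        assert np.array_equal(dc.scale_inputs(np.zeros(3), scaler), np.zeros(3))
        assert np.array_equal(dc.scale_inputs(panel3.max_levels, scaler), np.ones(3))
        assert dc.scale_inputs(np.array([150.0, 0, 0]), scaler)[0] == pytest.approx(0.5)

    def test_nonpositive_max_rejected(self):
        with pytest.raises(ScalerError):
            dc.InputScaler(np.array([1.0, 0.0]))


class TestRegressors:
    def test_full_interaction_count_and_subset_expansion(self):
        assert dc.lr_regressors(np.zeros((1, 4))).shape[1] == 15
        assert np.all(dc.lr_regressors(np.zeros((1, 4))) == 0)
        a, b = 0.3, 0.7
        row = dc.lr_regressors(np.array([a, b]))[0]
        assert row == pytest.approx([a, b, a * b])

    def test_subset_order_is_size_then_lexicographic(self):
        subs = dc.lr_subsets(4)
        assert subs[:4] == [(0,), (1,), (2,), (3,)]
        assert subs[4:10] == [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
        assert subs[-1] == (0, 1, 2, 3)

    @pytest.mark.parametrize("n,expected", [(4, 14), (3, 9)])
    def test_quadratic_surface_count(self, n, expected):
        assert qrf_regressors(np.zeros((1, n))).shape[1] == expected
        assert np.all(qrf_regressors(np.zeros((2, n))) == 0)


def two_level_grid(panel4):
    """All 16 corners of the 4-drug grid (each drug at 0 or max)."""
    import itertools

    corners = np.array(
        [
            [panel4.levels[i][-1] if bit else 0.0 for i, bit in enumerate(bits)]
            for bits in itertools.product([0, 1], repeat=4)
        ]
    )
    return corners


class TestLinearFamilies:
    def test_exact_linear_recovery(self, panel3, grid3):
        scaler = dc.InputScaler.from_panel(panel3)
        x = scaler.scale(grid3.conc)
        y = 0.9 - 0.4 * x[:, 0]
        m = fit_linear_family(grid3.conc, y, "LR_FULL_INTERACTION", scaler)
        expected = np.zeros(8)
        expected[0], expected[1] = 0.9, -0.4
        assert m.params == pytest.approx(expected, abs=1e-8)

    def test_full_interaction_interpolates_two_level_factorial(self, panel4):
        corners = two_level_grid(panel4)
        rng = np.random.default_rng(0)
        y = rng.uniform(0, 1, 16)
        scaler = dc.InputScaler.from_panel(panel4)
        m = fit_linear_family(corners, y, "LR_FULL_INTERACTION", scaler)
        assert np.linalg.norm(m.predict_raw(corners) - y) < 1e-8

    def test_constant_response_gives_intercept_only(self, panel3, grid3):
        scaler = dc.InputScaler.from_panel(panel3)
        y = np.full(len(grid3), 0.7)
        m = fit_linear_family(grid3.conc, y, "QUADRATIC_RSF", scaler)
        assert m.params[0] == pytest.approx(0.7, abs=1e-8)
        assert np.all(np.abs(m.params[1:]) < 1e-8)

    def test_underdetermined_raises_unless_ridge(self, panel4):
        corners = two_level_grid(panel4)[:10]  # 10 rows < 16 params
        y = np.linspace(0.2, 0.9, 10)
        scaler = dc.InputScaler.from_panel(panel4)
        with pytest.raises(RankError):
            fit_linear_family(corners, y, "LR_FULL_INTERACTION", scaler)
        m = fit_linear_family(corners, y, "LR_FULL_INTERACTION", scaler, ridge=True)
        assert np.isfinite(m.params).all()

    def test_ols_minimizes_training_mse(self, panel3, grid3):
        rng = np.random.default_rng(1)
        y = rng.uniform(0, 1, len(grid3))
        scaler = dc.InputScaler.from_panel(panel3)
        m = fit_linear_family(grid3.conc, y, "QUADRATIC_RSF", scaler)
        base = np.mean((m.predict_raw(grid3.conc) - y) ** 2)
        for j in range(len(m.params)):
            for eps in (1e-3, -1e-3):
                pert = m.params.copy()
                pert[j] += eps
                mp = dc.FittedResponseModel(spec=m.spec, scaler=scaler, params=pert)
                assert np.mean((mp.predict_raw(grid3.conc) - y) ** 2) >= base - 1e-12


class TestNetworks:
    def test_constant_response_fit(self, panel3, grid3):
        idx = dc.sample_training_design(grid3, 60, seed=0).grid_indices
        y = np.full(60, 0.5)
        scaler = dc.InputScaler.from_panel(panel3)
        for family in ("MLP_1x4", "CASCADE_2x1"):
            m = fit_network(grid3.conc[idx], y, ModelSpec(family=family, seed=0), scaler)
            assert np.max(np.abs(m.predict(grid3.conc) - 0.5)) < 1e-3

    def test_seeded_training_is_deterministic(self, panel3, grid3, truth3):
        idx = dc.sample_training_design(grid3, 50, seed=1).grid_indices
        y = dc.truth_response(truth3, grid3.conc[idx])
        scaler = dc.InputScaler.from_panel(panel3)
        spec = ModelSpec(family="MLP_1x4", seed=7, restarts=2)
        m1 = fit_network(grid3.conc[idx], y, spec, scaler)
        m2 = fit_network(grid3.conc[idx], y, spec, scaler)
        assert np.array_equal(m1.params, m2.params)
        assert m1.restart_chosen == m2.restart_chosen

    def test_recovers_noiseless_quadratic_surface(self, panel3, grid3):
        # ground truth inside the QRF span; MLP must reproduce it off-sample
        scaler = dc.InputScaler.from_panel(panel3)
        x = scaler.scale(grid3.conc)
        y_full = 0.95 - 0.3 * x[:, 0] - 0.25 * x[:, 1] - 0.2 * x[:, 2] \
            + 0.15 * x[:, 0] * x[:, 1] - 0.1 * x[:, 2] ** 2
        idx = dc.sample_training_design(grid3, 80, seed=3).grid_indices
        m = fit_network(grid3.conc[idx], y_full[idx], ModelSpec(family="MLP_1x4", seed=3), scaler)
        ev = dc.evaluate_fit(m.predict(grid3.conc), y_full)
        assert ev.pearson_r >= 0.99


class TestPredictionSaturation:
    @pytest.mark.parametrize("raw,expected", [(1.3, 1.0), (-0.2, 0.0), (0.42, 0.42)])
    def test_outputs_clamped_to_unit_interval(self, panel3, raw, expected):
        from conftest import constant_model

        m = constant_model(panel3, raw)
        assert m.predict(np.zeros(3)) == pytest.approx(expected)

    def test_all_families_predict_in_unit_interval(self, panel3, grid3, truth3):
        idx = dc.sample_training_design(grid3, 60, seed=2).grid_indices
        y = dc.truth_response(truth3, grid3.conc[idx])
        scaler = dc.InputScaler.from_panel(panel3)
        for family in ("LR_FULL_INTERACTION", "QUADRATIC_RSF", "MLP_1x4", "CASCADE_2x1"):
            spec = ModelSpec(family=family, seed=0, restarts=2)
            m = dc.fit_response_model(grid3.conc[idx], y, spec, scaler)
            pred = m.predict(grid3.conc)
            assert np.all((pred >= 0) & (pred <= 1))


class TestEvaluateFit:
    def test_perfect_and_anticorrelated(self):
        y = np.array([0.1, 0.5, 0.9])
        ev = dc.evaluate_fit(y, y)
        assert ev.mse == 0.0
        assert ev.pearson_r == pytest.approx(1.0)
        ev = dc.evaluate_fit(1 - y, y)
        assert ev.pearson_r == pytest.approx(-1.0)

    def test_hand_computed_mse_and_r(self):
        ev = dc.evaluate_fit(np.array([0.1, 0.2, 0.3]), np.array([0.1, 0.2, 0.6]))
        assert ev.mse == pytest.approx(0.03)
        assert ev.pearson_r == pytest.approx(
            np.corrcoef([0.1, 0.2, 0.3], [0.1, 0.2, 0.6])[0, 1]
        )

    def test_constant_observed_raises_but_carries_mse(self):
        with pytest.raises(UndefinedCorrelationError) as exc:
            dc.evaluate_fit(np.array([0.1, 0.2]), np.array([0.5, 0.5]))
        assert exc.value.mse == pytest.approx(np.mean([0.16, 0.09]))


class TestLearningCurve:
    def test_fixed_seed_curve_is_reproducible(self, panel3, grid3, truth3):
        table = dc.simulate_measurements(truth3, grid3, sigma=0.0, seed=0)
        kwargs = dict(
            cell_line="cancer-like", grid=grid3, family="LR_FULL_INTERACTION",
            sizes=(20, 60), repeats=1, seed=4,
        )
        c1 = dc.learning_curve(table, **kwargs)
        c2 = dc.learning_curve(table, **kwargs)
        assert c1 == c2

    def test_interpolation_limit_on_two_level_grid(self, panel4):
        corners = two_level_grid(panel4)
        panel2 = dc.DrugPanel(
            drugs=panel4.drugs,
            levels=tuple((lv[0], lv[-1]) for lv in panel4.levels),
        )
        grid2 = dc.enumerate_grid(panel2)
        rng = np.random.default_rng(5)
        table = dc.ResponseTable(
            panel=panel2, conc=grid2.conc, responses={"c": rng.uniform(0.2, 0.8, 16)}
        )
        curve = dc.learning_curve(
            table, "c", grid2, "LR_FULL_INTERACTION", sizes=(16,), repeats=1, seed=0
        )
        assert curve[16] == pytest.approx(0.0, abs=1e-12)
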