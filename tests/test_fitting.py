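"""Tests for degree estimation, initialization, and the optimizer."""

import numpy as np
import pytest
from scipy.optimize import approx_fprime

from wspfit.fitting import (
    FitOptions,
    GeneModel,
    WspParams,
    fit,
    initialize_params,
    lro_degree_estimate,
)
from wspfit.likelihood import estimate_dispersion, joint_loglik
from wspfit.model import EffectArray, FixedEffectDesign, SpatialAxis
from tests.conftest import make_model_grid


def _random_params(seed=0, n_genes=2, n_ct=2, J=4, K=3):
    rng = np.random.default_rng(seed)
    design = FixedEffectDesign(factors=("a", "b"))
    genes = [f"g{i}" for i in range(n_genes)]
    cts = [f"c{i}" for i in range(n_ct)]
    effects, rho = {}, {}
    for g in genes:
        effects[g] = {}
        for c in cts:
            d = int(rng.integers(0, 4))
            e = EffectArray.zeros(d, J)
            e.rates[:] = rng.normal(1, 0.5, e.rates.shape)
            e.slopes[:] = rng.normal(3, 1, e.slopes.shape)
            e.points[:] = rng.uniform(0, 50, e.points.shape)
            effects[g][c] = e
        rho[g] = rng.normal(0, 0.3, (K, 3))
    return WspParams(
        design=design, axis=SpatialAxis(50), genes=genes, cell_types=cts,
        random_levels=["none"] + [f"m{i}" for i in range(K)],
        effects=effects, rho=rho,
    )


class TestWspParams:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_flatten_unflatten_roundtrip(self, seed):
        p = _random_params(seed)
        vec = p.flatten()
        assert vec.shape == (p.n_parameters,)
        p2 = p.unflatten(vec)
        assert np.allclose(p2.flatten(), vec)
        for g in p.genes:
            for c in p.cell_types:
                assert np.allclose(p.effects[g][c].rates, p2.effects[g][c].rates)
                assert np.allclose(p.effects[g][c].points, p2.effects[g][c].points)

    def test_table_roundtrip(self):
        p = _random_params(3)
        t = p.to_table()
        p2 = WspParams.from_table(t, p.design, p.axis, p.random_levels)
        assert np.allclose(p.flatten(), p2.flatten())
        # the table row order must match the flat vector order (inference
        # relies on this alignment)
        assert np.allclose(t["value"].to_numpy(), p.flatten())

    def test_parameter_count_formula(self):
        """Total length is sum over (g, c) of (3d+1) * J plus 3 * K_real per gene."""
        p = _random_params(4)
        J = p.design.n_interactions
        expect = sum(
            (3 * p.effects[g][c].degree + 1) * J
            for g in p.genes for c in p.cell_types
        ) + len(p.genes) * 3 * len(p.real_levels)
        assert p.n_parameters == expect

    def test_cortex_scale_parameter_count(self):
        """6 genes x 2 cell types x 4 interactions x 4 mice: total degree 41
        across the 12 profiles yields a 612-parameter model."""
        rng = np.random.default_rng(6)
        design = FixedEffectDesign(factors=("hemisphere", "age"))
        genes = [f"g{i}" for i in range(6)]
        cts = ["glut", "gaba"]
        degs = [3, 4, 4, 3, 4, 3, 4, 3, 4, 3, 3, 3]  # sums to 41
        effects = {}
        it = iter(degs)
        for g in genes:
            effects[g] = {c: EffectArray.zeros(next(it), 4) for c in cts}
        p = WspParams(
            design=design, axis=SpatialAxis(100), genes=genes, cell_types=cts,
            random_levels=["none", "m1", "m2", "m3", "m4"],
            effects=effects, rho={g: np.zeros((4, 3)) for g in genes},
        )
        assert p.n_parameters == 612


class TestLRO:
    def test_flat_profile_mostly_degree_zero(self):
        hits = 0
        for s in range(20):
            grid, design, *_ = make_model_grid(
                [np.log(6.0)], [], [], [0.0], zeta=0.0, n_bins=100, n_levels=1,
                rho_sd=0.0, seed=100 + s,
            )
            cps = lro_degree_estimate(grid)
            hits += cps.degrees["g"]["all"] == 0
        assert hits >= 18  # flat Poisson stays degree 0 with high probability

    def test_step_profile_detected_within_three_bins(self):
        for s in range(10):
            grid, design, *_ = make_model_grid(
                [np.log(4.0), np.log(31.0)], [50.0], [50.0], [0.0], zeta=0.0,
                n_bins=100, n_levels=1, rho_sd=0.0, seed=200 + s,
            )
            cps = lro_degree_estimate(grid)
            pts = cps.points[("g", "all")]
            assert len(pts) == 1
            assert abs(pts[0] - 50.0) <= 3.0

    def test_max_degree_zero_forces_flat(self, step_grid):
        grid, design, *_ = step_grid
        cps = lro_degree_estimate(grid, max_degree=0)
        assert cps.degrees["g"]["all"] == 0

    def test_detection_power_increases_with_segment_length(self):
        """A rate doubling is detected more often the longer its segment."""
        rates = (np.log(5.0), np.log(10.0))
        hits = {}
        for seg in (6, 15, 40):
            found = 0
            for s in range(12):
                grid, design, *_ = make_model_grid(
                    [rates[0], rates[1]], [60.0], [float(100 - seg)], [0.0],
                    zeta=0.0, n_bins=100, n_levels=1, rho_sd=0.0,
                    seed=700 + 13 * seg + s,
                )
                cps = lro_degree_estimate(grid)
                found += cps.degrees["g"]["all"] >= 1
            hits[seg] = found
        assert hits[6] <= hits[15] <= hits[40]
        assert hits[40] >= 10

    def test_constant_zero_profile(self):
        grid, design, *_ = make_model_grid(
            [1.0], [], [], [0.0], n_bins=20, n_levels=1, seed=0
        )
        grid.data["count"] = 0
        cps = lro_degree_estimate(grid)
        assert cps.degrees["g"]["all"] == 0


class TestInitialization:
    def test_flat_equal_counts(self):
        grid, design, *_ = make_model_grid(
            [1.0], [], [], [0.0], n_bins=10, n_levels=1, seed=0
        )
        grid.data["count"] = 7
        cps = lro_degree_estimate(grid, max_degree=0)
        init = initialize_params(grid, cps, design)
        assert init.effects["g"]["all"].rates[0, 0] == pytest.approx(np.log(8.0))

    def test_treatment_effects_start_at_zero(self, step_grid):
        grid, design, *_ = step_grid
        cps = lro_degree_estimate(grid)
        init = initialize_params(grid, cps, design)
        assert np.all(init.effects["g"]["all"].rates[:, 1:] == 0.0)
        assert np.all(init.effects["g"]["all"].points[:, 1:] == 0.0)

    def test_step_rates_within_twenty_percent(self, step_grid):
        grid, design, *_ = step_grid
        cps = lro_degree_estimate(grid)
        init = initialize_params(grid, cps, design)
        est = init.effects["g"]["all"].rates[:, 0]
        assert est[0] == pytest.approx(3.0, rel=0.2)
        assert est[-1] == pytest.approx(1.0, rel=0.2)


class TestGeneModel:
    def _setup(self, step_grid):
        grid, design, *_ = step_grid
        disp = estimate_dispersion(grid)
        cps = lro_degree_estimate(grid)
        init = initialize_params(grid, cps, design)
        zeta = disp.zeta("g", "all")
        gm = GeneModel(grid, "g", design, init.degrees["g"], {"all": zeta})
        return grid, design, disp, init, gm

    def test_pack_unpack_roundtrip(self, step_grid):
        _, _, _, init, gm = self._setup(step_grid)
        u = gm.pack(init.effects["g"], init.rho["g"])
        eff, rho = gm.unpack(u)
        assert np.allclose(eff["all"].rates, init.effects["g"]["all"].rates)
        assert np.allclose(eff["all"].points, init.effects["g"]["all"].points)
        assert np.allclose(rho, init.rho["g"])

    def test_objective_matches_reference_joint_loglik(self, step_grid):
        """The vectorized objective equals the scalar per-row reference path."""
        grid, design, disp, init, gm = self._setup(step_grid)
        rng = np.random.default_rng(0)
        for _ in range(3):
            u = gm.pack(init.effects["g"], init.rho["g"])
            u = u + 0.05 * rng.standard_normal(len(u))
            eff, rho = gm.unpack(u)
            params = WspParams(
                design=design, axis=grid.axis, genes=["g"], cell_types=["all"],
                random_levels=grid.random_levels, effects={"g": eff}, rho={"g": rho},
            )
            ref = joint_loglik(params, grid, disp)
            fast = -gm.value_and_grad(u)[0]
            assert fast == pytest.approx(ref, rel=1e-9)

    def test_analytic_gradient_matches_central_differences(self, step_grid):
        grid, design, disp, init, gm = self._setup(step_grid)
        rng = np.random.default_rng(1)
        u0 = gm.pack(init.effects["g"], init.rho["g"])
        for _ in range(3):
            u = u0 + 0.1 * rng.standard_normal(len(u0))
            _, grad = gm.value_and_grad(u)
            num = approx_fprime(u, lambda v: gm.value_and_grad(v)[0], 1e-6)
            assert np.max(np.abs(grad - num) / (1 + np.abs(num))) < 1e-3


class TestFit:
    def test_recovers_known_step_model(self):
        """Known truth: rates e^3 - 1 and e^1 - 1 with a step at bin 50."""
        grid, design, *_ = make_model_grid(
            [3.0, 1.0], [5.0], [50.0], [0.3], zeta=0.05, n_bins=100, seed=42
        )
        res = fit(grid, design)
        e = res.params.effects["g"]["all"]
        assert e.degree == 1
        assert e.rates[0, 0] == pytest.approx(3.0, rel=0.1)
        assert e.rates[1, 0] == pytest.approx(1.0, rel=0.1)
        assert abs(e.points[0, 0] - 50.0) <= 5.0
        assert res.objective > -np.inf

    def test_objective_improves_over_initialization(self, step_grid):
        grid, design, *_ = step_grid
        disp = estimate_dispersion(grid)
        from wspfit.fitting import lro_degree_estimate, initialize_params

        cps = lro_degree_estimate(grid)
        init = initialize_params(grid, cps, design)
        before = joint_loglik(init, grid, disp)
        res = fit(grid, design)
        assert res.objective >= before

    def test_refit_from_optimum_is_a_fixed_point(self, step_grid):
        grid, design, *_ = step_grid
        res = fit(grid, design)
        res2 = fit(grid, design, init=res.params, dispersion=res.dispersion)
        assert abs(res2.objective - res.objective) < 1e-3 * max(1, abs(res.objective))

    def test_deterministic(self, step_grid):
        grid, design, *_ = step_grid
        r1 = fit(grid, design)
        r2 = fit(grid, design)
        assert np.array_equal(r1.params.flatten(), r2.params.flatten())

    def test_gaussian_loglink_objective_runs(self, step_grid):
        grid, design, *_ = step_grid
        res = fit(grid, design, options=FitOptions(objective="gaussian-loglink"))
        e = res.params.effects["g"]["all"]
        assert e.rates[0, 0] == pytest.approx(3.0, rel=0.15)

    def test_predictions_cover_empty_rows(self, step_grid):
        grid, design, *_ = step_grid
        grid2 = grid
        df = grid2.data.copy()
        df.loc[df.index[:5], "empty"] = True
        from wspfit.likelihood import CountGrid

        g2 = CountGrid(
            data=df, genes=grid.genes, cell_types=grid.cell_types,
            combo_labels=grid.combo_labels, combos=grid.combos,
            random_levels=grid.random_levels, n_bins=grid.n_bins,
        )
        res = fit(g2, design)
        pred = res.predictions(g2)
        assert len(pred) == len(df)
        assert np.isfinite(pred["psi"]).all()
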