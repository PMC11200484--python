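import numpy as np
import pytest

from organoidseg.core import (
    CurvatureField,
    ImageGrid,
    LevelSetField,
    RegionStats,
    SmoothingParams,
    compute_region_means,
    edge_indicator,
    smoothed_dirac,
)
from organoidseg.errors import ContractError, ParameterError
from organoidseg.evaluation import dice
from organoidseg.init import InitRectangle, SeedPoint, rectangle_to_levelset
from organoidseg.models import (
    BUDGET,
    CONTOUR_VANISHED,
    CPLSEParams,
    CVParams,
    EvolutionParams,
    contour_curvature,
    cplse_evolve,
    cv_evolve,
    cv_rhs,
    drlse_dp,
    evolve_proposed,
    proposed_rhs,
    suggest_time_step,
)

from .conftest import disk_sdf


def _random_instance(seed):
    rng = np.random.default_rng(seed)
    grid = ImageGrid(rng.uniform(0, 1, (32, 32)))
    phi = LevelSetField(rng.normal(scale=3.0, size=(32, 32)))
    return grid, phi


class TestProposedRHS:
    def setup_method(self):
        self.grid, self.phi = _random_instance(0)
        self.params = EvolutionParams(lambda1=2.0)
        self.stats = compute_region_means(self.grid, self.phi, 1.5)
        self.edges = edge_indicator(self.grid, 1.5, 255.0)
        self.curv = contour_curvature(self.phi)

    def test_zero_outside_band(self):
        update = proposed_rhs(
            self.phi, self.grid, self.stats, self.edges, self.curv, self.params
        )
        far = np.abs(self.phi.values) > self.params.smoothing.epsilon
        assert np.all(update[far] == 0.0)

    def test_data_term_vanishes_at_midpoint_intensity(self):
        # lambda1 = lambda2 and I = (c1+c2)/2 -> equal squared residuals
        stats = RegionStats(c1=0.3, c2=0.7)
        img = np.full((32, 32), 0.5)
        grid = ImageGrid(img)
        params = EvolutionParams(lambda1=1.0, lambda2=1.0)
        curv = CurvatureField(kappa=np.zeros((32, 32)))
        edges = edge_indicator(grid, 1.5)
        phi = LevelSetField(np.zeros((32, 32)) + 0.1)
        update = proposed_rhs(phi, grid, stats, edges, curv, params)
        # with kappa=0 and residuals equal, only the area term survives
        delta = smoothed_dirac(phi.values, params.smoothing.epsilon)
        assert np.allclose(update, params.mu * edges.g * delta, atol=1e-14)

    def test_concave_pixels_drop_data_term(self):
        # s = 0 everywhere: update must equal alpha*L + mu*A + beta*kappa*delta
        curv = CurvatureField(
            kappa=self.curv.kappa, s=np.zeros_like(self.curv.kappa)
        )
        update = proposed_rhs(
            self.phi, self.grid, self.stats, self.edges, curv, self.params
        )
        p = self.params
        delta = smoothed_dirac(self.phi.values, p.smoothing.epsilon)
        expected = (
            p.alpha * curv.kappa * delta
            + p.mu * self.edges.g * delta
            + p.beta * curv.kappa * delta
        )
        assert np.allclose(update, expected, atol=1e-14)

    def test_shape_mismatch_rejected(self):
        bad = CurvatureField(kappa=np.zeros((8, 8)))
        with pytest.raises(ContractError):
            proposed_rhs(
                self.phi, self.grid, self.stats, self.edges, bad, self.params
            )


class TestReductionToChanVese:
    @pytest.mark.parametrize("seed", range(20))
    def test_s_pinned_equals_mapped_cv_update(self, seed):
        grid, phi = _random_instance(seed)
        params = EvolutionParams(lambda1=1.7, lambda2=0.8, alpha=0.6, mu=4.0, beta=9.9)
        stats = compute_region_means(grid, phi, params.smoothing.epsilon)
        edges = edge_indicator(grid, params.smoothing.sigma, params.gradient_scale)
        curv = contour_curvature(phi, params.csi_sigma)
        pinned = CurvatureField(kappa=curv.kappa, s=np.ones_like(curv.kappa))
        proposed = proposed_rhs(phi, grid, stats, edges, pinned, params)
        cv_params = CVParams(
            mu_cv=params.alpha,
            lambda1=params.lambda1,
            lambda2=params.lambda2,
            epsilon=params.smoothing.epsilon,
        )
        mapped = cv_rhs(
            phi, grid, stats, curv, cv_params, area_force=params.mu * edges.g
        )
        assert np.max(np.abs(proposed - mapped)) < 1e-10


class TestDrlseDp:
    def test_branch_values(self):
        assert drlse_dp(1.0) == pytest.approx(0.0, abs=1e-15)
        assert drlse_dp(2.0) == pytest.approx(0.5)
        assert drlse_dp(0.5) == pytest.approx(np.sin(np.pi) / np.pi, abs=1e-15)

    def test_zero_limit(self):
        assert drlse_dp(0.0) == 1.0
        assert drlse_dp(1e-9) == pytest.approx(1.0, abs=1e-6)

    def test_continuous_at_one(self):
        assert drlse_dp(1.0 - 1e-9) == pytest.approx(drlse_dp(1.0 + 1e-9), abs=1e-6)

    def test_negative_rejected(self):
        with pytest.raises(ContractError):
            drlse_dp(-0.1)

    def test_array_input(self):
        out = drlse_dp(np.array([0.0, 0.5, 1.0, 2.0]))
        assert out == pytest.approx([1.0, 0.0, 0.0, 0.5], abs=1e-12)


class TestSuggestTimeStep:
    def test_advective_bound_binds(self):
        params = EvolutionParams(alpha=1.0)
        assert suggest_time_step(params, 5.0) == pytest.approx(0.1)

    def test_parabolic_bound_binds(self):
        params = EvolutionParams(alpha=1.0)
        assert suggest_time_step(params, 0.1) == pytest.approx(0.25)

    def test_zero_speed_returns_parabolic(self):
        params = EvolutionParams(alpha=2.0)
        assert suggest_time_step(params, 0.0) == pytest.approx(0.125)

    def test_doubling_alpha_never_increases(self):
        for speed in (0.0, 0.1, 5.0):
            a1 = suggest_time_step(EvolutionParams(alpha=1.0), speed)
            a2 = suggest_time_step(EvolutionParams(alpha=2.0), speed)
            assert a2 <= a1


class TestEvolveProposed:
    def test_two_phase_disk(self, two_phase_disk):
        grid, truth, phi0 = two_phase_disk
        result = evolve_proposed(
            phi0, grid, EvolutionParams(lambda1=1.0, lambda2=1.0)
        )
        assert dice(result.mask, truth).value >= 0.98

    def test_deterministic(self):
        rng = np.random.default_rng(2)
        grid = ImageGrid(rng.uniform(0.2, 0.8, (48, 48)))
        phi0 = disk_sdf((48, 48), (24, 24), 15)
        params = EvolutionParams(max_iterations=60)
        a = evolve_proposed(phi0, grid, params)
        b = evolve_proposed(phi0, grid, params)
        assert np.array_equal(a.phi.values, b.phi.values)
        assert np.array_equal(a.mask, b.mask)
        assert a.iterations == b.iterations and a.reason == b.reason

    def test_single_sign_phi0_vanishes_immediately(self):
        grid = ImageGrid(np.full((32, 32), 0.5))
        result = evolve_proposed(LevelSetField(np.full((32, 32), 3.0)), grid)
        assert result.reason == CONTOUR_VANISHED
        assert result.iterations == 0

    def test_monotone_shrinkage_under_area_term_only(self):
        # data terms off, positive mu: the inside area never grows
        grid = ImageGrid(np.full((64, 64), 0.5))
        phi0 = rectangle_to_levelset(InitRectangle(SeedPoint(32, 32), 20, 20), grid)
        params = EvolutionParams(
            lambda1=0.0, lambda2=0.0, mu=10.0, max_iterations=800, tolerance=0.0
        )
        result = evolve_proposed(phi0, grid, params)
        areas = [a for _, a in result.diagnostics["inside_area"]]
        assert all(a2 <= a1 for a1, a2 in zip(areas, areas[1:]))
        assert result.reason == CONTOUR_VANISHED

    def test_iterations_bounded_by_budget(self):
        grid = ImageGrid(np.full((32, 32), 0.5))
        phi0 = disk_sdf((32, 32), (16, 16), 10)
        result = evolve_proposed(phi0, grid, EvolutionParams(max_iterations=7))
        assert result.iterations <= 7
        assert result.reason in (BUDGET, CONTOUR_VANISHED, "converged")

    def test_mask_matches_negative_phi(self):
        grid = ImageGrid(np.full((32, 32), 0.5))
        phi0 = disk_sdf((32, 32), (16, 16), 10)
        result = evolve_proposed(phi0, grid, EvolutionParams(max_iterations=30))
        assert np.array_equal(result.mask, result.phi.values < 0)


class TestChanVese:
    def test_two_phase_exactness(self, two_phase_disk):
        grid, truth, phi0 = two_phase_disk
        result = cv_evolve(phi0, grid, CVParams())
        assert dice(result.mask, truth).value >= 0.99

    def test_constant_image_small_drift(self):
        # c1 ~ c2: data force ~ 0; only length/area terms may move the contour
        grid = ImageGrid(np.full((64, 64), 0.5))
        phi0 = disk_sdf((64, 64), (32, 32), 18)
        result = cv_evolve(phi0, grid, CVParams(max_iterations=200, tolerance=0.0))
        area0 = np.pi * 18**2
        assert abs(int(result.mask.sum()) - area0) / area0 < 0.25

    def test_deterministic(self):
        rng = np.random.default_rng(4)
        grid = ImageGrid(rng.uniform(0.2, 0.8, (48, 48)))
        phi0 = disk_sdf((48, 48), (24, 24), 15)
        a = cv_evolve(phi0, grid, CVParams(max_iterations=60))
        b = cv_evolve(phi0, grid, CVParams(max_iterations=60))
        assert np.array_equal(a.phi.values, b.phi.values)


class TestCPLSE:
    def test_distance_regularizer_maintains_gradient_norm(self):
        # no image forces: R(phi) alone must keep |grad phi| near 1 in the band
        grid = ImageGrid(np.full((96, 96), 0.5))
        phi0 = disk_sdf((96, 96), (48, 48), 25)
        params = CPLSEParams(
            lambda_len=0.0,
            alpha_area=0.0,
            max_iterations=500,
            tolerance=0.0,
            reinit_every=0,
        )
        result = cplse_evolve(phi0, grid, params)
        gy, gx = np.gradient(result.phi.values)
        norm = np.hypot(gx, gy)
        band = np.abs(result.phi.values) < 5.0
        assert norm[band].min() > 0.9
        assert norm[band].max() < 1.1

    def test_reduces_to_drlse_when_convex(self):
        # flat front: kappa = 0 everywhere, so s = 1 on the whole band and
        # one step must equal the plain three-term DRLSE update
        from .conftest import halfplane_sdf

        grid = ImageGrid(np.full((64, 64), 0.5))
        phi0 = halfplane_sdf((64, 64), 31.5)
        params = CPLSEParams(max_iterations=1, reinit_every=0)
        result = cplse_evolve(phi0, grid, params)

        from organoidseg.core import GRAD_FLOOR, divergence, gradient

        g = edge_indicator(grid, params.sigma, params.gradient_scale).g
        values = phi0.values
        gx, gy = gradient(values)
        norm = np.sqrt(gx**2 + gy**2)
        dp = drlse_dp(norm)
        reg = params.mu_reg * divergence(dp * gx, dp * gy)
        safe = np.maximum(norm, GRAD_FLOOR)
        delta = smoothed_dirac(values, params.epsilon)
        edge_len = params.lambda_len * delta * divergence(g * gx / safe, g * gy / safe)
        balloon = params.alpha_area * g * delta
        drlse_update = np.clip(params.dt * (reg + edge_len + balloon), -0.5, 0.5)

        band = np.abs(values) < params.epsilon
        expected = values + drlse_update
        assert np.allclose(result.phi.values[band], expected[band], atol=1e-12)

    def test_dt_stability_bound_enforced(self):
        with pytest.raises(ParameterError):
            CPLSEParams(mu_reg=0.3, dt=1.0)

    def test_deterministic(self):
        rng = np.random.default_rng(6)
        grid = ImageGrid(rng.uniform(0.2, 0.8, (48, 48)))
        phi0 = disk_sdf((48, 48), (24, 24), 15)
        a = cplse_evolve(phi0, grid, CPLSEParams(max_iterations=40))
        b = cplse_evolve(phi0, grid, CPLSEParams(max_iterations=40))
        assert np.array_equal(a.phi.values, b.phi.values)


class TestParamValidation:
    def test_evolution_params(self):
        with pytest.raises(ParameterError):
            EvolutionParams(alpha=0.0)
        with pytest.raises(ParameterError):
            EvolutionParams(beta=-1.0)
        with pytest.raises(ParameterError):
            EvolutionParams(lambda1=-0.5)
        with pytest.raises(ParameterError):
            EvolutionParams(max_iterations=0)

    def test_cv_params(self):
        with pytest.raises(ParameterError):
            CVParams(lambda1=0.0)
        with pytest.raises(ParameterError):
            CVParams(mu_cv=-0.1)

    def test_mu_sign_free(self):
        EvolutionParams(mu=-5.0)  # negative area weight = outward motion
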