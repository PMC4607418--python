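"""Monte Carlo kernel: per-photon operations and whole-run oracles."""

import math

import numpy as np
import pytest

from drupemc import (
    FruitStack,
    OpticalLayer,
    ScoringGrids,
    SimulationConfig,
    launch_photon,
    run_simulation,
    trace_photon,
)
from drupemc.transport import (
    absorb,
    cross_or_reflect,
    distance_to_boundary,
    roulette,
    sample_step,
    scatter,
)
from drupemc._kernel import _hg_cos
from drupemc.experiments import baseline_stack, preset_stack


def _matched_slab(mu_a=1.0, mu_s=0.0, g=0.0, d=1.0):
    return FruitStack(1.0, (OpticalLayer(1.0, mu_a, mu_s, g, d),), 1.0)


class TestLaunch:
    def test_matched_surface_full_weight(self, rng):
        p = launch_photon(_matched_slab(), rng)
        assert p.weight == 1.0

    def test_specular_decrement_for_peach_skin(self, rng):
        p = launch_photon(preset_stack("table2"), rng)
        assert p.weight == pytest.approx(1.0 - 0.02079, abs=5e-6)

    def test_direction_is_straight_down(self, rng):
        p = launch_photon(preset_stack("table2"), rng)
        assert np.array_equal(p.direction, [0.0, 0.0, 1.0])
        assert p.layer_index == 0 and not p.interacted_in_flesh


class TestSampleStep:
    def test_xi_one_gives_zero(self, stub_rng):
        assert sample_step(0.024, 28.4, stub_rng([1.0])) == 0.0

    def test_xi_inverse_e_gives_mean_free_path(self, stub_rng):
        s = sample_step(0.024, 28.4, stub_rng([math.exp(-1.0)]))
        assert s == pytest.approx(1.0 / 28.424, rel=1e-12)

    def test_sample_mean_matches_exponential(self, rng):
        n = 200_000
        mu_t = 28.424
        draws = np.array([sample_step(0.024, 28.4, rng) for _ in range(2000)])
        # vectorized equivalent for the bulk of the sample
        draws = np.concatenate([draws, -np.log(rng.random(n - 2000)) / mu_t])
        se = draws.std(ddof=1) / math.sqrt(n)
        assert abs(draws.mean() - 1.0 / mu_t) < 3.0 * se

    def test_non_interacting_layer_rejected(self, rng):
        with pytest.raises(ValueError):
            sample_step(0.0, 0.0, rng)


class TestDistanceToBoundary:
    def test_downward_to_lower_plane(self, rng):
        p = launch_photon(preset_stack("table2"), rng)
        p.position[2] = 0.01
        d, which = distance_to_boundary(p, preset_stack("table2"))
        assert which == "lower" and d == pytest.approx(0.02)

    def test_oblique_upward_to_surface(self, rng):
        stack = preset_stack("table2")
        p = launch_photon(stack, rng)
        p.position[2] = 0.02
        p.direction = np.array([math.sqrt(0.75), 0.0, -0.5])
        d, which = distance_to_boundary(p, stack)
        assert which == "upper" and d == pytest.approx(0.04)

    def test_horizontal_direction_has_no_boundary(self, rng):
        stack = preset_stack("table2")
        p = launch_photon(stack, rng)
        p.position[2] = 0.01
        p.direction = np.array([1.0, 0.0, 0.0])
        assert distance_to_boundary(p, stack) == (None, None)

    def test_inconsistent_layer_flagged(self, rng):
        stack = preset_stack("table2")
        p = launch_photon(stack, rng)
        p.position[2] = 1.0  # deep in flesh but recorded in the skin layer
        with pytest.raises(RuntimeError):
            distance_to_boundary(p, stack)


class TestAbsorb:
    def test_no_absorption_no_deposit(self, rng):
        lay = OpticalLayer(1.3, 0.0, 10.0, 0.0, 1.0)
        p = launch_photon(FruitStack(1.3, (lay,), 1.3), rng)
        assert absorb(p, lay) == 0.0

    def test_flesh_deposit_fraction(self, rng):
        lay = OpticalLayer(1.342, 0.024, 28.4, 0.61, 2.0)
        p = launch_photon(FruitStack(1.342, (lay,), 1.342), rng)
        dw = absorb(p, lay, flesh_layer_index=0)
        assert dw == pytest.approx(0.024 / 28.424, rel=1e-12)
        assert p.interacted_in_flesh

    def test_skin_deposit_at_half_weight(self, rng):
        lay = OpticalLayer(1.337, 0.075, 102.0, 0.65, 0.03)
        p = launch_photon(FruitStack(1.337, (lay,), 1.337), rng)
        p.weight = 0.5
        dw = absorb(p, lay, flesh_layer_index=1)
        assert dw == pytest.approx(0.5 * 0.075 / 102.075, rel=1e-12)
        assert not p.interacted_in_flesh


class TestScatter:
    def test_isotropic_cosine_is_linear_in_xi(self):
        for xi in (0.0, 0.25, 0.5, 1.0):
            assert _hg_cos(0.0, xi) == pytest.approx(2.0 * xi - 1.0)

    def test_hg_endpoints(self):
        assert _hg_cos(0.61, 1.0) == pytest.approx(1.0)
        assert _hg_cos(0.61, 0.0) == pytest.approx(-1.0)

    def test_hg_sample_mean_equals_g(self, rng):
        g = 0.61
        xs = np.array([_hg_cos(g, x) for x in rng.random(200_000)])
        se = xs.std(ddof=1) / math.sqrt(xs.size)
        assert abs(xs.mean() - g) < 3.0 * se

    def test_direction_stays_unit(self, rng):
        stack = preset_stack("table2")
        p = launch_photon(stack, rng)
        for _ in range(200):
            u = scatter(p, 0.61, rng)
            assert np.linalg.norm(u) == pytest.approx(1.0, abs=1e-6)


class TestCrossOrReflect:
    def test_matched_indices_always_cross(self, rng):
        lay = OpticalLayer(1.342, 0.024, 28.4, 0.61, 2.0)
        stack = FruitStack(1.342, (lay,), 1.342)
        p = launch_photon(stack, rng)
        p.position[2] = 2.0
        before = p.direction.copy()
        out = cross_or_reflect(p, "lower", stack, rng)
        assert out.kind == "escaped_below"
        assert np.allclose(before, [0, 0, 1])

    def test_total_internal_reflection_at_60_degrees(self, stub_rng):
        lay = OpticalLayer(1.342, 0.024, 28.4, 0.61, 2.0)
        stack = FruitStack(1.00, (lay,), 1.46)
        p = launch_photon(stack, stub_rng([]))
        p.position[2] = 0.0
        p.direction = np.array([math.sin(math.radians(60)), 0.0, -math.cos(math.radians(60))])
        out = cross_or_reflect(p, "upper", stack, stub_rng([0.999999]))
        assert out.kind == "reflected"
        assert p.direction[2] == pytest.approx(math.cos(math.radians(60)))

    def test_flesh_to_stone_crossing_above_fresnel_draw(self, stub_rng):
        lay = OpticalLayer(1.342, 0.024, 28.4, 0.61, 2.0)
        stack = FruitStack(1.00, (lay,), 1.46)
        p = launch_photon(stack, stub_rng([]))
        p.position[2] = 2.0
        out = cross_or_reflect(p, "lower", stack, stub_rng([0.5]))  # 0.5 > 0.00177
        assert out.kind == "escaped_below"
        assert out.exit_weight == pytest.approx(p.weight)

    def test_flesh_to_stone_reflection_below_fresnel_draw(self, stub_rng):
        lay = OpticalLayer(1.342, 0.024, 28.4, 0.61, 2.0)
        stack = FruitStack(1.00, (lay,), 1.46)
        p = launch_photon(stack, stub_rng([]))
        p.position[2] = 2.0
        out = cross_or_reflect(p, "lower", stack, stub_rng([0.0005]))  # < 0.00177
        assert out.kind == "reflected" and p.direction[2] == -1.0


class TestRoulette:
    def test_survivor_weight_times_m(self, rng, stub_rng):
        p = launch_photon(_matched_slab(), rng)
        p.weight = 5e-5
        roulette(p, 1e-4, 10.0, stub_rng([0.05]))
        assert p.alive and p.weight == pytest.approx(5e-4)

    def test_loser_terminated_with_nothing(self, rng, stub_rng):
        p = launch_photon(_matched_slab(), rng)
        p.weight = 5e-5
        roulette(p, 1e-4, 10.0, stub_rng([0.5]))
        assert not p.alive and p.weight == 0.0

    def test_above_threshold_untouched(self, rng, stub_rng):
        p = launch_photon(_matched_slab(), rng)
        roulette(p, 1e-4, 10.0, stub_rng([]))
        assert p.alive and p.weight == 1.0

    def test_expected_weight_preserved(self, rng):
        w0, m, n = 5e-5, 10.0, 50_000
        survived = rng.random(n) < 1.0 / m
        post = np.where(survived, m * w0, 0.0)
        se = post.std(ddof=1) / math.sqrt(n)
        assert abs(post.mean() - w0) < 3.0 * se


class TestTracePhoton:
    """Pure-Python tracer, also the structural cross-check of the kernel."""

    def _grids(self, nz=100):
        return ScoringGrids(dr=0.01, dz=0.01, nr=50, nz=nz, na=90, flesh_layer_index=0)

    def test_beer_lambert_transmittance(self, rng):
        stack = _matched_slab(mu_a=1.0, mu_s=0.0, d=1.0)
        cfg = SimulationConfig(n_photons=1, seed=0, nr=50, nz=100)
        grids = self._grids()
        n = 20_000
        below = sum(
            trace_photon(stack, cfg, rng, grids).kind == "escaped_below"
            for _ in range(n)
        )
        p = below / n
        se = math.sqrt(p * (1 - p) / n)
        assert abs(p - math.exp(-1.0)) < 3.0 * se

    def test_per_photon_energy_conservation(self, rng):
        # w_th tiny so roulette never fires; scored energy == launch weight
        stack = preset_stack("table2")
        cfg = SimulationConfig(n_photons=1, seed=0, nr=50, nz=250, w_th=1e-12)
        grids = ScoringGrids(dr=0.01, dz=0.01, nr=50, nz=250, na=90, flesh_layer_index=1)
        w0 = 1.0 - 0.0207942076718
        for _ in range(40):
            ev = trace_photon(stack, cfg, rng, grids)
            scored = ev.absorbed_by_layer.sum() + ev.weight
            assert scored == pytest.approx(w0, abs=1e-9)

    def test_runaway_guard(self, rng):
        # the first hop is always an interaction (boundary 500 mfp away),
        # so a one-event cap must trip the guard
        stack = _matched_slab(mu_a=1e-6, mu_s=100.0, d=5.0)
        cfg = SimulationConfig(n_photons=1, seed=0, nr=50, nz=100, max_events=1)
        ev = trace_photon(stack, cfg, rng, self._grids())
        assert ev.kind == "runaway"


class TestRunSimulation:
    def test_beer_lambert_against_kernel(self):
        stack = _matched_slab(mu_a=1.0, mu_s=0.0, d=1.0)
        res = run_simulation(stack, SimulationConfig(n_photons=100_000, seed=7, nr=50))
        se = max(res.t_below_se, 1e-4)
        assert abs(res.t_below - math.exp(-1.0)) < 3.0 * se

    def test_python_and_compiled_paths_agree(self, rng):
        # same physics, independent draw streams: compare statistically
        stack = _matched_slab(mu_a=1.0, mu_s=0.0, d=1.0)
        cfg = SimulationConfig(n_photons=1, seed=0, nr=50, nz=100)
        grids = ScoringGrids(dr=0.01, dz=0.01, nr=50, nz=100, na=90, flesh_layer_index=0)
        n = 10_000
        below = sum(
            trace_photon(stack, cfg, rng, grids).kind == "escaped_below"
            for _ in range(n)
        )
        py = below / n
        res = run_simulation(stack, SimulationConfig(n_photons=100_000, seed=3, nr=50))
        se = math.sqrt(py * (1 - py) / n + res.t_below_se**2)
        assert abs(py - res.t_below) < 4.0 * se

    def test_lossless_medium_reflects_everything(self):
        # near-zero absorption, matched deep slab: the walk escapes upward
        stack = _matched_slab(mu_a=1e-6, mu_s=10.0, g=0.0, d=30.0)
        res = run_simulation(stack, SimulationConfig(n_photons=20_000, seed=5, nr=50))
        assert res.rd_total == pytest.approx(1.0, abs=0.01)

    def test_specular_term_is_exact(self, baseline_run):
        assert baseline_run.r_sp == pytest.approx((0.337 / 2.337) ** 2, abs=1e-12)

    def test_energy_conservation(self, baseline_run):
        assert abs(baseline_run.energy_budget_residual) < 1e-3

    def test_seed_determinism_bit_identical(self):
        stack = baseline_stack()
        cfg = SimulationConfig(n_photons=20_000, seed=99)
        a = run_simulation(stack, cfg)
        b = run_simulation(stack, cfg)
        assert a.rd_total == b.rd_total and a.t_below == b.t_below
        assert np.array_equal(a.grids.refl_r_alpha, b.grids.refl_r_alpha)
        assert np.array_equal(a.grids.absorb_r_z, b.grids.absorb_r_z)
        c = run_simulation(stack, SimulationConfig(n_photons=20_000, seed=100))
        assert c.rd_total != a.rd_total

    def test_rd_total_equals_grid_sum(self, baseline_run):
        grid_sum = baseline_run.grids.refl_r_alpha.sum() / baseline_run.n_photons
        assert baseline_run.rd_total == pytest.approx(grid_sum, rel=1e-12)


class TestMonotonicity:
    def test_more_absorption_less_reflectance(self, optics_grid_runs):
        lo = optics_grid_runs[(0.019, 22.7)]
        hi = optics_grid_runs[(0.029, 22.7)]
        se = 3.0 * math.hypot(lo.rd_se, hi.rd_se)
        assert hi.rd_total < lo.rd_total - se

    def test_more_scattering_more_reflectance(self, optics_grid_runs):
        lo = optics_grid_runs[(0.029, 22.7)]
        hi = optics_grid_runs[(0.029, 34.1)]
        se = 3.0 * math.hypot(lo.rd_se, hi.rd_se)
        assert hi.rd_total > lo.rd_total + se

    def test_stone_lowers_reflectance_and_raises_below_escape(self, core_comparison_runs):
        with_core = core_comparison_runs[1.46]
        no_core = core_comparison_runs[1.00]
        se_rd = 3.0 * math.hypot(with_core.rd_se, no_core.rd_se)
        se_tb = 3.0 * math.hypot(with_core.t_below_se, no_core.t_below_se)
        assert with_core.rd_total < no_core.rd_total - se_rd
        assert with_core.t_below > no_core.t_below + se_tb
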