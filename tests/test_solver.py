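"""Bioheat solver: equilibria, closed-form limits, boundary fluxes, energy
conservation, scheme agreement and convergence behaviour."""

import numpy as np
import pytest

import ledtherm as lt
from ledtherm.exceptions import ConfigurationError, SolverError
from ledtherm.grid import SimulationGrid
from ledtherm.materials import SIGMA_SB, LayerSpec, MaterialProps, TissueStack, rasterize_properties
from ledtherm.metrics import celsius
from ledtherm.optics import BeamModel
from ledtherm.solver import BioheatSolver, initialize, solve
from ledtherm.scenarios import Scenario, skin_scenario


def _uniform_stack(perfusion=0.0, metabolic=0.0, k=0.42, rho=1090.0, cp=3350.0,
                   depth=0.01):
    props = MaterialProps(rho, cp, k, perfusion, 95.0, 2000.0)
    return TissueStack((LayerSpec("m", depth, props),), metabolic_heat=metabolic)


def _scenario(stack, grid, settings, beams=(), duration=10.0, **kw):
    return Scenario("test", stack, tuple(beams), grid, settings, duration,
                    isotherm_thresholds=(), **kw)


class TestEquilibriumAndInitialization:
    def test_initialize_uniform_at_t0(self, small_grid):
        s = lt.SolverSettings(initial_temp=310.15)
        f = initialize(small_grid, s)
        assert f.time == 0.0
        assert np.all(f.values == 310.15)

    @pytest.mark.parametrize("scheme", ["explicit", "backward_euler", "crank_nicolson"])
    def test_insulated_uniform_field_is_fixed_point(self, small_grid, scheme):
        """No source, no perfusion, no surface exchange: a uniform field must
        stay put to machine precision under every scheme."""
        stack = _uniform_stack()
        props = rasterize_properties(stack, small_grid)
        s = lt.SolverSettings(dt=0.1, scheme=scheme, h_conv=0.0, emissivity=0.0)
        solver = BioheatSolver(small_grid, props, s)
        f = initialize(small_grid, s)
        for _ in range(5):
            f = solver.step(f)
        assert np.max(np.abs(f.values - s.initial_temp)) < 1e-10

    def test_zero_power_skin_run_stays_near_core(self):
        """With the LED off, only surface cooling acts: the maximum stays
        within 0.2 K of 37 degC over a minute."""
        grid = SimulationGrid.regular(9, 9, 12, 2e-3, 2e-3, 0.5e-3)
        scn = skin_scenario(0.0, "90deg", duration=60.0, grid=grid,
                            settings=lt.SolverSettings(dt=1.0))
        res = solve(scn)
        assert abs(lt.max_temperature(res.final_field) - 37.0) < 0.2


class TestClosedForms:
    def test_uniform_perfusion_ode_limit(self, insulated_settings):
        """Insulated, uniform perfusion + metabolism: the field follows the
        scalar ODE solution T_b + Q/(rho_b c_b w_b) + (T0 - ...) exp(-t/tau)
        with tau = rho c_p / (rho_b c_b w_b)."""
        stack = _uniform_stack(perfusion=0.002, metabolic=368.0)
        grid = SimulationGrid.regular(4, 4, 4, 1e-3, 1e-3, 1e-3)
        props = rasterize_properties(stack, grid)
        s = insulated_settings
        solver = BioheatSolver(grid, props, s)
        f = initialize(grid, s)
        n = 200
        for _ in range(n):
            f = solver.step(f)
        w = stack.blood_density * stack.blood_specific_heat * 0.002
        offset = 368.0 / w
        tau = 1090.0 * 3350.0 / w
        expect = stack.arterial_temp + offset + (
            s.initial_temp - stack.arterial_temp - offset) * np.exp(-n * s.dt / tau)
        assert offset == pytest.approx(0.04845, abs=2e-4)
        assert np.max(np.abs(f.values - expect)) < 1e-3

    def test_semi_infinite_constant_flux_erfc_solution(self):
        """1-D conduction with constant surface flux matches the analytic
        erfc solution to <1% of the surface rise before the front reaches
        the bottom."""
        from scipy.special import erfc

        k, rho, cp = 0.5, 1000.0, 4000.0
        q0 = 1000.0
        stack = _uniform_stack(k=k, rho=rho, cp=cp, depth=0.03)
        grid = SimulationGrid.regular(3, 3, 150, 5e-3, 5e-3, 0.2e-3)
        s = lt.SolverSettings(dt=0.25, h_conv=0.0, emissivity=0.0,
                              surface_flux=q0, initial_temp=300.0)
        props = rasterize_properties(stack, grid)
        solver = BioheatSolver(grid, props, s)
        f = initialize(grid, s)
        t_end = 100.0
        for _ in range(int(t_end / s.dt)):
            f = solver.step(f)
        alpha = k / (rho * cp)
        z = grid.z_centers
        arg = z / (2 * np.sqrt(alpha * t_end))
        analytic = s.initial_temp + (q0 / k) * (
            2 * np.sqrt(alpha * t_end / np.pi) * np.exp(-(arg**2)) - z * erfc(arg)
        )
        rise_surf = analytic[0] - s.initial_temp
        err = np.max(np.abs(f.values[1, 1, :] - analytic)) / rise_surf
        assert err < 0.01

    def test_top_boundary_flux_arithmetic(self, small_grid):
        """Mixed convective-radiative flux at T_s = 37 degC against 25 degC
        ambient equals the hand-computed h*dT + eps*sigma*(T^4-Tinf^4)."""
        stack = _uniform_stack()
        props = rasterize_properties(stack, small_grid)
        s = lt.SolverSettings()
        solver = BioheatSolver(small_grid, props, s)
        Ts, Ti = 310.15, 298.15
        expected = 10.0 * (Ts - Ti) + 0.95 * SIGMA_SB * (Ts**4 - Ti**4)
        assert solver.boundary_flux_density(Ts) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(192.6, abs=0.5)
        assert solver.boundary_flux_density(Ti) == 0.0

    def test_radiation_disabled_gives_pure_robin(self, small_grid):
        stack = _uniform_stack()
        props = rasterize_properties(stack, small_grid)
        s = lt.SolverSettings(emissivity=0.0)
        solver = BioheatSolver(small_grid, props, s)
        assert solver.boundary_flux_density(310.15) == pytest.approx(10.0 * 12.0)


class TestConservationAndBounds:
    def _heated_setup(self, scheme="crank_nicolson", dt=0.5):
        stack = _uniform_stack(perfusion=0.002, metabolic=368.0)
        grid = SimulationGrid.regular(10, 10, 10, 1e-3, 1e-3, 1e-3)
        props = rasterize_properties(stack, grid)
        s = lt.SolverSettings(dt=dt, scheme=scheme, h_conv=0.0, emissivity=0.0)
        src = lt.volumetric_source(grid, [BeamModel(0.1, 3e-3)], props)
        return grid, props, s, src

    @pytest.mark.parametrize("scheme,theta", [("backward_euler", 1.0),
                                              ("crank_nicolson", 0.5)])
    def test_discrete_energy_balance_per_step(self, scheme, theta):
        """Insulated domain: enthalpy change per step equals dt * (source -
        perfusion sink) evaluated at the scheme's time level, to <0.1%."""
        grid, props, s, src = self._heated_setup(scheme)
        solver = BioheatSolver(grid, props, s, src)
        f = initialize(grid, s)
        vol = np.broadcast_to(grid.cell_volume, grid.shape)
        C = props.volumetric_heat_capacity * vol
        P = props.perfusion_coeff * vol
        Q = (src.values + 368.0) * vol
        for _ in range(20):
            f2 = solver.step(f)
            dH = float(np.sum(C * (f2.values - f.values)))
            T_theta = theta * f2.values + (1 - theta) * f.values
            budget = s.dt * float(np.sum(Q - P * (T_theta - props.stack.arterial_temp)))
            assert dH == pytest.approx(budget, rel=1e-3)
            f = f2

    def test_maximum_principle_no_source(self):
        """Surface cooling only: temperatures stay inside
        [min(T0, Tinf), max(T0, Tb + Qmet/(rho_b c_b w_b))]."""
        grid = SimulationGrid.regular(9, 9, 12, 2e-3, 2e-3, 0.5e-3)
        scn = skin_scenario(0.0, "90deg", duration=120.0, grid=grid,
                            settings=lt.SolverSettings(dt=1.0))
        res = solve(scn)
        stack = scn.stack
        w = stack.blood_density * stack.blood_specific_heat * 0.002
        upper = stack.arterial_temp + 368.0 / w
        s = scn.settings
        assert res.final_field.values.min() >= min(s.initial_temp, s.ambient_temp) - 1e-6
        assert res.final_field.values.max() <= max(s.initial_temp, upper) + 1e-6

    def test_final_max_increasing_in_power(self):
        grid = SimulationGrid.regular(11, 11, 12, 2e-3, 2e-3, 0.5e-3)
        maxes = []
        for p in (50.0, 150.0, 300.0):
            scn = skin_scenario(p, "90deg", duration=60.0, grid=grid,
                                settings=lt.SolverSettings(dt=2.0))
            maxes.append(lt.max_temperature(solve(scn).final_field))
        assert maxes[0] < maxes[1] < maxes[2]


class TestSpectralOracle:
    def test_steady_gaussian_beam_matches_hankel_solution(self):
        """Homogeneous perfused half-space under a Gaussian Beer-Lambert
        source with a linear Robin surface: the long-time on-axis rise
        matches an independent Hankel-transform steady solution (exact
        two-exponential profile per radial mode) to ~1%."""
        k, rho, cp = 0.42, 1090.0, 3350.0
        beta = 1050.0 * 3617.0 * 0.002
        P, sig, h = 0.3, 4.6e-3, 16.5
        mu = lt.effective_attenuation(95.0, 2000.0)
        I0 = P / (2 * np.pi * sig**2)

        kap = np.linspace(0, 4000, 8000)[1:]
        Ihat = I0 * sig**2 * np.exp(-(kap**2) * sig**2 / 2)
        m = np.sqrt(kap**2 + beta / k)
        A = mu * Ihat / (k * (m**2 - mu**2))
        B = -A * (mu + h / k) / (m + h / k)
        zs = np.array([0.35e-3, 1e-3, 2e-3])
        analytic = np.array([
            np.trapezoid((A * np.exp(-mu * z) + B * np.exp(-m * z)) * kap, kap)
            for z in zs
        ])

        props = MaterialProps(rho, cp, k, 0.002, 95.0, 2000.0)
        stack = TissueStack((LayerSpec("dermis", 0.02, props),), metabolic_heat=0.0)
        grid = SimulationGrid.for_domain(
            40e-3, 1.0e-3, [(0.5e-3, 0.1e-3), (3e-3, 0.25e-3), (20e-3, 0.5e-3)])
        s = lt.SolverSettings(dt=2.0, h_conv=h, emissivity=0.0, ambient_temp=310.0,
                              initial_temp=310.0, cg_rtol=1e-6)
        scn = Scenario("spectral", stack, (lt.BeamModel(P, sig),), grid, s,
                       duration=1800.0, isotherm_thresholds=(),
                       record_interval=300.0)
        res = solve(scn)
        zc, prof = lt.depth_profile(res.final_field)
        sim_rise = np.interp(zs, zc, prof) - celsius(310.0)
        np.testing.assert_allclose(sim_rise, analytic, rtol=0.015)


class TestGridConvergence:
    def test_refinement_study_reaches_half_percent(self):
        """Successive refinement of a coarse beam-heating scenario meets the
        0.5% max-temperature convergence criterion within a few levels."""
        grid = SimulationGrid.regular(15, 15, 12, 2.5e-3, 2.5e-3, 0.8e-3)
        scn = skin_scenario(300.0, "90deg", duration=60.0, grid=grid,
                            settings=lt.SolverSettings(dt=2.0, cg_rtol=1e-6),
                            isotherm_thresholds=())
        rep = lt.grid_refinement_study(scn, refinement_factor=1.5,
                                       tol_fraction=0.005, max_levels=4)
        assert rep.converged
        assert rep.rel_changes[-1] < 0.005
        # successive changes shrink as the grid refines
        if len(rep.rel_changes) > 1:
            assert rep.rel_changes[-1] < rep.rel_changes[0]


class TestSchemes:
    def test_explicit_matches_implicit_on_coarse_grid(self):
        """Explicit (stability-limited dt) and Crank-Nicolson agree to O(dt)
        after the same simulated time."""
        stack = _uniform_stack(perfusion=0.002, metabolic=368.0, depth=0.016)
        grid = SimulationGrid.regular(8, 8, 8, 2e-3, 2e-3, 2e-3)
        props = rasterize_properties(stack, grid)
        src = lt.volumetric_source(grid, [BeamModel(0.3, 4e-3)], props)
        results = {}
        t_end = 20.0
        for scheme, dt in (("explicit", 0.5), ("crank_nicolson", 1.0),
                           ("backward_euler", 1.0)):
            s = lt.SolverSettings(dt=dt, scheme=scheme)
            solver = BioheatSolver(grid, props, s, src)
            assert s.dt <= solver.stability_limit() or scheme != "explicit"
            f = initialize(grid, s)
            for _ in range(int(t_end / dt)):
                f = solver.step(f)
            results[scheme] = f.values
        for other in ("explicit", "backward_euler"):
            diff = np.max(np.abs(results["crank_nicolson"] - results[other]))
            assert diff < 0.05  # K; both converge to the same trajectory

    def test_explicit_unstable_dt_rejected(self):
        stack = _uniform_stack()
        grid = SimulationGrid.regular(6, 6, 6, 0.5e-3, 0.5e-3, 0.5e-3)
        props = rasterize_properties(stack, grid)
        s = lt.SolverSettings(dt=10.0, scheme="explicit")
        solver = BioheatSolver(grid, props, s)
        with pytest.raises(SolverError):
            solver.step(initialize(grid, s))

    def test_picard_nonconvergence_reports_diagnostics(self, small_grid):
        stack = _uniform_stack()
        props = rasterize_properties(stack, small_grid)
        src = lt.volumetric_source(small_grid, [BeamModel(3.0, 2e-3)], props)
        s = lt.SolverSettings(dt=5.0, picard_tol=1e-13, max_picard_iters=2)
        solver = BioheatSolver(small_grid, props, s, src)
        with pytest.raises(SolverError, match="Picard"):
            solver.step(initialize(small_grid, s))

    def test_solve_is_deterministic(self):
        grid = SimulationGrid.regular(7, 7, 8, 2e-3, 2e-3, 0.5e-3)
        scn = skin_scenario(200.0, "90deg", duration=20.0, grid=grid,
                            settings=lt.SolverSettings(dt=1.0))
        a = solve(scn)
        b = solve(scn)
        np.testing.assert_array_equal(a.final_field.values, b.final_field.values)
        assert a.summary.equals(b.summary)


class TestValidation:
    def test_nonpositive_duration_rejected(self, small_grid):
        with pytest.raises(ConfigurationError):
            _scenario(_uniform_stack(), small_grid, lt.SolverSettings(), duration=0.0)

    def test_invalid_settings_rejected(self):
        with pytest.raises(ConfigurationError):
            lt.SolverSettings(dt=-1.0)
        with pytest.raises(ConfigurationError):
            lt.SolverSettings(scheme="dufort_frankel")
        with pytest.raises(ConfigurationError):
            lt.SolverSettings(emissivity=1.5)
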