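"""Shared fixtures: small grids, stacks, and cached expensive runs.

The heavyweight parametric runs used by the reproduction tests are computed
once per session and shared; all of them use coarsened preview grids whose
agreement with finer grids is itself covered by the convergence tests.
"""

from __future__ import annotations

import pytest
from hypothesis import settings as hyp_settings

import ledtherm as lt
from ledtherm.grid import SimulationGrid

hyp_settings.register_profile("deterministic", derandomize=True, deadline=None)
hyp_settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def skin_stack():
    return lt.build_skin_model()


@pytest.fixture()
def small_grid():
    """Tiny uniform grid for unit tests (8x8x8, 1 mm cells)."""
    return SimulationGrid.regular(8, 8, 8, 1e-3, 1e-3, 1e-3)


@pytest.fixture()
def uniform_dermis_stack():
    """Single-layer stack of dermis-like material, 10 mm deep."""
    props = lt.MaterialProps(
        density=1090.0, specific_heat=3350.0, conductivity=0.42,
        perfusion_rate=0.002, absorption_coeff=95.0,
        reduced_scattering_coeff=2000.0,
    )
    return lt.TissueStack((lt.LayerSpec("dermis", 0.010, props),))


@pytest.fixture()
def insulated_settings():
    """No convection, no radiation: fully insulated domain."""
    return lt.SolverSettings(dt=1.0, h_conv=0.0, emissivity=0.0)


# -- cached expensive runs (coarse acceptance grids) -------------------------

FAST_SETTINGS = lt.SolverSettings(dt=1.0, cg_rtol=1e-6)


@pytest.fixture(scope="session")
def sweep_runs():
    """Power sweeps 100-700 mW for both LEDs on the coarse sweep grid,
    integrated to 900 s with a 600 s snapshot (shared by the onset,
    safety-bound and saturation tests)."""
    grid = lt.fast_skin_grid()
    out = {}
    for label in ("90deg", "150deg"):
        out[label] = lt.run_power_sweep(
            label, duration=900.0, grid=grid, settings=FAST_SETTINGS,
            snapshot_times=(600.0,),
        )
    return out


@pytest.fixture(scope="session")
def contact_500mw_90deg_run():
    """600 s run, 90 deg LED at 500 mW, contact, preview grid (isotherm
    depth; the 150 deg counterpart comes from the gap-study fixture)."""
    return lt.solve(lt.skin_scenario(500, "90deg", duration=600.0,
                                     grid=lt.preview_skin_grid(),
                                     settings=FAST_SETTINGS,
                                     record_interval=5.0))


@pytest.fixture(scope="session")
def gap_study_results():
    """Gap studies: 90 deg at 300 mW and 150 deg at 500 mW, contact vs
    2000 um, preview grid."""
    grid = lt.preview_skin_grid()
    return {
        "90deg": lt.run_gap_study("90deg", 300.0, grid=grid, settings=FAST_SETTINGS),
        "150deg": lt.run_gap_study("150deg", 500.0, grid=grid, settings=FAST_SETTINGS),
    }


@pytest.fixture(scope="session")
def multi_led_result():
    """Multi-LED study (n = 1, 2, 5) on a widened coarse grid."""
    grid = SimulationGrid.for_domain(
        50e-3, 1.0e-3, [(0.5e-3, 0.1e-3), (3e-3, 0.25e-3), (10e-3, 0.5e-3)]
    )
    return lt.run_multi_led((1, 2, 5), 300.0, grid=grid, settings=FAST_SETTINGS)
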