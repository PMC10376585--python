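"""Transient Pennes bioheat solver on a structured finite-volume grid.

The governing balance per cell is

    rho c_p dT/dt = div(k grad T) - rho_b c_b omega_b (T - T_b)
                    + Q_met + Q_source

with an insulated bottom and sides and a mixed convective-radiative top
boundary  -k dT/dz = h (T_s - T_inf) + eps sigma_SB (T_s^4 - T_inf^4).

Discretization notes
--------------------
* Finite volumes with harmonic-mean face conductivities, so heat flux is
  continuous across layer interfaces and the scheme is exactly conservative.
* theta time stepping (backward Euler theta=1, Crank-Nicolson theta=1/2,
  explicit theta=0) written in increment form: each implicit step solves
  A delta = r with A = C/dt + theta (K + P + B), which a Jacobi-
  preconditioned conjugate-gradient solves matrix-free (K is SPD).  The
  increment form keeps uniform equilibria exact fixed points and gives CG a
  well-scaled residual.
* The quartic radiation term is linearized as an effective surface
  conductance h_rad(T_s) = eps sigma_SB (T_s^2 + T_inf^2)(T_s + T_inf),
  updated by Picard iteration each implicit step (or frozen at the
  start-of-step surface temperature).  The surface temperature itself is
  recovered from the half-cell flux balance, not taken as the first cell
  centre.
* All temperatures are kelvin internally; summaries report degC.
"""

from __future__ import annotations

import logging
import time as _time
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import metrics
from .exceptions import ConfigurationError, SolverError
from .grid import SimulationGrid
from .materials import SIGMA_SB, PropertyArrays, rasterize_properties
from .optics import SourceField, volumetric_source

logger = logging.getLogger(__name__)

_SCHEME_THETA = {"backward_euler": 1.0, "crank_nicolson": 0.5, "explicit": 0.0}


@dataclass(frozen=True)
class SolverSettings:
    """Time-integration and boundary-condition settings.

    ambient_temp/initial_temp in kelvin; h_conv in W/m^2/K; surface_flux is
    an optional imposed inward heat flux at the top (W/m^2), useful for
    analytic benchmarks.
    """

    dt: float = 0.25
    scheme: str = "crank_nicolson"
    radiation_linearization: str = "picard"
    picard_tol: float = 1e-4
    max_picard_iters: int = 30
    ambient_temp: float = 298.15
    h_conv: float = 10.0
    emissivity: float = 0.95
    initial_temp: float = 310.15
    surface_flux: float = 0.0
    cg_rtol: float = 1e-8
    cg_maxiter: int = 500

    def __post_init__(self):
        if not self.dt > 0:
            raise ConfigurationError("dt must be positive")
        if self.scheme not in _SCHEME_THETA:
            raise ConfigurationError(f"unknown scheme '{self.scheme}'")
        if self.radiation_linearization not in ("picard", "frozen"):
            raise ConfigurationError("radiation_linearization must be 'picard' or 'frozen'")
        if not self.picard_tol > 0:
            raise ConfigurationError("picard_tol must be positive")
        if not 0.0 <= self.emissivity <= 1.0:
            raise ConfigurationError("emissivity must lie in [0, 1]")


@dataclass
class TemperatureField:
    """Temperature values (K) on a grid at one time instant."""

    values: np.ndarray
    time: float
    grid: SimulationGrid = field(repr=False, default=None)

    def copy(self) -> "TemperatureField":
        return TemperatureField(self.values.copy(), self.time, self.grid)


@dataclass
class ProbeRecord:
    """Temperature trace at a fixed point, degC."""

    location: tuple[float, float, float]
    times: np.ndarray
    temperatures: np.ndarray


def initialize(grid: SimulationGrid, settings: SolverSettings) -> TemperatureField:
    """Uniform field at the configured initial temperature, t = 0."""
    return TemperatureField(
        np.full(grid.shape, float(settings.initial_temp)), 0.0, grid
    )


class BioheatSolver:
    """Pre-assembled operator for one (grid, properties, settings, source)
    combination; repeated calls to :meth:`step` advance the field."""

    def __init__(self, grid: SimulationGrid, props: PropertyArrays,
                 settings: SolverSettings, source: SourceField | None = None):
        self.grid = grid
        self.props = props
        self.settings = settings
        self.theta = _SCHEME_THETA[settings.scheme]

        dz = grid.dz                      # (nz,)
        zc = grid.z_centers
        k = props.conductivity            # (nz,)
        vol = grid.cell_volume            # (nz,)

        # face conductances (W/K); properties vary only with z, so lateral
        # conductances are z-profiles and vertical ones a (nz-1,) array
        self.Gx = (k * dz * grid.dy / grid.dx)[None, None, :]
        self.Gy = (k * dz * grid.dx / grid.dy)[None, None, :]
        d_lo, d_hi = dz[:-1] / 2.0, dz[1:] / 2.0
        k_face = (d_lo + d_hi) / (d_lo / k[:-1] + d_hi / k[1:])  # harmonic mean
        self.Gz = (k_face * grid.dx * grid.dy / (zc[1:] - zc[:-1]))[None, None, :]

        self.C = (props.volumetric_heat_capacity * vol)[None, None, :]   # J/K
        self.P = (props.perfusion_coeff * vol)[None, None, :]            # W/K
        self.Tb = props.stack.arterial_temp

        q = source.values if source is not None else 0.0
        self.S = (q + props.stack.metabolic_heat) * vol[None, None, :]   # W
        self.S = np.broadcast_to(np.asarray(self.S, dtype=float), grid.shape).copy()
        # imposed surface flux enters the top-cell budget directly
        self.area_top = grid.dx * grid.dy
        self.S[:, :, 0] += settings.surface_flux * self.area_top

        # half-cell conductive resistance between the first cell centre and
        # the surface, per unit area (m^2 K / W)
        self.half_res = dz[0] / (2.0 * k[0])

        # Jacobi diagonal of K (exact, including boundary-reduced entries)
        Kd = np.zeros(grid.shape)
        Kd[:-1, :, :] += self.Gx
        Kd[1:, :, :] += self.Gx
        Kd[:, :-1, :] += self.Gy
        Kd[:, 1:, :] += self.Gy
        Kd[:, :, :-1] += self.Gz
        Kd[:, :, 1:] += self.Gz
        self.K_diag = Kd

        # z-line preconditioner data: the vertical coupling is the stiffest
        # (finest spacing), so a symmetric block-tridiagonal-in-z solve with
        # z-only scalar coefficients makes an effective CG preconditioner
        self._Kdiag_profile = np.zeros(grid.nz)
        self._Kdiag_profile += 2.0 * self.Gx[0, 0] + 2.0 * self.Gy[0, 0]
        self._Kdiag_profile[:-1] += self.Gz[0, 0]
        self._Kdiag_profile[1:] += self.Gz[0, 0]

        self._delta_prev = None  # warm start for CG
        self.total_cg_iters = 0
        self.total_picard_iters = 0

    # -- operator pieces ----------------------------------------------------

    def apply_K(self, T: np.ndarray) -> np.ndarray:
        """Negative conduction operator (SPD): K T = -div(k grad T) * vol."""
        out = np.zeros_like(T)
        F = self.Gx * np.diff(T, axis=0)
        out[:-1, :, :] -= F
        out[1:, :, :] += F
        F = self.Gy * np.diff(T, axis=1)
        out[:, :-1, :] -= F
        out[:, 1:, :] += F
        F = self.Gz * np.diff(T, axis=2)
        out[:, :, :-1] -= F
        out[:, :, 1:] += F
        return out

    def _surface_conductance(self, h_rad: np.ndarray) -> np.ndarray:
        """Effective top-cell conductance per area, combining the linearized
        film coefficient with the half-cell conduction path (W/m^2/K)."""
        h_lin = self.settings.h_conv + h_rad
        with np.errstate(divide="ignore"):
            U = np.where(h_lin > 0, 1.0 / (1.0 / np.maximum(h_lin, 1e-300) + self.half_res), 0.0)
        return U

    def surface_temperature(self, T1: np.ndarray, h_rad: np.ndarray) -> np.ndarray:
        """Surface temperature from the half-cell flux balance."""
        U = self._surface_conductance(h_rad)
        flux = U * (T1 - self.settings.ambient_temp)
        return T1 - flux * self.half_res

    def _h_rad(self, Ts: np.ndarray) -> np.ndarray:
        s = self.settings
        if s.emissivity == 0.0:
            return np.zeros_like(Ts)
        Ti = s.ambient_temp
        return s.emissivity * SIGMA_SB * (Ts**2 + Ti**2) * (Ts + Ti)

    def boundary_flux_density(self, Ts):
        """Outward surface heat-flux density h(Ts-Tinf)+eps sig(Ts^4-Tinf^4),
        W/m^2 (diagnostic; exact nonlinear form)."""
        s = self.settings
        return s.h_conv * (Ts - s.ambient_temp) + s.emissivity * SIGMA_SB * (
            Ts**4 - s.ambient_temp**4
        )

    # -- residual and linear solve ------------------------------------------

    def _residual(self, T: np.ndarray, U: np.ndarray) -> np.ndarray:
        """r = S - K T - P (T - Tb) - U A (T1 - Tinf)  (W per cell)."""
        r = self.S - self.apply_K(T) - self.P * (T - self.Tb)
        r[:, :, 0] -= U * self.area_top * (T[:, :, 0] - self.settings.ambient_temp)
        return r

    def _solve_linear(self, U: np.ndarray, r: np.ndarray) -> np.ndarray:
        """PCG solve of (C/dt + theta (K + P + B)) delta = r."""
        s = self.settings
        th = self.theta
        Cdt = self.C / s.dt

        def apply_A(x):
            out = Cdt * x + th * (self.apply_K(x) + self.P * x)
            out[:, :, 0] += th * U * self.area_top * x[:, :, 0]
            return out

        # symmetric z-line tridiagonal preconditioner (LDL^T with scalar
        # per-level coefficients; the surface conductance enters as its mean)
        nz = self.grid.nz
        b = (Cdt[0, 0] + th * (self._Kdiag_profile + self.P[0, 0])).copy()
        b[0] += th * float(np.mean(U)) * self.area_top
        a = -th * self.Gz[0, 0]  # sub/super-diagonal, length nz-1
        d = np.empty(nz)
        l = np.empty(nz - 1)
        d[0] = b[0]
        for k in range(1, nz):
            l[k - 1] = a[k - 1] / d[k - 1]
            d[k] = b[k] - l[k - 1] * a[k - 1]

        def precond(res):
            y = np.empty_like(res)
            y[:, :, 0] = res[:, :, 0]
            for k in range(1, nz):
                y[:, :, k] = res[:, :, k] - l[k - 1] * y[:, :, k - 1]
            y /= d
            out = np.empty_like(res)
            out[:, :, nz - 1] = y[:, :, nz - 1]
            for k in range(nz - 2, -1, -1):
                out[:, :, k] = y[:, :, k] - l[k] * out[:, :, k + 1]
            return out

        x = self._delta_prev.copy() if self._delta_prev is not None else np.zeros_like(r)
        res = r - apply_A(x)
        z = precond(res)
        p = z.copy()
        rz = float(np.sum(res * z))
        b_norm = float(np.linalg.norm(r))
        tol = max(s.cg_rtol * b_norm, 1e-300)
        n_it = 0
        while np.linalg.norm(res) > tol and n_it < s.cg_maxiter:
            Ap = apply_A(p)
            alpha = rz / float(np.sum(p * Ap))
            x += alpha * p
            res -= alpha * Ap
            z = precond(res)
            rz_new = float(np.sum(res * z))
            p = z + (rz_new / rz) * p
            rz = rz_new
            n_it += 1
        if n_it >= s.cg_maxiter:
            raise SolverError(
                f"CG failed to reach rtol={s.cg_rtol} within {s.cg_maxiter} iterations "
                f"(residual {np.linalg.norm(res):.3e}, target {tol:.3e})"
            )
        self.total_cg_iters += n_it
        return x

    # -- time stepping -------------------------------------------------------

    def stability_limit(self) -> float:
        """Largest stable dt for the explicit scheme (s)."""
        U0 = self._surface_conductance(self._h_rad(np.array(self.settings.initial_temp)))
        denom = np.array(np.broadcast_to(self.K_diag + self.P, self.grid.shape))
        denom[:, :, 0] += float(U0) * self.area_top
        return float(np.min(self.C / np.maximum(denom, 1e-300)))

    def step(self, fld: TemperatureField) -> TemperatureField:
        """Advance one dt; returns a new field (input left untouched)."""
        s = self.settings
        T = fld.values

        Ts = getattr(self, "_Ts_prev", None)
        if Ts is None:
            Ts = np.full((self.grid.nx, self.grid.ny), float(T[:, :, 0].mean()))
        h_rad = self._h_rad(Ts)

        if self.theta == 0.0:
            dt_max = self.stability_limit()
            if s.dt > dt_max * (1 + 1e-9):
                raise SolverError(
                    f"explicit scheme unstable: dt={s.dt:.3g}s exceeds limit {dt_max:.3g}s"
                )
            # resolve the surface temperature consistently before fluxing
            for _ in range(3):
                Ts = self.surface_temperature(T[:, :, 0], h_rad)
                h_rad = self._h_rad(Ts)
            U = self._surface_conductance(h_rad)
            delta = (s.dt / self.C) * self._residual(T, U)
            T_new = T + delta
        else:
            delta = np.zeros_like(T)
            n_picard = 0
            while True:
                U = self._surface_conductance(h_rad)
                r = self._residual(T, U)
                delta = self._solve_linear(U, r)
                self._delta_prev = delta
                T_theta1 = T[:, :, 0] + self.theta * delta[:, :, 0]
                Ts_new = self.surface_temperature(T_theta1, h_rad)
                change = float(np.max(np.abs(Ts_new - Ts)))
                Ts = Ts_new
                h_rad = self._h_rad(Ts)
                n_picard += 1
                if s.radiation_linearization == "frozen" or s.emissivity == 0.0:
                    break
                if change < s.picard_tol:
                    break
                if n_picard >= s.max_picard_iters:
                    raise SolverError(
                        f"Picard iteration on the radiation term did not converge: "
                        f"{n_picard} iterations, last surface change {change:.3e} K "
                        f"(tol {s.picard_tol} K)"
                    )
            self.total_picard_iters += n_picard
            T_new = T + delta

        if not np.all(np.isfinite(T_new)):
            raise SolverError(f"non-finite temperatures at t={fld.time + s.dt:.3f} s")
        self._Ts_prev = Ts
        return TemperatureField(T_new, fld.time + s.dt, self.grid)


# ---------------------------------------------------------------------------
# scenario driver


@dataclass
class RunResult:
    """Everything recorded during one scenario run."""

    final_field: TemperatureField
    summary: pd.DataFrame
    probes: list[ProbeRecord]
    snapshots: dict[float, TemperatureField]
    provenance: dict

    def summary_at(self, t: float, column: str) -> float:
        """Summary value at recorded time t (nearest recorded sample)."""
        idx = (self.summary["time_s"] - t).abs().idxmin()
        return float(self.summary.loc[idx, column])


def solve(scenario) -> RunResult:
    """Run a scenario: initialize, step to the requested duration, record
    the summary series (max T, isotherm volumes) and probe traces."""
    grid: SimulationGrid = scenario.grid
    settings: SolverSettings = scenario.settings
    if not scenario.duration > 0:
        raise ConfigurationError("scenario duration must be positive")

    props = rasterize_properties(scenario.stack, grid)
    source = (
        volumetric_source(grid, list(scenario.beams), props, mode=scenario.source_mode)
        if scenario.beams else None
    )
    solver = BioheatSolver(grid, props, settings, source)

    fld = initialize(grid, settings)
    thresholds = tuple(scenario.isotherm_thresholds)
    probes = list(scenario.probes)
    record_every = max(int(round(scenario.record_interval / settings.dt)), 1)
    n_steps = int(round(scenario.duration / settings.dt))
    snapshot_times = sorted(set(float(t) for t in scenario.snapshot_times))

    rows = []
    probe_t: list[float] = []
    probe_vals: list[list[float]] = [[] for _ in probes]
    snapshots: dict[float, TemperatureField] = {}

    def record(f: TemperatureField):
        row = {"time_s": f.time, "max_T_C": metrics.max_temperature(f)}
        for thr in thresholds:
            row[f"vol{thr:g}_mm3"] = metrics.isotherm_volume(f, thr, subdiv=3) * 1e9
        rows.append(row)
        if probes:
            probe_t.append(f.time)
            for j, (px, py, pz) in enumerate(probes):
                probe_vals[j].append(
                    float(metrics.celsius(metrics._trilinear(grid, f.values, px, py, pz)))
                )

    t_wall = _time.perf_counter()
    record(fld)
    for istep in range(1, n_steps + 1):
        fld = solver.step(fld)
        if istep % record_every == 0 or istep == n_steps:
            record(fld)
        for ts in snapshot_times:
            if abs(fld.time - ts) < settings.dt / 2 and ts not in snapshots:
                snapshots[ts] = fld.copy()

    summary = pd.DataFrame(rows)
    probe_records = [
        ProbeRecord(loc, np.asarray(probe_t), np.asarray(vals))
        for loc, vals in zip(probes, probe_vals)
    ]
    provenance = {
        "scenario_id": scenario.id,
        "scheme": settings.scheme,
        "dt_s": settings.dt,
        "grid_shape": list(grid.shape),
        "dx_mm": grid.dx * 1e3,
        "source_mode": scenario.source_mode,
        "initial_temp_K": settings.initial_temp,
        "ambient_temp_K": settings.ambient_temp,
        "layer_thicknesses_mm": {l.name: l.thickness * 1e3 for l in scenario.stack.layers},
        "total_absorbed_W": source.total_absorbed if source is not None else 0.0,
        "wall_time_s": _time.perf_counter() - t_wall,
        "mean_cg_iters_per_step": solver.total_cg_iters / max(n_steps, 1),
    }
    logger.info(
        "run '%s': %d steps, %.1f s wall, max T %.2f degC",
        scenario.id, n_steps, provenance["wall_time_s"], rows[-1]["max_T_C"],
    )
    return RunResult(fld, summary, probe_records, snapshots, provenance)


@dataclass
class ConvergenceReport:
    """Outcome of a grid-refinement study."""

    grids: list[SimulationGrid]
    max_temps_C: list[float]
    rel_changes: list[float]
    converged: bool
    accepted_grid: SimulationGrid | None


def grid_refinement_study(scenario, refinement_factor: float = 1.5,
                          tol_fraction: float = 0.005,
                          max_levels: int = 5) -> ConvergenceReport:
    """Refine all spacings by ``refinement_factor`` until the final maximum
    temperature changes by less than ``tol_fraction`` (relative, on the rise
    above the initial temperature) between two contiguous grids."""
    if not tol_fraction > 0:
        raise ConfigurationError("tol_fraction must be positive")
    grids = [scenario.grid]
    maxT = [metrics.max_temperature(solve(scenario).final_field)]
    rel_changes: list[float] = []
    for _ in range(max_levels):
        g = grids[-1].refined(refinement_factor)
        grids.append(g)
        maxT.append(metrics.max_temperature(solve(replace(scenario, grid=g)).final_field))
        rel = abs(maxT[-1] - maxT[-2]) / max(abs(maxT[-2]), 1e-12)
        rel_changes.append(rel)
        if rel < tol_fraction:
            return ConvergenceReport(grids, maxT, rel_changes, True, g)
    raise SolverError(
        f"grid study did not reach {tol_fraction:.1%} within {max_levels} refinements "
        f"(changes: {[f'{c:.2%}' for c in rel_changes]})"
    )
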