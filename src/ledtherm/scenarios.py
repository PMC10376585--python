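"""Declarative scenarios and pre-built parametric studies.

A Scenario bundles a tissue stack, one or more beams, a grid, solver
settings and a duration.  The study drivers reproduce the standard
parametric analyses for this kind of LED photothermal model: power sweeps
with ablation-onset detection, LED-to-skin gap comparisons, multi-LED
arrays, and the agar-phantom validation configuration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml

from . import metrics
from .exceptions import ConfigurationError
from .grid import SimulationGrid, phantom_grid, preview_skin_grid
from .materials import TissueStack, build_phantom_model, build_skin_model, stack_from_dict, stack_to_dict
from .optics import BeamModel, sigma_at_gap
from .solver import ProbeRecord, RunResult, SolverSettings, solve

logger = logging.getLogger(__name__)

#: Default therapy duration (s): 10 minutes of LED irradiation.
DEFAULT_DURATION = 600.0


@dataclass(frozen=True)
class Scenario:
    """Complete description of one run."""

    id: str
    stack: TissueStack
    beams: tuple[BeamModel, ...]
    grid: SimulationGrid
    settings: SolverSettings
    duration: float = DEFAULT_DURATION
    probes: tuple[tuple[float, float, float], ...] = ()
    record_interval: float = 1.0
    snapshot_times: tuple[float, ...] = ()
    isotherm_thresholds: tuple[float, ...] = (43.0, 50.0)
    source_mode: str = "cumulative"

    def __post_init__(self):
        if not self.duration > 0:
            raise ConfigurationError("duration must be positive")
        hx = self.grid.nx * self.grid.dx / 2
        hy = self.grid.ny * self.grid.dy / 2
        for b in self.beams:
            if abs(b.center[0]) > hx or abs(b.center[1]) > hy:
                raise ConfigurationError(
                    f"beam centre {b.center} outside the lateral domain (±{hx:g}, ±{hy:g})"
                )


def skin_scenario(power_mW: float, emission_label: str = "90deg", gap_um: float = 0.0,
                  duration: float = DEFAULT_DURATION, grid: SimulationGrid | None = None,
                  stack: TissueStack | None = None, settings: SolverSettings | None = None,
                  sigma: float | None = None, scenario_id: str | None = None,
                  **kwargs) -> Scenario:
    """Single-LED skin scenario at the given power (mW) and gap (um)."""
    stack = stack or build_skin_model()
    grid = grid or preview_skin_grid()
    settings = settings or SolverSettings()
    if sigma is None:
        beam = BeamModel.from_label(emission_label, power_mW * 1e-3, gap_um * 1e-6)
    else:
        beam = BeamModel(power_mW * 1e-3, sigma, (0.0, 0.0), emission_label)
    sid = scenario_id or f"skin_{emission_label}_{power_mW:g}mW_gap{gap_um:g}um"
    return Scenario(sid, stack, (beam,), grid, settings, duration, **kwargs)


# ---------------------------------------------------------------------------
# multi-LED layouts

@dataclass(frozen=True)
class LedLayout:
    """n LEDs: one central plus n-1 satellites on a circle of radius
    ``spacing`` (the centre-to-satellite distance, default 10 mm)."""

    n_leds: int
    spacing: float = 0.010
    power: float = 0.3

    def __post_init__(self):
        if not 1 <= self.n_leds <= 5:
            raise ConfigurationError("n_leds must be between 1 and 5")
        if not self.spacing > 0:
            raise ConfigurationError("spacing must be positive")


def make_layout(n_leds: int, spacing: float = 0.010, power: float = 0.3,
                emission_label: str = "90deg", gap: float = 0.0,
                start_angle: float = 0.0) -> list[BeamModel]:
    """Beams for an n-LED array: one at the origin, the rest equally spaced
    in angle on a circle of radius ``spacing``, starting from +x.

    The angular placement is a declared convention (only the 10 mm
    centre-to-satellite distance is constrained by the layout definition).
    """
    layout = LedLayout(n_leds, spacing, power)  # validation
    sigma = sigma_at_gap(emission_label, gap)
    beams = [BeamModel(power, sigma, (0.0, 0.0), emission_label)]
    n_sat = layout.n_leds - 1
    for i in range(n_sat):
        ang = start_angle + 2.0 * np.pi * i / max(n_sat, 1)
        beams.append(BeamModel(
            power, sigma,
            (spacing * float(np.cos(ang)), spacing * float(np.sin(ang))),
            emission_label,
        ))
    return beams


# ---------------------------------------------------------------------------
# parametric studies

@dataclass
class StudyResult:
    """A metrics table plus the underlying runs, keyed by study parameter."""

    table: pd.DataFrame
    runs: dict


def run_power_sweep(emission_label: str = "90deg",
                    powers_mW: list[float] | None = None,
                    duration: float = DEFAULT_DURATION,
                    grid: SimulationGrid | None = None,
                    stack: TissueStack | None = None,
                    settings: SolverSettings | None = None,
                    snapshot_times: tuple[float, ...] = (),
                    record_interval: float = 1.0) -> StudyResult:
    """One run per power; reports final max T, 43/50 degC isotherm volume and
    depth, and the ablation-onset power (smallest power with any tissue at
    or above 50 degC)."""
    powers_mW = list(powers_mW) if powers_mW is not None else [100.0 * i for i in range(1, 8)]
    if not powers_mW:
        raise ConfigurationError("powers list must be non-empty")
    runs: dict[float, RunResult] = {}
    rows = []
    for p in powers_mW:
        scn = skin_scenario(p, emission_label, duration=duration, grid=grid,
                            stack=stack, settings=settings, snapshot_times=snapshot_times,
                            record_interval=record_interval)
        try:
            res = solve(scn)
        except Exception as exc:  # noqa: BLE001 - annotate and re-raise
            raise type(exc)(f"power {p:g} mW: {exc}") from exc
        runs[p] = res
        f = res.final_field
        r43 = metrics.isotherm_metrics(f, 43.0)
        r50 = metrics.isotherm_metrics(f, 50.0)
        rows.append({
            "power_mW": p,
            "max_T_C": metrics.max_temperature(f),
            "vol43_mm3": r43.volume_m3 * 1e9,
            "vol50_mm3": r50.volume_m3 * 1e9,
            "depth43_mm": (r43.max_depth_m or np.nan) * 1e3,
            "depth50_mm": (r50.max_depth_m or np.nan) * 1e3,
        })
    table = pd.DataFrame(rows).sort_values("power_mW", ignore_index=True)
    onset = table.loc[table["vol50_mm3"] > 0, "power_mW"]
    result = StudyResult(table, runs)
    result.ablation_onset_mW = float(onset.iloc[0]) if len(onset) else None
    return result


def run_gap_study(emission_label: str = "90deg", power_mW: float = 300.0,
                  gaps_um: tuple[float, ...] = (0.0, 2000.0),
                  duration: float = DEFAULT_DURATION,
                  grid: SimulationGrid | None = None,
                  stack: TissueStack | None = None,
                  settings: SolverSettings | None = None,
                  baseline_C: float = 37.0,
                  record_interval: float = 1.0) -> StudyResult:
    """One run per LED-to-skin gap; percent drops of the maximum and of the
    layer-interface temperature rises are reported relative to the smallest
    gap (rise above ``baseline_C``)."""
    stack = stack or build_skin_model()
    gaps = sorted(gaps_um)
    runs: dict[float, RunResult] = {}
    rows = []
    interfaces = stack.interfaces[:-1]  # epidermis-dermis, dermis-fat depths
    for g in gaps:
        scn = skin_scenario(power_mW, emission_label, gap_um=g, duration=duration,
                            grid=grid, stack=stack, settings=settings,
                            record_interval=record_interval)
        res = solve(scn)
        runs[g] = res
        f = res.final_field
        z, prof = metrics.depth_profile(f)
        row = {
            "gap_um": g,
            "sigma_mm": sigma_at_gap(emission_label, g * 1e-6) * 1e3,
            "max_T_C": metrics.max_temperature(f),
            "vol43_mm3": metrics.isotherm_volume(f, 43.0) * 1e9,
            "t_to_43C_s": metrics.time_to_threshold(
                res.summary["time_s"], res.summary["max_T_C"], 43.0),
        }
        for j, zi in enumerate(interfaces):
            row[f"iface{j}_T_C"] = float(np.interp(zi, z, prof))
        rows.append(row)
    table = pd.DataFrame(rows)
    ref = table.iloc[0]
    # Two drop conventions are emitted side by side: `_pct` uses the rise
    # above baseline_C (heating-relevant, default for the maximum), `_abs_pct`
    # the absolute Celsius reading (baseline 0), since published drop figures
    # are quoted in either convention depending on the quantity.
    table["drop_max_pct"] = [
        metrics.percent_drop(ref["max_T_C"], row["max_T_C"], baseline_C)
        for _, row in table.iterrows()
    ]
    for j in range(len(interfaces)):
        col = f"iface{j}_T_C"
        table[f"drop_iface{j}_pct"] = [
            metrics.percent_drop(ref[col], row[col], baseline_C)
            for _, row in table.iterrows()
        ]
        table[f"drop_iface{j}_abs_pct"] = [
            metrics.percent_drop(ref[col], row[col], 0.0)
            for _, row in table.iterrows()
        ]
    logger.info("gap study drops: rise above %.1f degC (_pct) and absolute "
                "Celsius (_abs_pct)", baseline_C)
    return StudyResult(table, runs)


def run_multi_led(n_list=(1, 2, 3, 4, 5), power_mW: float = 300.0,
                  duration: float = DEFAULT_DURATION,
                  spacing: float = 0.010,
                  grid: SimulationGrid | None = None,
                  stack: TissueStack | None = None,
                  settings: SolverSettings | None = None,
                  emission_label: str = "90deg") -> StudyResult:
    """One run per array size; reports the 43 degC isotherm volume, its
    percent increase over the single-LED case, the ratio form, and the time
    to first reach 43 degC."""
    if not set(n_list) <= set(range(1, 6)):
        raise ConfigurationError("n_list entries must lie in 1..5")
    stack = stack or build_skin_model()
    # the default domain is widened so satellite beams at 10 mm stay well
    # inside the lateral boundaries
    grid = grid or preview_skin_grid(lateral_extent=50e-3)
    settings = settings or SolverSettings()
    runs: dict[int, RunResult] = {}
    rows = []
    for n in sorted(n_list):
        beams = tuple(make_layout(n, spacing, power_mW * 1e-3, emission_label))
        scn = Scenario(f"multi_{n}led_{power_mW:g}mW", stack, beams, grid,
                       settings, duration)
        res = solve(scn)
        runs[n] = res
        rows.append({
            "n_leds": n,
            "vol43_mm3": metrics.isotherm_volume(res.final_field, 43.0) * 1e9,
            "max_T_C": metrics.max_temperature(res.final_field),
            "t_to_43C_s": metrics.time_to_threshold(
                res.summary["time_s"], res.summary["max_T_C"], 43.0),
        })
    table = pd.DataFrame(rows)
    v1 = float(table.loc[table["n_leds"] == table["n_leds"].min(), "vol43_mm3"].iloc[0])
    table["vol_increase_pct"] = 100.0 * (table["vol43_mm3"] - v1) / v1
    table["vol_ratio_pct"] = 100.0 * table["vol43_mm3"] / v1
    return StudyResult(table, runs)


def run_phantom_validation(power_mW: float, duration: float = 300.0,
                           probe_depth: float = 2e-3,
                           emission_label: str = "90deg",
                           measured: ProbeRecord | None = None,
                           synthesize: bool = True,
                           noise_sd_C: float = 0.3,
                           seed: int = 0,
                           initial_temp_C: float = 25.0,
                           grid: SimulationGrid | None = None,
                           settings: SolverSettings | None = None):
    """Agar-phantom run with a thermocouple probe 2 mm under the beam centre.

    The phantom's equilibration temperature is a required modelling input
    (default: ambient 25 degC).  If no measured trace is given, a synthetic
    noisy one is generated from the simulation itself (stand-in for the lab
    thermocouple record).  Returns (RunResult, simulated ProbeRecord,
    measured ProbeRecord, TraceComparison).
    """
    stack = build_phantom_model()
    grid = grid or phantom_grid()
    settings = settings or SolverSettings(
        initial_temp=metrics.kelvin(initial_temp_C), dt=0.5)
    logger.info("phantom run: initial temperature %.2f degC (configured, not a "
                "literature value)", initial_temp_C)
    scn = Scenario(
        f"phantom_{emission_label}_{power_mW:g}mW", stack,
        (BeamModel.from_label(emission_label, power_mW * 1e-3),),
        grid, settings, duration,
        probes=((0.0, 0.0, probe_depth),),
        isotherm_thresholds=(),
    )
    res = solve(scn)
    sim = res.probes[0]
    if measured is None:
        if not synthesize:
            raise ConfigurationError("no measured trace supplied and synthesis disabled")
        from .synthetic import synth_trace_from_probe

        measured = synth_trace_from_probe(sim, noise_sd_C, seed)
    comparison = metrics.compare_traces(sim, measured)
    return res, sim, measured, comparison


# ---------------------------------------------------------------------------
# config round-trip

def scenario_to_dict(scn: Scenario) -> dict:
    return {
        "id": scn.id,
        "duration_s": scn.duration,
        "record_interval_s": scn.record_interval,
        "source_mode": scn.source_mode,
        "isotherm_thresholds_C": list(scn.isotherm_thresholds),
        "stack": stack_to_dict(scn.stack),
        "beams": [
            {
                "power_mW": b.power * 1e3,
                "sigma_mm": b.sigma * 1e3,
                "center_mm": [b.center[0] * 1e3, b.center[1] * 1e3],
                "emission_label": b.emission_label,
            }
            for b in scn.beams
        ],
        "grid": {
            "nx": scn.grid.nx, "ny": scn.grid.ny,
            "dx_mm": scn.grid.dx * 1e3, "dy_mm": scn.grid.dy * 1e3,
            "z_edges_mm": (scn.grid.z_edges * 1e3).tolist(),
        },
        "settings": {
            "dt_s": scn.settings.dt,
            "scheme": scn.settings.scheme,
            "radiation_linearization": scn.settings.radiation_linearization,
            "ambient_temp_C": float(metrics.celsius(scn.settings.ambient_temp)),
            "initial_temp_C": float(metrics.celsius(scn.settings.initial_temp)),
            "h_conv_W_per_m2K": scn.settings.h_conv,
            "emissivity": scn.settings.emissivity,
        },
        "probes_mm": [[p[0] * 1e3, p[1] * 1e3, p[2] * 1e3] for p in scn.probes],
    }


def scenario_from_dict(d: dict) -> Scenario:
    g = d["grid"]
    grid = SimulationGrid(g["nx"], g["ny"], g["dx_mm"] * 1e-3, g["dy_mm"] * 1e-3,
                          np.asarray(g["z_edges_mm"]) * 1e-3)
    s = d.get("settings", {})
    settings = SolverSettings(
        dt=s.get("dt_s", 0.25),
        scheme=s.get("scheme", "crank_nicolson"),
        radiation_linearization=s.get("radiation_linearization", "picard"),
        ambient_temp=metrics.kelvin(s.get("ambient_temp_C", 25.0)),
        initial_temp=metrics.kelvin(s.get("initial_temp_C", 37.0)),
        h_conv=s.get("h_conv_W_per_m2K", 10.0),
        emissivity=s.get("emissivity", 0.95),
    )
    beams = []
    for b in d["beams"]:
        if "sigma_mm" in b:
            beams.append(BeamModel(
                b["power_mW"] * 1e-3, b["sigma_mm"] * 1e-3,
                tuple(np.asarray(b.get("center_mm", [0, 0])) * 1e-3),
                b.get("emission_label", "custom"),
            ))
        else:
            beams.append(BeamModel.from_label(
                b["emission_label"], b["power_mW"] * 1e-3,
                b.get("gap_um", 0.0) * 1e-6,
                tuple(np.asarray(b.get("center_mm", [0, 0])) * 1e-3),
            ))
    return Scenario(
        id=d["id"],
        stack=stack_from_dict(d["stack"]),
        beams=tuple(beams),
        grid=grid,
        settings=settings,
        duration=d.get("duration_s", DEFAULT_DURATION),
        probes=tuple(tuple(np.asarray(p) * 1e-3) for p in d.get("probes_mm", [])),
        record_interval=d.get("record_interval_s", 1.0),
        isotherm_thresholds=tuple(d.get("isotherm_thresholds_C", (43.0, 50.0))),
        source_mode=d.get("source_mode", "cumulative"),
    )


def save_scenario(scn: Scenario, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(scenario_to_dict(scn), fh, sort_keys=False)


def load_scenario(path) -> Scenario:
    with open(path) as fh:
        return scenario_from_dict(yaml.safe_load(fh))
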