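"""Post-processing of temperature fields and time series.

Reported quantities mirror standard photothermal dosimetry: global maxima,
beam-axis depth profiles, threshold-isotherm volumes and depths (43 degC
therapeutic, 50 degC ablative), percent drops of the temperature rise, time
to reach a threshold, and simulated-vs-measured trace statistics.

Percent drops are computed on the temperature RISE above a baseline
(default: the 37 degC core temperature), not on the absolute temperature:
heating can only move tissue between the baseline and its peak, so a
fractional drop of the absolute Celsius reading would be physically
meaningless.  The baseline is explicit in the API so ambient-referenced or
absolute conventions can be probed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import ConfigurationError

ZERO_C = 273.15


def celsius(t_kelvin):
    return np.asarray(t_kelvin) - ZERO_C


def kelvin(t_celsius):
    return np.asarray(t_celsius) + ZERO_C


@dataclass(frozen=True)
class IsothermReport:
    """Volume (m^3) at/above a threshold, deepest beam-axis point reaching it
    (m, None if never), and first time the volume became positive (s, None
    if unknown/never)."""

    threshold_C: float
    volume_m3: float
    max_depth_m: float | None
    first_crossing_time_s: float | None = None


@dataclass(frozen=True)
class TraceComparison:
    """Agreement statistics between two temperature traces."""

    mae_C: float
    correlation: float
    mean_rel_sd: float | None = None


def _trilinear(grid, values, x, y, z):
    """Trilinear interpolation of a cell-centred field at one or more points."""
    from scipy.interpolate import RegularGridInterpolator

    rgi = RegularGridInterpolator(
        (grid.x_centers, grid.y_centers, grid.z_centers), values,
        bounds_error=False, fill_value=None,  # linear extrapolation at edges
    )
    pts = np.column_stack([np.atleast_1d(x), np.atleast_1d(y), np.atleast_1d(z)])
    out = rgi(pts)
    return float(out[0]) if out.size == 1 else out


def max_temperature(field) -> float:
    """Global maximum of a temperature field, degC."""
    vals = field.values
    if not np.all(np.isfinite(vals)):
        raise ConfigurationError("temperature field contains non-finite values")
    return float(celsius(vals.max()))


def depth_profile(field, x0: float = 0.0, y0: float = 0.0):
    """(depth_m, temp_C) arrays along the vertical column through (x0, y0).

    Values are sampled at the cell-centre depths with lateral trilinear
    interpolation; the profile at a cell-centre column equals the stored
    field exactly.
    """
    grid = field.grid
    xs, ys = grid.x_centers, grid.y_centers
    if not (xs[0] <= x0 <= xs[-1] and ys[0] <= y0 <= ys[-1]):
        raise ConfigurationError(f"column ({x0}, {y0}) outside the lateral domain")
    z = grid.z_centers
    temps = _trilinear(grid, field.values, np.full_like(z, x0), np.full_like(z, y0), z)
    return z, celsius(np.atleast_1d(temps))


_SUBDIV_CACHE: dict[int, np.ndarray] = {}


def _subcell_weights(s: int) -> np.ndarray:
    """Trilinear weights of the s^3 subcell centres w.r.t. the 8 corners,
    shape (s^3, 8)."""
    if s not in _SUBDIV_CACHE:
        t = (np.arange(s) + 0.5) / s
        u, v, w = np.meshgrid(t, t, t, indexing="ij")
        u, v, w = u.ravel(), v.ravel(), w.ravel()
        cols = []
        for ci in (1 - u, u):
            for cj in (1 - v, v):
                for ck in (1 - w, w):
                    cols.append(ci * cj * ck)
        _SUBDIV_CACHE[s] = np.column_stack(cols)
    return _SUBDIV_CACHE[s]


def isotherm_volume(field, threshold_C: float, subdiv: int = 4) -> float:
    """Volume (m^3) with T >= threshold, with trilinear sub-voxel occupancy.

    The occupancy is that of the trilinear interpolant over the cell-centre
    lattice: the domain splits into dual cells whose corners are the stored
    cell-centre values (half-cell boundary margins carry the clamped edge
    value).  Dual cells entirely above (below) the threshold count fully
    (not at all); straddling cells are subsampled on a subdiv^3 lattice of
    trilinearly interpolated points.
    """
    grid = field.grid
    thr = kelvin(threshold_C)
    # dual-lattice node spacings, including the half-cell boundary margins
    wx = np.diff(np.concatenate([[grid.x_centers[0] - grid.dx / 2],
                                 grid.x_centers, [grid.x_centers[-1] + grid.dx / 2]]))
    wy = np.diff(np.concatenate([[grid.y_centers[0] - grid.dy / 2],
                                 grid.y_centers, [grid.y_centers[-1] + grid.dy / 2]]))
    wz = np.diff(np.concatenate([[0.0], grid.z_centers, [grid.z_edges[-1]]]))
    dualvol = wx[:, None, None] * wy[None, :, None] * wz[None, None, :]

    padded = np.pad(field.values, 1, mode="edge")
    n0, n1, n2 = padded.shape
    corners = [
        padded[di:di + n0 - 1, dj:dj + n1 - 1, dk:dk + n2 - 1]
        for di in (0, 1) for dj in (0, 1) for dk in (0, 1)
    ]
    cmin = np.minimum.reduce(corners)
    cmax = np.maximum.reduce(corners)

    vol = float(np.sum(dualvol[cmin >= thr]))
    straddle = (cmin < thr) & (cmax >= thr)
    if np.any(straddle):
        cvals = np.stack([c[straddle] for c in corners], axis=1)  # (m, 8)
        sub = cvals @ _subcell_weights(subdiv).T  # (m, s^3)
        frac = np.mean(sub >= thr, axis=1)
        vol += float(np.sum(frac * dualvol[straddle]))
    return vol


def isotherm_max_depth(field, threshold_C: float, x0: float = 0.0, y0: float = 0.0):
    """Deepest point on the (x0, y0) column with T >= threshold (m), linearly
    interpolated between cell centres; None if the column never reaches it."""
    z, temps = depth_profile(field, x0, y0)
    above = temps >= threshold_C
    if not above.any():
        return None
    last = int(np.max(np.nonzero(above)))
    if last == len(z) - 1:
        return float(z[-1])
    # linear crossing between the last above-threshold centre and the next one
    t0, t1 = temps[last], temps[last + 1]
    return float(z[last] + (z[last + 1] - z[last]) * (t0 - threshold_C) / (t0 - t1))


def isotherm_metrics(field, threshold_C: float, columns=((0.0, 0.0),),
                     first_crossing_time_s=None, subdiv: int = 4) -> IsothermReport:
    """Full isotherm report; ``columns`` are the beam-centre columns over
    which the maximum depth is taken (one per LED for arrays)."""
    vol = isotherm_volume(field, threshold_C, subdiv=subdiv)
    depths = [isotherm_max_depth(field, threshold_C, x0, y0) for x0, y0 in columns]
    depths = [d for d in depths if d is not None]
    return IsothermReport(
        threshold_C=threshold_C,
        volume_m3=vol,
        max_depth_m=max(depths) if depths else None,
        first_crossing_time_s=first_crossing_time_s,
    )


def percent_drop(reference_C: float, altered_C: float, baseline_C: float = 37.0) -> float:
    """Percent decrease of the temperature rise above ``baseline_C`` when the
    reference case is replaced by the altered one."""
    if reference_C <= baseline_C:
        raise ConfigurationError("reference temperature must exceed the baseline")
    rise_ref = reference_C - baseline_C
    rise_alt = altered_C - baseline_C
    return 100.0 * (rise_ref - rise_alt) / rise_ref


def time_to_threshold(times, values, threshold):
    """First time ``values`` crosses up through ``threshold``, linearly
    interpolated between samples; 0 if it starts above; None if never."""
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if values[0] >= threshold:
        return 0.0
    above = values >= threshold
    if not above.any():
        return None
    i = int(np.argmax(above))
    v0, v1 = values[i - 1], values[i]
    return float(times[i - 1] + (times[i] - times[i - 1]) * (threshold - v0) / (v1 - v0))


def compare_traces(simulated, measured) -> TraceComparison:
    """MAE (degC) and Pearson correlation between a simulated probe trace and
    a measured one, resampled to the simulated time base over their overlap."""
    st = np.asarray(simulated.times, dtype=float)
    sv = np.asarray(simulated.temperatures, dtype=float)
    mt = np.asarray(measured.times, dtype=float)
    mv = np.asarray(measured.temperatures, dtype=float)
    lo, hi = max(st[0], mt[0]), min(st[-1], mt[-1])
    mask = (st >= lo) & (st <= hi)
    if mask.sum() < 3:
        raise ConfigurationError("need at least 3 overlapping samples to compare traces")
    sv = sv[mask]
    mv_resampled = np.interp(st[mask], mt, mv)
    mae = float(np.mean(np.abs(sv - mv_resampled)))
    if np.std(sv) == 0 or np.std(mv_resampled) == 0:
        corr = 1.0 if mae == 0 else 0.0
    else:
        corr = float(np.corrcoef(sv, mv_resampled)[0, 1])
    return TraceComparison(mae_C=mae, correlation=corr)
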