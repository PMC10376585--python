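"""Synthetic stand-ins for the two laboratory measurement streams.

No laboratory data ships with this package.  Instead, two generators emulate
the measurements a bench characterization would produce:

* beam-profiler scans - samples of a known Gaussian irradiance field with
  additive detector noise (a fraction of the peak reading), used to exercise
  the 2-D Gaussian beam fit;
* thermocouple traces - a simulated probe temperature series with additive
  absolute noise (default 0.3 degC, bracketing typical few-percent
  trial-to-trial variability), used to exercise the trace-comparison
  statistics.

Every generator is deterministic for a given seed and carries its seed in
the output object.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .exceptions import ConfigurationError, FitError
from .optics import BeamModel, gaussian_irradiance
from .solver import ProbeRecord


@dataclass
class ProfilerScan:
    """Regular x/y grid of irradiance samples (detector units ~ W/m^2)."""

    x: np.ndarray           # (nx,), m
    y: np.ndarray           # (ny,), m
    intensity: np.ndarray   # (nx, ny), clipped at 0
    noise_sd: float         # fraction of peak
    seed: int


@dataclass
class SyntheticTrace:
    """Noisy thermocouple-style temperature trace, degC."""

    times: np.ndarray
    temperatures: np.ndarray
    noise_sd: float
    seed: int


@dataclass
class GaussianFit:
    """Result of a 2-D Gaussian fit to a profiler scan."""

    sigma: float
    peak: float
    center: tuple[float, float]
    residual_norm: float
    ill_conditioned: bool

    @property
    def power(self) -> float:
        """Radiometric power implied by the fit: P = 2 pi sigma^2 I0."""
        return 2.0 * np.pi * self.sigma**2 * self.peak

    def to_beam(self, emission_label: str = "custom") -> BeamModel:
        return BeamModel(self.power, self.sigma, self.center, emission_label)


def synth_profiler_scan(beam: BeamModel, half_extent: float | None = None,
                        shape: tuple[int, int] = (64, 64),
                        noise_sd: float = 0.02, seed: int = 0) -> ProfilerScan:
    """Sample a beam's irradiance on a regular grid and add detector noise.

    ``half_extent`` is the scan half-width (default 3 sigma around the beam
    centre); noise is zero-mean Gaussian with sd = noise_sd * peak, and
    negative readings are clipped to zero as a detector would.
    """
    if noise_sd < 0:
        raise ConfigurationError("noise_sd must be >= 0")
    if half_extent is None:
        half_extent = 3.0 * beam.sigma
    x = np.linspace(-half_extent, half_extent, shape[0]) + beam.center[0]
    y = np.linspace(-half_extent, half_extent, shape[1]) + beam.center[1]
    X, Y = np.meshgrid(x, y, indexing="ij")
    truth = gaussian_irradiance(X, Y, beam)
    rng = np.random.default_rng(seed)
    noisy = truth + rng.normal(0.0, noise_sd * beam.peak_irradiance, size=truth.shape)
    return ProfilerScan(x, y, np.clip(noisy, 0.0, None), noise_sd, seed)


def fit_gaussian_profile(scan: ProfilerScan) -> GaussianFit:
    """Least-squares fit of I0 exp(-((x-cx)^2+(y-cy)^2)/(2 sigma^2)).

    Initial values come from the sample moments.  A scan whose footprint
    spans less than ~1 fitted sigma from the centre cannot constrain the
    width and is flagged ill-conditioned.
    """
    if scan.intensity.size < 25:
        raise ConfigurationError("scan needs at least 25 samples")
    X, Y = np.meshgrid(scan.x, scan.y, indexing="ij")
    I = scan.intensity
    w = np.maximum(I, 0.0)
    w_sum = w.sum()
    if w_sum <= 0:
        raise FitError("scan contains no positive intensity")
    cx0 = float((w * X).sum() / w_sum)
    cy0 = float((w * Y).sum() / w_sum)
    var0 = float((w * ((X - cx0) ** 2 + (Y - cy0) ** 2)).sum() / w_sum) / 2.0
    sigma0 = max(np.sqrt(var0), 1e-6)
    p0 = [float(I.max()), cx0, cy0, sigma0]

    def resid(p):
        peak, cx, cy, sigma = p
        model = peak * np.exp(-(((X - cx) ** 2 + (Y - cy) ** 2) / (2.0 * sigma**2)))
        return (model - I).ravel()

    sol = least_squares(resid, p0, method="lm", max_nfev=2000)
    if not sol.success:
        raise FitError(f"Gaussian fit did not converge: {sol.message}")
    peak, cx, cy, sigma = sol.x
    sigma = abs(float(sigma))
    span = min(scan.x[-1] - cx, cx - scan.x[0], scan.y[-1] - cy, cy - scan.y[0])
    ill = span < sigma  # footprint narrower than one sigma: width unconstrained
    return GaussianFit(
        sigma=sigma, peak=float(peak), center=(float(cx), float(cy)),
        residual_norm=float(np.linalg.norm(sol.fun)), ill_conditioned=bool(ill),
    )


def synth_trace_from_probe(probe: ProbeRecord, noise_sd: float = 0.3,
                           seed: int = 0) -> SyntheticTrace:
    """One noisy replicate of an already-simulated probe trace."""
    rng = np.random.default_rng(seed)
    noisy = np.asarray(probe.temperatures, dtype=float) + rng.normal(
        0.0, noise_sd, size=len(probe.temperatures))
    return SyntheticTrace(np.asarray(probe.times, dtype=float), noisy, noise_sd, seed)


def synth_thermocouple_trace(scenario, probe: tuple[float, float, float],
                             noise_sd: float = 0.3, n_replicates: int = 1,
                             seed: int = 0) -> list[SyntheticTrace]:
    """Solve a scenario once and emit noisy replicates of the probe trace.

    Replicates are independent (seeded seed, seed+1, ...); noise_sd is in
    absolute degC.  With noise_sd = 0 the trace equals the simulation.
    """
    from dataclasses import replace

    from .solver import solve

    if noise_sd < 0:
        raise ConfigurationError("noise_sd must be >= 0")
    scn = replace(scenario, probes=(tuple(probe),))
    res = solve(scn)
    sim = res.probes[0]
    return [synth_trace_from_probe(sim, noise_sd, seed + i) for i in range(n_replicates)]


def scan_to_frame(scan: ProfilerScan) -> pd.DataFrame:
    """Long-format table (x_mm, y_mm, intensity) for plain-text export."""
    X, Y = np.meshgrid(scan.x, scan.y, indexing="ij")
    return pd.DataFrame({
        "x_mm": X.ravel() * 1e3, "y_mm": Y.ravel() * 1e3,
        "intensity_W_per_m2": scan.intensity.ravel(),
    })


def trace_to_frame(trace: SyntheticTrace) -> pd.DataFrame:
    return pd.DataFrame({"time_s": trace.times, "temperature_C": trace.temperatures})
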