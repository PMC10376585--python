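"""Structured 3-D simulation grid.

Lateral spacing is uniform (dx, dy); vertical spacing may be graded (finer
cells near the irradiated surface where the Beer-Lambert source decays over
~1 mm).  Cell counts are kept odd laterally so the beam axis (0, 0) falls on
a cell-centre column.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import ConfigurationError


@dataclass(frozen=True)
class SimulationGrid:
    """Cell-centred structured grid.

    x/y cell centres are symmetric about 0; z_edges[0] = 0 is the tissue
    surface and z increases downward.  ``dz`` may be a scalar (uniform) or a
    per-cell array of spacings.
    """

    nx: int
    ny: int
    dx: float
    dy: float
    z_edges: np.ndarray  # shape (nz+1,), z_edges[0] == 0

    def __post_init__(self):
        z = np.asarray(self.z_edges, dtype=float)
        object.__setattr__(self, "z_edges", z)
        if self.nx < 3 or self.ny < 3 or self.nz < 3:
            raise ConfigurationError("grid needs at least 3 cells per axis")
        if not (self.dx > 0 and self.dy > 0):
            raise ConfigurationError("lateral spacings must be positive")
        if abs(z[0]) > 1e-15 or np.any(np.diff(z) <= 0):
            raise ConfigurationError("z_edges must start at 0 and increase")

    # -- constructors -------------------------------------------------------

    @staticmethod
    def regular(nx: int, ny: int, nz: int, dx: float, dy: float, dz) -> "SimulationGrid":
        dz = np.broadcast_to(np.asarray(dz, dtype=float), (nz,))
        z_edges = np.concatenate([[0.0], np.cumsum(dz)])
        return SimulationGrid(nx, ny, dx, dy, z_edges)

    @staticmethod
    def for_domain(lateral_extent: float, dx: float,
                   z_spec: list[tuple[float, float]]) -> "SimulationGrid":
        """Grid covering ``lateral_extent`` (m, centred on 0) laterally.

        ``z_spec`` is a list of (depth_limit, spacing) pairs: cells of the
        given spacing are laid down until the running depth reaches each
        limit, e.g. ``[(3e-3, 1e-4), (10e-3, 2.5e-4)]`` for 0.1 mm cells in
        the top 3 mm graded to 0.25 mm below.
        """
        n = int(round(lateral_extent / dx))
        if n % 2 == 0:
            n += 1  # odd count puts a cell centre on the beam axis
        edges = [0.0]
        for depth_limit, spacing in z_spec:
            while edges[-1] + spacing <= depth_limit + 1e-12:
                edges.append(edges[-1] + spacing)
        return SimulationGrid(n, n, dx, dx, np.array(edges))

    # -- derived geometry ----------------------------------------------------

    @property
    def nz(self) -> int:
        return len(self.z_edges) - 1

    @property
    def shape(self) -> tuple[int, int, int]:
        return (self.nx, self.ny, self.nz)

    @property
    def n_cells(self) -> int:
        return self.nx * self.ny * self.nz

    @property
    def dz(self) -> np.ndarray:
        return np.diff(self.z_edges)

    @property
    def x_centers(self) -> np.ndarray:
        return (np.arange(self.nx) - (self.nx - 1) / 2) * self.dx

    @property
    def y_centers(self) -> np.ndarray:
        return (np.arange(self.ny) - (self.ny - 1) / 2) * self.dy

    @property
    def z_centers(self) -> np.ndarray:
        return 0.5 * (self.z_edges[:-1] + self.z_edges[1:])

    @property
    def cell_volume(self) -> np.ndarray:
        """Per-z-cell volume profile (m^3), shape (nz,)."""
        return self.dx * self.dy * self.dz

    @property
    def lateral_extent(self) -> tuple[float, float]:
        return (self.nx * self.dx, self.ny * self.dy)

    @property
    def depth(self) -> float:
        return float(self.z_edges[-1])

    def refined(self, factor: float) -> "SimulationGrid":
        """New grid with all spacings divided by ``factor`` (same extents)."""
        nx = int(round(self.nx * factor))
        if nx % 2 == 0:
            nx += 1
        ny = int(round(self.ny * factor))
        if ny % 2 == 0:
            ny += 1
        dx = self.nx * self.dx / nx
        dy = self.ny * self.dy / ny
        # split each z cell into round(factor) subcells (>=1), preserving edges
        sub = max(int(round(factor)), 1)
        edges = [0.0]
        for z0, z1 in zip(self.z_edges[:-1], self.z_edges[1:]):
            for i in range(1, sub + 1):
                edges.append(z0 + (z1 - z0) * i / sub)
        return SimulationGrid(nx, ny, dx, dy, np.array(edges))


def default_skin_grid() -> SimulationGrid:
    """Production grid: ~40 mm lateral at 0.25 mm; 0.1 mm z-cells in the top
    3 mm graded to 0.25 mm below, 10 mm deep."""
    return SimulationGrid.for_domain(40e-3, 0.25e-3, [(3e-3, 0.1e-3), (10e-3, 0.25e-3)])


def preview_skin_grid(lateral_extent: float = 40e-3) -> SimulationGrid:
    """Coarsened preview grid (0.5 mm lateral; graded z: 0.1 mm in the top
    0.5 mm, 0.25 mm to 3 mm, 0.5 mm below).  Layer interfaces at 0.1 mm and
    2.0 mm depth coincide with cell faces."""
    return SimulationGrid.for_domain(
        lateral_extent, 0.5e-3, [(0.5e-3, 0.1e-3), (3e-3, 0.25e-3), (10e-3, 0.5e-3)]
    )


def fast_skin_grid(lateral_extent: float = 40e-3) -> SimulationGrid:
    """Very coarse sweep/preview grid (1 mm lateral, same graded z as
    :func:`preview_skin_grid`)."""
    return SimulationGrid.for_domain(
        lateral_extent, 1.0e-3, [(0.5e-3, 0.1e-3), (3e-3, 0.25e-3), (10e-3, 0.5e-3)]
    )


def phantom_grid(diameter: float = 40e-3, height: float = 9e-3,
                 dx: float = 0.5e-3) -> SimulationGrid:
    """Grid for the agar-phantom block (square footprint covering the probe
    region; graded z)."""
    return SimulationGrid.for_domain(
        diameter, dx, [(1e-3, 0.1e-3), (3e-3, 0.25e-3), (height, 0.5e-3)]
    )
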