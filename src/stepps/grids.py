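"""Grid geometry, dispersal kernels, and kernel weight matrices.

The spatial domain is a regular square lattice of grid cells on projected
planar coordinates in kilometres (8-km cells for calibration, 24-km cells for
prediction by default).  Pollen dispersal between cells is described by a
radially symmetric, spatially invariant kernel — either an inverse power-law
(long-tailed, the default) or a Gaussian — normalized to integrate to one over
the plane.  The weight matrix collects kernel densities between all cell
pairs, scaled by cell area; its per-focal-cell off-diagonal row sum ``C`` is
the scaling factor that turns the non-local pollen term into a proper
weighted average.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

__all__ = [
    "Grid",
    "KernelParams",
    "WeightMatrix",
    "build_grid",
    "pairwise_distance",
    "kernel_density",
    "weight_matrix",
]


@dataclass(frozen=True)
class Grid:
    """A regular square lattice of cells on planar km coordinates.

    Parameters
    ----------
    cell_centers : (n_cells, 2) array
        Planar (x, y) coordinates of cell midpoints, in km, row-major
        (x fastest).
    cell_size : float
        Side length of a square cell in km.
    """

    cell_centers: np.ndarray
    cell_size: float

    def __post_init__(self) -> None:
        centers = np.asarray(self.cell_centers, dtype=float)
        if centers.ndim != 2 or centers.shape[1] != 2:
            raise ValueError("cell_centers must be an (n, 2) array")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if len(np.unique(centers, axis=0)) != len(centers):
            raise ValueError("cell centers must be distinct")
        object.__setattr__(self, "cell_centers", centers)

    @property
    def n_cells(self) -> int:
        return len(self.cell_centers)

    @property
    def cell_area(self) -> float:
        return self.cell_size**2

    @property
    def shape(self) -> tuple[int, int]:
        """(ny, nx) lattice shape."""
        nx = len(np.unique(self.cell_centers[:, 0]))
        ny = len(np.unique(self.cell_centers[:, 1]))
        return ny, nx

    def cell_of(self, points: np.ndarray) -> np.ndarray:
        """Map point coordinates (km) to containing-cell indices.

        Sites are assigned to the nearest cell center; ties break to the
        lowest cell index (argmin convention).
        """
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        d = cdist(pts, self.cell_centers)
        return np.argmin(d, axis=1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cell_id": np.arange(self.n_cells),
                "x_km": self.cell_centers[:, 0],
                "y_km": self.cell_centers[:, 1],
            }
        )


@dataclass(frozen=True)
class KernelParams:
    """Dispersal-kernel parameters.

    ``a`` is the distance scale in km; ``b`` the dimensionless shape of the
    inverse power-law tail (must exceed 2 for a finite 2-D normalization).
    """

    family: Literal["inverse_power_law", "gaussian"] = "inverse_power_law"
    a: float = 100.0
    b: float = 4.0

    def __post_init__(self) -> None:
        if self.family not in ("inverse_power_law", "gaussian"):
            raise ValueError(f"unknown kernel family {self.family!r}")
        if self.a <= 0:
            raise ValueError("kernel scale a must be positive")
        if self.family == "inverse_power_law" and self.b <= 2:
            raise ValueError("inverse power-law shape b must exceed 2")


@dataclass
class WeightMatrix:
    """Kernel weights between all cell pairs and the domain-sum scaling C.

    ``W[i, j]`` is the kernel density at the distance between cells i and j
    times the cell area, for j != i; the diagonal is zero (the focal cell's
    own contribution is the *local* term, handled separately).  ``C[i]`` is
    the off-diagonal row sum for focal cell i, so that W[i, :] / C[i] is a
    proper weighting of non-local cells and edge cells are treated
    consistently with interior ones.
    """

    W: np.ndarray
    C: np.ndarray
    params: KernelParams = field(default_factory=KernelParams)

    @property
    def normalized(self) -> np.ndarray:
        """Row-normalized weights W[i, j] / C[i] (zero rows stay zero)."""
        C = np.where(self.C > 0, self.C, 1.0)
        return self.W / C[:, None]


def build_grid(extent: tuple[float, float], cell_size: float) -> Grid:
    """Build a regular square grid covering ``extent = (width, height)`` km.

    Cell centers sit at cell midpoints, ordered row-major (x varies fastest).
    Side lengths must be positive multiples of ``cell_size``.
    """
    width, height = float(extent[0]), float(extent[1])
    if cell_size <= 0:
        raise ValueError("cell_size must be positive")
    nx, ny = width / cell_size, height / cell_size
    if width <= 0 or height <= 0 or abs(nx - round(nx)) > 1e-9 or abs(ny - round(ny)) > 1e-9:
        raise ValueError(
            f"extent {extent} must have positive sides divisible by cell_size={cell_size}"
        )
    nx, ny = int(round(nx)), int(round(ny))
    xs = (np.arange(nx) + 0.5) * cell_size
    ys = (np.arange(ny) + 0.5) * cell_size
    xx, yy = np.meshgrid(xs, ys)
    centers = np.column_stack([xx.ravel(), yy.ravel()])
    return Grid(cell_centers=centers, cell_size=cell_size)


def pairwise_distance(points_a: np.ndarray, points_b: np.ndarray) -> np.ndarray:
    """Planar Euclidean distance matrix (km) between two point sets."""
    a = np.atleast_2d(np.asarray(points_a, dtype=float))
    b = np.atleast_2d(np.asarray(points_b, dtype=float))
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("coordinates must be finite")
    return cdist(a, b)


def kernel_density(d: np.ndarray, params: KernelParams) -> np.ndarray:
    """Dispersal-kernel density (km^-2) at distance ``d`` km.

    Inverse power-law:  k(d) = (b-2)(b-1) / (2 pi a^2) * (1 + d/a)^(-b)
    Gaussian:           k(d) = 1 / (pi a^2) * exp(-(d/a)^2)

    Both integrate to one over the plane.
    """
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("distances must be nonnegative")
    a = params.a
    if params.family == "inverse_power_law":
        b = params.b
        norm = (b - 2.0) * (b - 1.0) / (2.0 * np.pi * a**2)
        return norm * (1.0 + d / a) ** (-b)
    return np.exp(-((d / a) ** 2)) / (np.pi * a**2)


def weight_matrix(grid: Grid, params: KernelParams) -> WeightMatrix:
    """Kernel weight matrix over a grid, with per-focal-cell scaling C.

    W[i, j] = k(d(s_i, s_j)) * cell_area for j != i; W[i, i] = 0.
    C[i] = sum_j W[i, j].  A single-cell grid has no non-local term: W is all
    zero and C is zero (guarded downstream).
    """
    if grid.n_cells == 0:
        raise ValueError("grid must be non-empty")
    d = pairwise_distance(grid.cell_centers, grid.cell_centers)
    W = kernel_density(d, params) * grid.cell_area
    np.fill_diagonal(W, 0.0)
    C = W.sum(axis=1)
    return WeightMatrix(W=W, C=C, params=params)
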