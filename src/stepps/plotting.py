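"""Quick-look maps for composition fields, change classes, and ecotones.

Basic map export on the model's km grid (no geographic reprojection).
"""

from __future__ import annotations

import numpy as np

from .grids import Grid

__all__ = ["plot_composition_map", "plot_change_map", "plot_ecotone_lines"]


def _field_to_image(field: np.ndarray, grid: Grid) -> np.ndarray:
    ny, nx = grid.shape
    return np.asarray(field, dtype=float).reshape(ny, nx)


def _extent(grid: Grid):
    half = grid.cell_size / 2.0
    x, y = grid.cell_centers[:, 0], grid.cell_centers[:, 1]
    return [x.min() - half, x.max() + half, y.min() - half, y.max() + half]


def plot_composition_map(field: np.ndarray, grid: Grid, ax=None, title: str | None = None,
                         vmax: float | None = None):
    """Map one per-cell composition (or any scalar) field."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    im = ax.imshow(_field_to_image(field, grid), origin="lower",
                   extent=_extent(grid), vmin=0.0, vmax=vmax, cmap="viridis")
    ax.set_xlabel("x (km)")
    ax.set_ylabel("y (km)")
    if title:
        ax.set_title(title)
    ax.figure.colorbar(im, ax=ax, shrink=0.8)
    return ax


def plot_change_map(labels: np.ndarray, grid: Grid, ax=None, title: str | None = None):
    """Map community change classes (large_change / stable_all / neither)."""
    import matplotlib.pyplot as plt
    from matplotlib.colors import ListedColormap

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    codes = np.select(
        [labels == "large_change", labels == "stable_all"], [2, 1], default=0
    ).astype(float)
    cmap = ListedColormap(["#d9d9d9", "#2c7fb8", "#d95f0e"])
    ax.imshow(_field_to_image(codes, grid), origin="lower", extent=_extent(grid),
              cmap=cmap, vmin=0, vmax=2)
    ax.set_xlabel("x (km)")
    ax.set_ylabel("y (km)")
    if title:
        ax.set_title(title)
    return ax


def plot_ecotone_lines(lines: dict, ax=None, cmap_name: str = "plasma"):
    """Overlay per-time ecotone polylines, colored oldest to youngest."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    times = sorted(lines)
    cmap = plt.get_cmap(cmap_name)
    for i, t in enumerate(times):
        v = lines[t].vertices if hasattr(lines[t], "vertices") else np.asarray(lines[t])
        ax.plot(v[:, 0], v[:, 1], color=cmap(i / max(len(times) - 1, 1)),
                label=f"bin {t}")
    ax.set_xlabel("x (km)")
    ax.set_ylabel("y (km)")
    ax.legend(fontsize=7)
    return ax
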