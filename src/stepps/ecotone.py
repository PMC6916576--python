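"""Ecotone position and displacement from EOF analysis.

The composition fields are decomposed by empirical orthogonal functions
(EOFs) via singular value decomposition of the column-centered cell x
(taxon, time) data matrix.  The first spatial mode captures the dominant
north-south community gradient (the tension zone between mixed
conifer-hardwood and temperate hardwood forests); its zero-crossing line is
the ecotone proxy.  Per time bin, a score field is obtained by projecting
that bin's centered composition onto the first mode's taxon loadings for
that bin, so the zero line moves as composition changes; displacement is
measured in km along transects roughly perpendicular to the ecotone,
relative to its position at a reference time bin (350-250 YB1950 in the
published analysis).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import LineString, Point
from skimage import measure

from .grids import Grid

__all__ = [
    "EofResult",
    "EcotoneLine",
    "Transect",
    "eof_decompose",
    "pc1_score_fields",
    "extract_zero_line",
    "default_transects",
    "transect_displacement",
]


@dataclass
class EofResult:
    """SVD-based EOF decomposition of a cells x variables matrix."""

    modes: np.ndarray              # (cells, n_modes), orthonormal
    coefficients: np.ndarray       # (variables, n_modes) expansion coefficients
    singular_values: np.ndarray    # (n_modes,)
    variance_fraction: np.ndarray  # (n_modes,)
    column_means: np.ndarray       # (variables,)

    @property
    def n_modes(self) -> int:
        return self.modes.shape[1]


def eof_decompose(X: np.ndarray, center: bool = True,
                  north_y: np.ndarray | None = None) -> EofResult:
    """EOF decomposition by SVD of the (column-centered) data matrix.

    Sign convention: the first mode is oriented so its spatial mean over
    the northern half of the domain (cells with ``north_y`` above the
    median) is positive; without ``north_y`` the orientation makes the
    first mode's own mean positive.  Deterministic either way.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("need a 2-D matrix with at least two columns")
    if not np.isfinite(X).all():
        raise ValueError("data matrix must be finite")
    means = X.mean(axis=0) if center else np.zeros(X.shape[1])
    Xc = X - means
    if np.allclose(Xc, 0):
        raise ValueError("degenerate (zero-variance) data matrix")
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    var_frac = s**2 / np.sum(s**2)
    # orient mode 1 north-positive
    if north_y is not None:
        north = np.asarray(north_y) > np.median(north_y)
        flip = U[north, 0].mean() < 0
    else:
        flip = U[:, 0].mean() < 0
    if flip:
        U[:, 0] *= -1
        Vt[0] *= -1
    return EofResult(
        modes=U, coefficients=Vt.T * s[None, :], singular_values=s,
        variance_fraction=var_frac, column_means=means,
    )


def pc1_score_fields(r_mean: np.ndarray, grid: Grid) -> tuple[np.ndarray, EofResult]:
    """Per-time first-PC score fields of a composition stack.

    ``r_mean`` is (cells, T, K) posterior-mean composition.  The EOF is
    computed once on the cells x (taxon, time) stacked matrix; each time
    bin's centered composition is then projected onto the first mode's
    taxon loadings for that bin, giving a (cells, T) score field whose
    per-time zero contour is the ecotone line.
    """
    N, T, K = r_mean.shape
    X = r_mean.reshape(N, T * K)  # column (t, k) ordering: time-major
    eof = eof_decompose(X, center=True, north_y=grid.cell_centers[:, 1])
    v1 = eof.coefficients[:, 0].reshape(T, K)
    Xc = (X - eof.column_means).reshape(N, T, K)
    scores = np.empty((N, T))
    for t in range(T):
        w = v1[t]
        nrm = np.linalg.norm(w)
        scores[:, t] = Xc[:, t, :] @ (w / nrm if nrm > 0 else w)
    return scores, eof


@dataclass
class EcotoneLine:
    """Zero-crossing polyline of a first-PC field at one time bin."""

    vertices: np.ndarray   # (n, 2) km
    time_bin: int = 0

    @property
    def linestring(self) -> LineString:
        return LineString(self.vertices)


def extract_zero_line(field: np.ndarray, grid: Grid, time_bin: int = 0) -> EcotoneLine:
    """Marching-squares zero contour of a per-cell field; the longest
    connected component is retained as the ecotone.

    Vertices are linear interpolations between adjacent cell centers of
    opposite sign, in km.
    """
    f = np.asarray(field, dtype=float).ravel()
    if f.min() >= 0 or f.max() <= 0:
        raise ValueError("no ecotone in domain: field does not change sign")
    ny, nx = grid.shape
    img = f.reshape(ny, nx)
    contours = measure.find_contours(img, 0.0)
    if not contours:
        raise ValueError("no zero contour found")
    cs = grid.cell_size
    x0 = grid.cell_centers[:, 0].min()
    y0 = grid.cell_centers[:, 1].min()
    best, best_len = None, -1.0
    for c in contours:
        xy = np.column_stack([x0 + c[:, 1] * cs, y0 + c[:, 0] * cs])
        if len(xy) < 2:
            continue
        length = np.sum(np.hypot(*np.diff(xy, axis=0).T))
        if length > best_len:
            best, best_len = xy, length
    if best is None:
        raise ValueError("no zero contour with positive length")
    return EcotoneLine(vertices=best, time_bin=time_bin)


@dataclass
class Transect:
    """A straight transect: anchor point, unit direction, and length (km)."""

    anchor: np.ndarray
    direction: np.ndarray
    length: float

    def __post_init__(self) -> None:
        d = np.asarray(self.direction, dtype=float)
        n = np.linalg.norm(d)
        if n == 0:
            raise ValueError("direction must be nonzero")
        self.direction = d / n
        self.anchor = np.asarray(self.anchor, dtype=float)

    @property
    def segment(self) -> LineString:
        h = 0.5 * self.length * self.direction
        return LineString([self.anchor - h, self.anchor + h])


def default_transects(reference: EcotoneLine, n: int = 10, length: float = 200.0,
                      window: int = 5) -> list[Transect]:
    """Equally spaced transects perpendicular to the reference-time line.

    Normals are averaged over a ``window``-vertex neighborhood to damp
    contour noise.
    """
    v = reference.vertices
    seg = np.diff(v, axis=0)
    arclen = np.concatenate([[0.0], np.cumsum(np.hypot(*seg.T))])
    targets = np.linspace(0, arclen[-1], n + 2)[1:-1]
    transects = []
    half = window // 2
    for s in targets:
        i = int(np.searchsorted(arclen, s))
        i = min(max(i, 1), len(v) - 1)
        lo, hi = max(0, i - half), min(len(v) - 1, i + half)
        tangent = v[hi] - v[lo]
        tangent = tangent / (np.linalg.norm(tangent) or 1.0)
        normal = np.array([-tangent[1], tangent[0]])
        anchor = v[i]
        transects.append(Transect(anchor=anchor, direction=normal, length=length))
    return transects


def transect_displacement(
    lines: dict[int, EcotoneLine],
    transects: list[Transect],
    reference_time: int,
) -> pd.DataFrame:
    """Signed km of ecotone movement along each transect, per time bin,
    relative to the reference-time intersection.

    Multiple intersections resolve to the one nearest the anchor; a missing
    intersection yields NaN.
    """
    if reference_time not in lines:
        raise ValueError("reference time has no ecotone line")

    def _param(tr: Transect, line: EcotoneLine) -> float:
        inter = tr.segment.intersection(line.linestring)
        if inter.is_empty:
            return np.nan
        pts: list[Point] = []
        if inter.geom_type == "Point":
            pts = [inter]
        elif hasattr(inter, "geoms"):
            for gobj in inter.geoms:
                pts.extend([Point(c) for c in gobj.coords] if gobj.geom_type != "Point" else [gobj])
        else:
            pts = [Point(c) for c in inter.coords]
        anchor = Point(tr.anchor)
        p = min(pts, key=lambda q: q.distance(anchor))
        return float((np.array([p.x, p.y]) - tr.anchor) @ tr.direction)

    rows = []
    ref_params = [_param(tr, lines[reference_time]) for tr in transects]
    for t, line in sorted(lines.items()):
        for j, tr in enumerate(transects):
            p = _param(tr, line)
            rows.append({
                "transect_id": j,
                "time_bin": t,
                "displacement_km": p - ref_params[j],
            })
    return pd.DataFrame(rows)
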