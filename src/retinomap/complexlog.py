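"""Analytic complex-logarithmic retino-cortical transform.

The transform ``u + iv = log(x + iy + a)`` sends a visual-field point at
eccentricity r and meridional angle theta to cortical coordinates in
which eccentricity runs along u (nasotemporal) and meridional angle along
v (dorsoventral).  The image of the vertical meridian (the retinal line
x = 0) is the curve ``u = log(a / cos v)``; it bounds the cortical sheet
on its foveal side and is used both as the training-time boundary
constraint of the network models and as the analytic ground truth they
are validated against.  Only the right hemifield (x >= 0), i.e. one
hemisphere's V1, is modeled.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from retinomap.stimuli import StimulusImage, pixels_per_degree

__all__ = [
    "RetinalPoint",
    "CorticalPoint",
    "MapParams",
    "BoundaryMask",
    "SPECIES_PRESETS",
    "forward_map",
    "forward_map_xy",
    "boundary_u",
    "default_v_range",
    "default_u_range",
    "make_boundary_mask",
    "transform_image",
]

#: Species constants of the map parameter ``a`` (boundary-shape presets).
SPECIES_PRESETS = {"squirrel-monkey": 1.0, "owl-monkey": 2.5, "cat": 4.0}


@dataclass(frozen=True)
class RetinalPoint:
    """A visual-field point in Cartesian degrees (x, y)."""

    x: float
    y: float

    @property
    def r(self) -> float:
        """Eccentricity in degrees."""
        return math.hypot(self.x, self.y)

    @property
    def theta(self) -> float:
        """Meridional angle in radians."""
        return math.atan2(self.y, self.x)


@dataclass(frozen=True)
class CorticalPoint:
    """A point in dimensionless log-map cortical coordinates (u, v)."""

    u: float
    v: float


@dataclass(frozen=True)
class MapParams:
    """Parameters of the complex-log transform."""

    a: float = 1.0
    eccentricity_max: float = 4.0

    def __post_init__(self) -> None:
        if self.a <= 0:
            raise ValueError("a must be > 0")
        if self.eccentricity_max <= 0:
            raise ValueError("eccentricity_max must be > 0")


def forward_map(p: RetinalPoint, params: MapParams) -> CorticalPoint:
    """Map a retinal point through ``u + iv = log(x + iy + a)``.

    v is the principal argument in (-pi, pi].  Raises at the singular
    point z = 0.
    """
    zx = p.x + params.a
    zy = p.y
    if zx == 0 and zy == 0:
        raise ValueError("singular point: x + a and y are both zero")
    return CorticalPoint(u=0.5 * math.log(zx * zx + zy * zy), v=math.atan2(zy, zx))


def forward_map_xy(
    x: np.ndarray, y: np.ndarray, params: MapParams
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized :func:`forward_map` over coordinate arrays."""
    zx = np.asarray(x, dtype=float) + params.a
    zy = np.asarray(y, dtype=float)
    mag2 = zx * zx + zy * zy
    if np.any(mag2 == 0):
        raise ValueError("singular point: x + a and y are both zero")
    return 0.5 * np.log(mag2), np.arctan2(zy, zx)


def boundary_u(v: np.ndarray | float, params: MapParams) -> np.ndarray | float:
    """u-coordinate of the vertical-meridian image at dorsoventral
    coordinate v: ``u = log(a / cos v)``, defined for |v| < pi/2.

    Equals ``forward_map`` of the retinal point (0, a * tan(v)).
    """
    varr = np.asarray(v, dtype=float)
    if np.any(np.abs(varr) >= math.pi / 2):
        raise ValueError("boundary_u requires |v| < pi/2")
    out = np.log(params.a / np.cos(varr))
    return float(out) if np.isscalar(v) else out


def default_v_range(params: MapParams) -> tuple[float, float]:
    """Dorsoventral extent of the cortical window: the image of the
    vertical meridian out to the maximum eccentricity, i.e.
    v = +/- atan(ecc_max / a) (clipped inside the tan singularity)."""
    vmax = min(math.atan(params.eccentricity_max / params.a), 1.37)
    return (-vmax, vmax)


def default_u_range(params: MapParams) -> tuple[float, float]:
    """Nasotemporal extent: from the foveal apex u = log(a) to the image
    of the maximum eccentricity on the horizontal meridian,
    u = log(a + ecc_max)."""
    return (math.log(params.a), math.log(params.a + params.eccentricity_max))


@dataclass(frozen=True)
class BoundaryMask:
    """Boolean field over a cortical grid marking neurons inside the
    complex-log boundary, together with the affine (u, v) window that
    places the curve on the grid.

    Rows map to v (top row = v_max, i.e. v increases upward) and columns
    map to u (left column = u_min).
    """

    mask: np.ndarray
    params: MapParams
    u_range: tuple[float, float]
    v_range: tuple[float, float]

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape

    @property
    def inside_count(self) -> int:
        return int(np.count_nonzero(self.mask))

    def grid_uv(self) -> tuple[np.ndarray, np.ndarray]:
        """(u, v) coordinates of every grid cell."""
        h, w = self.mask.shape
        u = np.linspace(self.u_range[0], self.u_range[1], w)
        v = np.linspace(self.v_range[1], self.v_range[0], h)
        return np.broadcast_to(u[None, :], (h, w)), np.broadcast_to(v[:, None], (h, w))

    def uv_to_cell(self, u: np.ndarray, v: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Nearest grid cell of (u, v) points (rows/cols may fall outside)."""
        h, w = self.mask.shape
        u0, u1 = self.u_range
        v0, v1 = self.v_range
        col = np.rint((np.asarray(u) - u0) / (u1 - u0) * (w - 1)).astype(int)
        row = np.rint((v1 - np.asarray(v)) / (v1 - v0) * (h - 1)).astype(int)
        return row, col

    def apex(self) -> tuple[int, int]:
        """Grid position of the foveal apex: the middle in-mask row of the
        leftmost column containing any in-mask cell."""
        cols = np.flatnonzero(self.mask.any(axis=0))
        if cols.size == 0:
            raise ValueError("empty mask")
        col = int(cols[0])
        rows = np.flatnonzero(self.mask[:, col])
        return int(rows[(rows.size - 1) // 2]), col

    def save_csv(self, path: str | Path) -> None:
        np.savetxt(Path(path), self.mask.astype(int), fmt="%d", delimiter=",")

    def save_png(self, path: str | Path) -> None:
        from PIL import Image

        Image.fromarray((self.mask * 255).astype(np.uint8), mode="L").save(Path(path))


def all_true_mask(grid: tuple[int, int], params: MapParams | None = None) -> BoundaryMask:
    """Unconstrained sheet: every neuron available (no-boundary control)."""
    params = params or MapParams()
    return BoundaryMask(
        mask=np.ones(grid, dtype=bool),
        params=params,
        u_range=default_u_range(params),
        v_range=default_v_range(params),
    )


def make_boundary_mask(
    grid: tuple[int, int],
    params: MapParams,
    u_range: tuple[float, float] | None = None,
    v_range: tuple[float, float] | None = None,
) -> BoundaryMask:
    """Rasterize the boundary curve onto a cortical grid.

    Cell (i, j) is inside iff its (u, v) coordinates satisfy
    ``boundary_u(v) <= u <= u_max``.  Raises if no cell is inside.
    """
    u_range = u_range or default_u_range(params)
    v_range = v_range or default_v_range(params)
    if not (-math.pi / 2 < v_range[0] < v_range[1] < math.pi / 2):
        raise ValueError("v_range must lie inside (-pi/2, pi/2)")
    h, w = grid
    u = np.linspace(u_range[0], u_range[1], w)
    v = np.linspace(v_range[1], v_range[0], h)
    bu = boundary_u(v, params)
    mask = (u[None, :] >= bu[:, None]) & (u[None, :] <= u_range[1])
    if not mask.any():
        raise ValueError("boundary mask is empty for the given ranges")
    return BoundaryMask(mask=mask, params=params, u_range=u_range, v_range=v_range)


def transform_image(
    img: StimulusImage,
    params: MapParams,
    out_grid: tuple[int, int],
    u_range: tuple[float, float] | None = None,
    v_range: tuple[float, float] | None = None,
    supersample: int = 4,
) -> StimulusImage:
    """Forward-scatter an image through the complex-log map.

    Retinal pixel coordinates are converted to degrees with the stimulus
    convention (grid half-width = eccentricity_max).  An output pixel is
    active iff some active right-hemifield retinal pixel maps into it
    under :func:`forward_map` followed by the same (u, v) -> grid affine
    map used by :func:`make_boundary_mask`.  Each active pixel is treated
    as a ``supersample x supersample`` patch of sub-pixel points so that
    filled retinal regions map to filled cortical regions (the map
    expands area strongly near the fovea).  Left-hemifield pixels are
    ignored with a warning.
    """
    u_range = u_range or default_u_range(params)
    v_range = v_range or default_v_range(params)
    if supersample < 1:
        raise ValueError("supersample must be >= 1")
    h, w = img.shape
    ppd = pixels_per_degree(w, params.eccentricity_max)
    rows, cols = np.nonzero(img.pixels)
    x_px = cols - (w - 1) / 2.0
    y_px = (h - 1) / 2.0 - rows
    keep = x_px >= 0
    if np.any(~keep):
        warnings.warn(
            f"{int(np.count_nonzero(~keep))} active left-hemifield pixels ignored",
            stacklevel=2,
        )
    out = np.zeros(out_grid)
    if not np.any(keep):
        return StimulusImage(out)
    x_px, y_px = x_px[keep], y_px[keep]
    if supersample > 1:
        off = (np.arange(supersample) + 0.5) / supersample - 0.5
        ox, oy = np.meshgrid(off, off)
        x_px = (x_px[:, None] + ox.ravel()[None, :]).ravel()
        y_px = (y_px[:, None] + oy.ravel()[None, :]).ravel()
        inside = x_px >= 0
        x_px, y_px = x_px[inside], y_px[inside]
    u, v = forward_map_xy(x_px / ppd, y_px / ppd, params)
    holder = BoundaryMask(np.ones(out_grid, dtype=bool), params, u_range, v_range)
    row, col = holder.uv_to_cell(u, v)
    ok = (row >= 0) & (row < out_grid[0]) & (col >= 0) & (col < out_grid[1])
    out[row[ok], col[ok]] = 1.0
    return StimulusImage(out)
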