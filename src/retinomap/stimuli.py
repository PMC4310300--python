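"""Synthesis of training and probe stimuli.

All model inputs are generated here: filled rectangular bars at a set of
rotations and dilations, circular rings, single-point probes, and discs
carrying a circular "lesion" (a zeroed region).  Rasterization is binary
and deterministic: a pixel is active iff its *center* lies inside the
analytic shape.  Coordinates use pixel centers with the origin at the
image center, x rightward and y upward.
"""

from __future__ import annotations

import csv
import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "StimulusImage",
    "BarSpec",
    "LesionSpec",
    "pixel_coords",
    "pixels_per_degree",
    "make_bar",
    "bar_lengths",
    "enumerate_bar_set",
    "make_ring",
    "make_point",
    "make_lesioned_disc",
    "save_stimulus_set",
]

#: Half-width of the retina in visual degrees; the square input grid spans
#: the central ``2 * ECCENTRICITY_MAX`` degrees of visual space.
ECCENTRICITY_MAX = 4.0


@dataclass(frozen=True)
class StimulusImage:
    """A 2D grayscale image with intensities in [0, 1].

    The single input currency of every model in the package.
    """

    pixels: np.ndarray

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2:
            raise ValueError(f"stimulus must be 2D, got shape {px.shape}")
        if px.size and (px.min() < 0 or px.max() > 1):
            raise ValueError("stimulus intensities must lie in [0, 1]")
        object.__setattr__(self, "pixels", px)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def as_vector(self) -> np.ndarray:
        return self.pixels.ravel()

    def active_count(self) -> int:
        return int(np.count_nonzero(self.pixels))

    def save_png(self, path: str | Path) -> None:
        from PIL import Image

        arr = np.clip(np.rint(self.pixels * 255), 0, 255).astype(np.uint8)
        Image.fromarray(arr, mode="L").save(Path(path))

    @classmethod
    def load_png(cls, path: str | Path) -> "StimulusImage":
        from PIL import Image

        arr = np.asarray(Image.open(Path(path)).convert("L"), dtype=float) / 255.0
        return cls(arr)


@dataclass(frozen=True)
class BarSpec:
    """A filled rectangular bar: rotation about the image center plus a
    dilation level indexing its length."""

    rotation_deg: float
    dilation_level: int
    length: float
    aspect_ratio: float = 0.1

    def __post_init__(self) -> None:
        if self.aspect_ratio <= 0:
            raise ValueError("aspect_ratio must be > 0")
        if not (0 <= self.rotation_deg < 180):
            raise ValueError("rotation_deg must lie in [0, 180)")
        if self.length <= 0:
            raise ValueError("length must be > 0")
        # width must rasterize to at least one pixel
        if math.floor(self.width + 0.5) < 1:
            raise ValueError(
                f"bar width {self.width:.3f}px (length {self.length} x aspect "
                f"{self.aspect_ratio}) rounds below 1 pixel"
            )

    @property
    def width(self) -> float:
        return self.aspect_ratio * self.length


@dataclass(frozen=True)
class LesionSpec:
    """A filled disc with a circular zeroed (lesioned) region inside it.

    Centers are given in pixel-center coordinates (origin at image center).
    """

    disc_center: tuple[float, float] = (0.0, 0.0)
    disc_radius: float = 8.0
    lesion_center: tuple[float, float] = (0.0, 0.0)
    lesion_radius: float = 2.0

    def __post_init__(self) -> None:
        if self.disc_radius <= 0:
            raise ValueError("disc_radius must be > 0")
        if self.lesion_radius < 0:
            raise ValueError("lesion_radius must be >= 0")
        if self.lesion_radius >= self.disc_radius:
            raise ValueError("lesion_radius must be < disc_radius")
        sep = math.hypot(
            self.lesion_center[0] - self.disc_center[0],
            self.lesion_center[1] - self.disc_center[1],
        )
        if sep + self.lesion_radius > self.disc_radius:
            raise ValueError("lesion region must lie inside the disc")


def pixel_coords(grid: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    """Return (x, y) coordinate arrays of pixel centers for an (h, w) grid.

    Origin at the image center, x rightward, y upward.
    """
    h, w = grid
    cols = np.arange(w) - (w - 1) / 2.0
    rows = (h - 1) / 2.0 - np.arange(h)
    x = np.broadcast_to(cols[None, :], (h, w))
    y = np.broadcast_to(rows[:, None], (h, w))
    return x, y


def pixels_per_degree(grid_width: int, eccentricity_max: float = ECCENTRICITY_MAX) -> float:
    """Pixels per visual degree when the grid half-width spans the
    configured maximum eccentricity."""
    return ((grid_width - 1) / 2.0) / eccentricity_max


def make_bar(grid: tuple[int, int], spec: BarSpec) -> StimulusImage:
    """Rasterize a filled rectangle centered at the image center and rotated
    by ``spec.rotation_deg`` about it.

    A pixel is active iff its center lies inside the rotated rectangle
    (no anti-aliasing).  Raises if the bar cannot fit the grid at every
    rotation of its dilation level.
    """
    h, w = grid
    half_diag = math.hypot(spec.length, spec.width) / 2.0
    half_extent = (min(h, w) - 1) / 2.0
    if half_diag > half_extent + 0.5:
        raise ValueError(
            f"bar of dilation level {spec.dilation_level} (length "
            f"{spec.length:.2f}px) exceeds the {h}x{w} grid at some rotation"
        )
    x, y = pixel_coords(grid)
    th = math.radians(spec.rotation_deg)
    c, s = math.cos(th), math.sin(th)
    # snap to exact axis alignment so boundary pixels are not lost to
    # floating-point residue at multiples of 90 degrees
    if abs(c) < 1e-12:
        c = 0.0
    if abs(s) < 1e-12:
        s = 0.0
    # rotate pixel coords into the bar frame; bar at 0 deg lies along x
    along = x * c + y * s
    across = -x * s + y * c
    inside = (np.abs(along) <= spec.length / 2.0) & (np.abs(across) <= spec.width / 2.0)
    return StimulusImage(inside.astype(float))


def bar_lengths(
    grid: tuple[int, int],
    n_dilations: int = 16,
    aspect: float = 0.1,
    spacing: Literal["linear", "exponential"] = "linear",
    min_length: float | None = None,
    max_length: float | None = None,
) -> np.ndarray:
    """Lengths of the dilation levels.

    Defaults: the smallest bar is the shortest one whose width still
    rounds to >= 1 pixel; the largest is 0.95x the grid width so every
    rotation fits.  ``linear`` spacing is used to train the models;
    ``exponential`` spacing (same endpoints) defines the inputs of the
    complex-log reference.
    """
    h, w = grid
    if min_length is None:
        min_length = math.ceil(0.5 / aspect)
    if max_length is None:
        max_length = 0.95 * min(h, w)
    if n_dilations == 1:
        return np.asarray([max_length], dtype=float)
    if spacing == "linear":
        return np.linspace(min_length, max_length, n_dilations)
    if spacing == "exponential":
        return np.geomspace(min_length, max_length, n_dilations)
    raise ValueError(f"unknown spacing {spacing!r}")


def enumerate_bar_set(
    grid: tuple[int, int],
    n_rotations: int = 9,
    n_dilations: int = 16,
    aspect: float = 0.1,
    spacing: Literal["linear", "exponential"] = "linear",
    min_length: float | None = None,
    max_length: float | None = None,
) -> tuple[list[StimulusImage], list[BarSpec]]:
    """Enumerate the full rotation x dilation bar set.

    Rotations step over the half circle (180 deg identified with 0 deg);
    the defaults give the 9 x 16 = 144 configurations of the basic SOM
    training set.  Returns the images and their specs in
    rotation-major order.  Emits a warning for any two specs that
    rasterize to identical images.
    """
    if n_rotations < 1 or n_dilations < 1:
        raise ValueError("n_rotations and n_dilations must be >= 1")
    rotations = np.arange(n_rotations) * (180.0 / n_rotations)
    lengths = bar_lengths(grid, n_dilations, aspect, spacing, min_length, max_length)
    images: list[StimulusImage] = []
    specs: list[BarSpec] = []
    seen: dict[bytes, BarSpec] = {}
    for rot in rotations:
        for level, length in enumerate(lengths, start=1):
            spec = BarSpec(rotation_deg=float(rot), dilation_level=level,
                           length=float(length), aspect_ratio=aspect)
            img = make_bar(grid, spec)
            key = img.pixels.tobytes()
            if key in seen:
                warnings.warn(
                    f"bar specs {seen[key]} and {spec} rasterize identically",
                    stacklevel=2,
                )
            else:
                seen[key] = spec
            images.append(img)
            specs.append(spec)
    return images, specs


def make_ring(grid: tuple[int, int], radius: float, thickness: float) -> StimulusImage:
    """Binary annulus centered at the image center: active iff the pixel
    center's distance to the center is within thickness/2 of ``radius``."""
    if radius <= 0:
        raise ValueError("radius must be > 0")
    h, w = grid
    if radius + thickness / 2.0 > (min(h, w) - 1) / 2.0 + 0.5:
        raise ValueError("ring does not fit the grid")
    x, y = pixel_coords(grid)
    d = np.hypot(x, y)
    inside = np.abs(d - radius) <= thickness / 2.0
    return StimulusImage(inside.astype(float))


def make_point(grid: tuple[int, int], x: float, y: float) -> StimulusImage:
    """Unit point probe at (x, y) in pixel-center coordinates.

    On-center requests activate exactly one pixel.  A request falling
    exactly between four pixel centers activates the 2x2 block; a
    half-integer offset along a single axis ties toward the lower row,
    then the lower column.
    """
    h, w = grid
    row_f = (h - 1) / 2.0 - y
    col_f = (w - 1) / 2.0 + x
    if not (-0.5 <= row_f <= h - 0.5 and -0.5 <= col_f <= w - 0.5):
        raise ValueError(f"point ({x}, {y}) lies outside the {h}x{w} grid")

    def _indices(f: float, n: int) -> list[int]:
        lo = math.floor(f)
        if abs(f - lo - 0.5) < 1e-12 and 0 <= lo and lo + 1 < n:
            return [lo, lo + 1]
        return [int(np.clip(round(f), 0, n - 1))]

    rows = _indices(row_f, h)
    cols = _indices(col_f, w)
    if len(rows) != len(cols):
        # half-integer along one axis only: tie toward the lower index
        if len(rows) == 2:
            rows = rows[:1]
        if len(cols) == 2:
            cols = cols[:1]
    px = np.zeros((h, w))
    for i in rows:
        for j in cols:
            px[i, j] = 1.0
    return StimulusImage(px)


def make_lesioned_disc(grid: tuple[int, int], spec: LesionSpec) -> StimulusImage:
    """Filled disc of 1s with the lesion region forced to 0."""
    x, y = pixel_coords(grid)
    d_disc = np.hypot(x - spec.disc_center[0], y - spec.disc_center[1])
    px = d_disc <= spec.disc_radius
    if spec.lesion_radius > 0:
        d_les = np.hypot(x - spec.lesion_center[0], y - spec.lesion_center[1])
        px = px & ~(d_les <= spec.lesion_radius)
    return StimulusImage(px.astype(float))


def save_stimulus_set(
    images: Sequence[StimulusImage],
    specs: Sequence[BarSpec],
    out_dir: str | Path,
) -> Path:
    """Write a bar set as PNGs plus a CSV manifest; returns the manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = out / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["filename", "rotation_deg", "dilation_level", "length_px"])
        for i, (img, spec) in enumerate(zip(images, specs)):
            name = f"bar_{i:04d}.png"
            img.save_png(out / name)
            writer.writerow([name, spec.rotation_deg, spec.dilation_level,
                             f"{spec.length:.4f}"])
    return manifest
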