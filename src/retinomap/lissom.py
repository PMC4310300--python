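"""LISSOM cortical sheet.

Each cortical neuron carries three projection fields: afferent weights
from the retina plus lateral excitatory and inhibitory weights from other
cortical neurons.  Activity is computed by a piecewise-linear sigmoid of
the afferent drive and then settles for several steps under the lateral
contributions; all three weight fields learn with a divisively normalized
Hebbian rule.  Projection radii start small and grow to their bounds over
the first part of training, the sheet can be restricted by a complex-log
boundary mask, and a rough initial retinotopy seeds the afferent centers.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from retinomap import complexlog
from retinomap.complexlog import BoundaryMask, MapParams
from retinomap.stimuli import LesionSpec, StimulusImage, pixel_coords, pixels_per_degree

__all__ = [
    "LissomParams",
    "ProjectionField",
    "LissomState",
    "sigmoid_g",
    "sheet_to_grid",
    "grid_to_cortex_mm",
    "count_excitatory_neighbors",
    "init_state",
    "initial_response",
    "settle",
    "hebbian_update",
    "grow_radii",
    "train_step",
    "train_lissom",
    "apply_retinal_lesion",
]


@dataclass(frozen=True)
class LissomParams:
    """Model parameters; defaults follow the reference simulation.

    Radii (``rad_A``, ``rad_E``, ``rad_I``) are maximum radii in
    normalized sheet units (source sheet width = 1); ``rad_A`` is a
    fraction of the retina width, the lateral radii are fractions of the
    cortex width.
    """

    p: float = 1.5                 # afferent scaling factor
    q: float = 1.1                 # excitatory scaling factor
    r_scale: float = 1.1           # inhibitory scaling factor
    eta_A: float = 0.3
    eta_E: float = 0.25
    eta_I_initial: float = 0.25
    eta_I_late: float = 0.5
    eta_I_switch_iter: int = 500
    rad_A: float = 1.0
    rad_E: float = 0.03
    rad_I: float = 0.55
    alpha_l: float = 0.083
    alpha_u: float = 0.083 + 0.55
    settle_steps: int = 9
    settle_tol: float = 1e-4
    retina_shape: tuple[int, int] = (25, 25)
    cortex_shape: tuple[int, int] = (48, 48)
    #: one hemisphere's V1 receives afferents from one hemifield only;
    #: restrict afferent supports to retinal pixels with x >= 0
    afferent_hemifield: bool = True
    #: interpret learning rates per connection (divided by the neuron's
    #: support size), making them independent of projection-field area
    eta_per_connection: bool = True
    #: calibration of the afferent rate into per-connection units; the
    #: retina-sourced projection needs a slower effective rate than the
    #: cortex-sourced laterals for the seeded retinotopy to refine
    #: rather than wash out over the 900-iteration schedule
    eta_A_calibration: float = 0.1
    #: scale of the random weights given to newly recruited connections,
    #: relative to the mean existing weight of the neuron
    recruit_weight_scale: float = 0.001
    # initial radii (grid units) and linear growth horizon
    init_rad_A_grid: float = 4.0
    init_rad_frac: float = 0.25    # lateral radii start at bound * this
    growth_end_iter: int = 200
    eccentricity_max: float = 4.0
    mm_per_grid_unit: float = 0.375
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not (self.alpha_l < self.alpha_u):
            raise ValueError("alpha_l must be < alpha_u")
        for name in ("rad_A", "rad_E", "rad_I"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    @property
    def rad_A_grid(self) -> float:
        return sheet_to_grid(self.rad_A, self.retina_shape[1])

    @property
    def rad_E_grid(self) -> float:
        return sheet_to_grid(self.rad_E, self.cortex_shape[1])

    @property
    def rad_I_grid(self) -> float:
        return sheet_to_grid(self.rad_I, self.cortex_shape[1])

    def eta_I_at(self, iteration: int) -> float:
        return self.eta_I_initial if iteration < self.eta_I_switch_iter else self.eta_I_late


def sigmoid_g(s: np.ndarray | float, alpha_l: float, alpha_u: float) -> np.ndarray | float:
    """Piecewise-linear sigmoid: 0 below ``alpha_l``, 1 above ``alpha_u``,
    linear in between."""
    if not alpha_l < alpha_u:
        raise ValueError("alpha_l must be < alpha_u")
    out = np.clip((np.asarray(s, dtype=float) - alpha_l) / (alpha_u - alpha_l), 0.0, 1.0)
    return float(out) if np.isscalar(s) else out


def sheet_to_grid(radius_sheet: float, grid_width: int) -> float:
    """Convert a radius in normalized sheet units to source-grid units."""
    return radius_sheet * grid_width


def grid_to_cortex_mm(radius_grid: float, mm_per_grid_unit: float = 0.375) -> float:
    """Convert a cortical radius in grid units to millimetres."""
    return radius_grid * mm_per_grid_unit


def count_excitatory_neighbors(rad_E_grid: float) -> int:
    """Number of integer lattice offsets (di, dj) != (0, 0) within
    Euclidean distance ``rad_E_grid``."""
    if rad_E_grid <= 0:
        raise ValueError("rad_E_grid must be > 0")
    m = math.ceil(rad_E_grid)
    count = 0
    for di in range(-m, m + 1):
        for dj in range(-m, m + 1):
            if (di, dj) != (0, 0) and di * di + dj * dj <= rad_E_grid * rad_E_grid:
                count += 1
    return count


@dataclass
class ProjectionField:
    """Weights of one projection type for the whole sheet.

    ``weights[i, j]`` is the connection from source unit j (flattened
    source grid) to cortical neuron i; each in-mask neuron's weights are
    nonnegative, supported only within ``radius`` of its center, and sum
    to 1.
    """

    name: str
    weights: np.ndarray            # (n_post, n_pre) float64
    support: np.ndarray            # (n_post, n_pre) bool
    dist: np.ndarray               # (n_post, n_pre) float32, center-to-source
    centers: np.ndarray            # (n_post, 2) float, (row, col) in source grid
    radius: float
    bound: float
    init_radius: float
    support_radius: float          # radius at which support was last rebuilt
    _support_counts: np.ndarray | None = None

    def row_sums(self) -> np.ndarray:
        return self.weights.sum(axis=1)

    def support_counts(self) -> np.ndarray:
        """Per-neuron support size, cached between support rebuilds."""
        if self._support_counts is None:
            self._support_counts = self.support.sum(axis=1)
        return self._support_counts


@dataclass
class LissomState:
    params: LissomParams
    mask: BoundaryMask
    afferent: ProjectionField
    excitatory: ProjectionField
    inhibitory: ProjectionField
    rng: np.random.Generator
    iteration: int = 0
    activity: np.ndarray | None = None       # last settled activity (flat)
    _lateral_cache: np.ndarray | None = None

    @property
    def in_mask(self) -> np.ndarray:
        return self.mask.mask.ravel()

    @property
    def n_cortex(self) -> int:
        return self.mask.mask.size

    def invalidate_laterals(self) -> None:
        self._lateral_cache = None

    def lateral_matrix(self) -> np.ndarray:
        """Combined lateral operator q*E - r*I, cached between updates."""
        if self._lateral_cache is None:
            self._lateral_cache = (
                self.params.q * self.excitatory.weights
                - self.params.r_scale * self.inhibitory.weights
            )
        return self._lateral_cache


def _initial_retinotopy(
    mask: BoundaryMask, retina_shape: tuple[int, int], ecc_max: float
) -> np.ndarray:
    """Rough polar retinotopy: a cortical neuron at local polar coordinates
    (rho, phi) about the foveal apex is assigned the retinal point at
    eccentricity ``rho / rho_max * ecc_max`` and meridional angle phi.

    Returns (n_cortex, 2) afferent centers as (row, col) retinal pixels.
    """
    hc, wc = mask.shape
    hr, wr = retina_shape
    apex_r, apex_c = mask.apex()
    rows, cols = np.mgrid[0:hc, 0:wc]
    dx = (cols - apex_c).astype(float)
    dy = (apex_r - rows).astype(float)      # y upward
    rho = np.hypot(dx, dy)
    rho_max = rho[mask.mask].max() if mask.mask.any() else rho.max()
    phi = np.arctan2(dy, dx)
    r_deg = rho / max(rho_max, 1e-12) * ecc_max
    x_deg = r_deg * np.cos(phi)
    y_deg = r_deg * np.sin(phi)
    ppd = pixels_per_degree(wr, ecc_max)
    c_col = (wr - 1) / 2.0 + x_deg * ppd
    c_row = (hr - 1) / 2.0 - y_deg * ppd
    centers = np.stack(
        [np.clip(c_row, 0, hr - 1).ravel(), np.clip(c_col, 0, wr - 1).ravel()], axis=1
    )
    return centers


def _source_grid_positions(shape: tuple[int, int]) -> np.ndarray:
    h, w = shape
    rows, cols = np.mgrid[0:h, 0:w]
    return np.stack([rows.ravel(), cols.ravel()], axis=1).astype(float)


def _make_field(
    name: str,
    centers: np.ndarray,
    source_shape: tuple[int, int],
    init_radius: float,
    bound: float,
    in_mask_rows: np.ndarray,
    source_in_mask: np.ndarray | None,
    rng: np.random.Generator,
    exclude_self: bool = False,
) -> ProjectionField:
    src = _source_grid_positions(source_shape)
    diff = centers[:, None, :] - src[None, :, :]
    dist = np.sqrt((diff * diff).sum(axis=2)).astype(np.float32)
    if exclude_self:
        # lateral fields couple distinct neurons: no autapses (otherwise
        # Hebbian self-correlation funnels all mass onto the diagonal)
        np.fill_diagonal(dist, np.inf)
    support = dist <= init_radius
    support &= in_mask_rows[:, None]
    if source_in_mask is not None:
        support &= source_in_mask[None, :]
    weights = np.where(support, rng.random(support.shape), 0.0)
    sums = weights.sum(axis=1, keepdims=True)
    np.divide(weights, sums, out=weights, where=sums > 0)
    return ProjectionField(
        name=name, weights=weights, support=support, dist=dist, centers=centers,
        radius=init_radius, bound=bound, init_radius=init_radius,
        support_radius=init_radius,
    )


def _afferent_source_mask(params: LissomParams) -> np.ndarray | None:
    """Flat retinal mask of allowed afferent sources (right hemifield,
    including the vertical meridian), or None when unrestricted."""
    if not params.afferent_hemifield:
        return None
    hr, wr = params.retina_shape
    cols = np.tile(np.arange(wr), hr)
    return cols >= (wr - 1) // 2


def init_state(
    params: LissomParams,
    mask: BoundaryMask | None = None,
    seed: int | None = None,
) -> LissomState:
    """Build a fresh sheet: afferent centers from the rough initial
    retinotopy, uniform-random normalized weights inside small initial
    radii, lateral centers at the neurons' own positions."""
    if mask is None:
        mask = complexlog.make_boundary_mask(
            params.cortex_shape, MapParams(a=1.0, eccentricity_max=params.eccentricity_max)
        )
    if mask.shape != tuple(params.cortex_shape):
        raise ValueError("mask shape does not match cortex_shape")
    if not mask.mask.any():
        raise ValueError("mask is empty")
    rng = np.random.default_rng(params.rng_seed if seed is None else seed)
    in_mask = mask.mask.ravel()

    aff_centers = _initial_retinotopy(mask, params.retina_shape, params.eccentricity_max)
    afferent = _make_field(
        "afferent", aff_centers, params.retina_shape,
        min(params.init_rad_A_grid, params.rad_A_grid), params.rad_A_grid,
        in_mask, _afferent_source_mask(params), rng,
    )
    cort_pos = _source_grid_positions(params.cortex_shape)
    excitatory = _make_field(
        "excitatory", cort_pos, params.cortex_shape,
        max(1.0, params.rad_E_grid * params.init_rad_frac), params.rad_E_grid,
        in_mask, in_mask, rng, exclude_self=True,
    )
    inhibitory = _make_field(
        "inhibitory", cort_pos, params.cortex_shape,
        params.rad_I_grid * params.init_rad_frac, params.rad_I_grid,
        in_mask, in_mask, rng, exclude_self=True,
    )
    return LissomState(
        params=params, mask=mask, afferent=afferent,
        excitatory=excitatory, inhibitory=inhibitory, rng=rng,
    )


def _as_flat_input(state: LissomState, x: StimulusImage | np.ndarray) -> np.ndarray:
    arr = x.pixels if isinstance(x, StimulusImage) else np.asarray(x, dtype=float)
    if arr.shape != tuple(state.params.retina_shape):
        raise ValueError(
            f"input shape {arr.shape} does not match retina {state.params.retina_shape}"
        )
    return arr.ravel()


def initial_response(state: LissomState, x: StimulusImage | np.ndarray) -> np.ndarray:
    """Afferent-only activity ``g(sum A x)`` per in-mask neuron."""
    xf = _as_flat_input(state, x)
    s = state.afferent.weights @ xf
    y = sigmoid_g(s, state.params.alpha_l, state.params.alpha_u)
    y[~state.in_mask] = 0.0
    return y.reshape(state.params.cortex_shape)


def settle(
    state: LissomState, x: StimulusImage | np.ndarray, steps: int | None = None
) -> np.ndarray:
    """Settle the sheet on input ``x``: start from the afferent-only
    response and iterate
    ``y <- g(p * afferent_drive + q * E y - r * I y)``
    with the afferent term held fixed, stopping after ``steps`` steps or
    when the activity change falls below the configured tolerance."""
    prm = state.params
    steps = prm.settle_steps if steps is None else steps
    xf = _as_flat_input(state, x)
    s_aff = state.afferent.weights @ xf
    y = sigmoid_g(s_aff, prm.alpha_l, prm.alpha_u)
    y[~state.in_mask] = 0.0
    if steps > 0:
        lat = state.lateral_matrix()
        drive_aff = prm.p * s_aff
        for _ in range(steps):
            y_new = sigmoid_g(drive_aff + lat @ y, prm.alpha_l, prm.alpha_u)
            y_new[~state.in_mask] = 0.0
            if not np.all(np.isfinite(y_new)):
                raise FloatingPointError("non-finite activity during settling")
            delta = float(np.abs(y_new - y).max())
            y = y_new
            if prm.settle_tol > 0 and delta < prm.settle_tol:
                break
    state.activity = y
    return y.reshape(prm.cortex_shape)


def hebbian_update(
    field: ProjectionField, y: np.ndarray, P: np.ndarray, eta: float | np.ndarray
) -> float:
    """Normalized Hebbian step
    ``w' = (w + eta * y_i * P) / sum(w + eta * y_i * P)``
    applied over each neuron's support.  ``eta`` may be a scalar or a
    per-neuron array (used for area-independent learning rates).
    Mutates the field in place and returns the Frobenius norm of the
    actual weight change.

    Neurons with zero activity are untouched (the rule is then the
    identity on already-normalized weights).
    """
    eta_arr = np.asarray(eta, dtype=float)
    if np.any(eta_arr < 0):
        raise ValueError("eta must be >= 0")
    yf = np.asarray(y, dtype=float).ravel()
    Pf = np.asarray(P, dtype=float).ravel()
    rows = np.flatnonzero(yf > 0)
    if rows.size == 0 or np.all(eta_arr == 0):
        return 0.0
    eta_rows = eta_arr[rows] if eta_arr.ndim else eta_arr
    cols = np.flatnonzero(Pf > 0)
    W = field.weights
    before = W[rows].copy()
    if cols.size:
        block = np.ix_(rows, cols)
        gain = eta_rows[:, None] if eta_arr.ndim else eta_rows
        W[block] += (gain * yf[rows, None] * Pf[None, cols]) * field.support[block]
    sums = W[rows].sum(axis=1)
    bad = sums <= 0
    if np.any(bad):
        warnings.warn(
            f"{int(bad.sum())} {field.name} rows have zero weight mass; left unchanged",
            stacklevel=2,
        )
        sums[bad] = 1.0
        W[rows[bad]] = before[bad]
    W[rows] /= sums[:, None]
    return float(np.linalg.norm(W[rows] - before))


def _rebuild_support(
    field: ProjectionField,
    new_radius: float,
    in_mask_rows: np.ndarray,
    source_in_mask: np.ndarray | None,
    rng: np.random.Generator,
    recruit_scale: float = 0.001,
) -> None:
    """Enlarge the support to ``new_radius``; recruited connections get
    small random weights and the affected rows are renormalized."""
    new_support = field.dist <= new_radius
    new_support &= in_mask_rows[:, None]
    if source_in_mask is not None:
        new_support &= source_in_mask[None, :]
    recruited = new_support & ~field.support
    if recruited.any():
        rrows, rcols = np.nonzero(recruited)
        old_counts = field.support.sum(axis=1)
        scale = recruit_scale / np.maximum(old_counts[rrows], 1)
        field.weights[rrows, rcols] = rng.random(rrows.size) * scale
        touched = np.unique(rrows)
        sums = field.weights[touched].sum(axis=1)
        sums[sums <= 0] = 1.0
        field.weights[touched] /= sums[:, None]
    field.support = new_support
    field.support_radius = new_radius
    field._support_counts = None


def grow_radii(state: LissomState, rebuild_quantum: float = 0.2) -> LissomState:
    """Advance each projection's radius along its linear growth schedule
    (initial radius -> bound over the first ``growth_end_iter``
    iterations).  Support masks are rebuilt whenever the radius has
    advanced by ``rebuild_quantum`` grid units since the last rebuild (and
    always at the bound), keeping supports within the current radius."""
    prm = state.params
    t = state.iteration
    frac = 1.0 if prm.growth_end_iter <= 0 else min(1.0, t / prm.growth_end_iter)
    in_mask = state.in_mask
    for fld, source_in_mask in (
        (state.afferent, _afferent_source_mask(prm)),
        (state.excitatory, in_mask),
        (state.inhibitory, in_mask),
    ):
        target = fld.init_radius + (fld.bound - fld.init_radius) * frac
        target = min(target, fld.bound)
        if target > fld.radius:
            fld.radius = target
        if fld.radius > fld.support_radius and (
            fld.radius - fld.support_radius >= rebuild_quantum or fld.radius >= fld.bound
        ):
            _rebuild_support(
                fld, fld.radius, in_mask, source_in_mask, state.rng,
                recruit_scale=prm.recruit_weight_scale,
            )
            state.invalidate_laterals()
    return state


def train_step(state: LissomState, x: StimulusImage | np.ndarray) -> dict:
    """One training iteration on a fixed input: settle, update all three
    projections, grow radii, advance the iteration counter."""
    prm = state.params
    xf = _as_flat_input(state, x)
    y = settle(state, x).ravel()

    def eff_eta(fld: ProjectionField, eta: float) -> float | np.ndarray:
        if not prm.eta_per_connection:
            return eta
        n = fld.support_counts()
        return np.where(n > 0, eta / np.maximum(n, 1), 0.0)

    dw_a = hebbian_update(
        state.afferent, y, xf,
        eff_eta(state.afferent, prm.eta_A * prm.eta_A_calibration),
    )
    dw_e = hebbian_update(state.excitatory, y, y, eff_eta(state.excitatory, prm.eta_E))
    dw_i = hebbian_update(
        state.inhibitory, y, y, eff_eta(state.inhibitory, prm.eta_I_at(state.iteration))
    )
    if dw_e or dw_i:
        state.invalidate_laterals()
    state.iteration += 1
    grow_radii(state)
    return {
        "iteration": state.iteration,
        "mean_activity": float(y.mean()),
        "active_fraction": float((y > 0).mean()),
        "dw_afferent": dw_a,
        "dw_excitatory": dw_e,
        "dw_inhibitory": dw_i,
        "eta_I": prm.eta_I_at(state.iteration - 1),
        "rad_A": state.afferent.radius,
        "rad_E": state.excitatory.radius,
        "rad_I": state.inhibitory.radius,
    }


def train_lissom(
    state: LissomState,
    dataset: Sequence[StimulusImage],
    iterations: int = 900,
    callback: Callable[[LissomState, int], None] | None = None,
) -> tuple[LissomState, list[dict]]:
    """Train on inputs drawn uniformly at random (seeded via the state's
    generator) from ``dataset``.  ``callback(state, iteration)`` runs
    after every iteration; returns the state and the per-iteration
    metrics log."""
    if iterations < 0:
        raise ValueError("iterations must be >= 0")
    metrics: list[dict] = []
    n = len(dataset)
    if n == 0 and iterations > 0:
        raise ValueError("dataset is empty")
    for _ in range(iterations):
        x = dataset[int(state.rng.integers(n))]
        metrics.append(train_step(state, x))
        if callback is not None:
            callback(state, state.iteration)
    return state, metrics


def apply_retinal_lesion(x: StimulusImage, lesion: LesionSpec) -> StimulusImage:
    """Zero the retinal pixels inside the lesion circle."""
    if lesion.lesion_radius <= 0:
        return StimulusImage(x.pixels.copy())
    h, w = x.shape
    px, py = pixel_coords((h, w))
    d = np.hypot(px - lesion.lesion_center[0], py - lesion.lesion_center[1])
    out = x.pixels.copy()
    out[d <= lesion.lesion_radius] = 0.0
    return StimulusImage(out)
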