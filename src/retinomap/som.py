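"""Kohonen self-organizing map with an optional boundary mask.

A flat competitive network: every output node holds a weight vector in
input space, the closest node to each input wins, and nodes near the
winner move toward the input under a Gaussian neighborhood.  Trained on
the rotated/dilated bar set it maps the two stimulus features onto
roughly orthogonal axes of the output grid; a boundary mask restricts
winning and learning to the cortically available region.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from retinomap.complexlog import BoundaryMask
from retinomap.stimuli import StimulusImage

__all__ = [
    "SOMState",
    "init_som",
    "find_winner",
    "update_weights",
    "som_response",
    "train_som",
    "axis_orthogonality",
]


@dataclass
class SOMState:
    """Weights plus learning schedule of a 2D SOM.

    ``sigma`` and ``eta_max`` decay linearly from their initial values to
    ``sigma_min`` / ``eta_min`` over ``schedule_iters`` single-input
    presentations, then stay at the floor; with ``schedule_iters = 0``
    they are constant.
    """

    weights: np.ndarray          # (rows, cols, d)
    mask: np.ndarray             # (rows, cols) bool
    eta_max: float = 0.5
    sigma: float = 4.0
    eta_min: float = 0.01
    sigma_min: float = 0.5
    schedule_iters: int = 0
    neighborhood_cutoff: float | None = None   # optional hard cutoff, units of sigma
    iteration: int = 0
    rng_seed: int | None = None

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.weights.shape[:2]

    @property
    def d(self) -> int:
        return self.weights.shape[2]

    def current_sigma(self) -> float:
        return _schedule(self.sigma, self.sigma_min, self.iteration, self.schedule_iters)

    def current_eta(self) -> float:
        return _schedule(self.eta_max, self.eta_min, self.iteration, self.schedule_iters)


def _schedule(v0: float, v_min: float, t: int, horizon: int) -> float:
    if horizon <= 0:
        return v0
    frac = min(1.0, t / horizon)
    return v0 + (v_min - v0) * frac


def _as_vector(v: StimulusImage | np.ndarray) -> np.ndarray:
    if isinstance(v, StimulusImage):
        return v.as_vector()
    return np.asarray(v, dtype=float).ravel()


def init_som(
    grid: tuple[int, int],
    d: int,
    mask: BoundaryMask | np.ndarray | None = None,
    seed: int | None = None,
    **kwargs,
) -> SOMState:
    """Fresh SOM with weights uniform in [0, 1], seeded."""
    rng = np.random.default_rng(seed)
    if mask is None:
        m = np.ones(grid, dtype=bool)
    elif isinstance(mask, BoundaryMask):
        m = mask.mask.copy()
    else:
        m = np.asarray(mask, dtype=bool)
    if m.shape != tuple(grid):
        raise ValueError(f"mask shape {m.shape} does not match grid {grid}")
    if not m.any():
        raise ValueError("mask is empty")
    weights = rng.random((grid[0], grid[1], d))
    return SOMState(weights=weights, mask=m, rng_seed=seed, **kwargs)


def find_winner(state: SOMState, v: StimulusImage | np.ndarray) -> tuple[int, int]:
    """In-mask node minimizing Euclidean distance to the input; ties break
    lexicographically by (row, col)."""
    vec = _as_vector(v)
    if vec.size != state.d:
        raise ValueError(f"input length {vec.size} != weight dimension {state.d}")
    if not state.mask.any():
        raise ValueError("mask is empty")
    diff = state.weights - vec.reshape(1, 1, -1)
    d2 = np.einsum("ijd,ijd->ij", diff, diff)
    d2 = np.where(state.mask, d2, np.inf)
    flat = int(np.argmin(d2))   # first minimum in C order = (row, col) lexicographic
    return flat // d2.shape[1], flat % d2.shape[1]


def _neighborhood(
    state: SOMState, winner: tuple[int, int], eta_max: float, sigma: float
) -> np.ndarray:
    rows, cols = state.grid_shape
    k, l = winner
    di = np.arange(rows)[:, None] - k
    dj = np.arange(cols)[None, :] - l
    d2 = di * di + dj * dj
    eta = eta_max * np.exp(-d2 / (2.0 * sigma * sigma))
    if state.neighborhood_cutoff is not None:
        eta = np.where(np.sqrt(d2) <= state.neighborhood_cutoff * sigma, eta, 0.0)
    return eta


def update_weights(
    state: SOMState,
    v: StimulusImage | np.ndarray,
    winner: tuple[int, int],
    eta_max: float | None = None,
    sigma: float | None = None,
) -> SOMState:
    """Competitive update: every in-mask node moves toward the input by
    ``eta_ij (V - W)`` with the Gaussian neighborhood factor centered on
    the winner.  Out-of-mask nodes are untouched.  Mutates and returns
    ``state``.
    """
    vec = _as_vector(v)
    eta_max = state.current_eta() if eta_max is None else eta_max
    sigma = state.current_sigma() if sigma is None else sigma
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    if not state.mask[winner]:
        raise ValueError(f"winner {winner} is outside the mask")
    eta = _neighborhood(state, winner, eta_max, sigma)
    eta = np.where(state.mask, eta, 0.0)
    state.weights += eta[:, :, None] * (vec.reshape(1, 1, -1) - state.weights)
    return state


def som_response(
    state: SOMState, v: StimulusImage | np.ndarray, sigma: float | None = None
) -> np.ndarray:
    """Gaussian response ``exp(-||W - V||^2 / (2 sigma^2))`` per in-mask
    node, 0 outside the mask."""
    vec = _as_vector(v)
    sigma = state.current_sigma() if sigma is None else sigma
    diff = state.weights - vec.reshape(1, 1, -1)
    d2 = np.einsum("ijd,ijd->ij", diff, diff)
    y = np.exp(-d2 / (2.0 * sigma * sigma))
    return np.where(state.mask, y, 0.0)


def train_som(
    state: SOMState,
    dataset: Sequence[StimulusImage | np.ndarray],
    epochs: int = 10,
    shuffle_seed: int | None = None,
) -> tuple[SOMState, np.ndarray]:
    """Train for ``epochs`` passes over the dataset in seeded random order.

    Returns the trained state together with the final winner log: an
    (n_inputs, 2) array of winner (row, col) per input, computed with the
    trained weights in dataset order.
    """
    if len(dataset) == 0:
        raise ValueError("dataset is empty")
    vectors = np.stack([_as_vector(v) for v in dataset])
    if vectors.shape[1] != state.d:
        raise ValueError("dataset vector length does not match SOM dimension")
    rng = np.random.default_rng(state.rng_seed if shuffle_seed is None else shuffle_seed)
    n = len(dataset)
    for _ in range(epochs):
        order = rng.permutation(n)
        for idx in order:
            winner = find_winner(state, vectors[idx])
            update_weights(state, vectors[idx], winner)
            state.iteration += 1
    winners = np.array([find_winner(state, vec) for vec in vectors])
    return state, winners


def winner_log_table(
    winners: np.ndarray, n_rotations: int, n_dilations: int
) -> np.ndarray:
    """Reshape a rotation-major winner log to (n_rotations, n_dilations, 2)."""
    return np.asarray(winners).reshape(n_rotations, n_dilations, 2)


def axis_orthogonality(
    winners: np.ndarray, n_rotations: int, n_dilations: int
) -> float:
    """Angle in [0, 90] degrees between the output-grid directions onto
    which dilation and rotation changes are mapped.

    The two feature directions are evaluated locally: at every
    (rotation, dilation) cell the winner displacement under a dilation
    step and under a rotation step (central differences; rotation wraps,
    being periodic) span a local angle, and the magnitude-weighted mean
    of these local angles is returned.  A local measure is required
    because the trained maps organize the periodic rotation feature
    angularly and dilation radially, which makes globally averaged
    directions cancel even though the axes are orthogonal everywhere.
    Raises for a degenerate (collapsed) winner log.
    """
    table = winner_log_table(winners, n_rotations, n_dilations).astype(float)
    if np.allclose(table, table.reshape(-1, 2)[0]):
        raise ValueError("degenerate winner log: all winners identical")
    angles: list[float] = []
    weights: list[float] = []
    for r in range(n_rotations):
        for k in range(n_dilations):
            d_dil = table[r, min(k + 1, n_dilations - 1)] - table[r, max(k - 1, 0)]
            d_rot = table[(r + 1) % n_rotations, k] - table[(r - 1) % n_rotations, k]
            m_dil = float(np.linalg.norm(d_dil))
            m_rot = float(np.linalg.norm(d_rot))
            if m_dil > 0 and m_rot > 0:
                cosang = abs(float(d_dil @ d_rot)) / (m_dil * m_rot)
                angles.append(math.degrees(math.acos(min(1.0, cosang))))
                weights.append(m_dil * m_rot)
    if not angles:
        raise ValueError("degenerate winner log: no displacement along an axis")
    return float(np.average(angles, weights=weights))
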