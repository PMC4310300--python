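"""Readout and validation of trained networks.

Point-probe retinotopic maps, meridional-angle preference/selectivity,
RMS error against the complex-log reference, angle histograms, map
monotonicity statistics, lesion-projection-zone measurement, and the
foveal-boundary curvature used by the species comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from retinomap import complexlog, lissom, stimuli
from retinomap.complexlog import BoundaryMask
from retinomap.lissom import LissomState
from retinomap.stimuli import StimulusImage

__all__ = [
    "RetinotopicMap",
    "probe_point_map",
    "preference_from_responses",
    "meridional_preference",
    "family_rms",
    "rms_error_per_pixel",
    "angle_histogram",
    "map_correlations",
    "lpz_area",
    "lesion_footprint",
    "foveal_boundary_curvature",
    "excitatory_weight_spread",
]

#: Fraction of the peak activity above which a neuron counts as responsive.
RESPONSIVE_FRACTION = 0.1
#: Selectivity below which a neuron is rendered unselective in figures.
UNSELECTIVE_BELOW = 0.2


@dataclass
class RetinotopicMap:
    """Per-cortical-neuron map estimates on the cortex grid.

    ``preferred_eccentricity`` is in degrees, ``preferred_angle`` in
    degrees wrapped to [0, 180); both are NaN for unresponsive neurons.
    """

    preferred_eccentricity: np.ndarray
    preferred_angle: np.ndarray
    selectivity: np.ndarray
    responsive: np.ndarray
    mask: np.ndarray
    probe_centroids: np.ndarray | None = None   # (n_probes, 2) cortical (row, col)

    @property
    def shape(self) -> tuple[int, int]:
        return self.responsive.shape


def _probe_positions(retina_shape: tuple[int, int]) -> np.ndarray:
    """Probe grid at the positions between pixel centers: each probe
    activates a 2x2 retinal block, giving point inputs enough drive to
    clear the activation threshold of the piecewise sigmoid."""
    h, w = retina_shape
    xs = np.arange(w - 1) - (w - 1) / 2.0 + 0.5
    ys = (h - 1) / 2.0 - 0.5 - np.arange(h - 1)
    xx, yy = np.meshgrid(xs, ys)
    return np.stack([xx.ravel(), yy.ravel()], axis=1)


def probe_point_map(
    state: LissomState,
    threshold_frac: float = RESPONSIVE_FRACTION,
) -> RetinotopicMap:
    """Construct the positional retinotopic map with point probes.

    Every probe position is presented, the sheet settles, and the
    activity-weighted cortical centroid of each response is recorded.
    Each neuron's preferred retinal position is the activity-weighted
    mean of the probe positions that drive it; neurons never reaching
    ``threshold_frac`` of the peak activity are flagged unresponsive.
    """
    prm = state.params
    hc, wc = prm.cortex_shape
    positions = _probe_positions(prm.retina_shape)
    n_probes = positions.shape[0]
    responses = np.empty((n_probes, hc * wc))
    for k, (x, y) in enumerate(positions):
        img = stimuli.make_point(prm.retina_shape, float(x), float(y))
        responses[k] = lissom.settle(state, img).ravel()

    peak = responses.max()
    if peak <= 0:
        raise ValueError("no cortical neuron responds to any point probe")
    threshold = threshold_frac * peak
    above = responses >= threshold
    responsive = above.any(axis=0) & state.in_mask

    # per-probe cortical centroid
    rows, cols = np.mgrid[0:hc, 0:wc]
    tot = responses.sum(axis=1)
    with np.errstate(invalid="ignore"):
        cent_r = (responses @ rows.ravel()) / tot
        cent_c = (responses @ cols.ravel()) / tot
    centroids = np.stack([cent_r, cent_c], axis=1)

    # invert: activity-weighted probe position per neuron
    wts = np.where(above, responses, 0.0)
    mass = wts.sum(axis=0)
    px = np.full(hc * wc, np.nan)
    py = np.full(hc * wc, np.nan)
    ok = responsive & (mass > 0)
    px[ok] = (wts[:, ok] * positions[:, 0:1]).sum(axis=0) / mass[ok]
    py[ok] = (wts[:, ok] * positions[:, 1:2]).sum(axis=0) / mass[ok]

    ppd = stimuli.pixels_per_degree(prm.retina_shape[1], prm.eccentricity_max)
    ecc = np.hypot(px, py) / ppd
    # right-hemifield meridional angle: 0 = lower vertical meridian,
    # 90 = horizontal, 180 = upper vertical meridian (no wrap needed)
    ang = np.clip(np.degrees(np.arctan2(py, px)) + 90.0, 0.0, 180.0)
    if not responsive.any():
        raise ValueError("no responsive neurons in the point-probe map")
    return RetinotopicMap(
        preferred_eccentricity=ecc.reshape(hc, wc),
        preferred_angle=ang.reshape(hc, wc),
        selectivity=np.full((hc, wc), np.nan),
        responsive=responsive.reshape(hc, wc),
        mask=state.mask.mask.copy(),
        probe_centroids=centroids,
    )


def preference_from_responses(
    R: np.ndarray, rotations_deg: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Doubled-angle circular preference and selectivity from per-rotation
    responses ``R`` (n_rotations, n_units).

    Preference is returned as a meridional angle in [0, 180); selectivity
    is the resultant length in [0, 1] and is NaN where the total response
    is zero.
    """
    R = np.asarray(R, dtype=float)
    rot = np.asarray(rotations_deg, dtype=float)
    z = (R * np.exp(2j * np.radians(rot))[:, None]).sum(axis=0)
    total = R.sum(axis=0)
    pref = np.full(R.shape[1], np.nan)
    sel = np.full(R.shape[1], np.nan)
    ok = total > 0
    pref[ok] = (np.degrees(np.angle(z[ok])) / 2.0 + 90.0) % 180.0
    sel[ok] = np.abs(z[ok]) / total[ok]
    return pref, sel


def meridional_preference(
    state: LissomState,
    n_rotations: int = 9,
    n_dilations: int = 16,
) -> RetinotopicMap:
    """Angular part of the map from bar responses.

    Responses are summed over dilations at each rotation; preference and
    selectivity come from the doubled-angle circular vector sum (the
    doubling handles the 180-degree period of bar orientation).  The
    returned preference is converted from bar rotation to meridional
    angle (a bar rotated by theta lies on the meridian theta + 90).
    """
    prm = state.params
    hc, wc = prm.cortex_shape
    images, specs = stimuli.enumerate_bar_set(
        prm.retina_shape, n_rotations=n_rotations, n_dilations=n_dilations
    )
    rotations = np.array(sorted({s.rotation_deg for s in specs}))
    R = np.zeros((rotations.size, hc * wc))
    for img, spec in zip(images, specs):
        i = int(np.searchsorted(rotations, spec.rotation_deg))
        R[i] += lissom.settle(state, img).ravel()

    pref, sel = preference_from_responses(R, rotations)
    responsive = (R.sum(axis=0) > 0) & state.in_mask
    pref[~responsive] = np.nan
    sel[~responsive] = np.nan
    return RetinotopicMap(
        preferred_eccentricity=np.full((hc, wc), np.nan),
        preferred_angle=pref.reshape(hc, wc),
        selectivity=sel.reshape(hc, wc),
        responsive=responsive.reshape(hc, wc),
        mask=state.mask.mask.copy(),
    )


def rms_error_per_pixel(
    model_img: np.ndarray | StimulusImage,
    reference_img: np.ndarray | StimulusImage,
    mask: np.ndarray | None = None,
) -> float:
    """Root-mean-square difference per pixel between two cortical images,
    each max-normalized to [0, 1], over in-mask pixels."""
    a = model_img.pixels if isinstance(model_img, StimulusImage) else np.asarray(model_img, float)
    b = (reference_img.pixels if isinstance(reference_img, StimulusImage)
         else np.asarray(reference_img, float))
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    if mask is None:
        mask = np.ones(a.shape, dtype=bool)
    if a.max() > 0:
        a = a / a.max()
    if b.max() > 0:
        b = b / b.max()
    return float(np.sqrt(np.mean((a[mask] - b[mask]) ** 2)))


def angle_histogram(
    rmap: RetinotopicMap,
    region: BoundaryMask | np.ndarray | None = None,
    n_bins: int = 9,
) -> tuple[np.ndarray, np.ndarray]:
    """Counts of responsive in-region neurons per preferred-angle bin
    (default 9 bins of 20 degrees) plus the corresponding area fractions."""
    region_mask = (
        rmap.mask if region is None
        else region.mask if isinstance(region, BoundaryMask)
        else np.asarray(region, dtype=bool)
    )
    sel = rmap.responsive & region_mask & np.isfinite(rmap.preferred_angle)
    angles = rmap.preferred_angle[sel]
    counts, _ = np.histogram(angles, bins=n_bins, range=(0.0, 180.0))
    fractions = counts / counts.sum() if counts.sum() else counts.astype(float)
    return counts, fractions


def map_correlations(rmap: RetinotopicMap) -> dict[str, float]:
    """Spearman correlations quantifying map monotonicity: preferred
    eccentricity against cortical column index, preferred meridional
    angle against cortical row index (absolute values; the sign depends
    only on the axis orientation convention)."""
    hc, wc = rmap.shape
    rows, cols = np.mgrid[0:hc, 0:wc]
    out: dict[str, float] = {}
    sel_e = rmap.responsive & np.isfinite(rmap.preferred_eccentricity)
    if sel_e.sum() >= 3:
        rho, _ = stats.spearmanr(rmap.preferred_eccentricity[sel_e], cols[sel_e])
        out["eccentricity_vs_column"] = abs(float(rho))
    sel_a = rmap.responsive & np.isfinite(rmap.preferred_angle)
    if sel_a.sum() >= 3:
        rho, _ = stats.spearmanr(rmap.preferred_angle[sel_a], rows[sel_a])
        out["angle_vs_row"] = abs(float(rho))
    return out


def family_rms(
    state: LissomState,
    n_rings: int = 6,
    n_rotations: int = 9,
    n_dilations: int = 8,
) -> dict[str, float]:
    """Mean RMS error per pixel between the sheet's settled responses and
    the complex-log reference, for the three validation input families:
    rings of increasing radius, bars of fixed dilation and varying
    rotation, and vertical bars of varying dilation.

    Model inputs are linearly spaced in dilation while the reference
    inputs keep the matching exponential ratio (the analytic map is
    logarithmic in eccentricity where the model is linear); rotations are
    shared between the two.
    """
    prm = state.params
    mask = state.mask
    mp = mask.params
    hr, wr = prm.retina_shape

    def ref_img(img: StimulusImage) -> np.ndarray:
        with np.errstate(all="ignore"):
            import warnings as _w

            with _w.catch_warnings():
                _w.simplefilter("ignore")
                out = complexlog.transform_image(
                    img, mp, prm.cortex_shape, mask.u_range, mask.v_range
                )
        return out.pixels

    def mean_rms(pairs: list[tuple[StimulusImage, StimulusImage]]) -> float:
        vals = [
            rms_error_per_pixel(lissom.settle(state, m), ref_img(r), mask.mask)
            for m, r in pairs
        ]
        return float(np.mean(vals))

    out: dict[str, float] = {}
    # rings: linear radii for the model, exponential for the reference
    r_lo, r_hi = 2.0, (min(hr, wr) - 1) / 2.0 - 1.0
    lin_r = np.linspace(r_lo, r_hi, n_rings)
    exp_r = np.geomspace(r_lo, r_hi, n_rings)
    out["rings"] = mean_rms(
        [
            (stimuli.make_ring((hr, wr), rl, 1.5), stimuli.make_ring((hr, wr), re, 1.5))
            for rl, re in zip(lin_r, exp_r)
        ]
    )
    # rotations: fixed (largest) dilation, shared between model and reference
    lengths = stimuli.bar_lengths((hr, wr), n_dilations)
    rots = np.arange(n_rotations) * (180.0 / n_rotations)
    def bar(rot: float, length: float) -> StimulusImage:
        return stimuli.make_bar(
            (hr, wr), stimuli.BarSpec(rotation_deg=rot, dilation_level=1, length=length)
        )
    out["rotations"] = mean_rms(
        [(bar(rot, lengths[-1]), bar(rot, lengths[-1])) for rot in rots]
    )
    # dilations: vertical bars, linear lengths vs exponential reference
    exp_lengths = stimuli.bar_lengths((hr, wr), n_dilations, spacing="exponential")
    out["dilations"] = mean_rms(
        [(bar(90.0, ll), bar(90.0, le)) for ll, le in zip(lengths, exp_lengths)]
    )
    return out


def lpz_area(
    activity: np.ndarray,
    reference_activity: np.ndarray,
    threshold: float,
) -> int:
    """Lesion-projection-zone size: neurons active (>= threshold) for the
    unlesioned reference input but silent for the lesioned one."""
    act = np.asarray(activity, float)
    ref = np.asarray(reference_activity, float)
    if act.shape != ref.shape:
        raise ValueError("activity shapes differ")
    return int(np.count_nonzero((ref >= threshold) & (act < threshold)))


def lesion_footprint(
    activity: np.ndarray,
    reference_activity: np.ndarray,
    threshold: float,
) -> np.ndarray:
    """Cortical footprint of a lesion: the largest connected component of
    neurons silenced by the lesioned input (reference-active but silent),
    which separates the projection zone proper from isolated
    threshold-crossing speckle elsewhere on the sheet."""
    from scipy import ndimage

    lpz = (np.asarray(reference_activity) >= threshold) & (np.asarray(activity) < threshold)
    labels, n = ndimage.label(lpz)
    if n == 0:
        return np.zeros_like(lpz)
    sizes = ndimage.sum(lpz, labels, range(1, n + 1))
    return labels == (1 + int(np.argmax(sizes)))


def foveal_boundary_curvature(mask: BoundaryMask, depth: int = 6) -> float:
    """Sharpness of the foveal apex of a boundary mask, in grid units.

    Measured as the curvature of the parabola through the apex that
    matches the mask's row-extent at ``depth`` columns behind the apex:
    ``kappa = 2 * depth / halfwidth**2``.  A pointier foveal wedge gives
    a larger value; the parabolic proxy is robust to the stair-stepping
    of the rasterized curve, which defeats local quadratic fits.
    """
    m = mask.mask
    rows = np.flatnonzero(m.any(axis=1))
    left = np.array([np.flatnonzero(m[i])[0] for i in rows], dtype=float)
    apex_col = left.min()
    within = left <= apex_col + depth
    halfwidth = (within.sum() - 1) / 2.0
    if halfwidth <= 0:
        raise ValueError("mask too narrow to measure the apex")
    return float(2.0 * depth / halfwidth**2)


def excitatory_weight_spread(
    state: LissomState,
    neuron: tuple[int, int],
) -> float:
    """Effective radius of a neuron's excitatory projection: the
    weight-averaged RMS distance (grid units) from the neuron to its
    excitatory sources.  Grows when weight mass moves outward within the
    support, the signature of lesion-induced lateral plasticity."""
    hc, wc = state.params.cortex_shape
    idx = neuron[0] * wc + neuron[1]
    w = state.excitatory.weights[idx]
    tot = w.sum()
    if tot <= 0:
        return 0.0
    src = np.flatnonzero(w > 0)
    rr, cc = src // wc, src % wc
    d2 = (rr - neuron[0]) ** 2 + (cc - neuron[1]) ** 2
    return float(np.sqrt((w[src] * d2).sum() / tot))
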