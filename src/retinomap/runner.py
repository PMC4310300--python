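"""Experiment orchestration.

Six canned experiments cover the full study: the basic and
boundary-constrained SOMs, the boundary-constrained LISSOM and its
no-boundary control, the species comparison over the boundary parameter
``a``, and the retinal-lesion plasticity protocol.  Each run writes a
self-describing directory: the config, a metrics CSV, figure-style PNGs
and a JSON manifest of artifacts.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from retinomap import analysis, complexlog, lissom, som, stimuli
from retinomap.complexlog import MapParams, SPECIES_PRESETS
from retinomap.lissom import LissomParams
from retinomap.stimuli import LesionSpec

__all__ = ["ExperimentConfig", "EXPERIMENTS", "validate_config", "run_experiment"]

logger = logging.getLogger("retinomap")

EXPERIMENTS = (
    "som_basic",
    "som_bounded",
    "lissom_bounded",
    "lissom_unbounded",
    "lissom_species",
    "lissom_lesion",
)


@dataclass
class ExperimentConfig:
    """Everything needed to reproduce one experiment run."""

    experiment: str = "lissom_bounded"
    seed: int = 0
    out_dir: str = "runs/latest"
    a: float = 1.0
    # SOM settings
    som_grid: tuple[int, int] = (12, 12)
    som_input_grid: tuple[int, int] = (81, 81)
    som_epochs: int = 10
    som_sigma: float = 4.0
    som_sigma_min: float = 0.5
    som_eta: float = 0.5
    som_eta_min: float = 0.01
    n_rotations: int = 9
    n_dilations: int = 16
    aspect: float = 0.1
    # LISSOM settings (overrides onto LissomParams defaults)
    lissom: dict[str, Any] = field(default_factory=dict)
    iterations: int = 900
    snapshot_iters: tuple[int, ...] = (200, 300, 400, 500, 600, 700, 800, 900)
    # lesion protocol
    disc_radius: float = 9.0
    lesion_radius: float = 3.0
    lesion_center: tuple[float, float] = (5.0, 0.0)
    recovery_iterations: int = 200
    lpz_threshold: float = 0.5
    species: dict[str, float] = field(default_factory=lambda: dict(SPECIES_PRESETS))

    def lissom_params(self) -> LissomParams:
        overrides = dict(self.lissom)
        for key in ("retina_shape", "cortex_shape"):
            if key in overrides:
                overrides[key] = tuple(overrides[key])
        return LissomParams(rng_seed=self.seed, **overrides)

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        for key in ("som_grid", "som_input_grid", "snapshot_iters", "lesion_center"):
            if key in data and data[key] is not None:
                data[key] = tuple(data[key])
        return cls(**data)


def validate_config(config: ExperimentConfig) -> list[str]:
    """Return a list of constraint violations (empty list = valid)."""
    violations: list[str] = []
    if config.experiment not in EXPERIMENTS:
        violations.append(
            f"unknown experiment {config.experiment!r}; valid: {', '.join(EXPERIMENTS)}"
        )
    try:
        prm = config.lissom_params()
    except (TypeError, ValueError) as exc:
        return violations + [f"invalid LISSOM parameters: {exc}"]
    if not prm.rad_A > prm.rad_I:
        violations.append(f"rad_A ({prm.rad_A}) must be greater than rad_I ({prm.rad_I})")
    if not prm.p > prm.r_scale:
        violations.append(f"p ({prm.p}) must be greater than r_scale ({prm.r_scale})")
    if not prm.alpha_l < prm.alpha_u:
        violations.append(f"alpha_l ({prm.alpha_l}) must be < alpha_u ({prm.alpha_u})")
    for name, value in (("rad_A", prm.rad_A), ("rad_E", prm.rad_E), ("rad_I", prm.rad_I)):
        if value <= 0:
            violations.append(f"{name} must be > 0, got {value}")
    if prm.rad_I_grid > prm.cortex_shape[1]:
        violations.append("rad_I exceeds the cortical sheet width")
    if prm.init_rad_A_grid > prm.rad_A_grid:
        violations.append("initial afferent radius exceeds its bound")
    return violations


def _save_panel(arrays, titles, path: Path, cmap: str = "gray") -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n = len(arrays)
    ncols = min(4, n)
    nrows = (n + ncols - 1) // ncols
    fig, axes = plt.subplots(nrows, ncols, figsize=(3 * ncols, 3 * nrows), squeeze=False)
    for ax, arr, title in zip(axes.ravel(), arrays, titles):
        ax.imshow(arr, cmap=cmap, interpolation="nearest")
        ax.set_title(title, fontsize=8)
        ax.axis("off")
    for ax in axes.ravel()[n:]:
        ax.axis("off")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


def _preference_png(rmap: analysis.RetinotopicMap, path: Path) -> None:
    """HSV angle coding with selectivity (or responsiveness) as value."""
    import matplotlib

    matplotlib.use("Agg")
    from matplotlib.colors import hsv_to_rgb
    import matplotlib.pyplot as plt

    hue = np.nan_to_num(rmap.preferred_angle, nan=0.0) / 180.0
    val = np.where(rmap.responsive, 1.0, 0.0)
    sel = rmap.selectivity
    if np.isfinite(sel).any():
        val = val * np.clip(np.nan_to_num(sel, nan=0.0), 0.0, 1.0)
    rgb = hsv_to_rgb(np.stack([hue, np.ones_like(hue), val], axis=-1))
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.imshow(rgb, interpolation="nearest")
    ax.axis("off")
    fig.savefig(path, dpi=100)
    plt.close(fig)


def _run_som(config: ExperimentConfig, out: Path, bounded: bool) -> dict:
    grid = config.som_grid if not bounded else (24, 48)
    input_grid = config.som_input_grid if not bounded else (13, 25)
    images, specs = stimuli.enumerate_bar_set(
        input_grid, config.n_rotations, config.n_dilations, config.aspect
    )
    mask = None
    if bounded:
        mask = complexlog.make_boundary_mask(grid, MapParams(a=config.a))
    d = input_grid[0] * input_grid[1]
    state = som.init_som(
        grid, d, mask=mask, seed=config.seed,
        eta_max=config.som_eta, eta_min=config.som_eta_min,
        sigma=config.som_sigma, sigma_min=config.som_sigma_min,
        schedule_iters=config.som_epochs * len(images),
    )
    state, winners = som.train_som(state, images, epochs=config.som_epochs)
    log = pd.DataFrame(
        {
            "input_id": np.arange(len(specs)),
            "rotation_deg": [s.rotation_deg for s in specs],
            "dilation_level": [s.dilation_level for s in specs],
            "winner_row": winners[:, 0],
            "winner_col": winners[:, 1],
        }
    )
    log.to_csv(out / "winner_log.csv", index=False)
    angle = som.axis_orthogonality(winners, config.n_rotations, config.n_dilations)
    metrics = {"n_stimuli": len(images), "axis_orthogonality_deg": angle}
    # response panels in the style of the superimposed-output figures
    rot_sel = [0.0, 40.0, 80.0, 120.0]
    panels, titles = [], []
    for rot in rot_sel:
        resp = np.zeros(grid)
        for img, spec in zip(images, specs):
            if spec.rotation_deg == rot:
                resp = np.maximum(resp, som.som_response(state, img))
        panels.append(resp)
        titles.append(f"all dilations @ {rot:.0f} deg")
    name = "fig6_responses.png" if bounded else "fig4_responses.png"
    _save_panel(panels, titles, out / name, cmap="hot")
    np.savez(out / "som_weights.npz", weights=state.weights, mask=state.mask)
    return metrics


def _lissom_training_run(config: ExperimentConfig, out: Path, bounded: bool) -> dict:
    prm = config.lissom_params()
    map_params = MapParams(a=config.a, eccentricity_max=prm.eccentricity_max)
    if bounded:
        mask = complexlog.make_boundary_mask(prm.cortex_shape, map_params)
    else:
        mask = complexlog.all_true_mask(prm.cortex_shape, map_params)
    state = lissom.init_state(prm, mask=mask, seed=config.seed)
    images, _ = stimuli.enumerate_bar_set(
        prm.retina_shape, config.n_rotations, config.n_dilations, config.aspect
    )
    snap_iters = [t for t in config.snapshot_iters if t <= config.iterations]
    rms_rows: list[dict] = []

    def callback(st: lissom.LissomState, it: int) -> None:
        if it in snap_iters:
            fams = analysis.family_rms(st)
            fams["iteration"] = it
            rms_rows.append(fams)
            logger.info("iteration %d: rms %s", it, fams)

    state, metrics = lissom.train_lissom(state, images, config.iterations, callback)
    pd.DataFrame(metrics).to_csv(out / "metrics.csv", index=False)
    if rms_rows:
        pd.DataFrame(rms_rows).to_csv(out / "fig10_rms_vs_iteration.csv", index=False)

    summary: dict[str, Any] = {"iterations": config.iterations}
    pref = analysis.meridional_preference(state, config.n_rotations, config.n_dilations)
    _preference_png(pref, out / ("fig11_preference.png" if bounded else "fig13_preference.png"))
    counts, fractions = analysis.angle_histogram(pref)
    pd.DataFrame(
        {
            "bin_start_deg": np.arange(9) * 20.0,
            "count": counts,
            "area_fraction": fractions,
        }
    ).to_csv(out / "angle_histogram.csv", index=False)
    try:
        pmap = analysis.probe_point_map(state)
        summary.update(analysis.map_correlations(
            analysis.RetinotopicMap(
                preferred_eccentricity=pmap.preferred_eccentricity,
                preferred_angle=pref.preferred_angle,
                selectivity=pref.selectivity,
                responsive=pmap.responsive & pref.responsive,
                mask=pmap.mask,
            )
        ))
        _preference_png(pref, out / "fig8_preference.png")
    except ValueError as exc:
        summary["probe_map_error"] = str(exc)
    np.savez(
        out / "lissom_weights.npz",
        afferent=state.afferent.weights,
        excitatory=state.excitatory.weights,
        inhibitory=state.inhibitory.weights,
        mask=state.mask.mask,
    )
    return summary


def _run_species(config: ExperimentConfig, out: Path) -> dict:
    rows = []
    panels, titles = [], []
    for name, a in config.species.items():
        mp = MapParams(a=a)
        mask = complexlog.make_boundary_mask((48, 48), mp)
        # curvature measured on a finer rasterization of the same curve so
        # the close squirrel-monkey / owl-monkey pair is resolved
        fine = complexlog.make_boundary_mask((192, 192), mp)
        curv = analysis.foveal_boundary_curvature(fine, depth=24)
        rows.append({"species": name, "a": a, "inside_count": mask.inside_count,
                     "foveal_curvature": curv})
        mask.save_csv(out / f"mask_a{a}.csv")
        panels.append(mask.mask.astype(float))
        titles.append(f"{name} (a={a})")
    _save_panel(panels, titles, out / "fig14_species_masks.png")
    pd.DataFrame(rows).to_csv(out / "species.csv", index=False)
    return {"species": {r["species"]: r["foveal_curvature"] for r in rows}}


def _run_lesion(config: ExperimentConfig, out: Path) -> dict:
    """Train, lesion the retina, and track LPZ recovery under continued
    training on the lesioned disc (the testing input of the protocol)."""
    prm = config.lissom_params()
    state = lissom.init_state(prm, seed=config.seed)
    images, _ = stimuli.enumerate_bar_set(
        prm.retina_shape, config.n_rotations, config.n_dilations, config.aspect
    )
    state, _ = lissom.train_lissom(state, images, config.iterations)
    spec = LesionSpec(
        disc_radius=config.disc_radius,
        lesion_center=tuple(config.lesion_center),
        lesion_radius=config.lesion_radius,
    )
    disc = stimuli.make_lesioned_disc(prm.retina_shape, spec)
    full_disc = stimuli.StimulusImage(
        (np.hypot(*stimuli.pixel_coords(prm.retina_shape)) <= config.disc_radius).astype(float)
    )
    reference = lissom.settle(state, full_disc)
    act0 = lissom.settle(state, disc)
    footprint = analysis.lesion_footprint(act0, reference, config.lpz_threshold)
    rows = []
    checkpoints = sorted({0, config.recovery_iterations // 2, config.recovery_iterations})
    for i, it in enumerate(checkpoints):
        if i > 0:
            state, _ = lissom.train_lissom(state, [disc], it - checkpoints[i - 1])
        act = lissom.settle(state, disc)
        rows.append(
            {
                "recovery_iteration": it,
                "lpz_area": analysis.lpz_area(act, reference, config.lpz_threshold),
                "lpz_area_footprint": int(
                    (footprint & (act < config.lpz_threshold)).sum()
                ),
            }
        )
        _save_panel([disc.pixels, act], ["lesioned disc", f"activity @ {it}"],
                    out / f"fig15_activity_{it:04d}.png", cmap="hot")
    pd.DataFrame(rows).to_csv(out / "lpz_area.csv", index=False)
    return {
        "footprint_size": int(footprint.sum()),
        "lpz_area_footprint": {
            r["recovery_iteration"]: r["lpz_area_footprint"] for r in rows
        },
    }


def run_experiment(config: ExperimentConfig) -> Path:
    """Execute the named experiment end to end; returns the run directory."""
    violations = validate_config(config)
    if violations:
        raise ValueError("invalid config:\n" + "\n".join(violations))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    handler = logging.FileHandler(out / "run.log")
    logger.addHandler(handler)
    try:
        if config.experiment == "som_basic":
            summary = _run_som(config, out, bounded=False)
        elif config.experiment == "som_bounded":
            summary = _run_som(config, out, bounded=True)
        elif config.experiment == "lissom_bounded":
            summary = _lissom_training_run(config, out, bounded=True)
        elif config.experiment == "lissom_unbounded":
            summary = _lissom_training_run(config, out, bounded=False)
        elif config.experiment == "lissom_species":
            summary = _run_species(config, out)
        elif config.experiment == "lissom_lesion":
            summary = _run_lesion(config, out)
        else:  # pragma: no cover - guarded by validate_config
            raise ValueError(f"unknown experiment {config.experiment!r}")
    finally:
        logger.removeHandler(handler)
        handler.close()
    manifest = {
        "experiment": config.experiment,
        "seed": config.seed,
        "summary": summary,
        "artifacts": sorted(p.name for p in out.iterdir() if p.name != "manifest.json"),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=float)
    return out
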