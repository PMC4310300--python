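# retinomap

Activity-dependent development of the V1 retinotopic map.

The package implements two self-organizing models of how eccentricity and
meridional angle come to occupy roughly orthogonal axes of the primary
visual cortex:

- a **Kohonen SOM** trained on rotated/dilated rectangular bars, showing
  that the two stimulus features map onto distinct output axes, with an
  optional complex-log boundary constraint on the output sheet;
- a **LISSOM cortical sheet** (limited-radius afferent, lateral excitatory
  and lateral inhibitory projections; piecewise-sigmoid activation;
  multi-step settling; normalized Hebbian learning; growing projection
  radii) trained on the same bar ensemble, probed with point inputs, and
  validated against the analytic complex-logarithmic retino-cortical
  transform `u + iv = log(x + iy + a)`;
- **retinal-lesion experiments** demonstrating lateral-connection
  plasticity: the cortical lesion projection zone (LPZ) shrinks during
  recovery and disappears when it fits within the excitatory radius.

All inputs are synthesized in-package (bars, rings, point probes,
lesioned discs); there is no external data.

## Layout

| module | contents |
| --- | --- |
| `retinomap.stimuli` | stimulus rasterization: bars, rings, points, lesioned discs; PNG/CSV export |
| `retinomap.complexlog` | forward complex-log map, boundary curve `u = log(a / cos v)`, boundary masks, image transform, species presets (a = 1 / 2.5 / 4) |
| `retinomap.som` | SOM: winner search, Gaussian-neighborhood competitive updates, response maps, training, axis-orthogonality readout |
| `retinomap.lissom` | LISSOM sheet: projection fields, settling dynamics, normalized Hebbian updates, radius growth, lesion support |
| `retinomap.analysis` | point-probe retinotopic maps, meridional preference/selectivity, RMS error against the complex-log reference, angle histograms, LPZ measurement |
| `retinomap.runner` | the six canned experiments with YAML config, CSV metrics, figure PNGs and a JSON manifest |

## CLI

```sh
# generate the 144-bar training set
stimgen bars --grid 81x81 --out runs/bars

# run a full experiment (som_basic, som_bounded, lissom_bounded,
# lissom_unbounded, lissom_species, lissom_lesion)
retinomap run --experiment lissom_bounded --seed 1 --out runs/v1

# SOM / LISSOM shortcuts
retinomap som train --grid 12x12 --epochs 10 --seed 0 --out runs/som
retinomap lissom train --boundary --seed 1 --out runs/lissom
retinomap lissom lesion --disc-radius 9 --lesion-radius 3 --out runs/lesion

# validate a config against the model's parameter constraints
retinomap validate --config runs/v1/config.yaml
```

Every run directory contains the config copy, a log, metric CSVs
(winner logs, RMS-vs-iteration, angle histograms, LPZ areas), PNG panels
and `manifest.json`.

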