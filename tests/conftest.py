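"""Shared fixtures.

The expensive trained networks (the 900-iteration cortical sheets and the
SOM runs) are session-scoped so the acceptance tests and the module tests
share a single training run per configuration.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from retinomap import analysis, complexlog, lissom, som, stimuli

warnings.filterwarnings("ignore", message=".*rasterize identically.*")
warnings.filterwarnings("ignore", message=".*left-hemifield pixels ignored.*")

ACCEPTANCE_SEED = 1


@pytest.fixture(scope="session")
def bar_set_81():
    images, specs = stimuli.enumerate_bar_set((81, 81))
    return images, specs


@pytest.fixture(scope="session")
def bar_set_25():
    images, specs = stimuli.enumerate_bar_set((25, 25))
    return images, specs


@pytest.fixture(scope="session")
def som_runs(bar_set_81):
    """Three seeded 10-epoch SOM runs on the 144-bar set plus a 10-epoch
    continuation of each, with winner logs at both points."""
    images, _ = bar_set_81
    runs = {}
    for seed in (0, 1, 2):
        state = som.init_som(
            (12, 12), 81 * 81, seed=seed, schedule_iters=10 * len(images)
        )
        state, winners10 = som.train_som(state, images, epochs=10)
        state, winners20 = som.train_som(state, images, epochs=10)
        runs[seed] = {"state": state, "winners10": winners10, "winners20": winners20}
    return runs


def _train_lissom(bounded: bool, seed: int, snapshot_iters=(200, 900)):
    prm = lissom.LissomParams(rng_seed=seed)
    mask = None if bounded else complexlog.all_true_mask(prm.cortex_shape)
    state = lissom.init_state(prm, mask=mask)
    images, _ = stimuli.enumerate_bar_set(prm.retina_shape)
    rms = {}

    def cb(st, it):
        if it in snapshot_iters:
            rms[it] = analysis.family_rms(st)

    state, metrics = lissom.train_lissom(state, images, 900, cb)
    return {"state": state, "rms": rms, "metrics": metrics}


@pytest.fixture(scope="session")
def lissom_bounded():
    """The reference 900-iteration boundary-constrained run (seed fixed)."""
    return _train_lissom(bounded=True, seed=ACCEPTANCE_SEED)


@pytest.fixture(scope="session")
def lissom_unbounded():
    """The no-boundary control with the same seed."""
    return _train_lissom(bounded=False, seed=ACCEPTANCE_SEED)


@pytest.fixture(scope="session")
def probe_map_bounded(lissom_bounded):
    return analysis.probe_point_map(lissom_bounded["state"])


@pytest.fixture()
def toy_params():
    """Small sheet used by fast unit tests."""
    return lissom.LissomParams(
        rng_seed=7,
        retina_shape=(5, 5),
        cortex_shape=(6, 6),
        settle_steps=2,
        settle_tol=0.0,
        init_rad_A_grid=2.0,
        growth_end_iter=0,
    )
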