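import copy
import math

import numpy as np
import pytest

from retinomap import analysis, complexlog, lissom, stimuli
from retinomap.complexlog import BoundaryMask, MapParams
from retinomap.lissom import (
    LissomParams,
    apply_retinal_lesion,
    count_excitatory_neighbors,
    grid_to_cortex_mm,
    grow_radii,
    hebbian_update,
    init_state,
    initial_response,
    settle,
    sheet_to_grid,
    sigmoid_g,
    train_lissom,
    train_step,
)
from retinomap.stimuli import LesionSpec, StimulusImage


def custom_mask(arr):
    arr = np.asarray(arr, dtype=bool)
    return BoundaryMask(mask=arr, params=MapParams(),
                        u_range=(0.0, 1.6), v_range=(-1.3, 1.3))


@pytest.fixture()
def oracle_params():
    """5x5 retina / 6x6 cortex with all radii at their bounds from the
    start (no growth, no recruitment randomness)."""
    return LissomParams(
        rng_seed=7,
        retina_shape=(5, 5),
        cortex_shape=(6, 6),
        rad_E=0.25,            # bound 1.5: a real neighborhood on a 6-wide sheet
        settle_steps=2,
        settle_tol=0.0,
        init_rad_A_grid=5.0,   # = rad_A bound on the 5-wide retina
        init_rad_frac=1.0,
        growth_end_iter=0,
    )


class TestSigmoid:
    def test_zero_branch_boundary(self):
        assert sigmoid_g(0.083, 0.083, 0.633) == 0.0

    def test_one_branch_boundary(self):
        assert sigmoid_g(0.633, 0.083, 0.633) == 1.0

    def test_midpoint(self):
        assert sigmoid_g((0.083 + 0.633) / 2, 0.083, 0.633) == pytest.approx(0.5)

    def test_invalid_thresholds(self):
        with pytest.raises(ValueError):
            sigmoid_g(0.5, 0.7, 0.2)


class TestRadiusConversions:
    def test_inhibitory_sheet_to_grid(self):
        assert sheet_to_grid(0.55, 48) == pytest.approx(26.4)

    def test_excitatory_sheet_to_grid(self):
        assert sheet_to_grid(0.03, 48) == pytest.approx(1.44)

    def test_afferent_sheet_to_grid(self):
        assert sheet_to_grid(1.0, 25) == pytest.approx(25.0)

    def test_inhibitory_mm(self):
        assert grid_to_cortex_mm(26.4) == pytest.approx(9.9)

    def test_excitatory_mm(self):
        assert grid_to_cortex_mm(1.44) == pytest.approx(0.54)

    def test_zero_mm(self):
        assert grid_to_cortex_mm(0.0) == 0.0


class TestExcitatoryNeighbors:
    def test_printed_radius_gives_8(self):
        assert count_excitatory_neighbors(1.44) == 8

    def test_half_unit_gives_0(self):
        assert count_excitatory_neighbors(0.5) == 0

    def test_unit_gives_4(self):
        assert count_excitatory_neighbors(1.0) == 4

    def test_invalid(self):
        with pytest.raises(ValueError):
            count_excitatory_neighbors(0.0)


class TestParams:
    def test_defaults_satisfy_constraints(self):
        prm = LissomParams()
        assert prm.rad_A > prm.rad_I
        assert prm.p > prm.r_scale
        assert prm.alpha_l < prm.alpha_u
        assert prm.alpha_u == pytest.approx(0.083 + 0.55)

    def test_eta_I_switch(self):
        prm = LissomParams()
        assert prm.eta_I_at(499) == 0.25
        assert prm.eta_I_at(500) == 0.5

    def test_invalid_alpha_order(self):
        with pytest.raises(ValueError):
            LissomParams(alpha_l=0.7, alpha_u=0.2)


class TestInitState:
    def test_weight_sums_are_one(self, oracle_params):
        state = init_state(oracle_params)
        in_mask = state.in_mask
        for fld in (state.afferent, state.excitatory, state.inhibitory):
            sums = fld.row_sums()
            np.testing.assert_allclose(sums[in_mask], 1.0, atol=1e-12)
            np.testing.assert_array_equal(sums[~in_mask], 0.0)

    def test_deterministic(self, oracle_params):
        a = init_state(oracle_params)
        b = init_state(oracle_params)
        np.testing.assert_array_equal(a.afferent.weights, b.afferent.weights)
        np.testing.assert_array_equal(a.inhibitory.weights, b.inhibitory.weights)

    def test_apex_afferent_center_is_foveal(self):
        prm = LissomParams(rng_seed=0)
        state = init_state(prm)
        r, c = state.mask.apex()
        wc = prm.cortex_shape[1]
        center = state.afferent.centers[r * wc + c]
        origin = np.array([(prm.retina_shape[0] - 1) / 2, (prm.retina_shape[1] - 1) / 2])
        assert np.hypot(*(center - origin)) <= 2.0

    def test_no_lateral_autapses(self, oracle_params):
        state = init_state(oracle_params)
        assert np.diagonal(state.excitatory.support).sum() == 0
        assert np.diagonal(state.inhibitory.support).sum() == 0


class TestInitialResponse:
    def test_blank_input_gives_zero(self, oracle_params):
        state = init_state(oracle_params)
        y = initial_response(state, StimulusImage(np.zeros((5, 5))))
        np.testing.assert_array_equal(y, 0.0)

    def test_fully_covered_support_saturates(self, oracle_params):
        state = init_state(oracle_params)
        y = initial_response(state, StimulusImage(np.ones((5, 5))))
        # normalized weights on a bright field give drive 1 -> g(1) = 1
        np.testing.assert_allclose(y[state.mask.mask], 1.0)

    def test_matches_brute_force(self, oracle_params):
        state = init_state(oracle_params)
        x = np.random.default_rng(0).random((5, 5))
        y = initial_response(state, StimulusImage(x))
        prm = state.params
        for i in range(6):
            for j in range(6):
                drive = 0.0
                for a in range(5):
                    for b in range(5):
                        drive += state.afferent.weights[i * 6 + j, a * 5 + b] * x[a, b]
                expected = min(1.0, max(0.0, (drive - prm.alpha_l) / (prm.alpha_u - prm.alpha_l)))
                if not state.mask.mask[i, j]:
                    expected = 0.0
                assert y[i, j] == pytest.approx(expected, abs=1e-12)


class TestSettle:
    def test_without_laterals_matches_scaled_drive(self, oracle_params):
        import dataclasses

        prm = dataclasses.replace(oracle_params, q=0.0, r_scale=0.0)
        state = init_state(prm)
        x = StimulusImage(np.random.default_rng(1).random((5, 5)))
        xf = x.pixels.ravel()
        drive = state.afferent.weights @ xf
        expected = sigmoid_g(prm.p * drive, prm.alpha_l, prm.alpha_u)
        expected[~state.in_mask] = 0.0
        for steps in (1, 3, 7):
            y = settle(state, x, steps=steps)
            np.testing.assert_allclose(y.ravel(), expected, atol=1e-12)

    def test_activity_in_unit_interval(self, oracle_params):
        state = init_state(oracle_params)
        for seed in range(3):
            x = StimulusImage(np.random.default_rng(seed).random((5, 5)))
            y = settle(state, x)
            assert np.all(y >= 0.0) and np.all(y <= 1.0)

    def test_one_step_matches_hand_equation(self, oracle_params):
        state = init_state(oracle_params)
        prm = state.params
        x = StimulusImage(np.random.default_rng(2).random((5, 5)))
        xf = x.pixels.ravel()
        s = state.afferent.weights @ xf
        y0 = sigmoid_g(s, prm.alpha_l, prm.alpha_u)
        y0[~state.in_mask] = 0.0
        expected = sigmoid_g(
            prm.p * s
            + prm.q * (state.excitatory.weights @ y0)
            - prm.r_scale * (state.inhibitory.weights @ y0),
            prm.alpha_l,
            prm.alpha_u,
        )
        expected[~state.in_mask] = 0.0
        y = settle(state, x, steps=1)
        np.testing.assert_allclose(y.ravel(), expected, atol=1e-12)


class TestHebbianUpdate:
    def test_zero_activity_leaves_weights_unchanged(self, oracle_params):
        state = init_state(oracle_params)
        before = state.afferent.weights.copy()
        dw = hebbian_update(state.afferent, np.zeros(36), np.ones(25), 0.3)
        assert dw == 0.0
        np.testing.assert_array_equal(state.afferent.weights, before)

    def test_sums_remain_one(self, oracle_params):
        state = init_state(oracle_params)
        y = np.random.default_rng(0).random(36) * state.in_mask
        P = np.random.default_rng(1).random(25)
        hebbian_update(state.afferent, y, P, 0.3)
        sums = state.afferent.row_sums()
        np.testing.assert_allclose(sums[state.in_mask], 1.0, atol=1e-9)

    def test_two_weight_toy_case(self):
        # w = (0.5, 0.5), P = (1, 0), eta * y = 1  ->  w' = (0.75, 0.25)
        from retinomap.lissom import ProjectionField

        field = ProjectionField(
            name="toy",
            weights=np.array([[0.5, 0.5]]),
            support=np.ones((1, 2), dtype=bool),
            dist=np.zeros((1, 2), dtype=np.float32),
            centers=np.zeros((1, 2)),
            radius=1.0, bound=1.0, init_radius=1.0, support_radius=1.0,
        )
        hebbian_update(field, np.array([1.0]), np.array([1.0, 0.0]), 1.0)
        np.testing.assert_allclose(field.weights, [[0.75, 0.25]], atol=1e-12)

    def test_negative_eta_rejected(self, oracle_params):
        state = init_state(oracle_params)
        with pytest.raises(ValueError):
            hebbian_update(state.afferent, np.ones(36), np.ones(25), -0.1)


class TestGrowRadii:
    def test_radii_reach_printed_bounds(self):
        prm = LissomParams(rng_seed=0, growth_end_iter=100)
        state = init_state(prm)
        state.iteration = 100
        grow_radii(state)
        assert state.afferent.radius == pytest.approx(25.0)
        assert state.excitatory.radius == pytest.approx(1.44)
        assert state.inhibitory.radius == pytest.approx(26.4)

    def test_radii_nondecreasing_and_sums_stay_one(self):
        prm = LissomParams(rng_seed=0, growth_end_iter=50)
        state = init_state(prm)
        prev = (0.0, 0.0, 0.0)
        for it in range(0, 60, 10):
            state.iteration = it
            grow_radii(state)
            now = (state.afferent.radius, state.excitatory.radius, state.inhibitory.radius)
            assert all(a >= b for a, b in zip(now, prev))
            prev = now
        sums = state.afferent.row_sums()
        np.testing.assert_allclose(sums[state.in_mask], 1.0, atol=1e-9)

    def test_support_within_radius(self):
        prm = LissomParams(rng_seed=0, growth_end_iter=10)
        state = init_state(prm)
        for it in range(12):
            state.iteration = it
            grow_radii(state)
        for fld in (state.afferent, state.excitatory, state.inhibitory):
            assert np.all(fld.dist[fld.support] <= fld.radius + 1e-6)


class TestTrainLissom:
    def test_zero_iterations_is_identity(self, oracle_params):
        state = init_state(oracle_params)
        before = state.afferent.weights.copy()
        train_lissom(state, [StimulusImage(np.ones((5, 5)))], 0)
        np.testing.assert_array_equal(state.afferent.weights, before)

    def test_deterministic(self, oracle_params):
        data = [StimulusImage(np.random.default_rng(i).random((5, 5)) > 0.5)
                for i in range(4)]
        data = [StimulusImage(d.pixels.astype(float)) for d in data]
        results = []
        for _ in range(2):
            state = init_state(oracle_params)
            state, _ = train_lissom(state, data, 20)
            results.append(
                (state.afferent.weights.copy(), state.inhibitory.weights.copy())
            )
        np.testing.assert_array_equal(results[0][0], results[1][0])
        np.testing.assert_array_equal(results[0][1], results[1][1])

    def test_conservation_after_training(self, oracle_params):
        data = [StimulusImage((np.random.default_rng(i).random((5, 5)) > 0.4).astype(float))
                for i in range(4)]
        state = init_state(oracle_params)
        state, _ = train_lissom(state, data, 30)
        for fld in (state.afferent, state.excitatory, state.inhibitory):
            sums = fld.row_sums()
            np.testing.assert_allclose(sums[state.in_mask], 1.0, atol=1e-9)

    def test_boundary_inertness(self, oracle_params):
        arr = np.ones((6, 6), dtype=bool)
        arr[:, 0] = False
        arr[5, :] = False
        state = init_state(oracle_params, mask=custom_mask(arr))
        data = [StimulusImage((np.random.default_rng(i).random((5, 5)) > 0.3).astype(float))
                for i in range(3)]
        for it in range(10):
            x = data[it % 3]
            y = settle(state, x)
            assert np.all(y[~arr] == 0.0)
            train_step(state, x)
        for fld in (state.afferent, state.excitatory, state.inhibitory):
            np.testing.assert_array_equal(fld.weights[~arr.ravel()], 0.0)


class TestToyOracle:
    def test_full_iteration_matches_straight_loop(self, oracle_params):
        """One training iteration (response -> settle 2 steps -> all three
        Hebbian updates) against an independent nested-loop reference."""
        state = init_state(oracle_params)
        ref = copy.deepcopy(state)
        prm = state.params
        x = (np.random.default_rng(9).random((5, 5)) > 0.4).astype(float)

        train_step(state, StimulusImage(x))

        # ---- straight-loop reference ----
        def g(s):
            if s <= prm.alpha_l:
                return 0.0
            if s >= prm.alpha_u:
                return 1.0
            return (s - prm.alpha_l) / (prm.alpha_u - prm.alpha_l)

        n, m = 36, 25
        xf = x.ravel()
        in_mask = ref.in_mask
        s_aff = np.zeros(n)
        for i in range(n):
            for b in range(m):
                s_aff[i] += ref.afferent.weights[i, b] * xf[b]
        y = np.array([g(s_aff[i]) if in_mask[i] else 0.0 for i in range(n)])
        for _ in range(prm.settle_steps):
            y_new = np.zeros(n)
            for i in range(n):
                if not in_mask[i]:
                    continue
                exc = sum(ref.excitatory.weights[i, k] * y[k] for k in range(n))
                inh = sum(ref.inhibitory.weights[i, k] * y[k] for k in range(n))
                y_new[i] = g(prm.p * s_aff[i] + prm.q * exc - prm.r_scale * inh)
            y = y_new

        def update(field, P, eta):
            W = field.weights
            for i in range(n):
                if y[i] <= 0:
                    continue
                eta_i = eta / max(int(field.support[i].sum()), 1)
                row = W[i].copy()
                for k in range(len(P)):
                    if field.support[i, k]:
                        row[k] += eta_i * y[i] * P[k]
                W[i] = row / row.sum()

        update(ref.afferent, xf, prm.eta_A * prm.eta_A_calibration)
        update(ref.excitatory, y, prm.eta_E)
        update(ref.inhibitory, y, prm.eta_I_at(0))

        np.testing.assert_allclose(
            state.afferent.weights, ref.afferent.weights, atol=1e-12
        )
        np.testing.assert_allclose(
            state.excitatory.weights, ref.excitatory.weights, atol=1e-12
        )
        np.testing.assert_allclose(
            state.inhibitory.weights, ref.inhibitory.weights, atol=1e-12
        )


class TestApplyRetinalLesion:
    def test_lesion_outside_active_region_is_noop(self):
        img = stimuli.make_ring((25, 25), 8.0, 1.0)
        spec = LesionSpec(disc_radius=9.0, lesion_radius=2.0)
        out = apply_retinal_lesion(img, spec)
        np.testing.assert_array_equal(out.pixels, img.pixels)

    def test_lesioned_pixel_count(self):
        img = StimulusImage(np.ones((25, 25)))
        spec = LesionSpec(disc_radius=9.0, lesion_radius=3.0)
        out = apply_retinal_lesion(img, spec)
        x, y = stimuli.pixel_coords((25, 25))
        assert int((out.pixels == 0).sum()) == int((np.hypot(x, y) <= 3.0).sum())

    def test_idempotent_with_lesioned_disc(self):
        spec = LesionSpec(disc_radius=9.0, lesion_radius=3.0)
        disc = stimuli.make_lesioned_disc((25, 25), spec)
        np.testing.assert_array_equal(
            apply_retinal_lesion(disc, spec).pixels, disc.pixels
        )


def _small_run(seed=1, iters=400, **overrides):
    prm = LissomParams(rng_seed=seed, retina_shape=(15, 15),
                       cortex_shape=(24, 24), **overrides)
    state = init_state(prm)
    images, _ = stimuli.enumerate_bar_set(prm.retina_shape)
    state, _ = train_lissom(state, images, iters)
    return state


def _mean_active_area(state, n=48):
    images, _ = stimuli.enumerate_bar_set(state.params.retina_shape)
    return float(np.mean([(settle(state, im) > 0).sum() for im in images[:n]]))


class TestAblations:
    """Scaled-down versions of the parameter-ablation observations."""

    def test_halved_inhibitory_radius_leaves_discontinuities(self):
        state = _small_run(rad_I=0.275)
        pmap = analysis.probe_point_map(state)
        pos = np.stack(
            [
                pmap.preferred_eccentricity * np.cos(np.radians(pmap.preferred_angle - 90)),
                pmap.preferred_eccentricity * np.sin(np.radians(pmap.preferred_angle - 90)),
            ],
            axis=-1,
        )
        jumps = []
        h, w = pmap.shape
        for i in range(h):
            for j in range(w - 1):
                if pmap.responsive[i, j] and pmap.responsive[i, j + 1]:
                    jumps.append(float(np.linalg.norm(pos[i, j] - pos[i, j + 1])))
        jumps = np.array(jumps)
        assert jumps.max() > 3.0 * np.median(jumps)

    def test_tripled_excitatory_radius_increases_active_area(self):
        base = _small_run()
        wide = _small_run(rad_E=0.09)
        assert _mean_active_area(wide) > _mean_active_area(base)

    def test_removing_afferents_prevents_map_formation(self):
        prm = LissomParams(rng_seed=1, retina_shape=(15, 15), cortex_shape=(24, 24),
                           init_rad_A_grid=15.0, growth_end_iter=0,
                           init_rad_frac=1.0)
        state = init_state(prm)
        state.afferent.weights[:] = 0.0
        images, _ = stimuli.enumerate_bar_set((15, 15))
        state, _ = train_lissom(state, images, 20)
        with pytest.raises(ValueError):
            analysis.probe_point_map(state)
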