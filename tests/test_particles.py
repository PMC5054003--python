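"""Particle life dynamics, transfer functions, projection and the two
compositing modes, checked against closed forms and brute-force oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from spikescope import particles, simdata
from spikescope.particles import (
    CameraState,
    ParticleState,
    RenderSettings,
    SizeFunction,
    TransferFunction,
)
from conftest import make_neuron, random_report


class TestLifeDynamics:
    def test_spike_at_t_now_gives_full_life(self):
        state = particles.init_state([0, 1], decay=10.0)
        out = particles.advance(state, [5.0], [1], t_now=5.0)
        assert out.life[1] == 1.0 and out.life[0] == 0.0

    def test_linear_decay_half_and_exhaustion(self):
        state = particles.init_state([0], decay=10.0)
        state = particles.advance(state, [2.0], [0], t_now=2.0)
        assert particles.advance(state, [], [], 7.0).life[0] == pytest.approx(0.5)
        assert particles.advance(state, [], [], 12.0).life[0] == 0.0
        assert particles.advance(state, [], [], 50.0).life[0] == 0.0

    def test_respike_resets_to_one_without_stacking(self):
        state = particles.init_state([0], decay=10.0)
        state = particles.advance(state, [0.0], [0], t_now=0.0)
        state = particles.advance(state, [1.0], [0], t_now=1.0)
        assert state.life[0] == 1.0

    def test_time_backward_is_error(self):
        state = particles.init_state([0], decay=10.0, time=5.0)
        with pytest.raises(simdata.ValidationError):
            particles.advance(state, [], [], 4.0)

    def test_seek_before_any_spike_is_all_zero(self):
        report = simdata.SpikeReport.from_events([(10.0, 0)], 0.0, 50.0)
        state = particles.seek(report, 5.0, decay=10.0, gids=[0, 1])
        assert np.all(state.life == 0.0)

    def test_seek_after_final_spike_plus_decay_is_zero(self):
        report = simdata.SpikeReport.from_events([(10.0, 0)], 0.0, 50.0)
        state = particles.seek(report, 25.0, decay=10.0, gids=[0])
        assert np.all(state.life == 0.0)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_seek_equals_advance_from_start(self, seed):
        rng = np.random.default_rng(seed)
        report = random_report(rng, n_gids=15, n_events=120, duration=60.0)
        decay = float(rng.uniform(2.0, 25.0))
        t = float(rng.uniform(0.0, 60.0))
        gids = list(range(15))
        sought = particles.seek(report, t, decay, gids=gids)
        state = particles.init_state(gids, decay, time=0.0)
        # advance in several irregular hops
        hops = np.sort(rng.uniform(0.0, t, 4)).tolist() + [t]
        for t_now in hops:
            mask = (report.times > state.time) & (report.times <= t_now)
            state = particles.advance(
                state, report.times[mask], report.gids[mask], t_now
            )
        np.testing.assert_allclose(state.life, sought.life, atol=1e-12)
        assert np.all((state.life >= 0.0) & (state.life <= 1.0))


class TestTransferFunctions:
    def test_value_at_control_point_is_exact(self):
        tf = TransferFunction(((0.0, (0, 0, 1, 0.2)), (1.0, (1, 0, 0, 1.0))))
        np.testing.assert_array_equal(tf(0.0), [0, 0, 1, 0.2])
        np.testing.assert_array_equal(tf(1.0), [1, 0, 0, 1.0])

    def test_midpoint_linear_interpolation(self):
        tf = TransferFunction(((0.0, (0, 0, 1, 0.2)), (1.0, (1, 0, 0, 1.0))))
        np.testing.assert_allclose(tf(0.5), [0.5, 0, 0.5, 0.6], atol=1e-12)

    def test_out_of_range_clamps(self):
        tf = TransferFunction(((0.0, (0, 0, 1, 0.2)), (1.0, (1, 0, 0, 1.0))))
        np.testing.assert_array_equal(tf(-0.3), tf(0.0))
        np.testing.assert_array_equal(tf(1.7), tf(1.0))

    def test_knots_must_span_unit_interval(self):
        with pytest.raises(simdata.ValidationError):
            TransferFunction(((0.1, (0, 0, 0, 0)), (1.0, (1, 1, 1, 1))))
        with pytest.raises(simdata.ValidationError):
            SizeFunction(((0.0, 2.0), (0.5, 3.0)))

    def test_size_interpolation(self):
        sf = SizeFunction(((0.0, 2.0), (1.0, 10.0)))
        assert sf(0.25) == pytest.approx(4.0)


class TestVoltageMapping:
    def test_endpoints_and_midpoint(self):
        assert particles.voltage_to_t(-80.0, -80, -50) == 0.0
        assert particles.voltage_to_t(-50.0, -80, -50) == 1.0
        assert particles.voltage_to_t(-65.0, -80, -50) == pytest.approx(0.5)

    def test_direct_formula(self):
        assert particles.voltage_to_t(-62.0, -80, -50) == pytest.approx(0.6)

    def test_degenerate_range_is_error(self):
        with pytest.raises(simdata.ValidationError):
            particles.voltage_to_t(0.0, 5.0, 5.0)


class TestProjection:
    def test_optical_axis_maps_to_center(self):
        cam = CameraState(viewport=(200, 100), fov_deg=90.0)
        x, y, d = particles.project(cam, (0.0, 0.0, -7.0))
        assert (x, y) == (100.0, 50.0)
        assert d == pytest.approx(7.0)

    def test_focal_length_arithmetic(self):
        cam = CameraState(viewport=(200, 200), fov_deg=90.0)
        x, y, d = particles.project(cam, (1.0, 0.0, -1.0))
        assert x == pytest.approx(200.0)
        assert y == pytest.approx(100.0)

    def test_joint_translation_invariance(self):
        cam1 = CameraState(viewport=(64, 64))
        shift = np.array([3.0, -2.0, 5.0])
        view2 = np.eye(4)
        view2[:3, 3] = -shift
        cam2 = CameraState(view=view2, viewport=(64, 64))
        p = np.array([0.5, 1.0, -10.0])
        assert particles.project(cam1, p) == pytest.approx(
            particles.project(cam2, p + shift)
        )

    def test_point_behind_camera_flagged(self):
        cam = CameraState()
        assert particles.project(cam, (0.0, 0.0, 1.0)) is None

    def test_singular_view_rejected(self):
        with pytest.raises(simdata.ValidationError):
            CameraState(view=np.zeros((4, 4)))


def _scene(positions, lives, decay=10.0):
    gids = list(range(len(positions)))
    circuit = {g: positions[g] for g in gids}
    state = ParticleState(np.array(gids), np.array(lives, dtype=float), 0.0, decay)
    return circuit, state


_OPAQUE_TF = TransferFunction(((0.0, (0.0, 0.0, 1.0, 1.0)), (1.0, (1.0, 0.0, 0.0, 1.0))))
_FLAT_SIZE = SizeFunction(((0.0, 6.0), (1.0, 6.0)))
_CAM32 = CameraState(viewport=(32, 32), fov_deg=90.0)


def painter_oracle(circuit, state, tf, sizef, camera, settings):
    """Brute-force per-pixel renderer: explicit painter's algorithm with the
    source-over rule, one pixel at a time."""
    w, h = camera.viewport
    img = [[list(settings.background) for _ in range(w)] for _ in range(h)]
    parts = []
    for i, g in enumerate(state.gids):
        if state.mode == "spike" and state.life[i] <= 0:
            continue
        proj = particles.project(camera, circuit[int(g)])
        if proj is None:
            continue
        x, y, d = proj
        parts.append((d, int(g), x, y, float(sizef(state.life[i])) / 2.0,
                      [float(c) for c in tf(state.life[i])]))
    parts.sort(key=lambda p: (-p[0], p[1]))  # far to near, gid ascending
    for d, g, x, y, r, src in parts:
        for py in range(h):
            for px in range(w):
                if (px + 0.5 - x) ** 2 + (py + 0.5 - y) ** 2 <= r * r:
                    dst = img[py][px]
                    sa = src[3]
                    for c in range(3):
                        dst[c] = src[c] * sa + dst[c] * (1 - sa)
                    dst[3] = sa + dst[3] * (1 - sa)
    return np.array(img)


class TestRendering:
    def test_empty_scene_is_background(self):
        circuit, state = _scene([(0.0, 0.0, -5.0)], [0.0])
        settings = RenderSettings(background=(0.1, 0.2, 0.3, 1.0))
        img = particles.render_frame(circuit, state, _OPAQUE_TF, _FLAT_SIZE,
                                     _CAM32, settings)
        assert np.all(img == np.array([0.1, 0.2, 0.3, 1.0]))

    @pytest.mark.parametrize("blend", ["traditional", "accumulative"])
    def test_single_opaque_particle_exact_rgb(self, blend):
        circuit, state = _scene([(0.0, 0.0, -5.0)], [1.0])
        img = particles.render_frame(circuit, state, _OPAQUE_TF, _FLAT_SIZE,
                                     _CAM32, RenderSettings(blend=blend))
        center = img[16, 16]
        np.testing.assert_allclose(center, [1.0, 0.0, 0.0, 1.0], atol=1e-12)

    def test_accumulative_is_permutation_invariant(self):
        pos = [(0.0, 0.0, -5.0), (0.1, 0.0, -6.0), (-0.1, 0.1, -4.0)]
        tf = TransferFunction(((0.0, (0.1, 0.2, 0.7, 0.4)),
                               (1.0, (0.9, 0.5, 0.1, 0.5))))
        circuit, state = _scene(pos, [0.3, 0.6, 0.9])
        settings = RenderSettings(blend="accumulative")
        img1 = particles.render_frame(circuit, state, tf, _FLAT_SIZE, _CAM32, settings)
        perm = [2, 0, 1]
        circuit2 = {i: pos[perm[i]] for i in range(3)}
        state2 = ParticleState(np.array([0, 1, 2]),
                               np.array([0.3, 0.6, 0.9])[perm][[0, 1, 2]], 0.0, 10.0)
        # same particles listed in a different order
        state2 = ParticleState(np.array(perm), state.life[perm], 0.0, 10.0)
        img2 = particles.render_frame(circuit, state2, tf, _FLAT_SIZE, _CAM32, settings)
        np.testing.assert_allclose(img1, img2, atol=1e-12)

    def test_two_semitransparent_overlap_hand_computed(self):
        # both on the axis, half alpha; far particle first, then near over it
        tf = TransferFunction(((0.0, (0.0, 0.0, 1.0, 0.5)),
                               (1.0, (1.0, 0.0, 0.0, 0.5))))
        circuit, state = _scene([(0.0, 0.0, -8.0), (0.0, 0.0, -4.0)], [1.0, 0.0])
        state.mode = "voltage"  # render both, including the zero-parameter one
        img = particles.render_frame(circuit, state, tf, _FLAT_SIZE, _CAM32,
                                     RenderSettings(blend="traditional",
                                                    background=(0, 0, 0, 1)))
        # far red over black: (0.5,0,0); near blue over that:
        # (0,0,1)*0.5 + (0.5,0,0)*0.5 = (0.25, 0, 0.5); alpha stays 1
        np.testing.assert_allclose(img[16, 16], [0.25, 0.0, 0.5, 1.0], atol=1e-12)

    @pytest.mark.parametrize("seed", range(6))
    def test_traditional_matches_painter_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 6))
        pos = [(float(rng.uniform(-2, 2)), float(rng.uniform(-2, 2)),
                float(rng.uniform(-9, -2))) for _ in range(n)]
        lives = rng.uniform(0.05, 1.0, n).tolist()
        tf = TransferFunction(((0.0, (0.1, 0.3, 0.9, 0.3)),
                               (1.0, (0.9, 0.2, 0.1, 0.8))))
        sf = SizeFunction(((0.0, 3.0), (1.0, 9.0)))
        circuit, state = _scene(pos, lives)
        settings = RenderSettings(blend="traditional",
                                  background=(0.05, 0.05, 0.1, 1.0))
        got = particles.render_frame(circuit, state, tf, sf, _CAM32, settings)
        want = painter_oracle(circuit, state, tf, sf, _CAM32, settings)
        np.testing.assert_allclose(got, want, atol=1e-9)

    def test_selection_context_rendering(self):
        circuit, state = _scene([(-1.0, 0.0, -5.0), (1.0, 0.0, -5.0)], [1.0, 1.0])
        settings = RenderSettings(
            blend="traditional",
            selection=simdata.Selection("only0", frozenset({0})),
            context_color=(0.5, 0.5, 0.5, 1.0),
            context_size=4.0,
        )
        img = particles.render_frame(circuit, state, _OPAQUE_TF, _FLAT_SIZE,
                                     _CAM32, settings)
        x0 = particles.project(_CAM32, circuit[0])[0]
        x1 = particles.project(_CAM32, circuit[1])[0]
        np.testing.assert_allclose(img[16, int(x0)], [1.0, 0.0, 0.0, 1.0])
        np.testing.assert_allclose(img[16, int(x1)], [0.5, 0.5, 0.5, 1.0])

    def test_vanishing_decay_shows_only_current_spikes(self):
        # blinking limit: with a very short decay only neurons spiking at
        # (essentially) the query instant remain lit
        report = simdata.SpikeReport.from_events(
            [(10.0, 0), (19.999, 1)], 0.0, 30.0
        )
        state = particles.seek(report, 20.0, decay=0.01, gids=[0, 1])
        assert state.life[0] == 0.0
        assert state.life[1] > 0.0

    def test_zero_viewport_is_error(self):
        with pytest.raises(simdata.ValidationError):
            CameraState(viewport=(0, 32))
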