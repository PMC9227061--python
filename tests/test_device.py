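import numpy as np
import pytest

from wellstation import LedState, PumpModel, Scene, StageState, VirtualDevice
from wellstation.device import (
    RenderModel,
    SceneCell,
    capture_video,
    dispense,
    move_to,
    render_frame,
)
from wellstation.focus import sharpness

WHITE = LedState(w=255)
RED = LedState(r=255)


class TestStage:
    def test_move_updates_position_exactly(self):
        s = move_to(StageState(), (10, 20, 5))
        assert (s.x, s.y, s.z) == (10, 20, 5)

    def test_moves_compose(self):
        s = move_to(move_to(StageState(), (10, 20, 5)), (100, 110, 30))
        assert (s.x, s.y, s.z) == (100, 110, 30)

    def test_out_of_volume_rejected(self):
        with pytest.raises(ValueError, match="z"):
            move_to(StageState(), (10, 10, 300))

    def test_move_to_current_position_zero_duration(self, layout12):
        dev = VirtualDevice(layout12)
        dev.move_to(50, 50, 10)
        t = dev.clock
        dev.move_to(50, 50, 10)
        assert dev.clock == t

    def test_homing_noise_once_per_homing(self, layout12):
        """The positioning error is drawn at homing, not per move."""
        dev = VirtualDevice(layout12, seed=3)
        dev.home()
        err = dev.stage.home_error
        assert err != (0.0, 0.0, 0.0)
        dev.move_to(50, 50, 10)
        assert dev.stage.x == pytest.approx(50 + err[0])
        dev.move_to(80, 50, 10)
        assert dev.stage.x == pytest.approx(80 + err[0])  # same residual

    def test_homing_deviation_scale(self, layout12):
        """Homing deviations match the configured per-axis sigmas (µm)."""
        dev = VirtualDevice(layout12, seed=0)
        errs = []
        for _ in range(300):
            dev.home()
            errs.append(dev.stage.home_error)
        sd_um = np.std(np.array(errs), axis=0, ddof=1) * 1000
        assert sd_um == pytest.approx((22, 11, 2), rel=0.25)


class TestPump:
    def test_zero_error_is_exact(self):
        pump = PumpModel(relative_error_sd=0.0)
        assert dispense(pump, 1.0, np.random.default_rng(0)) == 1.0

    def test_nonpositive_volume_rejected(self):
        with pytest.raises(ValueError):
            dispense(PumpModel(), 0.0, np.random.default_rng(0))

    def test_mean_and_spread_recover_configuration(self):
        """10k draws at 1 mL: mean 1.0 mL, relative SD near the 3.5 % setting."""
        rng = np.random.default_rng(42)
        pump = PumpModel()
        vols = np.array([dispense(pump, 1.0, rng) for _ in range(10_000)])
        assert vols.mean() == pytest.approx(1.0, abs=0.002)
        assert np.std(vols - 1.0, ddof=1) == pytest.approx(0.035, abs=0.002)


def _one_cell_scene(**kw) -> Scene:
    cell = SceneCell(center=(0.0, 0.0, 2600.0), radius=5.0, **kw)
    return Scene(cells=[cell], column_depth=2600.0, rng_seed=1)


class TestRendering:
    def test_empty_scene_is_noise_floor(self):
        render = RenderModel(noise_sd=1.0)
        img = render_frame(Scene(cells=[], rng_seed=0), render, StageState(z=5.0), WHITE)
        # variance-of-Laplacian of pure sensor noise: sigma^2 * sum(kernel^2) = 20
        assert sharpness(img) < 60

    def test_in_focus_sharper_than_defocused(self):
        render = RenderModel(noise_sd=0.0)
        scene = _one_cell_scene()
        sharp = render_frame(scene, render, StageState(z=render.focal_offset), WHITE)
        blurry = render_frame(scene, render, StageState(z=render.focal_offset - 1.0), WHITE)
        assert sharpness(sharp) > sharpness(blurry)

    def test_sharpness_peaks_at_top_layer(self):
        """A deep cell never outscores a top-layer cell at the surface focus."""
        render = RenderModel(noise_sd=0.0)
        deep = Scene(
            cells=[SceneCell(center=(0, 0, 600.0), radius=5.0)],
            column_depth=2600.0,
            rng_seed=1,
        )
        top = _one_cell_scene()
        z = render.focal_offset
        assert sharpness(render_frame(top, render, StageState(z=z), WHITE)) > sharpness(
            render_frame(deep, render, StageState(z=z), WHITE)
        )

    def test_background_follows_leds(self):
        render = RenderModel(noise_sd=0.0)
        empty = Scene(cells=[], rng_seed=0)
        dark = render_frame(empty, render, StageState(z=5), LedState())
        lit = render_frame(empty, render, StageState(z=5), WHITE)
        assert lit.mean() > dark.mean() + 100

    def test_bright_field_cells_darker_than_background(self):
        render = RenderModel(noise_sd=0.0)
        img = render_frame(_one_cell_scene(), render, StageState(z=5), WHITE)
        h, w = img.shape
        assert img[h // 2, w // 2] < img[5, 5] - 50


class TestPhotoresponse:
    def test_red_light_speed_constant(self):
        scene = _one_cell_scene(velocity=(20.0, 0, 0))
        assert not scene.triggered_by(RED)
        assert scene.true_speeds(0.0)[0] == scene.true_speeds(0.0)[0]
        # positions advance linearly under red light
        p0 = scene.positions_at(0.0)
        p300 = scene.positions_at(300.0, exposed_s=0.0)
        assert p300[0, 0] - p0[0, 0] == pytest.approx(20.0 * 300)

    def test_white_light_arrests_motion_by_300s(self):
        scene = _one_cell_scene(velocity=(20.0, 0, 0))
        assert scene.triggered_by(WHITE)
        assert scene.speed_factor(300.0) < 0.05

    def test_displacement_saturates_under_trigger_light(self):
        """Total travel under constant trigger light approaches v*tau."""
        scene = _one_cell_scene(velocity=(20.0, 0, 0))
        p = scene.positions_at(600.0, exposed_s=600.0)
        assert p[0, 0] == pytest.approx(20.0 * scene.speed_decay_tau, rel=0.01)


class TestVideo:
    def test_frame_count(self):
        frames = capture_video(
            Scene(cells=[], rng_seed=0), RenderModel(), StageState(z=5), WHITE, 1.0, 30.0
        )
        assert len(frames) == 30

    def test_static_cells_identical_up_to_noise(self):
        render = RenderModel(noise_sd=0.0)
        frames = capture_video(_one_cell_scene(), render, StageState(z=5), RED, 0.2, 30.0)
        assert all(np.array_equal(frames[0], f) for f in frames[1:])

    def test_centroid_drift_matches_velocity(self):
        """15 µm/s at 0.5 µm/px and 30 fps drifts 1 px per frame."""
        render = RenderModel(noise_sd=0.0)
        scene = _one_cell_scene(velocity=(15.0, 0, 0))
        frames = capture_video(scene, render, StageState(z=5), RED, 10 / 30, 30.0)

        def centroid_x(img):
            inv = np.clip(np.median(img) - img.astype(float), 0, None)
            xs = np.arange(img.shape[1])
            return (inv.sum(axis=0) * xs).sum() / inv.sum()

        drift = np.diff([centroid_x(f) for f in frames])
        assert drift == pytest.approx(np.ones(9), abs=0.05)

    def test_seeded_reproducibility_bit_identical(self):
        a = capture_video(_one_cell_scene(), RenderModel(), StageState(z=5), WHITE, 0.2, 30)
        b = capture_video(_one_cell_scene(), RenderModel(), StageState(z=5), WHITE, 0.2, 30)
        assert all(np.array_equal(x, y) for x, y in zip(a, b))


class TestSceneValidation:
    def test_cell_outside_column_rejected(self):
        with pytest.raises(ValueError, match="column"):
            Scene(cells=[SceneCell(center=(0, 0, 9000.0), radius=5.0)], column_depth=2600.0)

    def test_nonpositive_radius_rejected(self):
        with pytest.raises(ValueError, match="radius"):
            Scene(cells=[SceneCell(center=(0, 0, 100.0), radius=0.0)])


class TestDeviceContract:
    def test_capture_over_well_uses_scene(self, layout12):
        from wellstation.plate_geometry import WellAddress, well_to_stage

        addr = WellAddress(1, 1)
        dev = VirtualDevice(
            layout12, scenes={addr: _one_cell_scene()}, render=RenderModel(noise_sd=0.0)
        )
        wx, wy = well_to_stage(layout12, addr)
        dev.set_led(addr, (0, 0, 0, 255))
        dev.move_to(wx, wy, dev.render.focal_offset)
        img = dev.capture()
        h, w = img.shape
        assert img[h // 2, w // 2] < img[5, 5] - 50  # the cell is visible

    def test_clock_advances_with_actions(self, layout12):
        dev = VirtualDevice(layout12)
        dev.move_to(50, 0, 0)  # 50 mm at 50 mm/s
        assert dev.clock == pytest.approx(1.0)
        dev.dispense(1.0)  # 1 mL at 0.5 mL/s
        assert dev.clock == pytest.approx(3.0)
        dev.capture()
        assert dev.clock == pytest.approx(3.0 + dev.capture_s)
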