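import json

import numpy as np
import pytest

from wellstation import (
    TimingModel,
    VirtualDevice,
    WellAddress,
    estimate_runtime,
    execute,
    safe_position,
    validate,
)
from wellstation.automation import ScriptError
from wellstation.device import WORKING_VOLUME_MM
from wellstation.fixtures import DEMO_SEQ_SCRIPT, MAX_THROUGHPUT_SCRIPT


class TestValidate:
    def test_demo_sequence(self):
        """The three-well demo script: per-well volumes, colours and delays."""
        s = validate(DEMO_SEQ_SCRIPT)
        assert s.name == "DemoSeq"
        assert s.pos == [WellAddress(0, 0), WellAddress(2, 3), WellAddress(3, 0)]
        assert s.volume == [1.0, 2.0, 3.0]
        assert s.delay == [30.0, 60.0, 0.0]
        assert s.light[0] == (255, 0, 0, 0) and s.light[2] == (0, 0, 255, 0)
        assert s.trash and s.sampling and s.capture

    def test_throughput_script_broadcasts_singletons(self):
        s = validate(MAX_THROUGHPUT_SCRIPT)
        assert len(s.pos) == 24
        assert s.volume == [1.0] * 24
        assert s.light == [(0, 0, 0, 255)] * 24
        assert s.delay == [0.0] * 24
        assert not s.trash

    @pytest.mark.parametrize("key", ["name", "pos"])
    def test_missing_required_key_named_in_error(self, key):
        obj = json.loads(DEMO_SEQ_SCRIPT)
        del obj[key]
        with pytest.raises(ScriptError, match=f'"{key}"'):
            validate(obj)

    def test_sampling_without_volume_names_volume(self):
        obj = json.loads(DEMO_SEQ_SCRIPT)
        del obj["volume"]
        with pytest.raises(ScriptError, match='"volume"'):
            validate(obj)

    def test_bad_list_length_is_shape_error(self):
        obj = json.loads(DEMO_SEQ_SCRIPT)
        obj["volume"] = [1, 2]  # neither 1 nor 3 entries
        with pytest.raises(ScriptError, match="1 or 3"):
            validate(obj)

    def test_unknown_key_warns_but_passes(self):
        obj = json.loads(DEMO_SEQ_SCRIPT)
        obj["frobnicate"] = True
        with pytest.warns(UserWarning, match="frobnicate"):
            s = validate(obj)
        assert s.name == "DemoSeq"

    def test_missing_delay_defaults_to_zero(self):
        s = validate({"name": "Fill", "pos": [[0, 0], [1, 0]], "sampling": True, "volume": [1]})
        assert s.delay == [0.0, 0.0]

    def test_normalization_idempotent(self):
        s1 = validate(DEMO_SEQ_SCRIPT)
        s2 = validate(
            {
                "name": s1.name,
                "pos": [[a.x, a.y] for a in s1.pos],
                "sampling": s1.sampling,
                "volume": s1.volume,
                "capture": s1.capture,
                "light": [list(l) for l in s1.light],
                "delay": s1.delay,
                "trash": s1.trash,
            }
        )
        assert s1 == s2


class TestEstimate:
    def test_delays_dominate_lower_bound(self, layout12):
        s = validate({"name": "waits", "pos": [[0, 0], [1, 0]], "delay": [100, 200]})
        assert estimate_runtime(s, layout12) >= 300

    def test_demo_estimate_covers_scripted_delays(self, layout12):
        s = validate(DEMO_SEQ_SCRIPT)
        assert estimate_runtime(s, layout12) >= 90

    @pytest.mark.parametrize("script_text", [DEMO_SEQ_SCRIPT, MAX_THROUGHPUT_SCRIPT])
    def test_matched_timing_within_10_percent_of_simulation(self, layout12, script_text):
        """With timing constants matching the simulator, |sim/est - 1| <= 0.1."""
        script = validate(script_text)
        dev = VirtualDevice(layout12, seed=1)
        report = execute(script, dev, out_dir="/tmp/ws_est_check")
        est = estimate_runtime(script, layout12, TimingModel.from_device(dev))
        assert report.completed
        assert report.elapsed / est == pytest.approx(1.0, abs=0.1)


class TestExecute:
    def test_demo_seq_produces_named_images(self, layout12, tmp_path):
        script = validate(DEMO_SEQ_SCRIPT)
        dev = VirtualDevice(layout12, seed=2)
        report = execute(script, dev, out_dir=tmp_path)
        assert report.completed
        assert report.images == ["DemoSeqX0Y0.png", "DemoSeqX2Y3.png", "DemoSeqX3Y0.png"]
        for name in report.images:
            assert (tmp_path / name).exists()
        assert len(report.dispensed) == 3
        # delays between wells are honoured in simulated time
        assert report.elapsed >= 90

    def test_throughput_24_images_and_parked(self, layout12, tmp_path):
        script = validate(MAX_THROUGHPUT_SCRIPT)
        dev = VirtualDevice(layout12, seed=2)
        report = execute(script, dev, out_dir=tmp_path)
        assert report.completed
        assert len(report.images) == 24
        assert len(set(report.images)) == 24
        # afterwards: all LEDs off and stage at the safe corner
        assert all(not led.any_on() for led in dev.leds.values())
        assert dev.stage.x == pytest.approx(WORKING_VOLUME_MM[0], abs=0.5)
        assert dev.stage.y == pytest.approx(WORKING_VOLUME_MM[1], abs=0.5)
        assert dev.stage.z == pytest.approx(WORKING_VOLUME_MM[2], abs=0.5)

    def test_no_actions_still_cycles_and_reports(self, layout12, tmp_path):
        script = validate({"name": "noop", "pos": [[0, 0], [1, 1]]})
        dev = VirtualDevice(layout12, seed=0)
        report = execute(script, dev, out_dir=tmp_path)
        assert report.completed
        assert report.images == []
        assert report.elapsed > 0

    def test_determinism_same_seed_same_report(self, layout12, tmp_path):
        script = validate(DEMO_SEQ_SCRIPT)
        r1 = execute(script, VirtualDevice(layout12, seed=7), out_dir=tmp_path / "a")
        r2 = execute(script, VirtualDevice(layout12, seed=7), out_dir=tmp_path / "b")
        assert r1.dispensed == r2.dispensed
        assert r1.elapsed == r2.elapsed
        assert r1.images == r2.images

    def test_device_error_yields_partial_report(self, layout12, tmp_path):
        script = validate(
            {"name": "bad", "pos": [[0, 0], [99, 0]], "capture": True}
        )  # second address off the holder
        dev = VirtualDevice(layout12, seed=0)
        report = execute(script, dev, out_dir=tmp_path)
        assert not report.completed
        assert report.error is not None
        assert len(report.images) == 1  # first well succeeded

    def test_notify_hook_called(self, layout12, tmp_path):
        seen = []
        script = validate({"name": "n", "pos": [[0, 0]]})
        execute(script, VirtualDevice(layout12), out_dir=tmp_path, notify=seen.append)
        assert len(seen) == 1 and seen[0].script_name == "n"


class TestSafePosition:
    def test_idempotent_and_in_volume(self, layout12):
        dev = VirtualDevice(layout12, seed=0)
        safe_position(dev)
        pose1 = (dev.stage.x, dev.stage.y, dev.stage.z)
        safe_position(dev)
        assert (dev.stage.x, dev.stage.y, dev.stage.z) == pose1
        assert pose1[0] <= WORKING_VOLUME_MM[0] + 0.1
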