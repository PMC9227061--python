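import pytest

from wellstation import Calibration, PlateFormat, PlateLayout


@pytest.fixture
def layout12() -> PlateLayout:
    """Two 12-well plates on the holder — the instrument's standard setup."""
    return PlateLayout(format=PlateFormat.standard(12))


@pytest.fixture
def cal_05() -> Calibration:
    """The 2.8 mm-lens calibration: 0.5 µm/px at 1920x1080."""
    return Calibration(um_per_px=0.5, image_size=(1920, 1080))
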