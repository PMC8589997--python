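import numpy as np
import pytest

import phasorflim as pf


@pytest.fixture(scope="session")
def meta() -> pf.AcquisitionMeta:
    return pf.AcquisitionMeta()


@pytest.fixture(scope="session")
def shg_calibrator(meta):
    """Calibration fitted on a noise-free zero-lifetime reference."""
    return pf.calibrate_channels({"NADPH": meta})["NADPH"]


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def foreground_iou(mask, truth_labels) -> float:
    fg, truth = mask.foreground, truth_labels > 0
    union = (fg | truth).sum()
    return float((fg & truth).sum() / union) if union else 1.0
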