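import numpy as np
import pytest

from scpredict import GeneratorConfig, LabelVolume, generate_benchmark


@pytest.fixture(scope="session")
def small_benchmark():
    """Small null dataset reused by read-only tests."""
    return generate_benchmark(
        GeneratorConfig(n_rois=10, n_subjects=60, effect_r2=0.0, seed=3)
    )


@pytest.fixture()
def toy_labels():
    """Hand-crafted 5-region volume on a 6x6x1 grid with background."""
    labels = np.zeros((6, 6, 1), dtype=np.int32)
    labels[0:2, 0:3, 0] = 1
    labels[0:2, 3:6, 0] = 2
    labels[2:4, 0:3, 0] = 3
    labels[2:4, 3:6, 0] = 4
    labels[4:6, 0:3, 0] = 5
    # rows 4-5, cols 3-5 stay background (0)
    return LabelVolume(labels)
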