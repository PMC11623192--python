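import numpy as np
import pandas as pd
import pytest

from vitalwatch.frames import SensorFrame
from vitalwatch.synthgen import ChannelSpec, generate_baseline


@pytest.fixture
def table1_heart_rate() -> np.ndarray:
    """Heart-rate column of the canonical bedside-monitor sample table."""
    return np.array([72.0, 75.0, 73.0, 74.0, 76.0])


@pytest.fixture
def hr_frame(table1_heart_rate) -> SensorFrame:
    return SensorFrame(
        pd.DataFrame({"time": np.arange(5.0), "heart_rate": table1_heart_rate})
    )


@pytest.fixture
def small_stream() -> SensorFrame:
    specs = [
        ChannelSpec("heart_rate", 74.0, 1.5, ar_coefficient=0.6, units="bpm"),
        ChannelSpec("spo2", 98.0, 0.4, ar_coefficient=0.5, units="%"),
    ]
    return generate_baseline(specs, 400, seed=5)
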