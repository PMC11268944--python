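import numpy as np
import pytest

from sdmkit.config import DEFAULT_THRESHOLDS
from sdmkit.model import (
    DeviceSource,
    Level,
    RawDataSet,
    Reading,
    ValueDefinition,
)
from sdmkit.registry import default_registry

TS = ValueDefinition("ts", "timestamp", "s", "timestamp")


def make_dataset(ds_id="data", timestamps=(0.0, 0.1, 0.2), values=None,
                 value_id="v", fs=None):
    cols = [TS, ValueDefinition(value_id, "value", "")]
    if values is None:
        values = [0.0] * len(timestamps)
    return RawDataSet(
        ds_id,
        DeviceSource("test", "sensor", fs, "none"),
        cols,
        [list(timestamps), list(values)],
    )


def make_reading(code="tap", n_levels=1, modalities=None, datasets=None):
    levels = []
    for k in range(n_levels):
        mods = modalities[k] if modalities else []
        level = Level(
            id="_".join(m.value for m in mods) or f"level{k}",
            modalities=mods,
            start=0.0,
            end=1.0,
        )
        for ds in (datasets[k] if datasets else [make_dataset()]):
            level.add_dataset(ds)
        levels.append(level)
    return Reading(
        evaluation_code=code, subject_id="subj001", session_id=f"{code}_001",
        levels=levels,
    )


@pytest.fixture(scope="session")
def registry():
    return default_registry(DEFAULT_THRESHOLDS)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
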