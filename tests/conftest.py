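import numpy as np
import pytest

from ecwsp import io, synthetic
from ecwsp.io import WavelengthGrid
from ecwsp.synthetic import InformativeBand, Peak, SyntheticConfig


def small_config(seed: int = 0) -> SyntheticConfig:
    """3-class toy conditions on a 31-point grid; fast enough for any test."""
    return SyntheticConfig(
        grid=WavelengthGrid(400.0, 460.0, 2.0),
        class_labels=(1, 2, 3),
        shared_peaks=(Peak(430.0, 30.0, 0.5),),
        informative_bands=(
            InformativeBand(412.0, 4.0, (0.0, 0.08, 0.0)),
            InformativeBand(448.0, 4.0, (0.0, 0.0, 0.08)),
        ),
        noise_sd=0.01,
        noise_correlation_length=4.0,
        bottle_offset_sd=0.002,
        bottles_per_class=6,
        samples_per_bottle=2,
        replicates_per_sample=2,
        seed=seed,
    )


@pytest.fixture
def small_dataset():
    """Split 3-class toy dataset (6 bottles/class -> 3/2/1 bottles)."""
    ds, truth = synthetic.generate(small_config(0))
    ds = io.grouped_split(ds, io.uniform_split_plan(ds, seed=0))
    return ds, truth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
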