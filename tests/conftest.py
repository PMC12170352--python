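import numpy as np
import pytest

from elemtraj.core import ElementRecord, TransformedRecord
from elemtraj.synthetic import generate, preset


@pytest.fixture
def toy_record() -> ElementRecord:
    """Small valid record: 6 samples, one organic + two terrigenous elements."""
    rng = np.random.default_rng(7)
    ages = np.array([100.0, 150.0, 220.0, 300.0, 410.0, 500.0])
    values = rng.uniform(1.0, 100.0, size=(6, 3))
    return ElementRecord("toy", ages, ["C", "Fe", "Ti"], values)


@pytest.fixture
def step_trec() -> TransformedRecord:
    """1-D two-level series: three samples at 0 then three at 1."""
    vals = np.array([0.0, 0.0, 0.0, 1.0, 1.0, 1.0])[:, None]
    return TransformedRecord(
        "step",
        ages=np.array([10.0, 20.0, 30.0, 40.0, 50.0, 60.0]),
        elements=["Fe"],
        values=vals,
        provenance={"Fe": (0.0, 1.0)},
    )


def make_trec(values, ages=None, record_id="t") -> TransformedRecord:
    """Wrap a raw matrix (assumed already in [0,1]) as a TransformedRecord."""
    values = np.asarray(values, dtype=float)
    if ages is None:
        ages = np.arange(len(values), dtype=float)
    elements = [f"e{j}" for j in range(values.shape[1])]
    return TransformedRecord(
        record_id,
        ages=np.asarray(ages, dtype=float),
        elements=elements,
        values=values,
        provenance={e: (0.0, 1.0) for e in elements},
    )


@pytest.fixture
def shallow_record():
    return generate(preset("shallow_small"))


@pytest.fixture
def stationary_record():
    return generate(preset("stationary"))
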