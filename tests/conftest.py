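import numpy as np
import pytest

from fastpetdn.phantom import (
    Lesion,
    NoiseParams,
    PhantomSpec,
    build_activity_map,
    build_label_mask,
)
from fastpetdn.volio import Volume


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_volume(rng) -> Volume:
    """A random 12^3 SUV-scale volume."""
    return Volume(rng.uniform(0.5, 3.0, size=(12, 12, 12)).astype(np.float32), (4.0, 4.0, 4.0))


@pytest.fixture(scope="session")
def default_phantom() -> PhantomSpec:
    """Desk-scale phantom with one conspicuous and one faint lesion."""
    spec = PhantomSpec(seed=99)
    cx, cy, cz = spec.body.center_mm
    spec.lesions = [
        Lesion(1, (cx - 40, cy, cz - 60), 26.0, 5.0),
        Lesion(2, (cx + 40, cy, cz + 40), 16.0, 2.8),
    ]
    spec.validate()
    return spec


@pytest.fixture(scope="session")
def phantom_truth(default_phantom) -> Volume:
    return build_activity_map(default_phantom)


@pytest.fixture(scope="session")
def phantom_labels(default_phantom):
    return build_label_mask(default_phantom)
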