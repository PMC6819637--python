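import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from morfmpm.features import (
    KIND_SCALE,
    KIND_SHANNON,
    KIND_TOPOLOGICAL,
    FeatureDescriptor,
    FeatureSet,
    ScaleRegistry,
    default_feature_set,
    load_default_registry,
)
from morfmpm.io_formats import AAINDEX_ORDER, PropertyScale

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def registry() -> ScaleRegistry:
    return load_default_registry()


@pytest.fixture(scope="session")
def feature_set() -> FeatureSet:
    return default_feature_set()


def make_scale(accession: str, values) -> PropertyScale:
    """A scale from 20 values in canonical order (or a constant)."""
    if np.isscalar(values):
        values = [values] * 20
    return PropertyScale(
        accession=accession, values=dict(zip(AAINDEX_ORDER, map(float, values)))
    )


@pytest.fixture(scope="session")
def toy_registry() -> ScaleRegistry:
    """Hand-valued scales for exact arithmetic: 'unit' is A=1, C=3, others 0;
    'const' is 2 everywhere; 'ramp' is 0..19 in canonical order."""
    unit = {aa: 0.0 for aa in AAINDEX_ORDER}
    unit["A"], unit["C"] = 1.0, 3.0
    return ScaleRegistry(
        [
            PropertyScale(accession="unit", values=unit),
            make_scale("const", 2.0),
            make_scale("ramp", range(20)),
        ]
    )


@pytest.fixture(scope="session")
def toy_feature_set() -> FeatureSet:
    return FeatureSet(
        descriptors=(
            FeatureDescriptor(kind=KIND_SCALE, name="unit", scale_ref="unit"),
            FeatureDescriptor(kind=KIND_SHANNON, name="shannon"),
            FeatureDescriptor(kind=KIND_TOPOLOGICAL, name="topo"),
        )
    )


def random_sequence(rng, length: int) -> str:
    return "".join(rng.choice(list(AAINDEX_ORDER), size=length))
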