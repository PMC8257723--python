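import numpy as np
import pytest

from kneequant.phantom import PhantomSpec, make_knee_phantom
from kneequant.geometry import quantify_volume


@pytest.fixture(scope="session")
def tiny_spec() -> PhantomSpec:
    """A compact phantom used across the suite; same spacing as the target
    acquisition, grid cropped tight around the joint for speed."""
    return PhantomSpec(
        volume_shape=(64, 64, 160), condyle_radius_mm=5.0, plateau_extent_mm=12.0
    )


@pytest.fixture(scope="session")
def tiny_phantom(tiny_spec):
    return make_knee_phantom(tiny_spec)


@pytest.fixture(scope="session")
def tiny_metrics(tiny_phantom):
    return quantify_volume(tiny_phantom)


def metric_value(df, bone, region, metric):
    sel = df[(df.bone == bone) & (df.region == region) & (df.metric == metric)]
    assert len(sel) == 1
    return float(sel.value.iloc[0])
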