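import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(20230915)


def make_simple_seg(
    plateau_x_hi=9,
    meniscus_x=(7, 12),
    n_slices=3,
    height=2,
    spacing=(1.0, 1.0, 1.0),
    nx=None,
):
    """Slab compartment: plateau x in [0, plateau_x_hi], meniscus x in
    meniscus_x (inclusive), identical in every slice."""
    from meniquant import SegmentedCompartment

    lo, hi = meniscus_x
    nx = nx or max(plateau_x_hi, hi) + 2
    men = np.zeros((n_slices, height + 1, nx), dtype=bool)
    plat = np.zeros((n_slices, nx), dtype=bool)
    men[:, :height, lo: hi + 1] = True
    plat[:, : plateau_x_hi + 1] = True
    return SegmentedCompartment(men, plat, spacing=spacing)


@pytest.fixture
def simple_seg():
    return make_simple_seg()
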