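import numpy as np
import pytest

from uspioquant.phantom import (
    DEFAULT_ECHO_TIMES_MS, Ellipse, PhantomSpec, Rect, TissueParams,
)

ECHO_TIMES = np.asarray(DEFAULT_ECHO_TIMES_MS)


@pytest.fixture
def echo_times():
    """The emulated acquisition's 7-echo train (ms)."""
    return ECHO_TIMES.copy()


def small_two_tissue_spec(noise_sigma: float = 0.0, seed: int = 0) -> PhantomSpec:
    """A 40x48 two-tissue phantom that fits in well under a second."""
    fast = TissueParams("graft_kidney", s0=1000.0, r2star_pre=80.0, delta_r2star=30.0)
    slow = TissueParams("native_kidney", s0=900.0, r2star_pre=40.0, delta_r2star=15.0)
    return PhantomSpec(
        tissue_layout=(
            (Ellipse(center=(12.0, 14.0), radii=(8.0, 9.0)), fast),
            (Rect(rows=(25, 37), cols=(28, 44)), slow),
        ),
        matrix=(40, 48), fov_mm=(10.0, 12.0),
        noise_sigma=noise_sigma, seed=seed,
    )


@pytest.fixture
def two_tissue_spec():
    return small_two_tissue_spec()
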