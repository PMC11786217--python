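import numpy as np
import pytest

from bmrano.mask_ops import Mask3D
from bmrano.synthetic import (
    TrueLesionState,
    default_analysis_config,
    generate_cohort,
    render_lesion_mask,
)

ANALYSIS_SEED = 1  # fixed seed of the default analysis cohort


def sphere_state(radius: float = 10.0) -> TrueLesionState:
    return TrueLesionState(
        center=(0.0, 0.0, 0.0),
        semi_axes=(radius,) * 3,
        orientation=(0.0, 0.0, 0.0),
        true_volume=4 / 3 * np.pi * radius**3,
        time_days=0.0,
    )


@pytest.fixture(scope="session")
def sphere_mask() -> Mask3D:
    """Digitized sphere of radius 10 mm on a 1 mm grid."""
    return render_lesion_mask(sphere_state(10.0), spacing=1.0)


@pytest.fixture(scope="session")
def default_cohort():
    """The ~200-lesion analysis cohort at the fixed seed (shared, read-only)."""
    return generate_cohort(default_analysis_config(seed=ANALYSIS_SEED))


@pytest.fixture(scope="session")
def rotation_stability_result(default_cohort):
    """Rotation stability over the default cohort (expensive; computed once)."""
    from bmrano.pipeline import rotation_stability

    return rotation_stability(default_cohort)


def random_small_mask(rng: np.random.Generator) -> Mask3D:
    """Random small blob mask for oracle comparisons."""
    shape = tuple(rng.integers(4, 12, size=3))
    occ = rng.random(shape) < rng.uniform(0.2, 0.7)
    if not occ.any():
        occ[tuple(s // 2 for s in shape)] = True
    return Mask3D(occ, (1.0, 1.0, 1.0))
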