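import numpy as np
import pytest

import isoassign as ia


@pytest.fixture(scope="session")
def world():
    """Small synthetic world: (grids, truth cluster map), fixed seed."""
    spec = ia.SyntheticWorldSpec(shape=(40, 40), seed=11)
    return ia.make_isoscapes(spec)


@pytest.fixture(scope="session")
def stack(world):
    grids, _ = world
    return ia.align_stack(grids)


@pytest.fixture(scope="session")
def separated_summary():
    """Cluster summary with strongly separated means relative to the default
    feather covariance (Mahalanobis separation >> 1), so assignments are
    near-deterministic — the regime of the published cohort."""
    means = np.array([
        [-20.0, -14.0, 12.0],
        [-80.0, -20.0, 7.0],
        [-140.0, -26.0, 2.0],
        [-200.0, -32.0, 16.0],
    ])
    sds = np.array([[5.0, 0.5, 0.4]] * 4)
    return ia.ClusterSummary(np.arange(1, 5), ("d2h", "d13c", "d15n"),
                             means, sds, np.array([400, 300, 200, 100]))


@pytest.fixture(scope="session")
def overlapping_summary(stack, world):
    """Zonal summary of the synthetic world's own clusters (partial overlap)."""
    _, truth = world
    return ia.zonal_summaries(stack, truth)


def exact_moment_sample(mean: float, sd: float, n: int) -> np.ndarray:
    """n values with exactly the requested sample mean and (ddof=1) SD."""
    base = np.linspace(-1.0, 1.0, n)
    base -= base.mean()
    base /= base.std(ddof=1)
    return mean + sd * base
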