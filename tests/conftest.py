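import numpy as np
import pytest

from coexpmi import (
    BinningConfig,
    CoexpressionIndex,
    ExpressionMatrix,
    simulate_matrix,
)

# Five-point worked examples: the same (x, y) multiset arranged once on a
# line (r = 0.8) and once with the y-positions permuted so the linear trend
# vanishes while the point-for-point predictability is untouched.
FIVE_X = np.array([0.1, 0.3, 0.5, 0.7, 0.9])
FIVE_Y_LINEAR = np.array([0.3, 0.1, 0.5, 0.9, 0.7])
FIVE_Y_SHUFFLED = np.array([0.3, 0.9, 0.5, 0.1, 0.7])


@pytest.fixture
def five_point_linear():
    return FIVE_X.copy(), FIVE_Y_LINEAR.copy()


@pytest.fixture
def five_point_shuffled():
    return FIVE_X.copy(), FIVE_Y_SHUFFLED.copy()


@pytest.fixture
def fixed5():
    """Five equal-width intervals over [0, 1] on each axis."""
    return BinningConfig(mode="fixed", n_bins=5, range_low=0.0, range_high=1.0)


@pytest.fixture
def five_point_matrix(five_point_linear):
    x, y = five_point_linear
    return ExpressionMatrix(["X", "Y"], [f"s{i}" for i in range(5)], np.vstack([x, y]))


# Shared synthetic cohort for rank-pattern checks: a latent-factor
# background (most probe pairs genuinely dependent, as in a real expression
# compendium) plus one planted pair per dependency kind.  Session-scoped:
# the all-pairs index build is the expensive part.
COHORT_SEED = 0
COHORT_PROBES = 48
COHORT_SAMPLES = 400


@pytest.fixture(scope="session")
def cohort():
    return simulate_matrix(
        COHORT_PROBES, COHORT_SAMPLES, kind="latent_factor",
        planted=("linear", "permuted_dependency", "independent"),
        seed=COHORT_SEED,
    )


@pytest.fixture(scope="session")
def cohort_index(cohort):
    return CoexpressionIndex.build(cohort)
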