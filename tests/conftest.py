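import numpy as np
import pytest

from dtiq import CohortSpec, PhantomSpec, generate_cohort, make_gradient_scheme


@pytest.fixture(scope="session")
def scheme30():
    """Default-style single-shell scheme: 30 directions at b = 1000."""
    return make_gradient_scheme(30, 1000.0, seed=11)


@pytest.fixture(scope="session")
def small_phantom():
    """Reduced phantom for fast cohort tests."""
    return PhantomSpec(grid=(16, 16, 3), n_directions=12)


@pytest.fixture(scope="session")
def small_cohort(small_phantom):
    """One reduced default-design cohort (3 groups x 6 subjects x 2 days)."""
    return generate_cohort(small_phantom, CohortSpec(n_per_group=6, seed=42))


def random_physical_tensors(n, rng, scale=1e-3):
    """Random physical tensors: eigenvalues uniform in [0, 2.5*scale],
    conjugated by random rotations.  Returns (n, 6) canonical components."""
    from scipy.stats import special_ortho_group

    from dtiq import tensor_from_matrix

    evals = rng.uniform(0.0, 2.5 * scale, size=(n, 3))
    rots = special_ortho_group.rvs(3, size=n, random_state=rng)
    mats = np.einsum("nij,nj,nkj->nik", rots, evals, rots)
    return tensor_from_matrix(mats)
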