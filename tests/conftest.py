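import numpy as np
import pytest

from conemosaic.lattice import make_lattice_spec
from conemosaic import synthetic as syn


@pytest.fixture(scope="session")
def spec():
    return make_lattice_spec()


@pytest.fixture(scope="session")
def alpha(spec):
    return 2.0 * spec.a_col / spec.a_row


@pytest.fixture(scope="session")
def clean_sample(spec, alpha):
    """Two well-separated planted insertions on a quiet frustum."""
    sched = syn.CustomSchedule([(14, 0.3 * alpha, "Y"), (14, 0.7 * alpha, "Y")])
    return syn.build_frustum_mosaic(spec, 120, 28, insertion_mode=sched, seed=0)


@pytest.fixture(scope="session")
def glide_sample(spec, alpha):
    """Two-defect sample with room around the cores for glide analysis."""
    sched = syn.CustomSchedule([(10, 0.3 * alpha, "Y"), (10, 0.7 * alpha, "Y")])
    return syn.build_frustum_mosaic(spec, 120, 20, insertion_mode=sched, seed=0)


@pytest.fixture(scope="session")
def cylinder_sample(spec):
    return syn.build_frustum_mosaic(spec, 40, 20, sector_angle=0.0, seed=1)


@pytest.fixture(scope="session")
def clustered_sample(spec):
    return syn.build_frustum_mosaic(spec, 200, 95,
                                    insertion_mode=syn.GrainBoundaryMode(4, 0.5),
                                    seed=1)


@pytest.fixture(scope="session")
def uniform_sample(spec):
    return syn.build_frustum_mosaic(spec, 200, 95, seed=1)


def match_cores_to_truth(cores_xy, truth_xy, tol):
    """One-to-one matching count between detected cores and planted truth."""
    from scipy.optimize import linear_sum_assignment

    if len(cores_xy) == 0 or len(truth_xy) == 0:
        return 0
    D = np.hypot(*(np.asarray(cores_xy)[:, None, :]
                   - np.asarray(truth_xy)[None, :, :]).transpose(2, 0, 1))
    cost = np.where(D < tol, D, 1e6)
    ri, ci = linear_sum_assignment(cost)
    return int(np.sum(cost[ri, ci] < 1e5))
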