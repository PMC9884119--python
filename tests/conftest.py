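import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from embryoquant import (SyntheticEmbryoSpec, make_cohort, render_stack,
                         segment_stack)

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


#: Reduced geometry for unit tests: fewer nuclei, smaller field of view,
#: same voxel calibration and intensity model as the full default.
SMALL_SPEC = SyntheticEmbryoSpec(
    n_epi=5, n_pre=3, n_te=14, slice_shape=(176, 176), seed=7,
)


@pytest.fixture(scope="session")
def small_spec():
    return SMALL_SPEC


@pytest.fixture(scope="session")
def small_embryo(small_spec):
    """One rendered E3.5 embryo (stack, truth) at test scale."""
    return render_stack(small_spec)


@pytest.fixture(scope="session")
def small_segmented(small_embryo):
    stack, truth = small_embryo
    labels, tracks = segment_stack(stack)
    return stack, truth, labels, tracks


@pytest.fixture(scope="session")
def acceptance_cohort():
    """Fixed-seed cohort at the published acquisition geometry (reduced
    field of view and cohort size): 3 stages x 5 embryos, ~30 nuclei each,
    256x256x40 voxels."""
    return make_cohort(5, SyntheticEmbryoSpec(), seed=101)


def match_detections(truth, table, radius_um):
    """Greedy one-to-one matching of ground-truth nuclei to measured rows.

    A truth nucleus matches the nearest unclaimed measured centroid within
    ``radius_um``. Returns (pairs, n_tp, n_fp, n_fn) where pairs is a list
    of (truth_row_index, table_row_index).
    """
    gt = truth[["x_um", "y_um", "z_um"]].to_numpy(dtype=float)
    mc = table[["x_um", "y_um", "z_um"]].to_numpy(dtype=float)
    if len(mc) == 0 or len(gt) == 0:
        return [], 0, len(mc), len(gt)
    d = np.linalg.norm(gt[:, None, :] - mc[None, :, :], axis=2)
    pairs = []
    claimed_t, claimed_m = set(), set()
    order = np.dstack(np.unravel_index(np.argsort(d, axis=None), d.shape))[0]
    for ti, mi in order:
        if d[ti, mi] >= radius_um:
            break
        if ti in claimed_t or mi in claimed_m:
            continue
        claimed_t.add(int(ti))
        claimed_m.add(int(mi))
        pairs.append((int(ti), int(mi)))
    tp = len(pairs)
    return pairs, tp, len(mc) - tp, len(gt) - tp
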