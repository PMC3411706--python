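import numpy as np
import pytest

import vqmouse as vq


@pytest.fixture(scope="session")
def spec1() -> vq.PhantomSpec:
    """Default-condition phantom spec (healthy 12-week-old study)."""
    return vq.PhantomSpec(seed=1)


@pytest.fixture(scope="session")
def study1(spec1):
    """Misaligned four-volume study plus the aligned bundle and truth."""
    return vq.generate_study(spec1)


@pytest.fixture(scope="session")
def bundle1(study1) -> vq.PhantomBundle:
    return study1["bundle"]


@pytest.fixture(scope="session")
def small_spec() -> vq.PhantomSpec:
    """Coarse, fast phantom (~9k lung voxels) for cheap tests."""
    return vq.PhantomSpec(shape=(48, 48, 64), spacing_mm=0.4, seed=2)


@pytest.fixture(scope="session")
def small_bundle(small_spec) -> vq.PhantomBundle:
    return vq.generate_phantom(small_spec)


def four_voxel_label(values_v, values_q, shape=(4, 2, 2)):
    """Tiny aligned V/Q fields on the first len(values) voxels of a label."""
    v = np.zeros(shape)
    q = np.zeros(shape)
    mask = np.zeros(shape, bool)
    flat_idx = [np.unravel_index(i, shape) for i in range(len(values_v))]
    for idx, vv, qq in zip(flat_idx, values_v, values_q):
        v[idx] = vv
        q[idx] = qq
        mask[idx] = True
    label = vq.LungLabel(mask=mask, spacing_mm=1.0)
    return v, q, label
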