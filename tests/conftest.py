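import math

import numpy as np
import pytest

from streamwarp import PhantomSpec, make_phantom_tractogram


@pytest.fixture(scope="session")
def small_phantom():
    """3 bundles x 30 streamlines on a 24^3 grid with 16 block regions."""
    spec = PhantomSpec(n_bundles=3, streamlines_per_bundle=30,
                       shape=(24, 24, 24), n_regions=16, spacing=1.25,
                       seed=11)
    return make_phantom_tractogram(spec)


def brute_force_matrix(t, parc, node_ids):
    """Independent per-streamline counting loop (pure Python).

    Re-derives endpoint voxels with its own half-away-from-zero rounding
    and tallies unordered region pairs into a dense symmetric matrix.
    """
    inv = np.linalg.inv(parc.labels.affine)
    shape = parc.labels.shape
    index = {int(lab): i for i, lab in enumerate(node_ids)}
    counts = np.zeros((len(node_ids), len(node_ids)), dtype=np.int64)
    for sl in t.streamlines:
        labs = []
        for pt in (sl[0], sl[-1]):
            v = inv[:3, :3] @ pt + inv[:3, 3]
            vox = tuple(
                int(math.copysign(math.floor(abs(x) + 0.5), x)) for x in v
            )
            if all(0 <= vox[d] < shape[d] for d in range(3)):
                labs.append(int(parc.labels.data[vox]))
            else:
                labs.append(0)
        a, b = labs
        if a != 0 and b != 0 and a != b:
            counts[index[a], index[b]] += 1
            counts[index[b], index[a]] += 1
    return counts
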