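"""Independent oracles used by the test suite.

The brute-force signed-rank enumeration here is deliberately written from
the definition (itertools over every sign assignment) and shares no code
with the package's dynamic-programming implementation.
"""

from itertools import product

import numpy as np
from scipy.stats import rankdata


def brute_force_signed_rank_p(x, y=None):
    """Smaller-tail exact signed-rank p by enumerating all sign assignments."""
    x = np.asarray(x, float)
    d = x.copy() if y is None else np.asarray(y, float) - x
    d = np.round(d, 10)
    d = d[d != 0]
    n = d.size
    if n == 0:
        return 1.0
    ranks = rankdata(np.abs(d))
    w_obs = min(ranks[d > 0].sum(), ranks[d < 0].sum())
    count = 0
    for signs in product((0, 1), repeat=n):
        w = sum(r for r, s in zip(ranks, signs) if s)
        if w <= w_obs + 1e-9:
            count += 1
    return count / 2.0**n


def slab_volume(n_cart_slices, spacing=(0.31, 0.31, 0.36), shape=(40, 40, 40), bone_top=10):
    """A flat cartilage slab of ``n_cart_slices`` voxels on a bone slab.

    The distance-transform thickness of an n-voxel column is (n+1)*dz, i.e.
    the physical slab thickness n*dz plus one voxel spacing.
    """
    from kneequant.volume import FEMORAL_CARTILAGE, FEMUR_BONE, LabelVolume

    data = np.zeros(shape, np.int16)
    data[:, :, :bone_top] = FEMUR_BONE
    data[:, :, bone_top : bone_top + n_cart_slices] = FEMORAL_CARTILAGE
    return LabelVolume(data=data, spacing_mm=spacing, knee_side="right")
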