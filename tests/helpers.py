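"""Shared construction helpers for the test suite."""

import numpy as np

from graftropy import LatticeConfig
from graftropy.sampling import anchored_environment
from graftropy.surfaces import AnchorSpec, HeightField


def small_anchored_env(field_z0: int = 0, size: int = 41, box_edge: int = 41,
                       bump_center: int | None = None):
    """Anchored environment on a small flat (optionally bumped) surface."""
    z = np.full((size, size), field_z0, dtype=np.int32)
    if bump_center is not None:
        z[bump_center, bump_center] += 1
    field = HeightField(z=z, L=size, meta={"type": "flat"})
    mid = size // 2
    anchor = AnchorSpec(
        mode="mean",
        region=((0, size - 1), (0, size - 1)),
        site=(mid, mid, int(z[mid, mid]) + 1),
    )
    return anchored_environment(field, anchor, LatticeConfig(box_edge=box_edge))
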