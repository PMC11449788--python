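import numpy as np
import pandas as pd
import pytest

from synfp import scaffold_shapes as ss
from synfp.synthgen import SimConfig, gen_scaffolds


@pytest.fixture(scope="session")
def small_scaffold():
    """One small scaffold volume with ground truth, shared across tests."""
    cfg = SimConfig(seed=11, n_objects=24, volume_shape=(36, 160, 160))
    vol, gt = gen_scaffolds(cfg)
    return cfg, vol, gt


def digitized_ball(radius_vox: float, voxel_size=(43.0, 43.0, 43.0),
                   pad: int = 3) -> ss.SegmentedObject:
    """Ball of given radius (in units of the x-voxel edge) digitized on the
    grid, as a segmented object; physically isotropic when the voxel size is
    anisotropic (the nm radius is radius_vox * x-edge)."""
    sx, sy, sz = voxel_size
    r_nm = radius_vox * sx
    nzyx = (int(np.ceil(2 * (r_nm / sz + pad))),
            int(np.ceil(2 * (r_nm / sy + pad))),
            int(np.ceil(2 * (r_nm / sx + pad))))
    c_nm = np.array([nzyx[0] / 2 * sz, nzyx[1] / 2 * sy, nzyx[2] / 2 * sx])
    zz, yy, xx = np.mgrid[: nzyx[0], : nzyx[1], : nzyx[2]]
    pts = np.stack([(zz + 0.5) * sz, (yy + 0.5) * sy, (xx + 0.5) * sx], axis=-1)
    inside = ((pts - c_nm) ** 2).sum(axis=-1) <= r_nm**2
    vox = np.column_stack(np.nonzero(inside))
    return ss.SegmentedObject(vox, 1, border=False)


def digitized_ellipsoid(semi_nm, voxel_size=(43.0, 43.0, 43.0),
                        shift_vox=(0, 0, 0), hole_frac: float = 0.0):
    """Axis-aligned ellipsoid (semi-axes in nm, given as (z, y, x)) digitized
    on the grid; optionally with a central cylindrical hole of relative
    radius hole_frac."""
    sx, sy, sz = voxel_size
    spacing = np.array([sz, sy, sx])
    semi = np.asarray(semi_nm, dtype=float)
    n = np.ceil(2 * (semi / spacing + 3)).astype(int)
    c_nm = n / 2 * spacing
    zz, yy, xx = np.mgrid[: n[0], : n[1], : n[2]]
    pts = (np.stack([zz, yy, xx], axis=-1) + 0.5) * spacing
    q = (pts - c_nm) / semi
    inside = (q**2).sum(axis=-1) <= 1.0
    if hole_frac > 0:
        rel = (pts - c_nm)
        hole = (rel[..., 1] ** 2 + rel[..., 2] ** 2) <= (hole_frac * semi[1:].min()) ** 2
        inside &= ~hole
    # integer lattice translation of the digitized object
    vox = np.column_stack(np.nonzero(inside)) + np.asarray(shift_vox)
    return ss.SegmentedObject(vox, 1, border=False)
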