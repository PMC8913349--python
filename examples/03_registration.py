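"""Distance-preserving registration vs boundary-only registration.

Registering the normalised distance maps of two shapes carries every
interior "shell" of the moving shape onto the equal-depth shell of the
fixed shape.  A standard structure-guided (binary-mask-driven)
registration matches the boundaries just as well but leaves the interior
correspondence undefined — the comparison below makes that visible.
"""

import warnings

import numpy as np
from scipy import ndimage

from voxatlas import DemonsConfig, distance_preserving_register, dice
from voxatlas.dpreg import _warp_image, normalised_distance_map
from voxatlas.grid import VoxelGrid


def ball(n, r, spacing=1.0):
    ax = (np.arange(n) - (n - 1) / 2) * spacing
    xx, yy, zz = np.meshgrid(ax, ax, ax, indexing="ij")
    m = (xx**2 + yy**2 + zz**2 <= r**2).astype(np.uint8)
    return VoxelGrid(m, (spacing,) * 3, (-(n - 1) / 2 * spacing,) * 3)


mov, fix = ball(48, 10.0), ball(48, 15.0)
cfg = DemonsConfig(pyramid_shrinks=(4, 2, 1), iterations=(40, 25, 15))

for guidance in ("distance", "binary"):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        disp = distance_preserving_register(mov, fix, config=cfg,
                                            guidance=guidance)
    warped = _warp_image(mov.values.astype(np.float32),
                         disp.field / mov.spacing) > 0.5
    nd_m = normalised_distance_map(mov).values.values
    nd_f = normalised_distance_map(fix).values.values
    idx = np.stack(np.meshgrid(*[np.arange(48)] * 3, indexing="ij"),
                   axis=-1).astype(float)
    pts = idx + disp.field / mov.spacing
    nd_at = ndimage.map_coordinates(nd_m, [pts[..., a] for a in range(3)],
                                    order=1)
    gland = fix.values.astype(bool)
    frac = (np.abs(nd_at - nd_f)[gland] <= 0.1).mean()
    print(f"{guidance:8s} guidance: boundary Dice {dice(warped, fix.values):.3f}, "
          f"shell preservation (|dND| <= 0.1) {frac:.1%}")
# Both match the boundary; only the distance-guided registration also
# preserves each point's relative depth inside the gland.
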