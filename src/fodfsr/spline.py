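"""Spline-interpolation baselines for 2x volume upsampling.

The low-resolution grid is the block-average of the high-resolution grid,
so (0-based) LR voxel ``j`` is centered at HR coordinate ``2j + 0.5``.
Upsampling evaluates a spline of order 0, 1 or 2 defined at those centers
at the integer HR coordinates: order 0 reproduces nearest-neighbor 2x2x2
block replication; order 1 is trilinear; order 2 uses exact quadratic
spline prefiltering.  Boundaries are mirror-extended.  Each SH coefficient
channel is interpolated independently.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import map_coordinates

__all__ = ["spline_upsample", "spline_upsample_sh"]

_ORDERS = (0, 1, 2)


def _hr_to_lr_coords(shape_lr: tuple[int, int, int]) -> np.ndarray:
    axes = [(np.arange(2 * n) - 0.5) / 2.0 for n in shape_lr]
    grid = np.meshgrid(*axes, indexing="ij")
    return np.stack(grid)


def spline_upsample(lr_vol: np.ndarray, order: int) -> np.ndarray:
    """Upsample a scalar 3D volume by 2 along each axis."""
    if order not in _ORDERS:
        raise ValueError(f"unsupported spline order {order}; use one of {_ORDERS}")
    lr_vol = np.asarray(lr_vol, dtype=float)
    if lr_vol.ndim != 3:
        raise ValueError("lr_vol must be 3D")
    coords = _hr_to_lr_coords(lr_vol.shape)
    return map_coordinates(lr_vol, coords, order=order, mode="reflect", prefilter=True)


def spline_upsample_sh(lr_sh: np.ndarray, order: int) -> np.ndarray:
    """Upsample a 4D (x, y, z, coefficient) volume channel by channel."""
    if lr_sh.ndim != 4:
        raise ValueError("lr_sh must be 4D")
    out = np.empty((*[2 * s for s in lr_sh.shape[:3]], lr_sh.shape[3]))
    for c in range(lr_sh.shape[3]):
        out[..., c] = spline_upsample(lr_sh[..., c], order)
    return out
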