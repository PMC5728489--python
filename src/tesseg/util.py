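"""Small shared helpers: structuring elements, box sums, coordinate checks.

Arrays throughout the package are indexed ``(z, y, x)`` (C order, x fastest
on disk); coordinate triples in CSV files are written ``x, y, z`` and
converted at the I/O boundary.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage


def ball_offsets(radius: float) -> np.ndarray:
    """Integer offsets of voxels whose centers lie within ``radius``."""
    r = int(np.floor(radius))
    zz, yy, xx = np.mgrid[-r : r + 1, -r : r + 1, -r : r + 1]
    keep = zz * zz + yy * yy + xx * xx <= radius * radius
    return np.stack([zz[keep], yy[keep], xx[keep]], axis=1)


def dilate_ball(mask: np.ndarray, radius: float) -> np.ndarray:
    """Morphological dilation of a boolean mask by a Euclidean ball.

    Implemented via the exact Euclidean distance transform of the complement,
    which is much faster than iterated binary dilation for large radii.
    """
    if radius <= 0:
        return mask.copy()
    if not mask.any():
        return mask.copy()
    dist = ndimage.distance_transform_edt(~mask)
    return dist <= radius


def box_sum(arr: np.ndarray, length: int) -> np.ndarray:
    """Sum of ``arr`` over the cube B(x, length) clipped at the grid border.

    ``length`` must be odd.  Uses running cumulative sums along each axis so
    the cost is O(N) independent of ``length`` — the same reuse idea as an
    incremental sliding-window sweep, and exactly equal to the naive O(l^3)
    per-voxel loop.
    """
    if length < 1 or length % 2 == 0:
        raise ValueError("box edge length must be odd and >= 1")
    r = length // 2
    out = np.asarray(arr, dtype=np.float64)
    for ax in range(out.ndim):
        n = out.shape[ax]
        c = np.cumsum(out, axis=ax)
        hi = np.minimum(np.arange(n) + r, n - 1)
        lo = np.arange(n) - r - 1
        upper = np.take(c, hi, axis=ax)
        lower = np.take(c, np.maximum(lo, 0), axis=ax)
        # where the lower edge is off-grid the prefix sum is zero
        shape = [1] * out.ndim
        shape[ax] = n
        lower = lower * (lo >= 0).reshape(shape)
        out = upper - lower
    return out


def face_adjacency_structure() -> np.ndarray:
    """6-connected (face) structuring element."""
    return ndimage.generate_binary_structure(3, 1)


def full_adjacency_structure() -> np.ndarray:
    """26-connected (face+edge+corner) structuring element."""
    return ndimage.generate_binary_structure(3, 3)


def downsample_mean(volume: np.ndarray, factor: int = 2) -> np.ndarray:
    """Mean-pooling downsample by an integer factor (trailing rows cropped).

    Mirrors the common preprocessing of halving scan resolution before
    segmentation.
    """
    if factor < 1:
        raise ValueError("factor must be >= 1")
    v = np.asarray(volume, dtype=np.float64)
    nz, ny, nx = (s - s % factor for s in v.shape)
    v = v[:nz, :ny, :nx]
    v = v.reshape(nz // factor, factor, ny // factor, factor, nx // factor, factor)
    return v.mean(axis=(1, 3, 5))
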