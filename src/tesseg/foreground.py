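"""Strip-restricted local thresholding producing the binary foreground mask.

Mineralized tiles are brighter than the surrounding tissue, but their
absolute intensity drifts across a skeletal element, so a single global
threshold fails.  A voxel ``x`` is foreground iff it lies inside a
user-defined *strip* ``S`` around the tiled layer and its intensity exceeds
``T_n`` times the mean intensity over its clipped cubic neighborhood
``N(x) = B(x, l) ∩ S``:

    x ∈ F  ⟺  x ∈ S  ∧  I_s(x) > (T_n / |N(x)|) · Σ_{y ∈ N(x)} I_s(y)

The strip restricts the ratio test to voxels near the layer so that far-away
background (whose box would contain no tile voxels) can never turn
foreground.  Finally, background cavities completely enclosed by foreground
are filled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .util import box_sum, dilate_ball, face_adjacency_structure

__all__ = ["ThresholdParams", "make_strip", "local_threshold", "fill_enclosed",
           "segment_foreground"]


@dataclass(frozen=True)
class ThresholdParams:
    """Parameters of strip construction and the local ratio test.

    Attributes
    ----------
    box_length:
        ``l`` — edge length (odd, voxels) of the cube ``B(x, l)``; choose two
        to three times the tile thickness so the box always samples some
        background.
    ratio_threshold:
        ``T_n`` — dimensionless ratio against the neighborhood mean
        (default 1, the value used throughout).
    strip_threshold:
        ``T_g`` — tolerant global intensity threshold seeding the strip;
        must lie below the lowest expected tile intensity.
    strip_grow_radius:
        ``r_g`` — Euclidean dilation radius (voxels) growing the seed into
        the strip; ``l/2`` keeps every strip voxel within reach of the layer.
    """

    box_length: int = 15
    ratio_threshold: float = 1.0
    strip_threshold: float = 0.0
    strip_grow_radius: float = 7.0

    def __post_init__(self) -> None:
        if self.box_length < 3 or self.box_length % 2 == 0:
            raise ValueError("box_length must be odd and >= 3")
        if not self.ratio_threshold > 0:
            raise ValueError("ratio_threshold must be positive")
        if self.strip_grow_radius < 0:
            raise ValueError("strip_grow_radius must be >= 0")


def make_strip(image: np.ndarray, params: ThresholdParams) -> np.ndarray:
    """Build the strip ``S``: tolerant global threshold + Euclidean growth.

    Returns a boolean mask that is a superset of ``{I_s > T_g}``.
    Raises if the seed mask is empty (``T_g`` chosen too high).
    """
    img = np.asarray(image, dtype=np.float64)
    seed = img > params.strip_threshold
    if not seed.any():
        raise ValueError(
            f"strip seed empty: no voxel exceeds strip_threshold="
            f"{params.strip_threshold}"
        )
    return dilate_ball(seed, params.strip_grow_radius)


def local_threshold(
    image: np.ndarray, strip: np.ndarray, params: ThresholdParams
) -> np.ndarray:
    """Apply the strip-restricted local ratio test (strict inequality).

    The cube ``B(x, l)`` is clipped at the volume border; the neighborhood
    mean is taken over box voxels that belong to the strip only.  Voxels
    outside the strip are never foreground.  The criterion is a ratio, so
    rescaling all intensities by a positive constant leaves the result
    unchanged.
    """
    img = np.asarray(image, dtype=np.float64)
    s = np.asarray(strip, dtype=bool)
    if img.shape != s.shape:
        raise ValueError("image and strip shapes differ")
    if not s.any():
        raise ValueError("strip is empty")
    l = params.box_length
    sum_in_strip = box_sum(np.where(s, img, 0.0), l)
    count_in_strip = box_sum(s.astype(np.float64), l)
    # every x in S has x in N(x), so the count is >= 1 wherever it matters
    with np.errstate(divide="ignore", invalid="ignore"):
        mean = sum_in_strip / count_in_strip
    crit = img > params.ratio_threshold * mean
    return s & crit


def fill_enclosed(mask: np.ndarray) -> np.ndarray:
    """Fill background cavities completely enclosed by foreground.

    6-connected background components that do not touch the volume border
    are set to foreground; everything else is unchanged.  Idempotent and
    monotone (only adds voxels).
    """
    m = np.asarray(mask, dtype=bool)
    background = ~m
    lab, n = ndimage.label(background, structure=face_adjacency_structure())
    if n == 0:
        return m.copy()
    border_labels = np.unique(
        np.concatenate(
            [
                lab[0].ravel(), lab[-1].ravel(),
                lab[:, 0].ravel(), lab[:, -1].ravel(),
                lab[:, :, 0].ravel(), lab[:, :, -1].ravel(),
            ]
        )
    )
    border_labels = border_labels[border_labels > 0]
    enclosed = np.ones(n + 1, dtype=bool)
    enclosed[0] = False
    enclosed[border_labels] = False
    return m | enclosed[lab]


def segment_foreground(image: np.ndarray, params: ThresholdParams) -> np.ndarray:
    """Convenience: strip -> local threshold -> enclosed-cavity fill."""
    strip = make_strip(image, params)
    mask = local_threshold(image, strip, params)
    return fill_enclosed(mask)
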