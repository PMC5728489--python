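"""Why a thin tiled layer needs the locally-planar distance map.

On a slab only 3 voxels thick, the standard 3D distance transform saturates
at the half-thickness (it measures the layer's height, not the distance to
the pores between tiles) and plateaus across the inter-tile connections; the
planar map keeps growing toward the tile centers, so the watershed can
separate tiles.
"""

import numpy as np

from tesseg import (
    DiffusionParams,
    PhantomSpec,
    ThresholdParams,
    compare_2d_vs_3d,
    distance_map_2d,
    distance_map_3d,
    generate_phantom,
    segment_foreground,
    smooth_anisotropic,
)

spec = PhantomSpec(shape=(14, 72, 72), thickness=3, n_tiles=20, seed=6)
volume, truth = generate_phantom(spec)

smoothed = smooth_anisotropic(volume.data, DiffusionParams(stop_threshold=100.0))
mask = segment_foreground(
    smoothed,
    ThresholdParams(box_length=9, strip_threshold=100.0, strip_grow_radius=4.0),
)
d3 = distance_map_3d(mask)
d2 = distance_map_2d(mask, n_rays=400, m_rays=180, cap=60)

lm = np.rint(truth.landmarks).astype(int)
z_mid = lm[0, 0]
print(f"at tile centers (mid-slab): D3D = {d3[z_mid, lm[:, 1], lm[:, 2]].mean():.2f} "
      f"(height-capped), D2D = {d2[z_mid, lm[:, 1], lm[:, 2]].mean():.2f}")

sizes = np.bincount(truth.labels.ravel())[1:]
sweep = compare_2d_vs_3d(
    volume.data, truth.landmarks,
    DiffusionParams(stop_threshold=100.0),
    ThresholdParams(box_length=9, strip_threshold=100.0, strip_grow_radius=4.0),
    persistences=range(0, 13), t_v=0.5 * sizes.min(),
    n_rays=400, m_rays=180, cap=60,
)
for variant in ("2d", "3d"):
    sub = sweep[sweep.variant == variant]
    best = np.minimum(sub.precision, sub.recall).max()
    print(f"{variant} distance map: best min(precision, recall) = {best:.3f}")
# The 3D variant undersegments badly (one height plateau spans many tiles);
# the planar variant recovers essentially every tile.
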