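"""Distance transforms: direction sets, plane fits, ray-cast distances."""

import numpy as np
import pytest
from scipy import ndimage

from tesseg import (
    distance2d_at,
    distance_map_2d,
    distance_map_3d,
    fit_plane,
    sphere_directions,
)


def _angle_deg(a, b):
    c = abs(np.dot(a, b)) / (np.linalg.norm(a) * np.linalg.norm(b))
    return np.degrees(np.arccos(np.clip(c, -1, 1)))


def slab(shape, z0, thickness):
    m = np.zeros(shape, dtype=bool)
    m[z0 : z0 + thickness] = True
    return m


# --- sphere_directions -----------------------------------------------------


@pytest.mark.parametrize("count", [1, 50, 500, 1214])
def test_sphere_directions_unit_norm(count):
    d = sphere_directions(count)
    assert d.shape == (count, 3)
    np.testing.assert_allclose(np.linalg.norm(d, axis=1), 1.0, atol=1e-12)


def test_sphere_directions_equidistributed():
    for count in (50, 500):
        d = sphere_directions(count)
        assert np.linalg.norm(d.mean(axis=0)) < 0.05


def test_sphere_directions_rejects_bad_count():
    with pytest.raises(ValueError):
        sphere_directions(0)


# --- fit_plane -------------------------------------------------------------


def test_plane_normal_on_axis_aligned_slab():
    m = slab((16, 32, 32), 6, 5)
    pl = fit_plane(m, (8, 16, 16), sphere_directions(300))
    assert _angle_deg(pl.normal, [1, 0, 0]) < 5.0


def test_plane_normal_on_tilted_slab():
    """Slab with true normal (1,1,1)/sqrt(3) recovered within 5 degrees."""
    n_true = np.array([1.0, 1.0, 1.0]) / np.sqrt(3.0)
    zz, yy, xx = np.mgrid[0:40, 0:40, 0:40].astype(np.float64)
    c = np.array([20.0, 20.0, 20.0])
    proj = (zz - c[0]) * n_true[0] + (yy - c[1]) * n_true[1] + (xx - c[2]) * n_true[2]
    m = np.abs(proj) <= 2.5
    pl = fit_plane(m, (20, 20, 20), sphere_directions(500))
    assert _angle_deg(pl.normal, n_true) < 5.0


def test_plane_fit_degenerate_ball_is_deterministic():
    """Isotropic hit cloud: any normal admissible, but must be unit and
    reproducible."""
    zz, yy, xx = np.mgrid[0:21, 0:21, 0:21].astype(np.float64)
    m = (zz - 10) ** 2 + (yy - 10) ** 2 + (xx - 10) ** 2 <= 64
    d = sphere_directions(200)
    p1 = fit_plane(m, (10, 10, 10), d)
    p2 = fit_plane(m, (10, 10, 10), d)
    assert np.linalg.norm(p1.normal) == pytest.approx(1.0, abs=1e-9)
    np.testing.assert_array_equal(p1.normal, p2.normal)


def test_plane_fit_unbounded_region_raises():
    m = np.ones((10, 10, 10), dtype=bool)
    with pytest.raises(ValueError, match="unbounded"):
        fit_plane(m, (5, 5, 5), sphere_directions(100), cap=4)


def test_plane_normal_on_spherical_cap_phantom(cap_phantom):
    """Angular error vs the analytic surface normal <= 10 degrees away from
    pores."""
    _, truth, spec = cap_phantom
    mask = truth.labels > 0
    interior = ndimage.binary_erosion(mask, iterations=2)
    dirs = sphere_directions(500)
    pts = np.argwhere(interior)
    rng = np.random.default_rng(0)
    pick = pts[rng.choice(len(pts), size=min(30, len(pts)), replace=False)]
    for p in pick:
        pl = fit_plane(mask, tuple(p), dirs)
        analytic = truth.normal_at(p)
        assert _angle_deg(pl.normal, analytic) <= 10.0


# --- distance2d_at ---------------------------------------------------------


def test_inplane_distance_adjacent_to_background():
    m = slab((12, 20, 20), 4, 4)
    m[:, :, 10:] = False  # in-plane background wall at x = 10
    pl = fit_plane(m, (6, 10, 9), sphere_directions(300))
    assert distance2d_at(m, pl, 361) == pytest.approx(1.0)


def test_inplane_distance_to_cylindrical_pore():
    """Distance to a pore wall matches in-plane EDT within 1 voxel (d<=20)."""
    m = slab((12, 56, 56), 4, 4)
    yy, xx = np.mgrid[0:56, 0:56]
    pore = (yy - 28) ** 2 + (xx - 28) ** 2 <= 9
    m[:, pore] = False
    # exact in-plane distance on a z-slice (border treated as background)
    sl = np.pad(m[6], 1, constant_values=False)
    exact = ndimage.distance_transform_edt(sl)[1:-1, 1:-1]
    dirs = sphere_directions(600)
    rng = np.random.default_rng(1)
    fg = np.argwhere(m[6] & (exact <= 20))
    for y, x in fg[rng.choice(len(fg), 25, replace=False)]:
        pl = fit_plane(m, (6, y, x), dirs)
        d = distance2d_at(m, pl, 361)
        assert abs(d - exact[y, x]) <= 1.0, (y, x, d, exact[y, x])


# --- distance_map_2d / 3d --------------------------------------------------


def test_map2d_all_background_is_zero():
    out = distance_map_2d(np.zeros((4, 4, 4), dtype=bool), 50, 30)
    np.testing.assert_array_equal(out, 0)


def test_map2d_escapes_height_capping():
    """On a thin slab, the 3D map reads the half-thickness while the planar
    map reads the much larger in-plane distance."""
    m = slab((12, 40, 40), 4, 3)
    d3 = distance_map_3d(m)
    d2 = distance_map_2d(m, 300, 120)
    assert d3[5, 20, 20] == 2.0  # height-capped
    assert d2[5, 20, 20] > 2.0 * d3[5, 20, 20]


def test_map2d_decreases_toward_connection(small_pipeline):
    """Across an inter-tile border the planar distance dips at the
    connection relative to the two tile centers."""
    truth = small_pipeline["truth"]
    dist = distance_map_2d(truth.labels > 0, 300, 120)
    a, b = truth.neighbor_pairs[0]
    lm = truth.landmarks
    centers = dist[tuple(np.rint([lm[a - 1], lm[b - 1]]).astype(int).T)]
    # connection voxels: label-a voxels face-adjacent to label b
    la = truth.labels == a
    lb = truth.labels == b
    conn = la & (
        np.roll(lb, 1, 1) | np.roll(lb, -1, 1)
        | np.roll(lb, 1, 2) | np.roll(lb, -1, 2)
    )
    assert conn.any()
    assert dist[conn].min() < centers.min()


def test_map3d_single_voxel():
    m = np.zeros((5, 5, 5), dtype=bool)
    m[2, 2, 2] = True
    assert distance_map_3d(m)[2, 2, 2] == 1.0


def test_map3d_slab_midplane():
    m = np.zeros((25, 8, 8), dtype=bool)
    m[10:15] = True
    assert distance_map_3d(m)[12, 4, 4] == 3.0


def test_map3d_matches_bruteforce_all_pairs():
    rng = np.random.default_rng(5)
    m = ndimage.binary_closing(rng.random((9, 9, 9)) > 0.4)
    d = distance_map_3d(m)
    bg = np.argwhere(~np.pad(m, 1, constant_values=False))
    fg = np.argwhere(np.pad(m, 1, constant_values=False))
    for p in fg:
        exact = np.sqrt(((bg - p) ** 2).sum(axis=1).min())
        assert d[tuple(p - 1)] == pytest.approx(exact, abs=1e-9)


def test_maps_deterministic():
    m = slab((10, 24, 24), 3, 4)
    a = distance_map_2d(m, 200, 90)
    b = distance_map_2d(m, 200, 90)
    np.testing.assert_array_equal(a, b)


def test_map2d_at_least_map3d_on_slab():
    """The in-plane minimum searches a subset of the background, so the
    planar distance can never fall below the 3D distance on flat slabs."""
    m = slab((12, 30, 30), 4, 4)
    yy, xx = np.mgrid[0:30, 0:30]
    m[:, (yy - 15) ** 2 + (xx - 8) ** 2 <= 4] = False
    d2 = distance_map_2d(m, 400, 181)
    d3 = distance_map_3d(m)
    assert np.all(d2[m] >= d3[m] - 1e-9)
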