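"""Distance transforms: the locally-planar 2D map and the standard 3D map.

For thin tiled layers the standard Euclidean distance transform ``D_3D``
measures the *thickness* of the layer rather than the in-plane distance to
the pores that actually separate tiles — whenever the inter-tile connection
is wider than the layer is thick, the 3D map plateaus and the watershed
cannot find the tile boundaries.  The locally-planar transform fixes this:
at each foreground voxel ``x`` it

1. shoots ``n`` equidistributed 3D rays (Fibonacci sphere) to the first
   background voxel, giving a point cloud ``P_x^3D`` on the layer surface;
2. fits the least-squares plane to that cloud (normal = direction of least
   scatter) and moves it to pass through ``x``;
3. shoots ``m`` equiangular rays *inside that plane* and returns the
   distance to the nearest background hit.

Rays are traversed voxel-by-voxel with the 3D Bresenham algorithm; a ray
leaving the volume counts as a background hit at the first out-of-grid voxel
center, so the volume border behaves like background (consistent with the
padded-EDT convention of :func:`distance_map_3d`).  Distances are
center-to-center in voxel units; multiply by the voxel size for physical
units (isotropic grids only).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit
from scipy import ndimage

__all__ = [
    "FitPlane",
    "sphere_directions",
    "fit_plane",
    "distance2d_at",
    "distance_map_2d",
    "distance_map_3d",
]

#: ray-length cap as a multiple of the largest grid dimension when the caller
#: does not provide one
_DEFAULT_CAP_FACTOR = 1.0


@dataclass(frozen=True)
class FitPlane:
    """Plane through the query voxel, ``point + span{u, v} ⟂ normal``."""

    point: np.ndarray  # (z, y, x) voxel coordinates of the query voxel
    normal: np.ndarray  # unit vector, direction of least hit-point scatter

    def __post_init__(self) -> None:
        n = np.asarray(self.normal, dtype=np.float64)
        if abs(np.linalg.norm(n) - 1.0) > 1e-8:
            raise ValueError("plane normal must have unit norm")


def sphere_directions(count: int) -> np.ndarray:
    """``count`` approximately equidistributed unit vectors (Fibonacci sphere).

    Deterministic; component order is (z, y, x) to match array indexing.
    """
    if count < 1:
        raise ValueError("count must be >= 1")
    i = np.arange(count, dtype=np.float64)
    z = 1.0 - 2.0 * (i + 0.5) / count
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    golden = np.pi * (3.0 - np.sqrt(5.0))
    phi = golden * i
    dirs = np.stack([z, r * np.sin(phi), r * np.cos(phi)], axis=1)
    return dirs / np.linalg.norm(dirs, axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# numba kernels
# ---------------------------------------------------------------------------


@njit(cache=True)
def _cast_ray(mask, z0, y0, x0, ez, ey, ex):
    """3D Bresenham from voxel (z0,y0,x0) toward integer endpoint.

    Returns (hz, hy, hx, hit): the first background (or out-of-grid) voxel
    along the line, excluding the start voxel.  hit==False means the ray
    stayed inside foreground all the way to the endpoint (cap reached).
    """
    nz, ny, nx = mask.shape
    dz = ez - z0
    dy = ey - y0
    dx = ex - x0
    az, ay, ax = abs(dz), abs(dy), abs(dx)
    sz = 1 if dz > 0 else -1
    sy = 1 if dy > 0 else -1
    sx = 1 if dx > 0 else -1
    z, y, x = z0, y0, x0
    if ax >= ay and ax >= az:
        p1 = 2 * ay - ax
        p2 = 2 * az - ax
        for _ in range(ax):
            x += sx
            if p1 >= 0:
                y += sy
                p1 -= 2 * ax
            if p2 >= 0:
                z += sz
                p2 -= 2 * ax
            p1 += 2 * ay
            p2 += 2 * az
            if z < 0 or z >= nz or y < 0 or y >= ny or x < 0 or x >= nx:
                return z, y, x, True
            if not mask[z, y, x]:
                return z, y, x, True
    elif ay >= ax and ay >= az:
        p1 = 2 * ax - ay
        p2 = 2 * az - ay
        for _ in range(ay):
            y += sy
            if p1 >= 0:
                x += sx
                p1 -= 2 * ay
            if p2 >= 0:
                z += sz
                p2 -= 2 * ay
            p1 += 2 * ax
            p2 += 2 * az
            if z < 0 or z >= nz or y < 0 or y >= ny or x < 0 or x >= nx:
                return z, y, x, True
            if not mask[z, y, x]:
                return z, y, x, True
    else:
        p1 = 2 * ay - az
        p2 = 2 * ax - az
        for _ in range(az):
            z += sz
            if p1 >= 0:
                y += sy
                p1 -= 2 * az
            if p2 >= 0:
                x += sx
                p2 -= 2 * az
            p1 += 2 * ay
            p2 += 2 * ax
            if z < 0 or z >= nz or y < 0 or y >= ny or x < 0 or x >= nx:
                return z, y, x, True
            if not mask[z, y, x]:
                return z, y, x, True
    return 0, 0, 0, False


@njit(cache=True)
def _hit_cloud_cov(mask, z0, y0, x0, dirs, cap):
    """Cast all 3D rays; return (count, centroid, covariance) of hit points."""
    n = dirs.shape[0]
    count = 0
    s = np.zeros(3)
    ss = np.zeros((3, 3))
    for k in range(n):
        ez = int(round(z0 + dirs[k, 0] * cap))
        ey = int(round(y0 + dirs[k, 1] * cap))
        ex = int(round(x0 + dirs[k, 2] * cap))
        hz, hy, hx, hit = _cast_ray(mask, z0, y0, x0, ez, ey, ex)
        if hit:
            count += 1
            p0, p1, p2 = float(hz), float(hy), float(hx)
            s[0] += p0
            s[1] += p1
            s[2] += p2
            ss[0, 0] += p0 * p0
            ss[0, 1] += p0 * p1
            ss[0, 2] += p0 * p2
            ss[1, 1] += p1 * p1
            ss[1, 2] += p1 * p2
            ss[2, 2] += p2 * p2
    mean = np.zeros(3)
    cov = np.zeros((3, 3))
    if count > 0:
        for i in range(3):
            mean[i] = s[i] / count
        for i in range(3):
            for j in range(i, 3):
                cov[i, j] = ss[i, j] / count - mean[i] * mean[j]
                cov[j, i] = cov[i, j]
    return count, mean, cov


@njit(cache=True)
def _normal_from_cov(cov):
    """Least-scatter direction with a fixed deterministic sign convention."""
    w, v = np.linalg.eigh(cov)
    normal = v[:, 0].copy()  # eigh returns ascending eigenvalues
    nrm = np.sqrt(normal[0] ** 2 + normal[1] ** 2 + normal[2] ** 2)
    for i in range(3):
        normal[i] /= nrm
    # sign: make the largest-magnitude component positive
    big = 0
    if abs(normal[1]) > abs(normal[big]):
        big = 1
    if abs(normal[2]) > abs(normal[big]):
        big = 2
    if normal[big] < 0:
        for i in range(3):
            normal[i] = -normal[i]
    return normal


@njit(cache=True)
def _inplane_basis(normal):
    """Orthonormal in-plane basis from the smallest-component axis rule."""
    small = 0
    if abs(normal[1]) < abs(normal[small]):
        small = 1
    if abs(normal[2]) < abs(normal[small]):
        small = 2
    e = np.zeros(3)
    e[small] = 1.0
    # u = normalize(normal x e)
    u = np.empty(3)
    u[0] = normal[1] * e[2] - normal[2] * e[1]
    u[1] = normal[2] * e[0] - normal[0] * e[2]
    u[2] = normal[0] * e[1] - normal[1] * e[0]
    nrm = np.sqrt(u[0] ** 2 + u[1] ** 2 + u[2] ** 2)
    for i in range(3):
        u[i] /= nrm
    # v = normal x u (unit by construction)
    v = np.empty(3)
    v[0] = normal[1] * u[2] - normal[2] * u[1]
    v[1] = normal[2] * u[0] - normal[0] * u[2]
    v[2] = normal[0] * u[1] - normal[1] * u[0]
    return u, v


@njit(cache=True)
def _min_inplane_distance(mask, z0, y0, x0, normal, m, cap):
    """Shortest center-to-center distance to background over m in-plane rays.

    Returns cap when no ray reaches background within the cap.
    """
    u, v = _inplane_basis(normal)
    best = cap
    for j in range(m):
        theta = 2.0 * np.pi * j / m
        c = np.cos(theta)
        s = np.sin(theta)
        dz = c * u[0] + s * v[0]
        dy = c * u[1] + s * v[1]
        dx = c * u[2] + s * v[2]
        ez = int(round(z0 + dz * cap))
        ey = int(round(y0 + dy * cap))
        ex = int(round(x0 + dx * cap))
        hz, hy, hx, hit = _cast_ray(mask, z0, y0, x0, ez, ey, ex)
        if hit:
            d = np.sqrt(
                float(hz - z0) ** 2 + float(hy - y0) ** 2 + float(hx - x0) ** 2
            )
            if d < best:
                best = d
    return best


@njit(cache=True)
def _distance_map_2d_kernel(mask, dirs, m, cap):
    nz, ny, nx = mask.shape
    out = np.zeros((nz, ny, nx))
    n_unbounded = 0
    for z in range(nz):
        for y in range(ny):
            for x in range(nx):
                if not mask[z, y, x]:
                    continue
                count, _, cov = _hit_cloud_cov(mask, z, y, x, dirs, cap)
                if count < 3:
                    n_unbounded += 1
                    continue
                normal = _normal_from_cov(cov)
                out[z, y, x] = _min_inplane_distance(
                    mask, z, y, x, normal, m, cap
                )
    return out, n_unbounded


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------


def _resolve_cap(mask: np.ndarray, cap: float | None) -> float:
    if cap is None:
        return float(max(mask.shape)) * _DEFAULT_CAP_FACTOR
    if cap <= 0:
        raise ValueError("ray cap must be positive")
    return float(cap)


def fit_plane(
    mask: np.ndarray,
    point: tuple[int, int, int],
    dirs: np.ndarray,
    cap: float | None = None,
) -> FitPlane:
    """Fit the locally-best plane at a foreground voxel by 3D ray casting.

    Casts one ray per direction to the first background voxel, then returns
    the least-squares plane through the hit cloud (normal = least-scatter
    eigenvector), translated to pass through the query voxel.  Raises if
    fewer than 3 rays hit background (unbounded foreground).
    """
    m = np.ascontiguousarray(mask, dtype=np.bool_)
    z, y, x = (int(point[0]), int(point[1]), int(point[2]))
    if not m[z, y, x]:
        raise ValueError("query voxel is not foreground")
    d = np.ascontiguousarray(dirs, dtype=np.float64)
    capv = _resolve_cap(m, cap)
    count, _, cov = _hit_cloud_cov(m, z, y, x, d, capv)
    if count < 3:
        raise ValueError(
            "fewer than 3 ray hits: foreground region unbounded at this voxel"
        )
    normal = _normal_from_cov(cov)
    return FitPlane(point=np.array([z, y, x], dtype=np.float64), normal=normal)


def distance2d_at(
    mask: np.ndarray,
    plane: FitPlane,
    m_rays: int = 361,
    cap: float | None = None,
) -> float:
    """In-plane distance to background at the plane's base voxel.

    ``m_rays`` equiangular rays in the plane; returns the shortest
    center-to-center hit distance, or the cap if every ray stays inside
    foreground.
    """
    msk = np.ascontiguousarray(mask, dtype=np.bool_)
    z, y, x = (int(round(c)) for c in plane.point)
    if not msk[z, y, x]:
        raise ValueError("plane base point is not foreground")
    capv = _resolve_cap(msk, cap)
    return float(
        _min_inplane_distance(
            msk, z, y, x, np.asarray(plane.normal, dtype=np.float64),
            int(m_rays), capv,
        )
    )


def distance_map_2d(
    mask: np.ndarray,
    n_rays: int = 1214,
    m_rays: int = 361,
    cap: float | None = None,
) -> np.ndarray:
    """Locally-planar 2D distance map over all foreground voxels.

    Each foreground voxel is processed independently (plane fit with
    ``n_rays`` 3D rays, then ``m_rays`` in-plane rays); background voxels
    are 0.  Deterministic: fixed direction sets, no randomness.
    """
    m = np.ascontiguousarray(mask, dtype=np.bool_)
    if not m.any():
        return np.zeros(m.shape, dtype=np.float64)
    dirs = sphere_directions(n_rays)
    capv = _resolve_cap(m, cap)
    out, n_unbounded = _distance_map_2d_kernel(m, dirs, int(m_rays), capv)
    if n_unbounded:
        raise ValueError(
            f"{n_unbounded} foreground voxels had <3 ray hits within the cap "
            f"({capv:g} voxels); foreground appears unbounded — increase cap"
        )
    return out


def distance_map_3d(mask: np.ndarray) -> np.ndarray:
    """Standard exact Euclidean distance to the nearest background voxel.

    The volume border counts as background (pad-with-zeros convention),
    matching the ray-cast out-of-grid rule of the 2D map.  0 on background.
    """
    m = np.asarray(mask, dtype=bool)
    padded = np.pad(m, 1, mode="constant", constant_values=False)
    d = ndimage.distance_transform_edt(padded)
    return d[1:-1, 1:-1, 1:-1] * m
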