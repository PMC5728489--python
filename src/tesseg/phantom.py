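"""Synthetic tessellated-shell phantoms with known ground truth.

Real scans of tessellated cartilage are a thin mineralized layer tiled into
convex cells (tesserae) whose narrow unmineralized pores sit mostly at the
junctions where three or more tiles meet, while the remaining inter-tile
border is a bright *connection* — typically wider than the layer is thick.
Small low-contrast cavities (cell lacunae) perforate the tile interiors, the
mineral density drifts smoothly across the element, and the scan adds noise.

The generator reproduces exactly this regime on a flat slab or a spherical
cap: ``K`` Poisson-disk seeds on the mid-surface, nearest-seed partition of
the shell, pores carved at tile junctions and along the outer
``1 - connection_fraction`` portion of every pairwise border, intensity
synthesis (holes, polynomial drift, Gaussian noise) *after* the truth labels
are recorded.  Fixed seed ⇒ bit-identical volume and truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml
from scipy import ndimage
from scipy.spatial import cKDTree

from .io import VolumeImage, write_volume, write_landmarks

__all__ = ["PhantomSpec", "PhantomTruth", "generate_phantom",
           "generate_profile_1d", "save_phantom"]


@dataclass(frozen=True)
class PhantomSpec:
    """Stated world of the phantom generator.

    Geometry is in voxels; intensities are arbitrary scanner units.  Defaults
    describe a flat shell of 100 tiles at the acceptance scale: connection
    width larger than shell thickness, pores of ~2 voxel radius at the
    junctions, faint intra-tile holes whose contrast (60) is well below the
    tile/pore contrast (160) so diffusion can remove the former but not the
    latter, 15% foreground-mean intensity drift and sigma-8 noise.
    """

    shape: tuple[int, int, int] = (48, 128, 128)  # (nz, ny, nx)
    voxel_size_um: float = 9.78
    mode: str = "flat"  # "flat" | "cap"
    thickness: int = 6
    n_tiles: int = 100
    tile_diameter: float | None = None  # None: equal-area-disc estimate
    pore_radius: float = 2.0
    connection_fraction: float = 0.5
    holes_per_tile: float = 2.0
    hole_radius: float = 1.5
    fg_mean: float = 180.0
    bg_mean: float = 20.0
    hole_contrast: float = 60.0
    drift_amplitude: float = 0.15  # fraction of fg_mean, peak-to-peak
    noise_sigma: float = 8.0
    cap_radius: float | None = None  # mode="cap": mid-surface sphere radius
    seed: int = 0

    def resolved_tile_diameter(self) -> float:
        if self.tile_diameter is not None:
            return float(self.tile_diameter)
        _, ny, nx = self.shape
        area = ny * nx / self.n_tiles
        return 2.0 * np.sqrt(area / np.pi)

    def validate(self) -> None:
        nz, ny, nx = self.shape
        if min(nz, ny, nx) < 1:
            raise ValueError("grid dims must be >= 1")
        if self.mode not in ("flat", "cap"):
            raise ValueError("mode must be 'flat' or 'cap'")
        if self.n_tiles < 2:
            raise ValueError("need at least 2 tiles")
        if self.thickness < 1 or self.thickness > nz:
            raise ValueError("thickness must fit inside the grid")
        d = self.resolved_tile_diameter()
        if not d > self.thickness:
            raise ValueError(
                f"tile diameter ({d:.1f}) must exceed shell thickness "
                f"({self.thickness}): the flat-tile regime"
            )
        if self.pore_radius < 1:
            raise ValueError("pore_radius must be >= 1 voxel")
        if not d > 2 * self.pore_radius:
            raise ValueError(
                f"infeasible geometry: tiles (diameter {d:.1f}) smaller than "
                f"pores (diameter {2 * self.pore_radius:.1f})"
            )
        if not (0 < self.connection_fraction < 1):
            raise ValueError("connection_fraction must lie in (0, 1)")
        pore_contrast = self.fg_mean - self.bg_mean
        if not (0 <= self.hole_contrast < pore_contrast):
            raise ValueError(
                "intra-tile hole contrast must be below the pore contrast"
            )

    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self, path) -> None:
        d = self.to_dict()
        d["shape"] = list(d["shape"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "PhantomSpec":
        d = yaml.safe_load(Path(path).read_text())
        d["shape"] = tuple(d["shape"])
        return cls(**d)


@dataclass
class PhantomTruth:
    """Ground truth: label field, one landmark per tile, neighbor pairs.

    ``landmarks[k]`` lies inside label ``k + 1``; ``neighbor_pairs`` holds
    unordered touching label pairs ``(a, b)`` with ``a < b`` (the symmetric
    relation, stored once per pair).
    """

    labels: np.ndarray  # int32, 0 = background/pore
    landmarks: np.ndarray  # (K, 3) float, internal (z, y, x)
    neighbor_pairs: list = field(default_factory=list)
    geometry: dict = field(default_factory=dict)  # analytic surface info

    @property
    def n_tiles(self) -> int:
        return int(self.labels.max())

    def normal_at(self, point) -> np.ndarray:
        """Analytic mid-surface normal at a (z, y, x) position."""
        if self.geometry.get("mode") == "flat":
            return np.array([1.0, 0.0, 0.0])
        c = np.asarray(self.geometry["center"], dtype=np.float64)
        v = np.asarray(point, dtype=np.float64) - c
        return v / np.linalg.norm(v)


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------


def _poisson_disk(rng, n_points, spacing, sampler, max_attempts_factor=400):
    """Dart-throwing Poisson-disk sampling; ``sampler()`` draws a candidate."""
    accepted: list[np.ndarray] = []
    attempts = 0
    limit = max_attempts_factor * n_points
    while len(accepted) < n_points:
        if attempts >= limit:
            raise ValueError(
                f"could not place {n_points} seeds with spacing "
                f"{spacing:.1f}: geometry too crowded"
            )
        attempts += 1
        cand = sampler()
        if all(np.linalg.norm(cand - a) >= spacing for a in accepted):
            accepted.append(cand)
    return np.array(accepted)


def _sites_within(shape, sites, radius):
    """Boolean mask of grid points within ``radius`` of any site voxel."""
    m = np.ones(shape, dtype=bool)
    idx = tuple(np.asarray(sites, dtype=np.int64).T)
    m[idx] = False
    return ndimage.distance_transform_edt(m) <= radius


def _principal_axis(points: np.ndarray) -> np.ndarray:
    """Largest-scatter direction of a point cloud (deterministic sign)."""
    pts = points - points.mean(axis=0)
    cov = pts.T @ pts
    w, v = np.linalg.eigh(cov)
    axis = v[:, -1]
    big = int(np.argmax(np.abs(axis)))
    return axis if axis[big] >= 0 else -axis


def _central_fraction_keep(positions, proj_axis, fraction):
    """Split border voxels into kept (bright connection) and carved sets.

    The border cloud is parametrized by projection onto its principal
    in-surface direction; the central ``fraction`` of the projection range
    stays bright, the ends (adjacent to the junctions) are carved.
    """
    t = (positions - positions.mean(axis=0)) @ proj_axis
    lo, hi = t.min(), t.max()
    if hi - lo < 1e-9:
        return np.ones(len(positions), dtype=bool)
    center = 0.5 * (lo + hi)
    half = 0.5 * fraction * (hi - lo)
    return np.abs(t - center) <= half


def _pair_borders(labels: np.ndarray, shell: np.ndarray) -> dict:
    """6-adjacency border voxel lists per unordered positive label pair."""
    borders: dict[tuple[int, int], list] = {}
    for ax in range(labels.ndim):
        lo = [slice(None)] * labels.ndim
        hi = [slice(None)] * labels.ndim
        lo[ax] = slice(0, -1)
        hi[ax] = slice(1, None)
        a = labels[tuple(lo)]
        b = labels[tuple(hi)]
        touch = (a > 0) & (b > 0) & (a != b)
        if not touch.any():
            continue
        ia = np.argwhere(touch)
        la = a[touch]
        lb = b[touch]
        ib = ia.copy()
        ib[:, ax] += 1
        for pa, pb, ca, cb in zip(la, lb, ia, ib):
            key = (int(min(pa, pb)), int(max(pa, pb)))
            borders.setdefault(key, []).append(ca)
            borders.setdefault(key, []).append(cb)
    return {k: np.array(v) for k, v in borders.items()}


def _junction_sites(labels: np.ndarray) -> np.ndarray:
    """Voxels whose 3x3x3 neighborhood holds >= 3 distinct positive labels."""
    fg = labels > 0
    distinct_seen = np.zeros(labels.shape, dtype=np.int16)
    # count distinct labels in the window by comparing each shifted copy
    # against a running "first two" registers
    reg1 = np.zeros(labels.shape, dtype=labels.dtype)
    reg2 = np.zeros(labels.shape, dtype=labels.dtype)
    for dz in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                sh = np.roll(labels, (dz, dy, dx), axis=(0, 1, 2))
                # roll wraps; mask wrapped borders
                if dz:
                    sh[0 if dz == 1 else -1, :, :] = 0
                if dy:
                    sh[:, 0 if dy == 1 else -1, :] = 0
                if dx:
                    sh[:, :, 0 if dx == 1 else -1] = 0
                new = sh > 0
                take1 = new & (reg1 == 0)
                reg1[take1] = sh[take1]
                take2 = new & (reg1 != sh) & (reg2 == 0)
                reg2[take2] = sh[take2]
                third = new & (reg1 != sh) & (reg2 != sh) & (reg2 != 0)
                distinct_seen[third] = 3
    return np.argwhere((distinct_seen >= 3) & fg)


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------


def generate_phantom(spec: PhantomSpec) -> tuple[VolumeImage, PhantomTruth]:
    """Generate a tessellated-shell volume and its ground truth.

    Deterministic for a fixed ``spec.seed``.  Raises on infeasible geometry
    (seeds cannot be placed, or pores erase a tile).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    nz, ny, nx = spec.shape
    diameter = spec.resolved_tile_diameter()
    spacing = 0.7 * diameter

    if spec.mode == "flat":
        labels, geometry, shell = _flat_labels(spec, rng, spacing)
    else:
        labels, geometry, shell = _cap_labels(spec, rng, spacing)

    # --- carve pores -------------------------------------------------------
    sites = []
    junctions = _junction_sites(labels)
    if len(junctions):
        sites.append(junctions)
    borders = _pair_borders(labels, shell)
    for (a, b), pos in sorted(borders.items()):
        axis = _border_projection_axis(pos, geometry)
        keep = _central_fraction_keep(pos, axis, spec.connection_fraction)
        carved = pos[~keep]
        if len(carved):
            sites.append(carved)
    if sites:
        all_sites = np.unique(np.concatenate(sites, axis=0), axis=0)
        pore = _sites_within(spec.shape, all_sites, spec.pore_radius)
        labels = np.where(pore, 0, labels)

    present = np.unique(labels[labels > 0])
    if len(present) != spec.n_tiles:
        raise ValueError(
            f"infeasible geometry: pores erased "
            f"{spec.n_tiles - len(present)} of {spec.n_tiles} tiles"
        )

    landmarks = _tile_landmarks(labels, spec, geometry)
    pairs = _adjacent_pairs(labels)
    truth = PhantomTruth(
        labels=labels.astype(np.int32),
        landmarks=landmarks,
        neighbor_pairs=pairs,
        geometry=geometry,
    )

    # --- intensity synthesis (truth already frozen) ------------------------
    vol = np.full(spec.shape, spec.bg_mean, dtype=np.float64)
    fg = labels > 0
    vol[fg] = spec.fg_mean

    hole_sites = _hole_sites(labels, spec, rng)
    if len(hole_sites):
        holes = _sites_within(spec.shape, hole_sites, spec.hole_radius) & fg
        vol[holes] = spec.fg_mean - spec.hole_contrast

    if spec.drift_amplitude > 0:
        vol += _polynomial_drift(spec, rng)
    if spec.noise_sigma > 0:
        vol += rng.normal(0.0, spec.noise_sigma, size=spec.shape)

    return VolumeImage(vol, spec.voxel_size_um), truth


def _flat_labels(spec, rng, spacing):
    nz, ny, nx = spec.shape
    z0 = (nz - spec.thickness) // 2
    margin = max(1.0, 0.25 * spacing)

    def sampler():
        return rng.uniform([margin, margin], [ny - margin, nx - margin])

    seeds = _poisson_disk(rng, spec.n_tiles, spacing, sampler)
    yy, xx = np.mgrid[0:ny, 0:nx]
    grid = np.stack([yy.ravel(), xx.ravel()], axis=1)
    _, nearest = cKDTree(seeds).query(grid)
    labels2d = (nearest + 1).reshape(ny, nx).astype(np.int32)
    labels = np.zeros(spec.shape, dtype=np.int32)
    labels[z0 : z0 + spec.thickness] = labels2d
    shell = labels > 0
    geometry = {
        "mode": "flat",
        "z_mid": z0 + (spec.thickness - 1) / 2.0,
        "z_range": (z0, z0 + spec.thickness),
        "seeds_2d": seeds,
    }
    return labels, geometry, shell


def _cap_labels(spec, rng, spacing):
    nz, ny, nx = spec.shape
    radius = spec.cap_radius if spec.cap_radius else 1.0 * max(ny, nx)
    apex_z = nz - 3 - spec.thickness / 2.0  # mid-surface apex
    center = np.array([apex_z - radius, (ny - 1) / 2.0, (nx - 1) / 2.0])
    zz, yy, xx = np.mgrid[0:nz, 0:ny, 0:nx].astype(np.float64)
    r = np.sqrt(
        (zz - center[0]) ** 2 + (yy - center[1]) ** 2 + (xx - center[2]) ** 2
    )
    shell = (r >= radius - spec.thickness / 2.0) & (
        r < radius + spec.thickness / 2.0
    )
    if not shell.any():
        raise ValueError("spherical cap shell does not intersect the grid")
    mid = np.argwhere(np.abs(r - radius) <= 0.6)
    if len(mid) < spec.n_tiles:
        raise ValueError("cap mid-surface too small for the tile count")

    def sampler():
        return mid[rng.integers(len(mid))].astype(np.float64)

    seeds = _poisson_disk(rng, spec.n_tiles, spacing, sampler)
    shell_idx = np.argwhere(shell)
    _, nearest = cKDTree(seeds).query(shell_idx)
    labels = np.zeros(spec.shape, dtype=np.int32)
    labels[tuple(shell_idx.T)] = nearest + 1
    geometry = {
        "mode": "cap",
        "center": center,
        "radius": float(radius),
        "seeds_3d": seeds,
    }
    return labels, geometry, shell


def _border_projection_axis(positions, geometry):
    """In-surface principal direction of a border cloud.

    For the flat shell the cloud is projected to the xy plane; for the cap it
    is projected onto the tangent plane at its centroid, so the through-
    thickness extent never dominates the parametrization.
    """
    pos = positions.astype(np.float64)
    if geometry["mode"] == "flat":
        flat = pos.copy()
        flat[:, 0] = 0.0
        return _principal_axis(flat)
    center = geometry["center"]
    centroid = pos.mean(axis=0)
    n = centroid - center
    n = n / np.linalg.norm(n)
    rel = pos - centroid
    tangential = rel - np.outer(rel @ n, n)
    return _principal_axis(tangential + centroid)


def _tile_landmarks(labels, spec, geometry):
    """One landmark per tile at its in-surface centroid (inside own label)."""
    k = int(labels.max())
    landmarks = np.zeros((k, 3), dtype=np.float64)
    coords_by_label = {lab: np.argwhere(labels == lab) for lab in range(1, k + 1)}
    for lab in range(1, k + 1):
        pts = coords_by_label[lab].astype(np.float64)
        c = pts.mean(axis=0)
        if geometry["mode"] == "flat":
            c[0] = geometry["z_mid"]
        else:
            center = geometry["center"]
            v = c - center
            c = center + geometry["radius"] * v / np.linalg.norm(v)
        p = np.rint(c).astype(np.int64)
        p = np.clip(p, 0, np.asarray(labels.shape) - 1)
        if labels[tuple(p)] != lab:
            # centroid fell on a pore or a neighbor: snap to the nearest
            # voxel of the tile (deterministic KD-tree query)
            _, j = cKDTree(coords_by_label[lab]).query(c)
            p = coords_by_label[lab][j]
        landmarks[lab - 1] = p
    return landmarks


def _adjacent_pairs(labels):
    pairs = set()
    for ax in range(3):
        lo = [slice(None)] * 3
        hi = [slice(None)] * 3
        lo[ax] = slice(0, -1)
        hi[ax] = slice(1, None)
        a = labels[tuple(lo)]
        b = labels[tuple(hi)]
        touch = (a > 0) & (b > 0) & (a != b)
        for pa, pb in zip(a[touch].ravel(), b[touch].ravel()):
            pairs.add((int(min(pa, pb)), int(max(pa, pb))))
    return sorted(pairs)


def _hole_sites(labels, spec, rng):
    # cell lacunae are interior cavities: keep the full hole ball inside the
    # tile so a hole never opens into a pore or the outer surface
    # margin sqrt(2): no hole voxel may share a face with background, else
    # the cavity drains into the background reservoir instead of filling in
    interior = (
        ndimage.distance_transform_edt(labels > 0)
        >= spec.hole_radius + np.sqrt(2.0)
    )
    sites = []
    for lab in range(1, int(labels.max()) + 1):
        voxels = np.argwhere((labels == lab) & interior)
        n_holes = rng.poisson(spec.holes_per_tile)
        if n_holes == 0 or len(voxels) == 0:
            continue
        pick = rng.integers(0, len(voxels), size=n_holes)
        sites.append(voxels[pick])
    if not sites:
        return np.empty((0, 3), dtype=np.int64)
    return np.concatenate(sites, axis=0)


def _polynomial_drift(spec, rng):
    """Smooth quadratic intensity drift, peak-to-peak = amplitude * fg mean."""
    nz, ny, nx = spec.shape
    z = np.linspace(-1, 1, nz)[:, None, None] if nz > 1 else np.zeros((1, 1, 1))
    y = np.linspace(-1, 1, ny)[None, :, None] if ny > 1 else np.zeros((1, 1, 1))
    x = np.linspace(-1, 1, nx)[None, None, :] if nx > 1 else np.zeros((1, 1, 1))
    monomials = [z, y, x, z * z, y * y, x * x, z * y, z * x, y * x]
    coeffs = rng.uniform(-1.0, 1.0, size=len(monomials))
    g = sum(c * m for c, m in zip(coeffs, monomials))
    g = np.broadcast_to(g, spec.shape).astype(np.float64)
    span = g.max() - g.min()
    if span < 1e-12:
        return np.zeros(spec.shape)
    g = (g - g.mean()) / span
    return g * spec.drift_amplitude * spec.fg_mean


# ---------------------------------------------------------------------------
# 1D watershed fixture
# ---------------------------------------------------------------------------


def generate_profile_1d(minima_values, saddle_values) -> np.ndarray:
    """Piecewise profile interleaving basin minima and their saddles.

    ``len(saddles) == len(minima) - 1`` and each saddle must be >= both of
    its flanking minima.  Used as a hand-checkable watershed fixture.
    """
    minima = [float(v) for v in minima_values]
    saddles = [float(v) for v in saddle_values]
    if len(saddles) != len(minima) - 1:
        raise ValueError("need exactly len(minima) - 1 saddles")
    for i, s in enumerate(saddles):
        if s < minima[i] or s < minima[i + 1]:
            raise ValueError(
                f"saddle {s} below a flanking minimum "
                f"({minima[i]}, {minima[i + 1]})"
            )
    out = []
    for i, m in enumerate(minima):
        out.append(m)
        if i < len(saddles):
            out.append(saddles[i])
    return np.array(out, dtype=np.float64)


def save_phantom(out_dir, volume: VolumeImage, truth: PhantomTruth,
                 spec: PhantomSpec, fmt: str = "nrrd") -> dict:
    """Write volume, truth labels, landmarks and spec to a directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "volume": out / f"volume.{fmt}",
        "labels": out / f"labels.{fmt}",
        "landmarks": out / "landmarks.csv",
        "spec": out / "phantom_spec.yaml",
    }
    write_volume(volume, paths["volume"])
    write_volume(
        VolumeImage(truth.labels.astype(np.uint16), volume.voxel_size_um),
        paths["labels"],
    )
    write_landmarks(truth.landmarks, paths["landmarks"])
    spec.to_yaml(paths["spec"])
    return {k: str(v) for k, v in paths.items()}
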