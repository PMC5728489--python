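"""Hierarchical watershed on the inverted distance map.

Basins are flooded from every local-minimum plateau of ``-D(x)``; the first
value at which two basins meet is recorded as their *saddle*.  The hierarchy
(basins + saddle-ordered merge events) is built once; segmentations at any
persistence threshold ``T_p`` / minimum-size threshold ``T_v`` are then
extracted by replaying the events, without re-flooding:

* events are replayed in ascending saddle order;
* two current regions merge when the shallower side's persistence
  ``saddle - max(min_A, min_B)`` is below ``T_p``, or when either region
  holds fewer than ``T_v`` voxels;
* the merged region keeps the deeper minimum.

``T_p = T_v = 0`` reproduces the classical oversegmentation (one label per
local-minimum plateau).  Watershed lines are not produced: every foreground
voxel receives a label, the background stays 0.
"""

from __future__ import annotations

import heapq
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

__all__ = [
    "WatershedHierarchy",
    "build_hierarchy",
    "extract_segmentation",
    "persistence_curve",
    "suggest_persistence",
]


def _neighbor_offsets(connectivity: int) -> np.ndarray:
    offs = []
    for dz in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                if dz == dy == dx == 0:
                    continue
                if connectivity == 6 and abs(dz) + abs(dy) + abs(dx) != 1:
                    continue
                offs.append((dz, dy, dx))
    return np.array(offs, dtype=np.int64)


@dataclass
class WatershedHierarchy:
    """Basins, minima and saddle-ordered merge events.

    ``base_labels`` is the persistence-0 oversegmentation (0 = background);
    basin ``i`` has its minimum value in ``basin_min[i]`` and its deepest
    voxel in ``basin_min_voxel[i]``.  ``events`` rows are
    (saddle value, basin a, basin b), sorted ascending by saddle; the
    persistence of an event is ``saddle - max(basin minima)`` evaluated on
    the *current* regions during replay.
    """

    base_labels: np.ndarray
    basin_min: np.ndarray  # (B+1,), index 0 unused
    basin_min_voxel: np.ndarray  # (B+1, 3) int
    basin_size: np.ndarray  # (B+1,) voxel counts of base basins
    event_saddle: np.ndarray  # (E,)
    event_a: np.ndarray  # (E,) base basin ids
    event_b: np.ndarray
    connectivity: int = 26
    _sizes_cache: dict = field(default_factory=dict, repr=False)

    @property
    def n_basins(self) -> int:
        return len(self.basin_min) - 1

    @property
    def n_events(self) -> int:
        return len(self.event_saddle)


def _plateau_labels(flat_idx: np.ndarray, values: np.ndarray,
                    shape: tuple[int, int, int], offsets: np.ndarray,
                    fg_flat: np.ndarray) -> np.ndarray:
    """Connected components of equal-valued foreground voxels.

    Returns an array over the full flat grid: plateau id (>=0) on
    foreground, -1 elsewhere.
    """
    nz, ny, nx = shape
    coords = np.stack(np.unravel_index(flat_idx, shape), axis=1)
    rows, cols = [], []
    pos_of = np.full(nz * ny * nx, -1, dtype=np.int64)
    pos_of[flat_idx] = np.arange(len(flat_idx))
    vals_flat = np.full(nz * ny * nx, np.nan)
    vals_flat[flat_idx] = values
    for off in offsets:
        nb = coords + off
        ok = (
            (nb[:, 0] >= 0) & (nb[:, 0] < nz)
            & (nb[:, 1] >= 0) & (nb[:, 1] < ny)
            & (nb[:, 2] >= 0) & (nb[:, 2] < nx)
        )
        nb_flat = np.ravel_multi_index(
            (nb[ok, 0], nb[ok, 1], nb[ok, 2]), shape
        )
        src = np.nonzero(ok)[0]
        good = fg_flat[nb_flat] & (vals_flat[nb_flat] == values[src])
        rows.append(src[good])
        cols.append(pos_of[nb_flat[good]])
    r = np.concatenate(rows)
    c = np.concatenate(cols)
    n = len(flat_idx)
    g = coo_matrix((np.ones(len(r), dtype=np.int8), (r, c)), shape=(n, n))
    _, comp = connected_components(g, directed=False)
    out = np.full(nz * ny * nx, -1, dtype=np.int64)
    out[flat_idx] = comp
    return out


def build_hierarchy(
    dist: np.ndarray, mask: np.ndarray, connectivity: int = 26
) -> WatershedHierarchy:
    """Flood ``-dist`` over the mask and record the merge hierarchy.

    ``dist`` must be zero exactly off the mask.  Local-minimum plateaus are
    collapsed into single basins before flooding; equal-value ties break by
    sorted voxel index, so the result is deterministic.
    """
    m = np.asarray(mask, dtype=bool)
    d = np.asarray(dist, dtype=np.float64)
    if d.shape != m.shape:
        raise ValueError("dist and mask shapes differ")
    if not m.any():
        raise ValueError("mask is empty")
    if np.any(d[~m] != 0):
        raise ValueError("dist must be zero exactly off the mask")

    shape = m.shape
    values_full = -d  # invert: tile centers become basin bottoms
    offsets = _neighbor_offsets(connectivity)
    flat_off = (
        offsets[:, 0] * shape[1] * shape[2]
        + offsets[:, 1] * shape[2]
        + offsets[:, 2]
    )

    fg_flat = m.ravel()
    flat_idx = np.nonzero(fg_flat)[0]
    vals = values_full.ravel()[flat_idx]

    # --- minima plateaus ---------------------------------------------------
    plateau = _plateau_labels(flat_idx, vals, shape, offsets, fg_flat)
    # a plateau is a minimum iff none of its voxels has a strictly lower
    # foreground neighbor
    coords = np.stack(np.unravel_index(flat_idx, shape), axis=1)
    has_lower = np.zeros(len(flat_idx), dtype=bool)
    nz, ny, nx = shape
    vflat = values_full.ravel()
    for off in offsets:
        nb = coords + off
        ok = (
            (nb[:, 0] >= 0) & (nb[:, 0] < nz)
            & (nb[:, 1] >= 0) & (nb[:, 1] < ny)
            & (nb[:, 2] >= 0) & (nb[:, 2] < nx)
        )
        nbf = np.ravel_multi_index((nb[ok, 0], nb[ok, 1], nb[ok, 2]), shape)
        src = np.nonzero(ok)[0]
        lower = fg_flat[nbf] & (vflat[nbf] < vals[src])
        has_lower[src[lower]] = True

    n_plateaus = plateau[flat_idx].max() + 1
    plateau_has_lower = np.zeros(n_plateaus, dtype=bool)
    np.logical_or.at(plateau_has_lower, plateau[flat_idx], has_lower)
    is_min_plateau = ~plateau_has_lower

    # deterministic basin numbering: ascending smallest linear index
    first_idx = np.full(n_plateaus, np.iinfo(np.int64).max)
    np.minimum.at(first_idx, plateau[flat_idx], flat_idx)
    min_plateau_ids = np.nonzero(is_min_plateau)[0]
    order = np.argsort(first_idx[min_plateau_ids])
    basin_of_plateau = np.zeros(n_plateaus, dtype=np.int64)
    for lab, p in enumerate(min_plateau_ids[order], start=1):
        basin_of_plateau[p] = lab
    n_basins = len(min_plateau_ids)

    labels = np.zeros(nz * ny * nx, dtype=np.int32)
    seeded = basin_of_plateau[plateau[flat_idx]]
    labels[flat_idx[seeded > 0]] = seeded[seeded > 0]

    basin_min = np.zeros(n_basins + 1)
    basin_min_voxel = np.zeros((n_basins + 1, 3), dtype=np.int64)
    seed_sel = seeded > 0
    seen = np.zeros(n_basins + 1, dtype=bool)
    for fi, lab in zip(flat_idx[seed_sel], seeded[seed_sel]):
        if not seen[lab]:  # flat_idx ascending -> smallest-index seed voxel
            seen[lab] = True
            basin_min[lab] = vflat[fi]
            basin_min_voxel[lab] = np.unravel_index(fi, shape)

    # --- flooding ----------------------------------------------------------
    heap: list[tuple[float, int, int]] = []
    seq = 0
    off_list = [
        (int(dz), int(dy), int(dx), int(f))
        for (dz, dy, dx), f in zip(offsets, flat_off)
    ]

    def neighbors_of(fi: int):
        z, rem = divmod(fi, ny * nx)
        y, x = divmod(rem, nx)
        for dz, dy, dx, f in off_list:
            if 0 <= z + dz < nz and 0 <= y + dy < ny and 0 <= x + dx < nx:
                yield fi + f

    # initial frontier: unlabeled fg neighbors of seeded voxels
    seeded_idx = np.sort(flat_idx[seed_sel])
    pushed = np.zeros(nz * ny * nx, dtype=bool)
    for fi in seeded_idx:
        for nb in neighbors_of(int(fi)):
            if fg_flat[nb] and labels[nb] == 0 and not pushed[nb]:
                heapq.heappush(heap, (vflat[nb], seq, int(nb)))
                seq += 1
                pushed[nb] = True

    events: dict[tuple[int, int], float] = {}
    while heap:
        v, _, fi = heapq.heappop(heap)
        if labels[fi] != 0:
            continue
        best_lab = 0
        best_val = np.inf
        nb_labs = []
        for nb in neighbors_of(fi):
            lab = labels[nb]
            if lab > 0:
                nb_labs.append(lab)
                nv = vflat[nb]
                if nv < best_val or (nv == best_val and lab < best_lab):
                    best_val = nv
                    best_lab = lab
        if best_lab == 0:
            # plateau interior reached before its rim; re-queue after rim
            heapq.heappush(heap, (v, seq, fi))
            seq += 1
            continue
        labels[fi] = best_lab
        if len(nb_labs) > 1:
            uniq = sorted(set(nb_labs))
            for i in range(len(uniq)):
                for j in range(i + 1, len(uniq)):
                    key = (uniq[i], uniq[j])
                    if key not in events:
                        events[key] = v
        for nb in neighbors_of(fi):
            if fg_flat[nb] and labels[nb] == 0 and not pushed[nb]:
                heapq.heappush(heap, (vflat[nb], seq, int(nb)))
                seq += 1
                pushed[nb] = True

    base = labels.reshape(shape)
    basin_size = np.bincount(labels[labels > 0], minlength=n_basins + 1)

    if events:
        ev = sorted(
            ((s, a, b) for (a, b), s in events.items()),
            key=lambda t: (t[0], t[1], t[2]),
        )
        saddle = np.array([e[0] for e in ev])
        ea = np.array([e[1] for e in ev], dtype=np.int64)
        eb = np.array([e[2] for e in ev], dtype=np.int64)
    else:
        saddle = np.empty(0)
        ea = np.empty(0, dtype=np.int64)
        eb = np.empty(0, dtype=np.int64)

    return WatershedHierarchy(
        base_labels=base,
        basin_min=basin_min,
        basin_min_voxel=basin_min_voxel,
        basin_size=basin_size.astype(np.int64),
        event_saddle=saddle,
        event_a=ea,
        event_b=eb,
        connectivity=connectivity,
    )


class _UnionFind:
    __slots__ = ("parent", "comp_min", "comp_size")

    def __init__(self, basin_min: np.ndarray, basin_size: np.ndarray):
        n = len(basin_min)
        self.parent = np.arange(n, dtype=np.int64)
        self.comp_min = basin_min.copy()
        self.comp_size = basin_size.copy()

    def find(self, i: int) -> int:
        p = self.parent
        while p[i] != i:
            p[i] = p[p[i]]
            i = p[i]
        return i

    def union(self, ra: int, rb: int) -> None:
        # merged region keeps the deeper minimum
        if self.comp_min[ra] <= self.comp_min[rb]:
            keep, drop = ra, rb
        else:
            keep, drop = rb, ra
        self.parent[drop] = keep
        self.comp_size[keep] += self.comp_size[drop]


def _replay(
    h: WatershedHierarchy, t_p: float, t_v: float, inclusive: bool
) -> _UnionFind:
    uf = _UnionFind(h.basin_min, h.basin_size)
    for s, a, b in zip(h.event_saddle, h.event_a, h.event_b):
        ra, rb = uf.find(int(a)), uf.find(int(b))
        if ra == rb:
            continue
        pers = s - max(uf.comp_min[ra], uf.comp_min[rb])
        merge = pers < t_p or (inclusive and pers <= t_p)
        if not merge:
            merge = uf.comp_size[ra] < t_v or uf.comp_size[rb] < t_v
        if merge:
            uf.union(ra, rb)
    return uf


def extract_segmentation(
    h: WatershedHierarchy,
    t_p: float,
    t_v: float = 0,
    inclusive: bool = False,
) -> np.ndarray:
    """Segmentation at persistence ``t_p`` and minimum size ``t_v``.

    Replays the merge events (no re-flooding); surviving regions are
    relabelled densely 1..L in order of their smallest base basin id.
    ``inclusive`` switches the merge test from ``pers < T_p`` (default, as
    printed) to ``pers <= T_p``.
    """
    if t_p < 0 or t_v < 0:
        raise ValueError("t_p and t_v must be >= 0")
    uf = _replay(h, t_p, t_v, inclusive)
    n = h.n_basins
    root = np.array([uf.find(i) for i in range(n + 1)], dtype=np.int64)
    # dense relabel: order roots by the smallest basin id they absorb
    mapping = np.zeros(n + 1, dtype=np.int32)
    next_label = 0
    root_to_dense: dict[int, int] = {}
    for basin in range(1, n + 1):
        r = int(root[basin])
        if r not in root_to_dense:
            next_label += 1
            root_to_dense[r] = next_label
        mapping[basin] = root_to_dense[r]
    return mapping[h.base_labels]


def _count_labels(h: WatershedHierarchy, t_p: float, t_v: float,
                  inclusive: bool) -> int:
    uf = _replay(h, t_p, t_v, inclusive)
    roots = {uf.find(i) for i in range(1, h.n_basins + 1)}
    return len(roots)


def persistence_curve(
    h: WatershedHierarchy,
    t_p_values,
    t_v: float = 0,
    inclusive: bool = False,
) -> pd.DataFrame:
    """Label count versus persistence threshold (event replay, no flooding).

    ``t_p_values`` must be sorted ascending; the returned count column is
    non-increasing.
    """
    vals = np.asarray(list(t_p_values), dtype=np.float64)
    if np.any(np.diff(vals) < 0):
        raise ValueError("t_p_values must be sorted ascending")
    counts = [_count_labels(h, float(v), t_v, inclusive) for v in vals]
    return pd.DataFrame({"persistence": vals, "n_labels": counts})


def suggest_persistence(curve: pd.DataFrame, smooth_window: int = 3) -> float:
    """Advisory knee of the label-count-vs-persistence curve.

    The count drops steeply at low persistence (oversegmentation collapsing)
    and levels off near the true tile count; the knee is the threshold
    maximizing the second finite difference of the moving-average-smoothed
    curve.  A flat curve returns the smallest threshold with a warning.
    """
    t = np.asarray(curve["persistence"], dtype=np.float64)
    c = np.asarray(curve["n_labels"], dtype=np.float64)
    if len(t) < 5:
        raise ValueError("curve needs at least 5 points")
    if np.any(np.diff(c) > 0):
        raise ValueError("curve must be non-increasing")
    if np.all(c == c[0]):
        warnings.warn("flat persistence curve; returning smallest threshold")
        return float(t[0])
    if smooth_window > 1:
        pad = smooth_window // 2
        cp = np.pad(c, pad, mode="edge")
        kernel = np.ones(smooth_window) / smooth_window
        cs = np.convolve(cp, kernel, mode="valid")
    else:
        cs = c
    d2 = cs[:-2] - 2 * cs[1:-1] + cs[2:]
    # the *first* sharp turn: first local maximum of the (positive) second
    # difference, not the global one — the curve usually has a second corner
    # where everything collapses into one label, which is not the knee
    padded = np.concatenate([[-np.inf], d2, [-np.inf]])
    for i in range(1, len(padded) - 1):
        if padded[i] > 0 and padded[i] >= padded[i - 1] and padded[i] > padded[i + 1]:
            return float(t[i])
    knee = int(np.argmax(d2)) + 1
    return float(t[knee])
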