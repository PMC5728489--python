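"""Region adjacency graph and scriptable proofreading operations.

The segmented tile network is represented as a graph with one vertex per
label (at the label's centroid) and one edge per pair of labels sharing at
least one voxel face.  The graph carries per-label statistics — volume,
neighbor count, nearest-vertex distance, in-plane width, height, and a
curvature proxy — whose outliers point at likely segmentation errors.
Corrections are explicit edits: merge labels, split a label by a local
watershed or by spectral clustering of its voxel graph.  Edits never change
which voxels are foreground, only how they are labelled, and every edit can
be journalled so a proofreading session replays deterministically.
Flagging is advisory; no correction is applied automatically.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy import ndimage, sparse
from scipy.spatial import cKDTree
from sklearn.cluster import KMeans

from . import watershed as ws

__all__ = [
    "LabelStats",
    "EditJournal",
    "build_region_graph",
    "compute_stats",
    "flag_outliers",
    "merge_labels",
    "split_label_watershed",
    "split_label_spectral",
    "merge_then_split",
    "graph_to_csv",
    "replay_journal",
]


@dataclass(frozen=True)
class LabelStats:
    """Per-label statistics used for outlier-based error detection.

    ``width`` is the largest voxel extent along the two in-layer principal
    axes, ``height`` the extent along the least-scatter axis; ``curvature``
    is the RMS deviation of the vertex's graph neighborhood from its
    best-fit plane, normalized by the mean neighbor distance (NaN when the
    vertex has fewer than 3 neighbors, as is ``nearest_vertex_distance``
    for an isolated vertex).
    """

    volume: int
    n_neighbors: int
    nearest_vertex_distance: float
    width: float
    height: float
    curvature: float


def build_region_graph(labels: np.ndarray) -> nx.Graph:
    """Graph with one vertex per positive label, edges for face contact.

    Node attributes: ``centroid`` (z, y, x float), ``volume``.  Edge
    attribute: ``contact_faces`` (number of shared voxel faces,
    6-adjacency).  Deterministic.
    """
    lab = np.asarray(labels)
    ids = np.unique(lab[lab > 0])
    g = nx.Graph()
    if len(ids) == 0:
        return g
    centroids = ndimage.center_of_mass(lab > 0, lab, ids)
    volumes = ndimage.sum_labels(np.ones_like(lab), lab, ids)
    for i, c, v in zip(ids, centroids, volumes):
        g.add_node(int(i), centroid=np.asarray(c, dtype=np.float64),
                   volume=int(v))
    contact: dict[tuple[int, int], int] = {}
    for ax in range(3):
        lo = [slice(None)] * 3
        hi = [slice(None)] * 3
        lo[ax] = slice(0, -1)
        hi[ax] = slice(1, None)
        a = lab[tuple(lo)]
        b = lab[tuple(hi)]
        touch = (a > 0) & (b > 0) & (a != b)
        if not touch.any():
            continue
        pa = np.minimum(a[touch], b[touch]).astype(np.int64)
        pb = np.maximum(a[touch], b[touch]).astype(np.int64)
        key = pa * (lab.max() + 1) + pb
        uniq, counts = np.unique(key, return_counts=True)
        for k, c in zip(uniq, counts):
            pair = (int(k // (lab.max() + 1)), int(k % (lab.max() + 1)))
            contact[pair] = contact.get(pair, 0) + int(c)
    for (a, b), c in sorted(contact.items()):
        g.add_edge(a, b, contact_faces=c)
    return g


def compute_stats(labels: np.ndarray, graph: nx.Graph) -> dict[int, LabelStats]:
    """Per-label statistics record for every vertex of the graph."""
    lab = np.asarray(labels)
    nodes = sorted(graph.nodes)
    centroids = np.array([graph.nodes[n]["centroid"] for n in nodes])
    if len(nodes) >= 2:
        tree = cKDTree(centroids)
        dists, _ = tree.query(centroids, k=2)
        nearest = dists[:, 1]
    else:
        nearest = np.full(len(nodes), np.nan)
    stats = {}
    slices = ndimage.find_objects(lab)
    for idx, n in enumerate(nodes):
        sl = slices[n - 1]
        sub = lab[sl] == n
        pts = np.argwhere(sub).astype(np.float64)
        vol = len(pts)
        ctr = pts.mean(axis=0)
        q = pts - ctr
        cov = q.T @ q / max(vol, 1)
        w, v = np.linalg.eigh(cov)  # ascending: v[:,0] least scatter
        proj = q @ v
        extents = proj.max(axis=0) - proj.min(axis=0) + 1.0
        height = float(extents[0])
        width = float(max(extents[1], extents[2]))
        stats[n] = LabelStats(
            volume=int(graph.nodes[n]["volume"]),
            n_neighbors=graph.degree[n],
            nearest_vertex_distance=float(nearest[idx]),
            width=width,
            height=height,
            curvature=_curvature_proxy(graph, n),
        )
    return stats


def _curvature_proxy(graph: nx.Graph, node: int) -> float:
    """RMS plane residual of the vertex neighborhood / mean neighbor distance."""
    nbrs = list(graph.neighbors(node))
    if len(nbrs) < 3:
        return float("nan")
    pts = np.array(
        [graph.nodes[node]["centroid"]]
        + [graph.nodes[m]["centroid"] for m in nbrs]
    )
    ctr = pts.mean(axis=0)
    q = pts - ctr
    _, v = np.linalg.eigh(q.T @ q)
    residuals = q @ v[:, 0]
    rms = float(np.sqrt(np.mean(residuals**2)))
    mean_dist = float(
        np.mean(
            np.linalg.norm(pts[1:] - pts[0], axis=1)
        )
    )
    return rms / mean_dist if mean_dist > 0 else float("nan")


def flag_outliers(stats: dict[int, LabelStats], z_cut: float = 3.0
                  ) -> pd.DataFrame:
    """Advisory outlier list via robust (median/MAD) z-scores.

    Returns a DataFrame (label, statistic, value, z) with one row per
    flagged label/statistic pair; no correction is applied.
    """
    if len(stats) < 5:
        raise ValueError("need at least 5 labels for outlier statistics")
    rows = []
    labels = sorted(stats)
    table = pd.DataFrame([asdict(stats[k]) for k in labels], index=labels)
    for col in table.columns:
        x = table[col].to_numpy(dtype=np.float64)
        ok = np.isfinite(x)
        if ok.sum() < 5:
            continue
        med = np.median(x[ok])
        mad = np.median(np.abs(x[ok] - med))
        if mad <= 0:
            continue
        z = 0.6745 * (x - med) / mad
        for lab_id, zi, xi in zip(np.asarray(labels)[ok], z[ok], x[ok]):
            if abs(zi) > z_cut:
                rows.append(
                    {"label": int(lab_id), "statistic": col,
                     "value": float(xi), "z": float(zi)}
                )
    return pd.DataFrame(rows, columns=["label", "statistic", "value", "z"])


# ---------------------------------------------------------------------------
# edits
# ---------------------------------------------------------------------------


class EditJournal:
    """Append-only record of proofreading edits, sufficient for replay."""

    def __init__(self) -> None:
        self.entries: list[dict] = []

    def append(self, op: str, **kwargs) -> None:
        self.entries.append({"op": op, **kwargs})

    def to_jsonl(self, path) -> None:
        with open(path, "w") as f:
            for e in self.entries:
                f.write(json.dumps(e) + "\n")

    @classmethod
    def from_jsonl(cls, path) -> "EditJournal":
        j = cls()
        for line in Path(path).read_text().splitlines():
            if line.strip():
                j.entries.append(json.loads(line))
        return j


def merge_labels(labels: np.ndarray, ids, journal: EditJournal | None = None
                 ) -> np.ndarray:
    """Merge the given labels into the smallest id of the set.

    Total labelled volume is conserved; the result is a coarsening of the
    input partition.  Unknown ids are rejected.
    """
    ids = sorted(int(i) for i in ids)
    if not ids:
        raise ValueError("ids must be nonempty")
    lab = np.asarray(labels)
    present = set(np.unique(lab[lab > 0]).tolist())
    missing = [i for i in ids if i not in present]
    if missing:
        raise ValueError(f"labels not present in field: {missing}")
    out = lab.copy()
    target = ids[0]
    for i in ids[1:]:
        out[out == i] = target
    if journal is not None:
        journal.append("merge", ids=ids)
    return out


def split_label_watershed(
    labels: np.ndarray,
    dist: np.ndarray,
    label_id: int,
    t_p_local: float,
    t_v: float = 0,
    journal: EditJournal | None = None,
) -> np.ndarray:
    """Split one label by a hierarchical watershed restricted to its voxels.

    Only the selected region enters the watershed; the resulting parts get
    fresh ids above the current maximum.  If the split yields a single part
    the field is returned unchanged with a notice.
    """
    lab = np.asarray(labels)
    region = lab == int(label_id)
    if not region.any():
        raise ValueError(f"label {label_id} not present")
    sub_dist = np.where(region, np.asarray(dist, dtype=np.float64), 0.0)
    h = ws.build_hierarchy(sub_dist, region)
    parts = ws.extract_segmentation(h, t_p_local, t_v)
    n_parts = int(parts.max())
    if n_parts <= 1:
        warnings.warn(
            f"watershed split of label {label_id} produced a single part; "
            "field unchanged"
        )
        return lab.copy()
    out = lab.copy()
    base = int(lab.max())
    out[region] = base + parts[region]
    if journal is not None:
        journal.append("split_watershed", label=int(label_id),
                       t_p=float(t_p_local), t_v=float(t_v))
    return out


def split_label_spectral(
    labels: np.ndarray,
    label_id: int,
    k: int,
    max_voxels: int = 20000,
    journal: EditJournal | None = None,
) -> np.ndarray:
    """Split one label into ``k`` parts by normalized spectral clustering.

    Builds the 6-adjacency voxel graph of the region with unit weights,
    embeds voxels with the first ``k`` eigenvectors of the symmetric
    normalized Laplacian, clusters with seeded k-means, then reassigns stray
    26-connected components to the neighboring part with the largest
    contact so every part comes out connected.  Regions larger than
    ``max_voxels`` are rejected (use the watershed split instead).
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    lab = np.asarray(labels)
    region = lab == int(label_id)
    n = int(region.sum())
    if n == 0:
        raise ValueError(f"label {label_id} not present")
    if n > max_voxels:
        raise ValueError(
            f"region has {n} voxels > cap {max_voxels}; "
            "use split_label_watershed for large regions"
        )
    coords = np.argwhere(region)
    index = -np.ones(lab.shape, dtype=np.int64)
    index[tuple(coords.T)] = np.arange(n)
    rows, cols = [], []
    for ax in range(3):
        shifted = coords.copy()
        shifted[:, ax] += 1
        ok = shifted[:, ax] < lab.shape[ax]
        j = index[tuple(shifted[ok].T)]
        i = np.arange(n)[ok]
        good = j >= 0
        rows.append(i[good])
        cols.append(j[good])
    r = np.concatenate(rows)
    c = np.concatenate(cols)
    adj = sparse.coo_matrix(
        (np.ones(len(r)), (r, c)), shape=(n, n)
    )
    adj = (adj + adj.T).tocsr()
    deg = np.asarray(adj.sum(axis=1)).ravel()
    deg[deg == 0] = 1.0
    d_inv_sqrt = sparse.diags(1.0 / np.sqrt(deg))
    lap = sparse.identity(n) - d_inv_sqrt @ adj @ d_inv_sqrt
    if n <= 1500:
        w, v = np.linalg.eigh(lap.toarray())
        emb = v[:, :k]
    else:
        w, v = sparse.linalg.eigsh(lap.tocsc(), k=k, sigma=0, which="LM")
        emb = v[:, np.argsort(w)]
    norms = np.linalg.norm(emb, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    emb = emb / norms
    km = KMeans(n_clusters=k, random_state=0, n_init=10)
    assign = km.fit_predict(emb)
    assign = _reconnect_parts(coords, assign, k, lab.shape)
    out = lab.copy()
    base = int(lab.max())
    out[tuple(coords.T)] = base + 1 + assign
    if journal is not None:
        journal.append("split_spectral", label=int(label_id), k=int(k))
    return out


def _reconnect_parts(coords, assign, k, shape):
    """Keep each part's largest 26-component; strays go to the neighboring
    part with the largest face contact (iterated until stable)."""
    part = np.zeros(shape, dtype=np.int32)
    part[tuple(coords.T)] = assign + 1
    struct = ndimage.generate_binary_structure(3, 3)
    for _ in range(k * 4):  # few passes suffice in practice
        changed = False
        for p in range(1, k + 1):
            comp, nc = ndimage.label(part == p, structure=struct)
            if nc <= 1:
                continue
            sizes = ndimage.sum_labels(np.ones_like(comp), comp,
                                       range(1, nc + 1))
            keep = int(np.argmax(sizes)) + 1
            for ci in range(1, nc + 1):
                if ci == keep:
                    continue
                stray = comp == ci
                target = _largest_contact_part(part, stray, exclude=p)
                if target > 0:
                    part[stray] = target
                    changed = True
        if not changed:
            break
    out = part[tuple(coords.T)] - 1
    # guarantee nonempty parts (k-means can collapse a cluster)
    for p in range(k):
        if not np.any(out == p):
            raise ValueError(
                "spectral split degenerated to fewer than k nonempty parts; "
                "reduce k"
            )
    return out


def _largest_contact_part(part, stray, exclude):
    best, best_faces = 0, 0
    for ax in range(3):
        for sign in (1, -1):
            shifted = np.roll(stray, sign, axis=ax)
            edge = [slice(None)] * 3
            edge[ax] = 0 if sign == 1 else -1
            shifted[tuple(edge)] = False
            touching = part[shifted & ~stray]
            touching = touching[(touching > 0) & (touching != exclude)]
            if len(touching):
                vals, counts = np.unique(touching, return_counts=True)
                i = int(np.argmax(counts))
                if counts[i] > best_faces:
                    best_faces = int(counts[i])
                    best = int(vals[i])
    return best


def merge_then_split(
    labels: np.ndarray,
    dist: np.ndarray | None,
    ids,
    method: str = "spectral",
    param: float | int = 2,
    journal: EditJournal | None = None,
) -> np.ndarray:
    """Merge the given labels, then split the merged region.

    ``method`` is ``"spectral"`` (param = number of parts k) or
    ``"watershed"`` (param = local persistence; requires ``dist``).  The
    combined voxel set is conserved.  The canonical use is fixing a badly
    placed boundary: merge the labels around it, split them again cleanly.
    """
    merged = merge_labels(labels, ids, journal=None)
    target = sorted(int(i) for i in ids)[0]
    if method == "spectral":
        out = split_label_spectral(merged, target, int(param), journal=None)
    elif method == "watershed":
        if dist is None:
            raise ValueError("watershed split needs a distance map")
        out = split_label_watershed(merged, dist, target, float(param),
                                    journal=None)
    else:
        raise ValueError(f"unknown split method {method!r}")
    if journal is not None:
        journal.append("merge_then_split", ids=sorted(int(i) for i in ids),
                       method=method, param=param)
    return out


def replay_journal(journal: EditJournal, labels: np.ndarray,
                   dist: np.ndarray | None = None) -> np.ndarray:
    """Re-apply a journalled proofreading session to a label field."""
    out = np.asarray(labels).copy()
    for e in journal.entries:
        op = e["op"]
        if op == "merge":
            out = merge_labels(out, e["ids"])
        elif op == "split_watershed":
            out = split_label_watershed(out, dist, e["label"], e["t_p"],
                                        e.get("t_v", 0))
        elif op == "split_spectral":
            out = split_label_spectral(out, e["label"], e["k"])
        elif op == "merge_then_split":
            out = merge_then_split(out, dist, e["ids"], e["method"],
                                   e["param"])
        else:
            raise ValueError(f"unknown journal op {op!r}")
    return out


def graph_to_csv(graph: nx.Graph, stats: dict[int, LabelStats],
                 vertices_path, edges_path) -> None:
    """Export the graph as a vertices.csv / edges.csv pair.

    Vertex coordinates are written x,y,z (0-based voxel coordinates).
    """
    rows = []
    for n in sorted(graph.nodes):
        c = graph.nodes[n]["centroid"]
        row = {"label": n, "x": c[2], "y": c[1], "z": c[0]}
        if n in stats:
            row.update(asdict(stats[n]))
        rows.append(row)
    pd.DataFrame(rows).to_csv(vertices_path, index=False)
    erows = [
        {"label_a": a, "label_b": b,
         "contact_faces": d.get("contact_faces", 0)}
        for a, b, d in sorted(graph.edges(data=True))
    ]
    pd.DataFrame(erows, columns=["label_a", "label_b", "contact_faces"]).to_csv(
        edges_path, index=False
    )
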