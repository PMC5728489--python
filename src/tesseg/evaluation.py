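"""Segmentation evaluation: landmark precision/recall, Rand index, VI.

Landmark counting rules (one manually placed landmark near each true tile
center): a label region hit by at least one landmark is a true positive; a
region with n hits contributes n - 1 false negatives (an undersegmented
n-cluster needing a split); a region with zero hits is a false positive
(oversegmentation needing a merge).  Then

    precision = t_p / (t_p + f_p),    recall = t_p / (t_p + f_n).

Landmarks falling on background are excluded from the counts and reported
separately (real landmarks sit on the rendered surface and always hit
foreground).  Hits use nearest-voxel rounding.

Region-based comparison of two partitions restricted to a common foreground
ROI: the Rand index (percentage of voxel pairs on which the partitions
agree) and the variation of information VI = H(A) + H(B) - 2 I(A;B) in nats
(a metric; base-2 available), both computed from the voxel-level
contingency table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import distmap, watershed as ws
from .diffusion import DiffusionParams, smooth_anisotropic
from .foreground import ThresholdParams, segment_foreground

__all__ = [
    "PRReport",
    "landmark_pr",
    "rand_index",
    "variation_of_information",
    "compare_2d_vs_3d",
]


@dataclass(frozen=True)
class PRReport:
    """Landmark-based precision/recall with per-label hit bookkeeping."""

    t_p: int
    f_n: int
    f_p: int
    precision: float
    recall: float
    hits_per_label: dict[int, int] = field(default_factory=dict)
    zero_hit_labels: list = field(default_factory=list)
    multi_hit_labels: list = field(default_factory=list)
    unassigned_landmarks: list = field(default_factory=list)


def landmark_pr(labels: np.ndarray, landmarks: np.ndarray) -> PRReport:
    """Apply the landmark hit rules to a label field.

    ``landmarks`` is (N, 3) in internal (z, y, x) voxel coordinates; points
    must lie inside the grid.  Raises on a field without positive labels.
    """
    lab = np.asarray(labels)
    ids = np.unique(lab[lab > 0])
    if len(ids) == 0:
        raise ValueError("label field has no positive labels")
    pts = np.asarray(landmarks, dtype=np.float64)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError("landmarks must be an (N, 3) array")
    idx = np.rint(pts).astype(np.int64)
    for ax in range(3):
        if np.any(idx[:, ax] < 0) or np.any(idx[:, ax] >= lab.shape[ax]):
            raise ValueError("landmark outside the volume grid")
    hit_labels = lab[tuple(idx.T)]
    unassigned = np.nonzero(hit_labels == 0)[0].tolist()
    hits = {int(i): 0 for i in ids}
    for h in hit_labels:
        if h > 0:
            hits[int(h)] += 1
    t_p = sum(1 for v in hits.values() if v >= 1)
    f_n = sum(v - 1 for v in hits.values() if v >= 1)
    f_p = sum(1 for v in hits.values() if v == 0)
    precision = t_p / (t_p + f_p) if (t_p + f_p) else 0.0
    recall = t_p / (t_p + f_n) if (t_p + f_n) else 0.0
    return PRReport(
        t_p=t_p, f_n=f_n, f_p=f_p, precision=precision, recall=recall,
        hits_per_label=hits,
        zero_hit_labels=[k for k, v in sorted(hits.items()) if v == 0],
        multi_hit_labels=[k for k, v in sorted(hits.items()) if v > 1],
        unassigned_landmarks=unassigned,
    )


def _contingency(a, b, roi):
    av = np.asarray(a)[roi]
    bv = np.asarray(b)[roi]
    if av.size < 2:
        raise ValueError("ROI must contain at least 2 voxels")
    if np.any(av <= 0) or np.any(bv <= 0):
        raise ValueError("ROI must lie inside positive labels of both fields")
    ua, ia = np.unique(av, return_inverse=True)
    ub, ib = np.unique(bv, return_inverse=True)
    table = np.zeros((len(ua), len(ub)), dtype=np.int64)
    np.add.at(table, (ia, ib), 1)
    return table, ua, ub


def rand_index(a: np.ndarray, b: np.ndarray, roi: np.ndarray) -> float:
    """Rand index of two label fields over an ROI, in percent.

    Fraction of unordered voxel pairs that are co-labelled in both fields or
    separated in both, x100.  Computed from the contingency table (O(N)),
    equal to exhaustive pair enumeration.
    """
    table, _, _ = _contingency(a, b, np.asarray(roi, dtype=bool))
    n = table.sum()
    pairs = n * (n - 1) // 2

    def c2(x):
        return (x * (x - 1) // 2).sum()

    p = c2(table)
    pa = c2(table.sum(axis=1))
    pb = c2(table.sum(axis=0))
    agree = pairs - pa - pb + 2 * p
    return 100.0 * agree / pairs


def variation_of_information(
    a: np.ndarray,
    b: np.ndarray,
    roi: np.ndarray,
    base: str = "e",
    return_contributions: bool = False,
):
    """Variation of information between two label fields over an ROI.

    VI = H(A) + H(B) - 2 I(A;B), computed from the contingency table;
    ``base='e'`` gives nats (default), ``'2'`` bits.  With
    ``return_contributions`` also returns a DataFrame of per-label-pair
    contributions (descending), so the worst-disagreeing label pair can be
    listed.
    """
    table, ua, ub = _contingency(a, b, np.asarray(roi, dtype=bool))
    n = table.sum()
    log = np.log2 if base == "2" else np.log
    p = table / n
    pa = p.sum(axis=1, keepdims=True)
    pb = p.sum(axis=0, keepdims=True)
    nz = p > 0
    contrib = np.zeros_like(p)
    # VI = sum_ij p_ij [ log(p_i/p_ij) + log(p_j/p_ij) ]
    contrib[nz] = p[nz] * (
        log(np.broadcast_to(pa, p.shape)[nz] / p[nz])
        + log(np.broadcast_to(pb, p.shape)[nz] / p[nz])
    )
    vi = float(contrib.sum())
    if not return_contributions:
        return vi
    ii, jj = np.nonzero(nz)
    df = pd.DataFrame(
        {
            "label_a": ua[ii],
            "label_b": ub[jj],
            "contribution": contrib[ii, jj],
        }
    ).sort_values("contribution", ascending=False, ignore_index=True)
    return vi, df


def compare_2d_vs_3d(
    image: np.ndarray,
    landmarks: np.ndarray,
    diffusion_params: DiffusionParams,
    threshold_params: ThresholdParams,
    persistences=range(0, 81),
    t_v: float = 50,
    n_rays: int = 1214,
    m_rays: int = 361,
    cap: float | None = None,
) -> pd.DataFrame:
    """Paired precision/recall sweeps for the 2D and 3D distance maps.

    Runs smoothing + foreground segmentation once, computes both distance
    maps, builds both watershed hierarchies, and evaluates the landmark
    precision/recall at every persistence value.  Returns a DataFrame with
    columns (variant, persistence, n_labels, precision, recall), sorted and
    deterministic.
    """
    smoothed = smooth_anisotropic(image, diffusion_params)
    mask = segment_foreground(smoothed, threshold_params)
    rows = []
    for variant, dist in (
        ("2d", distmap.distance_map_2d(mask, n_rays, m_rays, cap)),
        ("3d", distmap.distance_map_3d(mask)),
    ):
        h = ws.build_hierarchy(dist, mask)
        for t_p in persistences:
            seg = ws.extract_segmentation(h, float(t_p), t_v)
            rep = landmark_pr(seg, landmarks)
            rows.append(
                {
                    "variant": variant,
                    "persistence": float(t_p),
                    "n_labels": int(seg.max()),
                    "precision": rep.precision,
                    "recall": rep.recall,
                }
            )
    return pd.DataFrame(rows).sort_values(
        ["variant", "persistence"], ignore_index=True
    )
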