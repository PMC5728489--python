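"""Region graph: adjacency, statistics, outliers, merge/split edits."""

import itertools

import numpy as np
import pytest

from tesseg import (
    EditJournal,
    build_region_graph,
    compute_stats,
    distance_map_2d,
    flag_outliers,
    merge_labels,
    merge_then_split,
    replay_journal,
    split_label_spectral,
    split_label_watershed,
)
from conftest import three_tile_row
from tesseg.regiongraph import LabelStats


def _partition_signature(labels):
    """Voxel co-assignment signature, invariant to label renaming."""
    fg = labels > 0
    vals = labels[fg]
    _, inv = np.unique(vals, return_inverse=True)
    return fg, inv


# --- build_region_graph ----------------------------------------------------


def test_two_touching_labels():
    lab = np.zeros((3, 4, 4), dtype=np.int32)
    lab[1, :, :2] = 1
    lab[1, :, 2:] = 2
    g = build_region_graph(lab)
    assert sorted(g.nodes) == [1, 2]
    assert list(g.edges) == [(1, 2)]
    assert g.edges[1, 2]["contact_faces"] == 4


def test_single_label_no_edges():
    lab = np.zeros((3, 3, 3), dtype=np.int32)
    lab[1, 1, 1] = 5
    g = build_region_graph(lab)
    assert list(g.nodes) == [5]
    assert g.number_of_edges() == 0


def test_graph_matches_phantom_truth(small_phantom):
    _, truth, _ = small_phantom
    g = build_region_graph(truth.labels)
    assert sorted(tuple(sorted(e)) for e in g.edges) == truth.neighbor_pairs


# --- compute_stats ---------------------------------------------------------


def test_stats_on_axis_aligned_box():
    lab = np.zeros((10, 14, 14), dtype=np.int32)
    lab[3:6, 2:12, 2:12] = 1  # 3 x 10 x 10 box
    g = build_region_graph(lab)
    s = compute_stats(lab, g)[1]
    assert s.volume == 300
    assert s.width == pytest.approx(10.0)
    assert s.height == pytest.approx(3.0)
    assert np.isnan(s.nearest_vertex_distance)  # isolated vertex


def test_curvature_flat_vs_cap(small_phantom, cap_phantom):
    """Curvature proxy near zero on the flat shell, larger on the cap."""
    def mean_curv(truth):
        g = build_region_graph(truth.labels)
        stats = compute_stats(truth.labels, g)
        vals = [s.curvature for s in stats.values() if np.isfinite(s.curvature)]
        return np.mean(vals)

    flat = mean_curv(small_phantom[1])
    cap = mean_curv(cap_phantom[1])
    assert flat < 0.1
    assert cap > flat


# --- flag_outliers ---------------------------------------------------------


def _uniform_stats(n, volume=100):
    rng = np.random.default_rng(0)
    return {
        i: LabelStats(
            volume=volume + int(rng.integers(-3, 4)),
            n_neighbors=6,
            nearest_vertex_distance=10.0 + rng.normal(0, 0.1),
            width=12.0 + rng.normal(0, 0.2),
            height=4.0,
            curvature=0.01,
        )
        for i in range(1, n + 1)
    }


def test_no_outliers_in_uniform_population():
    flagged = flag_outliers(_uniform_stats(20), z_cut=3.0)
    assert flagged.empty


def test_large_volume_outlier_flagged():
    stats = _uniform_stats(20)
    s = stats[7]
    stats[7] = LabelStats(
        volume=s.volume * 10, n_neighbors=s.n_neighbors,
        nearest_vertex_distance=s.nearest_vertex_distance,
        width=s.width, height=s.height, curvature=s.curvature,
    )
    flagged = flag_outliers(stats, z_cut=3.0)
    assert 7 in flagged["label"].tolist()
    assert "volume" in flagged[flagged["label"] == 7]["statistic"].tolist()


def test_merged_tile_pair_flagged(small_phantom):
    """An artificial undersegmentation (two tiles fused) shows up as a
    volume outlier."""
    _, truth, _ = small_phantom
    a, b = truth.neighbor_pairs[0]
    lab = merge_labels(truth.labels, [a, b])
    g = build_region_graph(lab)
    stats = compute_stats(lab, g)
    flagged = flag_outliers(stats, z_cut=2.5)
    assert a in flagged["label"].tolist()


def test_outliers_need_five_labels():
    with pytest.raises(ValueError):
        flag_outliers(_uniform_stats(4))


# --- merge -----------------------------------------------------------------


def test_merge_single_id_identity(small_phantom):
    _, truth, _ = small_phantom
    out = merge_labels(truth.labels, [3])
    np.testing.assert_array_equal(out, truth.labels)


def test_merge_conserves_volume_and_coarsens():
    lab = np.zeros((3, 6, 6), dtype=np.int32)
    lab[1, :, :2] = 1
    lab[1, :, 2:4] = 2
    lab[1, :, 4:] = 5
    out = merge_labels(lab, [2, 5])
    assert (out > 0).sum() == (lab > 0).sum()
    assert (out == 2).sum() == (lab == 2).sum() + (lab == 5).sum()
    # coarsening: old co-assigned voxels stay co-assigned
    fg = lab > 0
    for v in np.unique(lab[fg]):
        assert len(np.unique(out[lab == v])) == 1


def test_merge_unknown_id_rejected():
    lab = np.zeros((2, 2, 2), dtype=np.int32)
    lab[0, 0, 0] = 1
    with pytest.raises(ValueError):
        merge_labels(lab, [1, 9])
    with pytest.raises(ValueError):
        merge_labels(lab, [])


# --- watershed split -------------------------------------------------------


def _dumbbell_labels():
    """Two in-plane discs joined by a thin neck, in a thin slab."""
    lab = np.zeros((8, 30, 50), dtype=np.int32)
    yy, xx = np.mgrid[0:30, 0:50]
    left = (yy - 15) ** 2 + (xx - 12) ** 2 <= 81
    right = (yy - 15) ** 2 + (xx - 38) ** 2 <= 81
    neck = (np.abs(yy - 15) <= 1) & (xx >= 12) & (xx <= 38)
    shape2d = left | right | neck
    lab[3:6, shape2d] = 1
    return lab


def test_watershed_split_dumbbell():
    lab = _dumbbell_labels()
    dist = distance_map_2d(lab > 0, 300, 120)
    out = split_label_watershed(lab, dist, 1, t_p_local=4.0)
    parts = np.unique(out[out > 0])
    assert len(parts) == 2
    # conservation: union of parts = original voxel set
    np.testing.assert_array_equal(out > 0, lab > 0)
    # the two disc centers end up in different parts
    assert out[4, 15, 12] != out[4, 15, 38]


def test_watershed_split_convex_region_unchanged():
    lab = np.zeros((8, 24, 24), dtype=np.int32)
    yy, xx = np.mgrid[0:24, 0:24]
    lab[3:6, (yy - 12) ** 2 + (xx - 12) ** 2 <= 64] = 1
    dist = distance_map_2d(lab > 0, 300, 120)
    with pytest.warns(UserWarning, match="single part"):
        out = split_label_watershed(lab, dist, 1, t_p_local=2.0)
    np.testing.assert_array_equal(out, lab)


# --- spectral split --------------------------------------------------------


def _bridged_cubes():
    lab = np.zeros((4, 4, 7), dtype=np.int32)
    lab[1:3, 1:3, 0:2] = 1  # left 2x2x2 cube
    lab[1:3, 1:3, 5:7] = 1  # right cube
    lab[1, 1, 2:5] = 1  # 3-voxel bridge
    return lab


def _bruteforce_min_ncut(coords):
    """Exhaustive minimum normalized cut over all 2-partitions (<=20 voxels)."""
    n = len(coords)
    adj = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            if np.abs(coords[i] - coords[j]).sum() == 1:
                adj[i, j] = adj[j, i] = 1
    deg = adj.sum(axis=1)
    best, best_cut = np.inf, None
    for bits in range(1, 2 ** (n - 1)):
        side = np.array([(bits >> i) & 1 for i in range(n)], dtype=bool)
        if side.all() or not side.any():
            continue
        cut = adj[np.ix_(side, ~side)].sum()
        va, vb = deg[side].sum(), deg[~side].sum()
        if va == 0 or vb == 0:
            continue
        ncut = cut / va + cut / vb
        if ncut < best - 1e-12:
            best, best_cut = ncut, side.copy()
    return best_cut


def test_spectral_split_bridged_cubes_matches_ncut_oracle():
    lab = _bridged_cubes()
    out = split_label_spectral(lab, 1, k=2)
    np.testing.assert_array_equal(out > 0, lab > 0)  # conservation
    coords = np.argwhere(lab == 1)
    oracle_side = _bruteforce_min_ncut(coords)
    got = out[tuple(coords.T)]
    # each cube must be wholly inside one part, as in the optimal cut
    left = coords[:, 2] <= 1
    right = coords[:, 2] >= 5
    assert len(np.unique(got[left])) == 1
    assert len(np.unique(got[right])) == 1
    assert got[left][0] != got[right][0]
    # oracle agrees that the optimal cut separates the cubes
    assert len(np.unique(oracle_side[left])) == 1
    assert len(np.unique(oracle_side[right])) == 1
    assert oracle_side[left][0] != oracle_side[right][0]


def test_spectral_split_symmetric_bar_balanced():
    lab = np.zeros((3, 3, 12), dtype=np.int32)
    lab[1, 1, :] = 1
    out = split_label_spectral(lab, 1, k=2)
    sizes = sorted(int((out == v).sum()) for v in np.unique(out[out > 0]))
    assert abs(sizes[0] - sizes[1]) <= 1


def test_spectral_split_validation():
    lab = _bridged_cubes()
    with pytest.raises(ValueError):
        split_label_spectral(lab, 1, k=1)
    with pytest.raises(ValueError):
        split_label_spectral(lab, 9, k=2)
    with pytest.raises(ValueError, match="cap"):
        split_label_spectral(lab, 1, k=2, max_voxels=5)


# --- merge then split ------------------------------------------------------


def test_merge_then_split_recovers_three_tiles():
    lab, landmarks = three_tile_row()
    # the defect: tiles 2 and 3 come out fused
    bad = merge_labels(lab, [2, 3])
    out = merge_then_split(bad, None, [1, 2], method="spectral", param=3)
    np.testing.assert_array_equal(out > 0, lab > 0)  # conservation
    parts = np.unique(out[out > 0])
    assert len(parts) == 3
    hit = out[tuple(np.rint(landmarks).astype(int).T)]
    assert len(np.unique(hit)) == 3  # one recovered part per true tile


def test_merge_then_split_fixed_point():
    """Re-applying the same edit to the recovered parts changes nothing."""
    lab, _ = three_tile_row()
    bad = merge_labels(lab, [2, 3])
    once = merge_then_split(bad, None, [1, 2], method="spectral", param=3)
    ids = sorted(np.unique(once[once > 0]))
    twice = merge_then_split(once, None, ids, method="spectral", param=3)
    fg1, sig1 = _partition_signature(once)
    fg2, sig2 = _partition_signature(twice)
    np.testing.assert_array_equal(fg1, fg2)
    np.testing.assert_array_equal(sig1, sig2)


# --- journal ---------------------------------------------------------------


def test_journal_replay_reproduces_edits(tmp_path):
    lab, _ = three_tile_row()
    j = EditJournal()
    edited = merge_labels(lab, [2, 3], journal=j)
    edited = merge_then_split(edited, None, [1, 2], method="spectral",
                              param=3, journal=j)
    path = tmp_path / "journal.jsonl"
    j.to_jsonl(path)
    j2 = EditJournal.from_jsonl(path)
    replayed = replay_journal(j2, lab)
    fg1, sig1 = _partition_signature(edited)
    fg2, sig2 = _partition_signature(replayed)
    np.testing.assert_array_equal(fg1, fg2)
    np.testing.assert_array_equal(sig1, sig2)
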