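"""Evaluation metrics: landmark PR rules, Rand index, VI, 2D-vs-3D sweep."""

import itertools

import numpy as np
import pytest

from tesseg import (
    DiffusionParams,
    PhantomSpec,
    ThresholdParams,
    compare_2d_vs_3d,
    generate_phantom,
    landmark_pr,
    rand_index,
    variation_of_information,
)


def _field(vals):
    return np.asarray(vals, dtype=np.int32).reshape(1, 1, -1)


# --- landmark_pr -----------------------------------------------------------


def test_pr_printed_rules_example():
    """Hits per region (2, 1, 0) -> t_p=2, f_n=1, f_p=1, P=R=2/3."""
    lab = _field([1, 1, 2, 2, 3, 3])
    lms = np.array([[0, 0, 0], [0, 0, 1], [0, 0, 2]], dtype=float)
    r = landmark_pr(lab, lms)
    assert (r.t_p, r.f_n, r.f_p) == (2, 1, 1)
    assert r.precision == pytest.approx(2 / 3)
    assert r.recall == pytest.approx(2 / 3)
    assert r.zero_hit_labels == [3]
    assert r.multi_hit_labels == [1]


def test_pr_perfect_segmentation():
    lab = _field([1, 1, 2, 2, 3, 3])
    lms = np.array([[0, 0, 0], [0, 0, 2], [0, 0, 4]], dtype=float)
    r = landmark_pr(lab, lms)
    assert r.precision == 1.0 and r.recall == 1.0


def test_pr_background_landmark_reported_separately():
    lab = _field([0, 1, 1])
    lms = np.array([[0, 0, 0], [0, 0, 1]], dtype=float)
    r = landmark_pr(lab, lms)
    assert r.unassigned_landmarks == [0]
    assert (r.t_p, r.f_n, r.f_p) == (1, 0, 0)


def test_pr_nearest_voxel_rounding():
    lab = _field([1, 2])
    r = landmark_pr(lab, np.array([[0, 0, 0.6]]))
    assert r.hits_per_label == {1: 0, 2: 1}


def test_pr_validation():
    with pytest.raises(ValueError):
        landmark_pr(_field([0, 0]), np.array([[0, 0, 0]], dtype=float))
    with pytest.raises(ValueError):
        landmark_pr(_field([1, 1]), np.array([[0, 0, 5]], dtype=float))


def test_pr_count_identities(small_pipeline):
    from tesseg import extract_segmentation

    truth = small_pipeline["truth"]
    seg = extract_segmentation(small_pipeline["hierarchy"], 1, 100)
    r = landmark_pr(seg, truth.landmarks)
    assert 0 <= r.precision <= 1 and 0 <= r.recall <= 1
    assert r.t_p <= len(truth.landmarks)
    assert r.t_p + r.f_p == len(np.unique(seg[seg > 0]))


# --- rand index ------------------------------------------------------------


def _bruteforce_rand(a, b, roi):
    av = a[roi]
    bv = b[roi]
    agree = total = 0
    for i, j in itertools.combinations(range(len(av)), 2):
        total += 1
        if (av[i] == av[j]) == (bv[i] == bv[j]):
            agree += 1
    return 100.0 * agree / total


def test_rand_identical_is_100(small_phantom):
    _, truth, _ = small_phantom
    roi = truth.labels > 0
    assert rand_index(truth.labels, truth.labels, roi) == 100.0


def test_rand_two_voxel_disagreement_is_0():
    a = _field([1, 1])
    b = _field([1, 2])
    roi = np.ones_like(a, dtype=bool)
    assert rand_index(a, b, roi) == 0.0


def test_rand_matches_bruteforce_pairs():
    rng = np.random.default_rng(17)
    a = rng.integers(1, 5, size=(1, 1, 200)).astype(np.int32)
    b = rng.integers(1, 5, size=(1, 1, 200)).astype(np.int32)
    roi = np.ones_like(a, dtype=bool)
    assert rand_index(a, b, roi) == pytest.approx(
        _bruteforce_rand(a, b, roi), abs=1e-9
    )


def test_rand_validation():
    a = _field([1, 0])
    roi = np.ones_like(a, dtype=bool)
    with pytest.raises(ValueError):
        rand_index(a, a, roi)  # roi touches background
    with pytest.raises(ValueError):
        rand_index(_field([1]), _field([1]), np.ones((1, 1, 1), bool))


# --- variation of information ---------------------------------------------


def _bruteforce_vi(a, b, roi):
    """Direct entropy computation from label counts (independent path)."""
    av = a[roi]
    bv = b[roi]
    n = len(av)

    def entropy(vals):
        h = 0.0
        for v in set(vals.tolist()):
            p = (vals == v).mean()
            h -= p * np.log(p)
        return h

    mutual = 0.0
    for va in set(av.tolist()):
        for vb in set(bv.tolist()):
            p = ((av == va) & (bv == vb)).mean()
            if p > 0:
                pa = (av == va).mean()
                pb = (bv == vb).mean()
                mutual += p * np.log(p / (pa * pb))
    return entropy(av) + entropy(bv) - 2 * mutual


def test_vi_identical_is_zero(small_phantom):
    _, truth, _ = small_phantom
    roi = truth.labels > 0
    assert variation_of_information(truth.labels, truth.labels, roi) == (
        pytest.approx(0.0, abs=1e-12)
    )


def test_vi_crossed_partition_is_2ln2():
    a = _field([1, 1, 2, 2])
    b = _field([1, 2, 1, 2])
    roi = np.ones_like(a, dtype=bool)
    assert variation_of_information(a, b, roi) == pytest.approx(2 * np.log(2))
    assert variation_of_information(a, b, roi, base="2") == pytest.approx(2.0)


def test_vi_matches_bruteforce_and_contributions():
    rng = np.random.default_rng(23)
    a = rng.integers(1, 4, size=(1, 1, 120)).astype(np.int32)
    b = rng.integers(1, 4, size=(1, 1, 120)).astype(np.int32)
    roi = np.ones_like(a, dtype=bool)
    vi, contrib = variation_of_information(a, b, roi, return_contributions=True)
    assert vi == pytest.approx(_bruteforce_vi(a, b, roi), abs=1e-9)
    assert contrib["contribution"].sum() == pytest.approx(vi, abs=1e-9)
    assert (contrib["contribution"].diff().dropna() <= 1e-12).all()


def test_vi_metric_properties():
    """Symmetry and the triangle inequality on random triples."""
    rng = np.random.default_rng(29)
    roi = np.ones((1, 1, 150), dtype=bool)
    for _ in range(5):
        a, b, c = (
            rng.integers(1, 6, size=(1, 1, 150)).astype(np.int32)
            for _ in range(3)
        )
        vab = variation_of_information(a, b, roi)
        vba = variation_of_information(b, a, roi)
        vac = variation_of_information(a, c, roi)
        vcb = variation_of_information(c, b, roi)
        assert vab == pytest.approx(vba, abs=1e-12)
        assert vab <= vac + vcb + 1e-9


# --- 2D vs 3D sweep --------------------------------------------------------


def test_compare_2d_vs_3d_on_thin_slab():
    spec = PhantomSpec(shape=(14, 72, 72), thickness=3, n_tiles=20, seed=6)
    vol, truth = generate_phantom(spec)
    sizes = np.bincount(truth.labels.ravel())[1:]
    df = compare_2d_vs_3d(
        vol.data,
        truth.landmarks,
        DiffusionParams(stop_threshold=100.0, steps=25),
        ThresholdParams(box_length=9, strip_threshold=100.0,
                        strip_grow_radius=4.0),
        persistences=range(0, 13),
        t_v=int(0.5 * sizes.min()),
        n_rays=400,
        m_rays=180,
        cap=60,
    )
    by = {
        v: np.minimum(df[df.variant == v].precision,
                      df[df.variant == v].recall).max()
        for v in ("2d", "3d")
    }
    # the planar map dominates on thin slabs
    assert by["2d"] > by["3d"]
    # persistence 0: everything oversegmented, recall ~1, precision low
    p0 = df[(df.variant == "2d") & (df.persistence == 0)].iloc[0]
    assert p0.recall > 0.95
    assert p0.precision < p0.recall
    # deterministic, sorted output
    assert df.equals(df.sort_values(["variant", "persistence"],
                                    ignore_index=True))
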