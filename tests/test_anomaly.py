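"""Similarity, baselines, anomaly scores and tumour-mask smoothing."""

import numpy as np
import pytest

from canomap.anomaly import (
    AnomalyMap,
    BaselineDistribution,
    SimilarityVector,
    anomaly_score,
    build_baseline,
    cohort_anomaly,
    patient_anomaly,
    positive_cosine_similarity,
    similarity_map,
    smooth_tumour_mask,
)
from canomap.connectome import compute_connectome, mean_reference
from canomap.grid import GridSpace, VoxelMask
from canomap.images import SegmentationVolume, TimeSeriesImage


def _ts(data):
    data = np.asarray(data, float)
    g = GridSpace((data.shape[0], 1, 1), (3, 3, 3))
    return TimeSeriesImage(g, VoxelMask(g, np.ones(g.shape, bool)), data)


def _full_mask(v):
    g = GridSpace((v, 1, 1), (3, 3, 3))
    return VoxelMask(g, np.ones(g.shape, bool))


# -- positive-clipped cosine --------------------------------------------------


def test_cosine_self_similarity_is_one():
    row = np.array([0.3, 0.7, 0.1])
    assert positive_cosine_similarity(row, row) == pytest.approx(1.0)


def test_cosine_hand_example():
    sim = positive_cosine_similarity([0.6, 0.8, -0.3], [0.8, 0.6, -0.5])
    assert sim == pytest.approx(0.96, abs=1e-12)


def test_cosine_all_negative_row_is_invalid_not_zero():
    assert np.isnan(positive_cosine_similarity([-0.1, -0.5], [0.3, 0.4]))


def test_cosine_length_mismatch():
    with pytest.raises(ValueError):
        positive_cosine_similarity([1.0], [1.0, 2.0])


def test_cosine_matches_bruteforce_on_random_rows(rng):
    for _ in range(100):
        n = rng.integers(3, 50)
        a = rng.standard_normal(n)
        b = rng.standard_normal(n)
        ac = np.clip(a, 0, None)
        bc = np.clip(b, 0, None)
        if ac.any() and bc.any():
            expect = ac @ bc / (np.linalg.norm(ac) * np.linalg.norm(bc))
            assert positive_cosine_similarity(a, b) == pytest.approx(expect, abs=1e-12)
        else:
            assert np.isnan(positive_cosine_similarity(a, b))


# -- similarity maps ----------------------------------------------------------


def test_similarity_identical_to_reference_is_one(rng):
    conn = compute_connectome(_ts(rng.standard_normal((10, 30))))
    ref = mean_reference([conn])
    sim = similarity_map(conn, ref)
    assert np.allclose(sim.values, 1.0)


def test_similarity_matches_per_row_bruteforce(rng):
    a = compute_connectome(_ts(rng.standard_normal((20, 30))))
    b = compute_connectome(_ts(rng.standard_normal((20, 30))))
    ref = mean_reference([b])
    sim = similarity_map(a, ref)
    for i in range(20):
        cols = [j for j in range(20) if j != i]
        expect = positive_cosine_similarity(a.values[i, cols], ref.values[i, cols])
        assert sim.values[i] == pytest.approx(expect, abs=1e-12)


def test_similarity_exclusion_bookkeeping(rng):
    conn = compute_connectome(_ts(rng.standard_normal((20, 30))))
    ref = mean_reference([conn])
    excl = VoxelMask.from_indices(conn.mask.grid, conn.mask.indices[:10])
    sim = similarity_map(conn, ref, exclude=excl)
    assert np.isnan(sim.values[:10]).all()
    assert np.isfinite(sim.values[10:]).all()


# -- baseline -----------------------------------------------------------------


def _sim_vectors(values_per_control, excluded=()):
    mask = _full_mask(len(values_per_control[0]))
    return [
        SimilarityVector(mask, np.asarray(v, float), np.asarray(excluded, np.intp))
        for v in values_per_control
    ]


def test_baseline_median_and_mad_hand_example():
    sims = _sim_vectors([[0.8], [0.9], [1.0], [0.7], [0.6]])
    base = build_baseline(sims)
    assert base.median[0] == pytest.approx(0.8)
    assert base.mad[0] == pytest.approx(0.1)


def test_baseline_matches_bruteforce_on_random_instances(rng):
    for _ in range(100):
        vals = rng.random((rng.integers(2, 12), rng.integers(1, 50)))
        base = build_baseline(_sim_vectors(list(vals)))
        med = np.array([np.median(vals[:, j]) for j in range(vals.shape[1])])
        mad = np.array(
            [np.median(np.abs(vals[:, j] - med[j])) for j in range(vals.shape[1])]
        )
        assert np.allclose(base.median, med, atol=1e-12)
        assert np.allclose(base.mad, mad, atol=1e-12)


def test_baseline_zero_dispersion_degenerates_at_scoring():
    sims = _sim_vectors([[0.9], [0.9], [0.9]])
    base = build_baseline(sims)
    assert base.mad[0] == 0.0
    amap = anomaly_score(sims[0], base)
    assert np.isnan(amap.scores[0])  # never +-inf


def test_baseline_invariant_to_control_order(rng):
    vals = list(rng.random((8, 20)))
    a = build_baseline(_sim_vectors(vals))
    b = build_baseline(_sim_vectors(vals[::-1]))
    assert np.array_equal(a.median, b.median)
    assert np.array_equal(a.mad, b.mad)


def test_baseline_needs_two_controls():
    with pytest.raises(ValueError):
        build_baseline(_sim_vectors([[0.5]]))


# -- anomaly scores -----------------------------------------------------------


def test_anomaly_score_arithmetic():
    mask = _full_mask(3)
    sim = SimilarityVector(mask, np.array([0.5, 0.7, 0.9]))
    base = BaselineDistribution(
        mask, np.array([0.7, 0.7, 0.7]), np.array([0.1, 0.1, 0.1]), n_controls=5
    )
    amap = anomaly_score(sim, base)
    assert amap.scores[0] == pytest.approx(-2.0)
    assert amap.scores[1] == pytest.approx(0.0)
    assert amap.scores[2] == pytest.approx(2.0)


def test_anomaly_score_requires_matching_exclusions():
    mask = _full_mask(3)
    sim = SimilarityVector(mask, np.array([0.5, 0.7, 0.9]), np.array([0], np.intp))
    base = BaselineDistribution(
        mask, np.full(3, 0.7), np.full(3, 0.1), n_controls=4,
        excluded=np.array([1], np.intp),
    )
    with pytest.raises(ValueError, match="exclusion"):
        anomaly_score(sim, base)


def test_anomaly_score_equivariant_under_similarity_shift(rng):
    mask = _full_mask(30)
    vals = [0.4 + 0.4 * rng.random(30) for _ in range(9)]
    target = 0.4 + 0.4 * rng.random(30)
    c = 0.05

    def score(shift):
        sims = [SimilarityVector(mask, v + shift) for v in vals]
        base = build_baseline(sims)
        return anomaly_score(SimilarityVector(mask, target + shift), base).scores

    assert np.allclose(score(0.0), score(c), atol=1e-9, equal_nan=True)


# -- patient anomaly ----------------------------------------------------------


def test_patient_anomaly_excluded_voxels_never_scored(rng, small_ph, model_fast,
                                                      control_cohort):
    from canomap.simulate import simulate_control

    conns = [compute_connectome(c) for c in control_cohort]
    target = compute_connectome(simulate_control(small_ph, model_fast, seed=777))
    excl = VoxelMask.from_indices(small_ph.grid, small_ph.mask.indices[50:90])
    amap = patient_anomaly(target, conns, excl)
    sel = np.isin(small_ph.mask.indices, excl.indices)
    assert np.isnan(amap.scores[sel]).all()
    assert np.isfinite(amap.scores[~sel]).mean() > 0.95


def test_streaming_cohort_matches_connectome_path(small_ph, model_fast,
                                                  control_cohort):
    from canomap.simulate import simulate_control

    target = simulate_control(small_ph, model_fast, seed=888)
    excl = VoxelMask.from_indices(small_ph.grid, small_ph.mask.indices[10:40])
    conns = [compute_connectome(c) for c in control_cohort]
    direct = patient_anomaly(compute_connectome(target), conns, excl)
    for block in (64, 1000):
        maps, _ = cohort_anomaly(control_cohort, [target], exclude=excl,
                                 block_rows=block)
        assert np.allclose(maps[0].scores, direct.scores, atol=1e-9, equal_nan=True)


def test_maps_with_and_without_tumour_exclusion_highly_correlated(
    small_ph, model_fast, control_cohort
):
    from canomap.phantom import network_tumour
    from canomap.simulate import LesionSpec, simulate_patient

    tum = network_tumour(small_ph, 2, n_blocks=2, seed=3)
    ts, seg = simulate_patient(
        small_ph, model_fast, LesionSpec(tum, "functional", 0.8), seed=55
    )
    excl = smooth_tumour_mask(seg).intersect(small_ph.mask)
    with_excl, _ = cohort_anomaly(control_cohort, [ts], exclude=excl)
    without, _ = cohort_anomaly(control_cohort, [ts])
    a, b = with_excl[0].scores, without[0].scores
    ok = np.isfinite(a) & np.isfinite(b)
    r = np.corrcoef(a[ok], b[ok])[0, 1]
    assert r > 0.9


# -- tumour-mask smoothing ----------------------------------------------------


def _seg_single_voxel(spacing=3.0, shape=(7, 7, 7)):
    g = GridSpace(shape, (spacing,) * 3)
    labels = np.zeros(shape, np.int16)
    labels[3, 3, 3] = 2
    return SegmentationVolume(g, labels)


def test_smooth_empty_segmentation_is_empty():
    g = GridSpace((5, 5, 5), (3, 3, 3))
    seg = SegmentationVolume.empty(g)
    assert smooth_tumour_mask(seg).empty()


def test_smooth_single_voxel_adds_face_neighbours():
    mask = smooth_tumour_mask(_seg_single_voxel(), fwhm_mm=3.0)
    ijk = mask.grid.flat_to_ijk(mask.indices) - 3
    got = {tuple(x) for x in ijk}
    expect = {(0, 0, 0), (1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0),
              (0, 0, 1), (0, 0, -1)}
    assert got == expect


def test_smooth_mask_monotone_in_fwhm():
    seg = _seg_single_voxel()
    small = smooth_tumour_mask(seg, fwhm_mm=3.0)
    large = smooth_tumour_mask(seg, fwhm_mm=6.0)
    assert small.issubset(large)
    assert large.n_voxels > small.n_voxels


def test_smooth_mask_always_contains_input():
    seg = _seg_single_voxel()
    assert smooth_tumour_mask(seg, fwhm_mm=0.5).n_voxels >= 1
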