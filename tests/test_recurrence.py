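"""Trajectories, new-tumour masks, vicinity, volume filter, recurrence test."""

import numpy as np
import pandas as pd
import pytest

from canomap.anomaly import AnomalyMap
from canomap.grid import GridSpace, VoxelMask
from canomap.images import NETWORKS, SegmentationVolume
from canomap.recurrence import (
    align_trajectories,
    fit_quadratic_trend,
    new_tumour_voxels,
    recurrence_test,
    tumour_vicinity,
    volume_filter,
)


def _session_table(medians, session):
    rows = []
    for n, net in enumerate(NETWORKS):
        for side in ("ipsi", "contra"):
            for comp in ("cerebrum", "cerebellum"):
                rows.append(
                    {"patient": "p0", "session": session, "network": net,
                     "side": side, "compartment": comp,
                     "median_anomaly": medians, "n_voxels": 5}
                )
    return pd.DataFrame(rows)


def test_align_subtracts_presurgical_baseline():
    tabs = [_session_table(m, s) for s, m in enumerate([-1.0, -1.5, -0.8])]
    out = align_trajectories(tabs)
    per_session = out.groupby("session")["delta_anomaly"].first()
    assert np.allclose(per_session.values, [0.0, -0.5, 0.2])


def test_align_constant_trajectory_is_zero():
    tabs = [_session_table(-0.7, s) for s in range(4)]
    out = align_trajectories(tabs)
    assert np.allclose(out["delta_anomaly"], 0.0)


def test_align_requires_session_zero():
    with pytest.raises(ValueError, match="pre-surgical"):
        align_trajectories([_session_table(-1.0, 1)])


def test_quadratic_exact_fit():
    fit = fit_quadratic_trend([0, 1, 2], [0, 1, 4])
    assert fit.quadratic == pytest.approx(1.0, abs=1e-10)
    assert fit.linear == pytest.approx(0.0, abs=1e-10)
    assert fit.intercept == pytest.approx(0.0, abs=1e-10)
    assert fit.r_squared == pytest.approx(1.0)
    assert fit.rmse == pytest.approx(0.0, abs=1e-10)


def test_quadratic_nested_linear_model():
    s = np.array([0, 1, 2, 3], float)
    fit = fit_quadratic_trend(s, 2.0 * s - 1.0)
    assert fit.r_squared == pytest.approx(1.0)
    assert abs(fit.quadratic) < 1e-10


def test_quadratic_matches_normal_equations(rng):
    for _ in range(25):
        s = rng.integers(0, 6, 30).astype(float)
        if np.unique(s).size < 3:
            continue
        y = rng.standard_normal(30)
        fit = fit_quadratic_trend(s, y)
        X = np.stack([np.ones_like(s), s, s**2], axis=1)
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert np.allclose([fit.intercept, fit.linear, fit.quadratic], beta, atol=1e-8)


def test_quadratic_constant_values_have_invalid_r2():
    fit = fit_quadratic_trend([0, 1, 2, 3], [1.0, 1.0, 1.0, 1.0])
    assert np.isnan(fit.r_squared)
    assert fit.rmse == pytest.approx(0.0, abs=1e-12)


def test_transient_deterioration_then_recovery_has_positive_curvature():
    # delta-anomaly pattern (0, -d, +r): the dip-and-recover shape
    fit = fit_quadratic_trend([0, 1, 2] * 5, [0.0, -1.2, 0.4] * 5)
    assert fit.quadratic > 0


def _seg(grid, coords, code=2):
    labels = np.zeros(grid.shape, np.int16)
    for c in coords:
        labels[c] = code
    return SegmentationVolume(grid, labels)


def test_new_tumour_set_difference():
    g = GridSpace((5, 5, 5), (3, 3, 3))
    a, b, c = (1, 1, 1), (2, 2, 2), (3, 3, 3)
    t0 = _seg(g, [a])
    t1 = _seg(g, [a, b, c])
    new = new_tumour_voxels(t0, t1)
    assert new.n_voxels == 2
    assert new_tumour_voxels(t1, t0).empty()  # t1 subset of t0
    assert new_tumour_voxels(_seg(g, []), _seg(g, [a])).n_voxels == 1


def test_new_tumour_ignores_relabelled_resection():
    g = GridSpace((5, 5, 5), (3, 3, 3))
    t0 = _seg(g, [(1, 1, 1)], code=5)  # resection at t0
    t1 = _seg(g, [(1, 1, 1)], code=2)  # same voxel enhancing at t1
    assert new_tumour_voxels(t0, t1).empty()


def test_vicinity_face_neighbours_at_matching_margin():
    g = GridSpace((7, 7, 7), (3, 3, 3))
    analysis = VoxelMask(g, np.ones(g.shape, bool))
    t0 = _seg(g, [(3, 3, 3)])
    vic = tumour_vicinity(t0, analysis, margin_mm=3.0)
    ijk = {tuple(x) for x in (g.flat_to_ijk(vic.indices) - 3)}
    assert ijk == {(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1),
                   (0, 0, -1)}


def test_vicinity_empty_when_margin_below_spacing():
    g = GridSpace((7, 7, 7), (3, 3, 3))
    analysis = VoxelMask(g, np.ones(g.shape, bool))
    assert tumour_vicinity(_seg(g, [(3, 3, 3)]), analysis, margin_mm=2.0).empty()


def test_vicinity_monotone_in_margin():
    g = GridSpace((9, 9, 9), (3, 3, 3))
    analysis = VoxelMask(g, np.ones(g.shape, bool))
    t0 = _seg(g, [(4, 4, 4)])
    small = tumour_vicinity(t0, analysis, margin_mm=5.0)
    big = tumour_vicinity(t0, analysis, margin_mm=10.0)
    assert small.issubset(big)


def test_vicinity_requires_prior_tumour():
    g = GridSpace((5, 5, 5), (3, 3, 3))
    analysis = VoxelMask(g, np.ones(g.shape, bool))
    with pytest.raises(ValueError):
        tumour_vicinity(SegmentationVolume.empty(g), analysis)


def test_volume_filter_at_three_cm3():
    g = GridSpace((10, 10, 10), (3.0, 3.0, 3.75))  # 33.75 mm^3 per voxel
    m89 = VoxelMask.from_indices(g, np.arange(89))
    m88 = VoxelMask.from_indices(g, np.arange(88))
    assert volume_filter(m89, g, min_cm3=3.0) is True  # 3003.75 mm^3
    assert volume_filter(m88, g, min_cm3=3.0) is False  # 2970 mm^3
    assert volume_filter(VoxelMask(g, np.zeros(g.shape, bool)), g) is False


def _amap(scores):
    scores = np.asarray(scores, float)
    g = GridSpace((scores.size, 1, 1), (3, 3, 3))
    return AnomalyMap(VoxelMask(g, np.ones(g.shape, bool)), scores)


def test_recurrence_exhaustive_toy():
    am = _amap([-3.0, -3.0, 0.0, 0.0])
    g = am.mask.grid
    fut = VoxelMask.from_indices(g, np.array([0, 1]))
    vic = VoxelMask.from_indices(g, np.array([0, 1, 2, 3]))
    rc = recurrence_test(am, fut, vic, n_perm=100)
    assert rc.perm.exhaustive
    assert rc.p_value == pytest.approx(1 / 6)
    assert rc.auc == pytest.approx(1.0)
    assert rc.n_future == 2 and rc.n_vicinity == 2  # future removed from vicinity


def test_recurrence_requires_valid_scores():
    am = _amap([np.nan, np.nan, 0.0, 0.0])
    g = am.mask.grid
    fut = VoxelMask.from_indices(g, np.array([0, 1]))
    vic = VoxelMask.from_indices(g, np.array([2, 3]))
    with pytest.raises(ValueError):
        recurrence_test(am, fut, vic)
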