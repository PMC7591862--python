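"""Generative model: expected correlations, lesion scaling, schedules."""

import numpy as np
import pytest

from canomap.grid import VoxelMask
from canomap.images import SegmentationVolume
from canomap.simulate import (
    LesionSpec,
    LongitudinalSchedule,
    SessionSpec,
    SignalModel,
    functional_proximity,
    segmentation_from_mask,
    simulate_control,
    simulate_longitudinal,
    simulate_patient,
    spatial_proximity,
)


def _pair_r(data, i, j):
    return np.corrcoef(data[i], data[j])[0, 1]


def _mean_pair_r(ph, data, rng, same_network=True, same_hemi=True, n_pairs=100):
    rs = []
    while len(rs) < n_pairs:
        i, j = rng.integers(ph.n_voxels, size=2)
        if i == j:
            continue
        if (ph.network[i] == ph.network[j]) != same_network:
            continue
        if same_network and (
            (ph.functional_hemisphere[i] == ph.functional_hemisphere[j]) != same_hemi
        ):
            continue
        rs.append(_pair_r(data, i, j))
    return float(np.mean(rs))


def test_within_network_correlation_matches_closed_form(small_ph, rng):
    # lambda=1, eta=0, sigma=1 -> expected r = 1/2
    model = SignalModel(n_timepoints=2000, network_loading=1.0,
                        hemisphere_loading=0.0, noise_sd=1.0)
    ts = simulate_control(small_ph, model, seed=11)
    r = _mean_pair_r(small_ph, ts.data, rng)
    assert abs(r - 0.5) < 0.05


def test_null_correlation_without_signal(small_ph, rng):
    model = SignalModel(n_timepoints=2000, network_loading=0.0,
                        hemisphere_loading=0.0, noise_sd=1.0)
    ts = simulate_control(small_ph, model, seed=12)
    rs = []
    for _ in range(100):
        i, j = rng.integers(small_ph.n_voxels, size=2)
        if i != j:
            rs.append(abs(_pair_r(ts.data, i, j)))
    assert np.mean(rs) <= 0.06  # ~2/sqrt(T)


def test_cross_hemisphere_same_network_correlation_positive(small_ph, rng):
    model = SignalModel(n_timepoints=2000, network_loading=1.0,
                        hemisphere_loading=0.5, noise_sd=1.0)
    ts = simulate_control(small_ph, model, seed=13)
    r = _mean_pair_r(small_ph, ts.data, rng, same_hemi=False)
    assert abs(r - 1.0 / 2.25) < 0.05  # lambda^2 / total


def test_same_seed_identical_series(small_ph, model_fast):
    a = simulate_control(small_ph, model_fast, seed=42)
    b = simulate_control(small_ph, model_fast, seed=42)
    assert np.array_equal(a.data, b.data)


def test_gamma_zero_reproduces_control(small_ph, model_fast):
    from canomap.phantom import network_tumour

    tum = network_tumour(small_ph, 1, seed=5)
    ts, _ = simulate_patient(
        small_ph, model_fast, LesionSpec(tum, "functional", 0.0), seed=42
    )
    ctrl = simulate_control(small_ph, model_fast, seed=42)
    assert np.array_equal(ts.data, ctrl.data)


def test_variance_preserved_under_lesion(small_ph):
    from canomap.phantom import network_tumour

    model = SignalModel(n_timepoints=2000)
    tum = network_tumour(small_ph, 2, seed=5)
    ts, _ = simulate_patient(
        small_ph, model, LesionSpec(tum, "functional", 0.8), seed=21
    )
    p = functional_proximity(small_ph, tum, model)
    v = ts.data.var(axis=1)
    ratio = v[p > 0].mean() / v[p == 0].mean()
    assert abs(ratio - 1.0) < 0.1


def test_functional_proximity_reduces_to_network_membership_when_eta_zero(small_ph):
    from canomap.phantom import network_tumour

    model = SignalModel(hemisphere_loading=0.0)
    tum = network_tumour(small_ph, 4, seed=6)
    p = functional_proximity(small_ph, tum, model)
    assert set(np.unique(p)) == {0.0, 1.0}
    assert np.array_equal(p == 1.0, small_ph.network == 4)


def test_spatial_proximity_decays_with_distance(small_ph):
    tum = VoxelMask.from_indices(small_ph.grid, small_ph.mask.indices[:1])
    p = spatial_proximity(small_ph, tum, tau_mm=6.0)
    assert p.max() == pytest.approx(1.0)  # inside the tumour, d = 0
    d = np.linalg.norm(
        small_ph.grid.voxel_centres_mm(small_ph.mask.indices)
        - small_ph.grid.voxel_centres_mm(small_ph.mask.indices[:1]),
        axis=1,
    )
    assert np.allclose(p, np.exp(-d / 6.0))


def test_invalid_lesion_specs_rejected(small_ph):
    tum = VoxelMask.from_indices(small_ph.grid, small_ph.mask.indices[:4])
    with pytest.raises(ValueError):
        LesionSpec(tum, "spatial", 0.5, tau_mm=0.0)
    with pytest.raises(ValueError):
        LesionSpec(tum, "weird", 0.5)
    with pytest.raises(ValueError):
        LesionSpec(VoxelMask(small_ph.grid, np.zeros(small_ph.grid.shape, bool)),
                   "functional", 0.5)


def _five_session_schedule(ph, gamma_rec=0.8):
    from canomap.phantom import spatial_tumour

    prim = spatial_tumour(ph, (2, 4, 6), radius_mm=4.0)
    rec = spatial_tumour(ph, (2, 7, 6), radius_mm=4.5).difference(prim)
    seg_pre = segmentation_from_mask(ph.grid, prim, code=2)
    cav = np.zeros(ph.grid.shape, np.int16)
    cav[prim.volume] = 5
    seg_post = SegmentationVolume(ph.grid, cav)
    with_rec = cav.copy()
    with_rec[rec.volume] = 2
    seg_rec = SegmentationVolume(ph.grid, with_rec)
    mk = lambda g: LesionSpec(prim, "spatial", g, 6.0)
    return LongitudinalSchedule((
        SessionSpec("pre", seg_pre, mk(0.8)),
        SessionSpec("post", seg_post, mk(0.3)),
        SessionSpec("followup-1", seg_post, mk(0.15)),
        SessionSpec("followup-2", seg_post, mk(0.15), recurrence_site=rec,
                    recurrence_gamma=gamma_rec, recurrence_silent=True),
        SessionSpec("followup-3", seg_rec, mk(0.15), recurrence_site=rec,
                    recurrence_gamma=gamma_rec, recurrence_silent=False),
    )), rec


def test_longitudinal_schedule_contract(small_ph, model_fast):
    sched, _ = _five_session_schedule(small_ph)
    sessions = simulate_longitudinal(small_ph, model_fast, sched, seed=3)
    assert len(sessions) == 5
    for ts, seg in sessions:
        assert ts.grid.same_as(small_ph.grid) and seg.grid.same_as(small_ph.grid)
    labels = [ts.session_label for ts, _ in sessions]
    assert labels == ["pre", "post", "followup-1", "followup-2", "followup-3"]
    again = simulate_longitudinal(small_ph, model_fast, sched, seed=3)
    assert all(
        np.array_equal(a[0].data, b[0].data) for a, b in zip(sessions, again)
    )


def test_silent_recurrence_must_be_segmented_later(small_ph):
    sched, rec = _five_session_schedule(small_ph)
    bad = list(sched.sessions)
    bad[4] = SessionSpec("followup-3", bad[2].segmentation, bad[2].lesion)
    with pytest.raises(ValueError, match="silent recurrence"):
        LongitudinalSchedule(tuple(bad))


def test_schedule_session_order_enforced(small_ph):
    sched, _ = _five_session_schedule(small_ph)
    with pytest.raises(ValueError, match="pre"):
        LongitudinalSchedule(tuple(sched.sessions[1:]))
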