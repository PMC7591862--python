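"""Frozen recovery and calibration experiments on synthetic cohorts.

These functions define the package's reference experiments — the study
conditions under which the method's properties (null calibration, lesion
recovery, attribution, symmetry, crossed-cerebellar concordance,
recurrence precedence, test calibration) are demonstrated.  Each takes a
single integer seed, derives every sub-seed from it, and returns a flat
dict of named scalar results.  Problem sizes are chosen so the full set
runs in minutes on one CPU; the methods note documents each design.
"""

from __future__ import annotations

import numpy as np

from .anomaly import cohort_anomaly, smooth_tumour_mask
from .attribution import attribute_patient, attribution_summary
from .connectome import compute_connectome, mean_reference
from .phantom import (
    PhantomSpec,
    build_phantom,
    demo_phantom,
    network_tumour,
    small_phantom,
    spatial_tumour,
)
from .recurrence import new_tumour_voxels, recurrence_test, tumour_vicinity
from .simulate import (
    LesionSpec,
    LongitudinalSchedule,
    SessionSpec,
    SignalModel,
    functional_proximity,
    segmentation_from_mask,
    simulate_control,
    simulate_longitudinal,
    simulate_patient,
)
from .stats import auc_mann_whitney, fdr_bh, paired_sign_flip_test, pearson, two_sample_permutation
from .symmetry import (
    DEFAULT_ANOMALY_THRESHOLDS,
    diagonal_excess_test,
    lesion_map,
    network_median_anomaly,
    symmetry_correlation,
)

__all__ = [
    "null_calibration",
    "lesion_recovery",
    "attribution_recovery",
    "symmetry_recovery",
    "crossed_cerebellum_recovery",
    "recurrence_recovery",
    "stats_calibration",
]


def _seeds(seed: int, n: int) -> np.ndarray:
    return np.random.SeedSequence(seed).generate_state(n) % (2**31)


# ---------------------------------------------------------------------------


def null_calibration(seed: int = 0, n_controls: int = 40, n_heldout: int = 10):
    """Held-out controls scored against a control baseline on the demo
    phantom (~2,500 voxels, T=300): the anomaly distribution should be
    centred at zero."""
    ph = demo_phantom(seed=1)
    model = SignalModel(n_timepoints=300)
    s = _seeds(seed, n_controls + n_heldout)
    controls = [simulate_control(ph, model, int(s[i])) for i in range(n_controls)]
    held = [
        simulate_control(ph, model, int(s[n_controls + i])) for i in range(n_heldout)
    ]
    maps, _ = cohort_anomaly(controls, held)
    pooled = np.concatenate([m.scores[m.valid] for m in maps])
    per_map_medians = [float(np.median(m.scores[m.valid])) for m in maps]
    return {
        "null_median_score": float(np.median(pooled)),
        "null_frac_below_-2.3": float(np.mean(pooled < -2.3)),
        "null_per_map_median_absmax": float(np.max(np.abs(per_map_medians))),
        "n_voxels": ph.n_voxels,
    }


def lesion_recovery(
    seed: int = 0, gammas=(0.0, 0.3, 0.6, 0.9), n_controls: int = 20
):
    """Functional-mode lesion recovery with common random numbers across
    gamma: AUC of (-anomaly) against perturbed-network ground truth at
    gamma = 0.8, and monotone deepening of perturbed-voxel anomaly."""
    ph = small_phantom(seed=1)
    model = SignalModel(n_timepoints=200)
    s = _seeds(seed, n_controls + 2)
    controls = [simulate_control(ph, model, int(s[i])) for i in range(n_controls)]
    tum = network_tumour(ph, network=2, n_blocks=2, seed=int(s[n_controls]))
    patient_seed = int(s[n_controls + 1])
    truth = functional_proximity(ph, tum, model) > 0

    def scored(gamma):
        lesion = LesionSpec(tum, "functional", gamma)
        ts, seg = simulate_patient(ph, model, lesion, patient_seed)
        excl = smooth_tumour_mask(seg).intersect(ph.mask)
        maps, _ = cohort_anomaly(controls, [ts], exclude=excl)
        return maps[0]

    means = []
    for g in gammas:
        am = scored(g)
        means.append(float(np.mean(am.scores[truth & am.valid])))
    am08 = scored(0.8)
    auc = auc_mann_whitney(-am08.scores[am08.valid], truth[am08.valid])
    return {
        "lesion_auc_gamma0.8": float(auc),
        "perturbed_mean_by_gamma": means,
        "monotone_decreasing": bool(np.all(np.diff(means) < 0)),
    }


def attribution_recovery(seed: int = 0, n_phantoms: int = 20, n_controls: int = 20):
    """Per-mode median percentage of tumour voxels attributed to the
    generating distance kind, over independently seeded phantoms."""
    out = {}
    s = _seeds(seed, 2 * n_phantoms * (n_controls + 2))
    si = iter(int(x) for x in s)
    for mode in ("functional", "spatial"):
        pcts = []
        for k in range(n_phantoms):
            ph = small_phantom(seed=k)
            model = SignalModel(n_timepoints=200)
            controls = [simulate_control(ph, model, next(si)) for _ in range(n_controls)]
            rng = np.random.default_rng(next(si))
            if mode == "functional":
                tum = network_tumour(ph, int(rng.integers(7)), n_blocks=2, seed=int(rng.integers(2**31)))
                lesion = LesionSpec(tum, "functional", 0.8)
            else:
                idx = ph.mask.indices[(ph.hemisphere == 0) & (ph.compartment == 0)]
                centre = ph.grid.flat_to_ijk(idx[rng.integers(idx.size)])
                tum = spatial_tumour(ph, centre, radius_mm=4.5)
                lesion = LesionSpec(tum, "spatial", 0.8, tau_mm=6.0)  # tau = 2 voxels
            ts, seg = simulate_patient(ph, model, lesion, next(si))
            excl = smooth_tumour_mask(seg).intersect(ph.mask)
            maps, _ = cohort_anomaly(controls, [ts], exclude=excl)
            ref = mean_reference([compute_connectome(c) for c in controls])
            tv = seg.enhancing_necrotic_mask().intersect(ph.mask)
            tab = attribute_patient(maps[0], ref, tv, ph.grid, ph.network, subject_id=f"{mode}{k}")
            summ = attribution_summary([tab])
            pcts.append(float(summ[f"pct_{mode}"].iloc[0]))
        out[f"attribution_median_pct_{mode}"] = float(np.median(pcts))
    return out


def _symmetry_cohort_table(ph, model, controls, gammas, networks, seeds, lesioned):
    import pandas as pd

    if not lesioned:
        patients = [
            simulate_control(ph, model, int(seeds[i])) for i in range(len(gammas))
        ]
        maps, _ = cohort_anomaly(controls, patients)
        for i, m in enumerate(maps):
            m.subject_id = f"p{i:02d}"
        return pd.concat(
            [network_median_anomaly(m, ph.parcellation, "L") for m in maps],
            ignore_index=True,
        )
    rows = []
    for i, (g, net) in enumerate(zip(gammas, networks)):
        tum = network_tumour(ph, int(net), n_blocks=2, seed=int(seeds[i]) + 7)
        ts, seg = simulate_patient(
            ph, model, LesionSpec(tum, "functional", float(g)), int(seeds[i])
        )
        excl = smooth_tumour_mask(seg).intersect(ph.mask)
        maps, _ = cohort_anomaly(controls, [ts], exclude=excl)
        maps[0].subject_id = f"p{i:02d}"
        rows.append(network_median_anomaly(maps[0], ph.parcellation, "L"))
    return pd.concat(rows, ignore_index=True)


def symmetry_recovery(
    seed: int = 0, n_patients: int = 15, n_controls: int = 20, n_null_seeds: int = 20
):
    """Bilateral symmetry: within-network ipsi-contra r^2 excess for a
    lesioned cohort, and the same test across unlesioned null cohorts."""
    ph = small_phantom(seed=1)
    model = SignalModel(n_timepoints=200)
    s = _seeds(seed, n_controls + n_patients + n_null_seeds * n_patients + 8)
    controls = [simulate_control(ph, model, int(s[i])) for i in range(n_controls)]
    rng = np.random.default_rng(int(s[n_controls]))
    gammas = rng.uniform(0.3, 0.9, n_patients)
    networks = rng.integers(0, 7, n_patients)
    tab = _symmetry_cohort_table(
        ph, model, controls, gammas, networks,
        s[n_controls + 1 : n_controls + 1 + n_patients], lesioned=True,
    )
    _, r2 = symmetry_correlation(tab, "cerebrum")
    excess, p = diagonal_excess_test(tab, "cerebrum")
    null_ps = []
    base = n_controls + 1 + n_patients
    for k in range(n_null_seeds):
        tn = _symmetry_cohort_table(
            ph, model, controls, np.zeros(n_patients), None,
            s[base + k * n_patients : base + (k + 1) * n_patients], lesioned=False,
        )
        null_ps.append(diagonal_excess_test(tn, "cerebrum")[1])
    return {
        "symmetry_diag_r2_mean": float(np.nanmean(np.diag(r2))),
        "symmetry_offdiag_r2_mean": float(np.nanmean(r2[~np.eye(7, dtype=bool)])),
        "symmetry_excess_p": float(p),
        "symmetry_null_frac_p_above_0.05": float(np.mean(np.asarray(null_ps) > 0.05)),
    }


def crossed_cerebellum_recovery(seed: int = 0, n_patients: int = 12, n_controls: int = 20):
    """Left-tumour cohort under a hemisphere-dominant signal model: the
    lesion-map/anomaly overlap concordance should be higher in the
    contralateral (right) cerebellum at every anomaly threshold."""
    from .images import CEREBELLUM

    ph = build_phantom(
        PhantomSpec(shape=(12, 12, 12), cerebral_blocks_per_network=6,
                    cerebellar_blocks_per_network=4, seed=2)
    )
    model = SignalModel(
        n_timepoints=200, network_loading=0.35, hemisphere_loading=0.55
    )
    s = _seeds(seed, n_controls + 2 * n_patients + 1)
    controls = [simulate_control(ph, model, int(s[i])) for i in range(n_controls)]
    ref = mean_reference([compute_connectome(c) for c in controls])
    rng = np.random.default_rng(int(s[n_controls]))
    networks = rng.integers(0, 7, n_patients)
    lmaps, amaps = [], []
    for k in range(n_patients):
        tum = network_tumour(ph, int(networks[k]), n_blocks=2, seed=int(s[n_controls + 1 + k]))
        ts, seg = simulate_patient(
            ph, model, LesionSpec(tum, "functional", 0.8),
            int(s[n_controls + 1 + n_patients + k]),
        )
        excl = smooth_tumour_mask(seg).intersect(ph.mask)
        maps, _ = cohort_anomaly(controls, [ts], exclude=excl)
        amaps.append(maps[0])
        lmaps.append(lesion_map(tum, ref))
    lesion_overlap = np.sum([lm > 0 for lm in lmaps], axis=0)
    comp = ph.compartment
    hemi = ph.hemisphere
    contra_minus_ipsi = []
    r_by_thr = {}
    for thr in DEFAULT_ANOMALY_THRESHOLDS:
        anom_overlap = np.sum(
            [np.nan_to_num(am.scores, nan=np.inf) < -thr for am in amaps], axis=0
        )
        rs = []
        for h in (0, 1):  # L (ipsi), R (contra)
            sel = (comp == CEREBELLUM) & (hemi == h)
            r = pearson(lesion_overlap[sel], anom_overlap[sel])
            rs.append(0.0 if np.isnan(r) else float(r))
        r_by_thr[thr] = rs
        contra_minus_ipsi.append(rs[1] - rs[0])
    return {
        "crossed_min_contra_minus_ipsi_r": float(np.min(contra_minus_ipsi)),
        "crossed_contra_r_at_2.3": float(r_by_thr[2.3][1]),
        "crossed_ipsi_r_at_2.3": float(r_by_thr[2.3][0]),
        "crossed_all_thresholds_contra_gt_ipsi": bool(np.min(contra_minus_ipsi) > 0),
    }


def _recurrence_schedule(ph, mode, tau_mm, gamma_rec, followup_gamma=0.15):
    from .images import SegmentationVolume

    centre = (2, 4, 6)
    prim = spatial_tumour(ph, centre, radius_mm=4.0)
    rec = spatial_tumour(ph, (2, 7, 6), radius_mm=5.5).difference(prim)
    seg_pre = segmentation_from_mask(ph.grid, prim, code=2)
    cavity = np.zeros(ph.grid.shape, np.int16)
    cavity[prim.volume] = 5
    seg_post = SegmentationVolume(ph.grid, cavity)
    with_rec = cavity.copy()
    with_rec[rec.volume] = 2
    seg_rec = SegmentationVolume(ph.grid, with_rec)

    def lesion(g):
        return LesionSpec(prim, mode, g, tau_mm)

    sessions = (
        SessionSpec("pre", seg_pre, lesion(0.8)),
        SessionSpec("post", seg_post, lesion(0.3)),
        SessionSpec("followup-1", seg_post, lesion(followup_gamma)),
        SessionSpec("followup-2", seg_post, lesion(followup_gamma),
                    recurrence_site=rec, recurrence_gamma=gamma_rec,
                    recurrence_silent=True),
        SessionSpec("followup-3", seg_rec, lesion(followup_gamma),
                    recurrence_site=rec, recurrence_gamma=gamma_rec,
                    recurrence_silent=False),
    )
    return LongitudinalSchedule(sessions)


def recurrence_recovery(seed: int = 0, n_schedules: int = 20, n_controls: int = 20):
    """Silent pre-recurrence perturbation: at the session before the
    recurrence is segmented, future-tumour voxels should already be more
    anomalous than the surrounding 1 cm vicinity."""
    ph = small_phantom(seed=1)
    model = SignalModel(n_timepoints=200)
    out = {}
    s = _seeds(seed, 2 * n_schedules * (n_controls + 2))
    si = iter(int(x) for x in s)
    for gamma_rec, tag in ((0.8, "lesioned"), (0.0, "null")):
        ps, aucs = [], []
        sched = _recurrence_schedule(ph, "spatial", 6.0, gamma_rec)
        for k in range(n_schedules):
            controls = [
                simulate_control(ph, model, next(si)) for _ in range(n_controls)
            ]
            sessions = simulate_longitudinal(ph, model, sched, next(si))
            ts3, seg3 = sessions[3]
            _, seg4 = sessions[4]
            excl = smooth_tumour_mask(seg3).intersect(ph.mask)
            maps, _ = cohort_anomaly(controls, [ts3], exclude=excl)
            fut = new_tumour_voxels(seg3, seg4).intersect(ph.mask)
            vic = tumour_vicinity(seg3, ph.mask)
            rc = recurrence_test(maps[0], fut, vic, n_perm=2000, seed=next(si))
            ps.append(rc.p_value)
            aucs.append(rc.auc)
        ps, aucs = np.asarray(ps), np.asarray(aucs)
        if tag == "lesioned":
            out["recurrence_frac_detected"] = float(
                np.mean((ps < 0.01) & (aucs >= 0.7))
            )
            out["recurrence_median_auc"] = float(np.median(aucs))
            out["recurrence_median_p"] = float(np.median(ps))
        else:
            out["recurrence_null_frac_auc_near_0.5"] = float(
                np.mean(np.abs(aucs - 0.5) <= 0.15)
            )
            out["recurrence_null_median_auc"] = float(np.median(aucs))
    return out


def stats_calibration(seed: int = 0, n_runs: int = 2000, n_perm: int = 500):
    """Type-I error of the permutation engines and realised FDR of BH."""
    rng = np.random.default_rng(seed)
    rej2, rejs = 0, 0
    for _ in range(n_runs):
        x = rng.standard_normal(20)
        y = rng.standard_normal(20)
        p = two_sample_permutation(
            x, y, "mean_diff", "two-sided", n_perm=n_perm,
            seed=int(rng.integers(2**31)),
        ).p_value
        rej2 += p <= 0.05
        d = rng.standard_normal(15)
        p = paired_sign_flip_test(
            d, "two-sided", n_perm=n_perm, seed=int(rng.integers(2**31))
        ).p_value
        rejs += p <= 0.05
    # realised FDR of BH on pure-null batches
    fdr_runs = 200
    fdps = []
    for _ in range(fdr_runs):
        p = rng.uniform(size=1000)
        reject, _ = fdr_bh(p, q=0.05)
        fdps.append(reject.mean() > 0)  # any false rejection => FDP = 1 (all null)
    return {
        "perm_type1_rate": rej2 / n_runs,
        "signflip_type1_rate": rejs / n_runs,
        "bh_realized_fdr_null": float(np.mean(fdps)),
    }
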