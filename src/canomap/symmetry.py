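"""Bi-hemispheric network symmetry and cerebellar lesion-map concordance.

Two complementary views of how a unilateral tumour reshapes both
hemispheres:

* per patient, the median anomaly score of each network in the ipsi- and
  contralateral hemisphere (cerebrum and cerebellum separately), and the
  across-patient correlation between ipsi and contra medians within and
  across networks;
* normative lesion-maps — the voxels connected (in the control reference)
  to the patient's tumour voxels — compared with thresholded anomaly
  overlap across patients, per cerebellar hemisphere, to expose the
  crossed cerebellar representation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .anomaly import AnomalyMap
from .connectome import ReferenceConnectome
from .grid import VoxelMask
from .images import (
    CEREBELLUM,
    CEREBRUM,
    HEMI_L,
    HEMI_R,
    NETWORKS,
    NetworkParcellation,
)
from .stats import pearson

__all__ = [
    "DEFAULT_ANOMALY_THRESHOLDS",
    "DEFAULT_CONNECTIVITY_THRESHOLD",
    "network_median_anomaly",
    "symmetry_correlation",
    "diagonal_excess_test",
    "lesion_map",
    "lesion_anomaly_overlap",
]

#: Anomaly thresholds swept by the overlap analysis (score < -t).
DEFAULT_ANOMALY_THRESHOLDS = (1.5, 2.0, 2.3, 2.6, 3.0)
#: Reference Fisher-z threshold for lesion maps (z > atanh(0.25)).
DEFAULT_CONNECTIVITY_THRESHOLD = float(np.arctanh(0.25))

_SIDES = ("ipsi", "contra")
_COMPARTMENTS = {"cerebrum": CEREBRUM, "cerebellum": CEREBELLUM}


def network_median_anomaly(
    anomaly: AnomalyMap,
    parcellation: NetworkParcellation,
    tumour_hemisphere: str,
) -> pd.DataFrame:
    """Median anomaly per (network, ipsi/contra, compartment) for one map.

    Ipsi/contra follow the anatomical side relative to the tumour, for the
    cerebellum as well.  Networks with no valid voxel get NaN.
    """
    if tumour_hemisphere not in ("L", "R"):
        raise ValueError("tumour_hemisphere must be 'L' or 'R'")
    t_hemi = HEMI_L if tumour_hemisphere == "L" else HEMI_R
    net = parcellation.network_of(anomaly.mask)
    hemi = parcellation.hemisphere_of(anomaly.mask)
    comp = parcellation.compartment_of(anomaly.mask)
    rows = []
    for n, network in enumerate(NETWORKS):
        for side in _SIDES:
            want_hemi = t_hemi if side == "ipsi" else 1 - t_hemi
            for comp_name, comp_code in _COMPARTMENTS.items():
                sel = (
                    (net == n)
                    & (hemi == want_hemi)
                    & (comp == comp_code)
                    & anomaly.valid
                )
                rows.append(
                    {
                        "patient": anomaly.subject_id,
                        "session": anomaly.session_index,
                        "network": network,
                        "side": side,
                        "compartment": comp_name,
                        "median_anomaly": float(np.median(anomaly.scores[sel]))
                        if sel.any()
                        else float("nan"),
                        "n_voxels": int(sel.sum()),
                    }
                )
    return pd.DataFrame(rows)


def _pivot(table: pd.DataFrame, compartment: str) -> tuple[np.ndarray, np.ndarray]:
    """(patients x networks) median matrices for ipsi and contra."""
    sub = table[table["compartment"] == compartment]
    ipsi = sub[sub["side"] == "ipsi"].pivot_table(
        index="patient", columns="network", values="median_anomaly", sort=False
    )[list(NETWORKS)]
    contra = sub[sub["side"] == "contra"].pivot_table(
        index="patient", columns="network", values="median_anomaly", sort=False
    )[list(NETWORKS)]
    contra = contra.loc[ipsi.index]
    return ipsi.to_numpy(), contra.to_numpy()


def symmetry_correlation(
    table: pd.DataFrame, compartment: str = "cerebrum"
) -> tuple[np.ndarray, np.ndarray]:
    """7x7 across-patient Pearson r (and r^2) between ipsi and contra
    network medians.  Entry (i, j) correlates network i ipsilateral with
    network j contralateral; constant columns yield NaN."""
    ipsi, contra = _pivot(table, compartment)
    if ipsi.shape[0] < 3:
        raise ValueError("need >= 3 patients")
    r = np.full((len(NETWORKS), len(NETWORKS)), np.nan)
    for i in range(len(NETWORKS)):
        for j in range(len(NETWORKS)):
            x, y = ipsi[:, i], contra[:, j]
            ok = np.isfinite(x) & np.isfinite(y)
            if ok.sum() >= 3:
                r[i, j] = pearson(x[ok], y[ok])
    return r, r**2


def diagonal_excess_test(
    table: pd.DataFrame,
    compartment: str = "cerebrum",
    n_perm: int = 10_000,
    seed: int | None = None,
) -> tuple[float, float]:
    """Is the within-network ipsi-contra r^2 larger than across-network?

    Statistic: mean diagonal r^2 minus mean off-diagonal r^2.  The null
    permutes the network identity of the contralateral columns (keeping
    patient pairing), which is exactly the exchangeability broken by
    network-specific symmetry.  Returns (statistic, p).
    """
    import itertools
    from math import factorial

    _, r2 = symmetry_correlation(table, compartment)
    k = len(NETWORKS)
    grand = np.nansum(r2)
    n_cells = np.isfinite(r2).sum()

    def stat(perm) -> float:
        diag = np.nanmean(r2[np.arange(k), list(perm)])
        off = (grand - np.nansum(r2[np.arange(k), list(perm)])) / max(n_cells - k, 1)
        return float(diag - off)

    observed = stat(range(k))
    if factorial(k) <= n_perm:  # exhaustive over network relabelings
        null = [stat(p) for p in itertools.permutations(range(k))]
        b = int(np.sum(np.asarray(null) >= observed - 1e-12))
        return observed, b / len(null)
    rng = np.random.default_rng(seed)
    null = [stat(rng.permutation(k)) for _ in range(n_perm)]
    b = int(np.sum(np.asarray(null) >= observed - 1e-12))
    return observed, (b + 1) / (n_perm + 1)


def lesion_map(
    tumour_mask: VoxelMask,
    reference: ReferenceConnectome,
    connectivity_threshold: float = DEFAULT_CONNECTIVITY_THRESHOLD,
) -> np.ndarray:
    """Per-voxel count of tumour voxels it is connected to in controls.

    Voxel v is counted once per tumour voxel t with reference z(v, t) above
    the threshold; tumour voxels themselves are zero.  Aligned to the
    reference-mask ordering.
    """
    if tumour_mask.empty():
        raise ValueError("empty tumour mask")
    ref_idx = reference.mask.indices
    t_pos = np.flatnonzero(np.isin(ref_idx, tumour_mask.indices))
    if t_pos.size == 0:
        raise ValueError("tumour mask does not intersect the reference mask")
    rows = reference.values[t_pos]  # (n_tumour, V) with NaN at self
    with np.errstate(invalid="ignore"):
        counts = np.nansum(rows > connectivity_threshold, axis=0).astype(np.int64)
    counts[t_pos] = 0
    return counts


def lesion_anomaly_overlap(
    lesion_maps: list[np.ndarray],
    anomaly_maps: list[AnomalyMap],
    parcellation: NetworkParcellation,
    anomaly_thresholds=DEFAULT_ANOMALY_THRESHOLDS,
) -> pd.DataFrame:
    """Correlate across-patient lesion-map overlap with anomaly overlap.

    Overlap is the per-voxel count of patients whose binarised map covers
    the voxel.  Correlations are evaluated separately over each cerebellar
    hemisphere, one row per (hemisphere, anomaly threshold).  The caller
    groups patients by tumour side.
    """
    if len(lesion_maps) != len(anomaly_maps) or len(anomaly_maps) < 2:
        raise ValueError("need matched lesion/anomaly maps for >= 2 patients")
    mask = anomaly_maps[0].mask
    lesion_overlap = np.sum([lm > 0 for lm in lesion_maps], axis=0)
    hemi = parcellation.hemisphere_of(mask)
    comp = parcellation.compartment_of(mask)
    rows = []
    for hemi_name, hemi_code in (("L", HEMI_L), ("R", HEMI_R)):
        sel = (comp == CEREBELLUM) & (hemi == hemi_code)
        for thr in anomaly_thresholds:
            anom_overlap = np.sum(
                [np.nan_to_num(am.scores, nan=np.inf) < -thr for am in anomaly_maps],
                axis=0,
            )
            r = pearson(lesion_overlap[sel], anom_overlap[sel])
            # a constant overlap map carries no concordance: report 0, flagged
            degenerate = bool(np.isnan(r))
            rows.append(
                {
                    "cerebellar_hemisphere": hemi_name,
                    "anomaly_threshold": thr,
                    "r": 0.0 if degenerate else r,
                    "degenerate": degenerate,
                    "n_voxels": int(sel.sum()),
                }
            )
    return pd.DataFrame(rows)
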