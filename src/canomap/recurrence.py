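"""Longitudinal anomaly trajectories and recurrence-location prediction.

Trajectories: per-network median anomaly over the session sequence, aligned
so the pre-surgical session is zero, pooled across patients and fitted with
a second-order polynomial (r^2 and RMSE characterise the fit).

Recurrence: between consecutive sessions t0 and t1, the voxels newly
labelled enhancing/necrotic at t1 are compared — at t0, before they were
visible — with the remaining "tumour vicinity" (a 1 cm rim around the t0
tumour/resection).  A one-sided two-sample permutation test asks whether
future-tumour voxels were already more anomalous, and the AUC of the
negated anomaly score quantifies voxel-wise discrimination.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .anomaly import AnomalyMap
from .grid import GridSpace, VoxelMask
from .images import SegmentationVolume
from .stats import (
    PermutationResult,
    auc_mann_whitney,
    two_sample_permutation,
)

__all__ = [
    "align_trajectories",
    "QuadraticFit",
    "fit_quadratic_trend",
    "new_tumour_voxels",
    "tumour_vicinity",
    "volume_filter",
    "RecurrenceComparison",
    "recurrence_test",
]


def align_trajectories(session_tables: list[pd.DataFrame]) -> pd.DataFrame:
    """Subtract the pre-surgical (session 0) median from every session.

    ``session_tables`` are :func:`canomap.symmetry.network_median_anomaly`
    outputs of one patient, ordered by session.  Returns tidy rows with a
    ``delta_anomaly`` column; session 0 is zero by construction.
    """
    if not session_tables:
        raise ValueError("no sessions")
    base = session_tables[0]
    if (base["session"] != 0).any():
        raise ValueError("missing pre-surgical (session 0) table")
    key = ["network", "side", "compartment"]
    base_vals = base.set_index(key)["median_anomaly"]
    out = []
    for tab in session_tables:
        tab = tab.copy()
        tab["delta_anomaly"] = (
            tab.set_index(key)["median_anomaly"] - base_vals
        ).to_numpy()
        out.append(tab)
    return pd.concat(out, ignore_index=True)


@dataclass(frozen=True)
class QuadraticFit:
    intercept: float
    linear: float
    quadratic: float
    r_squared: float
    rmse: float
    n_points: int

    def predict(self, s) -> np.ndarray:
        s = np.asarray(s, dtype=float)
        return self.intercept + self.linear * s + self.quadratic * s**2


def fit_quadratic_trend(sessions, values) -> QuadraticFit:
    """Least-squares fit of value = a + b*s + c*s^2 pooled across patients."""
    s = np.asarray(sessions, dtype=float).ravel()
    y = np.asarray(values, dtype=float).ravel()
    ok = np.isfinite(s) & np.isfinite(y)
    s, y = s[ok], y[ok]
    if np.unique(s).size < 3:
        raise ValueError("need >= 3 distinct session values")
    c2, c1, c0 = np.polyfit(s, y, 2)
    pred = c0 + c1 * s + c2 * s**2
    sse = float(np.sum((y - pred) ** 2))
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - sse / sst if sst > 0 else float("nan")
    rmse = float(np.sqrt(sse / s.size))
    return QuadraticFit(float(c0), float(c1), float(c2), r2, rmse, int(s.size))


def new_tumour_voxels(
    seg_t0: SegmentationVolume, seg_t1: SegmentationVolume
) -> VoxelMask:
    """Enhancing/necrotic tumour present at t1 but not at t0.

    The t0 side subtracts enhancing, necrotic *and* resection so that
    re-labelled cavity voxels do not count as new tumour.
    """
    seg_t0.grid.require_same(seg_t1.grid, "segmentation pair")
    t1 = seg_t1.enhancing_necrotic_mask()
    t0 = seg_t0.class_mask((1, 2, 5))
    return t1.difference(t0)


def tumour_vicinity(
    seg_t0: SegmentationVolume,
    analysis_mask: VoxelMask,
    margin_mm: float = 10.0,
) -> VoxelMask:
    """Analysis voxels within ``margin_mm`` of the t0 tumour/resection,
    excluding the tumour/resection voxels themselves (a rim)."""
    if margin_mm <= 0:
        raise ValueError("margin_mm must be > 0")
    prior = seg_t0.tumour_mask()
    if prior.empty():
        raise ValueError("t0 segmentation has no tumour/resection voxels")
    dist = ndimage.distance_transform_edt(
        ~prior.volume, sampling=seg_t0.grid.spacing
    )
    rim = (dist > 0) & (dist <= margin_mm)
    return VoxelMask(seg_t0.grid, rim).intersect(analysis_mask)


def volume_filter(mask: VoxelMask, grid: GridSpace, min_cm3: float = 3.0) -> bool:
    """True iff the mask volume reaches ``min_cm3`` cubic centimetres."""
    return mask.n_voxels * grid.voxel_volume_mm3() >= min_cm3 * 1000.0


@dataclass(frozen=True)
class RecurrenceComparison:
    session_pair: tuple[int, int]
    n_future: int
    n_vicinity: int
    mean_future: float
    mean_vicinity: float
    perm: PermutationResult
    auc: float
    auc_perm: PermutationResult

    @property
    def p_value(self) -> float:
        return self.perm.p_value

    def as_row(self) -> dict:
        return {
            "t0": self.session_pair[0],
            "t1": self.session_pair[1],
            "n_future": self.n_future,
            "n_vicinity": self.n_vicinity,
            "mean_future": self.mean_future,
            "mean_vicinity": self.mean_vicinity,
            "p_value": self.perm.p_value,
            "auc": self.auc,
            "auc_p_value": self.auc_perm.p_value,
        }


def recurrence_test(
    anomaly_t0: AnomalyMap,
    future_mask: VoxelMask,
    vicinity_mask: VoxelMask,
    n_perm: int = 10_000,
    seed: int | None = None,
    session_pair: tuple[int, int] = (0, 1),
) -> RecurrenceComparison:
    """Were future-tumour voxels already more anomalous than the vicinity?

    Future voxels are removed from the vicinity comparison set.  The
    permutation test is one-sided (future mean more negative); the AUC uses
    the negated anomaly score as predictor of future-tumour membership with
    midrank tie handling, and its p-value comes from label permutation.
    """
    mask_idx = anomaly_t0.mask.indices
    fut = np.isin(mask_idx, future_mask.indices) & anomaly_t0.valid
    vic = (
        np.isin(mask_idx, vicinity_mask.indices)
        & ~np.isin(mask_idx, future_mask.indices)
        & anomaly_t0.valid
    )
    x = anomaly_t0.scores[fut]
    y = anomaly_t0.scores[vic]
    if x.size == 0 or y.size == 0:
        raise ValueError("no valid anomaly scores in future or vicinity set")
    perm = two_sample_permutation(
        x, y, statistic="mean_diff", sidedness="less", n_perm=n_perm, seed=seed
    )
    scores = np.concatenate([-x, -y])
    labels = np.concatenate([np.ones(x.size), np.zeros(y.size)])
    auc = auc_mann_whitney(scores, labels)
    auc_perm = two_sample_permutation(
        -x, -y, statistic="auc", sidedness="greater", n_perm=n_perm,
        seed=None if seed is None else seed + 1,
    )
    return RecurrenceComparison(
        session_pair, int(x.size), int(y.size), float(x.mean()), float(y.mean()),
        perm, auc, auc_perm,
    )
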