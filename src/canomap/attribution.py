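"""Functional-vs-spatial attribution of network anomaly to the tumour.

For every enhancing/necrotic tumour voxel we ask whether the highly
anomalous voxels of the brain lie close to it *functionally* (strongly
correlated with it in the control-average connectome) or *spatially*
(small Euclidean distance).  Both predictors are oriented as distances —
functional distance = 1 - |r|, back-transformed from the reference z —
so that "anomaly follows X" corresponds to a positive Pearson correlation
between the X-distance and the anomaly score (closer => more negative
score).  The per-voxel label is the distance kind with the larger positive
correlation; voxels with no positive relationship are labelled ``none``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .anomaly import AnomalyMap
from .connectome import ReferenceConnectome
from .grid import GridSpace, VoxelMask
from .images import NETWORKS
from .stats import pearson

__all__ = [
    "ANOMALY_THRESHOLD",
    "DistanceFields",
    "distance_fields",
    "attribute_voxel",
    "attribute_patient",
    "attribution_summary",
]

#: Scores below this are "highly anomalous" (in MAD units).
ANOMALY_THRESHOLD = -2.3


@dataclass
class DistanceFields:
    """Spatial and functional distance from one tumour voxel to every
    non-tumour analysis voxel (aligned to the analysis-mask ordering,
    NaN at tumour voxels)."""

    tumour_voxel: int  # flat index
    spatial_mm: np.ndarray
    functional_proximity: np.ndarray  # |r| in [0, 1]

    @property
    def functional_distance(self) -> np.ndarray:
        return 1.0 - self.functional_proximity


def distance_fields(
    tumour_voxel: int,
    grid: GridSpace,
    reference: ReferenceConnectome,
    analysis_mask: VoxelMask,
    tumour_mask: VoxelMask,
) -> DistanceFields:
    """Distance fields of one tumour voxel over non-tumour analysis voxels.

    The reference must cover the analysis mask (tumour voxels included),
    since functional proximity is read from the tumour voxel's row.
    """
    mask_idx = analysis_mask.indices
    ref_idx = reference.mask.indices
    pos = np.searchsorted(ref_idx, tumour_voxel)
    if pos >= ref_idx.size or ref_idx[pos] != tumour_voxel:
        raise ValueError("tumour voxel is not covered by the reference mask")
    row = reference.values[pos]
    # align reference columns onto the analysis mask ordering
    col_pos = np.searchsorted(ref_idx, mask_idx)
    if not np.array_equal(ref_idx[col_pos], mask_idx):
        raise ValueError("reference does not cover the analysis mask")
    prox = np.abs(np.tanh(row[col_pos]))
    centres = grid.voxel_centres_mm(mask_idx)
    c = grid.voxel_centres_mm(np.array([tumour_voxel]))[0]
    dist = np.linalg.norm(centres - c, axis=1)
    in_tumour = np.isin(mask_idx, tumour_mask.indices)
    prox[in_tumour] = np.nan
    dist[in_tumour] = np.nan
    return DistanceFields(tumour_voxel, dist, prox)


def attribute_voxel(
    anomaly: AnomalyMap,
    fields: DistanceFields,
    anomaly_threshold: float = ANOMALY_THRESHOLD,
    restrict_to_anomalous: bool = True,
) -> tuple[float, float, str, str]:
    """Correlate one tumour voxel's distance fields with the anomaly map.

    Returns (r_spatial, r_functional, label, reason).  Correlations are
    computed over highly anomalous non-tumour voxels (score below the
    threshold) unless ``restrict_to_anomalous`` is False, in which case all
    valid non-tumour voxels enter.
    """
    sel = anomaly.valid & np.isfinite(fields.spatial_mm)
    if restrict_to_anomalous:
        sel &= anomaly.scores < anomaly_threshold
    if sel.sum() < 3:
        return float("nan"), float("nan"), "none", "too_few_anomalous_voxels"
    scores = anomaly.scores[sel]
    r_spatial = pearson(fields.spatial_mm[sel], scores)
    r_functional = pearson(fields.functional_distance[sel], scores)
    rs = r_spatial if np.isfinite(r_spatial) else -np.inf
    rf = r_functional if np.isfinite(r_functional) else -np.inf
    if rs <= 0 and rf <= 0:
        return r_spatial, r_functional, "none", "no_positive_relationship"
    if rs == rf:  # exact tie (measure zero) -> none, for determinism
        return r_spatial, r_functional, "none", "tie"
    label = "spatial" if rs > rf else "functional"
    return r_spatial, r_functional, label, ""


def attribute_patient(
    anomaly: AnomalyMap,
    reference: ReferenceConnectome,
    tumour_voxels: VoxelMask,
    grid: GridSpace,
    network_of_voxel: np.ndarray | None = None,
    anomaly_threshold: float = ANOMALY_THRESHOLD,
    restrict_to_anomalous: bool = True,
    subject_id: str = "",
) -> pd.DataFrame:
    """Attribution of every enhancing/necrotic tumour voxel of one patient.

    ``tumour_voxels`` must be the enhancing+necrotic voxels intersected with
    the analysis mask.  ``network_of_voxel`` (aligned to the analysis-mask
    ordering) adds each tumour voxel's network identity.
    """
    mask = anomaly.mask
    rows = []
    tumour_flat = tumour_voxels.indices
    for t in tumour_flat:
        fields = distance_fields(int(t), grid, reference, mask, tumour_voxels)
        r_s, r_f, label, reason = attribute_voxel(
            anomaly, fields, anomaly_threshold, restrict_to_anomalous
        )
        net = ""
        if network_of_voxel is not None:
            k = int(np.searchsorted(mask.indices, t))
            nid = int(network_of_voxel[k])
            net = NETWORKS[nid] if nid >= 0 else "none"
        rows.append(
            {
                "patient": subject_id,
                "voxel": int(t),
                "network": net,
                "r_spatial": r_s,
                "r_functional": r_f,
                "label": label,
                "reason": reason,
            }
        )
    return pd.DataFrame(rows)


def attribution_summary(voxel_tables: list[pd.DataFrame]) -> pd.DataFrame:
    """Per-patient percentages of tumour voxels per label (sum to 100)."""
    rows = []
    for table in voxel_tables:
        if len(table) == 0:
            raise ValueError("patient with no attributed tumour voxels")
        n = len(table)
        counts = table["label"].value_counts()
        pct = {
            lab: 100.0 * counts.get(lab, 0) / n
            for lab in ("functional", "spatial", "none")
        }
        rows.append(
            {
                "patient": table["patient"].iloc[0] if n else "",
                "n_tumour_voxels": n,
                "pct_functional": pct["functional"],
                "pct_spatial": pct["spatial"],
                "pct_none": pct["none"],
            }
        )
    return pd.DataFrame(rows)
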