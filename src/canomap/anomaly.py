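"""Connectivity-profile similarity, control baselines, and anomaly maps.

The per-voxel statistic is the cosine similarity between a subject's
connectivity profile (one connectome row) and the corresponding row of the
control-average reference, computed after discarding negative entries of
both rows so that similarity lies in [0, 1].  Across the control cohort this
yields a per-voxel distribution, summarised robustly by its median and MAD.
A subject's anomaly score at a voxel is

    score = (similarity - control median) / control MAD

with the MAD used raw (no 1.4826 normal-consistency factor), so the
conventional "highly anomalous" cut of -2.3 is in MAD units.  Tumour voxels
(the 3 mm FWHM smoothed union of all tumour tissue classes) are excluded
from the connectomes of the patient *and* of every control before the
baseline is built, making the baseline patient-specific.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .connectome import (
    Connectome,
    DEFAULT_CLIP,
    ReferenceConnectome,
    drop_voxels,
    fisher_z,
    mean_reference,
    standardize_timeseries,
)
from .grid import VoxelMask
from .images import SegmentationVolume, TimeSeriesImage

__all__ = [
    "MAD_FLOOR",
    "MAD_CONSISTENCY",
    "SimilarityVector",
    "BaselineDistribution",
    "AnomalyMap",
    "positive_cosine_similarity",
    "similarity_map",
    "build_baseline",
    "anomaly_score",
    "patient_anomaly",
    "smooth_tumour_mask",
    "cohort_anomaly",
]

#: Voxels whose control MAD falls below this floor are invalid, never +-inf.
MAD_FLOOR = 1e-6
#: Normal-consistency factor, applied only when explicitly requested.
MAD_CONSISTENCY = 1.4826


@dataclass
class SimilarityVector:
    """Per-voxel cosine similarity to the reference; NaN where invalid."""

    mask: VoxelMask
    values: np.ndarray  # length V (mask ordering), NaN invalid
    excluded: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=np.intp))
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (self.mask.n_voxels,):
            raise ValueError("similarity length does not match mask")
        self.excluded = np.asarray(self.excluded, dtype=np.intp)
        valid = self.values[np.isfinite(self.values)]
        if valid.size and (valid.min() < -1e-12 or valid.max() > 1 + 1e-12):
            raise ValueError("cosine similarities must lie in [0, 1]")


@dataclass
class BaselineDistribution:
    """Per-voxel median and MAD of control similarities."""

    mask: VoxelMask
    median: np.ndarray
    mad: np.ndarray
    n_controls: int
    excluded: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=np.intp))

    def __post_init__(self) -> None:
        if self.n_controls < 2:
            raise ValueError("baseline needs >= 2 controls")
        self.excluded = np.asarray(self.excluded, dtype=np.intp)


@dataclass
class AnomalyMap:
    """Per-voxel robust anomaly score; NaN at excluded/degenerate voxels."""

    mask: VoxelMask
    scores: np.ndarray
    excluded: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=np.intp))
    subject_id: str = ""
    session_label: str = ""
    session_index: int = 0

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=np.float64)
        if self.scores.shape != (self.mask.n_voxels,):
            raise ValueError("score length does not match mask")
        self.excluded = np.asarray(self.excluded, dtype=np.intp)

    @property
    def valid(self) -> np.ndarray:
        return np.isfinite(self.scores)


def positive_cosine_similarity(profile_row, reference_row) -> float:
    """Cosine of two connectivity rows after zeroing negative entries.

    Negative entries of each row are clipped to zero *independently*.  If
    either clipped row is all-zero the similarity is undefined (NaN) —
    cosine has no value at a zero vector.
    """
    a = np.asarray(profile_row, dtype=float).ravel()
    b = np.asarray(reference_row, dtype=float).ravel()
    if a.size != b.size:
        raise ValueError("row length mismatch")
    a = np.where(np.isfinite(a) & (a > 0), a, 0.0)
    b = np.where(np.isfinite(b) & (b > 0), b, 0.0)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return float("nan")
    return float(np.clip((a @ b) / (na * nb), 0.0, 1.0))


def _rowwise_positive_cosine(patient: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Vectorised positive-clipped cosine per row; NaN diagonal handled."""
    p = np.where(np.isfinite(patient) & (patient > 0), patient, 0.0)
    r = np.where(np.isfinite(reference) & (reference > 0), reference, 0.0)
    num = np.einsum("ij,ij->i", p, r)
    np_norm = np.linalg.norm(p, axis=1)
    nr_norm = np.linalg.norm(r, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = num / (np_norm * nr_norm)
    sim[(np_norm == 0) | (nr_norm == 0)] = np.nan
    return np.clip(sim, 0.0, 1.0)


def similarity_map(
    connectome: Connectome,
    reference: ReferenceConnectome,
    exclude: VoxelMask | None = None,
    use_fisher_z: bool = True,
) -> SimilarityVector:
    """Row-wise positive-clipped cosine similarity to the reference.

    ``exclude`` removes voxels (rows *and* columns) before the similarity is
    computed; excluded voxels are NaN in the returned full-length vector.
    When ``use_fisher_z`` is False the cosine is computed on back-transformed
    correlations rather than z values.
    """
    if connectome.mask != reference.mask:
        raise ValueError("connectome and reference masks differ")
    full_mask = connectome.mask
    if exclude is not None and not exclude.empty():
        conn = drop_voxels(connectome, exclude)
        ref = drop_voxels(reference, exclude)
        excluded = exclude.intersect(full_mask).indices
    else:
        conn, ref = connectome, reference
        excluded = np.zeros(0, dtype=np.intp)
    pv, rv = conn.values, ref.values
    if not use_fisher_z:
        pv, rv = np.tanh(pv), np.tanh(rv)
    sim_sub = _rowwise_positive_cosine(pv, rv)
    values = np.full(full_mask.n_voxels, np.nan)
    keep = np.isin(full_mask.indices, conn.mask.indices)
    values[keep] = sim_sub
    return SimilarityVector(full_mask, values, excluded, connectome.subject_id)


def build_baseline(
    control_similarities: list[SimilarityVector],
    mad_consistency: bool = False,
) -> BaselineDistribution:
    """Per-voxel median and MAD over the control similarity distribution.

    Voxels with fewer than 2 valid control values are invalid.  The MAD is
    median(|x - median|), stored raw unless ``mad_consistency`` applies the
    1.4826 factor.
    """
    if len(control_similarities) < 2:
        raise ValueError("need >= 2 control similarity vectors")
    mask = control_similarities[0].mask
    excluded = control_similarities[0].excluded
    for s in control_similarities[1:]:
        if s.mask != mask or not np.array_equal(np.sort(s.excluded), np.sort(excluded)):
            raise ValueError("control similarities have mismatched mask/exclusion")
    stack = np.stack([s.values for s in control_similarities])
    n_valid = np.isfinite(stack).sum(axis=0)
    med = np.full(stack.shape[1], np.nan)
    mad = np.full(stack.shape[1], np.nan)
    some = n_valid > 0  # all-NaN columns (excluded voxels) stay NaN silently
    med[some] = np.nanmedian(stack[:, some], axis=0)
    mad[some] = np.nanmedian(np.abs(stack[:, some] - med[some]), axis=0)
    bad = n_valid < 2
    med[bad] = np.nan
    mad[bad] = np.nan
    if mad_consistency:
        mad = mad * MAD_CONSISTENCY
    return BaselineDistribution(mask, med, mad, len(control_similarities), excluded)


def anomaly_score(
    similarity: SimilarityVector, baseline: BaselineDistribution
) -> AnomalyMap:
    """Robust z: (similarity - median) / MAD, NaN where MAD is degenerate."""
    if similarity.mask != baseline.mask:
        raise ValueError("similarity and baseline masks differ")
    if not np.array_equal(np.sort(similarity.excluded), np.sort(baseline.excluded)):
        raise ValueError(
            "similarity and baseline exclusion sets differ — the baseline "
            "must be rebuilt with the patient's tumour exclusion"
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        scores = (similarity.values - baseline.median) / baseline.mad
    scores[~np.isfinite(baseline.mad) | (baseline.mad < MAD_FLOOR)] = np.nan
    return AnomalyMap(
        similarity.mask, scores, similarity.excluded, similarity.subject_id
    )


def patient_anomaly(
    patient_connectome: Connectome,
    control_connectomes: list[Connectome],
    tumour_exclusion: VoxelMask | None = None,
    mad_consistency: bool = False,
    use_fisher_z: bool = True,
) -> AnomalyMap:
    """Full anomaly map for one subject against a control cohort.

    Excluded (tumour) voxels are removed from the patient and from every
    control connectome; the reference, the control similarities and the
    median/MAD baseline are all recomputed on the reduced voxel set, so the
    baseline is specific to this patient's exclusion.
    """
    mask = patient_connectome.mask
    if tumour_exclusion is not None:
        tumour_exclusion = tumour_exclusion.intersect(mask)
    reference = mean_reference(control_connectomes)
    control_sims = [
        similarity_map(c, reference, tumour_exclusion, use_fisher_z)
        for c in control_connectomes
    ]
    baseline = build_baseline(control_sims, mad_consistency)
    sim = similarity_map(patient_connectome, reference, tumour_exclusion, use_fisher_z)
    return anomaly_score(sim, baseline)


def smooth_tumour_mask(
    seg: SegmentationVolume,
    fwhm_mm: float = 3.0,
    rel_threshold: float = 0.05,
) -> VoxelMask:
    """Liberal tumour mask: Gaussian-smoothed union of all tumour classes.

    The binary union of the five tumour tissue classes is smoothed with a
    Gaussian of the given FWHM (sigma = FWHM / 2.3548 per axis, in mm) and
    thresholded at ``rel_threshold`` of the smoothed peak.  The output always
    contains the input voxels.
    """
    if fwhm_mm <= 0:
        raise ValueError("fwhm_mm must be > 0")
    binary = seg.tumour_mask().volume.astype(np.float64)
    if not binary.any():
        return VoxelMask(seg.grid, np.zeros(seg.grid.shape, dtype=bool))
    sigma_vox = [fwhm_mm / 2.3548 / s for s in seg.grid.spacing]
    smoothed = ndimage.gaussian_filter(binary, sigma=sigma_vox)
    out = smoothed > rel_threshold * smoothed.max()
    return VoxelMask(seg.grid, out | (binary > 0))


# -- memory-bounded cohort engine --------------------------------------------


def cohort_anomaly(
    control_ts: list[TimeSeriesImage],
    target_ts: list[TimeSeriesImage],
    exclude: VoxelMask | None = None,
    clip: float = DEFAULT_CLIP,
    block_rows: int = 512,
    mad_consistency: bool = False,
    use_fisher_z: bool = True,
) -> tuple[list[AnomalyMap], BaselineDistribution]:
    """Score target subjects against a control cohort without storing any
    per-subject V x V connectome.

    Equivalent to :func:`patient_anomaly` (verified in tests) but streams
    the connectivity rows in blocks: only the reference matrix and one
    ``block_rows x V`` block per subject are dense at any time.
    """
    if len(control_ts) < 2:
        raise ValueError("need >= 2 controls")
    full_mask = control_ts[0].mask
    for ts in list(control_ts) + list(target_ts):
        if ts.mask != full_mask:
            raise ValueError("all subjects must share one analysis mask")
    if exclude is not None:
        exclude = exclude.intersect(full_mask)
        keep = ~np.isin(full_mask.indices, exclude.indices)
        excluded_idx = exclude.indices
    else:
        keep = np.ones(full_mask.n_voxels, dtype=bool)
        excluded_idx = np.zeros(0, dtype=np.intp)

    z_ctrl = [standardize_timeseries(ts.data[keep]) for ts in control_ts]
    z_tgt = [standardize_timeseries(ts.data[keep]) for ts in target_ts]
    v = int(keep.sum())
    step = max(1, min(block_rows, v))

    # pass 1: reference matrix (mean Fisher-z over controls), block by block
    ref = np.empty((v, v), dtype=np.float64)
    for lo in range(0, v, step):
        hi = min(lo + step, v)
        acc = np.zeros((hi - lo, v))
        for z in z_ctrl:
            acc += fisher_z(z[lo:hi] @ z.T, clip)
        ref[lo:hi] = acc / len(z_ctrl)
    ref[np.arange(v), np.arange(v)] = np.nan

    # pass 2: per-subject row-wise positive cosine vs the reference
    def similarities(z: np.ndarray) -> np.ndarray:
        sim = np.empty(v)
        for lo in range(0, v, step):
            hi = min(lo + step, v)
            rows = fisher_z(z[lo:hi] @ z.T, clip)
            rows[np.arange(hi - lo), np.arange(lo, hi)] = np.nan
            pv, rv = rows, ref[lo:hi]
            if not use_fisher_z:
                pv, rv = np.tanh(pv), np.tanh(rv)
            sim[lo:hi] = _rowwise_positive_cosine(pv, rv)
        return sim

    def expand(sub_values: np.ndarray) -> np.ndarray:
        out = np.full(full_mask.n_voxels, np.nan)
        out[keep] = sub_values
        return out

    control_sims = [
        SimilarityVector(full_mask, expand(similarities(z)), excluded_idx, ts.subject_id)
        for z, ts in zip(z_ctrl, control_ts)
    ]
    baseline = build_baseline(control_sims, mad_consistency)
    maps = []
    for z, ts in zip(z_tgt, target_ts):
        sim = SimilarityVector(full_mask, expand(similarities(z)), excluded_idx, ts.subject_id)
        amap = anomaly_score(sim, baseline)
        amap.session_label = ts.session_label
        amap.session_index = ts.session_index
        maps.append(amap)
    return maps, baseline
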