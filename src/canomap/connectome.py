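"""Voxel-wise Fisher-z connectivity matrices and the control reference.

Connectivity between two voxels is the Pearson correlation of their BOLD
series, variance-stabilised with the Fisher z transform (atanh).  The
control-group reference is the element-wise mean of the individual z
matrices.  The self-connection carries no profile information and is kept
invalid (NaN on the diagonal) throughout.

Row-block computation keeps per-step memory at ``block_rows x V`` so that
large masks never require more than one dense block of rows at a time; at
demo scale the full matrix is materialised.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np

from .grid import VoxelMask

__all__ = [
    "DEFAULT_CLIP",
    "Connectome",
    "ReferenceConnectome",
    "standardize_timeseries",
    "fisher_z",
    "compute_connectome",
    "connectome_row_blocks",
    "mean_reference",
    "drop_voxels",
]

#: Correlations are clipped to |r| <= 1 - 1e-6 before atanh so that perfect
#: correlations (common in toy data) stay finite after the transform.
DEFAULT_CLIP = 1.0 - 1e-6


@dataclass
class Connectome:
    """V x V symmetric Fisher-z connectivity matrix with NaN diagonal."""

    mask: VoxelMask
    values: np.ndarray
    subject_id: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.shape != (self.mask.n_voxels, self.mask.n_voxels):
            raise ValueError("connectome shape does not match mask")
        self.values = v

    @property
    def n_voxels(self) -> int:
        return self.values.shape[0]

    def off_diagonal_finite(self) -> bool:
        od = self.values[~np.eye(self.n_voxels, dtype=bool)]
        return bool(np.isfinite(od).all())


@dataclass
class ReferenceConnectome(Connectome):
    n_controls: int = 0


def standardize_timeseries(data: np.ndarray) -> np.ndarray:
    """Row-standardize to zero mean, unit norm; errors on constant rows."""
    data = np.asarray(data, dtype=np.float64)
    centred = data - data.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centred, axis=1)
    bad = np.flatnonzero(norms == 0)
    if bad.size:
        raise ValueError(f"zero-variance time series at voxel row(s) {bad[:5].tolist()}")
    return centred / norms[:, None]


def fisher_z(r: np.ndarray, clip: float = DEFAULT_CLIP) -> np.ndarray:
    return np.arctanh(np.clip(r, -clip, clip))


def compute_connectome(
    ts, clip: float = DEFAULT_CLIP, block_rows: int | None = None
) -> Connectome:
    """Fisher-z Pearson connectivity of a masked time series.

    ``block_rows`` limits the number of correlation rows computed per matrix
    product; the result is identical to the all-at-once computation.
    """
    if ts.n_timepoints < 3:
        raise ValueError("need T >= 3 to estimate correlations")
    z = standardize_timeseries(ts.data)
    v = z.shape[0]
    out = np.empty((v, v), dtype=np.float64)
    for lo, hi, blk in connectome_row_blocks(z, clip=clip, block_rows=block_rows):
        out[lo:hi] = blk
    out = (out + out.T) / 2.0
    np.fill_diagonal(out, np.nan)
    return Connectome(ts.mask, out, subject_id=ts.subject_id)


def connectome_row_blocks(
    standardized: np.ndarray,
    clip: float = DEFAULT_CLIP,
    block_rows: int | None = None,
) -> Iterator[tuple[int, int, np.ndarray]]:
    """Yield (row_lo, row_hi, z_block) of the Fisher-z matrix.

    ``standardized`` must come from :func:`standardize_timeseries`.
    """
    v = standardized.shape[0]
    step = v if block_rows is None else max(1, int(block_rows))
    for lo in range(0, v, step):
        hi = min(lo + step, v)
        r = standardized[lo:hi] @ standardized.T
        yield lo, hi, fisher_z(r, clip)


def mean_reference(connectomes: Sequence[Connectome]) -> ReferenceConnectome:
    """Element-wise mean of control connectomes (z-space averaging)."""
    if len(connectomes) == 0:
        raise ValueError("need at least one connectome")
    mask = connectomes[0].mask
    for c in connectomes[1:]:
        if c.mask != mask:
            raise ValueError("connectome masks differ")
    acc = np.zeros_like(connectomes[0].values)
    for c in connectomes:
        acc += c.values
    acc /= len(connectomes)
    return ReferenceConnectome(mask, acc, n_controls=len(connectomes))


def drop_voxels(connectome: Connectome, exclude: VoxelMask) -> Connectome:
    """Remove rows/columns of excluded voxels, preserving the remaining order."""
    if not exclude.issubset(connectome.mask):
        raise ValueError("exclusion mask is not a subset of the connectome mask")
    keep_flat = connectome.mask.difference(exclude)
    if keep_flat.n_voxels < 2:
        raise ValueError("exclusion leaves fewer than 2 voxels")
    keep = np.isin(connectome.mask.indices, keep_flat.indices)
    sub = connectome.values[np.ix_(keep, keep)]
    if isinstance(connectome, ReferenceConnectome):
        return ReferenceConnectome(
            keep_flat, sub, subject_id=connectome.subject_id,
            n_controls=connectome.n_controls,
        )
    return Connectome(keep_flat, sub, subject_id=connectome.subject_id)
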