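"""NIfTI and tabular readers/writers.

Volumes are exchanged as NIfTI (.nii/.nii.gz) through nibabel; parcellation
label tables as TSV; connectomes as .npy with a JSON sidecar recording the
mask hash and provenance.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .grid import GridSpace, VoxelMask
from .images import (
    NETWORKS,
    NetworkParcellation,
    SegmentationVolume,
    TimeSeriesImage,
)

__all__ = [
    "grid_from_nifti",
    "read_volume",
    "read_timeseries",
    "read_mask",
    "read_segmentation",
    "write_timeseries",
    "write_mask",
    "write_segmentation",
    "write_scalar_map",
    "read_scalar_map",
    "read_parcellation",
    "write_parcellation",
    "mask_hash",
    "save_connectome_array",
    "load_connectome_array",
    "write_table",
]


def _check_grid(grid: GridSpace, expected: GridSpace | None, path) -> None:
    if expected is not None:
        expected.require_same(grid, str(path))


def grid_from_nifti(img: nib.Nifti1Image) -> GridSpace:
    shape = tuple(int(s) for s in img.shape[:3])
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return GridSpace(shape, spacing, affine=np.asarray(img.affine))


def _load(path) -> nib.Nifti1Image:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    return nib.load(str(path))


def read_volume(path, expected_grid: GridSpace | None = None):
    """Read a NIfTI volume, dispatching on dimensionality.

    4-D volumes return a :class:`TimeSeriesImage` over all nonzero-variance
    voxels unless a mask is supplied via :func:`read_timeseries`; 3-D integer
    volumes are returned as raw arrays by the typed readers below.
    """
    img = _load(path)
    if img.ndim == 4:
        return read_timeseries(path, expected_grid=expected_grid)
    return read_mask(path, expected_grid=expected_grid)


def read_timeseries(
    path,
    mask: VoxelMask | None = None,
    expected_grid: GridSpace | None = None,
    subject_id: str = "",
    session_label: str = "control",
    session_index: int = 0,
) -> TimeSeriesImage:
    img = _load(path)
    if img.ndim != 4:
        raise ValueError(f"{path}: expected a 4-D time series")
    grid = grid_from_nifti(img)
    _check_grid(grid, expected_grid, path)
    data4d = np.asarray(img.dataobj, dtype=np.float64)
    if mask is None:
        mask = VoxelMask(grid, np.any(data4d != 0, axis=3))
    else:
        grid.require_same(mask.grid, f"{path} mask")
    ijk = grid.flat_to_ijk(mask.indices)
    data = data4d[ijk[:, 0], ijk[:, 1], ijk[:, 2], :]
    if not np.isfinite(data).all():
        raise ValueError(f"{path}: non-finite voxels in time series")
    return TimeSeriesImage(grid, mask, data, subject_id, session_label, session_index)


def read_mask(path, expected_grid: GridSpace | None = None) -> VoxelMask:
    img = _load(path)
    grid = grid_from_nifti(img)
    _check_grid(grid, expected_grid, path)
    return VoxelMask(grid, np.asarray(img.dataobj) > 0)


def read_segmentation(path, expected_grid: GridSpace | None = None) -> SegmentationVolume:
    img = _load(path)
    grid = grid_from_nifti(img)
    _check_grid(grid, expected_grid, path)
    labels = np.rint(np.asarray(img.dataobj)).astype(np.int16)
    return SegmentationVolume(grid, labels)


def _nifti(data: np.ndarray, grid: GridSpace) -> nib.Nifti1Image:
    img = nib.Nifti1Image(data, grid.affine_array)
    img.header.set_zooms(tuple(grid.spacing) + ((1.0,) if data.ndim == 4 else ()))
    return img


def write_timeseries(ts: TimeSeriesImage, path) -> None:
    vol = np.zeros(ts.grid.shape + (ts.n_timepoints,), dtype=np.float64)
    ijk = ts.grid.flat_to_ijk(ts.mask.indices)
    vol[ijk[:, 0], ijk[:, 1], ijk[:, 2], :] = ts.data
    nib.save(_nifti(vol, ts.grid), str(path))


def write_mask(mask: VoxelMask, path) -> None:
    nib.save(_nifti(mask.volume.astype(np.uint8), mask.grid), str(path))


def write_segmentation(seg: SegmentationVolume, path) -> None:
    nib.save(_nifti(seg.labels.astype(np.int16), seg.grid), str(path))


def write_scalar_map(values: np.ndarray, mask: VoxelMask, path) -> None:
    """Write a per-mask-voxel scalar (e.g. an anomaly score) as NIfTI.

    Invalid voxels should be NaN in ``values``; voxels outside the mask are
    NaN in the output volume.
    """
    vol = np.full(mask.grid.shape, np.nan, dtype=np.float64)
    vol.ravel()[mask.indices] = np.asarray(values, dtype=np.float64)
    nib.save(_nifti(vol, mask.grid), str(path))


def read_scalar_map(path, mask: VoxelMask) -> np.ndarray:
    img = _load(path)
    grid_from_nifti(img).require_same(mask.grid, str(path))
    return np.asarray(img.dataobj, dtype=np.float64).ravel()[mask.indices]


# -- parcellation -------------------------------------------------------------

_HEMIS = ("L", "R")
_COMPARTMENTS = ("cerebrum", "cerebellum")


def write_parcellation(parc: NetworkParcellation, nifti_path, table_path) -> None:
    """Encode (network, hemisphere, compartment) as one label volume + TSV."""
    code = np.zeros(parc.grid.shape, dtype=np.int16)
    labelled = parc.network >= 0
    code[labelled] = (
        1
        + parc.network[labelled] * 4
        + parc.hemisphere[labelled] * 2
        + parc.compartment[labelled]
    )
    nib.save(_nifti(code, parc.grid), str(nifti_path))
    rows = []
    for n, net in enumerate(NETWORKS):
        for h, hemi in enumerate(_HEMIS):
            for c, comp in enumerate(_COMPARTMENTS):
                rows.append(
                    {
                        "code": 1 + n * 4 + h * 2 + c,
                        "name": f"{net}_{hemi}_{comp}",
                        "network": net,
                        "hemisphere": hemi,
                        "compartment": comp,
                    }
                )
    pd.DataFrame(rows).to_csv(table_path, sep="\t", index=False)


def read_parcellation(nifti_path, table_path, expected_grid: GridSpace | None = None) -> NetworkParcellation:
    img = _load(nifti_path)
    grid = grid_from_nifti(img)
    _check_grid(grid, expected_grid, nifti_path)
    code = np.rint(np.asarray(img.dataobj)).astype(np.int64)
    table = pd.read_csv(table_path, sep="\t")
    net = np.full(grid.shape, -1, dtype=np.int16)
    hemi = np.full(grid.shape, -1, dtype=np.int16)
    comp = np.full(grid.shape, -1, dtype=np.int16)
    known = {0}
    for row in table.itertuples():
        sel = code == row.code
        known.add(int(row.code))
        if not sel.any():
            continue
        net[sel] = NETWORKS.index(row.network)
        hemi[sel] = _HEMIS.index(row.hemisphere)
        comp[sel] = _COMPARTMENTS.index(row.compartment)
    unknown = set(np.unique(code).tolist()) - known
    if unknown:
        raise ValueError(f"parcellation codes {sorted(unknown)} missing from label table")
    return NetworkParcellation(grid, net, hemi, comp)


# -- connectome container -----------------------------------------------------


def mask_hash(mask: VoxelMask) -> str:
    h = hashlib.sha256()
    h.update(np.asarray(mask.grid.shape, dtype=np.int64).tobytes())
    h.update(np.asarray(mask.grid.spacing, dtype=np.float64).tobytes())
    h.update(mask.indices.astype(np.int64).tobytes())
    return h.hexdigest()[:16]


def save_connectome_array(values: np.ndarray, mask: VoxelMask, path, **meta) -> None:
    path = Path(path)
    np.save(path.with_suffix(".npy"), values)
    sidecar = {"mask_hash": mask_hash(mask), "ordering": "flat-C-ascending", **meta}
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def load_connectome_array(path, mask: VoxelMask) -> tuple[np.ndarray, dict]:
    path = Path(path)
    values = np.load(path.with_suffix(".npy"))
    meta = json.loads(path.with_suffix(".json").read_text())
    if meta.get("mask_hash") != mask_hash(mask):
        raise ValueError("connectome mask hash does not match the supplied mask")
    return values, meta


def write_table(df: pd.DataFrame, path) -> None:
    """Deterministic TSV output (fixed float formatting, no index)."""
    df.to_csv(path, sep="\t", index=False, float_format="%.10g", lineterminator="\n")
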