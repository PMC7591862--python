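"""In-memory containers for BOLD series, segmentations and parcellations."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grid import GridSpace, VoxelMask

__all__ = [
    "NETWORKS",
    "SEGMENTATION_CLASSES",
    "TUMOUR_CLASSES",
    "TimeSeriesImage",
    "SegmentationVolume",
    "NetworkParcellation",
]

#: The seven canonical supratentorial resting-state networks.
NETWORKS = ("VIS", "SM", "DAN", "VAN", "LIMB", "CON", "DMN")

#: Tissue label codes for tumour segmentations.
SEGMENTATION_CLASSES = {
    0: "background",
    1: "necrotic",
    2: "enhancing",
    3: "non-enhancing",
    4: "oedema",
    5: "resection",
}
#: Codes counted as tumour tissue (everything except background).
TUMOUR_CLASSES = (1, 2, 3, 4, 5)
#: Codes entering attribution and recurrence ("enhancing or necrotic").
ENHANCING_NECROTIC = (1, 2)


@dataclass
class TimeSeriesImage:
    """Masked voxel x time BOLD matrix on a common grid.

    ``data`` has one row per mask voxel, in the mask's stable ordering.
    """

    grid: GridSpace
    mask: VoxelMask
    data: np.ndarray  # (V, T)
    subject_id: str = ""
    session_label: str = "control"
    session_index: int = 0

    def __post_init__(self) -> None:
        self.grid.require_same(self.mask.grid, "time series mask")
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2 or self.data.shape[0] != self.mask.n_voxels:
            raise ValueError(
                f"data must be (V={self.mask.n_voxels}, T), got {self.data.shape}"
            )
        if self.data.shape[1] < 2:
            raise ValueError("time series needs T >= 2")
        if not np.isfinite(self.data).all():
            raise ValueError("non-finite values in time series")

    @property
    def n_voxels(self) -> int:
        return self.data.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[1]


@dataclass
class SegmentationVolume:
    """Per-voxel tumour tissue class labels (one class per voxel)."""

    grid: GridSpace
    labels: np.ndarray  # (nx, ny, nz) integer codes

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        if labels.shape != self.grid.shape:
            raise ValueError("segmentation shape does not match grid")
        unknown = set(np.unique(labels).tolist()) - set(SEGMENTATION_CLASSES)
        if unknown:
            raise ValueError(
                f"unknown segmentation label code(s) {sorted(unknown)}; "
                f"known codes are {sorted(SEGMENTATION_CLASSES)}"
            )
        self.labels = labels.astype(np.int16)

    def class_mask(self, codes) -> VoxelMask:
        return VoxelMask(self.grid, np.isin(self.labels, np.asarray(codes)))

    def tumour_mask(self) -> VoxelMask:
        """Union of all tumour tissue classes (incl. resection)."""
        return self.class_mask(TUMOUR_CLASSES)

    def enhancing_necrotic_mask(self) -> VoxelMask:
        return self.class_mask(ENHANCING_NECROTIC)

    @classmethod
    def empty(cls, grid: GridSpace) -> "SegmentationVolume":
        return cls(grid, np.zeros(grid.shape, dtype=np.int16))


# Hemisphere / compartment integer codes used in parcellation volumes.
HEMI_L, HEMI_R = 0, 1
CEREBRUM, CEREBELLUM = 0, 1
UNLABELLED = -1


@dataclass
class NetworkParcellation:
    """Voxel-wise network / hemisphere / compartment labels.

    ``network`` holds indices into :data:`NETWORKS` (-1 = none); hemisphere
    is 0=L, 1=R; compartment is 0=cerebrum, 1=cerebellum.  Every labelled
    voxel must carry a hemisphere and a compartment.
    """

    grid: GridSpace
    network: np.ndarray
    hemisphere: np.ndarray
    compartment: np.ndarray

    def __post_init__(self) -> None:
        for name in ("network", "hemisphere", "compartment"):
            arr = np.asarray(getattr(self, name))
            if arr.shape != self.grid.shape:
                raise ValueError(f"{name} shape does not match grid")
            setattr(self, name, arr.astype(np.int16))
        if self.network.max(initial=-1) >= len(NETWORKS):
            raise ValueError("network id outside the seven-network set")
        labelled = self.network >= 0
        if np.any(labelled & (self.hemisphere < 0)) or np.any(
            labelled & (self.compartment < 0)
        ):
            raise ValueError("labelled voxel missing hemisphere or compartment")

    def labelled_mask(self) -> VoxelMask:
        return VoxelMask(self.grid, self.network >= 0)

    # Flat-ordered label vectors restricted to a mask's stable ordering.
    def network_of(self, mask: VoxelMask) -> np.ndarray:
        return self.network.ravel()[mask.indices]

    def hemisphere_of(self, mask: VoxelMask) -> np.ndarray:
        return self.hemisphere.ravel()[mask.indices]

    def compartment_of(self, mask: VoxelMask) -> np.ndarray:
        return self.compartment.ravel()[mask.indices]
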