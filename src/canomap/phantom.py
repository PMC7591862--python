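"""Phantom brains: mirrored seven-network parcellations with a crossed
cerebellum.

The phantom is a rectangular grid split into a cerebral slab and a smaller
cerebellar slab.  Networks are assigned to small voxel blocks (2x2x2 in the
cerebrum, 2x2x1 in the cerebellum) scattered at random over each left
hemisphere and mirrored exactly onto the right, so that

* every cerebral network has equal voxel counts left and right,
* the left-right mirror map is an involution, and
* each network is spatially distributed rather than a single compact patch
  — which is what separates functional proximity from spatial distance in
  the recovery experiments.

Cerebellar voxels carry the *crossed* representation: a left-cerebellar
voxel of network k shares the hemisphere-specific signal of the right
cerebral hemisphere, and vice versa.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grid import GridSpace, VoxelMask
from .images import (
    CEREBELLUM,
    CEREBRUM,
    HEMI_L,
    HEMI_R,
    NETWORKS,
    NetworkParcellation,
)

__all__ = ["PhantomSpec", "Phantom", "build_phantom", "demo_phantom", "small_phantom",
           "network_tumour", "spatial_tumour"]

_CEREBELLUM_DEPTH = 2  # z-slices of cerebellum at the bottom of the grid
_GAP = 1  # empty slice between cerebellum and cerebrum


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and per-network voxel budget of a phantom brain.

    ``cerebral_blocks_per_network`` 2x2x2 blocks (8 voxels) per network per
    hemisphere; ``cerebellar_blocks_per_network`` 2x2x1 blocks (4 voxels).
    """

    shape: tuple[int, int, int] = (16, 16, 16)
    spacing: tuple[float, float, float] = (3.0, 3.0, 3.0)
    cerebral_blocks_per_network: int = 20
    cerebellar_blocks_per_network: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s < 6 for s in self.shape):
            raise ValueError("phantom shape too small")
        if self.cerebral_blocks_per_network < 1 or self.cerebellar_blocks_per_network < 1:
            raise ValueError("need at least one block per network")


@dataclass
class Phantom:
    """A built phantom: grid, analysis mask, parcellation and mirror map."""

    spec: PhantomSpec
    grid: GridSpace
    mask: VoxelMask
    parcellation: NetworkParcellation
    mirror: np.ndarray  # full-grid flat index -> mirrored flat index
    # per-masked-voxel labels in the mask's stable ordering
    network: np.ndarray = field(init=False)
    hemisphere: np.ndarray = field(init=False)
    compartment: np.ndarray = field(init=False)
    functional_hemisphere: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.network = self.parcellation.network_of(self.mask)
        self.hemisphere = self.parcellation.hemisphere_of(self.mask)
        self.compartment = self.parcellation.compartment_of(self.mask)
        # cerebellum carries the contralateral cerebral hemisphere's signal
        f = self.hemisphere.copy()
        cb = self.compartment == CEREBELLUM
        f[cb] = 1 - f[cb]
        self.functional_hemisphere = f

    @property
    def n_voxels(self) -> int:
        return self.mask.n_voxels

    def mirror_of(self, flat: np.ndarray) -> np.ndarray:
        return self.mirror[np.asarray(flat)]


def _block_origins(x_range, y_range, z_range, block) -> list[tuple[int, int, int]]:
    bx, by, bz = block
    return [
        (x, y, z)
        for x in range(x_range[0], x_range[1] - bx + 1, bx)
        for y in range(y_range[0], y_range[1] - by + 1, by)
        for z in range(z_range[0], z_range[1] - bz + 1, bz)
    ]


def _block_voxels(origin, block) -> list[tuple[int, int, int]]:
    ox, oy, oz = origin
    bx, by, bz = block
    return [
        (ox + i, oy + j, oz + k)
        for i in range(bx)
        for j in range(by)
        for k in range(bz)
    ]


def build_phantom(spec: PhantomSpec) -> Phantom:
    """Deterministically build a phantom from its spec."""
    nx, ny, nz = spec.shape
    grid = GridSpace(spec.shape, spec.spacing)
    rng = np.random.default_rng(spec.seed)

    half_x = nx // 2
    regions = {
        # (x-range, y-range, z-range, block shape, blocks per network)
        CEREBRUM: ((0, half_x), (0, ny), (_CEREBELLUM_DEPTH + _GAP, nz), (2, 2, 2),
                   spec.cerebral_blocks_per_network),
        CEREBELLUM: ((0, half_x), (0, ny), (0, _CEREBELLUM_DEPTH), (2, 2, 1),
                     spec.cerebellar_blocks_per_network),
    }

    net = np.full(spec.shape, -1, dtype=np.int16)
    hemi = np.full(spec.shape, -1, dtype=np.int16)
    comp = np.full(spec.shape, -1, dtype=np.int16)

    for compartment, (xr, yr, zr, block, per_net) in regions.items():
        origins = _block_origins(xr, yr, zr, block)
        need = len(NETWORKS) * per_net
        if len(origins) < need:
            raise ValueError(
                f"phantom too small: {len(origins)} blocks available in "
                f"compartment {compartment}, {need} needed"
            )
        order = rng.permutation(len(origins))[:need]
        for rank, oi in enumerate(order):
            network_id = rank // per_net
            for (x, y, z) in _block_voxels(origins[oi], block):
                mx = nx - 1 - x
                net[x, y, z] = network_id
                hemi[x, y, z] = HEMI_L
                comp[x, y, z] = compartment
                net[mx, y, z] = network_id
                hemi[mx, y, z] = HEMI_R
                comp[mx, y, z] = compartment

    parc = NetworkParcellation(grid, net, hemi, comp)
    mask = parc.labelled_mask()
    ii, jj, kk = np.meshgrid(
        np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
    )
    mirror = np.ravel_multi_index(
        ((nx - 1 - ii).ravel(), jj.ravel(), kk.ravel()), spec.shape
    )
    return Phantom(spec, grid, mask, parc, mirror)


def demo_phantom(seed: int = 0) -> Phantom:
    """The default demo phantom, ~2,500 masked voxels at 3 mm spacing."""
    return build_phantom(PhantomSpec(seed=seed))


def small_phantom(seed: int = 0) -> Phantom:
    """A small phantom (~560 voxels) for cohort-scale experiments."""
    return build_phantom(
        PhantomSpec(
            shape=(10, 10, 10),
            cerebral_blocks_per_network=4,
            cerebellar_blocks_per_network=2,
            seed=seed,
        )
    )


def network_tumour(
    phantom: Phantom, network: int, n_blocks: int = 2, seed: int = 0
) -> VoxelMask:
    """A tumour covering blocks of a single network in the left cerebrum.

    Picks a random seed block of the network and its nearest same-network
    blocks (by centre distance), giving a mask confined to one network.
    """
    rng = np.random.default_rng(seed)
    sel = (
        (phantom.network == network)
        & (phantom.hemisphere == HEMI_L)
        & (phantom.compartment == CEREBRUM)
    )
    flat = phantom.mask.indices[sel]
    if flat.size == 0:
        raise ValueError(f"network {network} has no left-cerebral voxels")
    ijk = phantom.grid.flat_to_ijk(flat)
    # group into the assignment's 2x2x2 blocks (z-aligned to the cerebrum base)
    z0 = _CEREBELLUM_DEPTH + _GAP
    origin = (ijk - (0, 0, z0)) // 2 * 2 + (0, 0, z0)
    uniq, inv = np.unique(origin, axis=0, return_inverse=True)
    seed_block = rng.integers(len(uniq))
    d = np.linalg.norm(uniq - uniq[seed_block], axis=1)
    chosen = np.argsort(d, kind="stable")[: min(n_blocks, len(uniq))]
    keep = np.isin(inv, chosen)
    return VoxelMask.from_indices(phantom.grid, flat[keep])


def spatial_tumour(
    phantom: Phantom, centre_ijk, radius_mm: float
) -> VoxelMask:
    """A compact spherical tumour centred on a voxel, clipped to the mask."""
    centres = phantom.grid.voxel_centres_mm(phantom.mask.indices)
    c = phantom.grid.voxel_centres_mm(
        np.array([phantom.grid.ijk_to_flat(np.asarray(centre_ijk))])
    )[0]
    inside = np.linalg.norm(centres - c, axis=1) <= radius_mm
    if not inside.any():
        raise ValueError("spatial tumour contains no masked voxels")
    return VoxelMask.from_indices(phantom.grid, phantom.mask.indices[inside])
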