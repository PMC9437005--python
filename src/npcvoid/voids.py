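"""Voxel void analysis: which parts of the pore can accommodate a spherical probe.

For one mesh configuration the space is partitioned into cubic voxels of side
``l_c`` (6 Å for PMF work, 1 Å for connectivity).  ``R_max`` is the distance
from each voxel center to the nearest chain-bead *surface* (bead radius 3 Å)
or to the nearest voxel carrying a non-zero steric potential (envelope,
scaffold or confinement), whichever is closer; a voxel is accessible to a
probe of radius ``R_p`` iff ``R_max >= R_p``.  Reducing the boolean void map
over thin coaxial cylindrical slabs yields the 1D occupancy profile that
feeds the potential-of-mean-force estimate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import distance_transform_edt
from scipy.spatial import cKDTree

from .grids import GridSpec, ScalarGrid3D
from .mesh import BEAD_RADIUS, MeshConfiguration

__all__ = [
    "VoidGridSpec",
    "RmaxMap",
    "VoidMap",
    "OccupancyProfile",
    "EnsembleOccupancy",
    "compute_rmax",
    "classify_voids",
    "occupancy_profile",
    "ensemble_average_occupancy",
]

EXCLUSION_TOL = 1e-9  # any steric grid value above this marks a voxel excluded
EXCLUDED_SENTINEL = -1.0  # R_max stored for voxels inside an exclusion


@dataclass(frozen=True)
class VoidGridSpec:
    """Void-analysis lattice: cubic voxels plus the 1D-profile reduction geometry."""

    grid: GridSpec
    slab_height: float = 6.0
    profile_radius: float = 500.0

    def __post_init__(self):
        if self.slab_height <= 0 or self.profile_radius <= 0:
            raise ValueError("slab_height and profile_radius must be positive")

    @classmethod
    def from_bounds(cls, lo, hi, voxel_size=6.0, slab_height=None,
                    profile_radius=500.0) -> "VoidGridSpec":
        gs = GridSpec.from_bounds(lo, hi, voxel_size)
        return cls(gs, slab_height or voxel_size, profile_radius)

    @property
    def voxel_size(self) -> float:
        return float(self.grid.spacing[0])


@dataclass
class RmaxMap:
    """Per-voxel clearance radius; negative values mark voxels inside obstacles."""

    grid: ScalarGrid3D
    frame_id: int = 0
    bead_radius: float = BEAD_RADIUS

    @property
    def values(self) -> np.ndarray:
        return self.grid.values


@dataclass
class VoidMap:
    """Boolean accessibility lattice for one configuration and one probe radius."""

    accessible: np.ndarray
    probe_radius: float
    spec: VoidGridSpec
    frame_id: int = 0

    def fraction_accessible(self) -> float:
        return float(self.accessible.mean())


@dataclass
class OccupancyProfile:
    """Per-slab available-voxel statistics along the pore axis."""

    z_centers: np.ndarray
    h: np.ndarray          # available voxel count per slab
    n_total: np.ndarray    # cylinder voxels per slab
    l_c: float
    A_c: float             # confinement cross-section, A^2
    slab_height: float = None
    frame_id: int = 0

    def __post_init__(self):
        if self.slab_height is None:
            self.slab_height = self.l_c

    @property
    def P1(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.n_total > 0, self.h / self.n_total, np.nan)

    @property
    def A(self) -> np.ndarray:
        """Available cross-section area per slab, h * l_c^2 (A^2)."""
        return self.h * self.l_c**2


@dataclass
class EnsembleOccupancy:
    """Ensemble mean of occupancy profiles with its standard error."""

    z_centers: np.ndarray
    h_mean: np.ndarray
    h_sem: np.ndarray
    n_frames: int
    l_c: float
    A_c: float
    slab_height: float = None

    def __post_init__(self):
        if self.slab_height is None:
            self.slab_height = self.l_c

    @property
    def A_mean(self) -> np.ndarray:
        return self.h_mean * self.l_c**2


def compute_rmax(
    mesh: MeshConfiguration | None,
    exclusion_grids=(),
    spec: VoidGridSpec = None,
    bead_radius: float = BEAD_RADIUS,
) -> RmaxMap:
    """Clearance radius of every voxel center.

    The bead contribution is (distance to the nearest bead center) minus the
    bead radius, via a k-d tree over all chain beads.  The steric contribution
    is the center-to-center distance to the nearest voxel whose interpolated
    exclusion potential exceeds zero, via a Euclidean distance transform.
    Voxels that are themselves excluded carry the sentinel ``-1``; with no
    beads and no exclusions every voxel is ``+inf``.
    """
    if spec is None:
        raise ValueError("a VoidGridSpec is required")
    gs = spec.grid
    centers = gs.centers()
    d_bead = np.full(len(centers), np.inf)
    beads = mesh.all_beads() if mesh is not None else np.empty((0, 3))
    if len(beads):
        tree = cKDTree(beads)
        d, _ = tree.query(centers)
        d_bead = d - bead_radius
    excluded = np.zeros(gs.shape, dtype=bool)
    for g in exclusion_grids:
        vals = g.sample_nearest(centers, outside=0.0).reshape(gs.shape)
        excluded |= vals > EXCLUSION_TOL
    if excluded.any():
        d_excl = distance_transform_edt(~excluded, sampling=gs.spacing)
    else:
        d_excl = np.full(gs.shape, np.inf)
    r = np.minimum(d_bead.reshape(gs.shape), d_excl)
    r[excluded] = EXCLUDED_SENTINEL
    return RmaxMap(ScalarGrid3D(gs, r, "A"))


def classify_voids(rmax: RmaxMap, probe_radius: float,
                   spec: VoidGridSpec | None = None) -> VoidMap:
    """Threshold the clearance map: accessible iff R_max >= R_p.

    Monotone by construction: a larger probe's accessible set is a subset of
    a smaller probe's.
    """
    if probe_radius < 0:
        raise ValueError("probe radius must be non-negative")
    acc = rmax.values >= probe_radius
    if spec is None:
        spec = VoidGridSpec(rmax.grid.spec, float(rmax.grid.spacing[0]))
    return VoidMap(accessible=acc, probe_radius=float(probe_radius), spec=spec,
                   frame_id=rmax.frame_id)


def occupancy_profile(voidmap: VoidMap, spec: VoidGridSpec | None = None
                      ) -> OccupancyProfile:
    """Reduce a void map to per-slab available-voxel counts.

    Slabs are coaxial cylindrical segments of height ``slab_height`` and
    radius ``profile_radius``; a voxel belongs to a slab iff its *center*
    lies inside the cylinder.
    """
    spec = spec or voidmap.spec
    gs = spec.grid
    xc = gs.axis_centers(0)
    yc = gs.axis_centers(1)
    zc = gs.axis_centers(2)
    rho2 = (xc[:, None] ** 2 + yc[None, :] ** 2)
    in_cyl = rho2 <= spec.profile_radius**2
    if not in_cyl.any():
        raise ValueError("profile cylinder lies outside the grid")
    zmin = gs.origin[2]
    slab_idx = np.floor((zc - zmin) / spec.slab_height).astype(int)
    n_slabs = slab_idx.max() + 1
    n_xy = int(in_cyl.sum())
    acc_xy = voidmap.accessible[in_cyl, :]  # (n_xy, nz)
    h = np.zeros(n_slabs)
    n_total = np.zeros(n_slabs)
    counts_z = acc_xy.sum(axis=0)
    np.add.at(h, slab_idx, counts_z)
    np.add.at(n_total, slab_idx, n_xy)
    z_centers = zmin + (np.arange(n_slabs) + 0.5) * spec.slab_height
    return OccupancyProfile(
        z_centers=z_centers, h=h, n_total=n_total, l_c=spec.voxel_size,
        A_c=np.pi * spec.profile_radius**2, slab_height=spec.slab_height,
        frame_id=voidmap.frame_id,
    )


def ensemble_average_occupancy(profiles: list[OccupancyProfile]
                               ) -> EnsembleOccupancy:
    """Pointwise mean and standard error of the slab counts over frames."""
    if not profiles:
        raise ValueError("no profiles")
    z0 = profiles[0].z_centers
    for p in profiles[1:]:
        if len(p.z_centers) != len(z0) or not np.allclose(p.z_centers, z0):
            raise ValueError("profiles use heterogeneous z grids")
    H = np.stack([p.h for p in profiles])
    n = len(profiles)
    sem = H.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else np.zeros_like(z0)
    return EnsembleOccupancy(
        z_centers=z0, h_mean=H.mean(axis=0), h_sem=sem, n_frames=n,
        l_c=profiles[0].l_c, A_c=profiles[0].A_c,
        slab_height=profiles[0].slab_height,
    )
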