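"""Static geometry of the pore: scalar voxel grids, nuclear-envelope surface,
scaffold interaction potentials, and the cylindrical confinement restraint.

All lengths are in Å, all grid potentials in kcal/mol unless the grid's
``unit_tag`` says otherwise.  The pore axis is ``z`` and the coordinate origin
sits at the pore midplane center.  Voxel ``(i, j, k)`` is centered at
``origin + (i + 1/2, j + 1/2, k + 1/2) * spacing``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import fftconvolve
from scipy.spatial import cKDTree

__all__ = [
    "GridSpec",
    "ScalarGrid3D",
    "EnvelopeSpec",
    "PairPotentialTable",
    "ConfinementSpec",
    "envelope_radius",
    "envelope_surface_points",
    "build_envelope_grid",
    "build_scaffold_potential",
    "direct_scaffold_potential",
    "build_confinement_grid",
]


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a regular voxel grid: corner origin, per-axis spacing, shape."""

    origin: tuple[float, float, float]
    spacing: tuple[float, float, float]
    shape: tuple[int, int, int]

    def __post_init__(self):
        if any(s <= 0 for s in self.spacing):
            raise ValueError("grid spacing must be positive on all axes")
        if any(n <= 0 for n in self.shape):
            raise ValueError("grid shape must be positive on all axes")

    @classmethod
    def from_bounds(cls, lo, hi, spacing) -> "GridSpec":
        """Smallest grid with the given (possibly scalar) spacing covering [lo, hi]."""
        lo = np.asarray(lo, float)
        hi = np.asarray(hi, float)
        sp = np.broadcast_to(np.asarray(spacing, float), (3,))
        shape = np.maximum(1, np.ceil((hi - lo) / sp - 1e-9).astype(int))
        return cls(tuple(lo), tuple(sp), tuple(int(n) for n in shape))

    def axis_centers(self, axis: int) -> np.ndarray:
        n = self.shape[axis]
        return self.origin[axis] + (np.arange(n) + 0.5) * self.spacing[axis]

    def center_mesh(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return np.meshgrid(*(self.axis_centers(a) for a in range(3)), indexing="ij")

    def centers(self) -> np.ndarray:
        """All voxel centers as an (N, 3) array in C order."""
        X, Y, Z = self.center_mesh()
        return np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))


@dataclass
class ScalarGrid3D:
    """A regularly spaced scalar field with unit metadata.

    The universal spatial currency of the package: steric potentials,
    densities and per-voxel clearance radii all live on this container.
    """

    spec: GridSpec
    values: np.ndarray
    unit_tag: str = "kcal/mol"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != tuple(self.spec.shape):
            raise ValueError(
                f"values shape {self.values.shape} != grid shape {self.spec.shape}"
            )

    @classmethod
    def zeros(cls, spec: GridSpec, unit_tag: str = "kcal/mol") -> "ScalarGrid3D":
        return cls(spec, np.zeros(spec.shape), unit_tag)

    @property
    def origin(self):
        return np.asarray(self.spec.origin)

    @property
    def spacing(self):
        return np.asarray(self.spec.spacing)

    @property
    def shape(self):
        return tuple(self.spec.shape)

    def same_geometry(self, other: "ScalarGrid3D", tol: float = 1e-9) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.origin, other.origin, atol=tol)
            and np.allclose(self.spacing, other.spacing, atol=tol)
        )

    def sample_nearest(self, points: np.ndarray, outside: float = 0.0) -> np.ndarray:
        """Value of the nearest voxel for each (N, 3) point; ``outside`` beyond the box."""
        points = np.atleast_2d(np.asarray(points, float))
        idx = np.floor((points - self.origin) / self.spacing).astype(int)
        inside = np.all((idx >= 0) & (idx < np.array(self.shape)), axis=1)
        out = np.full(len(points), float(outside))
        ii = idx[inside]
        out[inside] = self.values[ii[:, 0], ii[:, 1], ii[:, 2]]
        return out


@dataclass(frozen=True)
class EnvelopeSpec:
    """Parametric nuclear-envelope surface.

    The envelope midsurface in the (r, z) half-plane is the ellipse
    ``(r - 0.6 B)^2 + 4 z^2 = B^2`` for ``|z| < flatten_z``; beyond
    ``flatten_z`` the ellipse is flattened by translating the radial center
    outward by ``(|z| - flatten_z)^2`` so the membrane does not curl up at the
    box corners.  The flattening term squares a length and adds it to a
    length, exactly as the surface is defined; see the methods note.
    """

    B: float = 300.0
    flatten_z: float = 97.2
    wall_height: float = 15.0
    wall_softness: float = 10.0

    def __post_init__(self):
        if self.B <= 0:
            raise ValueError("B must be positive")
        if self.flatten_z <= 0:
            raise ValueError("flatten_z must be positive")
        if self.wall_height < 0 or self.wall_softness <= 0:
            raise ValueError("wall_height >= 0 and wall_softness > 0 required")


def envelope_radius(z: float, spec: EnvelopeSpec, branch: str = "outer"):
    """Radial coordinate of the envelope surface at height ``z``.

    Returns the non-negative root of the surface equation for the requested
    branch (``outer``: pore-distal, ``inner``: pore-proximal), or ``None``
    when there is no surface at that height (``|z| > B/2``, or a negative
    inner root).
    """
    if branch not in ("outer", "inner"):
        raise ValueError("branch must be 'outer' or 'inner'")
    az = abs(float(z))
    disc = spec.B**2 - 4.0 * z * z
    if disc < 0:
        return None
    base = 0.6 * spec.B
    if az >= spec.flatten_z:
        base += (az - spec.flatten_z) ** 2
    r = base + np.sqrt(disc) if branch == "outer" else base - np.sqrt(disc)
    if r < 0:
        return None
    return float(r)


def envelope_surface_points(spec: EnvelopeSpec, n: int = 4096) -> np.ndarray:
    """Dense (r, z) samples of the full envelope cross-section curve.

    Parametrized as z = (B/2) sin t, r = base(|z|) + B cos t over t in
    [0, 2pi); points with r < 0 (the inner branch near the midplane, where
    the torus hole has closed) are dropped.
    """
    t = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    z = 0.5 * spec.B * np.sin(t)
    az = np.abs(z)
    base = 0.6 * spec.B + np.where(
        az >= spec.flatten_z, (az - spec.flatten_z) ** 2, 0.0
    )
    r = base + spec.B * np.cos(t)
    keep = r >= 0
    return np.column_stack([r[keep], z[keep]])


def build_envelope_grid(spec: EnvelopeSpec, grid_spec: GridSpec) -> ScalarGrid3D:
    """Purely repulsive membrane potential on a voxel grid.

    The potential is a linear ramp in the distance ``d`` from the envelope
    midsurface: ``wall_height * max(0, 1 - d / wall_softness)``, so it equals
    ``wall_height`` on the surface itself and vanishes one softness-width
    away.  Values therefore span exactly [0, wall_height].  Rotational
    symmetry about z is exact by construction.
    """
    curve = envelope_surface_points(spec)
    tree = cKDTree(curve)
    X, Y, Z = grid_spec.center_mesh()
    rho = np.hypot(X, Y)
    pts = np.column_stack([rho.ravel(), Z.ravel()])
    d, _ = tree.query(pts)
    v = spec.wall_height * np.clip(1.0 - d / spec.wall_softness, 0.0, 1.0)
    return ScalarGrid3D(grid_spec, v.reshape(grid_spec.shape), "kcal/mol")


@dataclass
class PairPotentialTable:
    """Radial bead-bead potentials K_XY(r) tabulated per ordered type pair.

    ``kernels`` maps a frozenset pair key (symmetric by construction) to a
    callable-free table: (r_grid, values).  The default table applies one
    soft-core repulsion to every pair; users may load custom tables.
    """

    r_grid: np.ndarray
    tables: dict = field(default_factory=dict)
    cutoff: float = 50.0

    @staticmethod
    def _key(x: str, y: str):
        return frozenset((x, y)) if x != y else frozenset((x,))

    @classmethod
    def soft_core(
        cls,
        type_ids=("X",),
        eps: float = 1.0,
        r0: float = 6.0,
        cutoff: float = 50.0,
        n: int = 512,
    ) -> "PairPotentialTable":
        """Single soft-core repulsion eps*(1 - r/r0)^2 for r < r0, for all pairs."""
        r = np.linspace(0.0, cutoff, n)
        v = np.where(r < r0, eps * (1.0 - r / r0) ** 2, 0.0)
        tab = cls(r_grid=r, cutoff=cutoff)
        for x in type_ids:
            for y in type_ids:
                tab.tables[cls._key(x, y)] = v
        return tab

    @classmethod
    def step(
        cls, type_ids=("X",), height: float = 1.0, r0: float = 6.0, cutoff: float = 50.0
    ) -> "PairPotentialTable":
        """Hard tabulated step: ``height`` inside r0, zero outside (test kernel)."""
        r = np.linspace(0.0, cutoff, 2048)
        v = np.where(r < r0, height, 0.0)
        tab = cls(r_grid=r, cutoff=cutoff)
        for x in type_ids:
            for y in type_ids:
                tab.tables[cls._key(x, y)] = v
        return tab

    def evaluate(self, x: str, y: str, r: np.ndarray) -> np.ndarray:
        key = self._key(x, y)
        if key not in self.tables:
            raise KeyError(f"no kernel for pair ({x}, {y})")
        r = np.asarray(r, float)
        v = np.interp(r, self.r_grid, self.tables[key], right=0.0)
        return np.where(r > self.cutoff, 0.0, v)

    def has_pair(self, x: str, y: str) -> bool:
        return self._key(x, y) in self.tables


def _bin_counts(points: np.ndarray, grid_spec: GridSpec) -> np.ndarray:
    idx = np.floor((points - np.asarray(grid_spec.origin)) / np.asarray(grid_spec.spacing))
    idx = idx.astype(int)
    shape = np.array(grid_spec.shape)
    inside = np.all((idx >= 0) & (idx < shape), axis=1)
    counts = np.zeros(grid_spec.shape)
    np.add.at(counts, tuple(idx[inside].T), 1.0)
    return counts


def _kernel_lattice(
    kernels: PairPotentialTable, x: str, y: str, spacing
) -> np.ndarray:
    """K_XY sampled on an odd, centered voxel-offset lattice out to the cutoff."""
    sp = np.asarray(spacing, float)
    m = np.ceil(kernels.cutoff / sp).astype(int)
    axes = [np.arange(-mi, mi + 1) * si for mi, si in zip(m, sp)]
    DX, DY, DZ = np.meshgrid(*axes, indexing="ij")
    r = np.sqrt(DX**2 + DY**2 + DZ**2)
    return kernels.evaluate(x, y, r)


def build_scaffold_potential(
    bead_positions: np.ndarray,
    bead_types,
    residue_type: str,
    kernels: PairPotentialTable,
    grid_spec: GridSpec,
) -> ScalarGrid3D:
    """Scaffold interaction grid for probe residue type X.

    ``V_X = sum_Y K_XY * rho_Y`` where ``rho_Y`` is the voxel-binned number
    density of scaffold beads of type Y (each bead contributes a unit count to
    the voxel containing it) and ``*`` is evaluated by FFT convolution.  The
    direct-summation route :func:`direct_scaffold_potential` uses the same
    voxel-resolved density and agrees to float precision.
    """
    bead_positions = np.asarray(bead_positions, float).reshape(-1, 3)
    bead_types = list(bead_types)
    if len(bead_types) != len(bead_positions):
        raise ValueError("one type label per bead required")
    out = np.zeros(grid_spec.shape)
    for y in sorted(set(bead_types)):
        if not kernels.has_pair(residue_type, y):
            raise KeyError(f"no kernel for pair ({residue_type}, {y})")
        pts = bead_positions[[t == y for t in bead_types]]
        counts = _bin_counts(pts, grid_spec)
        if not counts.any():
            continue
        kern = _kernel_lattice(kernels, residue_type, y, grid_spec.spacing)
        out += fftconvolve(counts, kern, mode="same")
    return ScalarGrid3D(grid_spec, out, "kcal/mol")


def direct_scaffold_potential(
    bead_positions: np.ndarray,
    bead_types,
    residue_type: str,
    kernels: PairPotentialTable,
    grid_spec: GridSpec,
) -> ScalarGrid3D:
    """O(voxels x beads) evaluation of the scaffold potential (oracle route)."""
    bead_positions = np.asarray(bead_positions, float).reshape(-1, 3)
    origin = np.asarray(grid_spec.origin)
    spacing = np.asarray(grid_spec.spacing)
    snapped = (np.floor((bead_positions - origin) / spacing) + 0.5) * spacing + origin
    shape = np.array(grid_spec.shape)
    idx = np.floor((bead_positions - origin) / spacing).astype(int)
    inside = np.all((idx >= 0) & (idx < shape), axis=1)
    centers = grid_spec.centers()
    out = np.zeros(len(centers))
    for pos, typ, ok in zip(snapped, bead_types, inside):
        if not kernels.has_pair(residue_type, typ):
            raise KeyError(f"no kernel for pair ({residue_type}, {typ})")
        if not ok:
            continue
        r = np.linalg.norm(centers - pos, axis=1)
        out += kernels.evaluate(residue_type, typ, r)
    return ScalarGrid3D(grid_spec, out.reshape(grid_spec.shape), "kcal/mol")


@dataclass(frozen=True)
class ConfinementSpec:
    """Cylindrical harmonic confinement of a diffusing probe's center of mass."""

    radius: float = 500.0
    height: float = 1200.0
    spring_k: float = 0.01  # kcal mol^-1 A^-2

    def __post_init__(self):
        if self.radius <= 0 or self.height <= 0 or self.spring_k <= 0:
            raise ValueError("radius, height and spring_k must be positive")

    @property
    def cross_section(self) -> float:
        """Cross-section area of the confinement cylinder, pi R^2 (A^2)."""
        return float(np.pi * self.radius**2)

    def energy(self, points: np.ndarray) -> np.ndarray:
        """Harmonic overshoot energy: 0 inside the cylinder, 1/2 k d^2 outside."""
        points = np.atleast_2d(np.asarray(points, float))
        rho = np.hypot(points[:, 0], points[:, 1])
        dr = np.maximum(0.0, rho - self.radius)
        dz = np.maximum(0.0, np.abs(points[:, 2]) - 0.5 * self.height)
        return 0.5 * self.spring_k * (dr**2 + dz**2)


def build_confinement_grid(spec: ConfinementSpec, grid_spec: GridSpec) -> ScalarGrid3D:
    """Confinement potential evaluated at every voxel center."""
    v = spec.energy(grid_spec.centers())
    return ScalarGrid3D(grid_spec, v.reshape(grid_spec.shape), "kcal/mol")
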