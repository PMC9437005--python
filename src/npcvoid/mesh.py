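"""Synthetic ensembles of anchored, disordered FG-nucleoporin chains.

The disordered mesh inside the nuclear pore is represented one bead per
amino-acid residue (bead radius 3 Å, mass 120 Da, bond length 3.8 Å).  Chains
are grown as self-avoiding random walks from their anchor points, subject to
an interchain clash distance of 8 Å and to the steric grids of the envelope,
scaffold and confinement.  Frames of an ensemble are independent draws: the
downstream void / PMF / first-passage machinery is agnostic to how the
equilibrium ensemble was produced, and independent self-avoiding draws give a
valid, reproducible test ensemble without any force-field dynamics.

Built-in stoichiometries mirror three published pore compositions
(``lin2016``, ``kim2018``, ``kim2018plus``); anchor coordinates use a
deterministic synthetic ring layout (the experimentally derived scaffold
coordinates are not shipped).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import yaml
from scipy.spatial import cKDTree

from .grids import GridSpec, ScalarGrid3D

__all__ = [
    "BOND_LENGTH",
    "BEAD_RADIUS",
    "BEAD_MASS",
    "CLASH_DISTANCE",
    "Species",
    "StoichiometrySpec",
    "BeadChain",
    "MeshConfiguration",
    "PlacementError",
    "load_stoichiometry",
    "generate_chain",
    "generate_linker_chain",
    "build_mesh_ensemble",
    "interchain_contact_fraction",
    "apply_symmetry",
    "density_map",
    "charge_hydrophobicity_ratio",
    "chain_and_residue_totals",
    "toy_stoichiometry",
]

BOND_LENGTH = 3.8  # A between consecutive beads
BEAD_RADIUS = 3.0  # A, one residue
BEAD_MASS = 120.0  # Da per residue bead
CLASH_DISTANCE = 8.0  # A, interchain / chain-scaffold exclusion
DA_PER_A3_TO_MG_PER_ML = 1660.53907  # 1 Da/A^3 in mg/mL

# Kyte-Doolittle hydropathy, rescaled to [0, 1] when used.
_KD = {
    "I": 4.5, "V": 4.2, "L": 3.8, "F": 2.8, "C": 2.5, "M": 1.9, "A": 1.8,
    "G": -0.4, "T": -0.7, "S": -0.8, "W": -0.9, "Y": -1.3, "P": -1.6,
    "H": -3.2, "E": -3.5, "Q": -3.5, "D": -3.5, "N": -3.5, "K": -3.9,
    "R": -4.5,
}
_CHARGE = {"K": 1.0, "R": 1.0, "H": 0.5, "D": -1.0, "E": -1.0}


class PlacementError(RuntimeError):
    """Self-avoiding growth stalled; carries the failing residue index."""

    def __init__(self, residue_index: int, message: str = ""):
        self.residue_index = residue_index
        super().__init__(
            message or f"chain growth stalled at residue {residue_index}"
        )


@dataclass(frozen=True)
class Species:
    """One chain species: copy number, residue range and anchoring mode.

    ``residue_range`` is an inclusive 1-based interval; a reversed interval is
    allowed (C-terminally numbered constructs) and contributes the same number
    of residues.  ``anchor_end`` is 'N', 'C', or 'linker' (both termini
    restrained).
    """

    name: str
    copies: int
    residue_range: tuple[int, int]
    anchor_end: str = "C"
    sequence: str | None = None

    def __post_init__(self):
        if self.copies <= 0:
            raise ValueError(f"{self.name}: copy number must be positive")
        if self.anchor_end not in ("N", "C", "linker"):
            raise ValueError(f"{self.name}: bad anchor_end {self.anchor_end!r}")
        if self.sequence is not None and len(self.sequence) < self.length:
            raise ValueError(f"{self.name}: sequence shorter than residue range")

    @property
    def length(self) -> int:
        a, b = self.residue_range
        return abs(b - a) + 1


@dataclass
class StoichiometrySpec:
    """Full mesh composition: species list plus per-copy anchor coordinates."""

    name: str
    species: list[Species]
    anchors: dict[str, np.ndarray] = field(default_factory=dict)
    # linker species need a second anchor per copy
    anchors_end: dict[str, np.ndarray] = field(default_factory=dict)

    def validate(self):
        for sp in self.species:
            if sp.name in self.anchors:
                if len(self.anchors[sp.name]) != sp.copies:
                    raise ValueError(
                        f"{sp.name}: {len(self.anchors[sp.name])} anchors for "
                        f"{sp.copies} copies"
                    )
                if sp.anchor_end == "linker" and sp.name not in self.anchors_end:
                    raise ValueError(f"{sp.name}: linker species needs end anchors")
        return self

    def without(self, species_name: str) -> "StoichiometrySpec":
        """Deletion variant: the composition minus one species."""
        if species_name not in [s.name for s in self.species]:
            raise KeyError(species_name)
        return StoichiometrySpec(
            name=f"{self.name}-d{species_name}",
            species=[s for s in self.species if s.name != species_name],
            anchors={k: v for k, v in self.anchors.items() if k != species_name},
            anchors_end={
                k: v for k, v in self.anchors_end.items() if k != species_name
            },
        )


@dataclass
class BeadChain:
    """One disordered chain: ordered bead coordinates plus labels."""

    species: str
    positions: np.ndarray  # (n, 3) A
    anchor_index: int = 0
    bead_radius: float = BEAD_RADIUS
    residue_types: list | None = None

    def __post_init__(self):
        self.positions = np.asarray(self.positions, float).reshape(-1, 3)

    def __len__(self):
        return len(self.positions)

    def bond_lengths(self) -> np.ndarray:
        return np.linalg.norm(np.diff(self.positions, axis=0), axis=1)

    def radius_of_gyration(self) -> float:
        c = self.positions - self.positions.mean(axis=0)
        return float(np.sqrt((c**2).sum(axis=1).mean()))


@dataclass
class MeshConfiguration:
    """One instantaneous mesh: the unit of the configurational ensemble."""

    chains: list[BeadChain]
    frame_id: int = 0
    box: tuple[float, float, float] | None = None

    def all_beads(self) -> np.ndarray:
        if not self.chains:
            return np.empty((0, 3))
        return np.concatenate([c.positions for c in self.chains])

    def chain_ids(self) -> np.ndarray:
        if not self.chains:
            return np.empty(0, dtype=int)
        return np.repeat(np.arange(len(self.chains)), [len(c) for c in self.chains])

    @property
    def n_beads(self) -> int:
        return sum(len(c) for c in self.chains)


# ---------------------------------------------------------------------------
# built-in stoichiometries

def _ring_anchors(copies, radius, z_values, phase=0.0):
    """Deterministic 8-fold-symmetric ring layout (synthetic geometry)."""
    per_ring = max(1, copies // len(z_values))
    out = []
    k = 0
    for zi, z in enumerate(z_values):
        n = per_ring if zi < len(z_values) - 1 else copies - k
        for j in range(n):
            th = 2 * np.pi * j / max(n, 1) + phase + 0.15 * zi
            out.append([radius * np.cos(th), radius * np.sin(th), z])
            k += 1
    return np.asarray(out[:copies])


def _builtin_lin2016() -> StoichiometrySpec:
    # composite 8-fold symmetric pore: 32 copies each of five species
    species = [
        Species("Nup145N", 32, (1, 732), "C"),
        Species("Nic96", 32, (1, 139), "C"),
        Species("Nsp1", 32, (1, 467), "C"),
        Species("Nup49", 32, (1, 245), "C"),
        Species("Nup57", 32, (1, 77), "C"),
    ]
    spec = StoichiometrySpec("lin2016", species)
    z_inner = [-60.0, -20.0, 20.0, 60.0]
    z_outer = [-250.0, -160.0, 160.0, 250.0]
    for i, sp in enumerate(species):
        zs = z_outer if sp.name == "Nup145N" else z_inner
        spec.anchors[sp.name] = _ring_anchors(sp.copies, 220.0, zs, phase=0.3 * i)
    return spec.validate()


_KIM2018_SPECIES = [
    ("Nsp1", 48, (1, 620)),
    ("Nup159", 16, (1, 760)),
    ("Nup116", 16, (1, 760)),
    ("Nup100", 16, (1, 560)),
    ("Nup49", 32, (1, 220)),
    ("Nup57", 32, (1, 220)),
    ("Nup145N", 16, (1, 220)),
    ("Nup1", 8, (1, 720)),
    ("Nup60", 16, (1, 120)),
]


def _builtin_kim2018() -> StoichiometrySpec:
    species = [Species(n, c, r, "C") for n, c, r in _KIM2018_SPECIES]
    spec = StoichiometrySpec("kim2018", species)
    for i, sp in enumerate(species):
        side = -1.0 if sp.name in ("Nup1", "Nup60") else 1.0
        zs = [side * 40.0, side * 120.0] if sp.copies > 8 else [side * 120.0]
        spec.anchors[sp.name] = _ring_anchors(sp.copies, 220.0, zs, phase=0.25 * i)
    return spec.validate()


def _builtin_kim2018plus() -> StoichiometrySpec:
    """kim2018 plus Nup42/Nup2 and the flexible linker 'connector' domains.

    Nup1 keeps its 8 copies from kim2018 (only explicit differences are
    applied).  Nup1/Nup60 switch to N-terminal anchoring with reversed
    residue numbering; Nup159 starts at residue 382.
    """
    species = [
        Species("Nsp1", 48, (1, 620), "C"),
        Species("Nup159", 16, (382, 1141), "C"),
        Species("Nup116", 16, (1, 760), "C"),
        Species("Nup100", 16, (1, 560), "C"),
        Species("Nup49", 32, (1, 220), "C"),
        Species("Nup57", 32, (1, 220), "C"),
        Species("Nup145N", 16, (1, 220), "C"),
        Species("Nup1", 8, (1076, 357), "N"),
        Species("Nup60", 16, (539, 420), "N"),
        Species("Nup42", 8, (1, 382), "C"),
        Species("Nup2", 16, (1, 720), "C"),
        Species("Nup116-linker", 16, (561, 815), "linker"),
        Species("Nup100-linker", 16, (761, 965), "linker"),
        Species("Nup145N-linker", 16, (221, 458), "linker"),
    ]
    spec = StoichiometrySpec("kim2018plus", species)
    for i, sp in enumerate(species):
        side = -1.0 if sp.name in ("Nup1", "Nup60", "Nup2") else 1.0
        zs = [side * 40.0, side * 120.0] if sp.copies > 8 else [side * 120.0]
        spec.anchors[sp.name] = _ring_anchors(sp.copies, 220.0, zs, phase=0.2 * i)
        if sp.anchor_end == "linker":
            # second restraint one ring step away
            end = _ring_anchors(sp.copies, 220.0, zs, phase=0.2 * i + 0.35)
            spec.anchors_end[sp.name] = end
    return spec.validate()


_BUILTINS = {
    "lin2016": _builtin_lin2016,
    "kim2018": _builtin_kim2018,
    "kim2018plus": _builtin_kim2018plus,
}


def load_stoichiometry(name_or_path: str) -> StoichiometrySpec:
    """A built-in composition (lin2016 / kim2018 / kim2018plus) or a YAML/JSON file."""
    if name_or_path in _BUILTINS:
        return _BUILTINS[name_or_path]()
    try:
        with open(name_or_path) as fh:
            data = yaml.safe_load(fh)
    except FileNotFoundError:
        raise ValueError(f"unknown stoichiometry {name_or_path!r}") from None
    if not isinstance(data, dict) or "species" not in data:
        raise ValueError(f"malformed stoichiometry file {name_or_path!r}")
    species = [
        Species(
            s["name"],
            int(s["copies"]),
            tuple(s["residue_range"]),
            s.get("anchor_end", "C"),
            s.get("sequence"),
        )
        for s in data["species"]
    ]
    spec = StoichiometrySpec(data.get("name", name_or_path), species)
    for key, store in (("anchors", spec.anchors), ("anchors_end", spec.anchors_end)):
        for nm, arr in (data.get(key) or {}).items():
            store[nm] = np.asarray(arr, float).reshape(-1, 3)
    for sp in species:
        if sp.name not in spec.anchors:
            spec.anchors[sp.name] = _ring_anchors(sp.copies, 220.0, [40.0, 120.0])
            if sp.anchor_end == "linker":
                spec.anchors_end[sp.name] = _ring_anchors(
                    sp.copies, 220.0, [40.0, 120.0], phase=0.35
                )
    return spec.validate()


def chain_and_residue_totals(spec: StoichiometrySpec) -> tuple[int, int]:
    """(number of chains, number of residues) implied by a composition."""
    n_chains = sum(s.copies for s in spec.species)
    n_res = sum(s.copies * s.length for s in spec.species)
    return n_chains, n_res


def toy_stoichiometry(
    n_chains: int = 8,
    length: int = 40,
    radius: float = 45.0,
    z: float = 0.0,
    name: str = "toy",
) -> StoichiometrySpec:
    """Small single-species fixture: chains anchored on one ring."""
    sp = Species("toy", n_chains, (1, length), "C")
    spec = StoichiometrySpec(name, [sp])
    th = 2 * np.pi * np.arange(n_chains) / n_chains
    spec.anchors["toy"] = np.column_stack(
        [radius * np.cos(th), radius * np.sin(th), np.full(n_chains, z)]
    )
    return spec.validate()


# ---------------------------------------------------------------------------
# chain generation

def _random_unit_vectors(rng, n):
    v = rng.normal(size=(n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def _ok_position(pos, chain_so_far, i, obstacle_tree, steric_grids, scaffold_skip,
                 bead_radius):
    # intrachain excluded volume: non-bonded beads at >= 2*bead_radius
    if i >= 2:
        prior = chain_so_far[: i - 1]
        if np.min(np.linalg.norm(prior - pos, axis=1)) < 2 * bead_radius:
            return False
    if obstacle_tree is not None:
        if obstacle_tree.query_ball_point(pos, CLASH_DISTANCE, return_length=True):
            return False
    if i >= scaffold_skip:
        for g in steric_grids:
            # a steric constraint is a voxel grid or an analytic potential
            val = (g.sample_nearest(pos[None, :])[0]
                   if hasattr(g, "sample_nearest") else g(pos[None, :])[0])
            if val > 1e-9:
                return False
    return True


def generate_chain(
    anchor,
    length: int,
    obstacles: np.ndarray | None = None,
    steric_grids=(),
    rng=None,
    rng_seed: int | None = None,
    species: str = "chain",
    scaffold_skip: int = 3,
    bead_radius: float = BEAD_RADIUS,
    max_attempts: int = 40,
    max_backtracks: int = 2000,
) -> BeadChain:
    """Grow one anchored self-avoiding chain.

    Constraints, enforced at every bead: bond length exactly 3.8 Å;
    no bead within 8 Å of a bead of another chain (``obstacles``);
    no bead at least ``scaffold_skip`` residues from the anchor inside a
    non-zero steric grid; non-bonded intrachain beads at least two bead radii
    apart.  Growth backtracks on dead ends and raises
    :class:`PlacementError` with the failing residue index if it stalls.
    """
    if rng is None:
        rng = np.random.default_rng(rng_seed)
    anchor = np.asarray(anchor, float)
    tree = None
    if obstacles is not None and len(obstacles):
        tree = cKDTree(np.asarray(obstacles, float).reshape(-1, 3))
    pos = np.empty((length, 3))
    pos[0] = anchor
    i, backtracks = 1, 0
    while i < length:
        placed = False
        for v in _random_unit_vectors(rng, max_attempts):
            cand = pos[i - 1] + BOND_LENGTH * v
            if _ok_position(cand, pos, i, tree, steric_grids, scaffold_skip,
                            bead_radius):
                pos[i] = cand
                i += 1
                placed = True
                break
        if not placed:
            backtracks += 1
            if backtracks > max_backtracks:
                raise PlacementError(i)
            i = max(1, i - 1 - int(rng.integers(0, 3)))
    return BeadChain(species=species, positions=pos, anchor_index=0,
                     bead_radius=bead_radius)


def generate_linker_chain(
    anchor,
    anchor_end,
    length: int,
    obstacles: np.ndarray | None = None,
    steric_grids=(),
    rng=None,
    rng_seed: int | None = None,
    species: str = "linker",
    scaffold_skip: int = 3,
    bead_radius: float = BEAD_RADIUS,
    max_attempts: int = 60,
    max_backtracks: int = 4000,
) -> BeadChain:
    """Self-avoiding walk conditioned on both endpoint positions.

    Growth is biased by rejection: a candidate bead is feasible only if the
    target remains reachable with the remaining bonds; the final two beads
    are placed by exact sphere-sphere intersection so that every bond is
    exactly 3.8 Å and the last bead sits on the end anchor.
    """
    if rng is None:
        rng = np.random.default_rng(rng_seed)
    anchor = np.asarray(anchor, float)
    target = np.asarray(anchor_end, float)
    if length < 2:
        raise ValueError("a linker needs at least two beads")
    span = np.linalg.norm(target - anchor)
    if span > (length - 1) * BOND_LENGTH:
        raise PlacementError(0, "end anchors farther apart than the contour length")
    tree = None
    if obstacles is not None and len(obstacles):
        tree = cKDTree(np.asarray(obstacles, float).reshape(-1, 3))
    pos = np.empty((length, 3))
    pos[0] = anchor
    pos[length - 1] = target
    i, backtracks = 1, 0
    while i < length - 1:
        remaining = (length - 1 - i) * BOND_LENGTH
        placed = False
        for v in _random_unit_vectors(rng, max_attempts):
            if i == length - 2:
                # exact closure: bead at bond length from both neighbours
                cand = _close_triangle(pos[i - 1], target, rng)
                if cand is None:
                    break
            else:
                cand = pos[i - 1] + BOND_LENGTH * v
                if np.linalg.norm(target - cand) > remaining:
                    continue
            if _ok_position(cand, pos, i, tree, steric_grids, scaffold_skip,
                            bead_radius):
                pos[i] = cand
                i += 1
                placed = True
                break
        if not placed:
            backtracks += 1
            if backtracks > max_backtracks:
                raise PlacementError(i)
            i = max(1, i - 1 - int(rng.integers(0, 3)))
    return BeadChain(species=species, positions=pos, anchor_index=0,
                     bead_radius=bead_radius)


def _close_triangle(p, target, rng):
    """Point at BOND_LENGTH from both p and target, uniform on the circle."""
    d = target - p
    dist = np.linalg.norm(d)
    if dist > 2 * BOND_LENGTH or dist < 1e-12:
        return None
    mid = 0.5 * (p + target)
    h2 = BOND_LENGTH**2 - (0.5 * dist) ** 2
    if h2 < 0:
        return None
    n = d / dist
    # orthonormal basis of the plane normal to n
    a = np.array([1.0, 0.0, 0.0])
    if abs(n[0]) > 0.9:
        a = np.array([0.0, 1.0, 0.0])
    u = np.cross(n, a)
    u /= np.linalg.norm(u)
    w = np.cross(n, u)
    th = rng.uniform(0, 2 * np.pi)
    return mid + np.sqrt(h2) * (np.cos(th) * u + np.sin(th) * w)


def _chain_seed(master_seed: int, frame: int, species: str, copy: int,
                attempt: int = 0):
    """Stable per-chain seed stream: independent of the other species present."""
    tag = zlib.crc32(species.encode()) & 0x7FFFFFFF
    return np.random.SeedSequence(
        entropy=int(master_seed) & 0x7FFFFFFF, spawn_key=(frame, tag, copy, attempt)
    )


def build_mesh_ensemble(
    spec: StoichiometrySpec,
    steric_grids=(),
    n_frames: int = 1,
    rng_seed: int = 0,
    relax_steps: int = 0,
    relax_amplitude: float = 1.5,
) -> list[MeshConfiguration]:
    """Independent mesh configurations drawn from the self-avoiding generator.

    Each frame regenerates every chain from its own deterministic seed stream
    (keyed by frame, species and copy index, not by position in the species
    list, so deletion variants reuse identical streams).  ``relax_steps``
    optional single-bead Monte-Carlo moves with anchored termini perturb each
    chain after growth, rejecting moves that break any constraint.
    """
    spec.validate()
    # later chains must be able to start: every chain's anchor site is kept
    # clear during the growth of the others
    anchor_rows = []
    offsets = {}
    for sp in spec.species:
        offsets[sp.name] = len(anchor_rows)
        anchor_rows.extend(np.asarray(spec.anchors[sp.name]))
        if sp.name in spec.anchors_end:
            anchor_rows.extend(np.asarray(spec.anchors_end[sp.name]))
    all_anchors = np.asarray(anchor_rows).reshape(-1, 3)
    frames = []
    for f in range(n_frames):
        chains: list[BeadChain] = []
        obstacles: list[np.ndarray] = []
        for sp in spec.species:
            anchors = spec.anchors[sp.name]
            ends = spec.anchors_end.get(sp.name)
            for c in range(sp.copies):
                own = [anchors[c]] + ([ends[c]] if ends is not None else [])
                keep = np.ones(len(all_anchors), dtype=bool)
                for a in own:
                    keep &= np.linalg.norm(all_anchors - a, axis=1) > 1e-9
                other_anchors = all_anchors[keep]
                grown = np.concatenate(obstacles) if obstacles else None
                last_err = None
                for attempt in range(5):  # deterministic retry stream
                    rng = np.random.default_rng(
                        _chain_seed(rng_seed, f, sp.name, c, attempt))
                    obs = (other_anchors if grown is None
                           else np.vstack([grown, other_anchors]))
                    try:
                        if sp.anchor_end == "linker":
                            ch = generate_linker_chain(
                                anchors[c], ends[c], sp.length, obs,
                                steric_grids, rng, species=sp.name,
                            )
                        else:
                            ch = generate_chain(
                                anchors[c], sp.length, obs, steric_grids, rng,
                                species=sp.name,
                            )
                        break
                    except PlacementError as e:
                        last_err = e
                else:
                    raise last_err
                if relax_steps:
                    _mc_relax(ch, obs, steric_grids, rng, relax_steps,
                              relax_amplitude)
                chains.append(ch)
                obstacles.append(ch.positions)
        frames.append(MeshConfiguration(chains=chains, frame_id=f))
    return frames


def _mc_relax(chain: BeadChain, obstacles, steric_grids, rng, steps, amplitude):
    """Crude excluded-volume Monte-Carlo: random single-bead displacements that
    preserve both adjacent bond lengths (crankshaft for interior beads, sphere
    resampling for the free terminus); the anchored bead never moves."""
    tree = cKDTree(obstacles) if obstacles is not None and len(obstacles) else None
    n = len(chain)
    pos = chain.positions
    for _ in range(steps):
        i = int(rng.integers(1, n))
        old = pos[i].copy()
        if i == n - 1:
            v = rng.normal(size=3)
            v /= np.linalg.norm(v)
            pos[i] = pos[i - 1] + BOND_LENGTH * v
        else:
            axis = pos[i + 1] - pos[i - 1]
            norm = np.linalg.norm(axis)
            if norm < 1e-9:
                continue
            pos[i] = _rotate_about_axis(
                pos[i], pos[i - 1], axis / norm,
                rng.uniform(-amplitude, amplitude),
            )
        if not _ok_position(pos[i], pos, i, tree, steric_grids, 3,
                            chain.bead_radius) or (
            i + 1 < n
            and abs(np.linalg.norm(pos[i + 1] - pos[i]) - BOND_LENGTH) > 1e-6
        ):
            pos[i] = old


def _rotate_about_axis(point, origin, axis, angle):
    p = point - origin
    c, s = np.cos(angle), np.sin(angle)
    return origin + p * c + np.cross(axis, p) * s + axis * np.dot(axis, p) * (1 - c)


# ---------------------------------------------------------------------------
# mesh statistics

def interchain_contact_fraction(
    mesh: MeshConfiguration, cutoff: float = CLASH_DISTANCE
) -> tuple[dict[str, float], float]:
    """Fraction of chains with at least one interchain contact.

    A contact is two residues from different chains within ``cutoff``
    (default 8 Å) of one another.  Returns (per-species fractions, overall
    fraction).
    """
    if len(mesh.chains) < 2:
        raise ValueError("need at least two chains")
    beads = mesh.all_beads()
    cid = mesh.chain_ids()
    tree = cKDTree(beads)
    pairs = tree.query_pairs(cutoff, output_type="ndarray")
    contacted = np.zeros(len(mesh.chains), dtype=bool)
    if len(pairs):
        inter = cid[pairs[:, 0]] != cid[pairs[:, 1]]
        contacted[np.unique(cid[pairs[inter].ravel()])] = True
    per_species: dict[str, list] = {}
    for ch, hit in zip(mesh.chains, contacted):
        per_species.setdefault(ch.species, []).append(hit)
    frac = {k: float(np.mean(v)) for k, v in per_species.items()}
    return frac, float(contacted.mean())


def apply_symmetry(mesh: MeshConfiguration, symmetry: str) -> MeshConfiguration:
    """Replicate every chain through the pore's point-group operations.

    ``c8``: 8-fold rotation about z.  ``c8+mirror``: additionally the
    two-fold reflection through the midplane.  Applying the operation to an
    already-symmetrized mesh reproduces the same density map exactly (the
    image set is closed under the group), which makes map symmetrization
    idempotent.
    """
    if symmetry == "none":
        return mesh
    if symmetry not in ("c8", "c8+mirror"):
        raise ValueError(f"unknown symmetry {symmetry!r}")
    new_chains = []
    angles = 2 * np.pi * np.arange(8) / 8
    mirrors = (1.0, -1.0) if symmetry == "c8+mirror" else (1.0,)
    for ch in mesh.chains:
        for mz in mirrors:
            for a in angles:
                c, s = np.cos(a), np.sin(a)
                p = ch.positions
                q = np.column_stack(
                    [c * p[:, 0] - s * p[:, 1], s * p[:, 0] + c * p[:, 1],
                     mz * p[:, 2]]
                )
                new_chains.append(replace(ch, positions=q))
    return MeshConfiguration(chains=new_chains, frame_id=mesh.frame_id)


def density_map(
    ensemble: list[MeshConfiguration],
    grid_spec: GridSpec,
    bead_mass: float = BEAD_MASS,
    symmetry: str = "none",
    per_species: bool = False,
) -> ScalarGrid3D | dict[str, ScalarGrid3D]:
    """Time- and symmetry-averaged mass density map in mg/mL.

    Bead masses are binned to the voxel containing each bead (no smoothing),
    averaged over frames, and divided by the voxel volume; symmetry images
    carry mass 1/|group| each so total mass is conserved.
    """
    if not ensemble:
        raise ValueError("empty ensemble")
    order = 1 if symmetry == "none" else (8 if symmetry == "c8" else 16)
    accum: dict[str, np.ndarray] = {}
    for mesh in ensemble:
        m = apply_symmetry(mesh, symmetry)
        for ch in m.chains:
            key = ch.species if per_species else "all"
            grid = accum.setdefault(key, np.zeros(grid_spec.shape))
            idx = np.floor(
                (ch.positions - np.asarray(grid_spec.origin))
                / np.asarray(grid_spec.spacing)
            ).astype(int)
            inside = np.all(
                (idx >= 0) & (idx < np.array(grid_spec.shape)), axis=1
            )
            np.add.at(grid, tuple(idx[inside].T), bead_mass / order)
    scale = DA_PER_A3_TO_MG_PER_ML / (grid_spec.voxel_volume * len(ensemble))
    maps = {
        k: ScalarGrid3D(grid_spec, v * scale, "mg/mL") for k, v in accum.items()
    }
    return maps if per_species else maps["all"]


def charge_hydrophobicity_ratio(sequence: str) -> float:
    """|mean net charge per residue| / mean hydrophobicity (Kyte-Doolittle
    rescaled to [0, 1]); the Uversky-style composition statistic used to
    characterize disordered FG domains (low values, < 0.3, are typical)."""
    if not sequence:
        raise ValueError("empty sequence")
    seq = sequence.upper()
    bad = set(seq) - set(_KD)
    if bad:
        raise ValueError(f"unknown residue letters: {sorted(bad)}")
    charge = abs(float(np.mean([_CHARGE.get(a, 0.0) for a in seq])))
    hydro = float(np.mean([(_KD[a] + 4.5) / 9.0 for a in seq]))
    if hydro == 0.0:
        return float("inf") if charge > 0 else 0.0
    return charge / hydro
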