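import numpy as np
import pytest

from npcvoid.grids import GridSpec, ScalarGrid3D
from npcvoid.mesh import build_mesh_ensemble, toy_stoichiometry
from npcvoid.voids import VoidGridSpec


@pytest.fixture(scope="session")
def toy_spec():
    return toy_stoichiometry(8, 40, 40.0)


@pytest.fixture(scope="session")
def toy_ensemble(toy_spec):
    """Small anchored-chain ensemble reused across void/percolation tests."""
    return build_mesh_ensemble(toy_spec, n_frames=5, rng_seed=7)


@pytest.fixture(scope="session")
def toy_vspec():
    return VoidGridSpec.from_bounds(
        (-60, -60, -80), (60, 60, 80), 3.0, slab_height=6.0, profile_radius=55.0
    )


def random_exclusion_grid(rng, grid_spec, n_blobs=3):
    """A grid with a few rectangular excluded regions (values > 0)."""
    vals = np.zeros(grid_spec.shape)
    shape = np.array(grid_spec.shape)
    for _ in range(n_blobs):
        lo = rng.integers(0, shape - 1)
        size = rng.integers(1, np.maximum(2, shape // 3))
        hi = np.minimum(shape, lo + size)
        vals[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = rng.uniform(0.5, 15.0)
    return ScalarGrid3D(grid_spec, vals, "kcal/mol")


def brute_force_void_classifier(beads, excluded_mask, grid_spec, probe_radius,
                                bead_radius=3.0):
    """Independent accessibility oracle: explicit min over beads and excluded
    voxel centers for every voxel (no trees, no distance transforms)."""
    centers = grid_spec.centers()
    n = len(centers)
    rmax = np.full(n, np.inf)
    if beads is not None and len(beads):
        for b in np.asarray(beads, float).reshape(-1, 3):
            d = np.sqrt(((centers - b) ** 2).sum(axis=1)) - bead_radius
            rmax = np.minimum(rmax, d)
    excl_flat = excluded_mask.ravel()
    if excl_flat.any():
        excl_centers = centers[excl_flat]
        for i in range(n):
            d = np.sqrt(((excl_centers - centers[i]) ** 2).sum(axis=1)).min()
            rmax[i] = min(rmax[i], d)
        rmax[excl_flat] = -1.0
    return (rmax >= probe_radius).reshape(grid_spec.shape)


def canonical_labels(labels):
    """Relabel a component map by first appearance so partitions compare."""
    flat = labels.ravel()
    out = np.full_like(flat, -1)
    mapping = {}
    for i, lab in enumerate(flat):
        if lab < 0:
            continue
        if lab not in mapping:
            mapping[lab] = len(mapping)
        out[i] = mapping[lab]
    return out.reshape(labels.shape)


def bfs_labels(accessible, connectivity=6):
    """Flood-fill component labels (queue-based), the union-find oracle."""
    from collections import deque

    shape = accessible.shape
    labels = np.full(shape, -1, dtype=int)
    if connectivity == 6:
        neigh = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1),
                 (0, 0, -1)]
    else:
        neigh = [(dx, dy, dz) for dx in (-1, 0, 1) for dy in (-1, 0, 1)
                 for dz in (-1, 0, 1) if (dx, dy, dz) != (0, 0, 0)]
    nxt = 0
    for idx in np.ndindex(shape):
        if not accessible[idx] or labels[idx] >= 0:
            continue
        q = deque([idx])
        labels[idx] = nxt
        while q:
            x, y, z = q.popleft()
            for dx, dy, dz in neigh:
                xx, yy, zz = x + dx, y + dy, z + dz
                if (0 <= xx < shape[0] and 0 <= yy < shape[1]
                        and 0 <= zz < shape[2] and accessible[xx, yy, zz]
                        and labels[xx, yy, zz] < 0):
                    labels[xx, yy, zz] = nxt
                    q.append((xx, yy, zz))
        nxt += 1
    return labels
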