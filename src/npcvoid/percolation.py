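"""Lattice percolation: does an open path connect the two faces of the pore?

Accessible voxels are partitioned into connected components by union-find
with path compression; a configuration has an open path for a given probe
when one component touches both the source layer (above the mesh, default
z = +200 Å) and the sink layer (below, default z = −200 Å).  Repeating the
test over an ensemble of mesh configurations as a function of probe radius
yields the open-path probability curve whose drop locates the percolation
transition.

Neighbor topology defaults to 6-connectivity (face adjacency): a spherical
probe cannot pass through an edge or corner contact.  26-connectivity is
available for sensitivity checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy.stats import beta as beta_dist

from .mesh import MeshConfiguration
from .voids import VoidGridSpec, VoidMap, classify_voids, compute_rmax

__all__ = [
    "ConnectivityResult",
    "PercolationCurve",
    "label_components",
    "open_path_exists",
    "percolation_curve",
]


@dataclass
class ConnectivityResult:
    frame_id: int
    probe_radius: float
    open_path: bool
    n_components: int
    source_z: float = 200.0
    sink_z: float = -200.0


@dataclass
class PercolationCurve:
    """Open-path probability versus probe radius with a binomial band."""

    probe_radii: np.ndarray
    p_open: np.ndarray
    n_frames: int
    ci_lo: np.ndarray
    ci_hi: np.ndarray
    results: list = field(default_factory=list)

    def percolation_radius(self, level: float = 0.5):
        """Smallest probe radius at which p_open drops below ``level``.

        The point estimate interpolates linearly between the bracketing grid
        radii; returns (estimate, (R_lo, R_hi)) or (None, None) when the
        curve never crosses the level.
        """
        p = self.p_open
        r = self.probe_radii
        below = np.nonzero(p < level)[0]
        if len(below) == 0:
            return None, None
        j = below[0]
        if j == 0:
            return float(r[0]), (float(r[0]), float(r[0]))
        r0, r1 = r[j - 1], r[j]
        p0, p1 = p[j - 1], p[j]
        t = (level - p0) / (p1 - p0) if p1 != p0 else 0.5
        return float(r0 + t * (r1 - r0)), (float(r0), float(r1))

    def plot(self, ax=None):
        """Open-path probability vs probe radius with its confidence band."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.fill_between(self.probe_radii, self.ci_lo, self.ci_hi, alpha=0.25,
                        label="95% binomial band")
        ax.plot(self.probe_radii, self.p_open, "o-", label="p(open path)")
        ax.set_xlabel("probe radius (A)")
        ax.set_ylabel("open-path probability")
        ax.set_ylim(-0.02, 1.02)
        ax.legend()
        return ax

    def transition_window(self):
        """(largest R with p_open = 1, smallest R with p_open = 0) bracketing
        the percolation transition; grid edges are used when the curve never
        reaches 1 or 0."""
        r = self.probe_radii
        full = np.nonzero(self.p_open >= 1.0)[0]
        empty = np.nonzero(self.p_open <= 0.0)[0]
        lo = float(r[full[-1]]) if len(full) else float(r[0])
        hi = float(r[empty[0]]) if len(empty) else float(r[-1])
        return lo, hi


@njit(cache=False)
def _find(parent, i):
    root = i
    while parent[root] != root:
        root = parent[root]
    while parent[i] != root:  # path compression
        nxt = parent[i]
        parent[i] = root
        i = nxt
    return root


@njit(cache=False)
def _union_find_labels(acc, six_connectivity):
    nx, ny, nz = acc.shape
    n = nx * ny * nz
    parent = np.arange(n)
    flat = acc.ravel()
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                i = (x * ny + y) * nz + z
                if not flat[i]:
                    continue
                # backward neighbours only; each adjacency handled once
                if six_connectivity:
                    if x > 0 and acc[x - 1, y, z]:
                        ra = _find(parent, i)
                        rb = _find(parent, i - ny * nz)
                        parent[ra] = rb
                    if y > 0 and acc[x, y - 1, z]:
                        ra = _find(parent, i)
                        rb = _find(parent, i - nz)
                        parent[ra] = rb
                    if z > 0 and acc[x, y, z - 1]:
                        ra = _find(parent, i)
                        rb = _find(parent, i - 1)
                        parent[ra] = rb
                else:
                    for dx in range(-1, 1):
                        for dy in range(-1, 2):
                            for dz in range(-1, 2):
                                if dx == 0 and (dy > 0 or (dy == 0 and dz >= 0)):
                                    continue
                                xx, yy, zz = x + dx, y + dy, z + dz
                                if (0 <= xx < nx and 0 <= yy < ny
                                        and 0 <= zz < nz and acc[xx, yy, zz]):
                                    j = (xx * ny + yy) * nz + zz
                                    ra = _find(parent, i)
                                    rb = _find(parent, j)
                                    parent[ra] = rb
    labels = np.full(n, -1, dtype=np.int64)
    next_label = 0
    for i in range(n):
        if flat[i]:
            r = _find(parent, i)
            if labels[r] == -1:
                labels[r] = next_label
                next_label += 1
            labels[i] = labels[r]
    return labels, next_label


def label_components(voidmap: VoidMap, connectivity: int = 6):
    """Connected-component labels of the accessible lattice.

    Returns (labels, n_components); ``labels`` has the lattice shape with
    ``-1`` on inaccessible voxels and consecutive component ids elsewhere.
    Two accessible voxels share a label iff they are connected through a
    chain of neighboring accessible voxels.
    """
    if connectivity not in (6, 26):
        raise ValueError("connectivity must be 6 or 26")
    acc = np.ascontiguousarray(voidmap.accessible)
    labels, n = _union_find_labels(acc, connectivity == 6)
    return labels.reshape(acc.shape), int(n)


def _layer_index(spec: VoidGridSpec, z: float) -> int:
    zc = spec.grid.axis_centers(2)
    if z < zc[0] - spec.voxel_size or z > zc[-1] + spec.voxel_size:
        raise ValueError(f"layer z={z} lies outside the lattice")
    return int(np.argmin(np.abs(zc - z)))


def open_path_exists(
    voidmap: VoidMap,
    source_z: float = 200.0,
    sink_z: float = -200.0,
    connectivity: int = 6,
) -> ConnectivityResult:
    """True iff one accessible component intersects both boundary layers."""
    labels, n = label_components(voidmap, connectivity)
    ks = _layer_index(voidmap.spec, source_z)
    kk = _layer_index(voidmap.spec, sink_z)
    src = labels[:, :, ks]
    snk = labels[:, :, kk]
    src_set = set(np.unique(src[src >= 0]).tolist())
    snk_set = set(np.unique(snk[snk >= 0]).tolist())
    return ConnectivityResult(
        frame_id=voidmap.frame_id,
        probe_radius=voidmap.probe_radius,
        open_path=bool(src_set & snk_set),
        n_components=n,
        source_z=source_z,
        sink_z=sink_z,
    )


def _binomial_band(k: int, n: int, level: float = 0.95):
    """Clopper-Pearson interval for a binomial proportion."""
    a = (1 - level) / 2
    lo = 0.0 if k == 0 else float(beta_dist.ppf(a, k, n - k + 1))
    hi = 1.0 if k == n else float(beta_dist.ppf(1 - a, k + 1, n - k))
    return lo, hi


def percolation_curve(
    ensemble: list[MeshConfiguration],
    probe_radii,
    spec: VoidGridSpec,
    exclusion_grids=(),
    source_z: float = 200.0,
    sink_z: float = -200.0,
    connectivity: int = 6,
) -> PercolationCurve:
    """Open-path probability across an ensemble for each probe radius.

    The clearance map is computed once per frame (it does not depend on the
    probe) and thresholded per radius.
    """
    if not ensemble:
        raise ValueError("empty ensemble")
    radii = np.sort(np.asarray(probe_radii, float))
    hits = np.zeros(len(radii), dtype=int)
    results = []
    for mesh in ensemble:
        rmax = compute_rmax(mesh, exclusion_grids, spec)
        rmax.frame_id = mesh.frame_id
        for i, rp in enumerate(radii):
            vm = classify_voids(rmax, rp, spec)
            res = open_path_exists(vm, source_z, sink_z, connectivity)
            results.append(res)
            hits[i] += res.open_path
    n = len(ensemble)
    p = hits / n
    band = np.array([_binomial_band(int(k), n) for k in hits])
    return PercolationCurve(
        probe_radii=radii, p_open=p, n_frames=n,
        ci_lo=band[:, 0], ci_hi=band[:, 1], results=results,
    )
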