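"""Potentials of mean force along the pore axis.

Two routes produce the same object: Boltzmann inversion of the ensemble-mean
void occupancy,

    F(z_i) = -kT ln<h(z_i)> + kT ln(A_c / l_c^2),

whose second term pins the PMF to zero far from the pore (where the whole
confinement cross-section A_c is available), and Boltzmann inversion of a
center-of-mass trace histogram, -kT ln P(z), zeroed over an explicit
far-field window.  Energies are carried in units of kT; 1 kT = 0.5925
kcal/mol at 298.15 K.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .voids import EnsembleOccupancy

__all__ = [
    "KT_KCAL_PER_MOL",
    "PMFProfile",
    "pmf_from_occupancy",
    "pmf_from_trace",
    "symmetrize",
    "barrier_height",
]

KT_KCAL_PER_MOL = 0.5925  # kcal/mol per kT at 298.15 K


@dataclass
class PMFProfile:
    """1D free-energy profile in kT; +inf marks hard-wall (zero-occupancy) slabs."""

    z: np.ndarray
    F: np.ndarray
    source: str = "void"
    stderr: np.ndarray | None = None
    asymmetry: float | None = None
    hard_wall: np.ndarray = field(default=None)

    def __post_init__(self):
        self.z = np.asarray(self.z, float)
        self.F = np.asarray(self.F, float)
        if self.hard_wall is None:
            self.hard_wall = ~np.isfinite(self.F)

    @property
    def F_kcal(self) -> np.ndarray:
        return self.F * KT_KCAL_PER_MOL

    def plot(self, ax=None, kcal: bool = False):
        """Free-energy profile along the pore axis (hard walls omitted)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        f = self.F_kcal if kcal else self.F
        finite = np.isfinite(f)
        ax.plot(self.z[finite] / 10.0, f[finite], label=self.source)
        ax.set_xlabel("z (nm)")
        ax.set_ylabel("F (kcal/mol)" if kcal else "F (kT)")
        ax.legend()
        return ax

    def interpolate(self, z_new: np.ndarray) -> np.ndarray:
        """Linear interpolation onto a new axis; hard walls propagate as +inf."""
        z_new = np.asarray(z_new, float)
        finite = np.isfinite(self.F)
        out = np.interp(z_new, self.z[finite], self.F[finite])
        if self.hard_wall.any():
            half = 0.5 * np.median(np.diff(self.z))
            for zw in self.z[self.hard_wall]:
                out[np.abs(z_new - zw) <= half] = np.inf
        return out


def pmf_from_occupancy(occupancy: EnsembleOccupancy) -> PMFProfile:
    """Boltzmann inversion of the mean available-voxel count per slab.

    With slabs one voxel layer high the offset is the textbook
    ``kT ln(A_c / l_c^2)``; for thicker slabs the count spans
    ``slab_height / l_c`` layers and the offset generalizes to the slab
    volume, ``kT ln(A_c * slab_height / l_c^3)``, so the far field is zero
    either way.
    """
    if occupancy.A_c <= 0:
        raise ValueError("confinement cross-section must be positive")
    h = np.asarray(occupancy.h_mean, float)
    if (h < 0).any():
        raise ValueError("negative occupancy")
    const = np.log(occupancy.A_c * occupancy.slab_height / occupancy.l_c**3)
    with np.errstate(divide="ignore"):
        F = -np.log(h) + const
    F[h == 0] = np.inf
    stderr = None
    if occupancy.h_sem is not None:
        with np.errstate(divide="ignore", invalid="ignore"):
            stderr = np.where(h > 0, occupancy.h_sem / np.maximum(h, 1e-300), np.inf)
    return PMFProfile(z=occupancy.z_centers, F=F, source="void", stderr=stderr)


def pmf_from_trace(
    z_samples,
    bin_width: float = 10.0,
    z_range: tuple[float, float] | None = None,
    far_field: tuple[float, float] = (450.0, 550.0),
) -> PMFProfile:
    """PMF from a center-of-mass trace by Boltzmann inversion of its histogram.

    The profile is offset so that the mean over the far-field window
    ``|z| in [far_field)`` is zero; when the trace does not reach that
    window the outermost populated decile is used instead.  Empty bins inside
    the populated range are flagged as hard wall, never silently
    interpolated.
    """
    z = np.asarray(z_samples, float).ravel()
    if len(z) < 1000:
        raise ValueError("need at least 1000 samples for a trace PMF")
    if z_range is None:
        z_range = (z.min(), z.max())
    nbins = max(1, int(np.ceil((z_range[1] - z_range[0]) / bin_width)))
    counts, edges = np.histogram(z, bins=nbins, range=z_range)
    centers = 0.5 * (edges[:-1] + edges[1:])
    with np.errstate(divide="ignore"):
        F = -np.log(counts / counts.sum() / np.diff(edges))
    F[counts == 0] = np.inf
    ff = (np.abs(centers) >= far_field[0]) & (np.abs(centers) < far_field[1])
    ff &= np.isfinite(F)
    if not ff.any():
        lim = np.quantile(np.abs(z), 0.9)
        ff = (np.abs(centers) >= lim) & np.isfinite(F)
    F = F - F[ff].mean()
    return PMFProfile(z=centers, F=F, source="trace")


def _mirror_indices(z: np.ndarray):
    zr = -z[::-1]
    if not np.allclose(z, zr, atol=1e-6 * max(1.0, np.abs(z).max())):
        raise ValueError("z grid is not symmetric about 0")


def symmetrize(profile: PMFProfile, asym_window: float = 500.0) -> PMFProfile:
    """Average the underlying probabilities P(z) and P(-z) and re-invert.

    Averaging on probabilities (not free energies) keeps normalization exact
    and reproduces the symmetrized-distribution construction.  The
    ``asymmetry`` field records the mean point-by-point |F(z) - F(-z)| over
    ``|z| < asym_window`` (finite points only) of the *unsymmetrized*
    profile — a sampling-quality figure that doubles as the barrier
    uncertainty.
    """
    _mirror_indices(profile.z)
    with np.errstate(over="ignore"):
        P = np.exp(-profile.F)
    P_sym = 0.5 * (P + P[::-1])
    with np.errstate(divide="ignore"):
        F_sym = -np.log(P_sym)
    dF = np.abs(profile.F - profile.F[::-1])
    win = (np.abs(profile.z) < asym_window) & np.isfinite(dF)
    asym = float(dF[win].mean()) if win.any() else 0.0
    return replace(profile, F=F_sym, asymmetry=asym,
                   hard_wall=~np.isfinite(F_sym))


def barrier_height(profile: PMFProfile, half_width: float = 50.0
                   ) -> tuple[float, float]:
    """Mean PMF over the central region |z| < half_width, with uncertainty.

    The uncertainty is the profile's mirror asymmetry when available (the
    convention used for trace-derived barriers), else 0.
    """
    sel = np.abs(profile.z) < half_width
    if not sel.any():
        raise ValueError("profile does not cover the central region")
    if profile.z.min() > -half_width or profile.z.max() < half_width:
        raise ValueError("profile does not span |z| < half_width")
    val = float(np.mean(profile.F[sel]))
    err = float(profile.asymmetry) if profile.asymmetry is not None else 0.0
    return val, err
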