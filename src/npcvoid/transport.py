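"""1D Smoluchowski first-passage solver with position-dependent diffusivity.

The continuum equation

    drho/dt = d/dz [ D(z) e^{-V(z)} d/dz ( e^{V(z)} rho ) ]      (V in kT)

is discretized on nodes z_n = z_0 + n d as a nearest-neighbour master
equation with rates

    k_{n->m} = (D_n + D_m) / (2 d^2) * exp(-(V_m - V_n)/2),

a reflecting boundary at z_0 (the rates between the two leftmost nodes are
zero) and an absorbing boundary at z_{N+1} (density pinned to zero).  The
first-passage time density g(t) is accumulated from the absorbed-mass
increments of an explicit Euler march (algebraically identical to
differentiating the total surviving mass, numerically stabler), and the MFPT
is the time integral of t g(t).  An exact mean-first-passage solve of the
same rate matrix (tridiagonal adjoint equation) and a Brownian-dynamics
walker oracle provide independent cross-checks.

Units: lengths in Å, time in μs, D in Å²/μs, energies in kT.

The local diffusivity along a channel of varying available cross-section
A(z) = pi w(z)^2 follows the Fick–Jacobs-type corrections of Reguera–Rubi,
D = D0 [1 + (dw/dz)^2]^{-1/2}, or Zwanzig, D = D0 [1 + (dw/dz)^2/2]^{-1}.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy.linalg import solve_banded

__all__ = [
    "DiffusivityProfile",
    "TransitionRates",
    "FPTResult",
    "diffusivity_profile",
    "transition_rates",
    "solve_fpt",
    "mfpt_exact",
    "free_diffusion_fpt_density",
    "bd_oracle_mfpt",
    "stokes_einstein_d0",
]

KT_KCAL = 0.5925
# D0 = kT / (6 pi eta R): kT/(6 pi eta) at 298.15 K in water is ~2.45e5 A^3/us / A
_STOKES_NUM = 2.447e5  # A^2/us * A


def stokes_einstein_d0(radius: float) -> float:
    """Bulk diffusivity of a sphere of the given radius (Å) in water at
    298.15 K, in Å²/μs.  An approximation standing in for bead-model
    hydrodynamics calculations; pass measured D0 values when available."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    return _STOKES_NUM / radius


@dataclass
class DiffusivityProfile:
    """Position-dependent diffusivity with its channel-width bookkeeping."""

    z: np.ndarray
    D: np.ndarray
    D0: float
    model: str = "reguera_rubi"
    w: np.ndarray | None = None

    def __post_init__(self):
        self.z = np.asarray(self.z, float)
        self.D = np.asarray(self.D, float)

    @classmethod
    def constant(cls, z, D0: float) -> "DiffusivityProfile":
        z = np.asarray(z, float)
        return cls(z=z, D=np.full_like(z, float(D0)), D0=float(D0),
                   model="constant", w=None)


def diffusivity_profile(z, area, D0: float, model: str = "reguera_rubi"
                        ) -> DiffusivityProfile:
    """Local diffusivity from the available cross-section area profile A(z).

    ``model`` is one of ``reguera_rubi`` (default), ``zwanzig`` or
    ``constant``.  The effective half width is w = sqrt(A/pi); its slope is
    evaluated by central differences.
    """
    z = np.asarray(z, float)
    area = np.asarray(area, float)
    if model not in ("reguera_rubi", "zwanzig", "constant"):
        raise ValueError(f"unknown diffusion model {model!r}")
    if (area <= 0).any():
        raise ValueError("non-positive cross-section inside the solver domain "
                         "(hard wall): restrict the domain first")
    w = np.sqrt(area / np.pi)
    if model == "constant":
        D = np.full_like(z, float(D0))
    else:
        s = np.gradient(w, z)
        if model == "reguera_rubi":
            D = D0 / np.sqrt(1.0 + s**2)
        else:
            D = D0 / (1.0 + 0.5 * s**2)
    return DiffusivityProfile(z=z, D=D, D0=float(D0), model=model, w=w)


@dataclass
class TransitionRates:
    """Nearest-neighbour rates on a uniform node grid.

    ``k_up[n]`` is the rate n -> n+1 and ``k_dn[n]`` the rate n+1 -> n, for
    n = 0 .. M-2; node M-1 is the absorbing point.  Rates touching the two
    leftmost nodes are zero (reflecting wall) and rates into or out of
    hard-wall nodes (infinite potential) are zero.
    """

    z: np.ndarray
    k_up: np.ndarray
    k_dn: np.ndarray
    d: float
    V: np.ndarray
    D: np.ndarray

    @property
    def n_nodes(self) -> int:
        return len(self.z)


def transition_rates(D_profile: DiffusivityProfile, pmf, d: float | None = None
                     ) -> TransitionRates:
    """Discrete master-equation rates from a PMF (kT) and a diffusivity profile.

    Both profiles must share the same uniform grid.  Detailed balance,
    k_{n->m} / k_{m->n} = exp(-(V_m - V_n)), holds by construction.
    """
    z = np.asarray(D_profile.z, float)
    V = pmf.F if hasattr(pmf, "F") else np.asarray(pmf, float)
    if len(V) != len(z):
        raise ValueError("PMF and diffusivity grids differ in length")
    if hasattr(pmf, "z") and not np.allclose(pmf.z, z, atol=1e-6):
        raise ValueError("PMF and diffusivity grids differ")
    dz = np.diff(z)
    if d is None:
        d = float(dz[0])
    if not np.allclose(dz, d, atol=1e-6 * d):
        raise ValueError("node grid must be uniform")
    D = D_profile.D
    pref = (D[:-1] + D[1:]) / (2.0 * d * d)
    dV = V[1:] - V[:-1]
    wall = ~np.isfinite(V[1:]) | ~np.isfinite(V[:-1])
    with np.errstate(over="ignore", invalid="ignore"):
        k_up = np.where(wall, 0.0, pref * np.exp(-np.where(wall, 0.0, dV) / 2.0))
        k_dn = np.where(wall, 0.0, pref * np.exp(+np.where(wall, 0.0, dV) / 2.0))
    # reflecting wall: no exchange between the two leftmost nodes
    k_up[0] = 0.0
    k_dn[0] = 0.0
    return TransitionRates(z=z, k_up=k_up, k_dn=k_dn, d=d, V=np.asarray(V, float),
                           D=np.asarray(D, float))


@dataclass
class FPTResult:
    """First-passage-time density, its mean, and solver bookkeeping."""

    t_grid: np.ndarray          # bin centers, us
    g: np.ndarray               # FPT density, 1/us
    mfpt: float                 # us
    residual: float             # surviving probability at termination
    dt: float
    d: float
    z_start: float
    n_steps: int
    converged: bool
    survival: np.ndarray = field(default=None)  # survival at bin edges

    def absorbed_mass(self) -> float:
        return float(np.trapezoid(self.g, self.t_grid)) if len(self.t_grid) > 1 else 0.0


@njit(cache=False)
def _euler_chunk(rho, k_up, k_dn, dt, n_steps, record_every, absorbed_bins):
    """March the master equation; accumulate absorbed mass per output bin.

    rho has one entry per node; the last node is the absorbing point and is
    kept at zero, its inflow routed to the absorbed accumulator.
    """
    M = rho.shape[0]
    new = np.empty(M)
    bin_i = 0
    steps_in_bin = 0
    for step in range(n_steps):
        for n in range(M - 1):
            inflow = 0.0
            outflow = 0.0
            if n > 0:
                inflow += k_up[n - 1] * rho[n - 1]
                outflow += k_dn[n - 1] * rho[n]
            inflow += k_dn[n] * rho[n + 1]
            outflow += k_up[n] * rho[n]
            new[n] = rho[n] + dt * (inflow - outflow)
        absorbed_bins[bin_i] += dt * k_up[M - 2] * rho[M - 2]
        new[M - 1] = 0.0
        for n in range(M):
            rho[n] = new[n]
        steps_in_bin += 1
        if steps_in_bin == record_every:
            steps_in_bin = 0
            bin_i += 1
    return bin_i


def solve_fpt(
    rates: TransitionRates,
    z_start: float = -200.0,
    dt: float | None = None,
    t_max: float | None = None,
    residual_target: float = 1e-3,
    stability_factor: float = 0.8,
    n_bins_per_block: int = 512,
    max_blocks: int = 64,
    mass_tol: float = 1e-6,
) -> FPTResult:
    """Explicit-Euler first-passage solve from a delta start at ``z_start``.

    The time step defaults to ``stability_factor / max_n(total out-rate)``,
    which enforces the stability requirement D dt / d^2 < 1 with margin; an
    explicit ``dt`` violating it is reduced with a warning.  Integration
    blocks extend adaptively until the surviving probability falls below
    ``residual_target`` (or ``t_max`` / ``max_blocks`` is hit, in which case
    the result is flagged unconverged).  The MFPT integrates t g(t) by the
    midpoint/trapezoid rule and adds an exponential tail correction
    estimated from the terminal survival decay.
    """
    M = rates.n_nodes
    out_rate = np.zeros(M)
    out_rate[:-1] += rates.k_up
    out_rate[1:] += rates.k_dn
    max_rate = out_rate.max()
    if max_rate <= 0:
        raise ValueError("all rates vanish; nothing to solve")
    dt_stable = stability_factor / max_rate
    if dt is None:
        dt = dt_stable
    elif dt > dt_stable:
        warnings.warn(
            f"dt={dt:g} violates the stability criterion; reduced to {dt_stable:g}"
        )
        dt = dt_stable
    i0 = int(np.argmin(np.abs(rates.z - z_start)))
    if not np.isfinite(rates.V[i0]):
        raise ValueError("start node lies inside a hard wall")
    rho = np.zeros(M)
    rho[i0] = 1.0  # delta start: unit probability at one node
    # size the integration blocks from the exact MFPT of the same rate matrix
    tau_ref = mfpt_exact(rates, z_start)
    if not np.isfinite(tau_ref):
        if t_max is None:
            raise ValueError("absorbing boundary unreachable (hard wall); "
                             "supply t_max for a partial solve")
        tau_ref = t_max
    t_block = max(0.75 * tau_ref, 10.0 * dt)
    record_every = max(1, int(round(t_block / (n_bins_per_block * dt))))
    bin_dt = record_every * dt
    absorbed = []
    survival_hist = [1.0]
    total_steps = 0
    converged = False
    for block in range(max_blocks):
        n_steps = n_bins_per_block * record_every
        if t_max is not None:
            remaining = int(np.ceil((t_max - total_steps * dt) / dt))
            if remaining <= 0:
                break
            n_steps = min(n_steps, remaining)
        bins = np.zeros(int(np.ceil(n_steps / record_every)) + 1)
        _euler_chunk(rho, rates.k_up, rates.k_dn, dt, n_steps, record_every, bins)
        absorbed.append(bins[: int(np.ceil(n_steps / record_every))])
        total_steps += n_steps
        last_block_steps = n_steps
        surv = float(rho[:-1].sum())
        survival_hist.append(surv)
        drift = abs(surv + sum(a.sum() for a in absorbed) - 1.0)
        if drift > mass_tol * max(1, total_steps):
            raise RuntimeError(f"probability not conserved: drift {drift:g}")
        if surv < residual_target:
            converged = True
            break
    absorbed = np.concatenate(absorbed) if absorbed else np.zeros(0)
    n_bins = len(absorbed)
    t_edges = np.arange(n_bins + 1) * bin_dt
    t_mid = 0.5 * (t_edges[:-1] + t_edges[1:])
    g = absorbed / bin_dt
    mfpt = float(np.sum(t_mid * absorbed))
    residual = float(rho[:-1].sum())
    # exponential tail: S(t) ~ S_end exp(-(t - t_end)/tau_decay)
    if residual > 0 and len(survival_hist) >= 3 and survival_hist[-2] > residual:
        span = last_block_steps * dt
        lam = np.log(survival_hist[-2] / residual) / span
        if lam > 0:
            mfpt += residual * (total_steps * dt + 1.0 / lam)
    if not converged and t_max is None:
        warnings.warn(f"FPT solve unconverged: residual {residual:g}")
    surv_curve = 1.0 - np.cumsum(absorbed)
    return FPTResult(
        t_grid=t_mid, g=g, mfpt=mfpt, residual=residual, dt=dt, d=rates.d,
        z_start=float(rates.z[i0]), n_steps=total_steps, converged=converged,
        survival=surv_curve,
    )


def mfpt_exact(rates: TransitionRates, z_start: float = -200.0) -> float:
    """Mean first-passage time by the exact adjoint (tridiagonal) solve.

    Solves k_up[n](tau[n+1]-tau[n]) + k_dn[n-1](tau[n-1]-tau[n]) = -1 for the
    dynamic nodes with tau = 0 at the absorbing point — the exact mean of the
    same discrete master equation the Euler march integrates.  Node 0 is
    disconnected by the reflecting-wall convention and excluded; hard-wall
    nodes separating the start from the absorber give +inf.
    """
    M = rates.n_nodes
    i0 = int(np.argmin(np.abs(rates.z - z_start)))
    if i0 == 0:
        raise ValueError("start coincides with the disconnected reflecting node")
    # locate the connected block [lo, M-1] containing the start
    lo = i0
    while lo > 1 and rates.k_up[lo - 1] > 0:
        lo -= 1
    for n in range(i0, M - 1):
        if rates.k_up[n] <= 0:
            return np.inf
    idx = np.arange(lo, M - 1)  # unknown nodes
    m = len(idx)
    ab = np.zeros((3, m))
    b = -np.ones(m)
    for j, n in enumerate(idx):
        up = rates.k_up[n]
        dn = rates.k_dn[n - 1] if n > lo else 0.0
        ab[1, j] = -(up + dn)
        if j + 1 < m:
            ab[0, j + 1] = up       # super-diagonal: coeff of tau[n+1]
        if j - 1 >= 0:
            ab[2, j - 1] = dn       # sub-diagonal: coeff of tau[n-1]
    tau = solve_banded((1, 1), ab, b)
    return float(tau[i0 - lo])


def free_diffusion_fpt_density(l: float, D: float, t_grid) -> np.ndarray:
    """First-passage density of free 1D diffusion over distance l:
    P(t) = l / sqrt(4 pi D t^3) * exp(-l^2 / (4 D t)); its mode sits at
    t* = l^2 / (6 D)."""
    if l <= 0 or D <= 0:
        raise ValueError("l and D must be positive")
    t = np.asarray(t_grid, float)
    out = np.zeros_like(t)
    pos = t > 0
    tp = t[pos]
    out[pos] = l / np.sqrt(4.0 * np.pi * D * tp**3) * np.exp(-(l**2) / (4.0 * D * tp))
    return out


@njit(cache=False)
def _bd_walkers(z0, z_min, z_abs, grid_z0, d, V, D, Dp, Fp, dt, n_walkers,
                max_steps, seed):
    np.random.seed(seed)
    M = V.shape[0]
    times = np.empty(n_walkers)
    n_done = 0
    sq = np.sqrt(2.0 * dt)
    for w in range(n_walkers):
        z = z0
        t = 0.0
        absorbed = False
        for _ in range(max_steps):
            i = int(round((z - grid_z0) / d))
            if i < 0:
                i = 0
            elif i >= M:
                i = M - 1
            drift = -D[i] * Fp[i] + Dp[i]
            z = z + drift * dt + sq * np.sqrt(D[i]) * np.random.normal()
            t += dt
            if z >= z_abs:
                absorbed = True
                break
            if z < z_min:
                z = 2.0 * z_min - z
        if absorbed:
            times[n_done] = t
            n_done += 1
    return times[:n_done]


def bd_oracle_mfpt(
    pmf,
    D_profile: DiffusivityProfile,
    n_walkers: int = 2000,
    rng_seed: int = 0,
    z_start: float = -200.0,
    max_step: float = 1.0,
    max_steps: int | None = None,
) -> tuple[float, float]:
    """Overdamped Euler–Maruyama walker estimate of the MFPT (independent
    stochastic oracle for the grid solver).

    Includes the spurious-drift term dD/dz required for position-dependent
    diffusivity; reflecting at the left domain edge, absorbing at the right.
    Returns (mean, standard error); unabsorbed walkers past the step cap are
    dropped with a warning.
    """
    z = np.asarray(D_profile.z, float)
    V = pmf.F if hasattr(pmf, "F") else np.asarray(pmf, float)
    if not np.all(np.isfinite(V)):
        raise ValueError("BD oracle requires a finite (no hard wall) PMF")
    D = D_profile.D
    d = float(z[1] - z[0])
    Fp = np.gradient(V, z)
    Dp = np.gradient(D, z)
    dt = max_step**2 / (2.0 * D.max())
    # guard against drift overshoot
    vmax = np.max(np.abs(-D * Fp + Dp))
    if vmax > 0:
        dt = min(dt, max_step / vmax)
    if max_steps is None:
        max_steps = 1_000_000
    times = _bd_walkers(
        float(z_start), float(z[0]), float(z[-1]), float(z[0]), d, V, D, Dp, Fp,
        dt, int(n_walkers), int(max_steps), int(rng_seed) & 0x7FFFFFFF,
    )
    if len(times) < n_walkers:
        warnings.warn(f"{n_walkers - len(times)} walkers not absorbed; dropped")
    if len(times) == 0:
        return np.inf, np.inf
    return float(times.mean()), float(times.std(ddof=1) / np.sqrt(len(times)))
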