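"""Soft-to-hard barrier crossover: the MFPT scaling law and its fit.

The mean first-passage time of a spherical probe of radius R_p through the
disordered mesh follows

    tau(R_p) = tau0 * R_p * exp( ((R_p + 3 A) / R0)^alpha ),

a transition-rate form tau ~ e^{H_eff} / D_eff: the Stokes–Einstein
pre-factor tau0 R_p carries the bulk diffusivity, the stretched-exponential
carries the effective barrier, and the fixed 3 Å offset accounts for the
physical size of the mesh residues.  For R_p well below the threshold radius
R0 the curve looks like a power law; the exponential takes over where
ln R_p falls below ((R_p + 3)/R0)^alpha, and the root of

    ln R = ((R + 3) / R0)^alpha

defines the crossover radius separating the soft (power-law) from the hard
(exponential) barrier regime.

Fitting is least squares on ln tau (a multiplicative noise model), which
weighs the power-law and exponential regimes commensurately, with multiple
jittered starts to dodge the local minima of the stretched exponential.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import PchipInterpolator
from scipy.optimize import brentq, least_squares

__all__ = [
    "ScalingLawModel",
    "ScalingFitResults",
    "fit_scaling_law",
    "crossover_radius",
    "MassRadiusTable",
    "mass_to_radius",
]

RESIDUE_OFFSET = 3.0  # A added to the probe radius; fixed, not fitted


def _log_model(theta, r, offset):
    ln_tau0, ln_r0, ln_alpha = theta
    return ln_tau0 + np.log(r) + ((r + offset) / np.exp(ln_r0)) ** np.exp(ln_alpha)


class ScalingLawModel:
    """MFPT-versus-radius scaling model, statsmodels style.

    Parameters
    ----------
    radii : array
        Probe radii in Å (at least 4 distinct values spanning the crossover).
    taus : array
        Mean first-passage times in μs, all positive.
    weights : array, optional
        Multiplicative weights on the log-residuals.
    """

    def __init__(self, radii, taus, weights=None, offset: float = RESIDUE_OFFSET):
        self.radii = np.asarray(radii, float)
        self.taus = np.asarray(taus, float)
        if self.radii.shape != self.taus.shape:
            raise ValueError("radii and taus must have the same shape")
        if len(np.unique(self.radii)) < 4:
            raise ValueError("need >= 4 distinct radii to identify the fit")
        if (self.taus <= 0).any() or (self.radii <= 0).any():
            raise ValueError("radii and taus must be positive")
        self.weights = (np.ones_like(self.taus) if weights is None
                        else np.asarray(weights, float))
        self.offset = float(offset)

    def fit(self, alpha_fixed: float | None = None, n_starts: int = 5
            ) -> "ScalingFitResults":
        r, w = self.radii, self.weights
        ln_tau = np.log(self.taus)
        r0_init = float(np.median(r))
        alpha_init = 2.0 if alpha_fixed is None else float(alpha_fixed)
        i_min = int(np.argmin(r))
        tau0_init = self.taus[i_min] / (
            r[i_min] * np.exp(((r[i_min] + self.offset) / r0_init) ** alpha_init)
        )
        base = np.array([np.log(max(tau0_init, 1e-12)), np.log(r0_init),
                         np.log(alpha_init)])

        if alpha_fixed is None:
            def resid(theta):
                return w * (_log_model(theta, r, self.offset) - ln_tau)
            pack = lambda th: th
        else:
            la = np.log(alpha_fixed)

            def resid(theta2):
                return w * (_log_model(np.r_[theta2, la], r, self.offset) - ln_tau)
            pack = lambda th2: np.r_[th2, la]

        rng = np.random.default_rng(0)  # deterministic multi-start jitter
        best = None
        x0_full = base if alpha_fixed is None else base[:2]
        for s in range(n_starts):
            x0 = x0_full if s == 0 else x0_full + rng.normal(0, 0.4, len(x0_full))
            try:
                sol = least_squares(resid, x0, method="lm", max_nfev=5000)
            except Exception:
                continue
            if best is None or sol.cost < best.cost:
                best = sol
        if best is None:
            raise RuntimeError("scaling-law fit failed from every start")
        theta = pack(best.x)
        dof = max(1, len(r) - len(best.x))
        s2 = 2 * best.cost / dof
        JTJ = best.jac.T @ best.jac
        try:
            cov_theta = s2 * np.linalg.inv(JTJ)
        except np.linalg.LinAlgError:
            cov_theta = np.full((len(best.x),) * 2, np.nan)
        return ScalingFitResults(
            model=self, tau0=float(np.exp(theta[0])), R0=float(np.exp(theta[1])),
            alpha=float(np.exp(theta[2])), cov_log=cov_theta,
            residuals=resid(best.x) / np.where(w == 0, 1, w),
            alpha_fixed=alpha_fixed is not None,
        )


@dataclass
class ScalingFitResults:
    """Fitted (tau0, R0, alpha) with covariance, residuals and diagnostics."""

    model: ScalingLawModel
    tau0: float   # us/A
    R0: float     # A
    alpha: float
    cov_log: np.ndarray   # covariance of the fitted log-parameters
    residuals: np.ndarray  # ln tau residuals
    alpha_fixed: bool = False

    @property
    def offset(self) -> float:
        return self.model.offset

    def predict(self, radii) -> np.ndarray:
        r = np.asarray(radii, float)
        return self.tau0 * r * np.exp(((r + self.offset) / self.R0) ** self.alpha)

    def stderr(self) -> dict[str, float]:
        """Delta-method standard errors on the natural-scale parameters."""
        names = ["tau0", "R0"] + ([] if self.alpha_fixed else ["alpha"])
        vals = [self.tau0, self.R0] + ([] if self.alpha_fixed else [self.alpha])
        out = {}
        for i, (nm, v) in enumerate(zip(names, vals)):
            var = self.cov_log[i, i] if i < len(self.cov_log) else np.nan
            out[nm] = abs(v) * np.sqrt(var) if np.isfinite(var) else np.nan
        if self.alpha_fixed:
            out["alpha"] = 0.0
        return out

    def crossover_radius(self, bracket=(1.0, 200.0)) -> float:
        return crossover_radius(self.R0, self.alpha, self.offset, bracket)

    def regime(self, radius: float) -> str:
        """'power-law' below the crossover radius, 'exponential' above."""
        return "power-law" if radius < self.crossover_radius() else "exponential"

    def rss(self) -> float:
        return float(np.sum(self.residuals**2))

    def plot(self, ax=None):
        """MFPT data, fitted scaling law and the crossover radius."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        r = self.model.radii
        ax.loglog(r, self.model.taus, "ks", label="MFPT data")
        rr = np.linspace(r.min(), r.max(), 300)
        ax.loglog(rr, self.predict(rr), "r-", label="scaling-law fit")
        try:
            rx = self.crossover_radius()
            ax.axvline(rx, ls="--", color="gray",
                       label=f"crossover {rx:.1f} A")
        except ValueError:
            pass
        ax.set_xlabel("probe radius (A)")
        ax.set_ylabel("MFPT (us)")
        ax.legend()
        return ax

    def summary(self) -> str:
        se = self.stderr()
        rows = [
            ("tau0 (us/A)", self.tau0, se["tau0"]),
            ("R0 (A)", self.R0, se["R0"]),
            ("alpha", self.alpha, se["alpha"]),
        ]
        lines = [
            "MFPT scaling-law fit: tau = tau0 * R * exp(((R + 3 A)/R0)^alpha)",
            f"  n points: {len(self.model.radii)}   "
            f"ln-tau RSS: {self.rss():.4g}",
            f"  {'parameter':<12}{'estimate':>12}{'std err':>12}",
        ]
        for nm, v, s in rows:
            lines.append(f"  {nm:<12}{v:>12.4g}{s:>12.3g}")
        try:
            rx = self.crossover_radius()
            lines.append(f"  crossover radius (soft->hard): {rx:.1f} A")
        except ValueError:
            lines.append("  crossover radius: no root in bracket")
        return "\n".join(lines)


def fit_scaling_law(radii, taus, weights=None, **kw) -> ScalingFitResults:
    """Convenience wrapper: build the model and fit it."""
    return ScalingLawModel(radii, taus, weights).fit(**kw)


def crossover_radius(R0: float, alpha: float, offset: float = RESIDUE_OFFSET,
                     bracket=(1.0, 200.0), tol: float = 1e-3) -> float:
    """Radius where the exponential term of the scaling law starts to dominate.

    Solves ln R = ((R + offset)/R0)^alpha for the upper root (the barrier
    term grows faster than ln R, so the function ln R - (...)^alpha changes
    sign from + to - there); bracketed bisection to ``tol`` Å.
    """
    if R0 <= 0 or alpha <= 0:
        raise ValueError("R0 and alpha must be positive")

    def f(r):
        return np.log(r) - ((r + offset) / R0) ** alpha

    rs = np.linspace(bracket[0], bracket[1], 4096)
    fs = f(rs)
    sign_change = np.nonzero((fs[:-1] > 0) & (fs[1:] <= 0))[0]
    if len(sign_change) == 0:
        raise ValueError(f"no soft-to-hard root in {bracket}")
    j = sign_change[-1]
    return float(brentq(f, rs[j], rs[j + 1], xtol=tol))


class MassRadiusTable:
    """Monotone protein mass (Da) <-> effective probe radius (Å) conversion.

    Interpolation is monotone-cubic in log-log space through the anchor
    points; queries outside the anchor hull are extrapolated with a warning
    flag.  The default anchors are the three reference proteins whose
    effective spherical-probe radii are 12.75, 15.71 and 30.04 Å
    (aprotinin-, thioredoxin- and hemoglobin-scale).
    """

    def __init__(self, masses, radii):
        self.masses = np.asarray(masses, float)
        self.radii = np.asarray(radii, float)
        if len(self.masses) < 2:
            raise ValueError("need at least two anchors")
        if not (np.all(np.diff(self.masses) > 0) and np.all(np.diff(self.radii) > 0)):
            raise ValueError("table must be strictly increasing in both columns")
        self._fwd = PchipInterpolator(np.log(self.masses), np.log(self.radii),
                                      extrapolate=True)
        self._inv = PchipInterpolator(np.log(self.radii), np.log(self.masses),
                                      extrapolate=True)

    @classmethod
    def default(cls) -> "MassRadiusTable":
        return cls(masses=[6500.0, 11700.0, 62000.0],
                   radii=[12.75, 15.71, 30.04])

    def mass_to_radius(self, mass):
        m = np.asarray(mass, float)
        out = np.exp(self._fwd(np.log(m)))
        extrap = (m < self.masses[0]) | (m > self.masses[-1])
        return (float(out), bool(extrap)) if np.isscalar(mass) else (out, extrap)

    def _invert_one(self, log_r: float) -> float:
        from scipy.optimize import brentq

        lo, hi = np.log(self.masses[0]), np.log(self.masses[-1])
        if self._fwd(lo) <= log_r <= self._fwd(hi):
            # exact functional inverse of the forward interpolant
            return brentq(lambda lm: self._fwd(lm) - log_r, lo, hi, xtol=1e-12)
        return float(self._inv(log_r))  # extrapolated query: mirrored pchip

    def radius_to_mass(self, radius):
        r = np.asarray(radius, float)
        out = np.exp([self._invert_one(lr) for lr in np.atleast_1d(np.log(r))])
        extrap = (r < self.radii[0]) | (r > self.radii[-1])
        if np.isscalar(radius):
            return float(out[0]), bool(extrap)
        return out, extrap


def mass_to_radius(mass, table: MassRadiusTable | None = None):
    """Effective probe radius (Å) of a protein of the given mass (Da)."""
    table = table or MassRadiusTable.default()
    return table.mass_to_radius(mass)
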