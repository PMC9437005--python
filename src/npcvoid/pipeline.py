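"""Configuration-driven orchestration of the full analysis chain.

``run_pipeline`` executes mesh generation → void analysis → {percolation,
PMF → first-passage} → scaling-law fit on a single declarative config, writes
every artifact as text (TSV/JSON) and returns a manifest with SHA-256
checksums.  Identical config + seed gives byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io as nio
from .grids import ConfinementSpec, EnvelopeSpec, GridSpec, build_confinement_grid, \
    build_envelope_grid
from .mesh import build_mesh_ensemble, load_stoichiometry, toy_stoichiometry
from .percolation import percolation_curve
from .pmf import pmf_from_occupancy
from .scaling import fit_scaling_law
from .transport import DiffusivityProfile, diffusivity_profile, mfpt_exact, \
    solve_fpt, stokes_einstein_d0, transition_rates
from .voids import VoidGridSpec, classify_voids, compute_rmax, \
    ensemble_average_occupancy, occupancy_profile

__all__ = ["PipelineConfig", "run_pipeline", "StageError"]

log = logging.getLogger("npcvoid")


class StageError(RuntimeError):
    def __init__(self, stage: str, original: Exception, manifest: dict):
        self.stage = stage
        self.manifest = manifest
        super().__init__(f"pipeline stage {stage!r} failed: {original}")


@dataclass
class PipelineConfig:
    """Everything the pipeline needs; defaults describe a desk-scale fixture."""

    stoichiometry: str = "toy"
    toy_chains: int = 12
    toy_length: int = 60
    toy_anchor_radius: float = 40.0
    n_frames: int = 8
    seed: int = 0
    probe_radii: list = field(default_factory=lambda: [2.0, 4.0, 6.0, 8.0, 10.0,
                                                       12.0, 14.0, 16.0])
    confinement_radius: float = 60.0
    confinement_height: float = 240.0
    include_envelope: bool = False
    voxel_size: float = 3.0
    slab_height: float = 6.0
    z_extent: float = 120.0
    xy_pad: float = 12.0
    source_z: float = 90.0
    sink_z: float = -90.0
    connectivity: int = 6
    diffusion_model: str = "reguera_rubi"
    solver_d: float = 2.0
    solver_z: tuple = (-114.0, 96.0)
    solver_start: float = -90.0
    mfpt_method: str = "exact"
    outdir: str = "npcvoid_out"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def validate(self) -> "PipelineConfig":
        if self.stoichiometry != "toy":
            load_stoichiometry(self.stoichiometry)  # raises on unknown name
        if self.n_frames < 1 or not self.probe_radii:
            raise ValueError("need >= 1 frame and >= 1 probe radius")
        if self.mfpt_method not in ("exact", "euler"):
            raise ValueError("mfpt_method must be 'exact' or 'euler'")
        if not (self.solver_z[0] < self.solver_start < self.solver_z[1]):
            raise ValueError("solver_start outside solver domain")
        if abs(self.source_z) > self.z_extent or abs(self.sink_z) > self.z_extent:
            raise ValueError("source/sink layers outside the void grid")
        return self

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full chain; returns the manifest (also written to disk)."""
    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config_hash": config.config_hash(),
                      "seed": config.seed, "artifacts": {}}
    arts = manifest["artifacts"]

    def record(path: Path):
        arts[path.name] = _sha256(Path(path))

    stage = "setup"
    try:
        if config.stoichiometry == "toy":
            spec = toy_stoichiometry(config.toy_chains, config.toy_length,
                                     config.toy_anchor_radius)
        else:
            spec = load_stoichiometry(config.stoichiometry)
        R_c = config.confinement_radius
        lo = (-(R_c + config.xy_pad), -(R_c + config.xy_pad), -config.z_extent)
        hi = (R_c + config.xy_pad, R_c + config.xy_pad, config.z_extent)
        conf = ConfinementSpec(radius=R_c, height=config.confinement_height)
        gs = GridSpec.from_bounds(lo, hi, config.voxel_size)
        grids = [build_confinement_grid(conf, gs)]
        # growth uses the analytic confinement (defined everywhere), void
        # analysis the voxelized grids (defined on the analysis lattice)
        growth_constraints = [conf.energy]
        if config.include_envelope:
            grids.append(build_envelope_grid(EnvelopeSpec(), gs))
            growth_constraints.append(grids[-1])

        stage = "mesh"
        log.info("building %d frames of %s", config.n_frames, spec.name)
        ensemble = build_mesh_ensemble(spec, steric_grids=growth_constraints,
                                       n_frames=config.n_frames,
                                       rng_seed=config.seed)
        nio.write_ensemble_xyz(ensemble, out / "ensemble")
        record(out / "ensemble" / "frame_index.json")

        stage = "void"
        vspec = VoidGridSpec(gs, config.slab_height, profile_radius=R_c)
        radii = sorted(float(r) for r in config.probe_radii)
        rmax_maps = [compute_rmax(m, grids, vspec) for m in ensemble]
        for rm, m in zip(rmax_maps, ensemble):
            rm.frame_id = m.frame_id
        occ_by_radius = {}
        for rp in radii:
            profiles = [occupancy_profile(classify_voids(rm, rp, vspec), vspec)
                        for rm in rmax_maps]
            occ = ensemble_average_occupancy(profiles)
            occ_by_radius[rp] = occ
            record(nio.write_occupancy_tsv(occ, out / f"occupancy_R{rp:g}.tsv"))

        stage = "percolation"
        curve = percolation_curve(ensemble, radii, vspec, grids,
                                  source_z=config.source_z,
                                  sink_z=config.sink_z,
                                  connectivity=config.connectivity)
        record(nio.write_percolation_tsv(curve, out / "percolation.tsv"))

        stage = "pmf+fpt"
        mfpts = {}
        z_nodes = np.arange(config.solver_z[0], config.solver_z[1] + 1e-9,
                            config.solver_d)
        for rp in radii:
            occ = occ_by_radius[rp]
            profile = pmf_from_occupancy(occ)
            record(nio.write_pmf_tsv(profile, out / f"pmf_R{rp:g}.tsv",
                                     {"probe_radius": rp,
                                      "n_frames": occ.n_frames}))
            F = profile.interpolate(z_nodes)
            A = np.interp(z_nodes, occ.z_centers, occ.A_mean)
            D0 = stokes_einstein_d0(max(rp, 1.0))
            finite = np.isfinite(F)
            if not finite.all():
                mfpts[rp] = np.inf
                continue
            dprof = diffusivity_profile(z_nodes, np.maximum(A, 1e-6), D0,
                                        config.diffusion_model)
            rates = transition_rates(dprof, F, d=config.solver_d)
            if config.mfpt_method == "exact":
                mfpts[rp] = mfpt_exact(rates, config.solver_start)
            else:
                mfpts[rp] = solve_fpt(rates, config.solver_start).mfpt
        with open(out / "mfpt.tsv", "w") as fh:
            fh.write("R_p\tmfpt_us\n")
            for rp in radii:
                fh.write(f"{rp:g}\t{mfpts[rp]:.8g}\n")
        record(out / "mfpt.tsv")

        stage = "fit"
        fin = [(rp, t) for rp, t in mfpts.items() if np.isfinite(t) and t > 0]
        fit_info: dict = {"n_points": len(fin)}
        if len(fin) >= 4 and len({r for r, _ in fin}) >= 4:
            rr = np.array([r for r, _ in fin])
            tt = np.array([t for _, t in fin])
            try:
                res = fit_scaling_law(rr, tt)
                fit_info.update(tau0=res.tau0, R0=res.R0, alpha=res.alpha)
                try:
                    fit_info["crossover_radius"] = res.crossover_radius(
                        bracket=(1.0, max(rr) * 4))
                except ValueError:
                    fit_info["crossover_radius"] = None
            except RuntimeError as e:
                fit_info["error"] = str(e)
        perc_est, perc_bracket = curve.percolation_radius()
        fit_info["percolation_radius"] = perc_est
        fit_info["percolation_bracket"] = perc_bracket
        fit_info["transition_window"] = curve.transition_window()
        with open(out / "scaling_fit.json", "w") as fh:
            json.dump(fit_info, fh, indent=1, default=float)
        record(out / "scaling_fit.json")
    except Exception as e:  # annotate with the failing stage
        if isinstance(e, StageError):
            raise
        raise StageError(stage, e, manifest) from e

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
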