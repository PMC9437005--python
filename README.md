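# npcvoid

Void statistics, percolation and first-passage kinetics of passive transport
through the nuclear pore complex (NPC).

The permeability barrier of the NPC is a disordered mesh of FG-nucleoporin
chains grafted to the pore scaffold. `npcvoid` implements a geometric theory
of passive transport through that mesh: instead of simulating a probe
diffusing through the pore, it analyzes an equilibrium ensemble of mesh
configurations alone and derives, for a spherical probe of radius *R*ₚ,

1. **Void maps** — every voxel of the pore volume is classified as accessible
   if its clearance radius *R*ₘₐₓ (distance from the voxel center to the
   nearest chain-bead surface, bead radius 3 Å, or to the nearest sterically
   excluded voxel) satisfies *R*ₘₐₓ ≥ *R*ₚ.
2. **Percolation** — union-find connectivity of the accessible voxels decides
   whether an open path joins the two pore faces; the fraction of
   configurations with an open path, *p*(*R*ₚ), drops from 1 toward 0 at the
   percolation transition.
3. **Potential of mean force** — Boltzmann inversion of the mean accessible
   cross-section per slab, *F*(*z*) = −kT ln⟨*h*(*z*)⟩ + kT ln(𝒜꜀/*l*꜀²),
   zero far from the pore.
4. **Mean first-passage time (MFPT)** — a 1D Smoluchowski (Fokker–Planck)
   solve over *F*(*z*) with the Fick–Jacobs diffusivity correction
   D(z) = D₀ [1 + (dw/dz)²]^(−1/2), w(z) = √(𝒜(z)/π), between a reflecting
   and an absorbing boundary.
5. **Scaling law** — the crossover from a soft (power-law) to a hard
   (exponential) barrier is located by fitting
   τ(*R*ₚ) = τ₀ *R*ₚ exp(((*R*ₚ + 3 Å)/*R*₀)^α) and solving
   ln *R* = ((*R* + 3)/*R*₀)^α.

A synthetic mesh generator (anchored self-avoiding walks at 3.8 Å bond
length with an 8 Å interchain clash distance, confined by envelope/scaffold
steric grids) provides reproducible test ensembles, including the published
chain stoichiometries of three NPC models (`lin2016`, `kim2018`,
`kim2018plus`). Telegraph-trace analysis (first-passage and crossing-time
statistics of center-of-mass traces) closes the loop against
simulation-style data.

Intended users: biophysicists and structural-bioinformatics researchers
studying nucleocytoplasmic transport, polymer-brush permeability or
channel-confined diffusion in general.

## Worked example

```python
import numpy as np
from npcvoid import (toy_stoichiometry, build_mesh_ensemble, VoidGridSpec,
                     compute_rmax, classify_voids, occupancy_profile,
                     ensemble_average_occupancy, pmf_from_occupancy,
                     barrier_height, crossover_radius)

spec = toy_stoichiometry(n_chains=8, length=40, radius=40.0)
ensemble = build_mesh_ensemble(spec, n_frames=5, rng_seed=7)
vspec = VoidGridSpec.from_bounds((-60, -60, -80), (60, 60, 80),
                                 voxel_size=3.0, slab_height=6.0,
                                 profile_radius=55.0)
profiles = []
for mesh in ensemble:
    rmax = compute_rmax(mesh, (), vspec)
    vm = classify_voids(rmax, probe_radius=6.0, spec=vspec)
    profiles.append(occupancy_profile(vm, vspec))
pmf = pmf_from_occupancy(ensemble_average_occupancy(profiles))
height, err = barrier_height(pmf, half_width=50.0)
print(f"PMF barrier for a 6 A probe: {height:.2f} kT")
print(f"soft-to-hard crossover at R0=19.8 A, alpha=1.89: "
      f"{crossover_radius(19.8, 1.89):.1f} A")
```

prints

```
PMF barrier for a 6 A probe: 0.24 kT
soft-to-hard crossover at R0=19.8 A, alpha=1.89: 35.9 A
```

The 0.24 kT barrier is the mean free-energy cost, within 5 nm of the pore
midplane, of inserting a 6 Å probe into this small synthetic mesh; 35.9 Å is
the probe radius at which the exponential (hard-barrier) term of the MFPT
scaling law overtakes the power-law regime for the wide-confinement fit
parameters.

The same chain is available from the shell:

```sh
npcvoid run --config config.yaml --seed 3 --outdir out/
```

which writes occupancy and PMF profiles (TSV), the percolation curve, an
MFPT table, the scaling-law fit (JSON) and a checksummed manifest.

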