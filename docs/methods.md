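# Methods

## The model

`npcvoid` treats passive transport through the nuclear pore's disordered
FG-nucleoporin mesh as a purely geometric problem. The central assumption is
that a globular probe interacts with the mesh sterically only: the
probe–mesh interaction energy is +∞ on overlap and 0 otherwise. Under that
assumption the probe's equilibrium statistics along the pore axis are fixed
entirely by the volume the mesh leaves open, so everything — free-energy
profile, open-path probability, transport rate — can be computed from an
ensemble of *probe-free* mesh configurations. What the model deliberately
does not describe: specific probe–nucleoporin binding (facilitated
transport), non-spherical probes, disordered/polymeric cargo whose
entanglement with the mesh matters, and many-probe crowding.

## Void analysis

Space is partitioned into cubic voxels of side `l_c` (default 6 Å for
free-energy work; 1–3 Å recommended for connectivity, where the path
topology is sensitive to voxelization). For each voxel center the clearance
radius `R_max` is the smaller of

* distance to the nearest chain-bead *center* minus the 3 Å bead radius, and
* center-to-center distance to the nearest voxel whose steric potential
  (envelope, scaffold, confinement) exceeds 1e-9.

A voxel is accessible to a probe of radius `R_p` iff `R_max >= R_p`. The
bead term is evaluated with a k-d tree, the exclusion term with an exact
Euclidean distance transform; both reproduce an explicit brute-force scan
exactly (tested). Voxels inside an exclusion carry the sentinel −1 so that
even a point probe cannot sit there; a completely empty world is +∞
(clamped to ±1e30 when written to MRC/DX files).

Two conventions were genuinely open and are fixed as follows: the excluded
voxel is treated as a point at its center (the alternatives differ by at
most one voxel and vanish under refinement), and a voxel belongs to the 1D
profile cylinder iff its *center* is inside.

## Occupancy → potential of mean force

The void map is reduced to per-slab counts `h(z)` of accessible voxels whose
centers lie in a coaxial cylinder of radius `profile_radius` (default the
confinement radius). The ensemble mean over frames is Boltzmann-inverted,

    F(z) = -kT ln<h(z)> + kT ln(A_c * slab_height / l_c^3),

where `A_c = pi * profile_radius^2`. With one voxel layer per slab the
offset reduces to the textbook `kT ln(A_c / l_c^2)`; the generalized form
keeps the far field at exactly zero for thicker slabs. Slabs with zero mean
occupancy are hard walls: they carry +∞, never a large float, and the
transport solver treats them as disconnecting.

On an analytic hard constriction (annulus of inner radius a inside
confinement R_c) the pipeline reproduces the closed-form plateau
`-ln((a-R_p)^2/R_c^2)` to 0.07 kT at 6 Å voxels and 0.015 kT at 3 Å; the
residual is the half-voxel bias of the voxelized obstacle surface.

Trace-derived profiles (`pmf_from_trace`) invert a position histogram and
are zeroed over an explicit far-field window (default |z| ∈ [450, 550) Å;
the occupancy route needs no window because its offset is exact).
Symmetrization averages the *probabilities* P(z) and P(−z) and re-inverts,
which conserves normalization exactly; the mean point-by-point
|F(z) − F(−z)| of the raw profile is retained as the sampling-quality
figure and doubles as the uncertainty of the barrier height (the mean F
over |z| < 50 Å).

## Percolation

Accessible voxels are partitioned by union-find with path compression
(numba kernel; validated against BFS flood fill and
`scipy.ndimage.label`). Face adjacency (6-connectivity) is the default
because a spherical probe cannot pass through an edge or corner contact;
26-connectivity is available for sensitivity analysis. A configuration has
an open path when one component intersects both the source layer (default
z = +200 Å; ±70 Å on the toy fixture) and the sink layer. The open-path
probability over an ensemble gets a Clopper–Pearson 95% band, and the
percolation radius is reported as the linear interpolation of the p = 0.5
crossing together with its bracketing grid interval — the curve, not the
scalar, is the primary object.

## First-passage kinetics

The 1D Smoluchowski equation is discretized on nodes spaced `d` (default
0.5 Å on the production domain −600…+200 Å, start −200 Å) as a
nearest-neighbour master equation with rates
`k = (D_n + D_m)/(2 d^2) * exp(-(V_m - V_n)/2)` (energies in kT), which
satisfies detailed balance identically. The left boundary is reflecting in
the no-flux convention (the two leftmost nodes do not exchange), the right
node is absorbing (density pinned at zero). Explicit Euler marching with
`dt = 0.8 / max(total out-rate)` — comfortably inside the `D dt/d^2 < 1`
stability bound — accumulates the absorbed mass per output bin; the
first-passage density g(t) is that increment divided by the bin width
(algebraically the time derivative of total mass, numerically stabler), and
the MFPT is Σ t·Δm plus an exponential tail correction estimated from the
terminal survival decay. Integration blocks extend adaptively until the
surviving probability falls below 1e-3; block length is sized from the
exact MFPT of the same rate matrix, obtained by a tridiagonal adjoint
solve. That adjoint solve is also exposed (`mfpt_exact`) and is what the
pipeline uses for radius sweeps, where barriers of 10+ kT make
time-stepping prohibitively long while the mean remains a single linear
solve; the two routes agree to 0.5% or better wherever both are feasible
(tested).

Position-dependent diffusivity follows the Fick–Jacobs picture:
`w = sqrt(A/pi)`, slope by central differences, and either
`D = D0/sqrt(1+w'^2)` (Reguera–Rubi, default) or `D = D0/(1+w'^2/2)`
(Zwanzig). Since `sqrt(1+s^2) <= 1+s^2/2`, Zwanzig is the slower model
everywhere; swapping models changes the MFPT by a bounded factor (about 1%
on the test channel), consistent with the choice having little influence.
Bulk D0 defaults to Stokes–Einstein in water at 298.15 K
(`D0 ≈ 2.447e5/R_p` Å²/μs) — an explicit approximation; measured values
can be passed instead. An Euler–Maruyama walker oracle with the spurious
drift term `dD/dz` provides an independent stochastic check.

## Scaling law and crossover

`ScalingLawModel(radii, taus).fit()` minimizes least squares in ln τ — a
multiplicative noise model that weighs the power-law and exponential
regimes commensurately (the loss was an open choice) — over
log-parametrized (τ0, R0, α) with five deterministic jittered starts to
avoid the stretched exponential's local minima; the +3 Å residue offset is
a fixed constant, not fitted. The results object carries the delta-method
standard errors, residuals, `summary()`, and the crossover radius: the
upper root of `ln R = ((R+3)/R0)^alpha` by bracketed Brent iteration
(tolerance 1e-3 Å by default). For R0 = 19.8 Å, α = 1.89 the root is
35.9 Å. Mass ↔ radius conversion interpolates monotone-cubically in
log–log space through three reference-protein anchors (6.5, 11.7, 62 kDa →
12.75, 15.71, 30.04 Å); the inverse is obtained by root-finding on the
forward interpolant so round trips close to <0.1%.

## Trace statistics

Boundary crossings of z = ±200 Å are located by linear interpolation
between samples, so durations are exact for piecewise-linear traces. A
first passage runs from the *first* entry into the pore volume (after the
last completed passage) to the exit on the opposite side, including any
meandering back out of the entrance side; a crossing runs from that exit
back to the last prior crossing of the entrance boundary, and is therefore
always contained in, and no longer than, its first passage. Events
truncated by the end of a trace are discarded, not censored-corrected.
Whether pooled replicas are merged before or after event extraction was
unstated; events are pooled.

## Synthetic mesh generator

The generator emulates the *initialization* of a bead-per-residue mesh:
each chain is a self-avoiding random walk with exact 3.8 Å bonds, grown
from its anchor, rejecting candidates within 8 Å of another chain's beads,
within 6 Å (two bead radii) of a non-bonded bead of the same chain, or —
for beads at least three residues from the anchor — inside any non-zero
steric potential. Anchors are placed exactly (the harmonic anchor
restraint of a dynamical simulation applies only to dynamics, which are
out of scope); anchor sites of not-yet-grown chains are kept clear so the
growth order does not strand later chains. Linker species with both
termini restrained are grown as bridges: each step is rejected unless the
end anchor remains reachable with the remaining bonds, and the final two
beads are placed by exact sphere–sphere intersection. Frames are
independent draws from deterministic per-chain seed streams keyed by
(frame, species, copy), so deleting a species leaves the other chains'
streams — and, in dilute meshes, their coordinates — unchanged. An
optional bond-preserving single-bead Monte-Carlo relaxation is available.

What the ensemble does *not* emulate: the cohesive inter-residue force
field, Langevin dynamics, millisecond equilibration, and the resulting
sequence-specific condensation of the real mesh. Independent self-avoiding
draws are more homogeneous and less clustered than an interacting mesh at
equal density. Tests passing on this ensemble therefore validate the
void/percolation/PMF/transport machinery — which is agnostic to how the
ensemble was produced — not the conformational statistics of any real
pore.

Built-in stoichiometries reproduce the published compositions: 32 copies
each of five species (160 chains) for the composite model; 200 chains over
nine species for the yeast model; and the extended yeast variant that adds
two species plus three double-anchored linker domains for ≈29% more
residues (the one unrestated copy number is inherited from the base
model). Anchor coordinates use a deterministic synthetic ring layout
(8-fold symmetric rings at 220 Å radius) because the experimentally
derived scaffold coordinates are cluster-scale inputs not shipped here;
`load_stoichiometry` accepts YAML/JSON files carrying real anchors.

Auxiliary statistics: interchain contact fraction (two residues of
different chains within 8 Å), mass density maps (120 Da, 3 Å beads, binned
per voxel, optional exact C8/C8-plus-mirror symmetrization by coordinate
replication, output in mg/mL), and the charge-to-hydrophobicity ratio
(|mean net charge| with K/R = +1, H = +0.5, D/E = −1, over mean
Kyte–Doolittle hydropathy rescaled to [0, 1] — the scale was unstated, so
this pinned convention may shift absolute values relative to other
implementations even though FG-domain sequences still score < 0.3).

## Geometry

The nuclear envelope midsurface is the printed parametric curve
`(r − 0.6B)^2 + 4z^2 = B^2` (B = 300 Å) for |z| < 97.2 Å, with the radial
center translated outward by `(|z| − 97.2)^2` beyond that to flatten the
corners. Two unit quirks are implemented as printed and flagged: the
flattening term adds a squared length to a length, and 97.2 is taken to be
in Å (consistent with B). The membrane potential is a linear repulsive
ramp in distance from that surface, 15 kcal/mol on the surface falling to
zero over `wall_softness` = 10 Å — reproducing the documented 0–15
kcal/mol range without any all-atom membrane construction. Scaffold
potentials convolve the voxel-binned number density of each residue type
with tabulated radial kernels via FFT (default 6 Å grids); the shipped
default kernel is a single soft-core repulsion for all pairs, since the
published pair tables live in an out-of-scope force field, and custom
tables can be loaded. The confinement is zero inside a coaxial cylinder
(500/250 Å radius, 1200 Å height) with a harmonic 0.01 kcal mol⁻¹ Å⁻²
penalty on the overshoot.

## Problem sizes and numerical defaults

The shipped tests and the pipeline default to a desk-scale fixture — 8–12
chains of 40–60 residues in a ~50 Å confinement, 3–8 frames, 3 Å void
voxels — chosen so the full chain (mesh → voids → percolation → PMF → MFPT
→ fit) exhibits the percolation transition and the scaling crossover while
completing in seconds. The production-scale defaults (6 Å PMF voxels, 1 Å
connectivity voxels, −600…+200 Å solver domain at d = 0.5 Å, ±200 Å
source/sink) are retained wherever cost permits, e.g. the flat-potential
solver validation runs on the full 800 Å domain at d = 0.5 Å. All
randomness flows from explicit integer seeds; reruns are byte-identical.

## Known limitations

* Independent-draw ensembles understate mesh cohesion (above).
* The no-flux reflecting convention places the effective wall half a node
  inside the domain — an O(d) boundary effect, negligible on the 800 Å
  production domain but visible on very short toy domains.
* Stokes–Einstein D0 ignores protein shape anisotropy and rotational
  coupling.
* The percolation point estimate at p = 0.5 is an artifact-defined summary
  of a curve that is the real result.
* MRC headers store the corner origin in the origin words; software that
  expects nstart-based origins will see a zero offset.
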