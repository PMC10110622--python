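# Methods

This note documents the models, conventions and design choices behind
`poregate`, in the spirit of a simulation package's methods appendix.

## Geometry and units

All internal quantities are nm, ps, degrees and kJ/mol; energies are
reported in units of k_BT (T = 300 K by default), currents in pA,
voltages in mV. The central cavity is a closed cylinder: a particle is
inside when `z_lo <= z <= z_hi` and `r <= radius`, where (z, r) are its
axial and radial coordinates in the pore-axis frame. The +axis points
from the intracellular (lower) anchor toward the extracellular (upper)
anchor, so an ion "entering the cavity" from the cytoplasm moves toward
+z. The axis is resolved from the centroids of two anchor selections;
because crystallographic anchors fluctuate, the geometry can be fixed
from a reference frame (the default: resolve once on frame 0 via
`TrajectoryHandle.frame(0)`) or re-resolved on any frame of interest —
`resolve_pore_geometry` is a pure per-frame function either way.
Coincident anchor centroids raise a degenerate-axis error rather than
guessing. Minimum-image distances assume orthorhombic boxes; triclinic
input is rejected.

The exact cavity bounds and radius are deliberately *required
configuration*, not constants: the right choices depend on the channel
and on which binding sites (e.g. the cavity Sc site) should fall inside
the region.

## Hydration statistics

Occupancy series use the sample (n−1) standard deviation;
s.e.m. = sd/sqrt(n_frames). The relative standard deviation
rsd = sd/mean is the dewetting indicator: a cavity flickering between
wet and dry states has a large rsd even when its mean looks moderate.
Note that for autocorrelated trajectories sd/sqrt(n) understates the
uncertainty of the mean; where the package itself needs a defensible
error bar (the occupancy-vs-quadrature validation), it uses a 20-block
block-average s.e.m. instead.

Residence times are maximal runs of consecutive in-cavity frames per
particle, with a configurable gap tolerance (default 0: a single
excursion frame ends a dwell — the strictest, most reproducible
definition). Runs touching either trajectory end are flagged censored
rather than silently kept or dropped.

Axial density profiles are tallies over uniform z-bins inside the
cylinder radius, normalised by `n_frames * pi * radius^2 * bin_width`;
the bulk density comes from a disjoint axial slab of the same cylinder.
The axial–radial map normalises by the cylindrical shell volume, and
integrating it over r reproduces the axial profile to machine precision
(this identity is tested). Solvation shells default to r1 = 0.36 nm and
r2 = 0.61 nm, the usual first and second minima of the K+–water-oxygen
radial distribution function; both are configurable.

## Permeation counting

A permeation event is a full traversal established by a per-ion
three-compartment state machine: below (z < z_lo), inside (in the cavity
cylinder), above (z > z_hi). Only below → inside → above (+1) or
above → inside → below (−1) sequences count. Two guards remove
artifacts: frames in the axial range but outside the radial cutoff mark
an around-protein path and invalidate the passage until the ion
re-enters an outer compartment, and axial jumps larger than half the box
length are treated as periodic wraps that reset the state machine (so
box recycling can never masquerade as conduction). Traversals truncated
by the trajectory ends are not counted — an unbiased rate at the cost of
a little edge data. The current is
`I = (n_up − n_down) * e / T` converted to pA; replica currents pool to
mean ± s.e.m. Full-traversal counting (rather than flux integration) is
robust to recrossing noise and is the standard accounting in channel MD.

## Boltzmann inversion

`F(z) = −ln(rho(z)/rho_ref)` in k_BT, gauged so that F averages to zero
over a user-chosen reference slab (bulk-like solvent). Zero-count bins
are masked undefined, never clamped: a sampled zero only bounds the
barrier from below, and clamping would fabricate barrier heights.
Barrier height is the window maximum minus the minimum on its
intracellular (low-z) side — the climb faced on entry — not the global
minimum, which may sit past the barrier. Inversion presumes equilibrium;
profiles of field-driven species are refused unless explicitly
acknowledged (`driven=True`, with a warning). Default bin width 0.05 nm
resolves ~0.5 nm features at toy sampling depths (the validation runs
use 0.1 nm, trading resolution for per-bin counts).

## Order parameters

Superposition uses the Kabsch SVD solution restricted to proper
rotations (the smallest singular direction is flipped when the optimal
orthogonal matrix would be a reflection). Average structures are built
by iterative superposition — fit all frames to frame 0, average, re-fit
to the running mean (2 passes) — which removes the reference-choice bias
deterministically. Hydrogen bonds are reported as acceptor-O to donor-H
distances only, no angular criterion, because the observable of interest
is the bond-length distribution at the inner-helix kink. The side-chain
orientation is the angle between the Cα → tip-centroid vector and the
pore axis (tip = aromatic-ring atoms for Phe-like residues), which is
monotone in the swing of the side chain between cavity-facing and
interface-facing poses; the realisation is echoed into output metadata.
Diagonal Cα–Cα distances use minimum-image conventions; both tetramer
diagonals are available. The atom pairs behind labels like "297O-301HN"
are configuration, not constants.

## Chain reaction coordinate and dummy repulsion

The cavity cylinder is cut into `n_slices` axial slices. Each slice gets
a smooth occupancy `n_i = sum_w f_ax(z_w − z_i) * f_rad(r_w)` using C1
cosine-ramp switching functions (plateau 1 inside, half-cosine decay
over the ramp, 0 beyond). A smoothstep saturation
`h_i = S(min(n_i/n0, 1))`, `S(u) = 3u² − 2u³`, maps occupancy to a
hydrated degree, and the coordinate is the mean of cumulative products
along the fill direction:

    xi = (1/n_slices) * sum_i prod_{j<=i} h_j .

The sequential product is what makes the coordinate "slice by slice": a
slice contributes only when every slice nearer the fill end is hydrated,
so a harmonic restraint `U = k/2 (xi − xi_target)²` wets or dries the
cavity in spatial order instead of uniformly. xi is exactly 0 for an
empty cylinder, 1 when all slices are saturated, and k/n_slices when the
first k fill-order slices are saturated; it is invariant under water
permutation and never exceeds the plain hydrated-slice ratio. Forces are
the analytic chain-rule gradient through S and the switching functions
(saturated slices contribute zero derivative); they match central finite
differences to better than 1e-4 relative and satisfy the work–energy
identity along scripted displacements. These concrete functional forms
(cosine ramps, smoothstep, sequential product, harmonic restraint) are
this package's realisation of the slice-ratio coordinate contract —
continuous, differentiable, bounded — and all parameters echo into
output metadata. Defaults (`n_slices = 10`, `n0 = 4`,
`ramps = 0.05 nm`, `k = 5000 kJ/mol`) give smooth gradients at toy
scale.

Dummy-atom repulsion is a flat-bottom half-harmonic
`U = k_rep/2 (r_cut − r)²` for r < r_cut from a fixed site, with radial
forces (minimum image); it serves both uses of such sites — repelling
waters from a kink region to promote backbone hydrogen-bond re-formation,
and keeping lipid-tail carbons out of the cavity. A target exactly at
the site has an undefined direction and receives zero force (a measure-
zero tie-break). Forces are for analysis and the toy integrator only; no
MD-engine plugin compatibility is claimed.

## The toy-pore simulator

The generator emulates the *statistical structure* the analyses assume,
not molecular physics. Defaults: 400 waters, 12 ions, a 6×6×9 nm
periodic box, cavity z ∈ [3.5, 5.5] nm with radius 0.8 nm,
D = 0.05 nm²/ps, dt = 0.05 ps, 20,000 steps saving every 40th frame
(500 frames, 2×10⁵ water-position samples per run). Particles are
non-interacting and follow overdamped (Euler–Maruyama) Langevin
dynamics, `x ← x − D ∇u dt + sqrt(2 D dt) η` with u in k_BT. Waters feel
a z-only barrier: a cosine-ramped plateau of height B_w spanning the
cavity (ramp half-width 0.5 nm). Ions feel their own barrier B_i minus a
constant tilt (the voltage analogue). All boundaries are periodic; the
axial wrap doubles as reservoir recycling, sustaining a steady driven
flux. A stability guard rejects steps with `sqrt(2 D dt)` beyond half
the ramp width. Initial positions are drawn from exp(−u) by rejection
sampling, so runs start at equilibrium; D and dt were chosen once so a
run both mixes across the box and keeps the Euler–Maruyama
stationary-density bias well below the 0.3 k_BT validation band.

Telegraph wetting multiplies the water barrier by the hidden two-state
process (wet: barrier off; dry: barrier on) with switching rates k_wet
and k_dry per ps; the hidden state sequence is exported with the ground
truth so dwell-time and fluctuation analyses have an exact oracle. The
quadrature occupancy oracle
`N * A_cav ∫_cav e^{−u} / (A_box ∫_box e^{−u})` is valid for untilted
waters with wetting off.

The scaffold is a rigid pseudo-tetramer: four chains, each carrying kink
backbone O/HN sites (297/298 carbonyls against 301/302 amides), an
F304-like Cα and a side-chain tip. The closed template has a tighter
Cα ring (diagonal 2.0 vs 3.0 nm), shorter kink H-bonds (0.20/0.22 vs
0.50/0.45 nm) and uniform inward-pointing side chains (zero angle
spread); `morph(λ)` interpolates linearly with exact endpoints. The
scaffold is static during dynamics — conformational *series* come from
analysing morphs or templates, not from simulated protein motion.

Because the toy box contains no protein wall, ions diffuse radially
without confinement; the permeation detection region for synthetic runs
is therefore the axial slab cylinder covering the whole box cross-
section (`SyntheticPoreParams.detection_geometry()`). The radial
around-protein guard remains fully exercised by scripted-path tests.

What the toy does *not* emulate — water–water cooperativity (wetting
transitions arise from the imposed telegraph process, not collective
physics), explicit lipids, protein flexibility, electrostatics beyond
the constant tilt, and absolute magnitudes (microsecond all-atom scale
currents of ~14 pA or cavity populations of ~60 waters are out of reach
at desk scale). Passing tests therefore demonstrate correctness of the
*measurements* — counting, event detection, inversion, gradients,
statistics — under known ground truth, not realism of any particular
channel.

## Reproducibility and problem sizes

Every stochastic routine takes one seed feeding a single PCG64
generator; equal seeds give bitwise-identical systems and trajectories.
The validation suite uses desk-scale problem sizes chosen for tight
oracles: 2×10⁵ samples for potential recovery (max |ΔF| ≤ 0.3 k_BT),
10 seeds per condition for ordering claims (sign tests at p < 0.05
across barrier heights {0, 2, 4} k_BT), and 100 random configurations
per brute-force oracle comparison. `scripts/acceptance.py` re-derives
all headline numbers from scratch at these sizes.

## Known limitations

- Streaming analyses assume a constant particle count and stable
  particle identities across frames.
- The permeation state machine's wrap detection relies on frames being
  saved densely enough that genuine axial displacements stay below half
  a box length.
- Boltzmann inversion of telegraph-modulated runs mixes two ensembles;
  the result is the log of a mixture density, not either branch's PMF.
- `rsd` is undefined (None) for zero-mean series; callers must handle
  the flag.
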