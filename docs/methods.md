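# Methods

This note records the models and procedures implemented in poregate, the
defaults and why they were chosen, what the synthetic generators do and do
not emulate, and the numerical choices a maintainer would want to know.

## Coordinate conventions and units

All axial analyses run in a canonical frame: the centre of mass of a
reference selection (in channel work, the backbone of the residues at the
selectivity-filter entrance) defines the origin, the principal axis of a
pore-bundle selection defines +z, and the sign is chosen so the cavity lies
at positive z ("distance below the filter" is a positive number).
`align_to_pore_axis` performs this per frame by default; a fixed-lab-frame
variant (`per_frame=False`) applies the first frame's transform throughout,
since trajectory superposition conventions differ between studies.  The
rotation about the pore axis is an unconstrained degree of freedom; all
quantities computed here are invariant to it.

Lengths are in angstroms, times in picoseconds, energies in kcal/mol with
k_B = 0.0019872041 kcal mol⁻¹ K⁻¹ and T = 298 K by default.  Umbrella
spring constants are accepted in kJ mol⁻¹ nm⁻² (the unit restraint forces
are usually reported in) and converted internally.

## Pore-radius profiling

The profile r(z) is the radius of the largest sphere centred in the plane
at z that touches no atom:
r(z) = max_c min_i (|c − x_i| − R_i), with c constrained to the plane.
Contact is three-dimensional: every atom with |z_i − z| ≤ r_max + R_i
participates, not just atoms cut by the plane — a 2-D slice approximation
would overestimate radii near constrictions.  Hard-sphere radii are a
Bondi-type element table (H 1.20, C 1.70, N 1.55, O 1.52, S 1.80, P 1.80 Å,
default 1.70), overridable from a two-column file; published radius sets
differ, so profiles from different radius tables should not be compared
numerically.

The in-plane maximisation uses simulated annealing (5 restarts, 250 steps,
step size cooling 1.0 → 0.02 Å, temperature 0.3 → 0.003 Å) followed by a
deterministic Nelder–Mead polish; all randomness is seeded, and identical
seeds give bit-identical profiles.  One subtlety dictates the design: the
clearance objective is *globally* unbounded — far outside the structure
every centre is far from all atoms — so the maximisation must be local.
Candidates are rejected beyond a trust radius (default 4 Å) from the slice's
initial centre, and slices are traced sequentially from z_min to z_max,
each initialised at the previous slice's optimum (the first at the axis).
Slices reaching the cap r_max = 15 Å are flagged "open to bulk".  On
≤ 500-atom fixtures the optimiser agrees with an exhaustive 0.01 Å grid
search to 0.02 Å.

Replicate averaging (`average_profiles`) reports the per-z mean with either
the sample standard deviation among sources (ddof = 1) or its standard
error; a single source yields zero spread with a logged warning.

## Pore hydration and dewetting kinetics

Pore water is defined geometrically: water oxygens (residue names HOH,
TIP3, SOL, WAT by default) between two bounding planes, each the COM of a
ring selection recomputed every frame, and within a lateral cylinder
(default radius 10 Å) around the axis through the two plane COMs.  The
cylinder is needed because bulk water occupies the same axial range as the
cavity; defining the axis by the plane COMs (rather than the lab z-axis)
makes the count exactly invariant under rigid motions of the whole frame.
Whether the upper plane is the whole-residue ring COM or the Cα ring is a
selection-level choice; the default examples use whole-residue COMs.

State classification is scale-free: given a wet-reference count N_wet
(e.g. the mean over a declared fully-wet segment), a smoothed count n is
dry if n ≤ 0.15·N_wet, semihydrated if n ≤ 0.6·N_wet, wet otherwise, with a
5-frame centred moving average (window shrinking at the edges).  The
fractions encode the observed hydration levels of fully wet (~N_wet),
semihydrated (~N_wet/2) and essentially dry pores without binding the
classifier to any particular channel's absolute counts.

Dewetting kinetics uses the autocorrelation of the water count,
C(τ) = ⟨N(t)N(t+τ)⟩ / ⟨N²⟩, with numerator and denominator pooled over all
supplied trajectories and **no mean subtraction**: the plateau
⟨N⟩²/⟨N²⟩ then separates partial from complete dewetting (a series that
never dries plateaus near 1; one that spends most time dry decays toward
0), which mean-subtracted ACFs cannot show.  A mean-subtracted variant is
available behind a flag.  C(0) = 1 exactly by construction.  Finite-sample
caveat: the lag-τ numerator averages T−τ pairs while the denominator
averages T points, so on short, strongly periodic series C can exceed 1 by
up to the sharp bound T/(T−τ); for stationary series at lags well below the
series length — the regime the statistic is meant for — C stays in [0, 1].
The across-trajectory standard error is reported when several series are
supplied.

## Free-energy profiles

**Boltzmann inversion.**  G(z) = −k_BT ln(ρ(z)/ρ_bulk), with ρ the per-bin
mean occupancy inside the lateral cylinder and ρ_bulk the mean over an
explicit, caller-chosen bulk z-range (there is no universal convention for
the bulk region, so it is a required parameter).  Zero-count bins are set
to a cap (default 10 kcal/mol) and their indices recorded; they are
excluded from all downstream fits.  On noiseless ρ₀e^(−U/k_BT) input the
inversion returns U to machine precision.

**WHAM.**  Windows are harmonic restraints U_i(z) = k_i/2 (z − z_i)² at a
ladder of centres.  The self-consistent equations are iterated in log space
(logsumexp throughout):

    ln p_b = ln Σ_i h_ib − ln Σ_i N_i exp[(f_i − c_ib)/k_BT]
    f_i = −k_BT ln Σ_b p_b exp(−c_ib/k_BT),   f_1 ≡ 0

until the largest change in f_i is below 1e-8 kcal/mol (max 10⁵
iterations; a 13-window problem converges in a few hundred).  Default bin
width 0.2 Å — fine enough that discretisation sits well below the
statistical error at realistic sample counts.  The PMF is referenced to its
minimum; unvisited bins are capped and flagged.  Windows whose histograms
share no occupied bin with their neighbour leave the PMF pieces determined
only up to independent constants, so the result is marked unconverged with
a coverage diagnostic.  The estimate is invariant under window reordering,
and merging two windows with identical centre and spring is identical to
concatenating their samples.

**Errors.**  Uncertainty is estimated by the split-half scheme: the
estimator runs on the first and second halves of every window's samples,
the two half-profiles are aligned by the constant minimising their squared
difference over mutually valid bins (profiles are defined up to a
constant), and err(b) = |G₁(b) − G₂(b)|/2, the standard error of the
two-estimate mean.  Bins capped in either half are flagged rather than
scored.  On stochastic double-well fixtures the RMS split-half error
tracks the spread across independent replicates to well within a factor
of 3.

**Stitching.**  A single-ion umbrella PMF is valid only where the
single-occupancy assumption holds (the dewetted segment); the
bulk-connected side comes from equilibrium densities.  `stitch_pmf` shifts
the equilibrium profile by the least-squares constant over a declared
overlap range, then blends with a weight linear in z across the overlap —
umbrella below, equilibrium above.  "Linear interpolation" between two
profiles admits several readings (single-junction concatenation,
overlapping-bin interpolation); the linear crossfade was chosen as the
simplest continuous one and is recorded per bin in the output's provenance
array.  The overlap placement is the accuracy bottleneck: if it sits in a
poorly sampled region (e.g. a barrier top), the alignment constant
inherits that noise and offsets the entire far segment.

## Water-exposed surface areas

Accessible areas use a Shrake–Rupley estimator: 960 points per atom by
default on a golden-spiral lattice rotated by a seeded random rotation
(deterministic given seed; doubling the point count moves totals by
< 0.5 %), probe radius 1.4 Å (the water-probe convention).  A point on
atom i's accessible sphere (radius R_i + probe) is exposed if outside
every neighbour's accessible sphere.  Atoms are classified by a
first-match rule table — carbons and sulfurs hydrophobic; N, O, P polar;
hydrogens inherit the class of the nearest heavy atom within 1.6 Å — so
hydrophobic + polar = total by construction.  `pore_exposed_area`
restricts the tally to sample points inside the pore-region cylinder
(atoms straddling the boundary contribute only their pore-facing surface)
and can include lipid molecules with any atom within a cutoff (default
10 Å) of the pore-lining helix selection, since lipid tails penetrating
between splayed helices form part of the cavity lining.  Absolute areas
depend on the aggregation convention (single frame vs trajectory
accumulation, per subunit vs whole pore), which varies between studies;
this module is validated against closed-form sphere/two-sphere areas and
its own invariants, and comparisons between states should use a fixed
convention.

## Synthetic generators

The generators provide exact or analytically characterised ground truths;
they are first-class, tested code, not throwaway fixtures.

**Toy nanopore.**  Reduced units (σ = bead diameter, k_BT = 1, friction 1).
Two solvent reservoirs in a periodic box, joined by a cylindrical channel
through a fixed-atom wall slab: a unit lattice carved at hole radius
R + 0.4 σ plus explicit lining rings at exactly that radius (spacing
≤ 0.7 σ, leak-proof), so the solvent-accessible radius is ≈ R − 0.5 σ by
construction and the nominal R is the counting radius.  Solvent–solvent
interactions are purely repulsive WCA; solvent–wall adds a
truncated-shifted attractive well of depth ε_wall beyond the repulsive
core (ε_wall = 0 is the hydrophobic limit; one scalar knob spans the
hydrophobic → hydrophilic contrast).  Dynamics are overdamped
Euler–Maruyama with dt = 5e-4 (stability bound 2e-3; the conservative
per-step displacement is additionally capped at 0.25 σ, which only
engages during rare core overshoots), periodic minimum-image boundaries,
exactly reproducible from the seed.  The default runs used for the phase
behaviour are 30 000 steps sampled every 40 with the first 25 % discarded
— several pore-length diffusion times, enough to resolve occupancy
statistics for ~160–400 beads at bulk density ~0.3 σ⁻³.

The diagnostic is the *wetting fraction*: the share of frames whose
channel occupancy (beads within the nominal cylinder) exceeds half the
bulk-expected occupancy ρ_bulk·πR²L, with ρ_bulk measured per frame in the
reservoirs.  A narrow (R = 1.2 σ) repulsive channel is predominantly dry
(entropic exclusion: the accessible radius is far below nominal), a wide
(R = 4 σ) or attractive channel stays wet, and the fraction rises
monotonically with ε_wall.  This reproduces the qualitative
radius/hydrophobicity sensitivity of model-nanopore wetting.  What it does
*not* emulate: real water's hydrogen-bond network and liquid–vapor
coexistence (purely repulsive WCA beads have no vapor phase), so there are
no collective drying *transitions* with hysteresis, no protein
flexibility, and no mapping of σ to angstroms.  Passing these checks
validates the analysis contracts and the direction of the physics, not any
absolute number of a real channel.

**Umbrella samplers.**  Windows are drawn exactly from
p_i(z) ∝ exp(−[U(z) + k/2 (z−z_i)²]/k_BT): closed-form Gaussians for flat
and harmonic truths (complete-the-square), rejection sampling against a
uniform proposal with a grid-maximum envelope for quartic/tabulated
truths.  Since samples are exact, estimator error measured against the
truth is pure estimator error — no MD sampling confound.  The canonical
validation truth (`double_well_truth`) is a quartic
U = a((z−18)² − 144)² with wells at z = 6 and 30 Å and a 5 k_BT central
barrier: the wells sit at the ends of the 13-window, 2 Å ladder so every
window samples near its own centre, the shape of a permeation barrier
across a dewetted segment.  With a 100 kJ mol⁻¹ nm⁻² spring the bias
curvature (0.239 kcal mol⁻¹ Å⁻²) exceeds the truth's maximum negative
curvature (|−4ab²| ≈ 0.082), so every window is properly confined — the
standard spring-selection criterion for umbrella sampling.

**Telegraph series.**  A discrete-time two-state Markov chain (levels
N₁, N₂, rates k₁₂, k₂₁ per ps, dt·max(k) < 0.1 enforced) with geometric
sojourns and a stationary start, generated by vectorised geometric draws.
Its autocovariance is Var(N)·e^(−(k₁₂+k₂₁)τ), giving the closed-form
target for the water-count ACF:
C(τ) = (⟨N⟩² + Var·e^(−(k₁₂+k₂₁)τ)) / ⟨N²⟩.

**Geometry fixtures.**  Stacked rings (cylinder) and linearly varying
rings (funnel) with inscribed radii known by construction.  For the
funnel, the maximal inscribed sphere touches the wall obliquely, so the
analytic radius is the perpendicular wall distance
r(z)/√(1+m²) − R_atom (m the wall slope) — still linear in z.

## Known limitations

- The profiler traces a straight, z-aligned centre line; curved pathways
  or side channels are out of scope.
- WHAM is one-dimensional; no MBAR estimator is provided.
- The SASA point estimator is O(n_atoms · n_points · neighbours) in
  Python/numpy; it is sized for cavity-scale selections, not proteome
  scans.
- Absolute SASA totals and HOLE-profile values depend on radius tables and
  aggregation conventions; only within-convention comparisons are
  meaningful.
- The toy nanopore validates contracts and qualitative phase behaviour
  only (see above).
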