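# Methods

## The model

Each nucleotide is a rigid body with centre-of-mass position **r** and an
orthonormal right-handed frame (**a1**, **a2**, **a3**): **a1** points from
the backbone through the base (the base-face direction), **a3** is the
stacking normal, **a2** = **a3** × **a1**. Three interaction sites are rigid
functions of the pose, displaced along **a1**: backbone at −0.4, stacking
site at +0.34 and hydrogen-bonding site at +0.4 (simulation length units).

Simulation units follow the published oxDNA conventions: one length unit is
0.8518 nm, and the temperature scale is chosen so that thermal energy in
simulation units is kT = T[K]/3000 (0.1 at 300 K); one energy unit is
5.9616 kcal/mol. Mass and moment of inertia are set to 1.

The potential is a sum of pairwise terms:

| term | between | radial form | orientation factors |
|---|---|---|---|
| backbone | bonded backbone sites | FENE, r₀ = 0.7241, Δ = 0.25, ε = 2 | — |
| stacking | bonded stacking sites | switched Morse, r₀ = 0.4210 | normals parallel |
| hydrogen bonding | non-bonded base sites, WC identities only | switched Morse, r₀ = 0.40 | normals antiparallel; both base faces point along the separation |
| cross-stacking | non-bonded base sites | switched Morse, r₀ = 0.545, shallow | normals antiparallel |
| coaxial stacking | non-bonded stacking sites (off by default) | switched Morse | normals parallel |
| excluded volume | non-bonded site pairs | WCA repulsion (σ 0.60/0.30/0.45) | — |

The Morse wells are truncated by a C¹ switching polynomial between
r_switch and r_cut; the orientation factors are C¹ clamped quadratics
((c − c₀)/(1 − c₀))² in the relevant cosine, zero beyond the threshold c₀.
These smooth forms are this package's own members of the model family: the
published reference parameterizations use piecewise-assembled modulation
functions whose full constant tables are not reproduced here, so the
package keeps the published headline constants — FENE spring, hydrogen-bond
depth 1.077 (average variant) or 0.88537/1.23238 for A·T/G·C
(sequence-dependent variant), stacking depth 1.3448 + 2.6568 kT — and
substitutes smooth, analytically differentiable angular envelopes, fixed by
the structural tests (a built duplex is a near-minimum; all native bonds
survive relaxation; low-temperature duplexes are stable and high-temperature
ones melt). Consequences: the model's absolute melting temperatures do not
match the reference code's (a 5-bp duplex here is stable at 300 K and melts
by 700 K), so all temperature-dependent statements are made within this
parameterization, and quantitative comparisons are made for ratios,
probabilities and directions rather than absolute temperatures or rates.

The sequence-dependent stacking factors are nearest-neighbour weights
normalized to mean 1, derived from the standard nearest-neighbour duplex
thermodynamic scale; the hydrogen-bonding depths carry the main
sequence effect (G·C ≈ 1.39 × A·T). Electrostatics is not explicit: the
parameterization represents a fixed high-salt condition, with screening
folded into the short-ranged excluded volume. The FENE spring is extended
linearly beyond 0.99 Δ so the energy stays C¹ with a consistent gradient;
the integrator's blow-up guard handles anything that strays out there.

Forces and torques are exact analytic gradients, assembled per term from
the radial derivative along the site separation, the derivatives of the
orientation cosines, site lever arms, and the frame-vector torque rule
τ = −u × ∂U/∂u. The test suite checks them against central differences at
relative tolerance 1e-6 and verifies momentum/angular-momentum balance and
rotation/translation invariance.

Pair screening is a per-step centre-of-mass distance cutoff over all pairs:
with at most a few tens of nucleotides in scope, a Verlet list with skin
bookkeeping would never pay for itself.

## Dynamics

Langevin dynamics uses a BAOAB-type splitting for rigid bodies: half kicks
from forces and torques, free streaming (frame rotation by the angular
velocity via Rodrigues' formula, re-orthonormalized by projection each
step), and an Ornstein–Uhlenbeck velocity refresh with
c = exp(−γ dt) and noise variance (1 − c²) kT m satisfying
fluctuation–dissipation. Friction is specified through diffusion
coefficients, γ = kT/(m D); an explicit friction override exists for the
zero-temperature drag limit. At zero friction the scheme is symplectic
velocity Verlet (energy drift < 1e-4 over 10⁴ steps at dt = 0.003 on a
4-nucleotide duplex). The default timestep is 0.003 simulation time units.

Kinetics in this model family are deliberately accelerated relative to
physical DNA (diffusion coefficients of order 1 in simulation units); the
`diffusion_scale` field is a logged run condition, and the relative-rate
helper refuses to compare estimates taken at different scales, boxes or
temperatures.

The Brownian propagator is first-order overdamped (drift D F dt/kT, noise
√(2 D dt)), used for the sequence-dependent runs.

## Monte Carlo and umbrella sampling

Equilibrium sampling uses single-nucleotide rigid-body Metropolis moves
plus rigid cluster translations/rotations. A cluster is the connected
component of the bond graph (backbone links plus hydrogen bonds below the
pairing threshold) containing a uniformly chosen seed particle; a cluster
move is rejected outright if it would change the cluster decomposition.
With that consistency check the proposal is symmetric and detailed balance
is exact, while bound duplexes still diffuse as wholes — a deliberately
simpler scheme than full virtual-move Monte Carlo, adopted because its
correctness is easy to audit (the suite logs acceptance ratios and verifies
the detailed-balance identity, and checks Boltzmann occupancies of a toy
dimer against quadrature).

Umbrella sampling multiplies the acceptance with w(n′)/w(n) on an integer
order parameter (by default the native base-pair count), accumulates visit
counts, reweights by 1/w, and reports F(n) = −kT ln P(n) offset so the
minimum is zero. Unvisited bins are flagged unsampled (NaN), never
interpolated. Uncertainties come from block averaging (5 blocks by
default). Weights can be iteratively adapted toward a flat histogram
(multiplicative update, damping 0.6) and then frozen.

## Forward flux sampling

Direct FFS with uniform resampling: the initial flux Φ₀ counts forward
crossings of the first interface that originate from the unbound basin
(λ ≤ λ_A), on a clock that only accumulates time while the trajectory's
history is in the basin — irrelevant for genuinely rare transitions, but it
keeps the estimator exact on toy systems where the product state is visited
during the flux run. Crossing states are stored with reservoir sampling
(default capacity 512); each stage fires fresh-momentum shots from
uniformly resampled stored states, succeeding if the next interface is
reached before the basin. Errors are Poisson (flux) and binomial (stages),
combined in quadrature on the log scale.

The staged order parameter is: −1 in the unbound basin (minimum interstrand
base-site distance above `d_far`, default 3.0 length units), 0 while
approaching, 1 at first contact (below `d_contact`, default 0.85), and
1 + n with n ≥ 1 detected base pairs, so the full duplex of an N-mer sits
at 1 + N. The native-only switch zeroes all non-native hydrogen bonds,
isolating the zippering channel from misaligned binding.

For repetitive sequences, long-lived misaligned intermediates make
end-to-end FFS inefficient; the intended protocol is to measure the rate
into a first-structure set (a ≥4-bp misaligned duplex or a stable
pseudoknot) and resolve eventual fates with separate unbiased runs, which
is what the classifier and census tools support.

The module's primary oracle is the 1D overdamped double-well walker: the
composed FFS rate agrees with the brute-force mean-first-passage rate and
with an analytic double-integral MFPT within statistical error, and is
invariant to interface placement.

## Secondary structure and mechanisms

A base pair is a non-bonded Watson–Crick pair whose hydrogen-bond energy is
at or below a threshold, by default 15% of the mean full well depth
(≈ −0.16 simulation energy units); conflicts keep the lower-energy pair,
ties the lower partner index. With both strands indexed 0…N−1 from the 5′
end and the native partner of i being N−1−i, the register of pair (i, j) is
r = j − (N−1−i). The sign convention is anchored by the AC/GT worked
example: the maximal 6-pair misalignment of the repeats that shifts
pairing toward the strands' low-index ends is register −8. A structure
whose strand-1 partner positions are non-monotonic in strand-0 position is
a pseudoknot, described by the two block registers reported in descending
order, e.g. (6, −6). A register histogram tie is resolved toward the
register of the lowest-energy pair.

The mechanism classifier reduces each frame to a coarse label (unbound /
dominant register / pseudoknot), collapses runs shorter than `dwell_min`
frames (default 10 saved frames; flickers are invisible), and walks the
dwelled sequence: a register replaced with no mediating pseudoknot label is
an inchworm event; a dwelled pseudoknot is a pseudoknot-displacement event;
no events with a full-duplex end is zippering; an unbound end is
detachment. Records with events of both kinds are labelled mixed, with the
ordered event list retained and the headline being the first displacement
mechanism. Classification is deterministic and stable under frame
subsampling coarser than the dwell threshold (the suite checks a 3×
subsample with proportionally reduced dwell).

## Analyses

* Apparent activation enthalpy: ΔH‡ = −R Δln k / Δ(1/T) per adjacent
  temperature pair (R = 1.9872 × 10⁻³ kcal/mol/K), reported at the
  harmonic-mean midpoint temperature, with first-order error propagation
  from rate standard errors. Planted exponential rates are recovered
  exactly; a planted linear ΔH(T) is recovered at the pair midpoints.
* Ensemble comparison at fixed base-pair count n: mean base-site distance
  to the native partner (converted to nm) and the intrastrand stacking
  count (a bonded neighbour pair is "stacked" below 15% of the typical full
  stacking depth), with state-level bootstrap errors; both ensembles must
  be conditioned on the same n.
* Relative rates: parametric bootstrap over Φ₀ (normal) and stage successes
  (binomial); comparisons across differing diffusion scales, boxes or
  temperatures are refused.
* Dissociation via detailed balance: k_off = k_on / K_eq, validated on a
  tilted double-well toy against the directly simulated reverse rate.

## Synthetic fixtures

Structures are built on an idealized helix (radius 0.6, rise 0.39, twist
0.62 rad per base pair; the backbone and stacking equilibrium distances in
the parameter tables are derived from exactly this geometry), then settled
by a short deterministic gradient quench (default 200 steps; 60 for
partially zipped states, where longer quenches would zip further). Paired
blocks occupy the helix track; pseudoknot stems stack coaxially with the
strand-0 linker bulged outward; unpaired tails extend straight past the
strand ends. Builders are deterministic given the seed, and every mode is
verified by round-tripping through detection. Separated-strand fixtures
place pre-built single-strand helices at a seed-derived orientation beyond
the basin distance; they are not pre-equilibrated by default — the flux
stage of FFS equilibrates the unbound ensemble on the fly, which avoids
paying an MC equilibration cost at every build.

Toy systems carry their own oracle observables, computed independently of
the machinery they validate: quadrature for occupancies, free-energy
differences and the dimer equilibrium constant; long vectorized direct
simulation for crossing rates.

What the generators do not emulate: sequence-dependent single-strand
stacking structure beyond the nearest-neighbour factors, hairpin-capable
sequences (excluded by design), explicit salt dependence, and physical
absolute timescales. Passing tests therefore demonstrate the internal
consistency and the qualitative sequence/temperature physics of the model,
not quantitative agreement with experiment.

## Problem sizes and scaled quantities

The validation suite and the acceptance script run at desk scale, chosen as
the smallest sizes at which each estimator's statistical error is
comfortably inside its tolerance: 64 free particles over 6 × 10⁴ steps for
the diffusion calibration; 600 decorrelated samples at strong friction for
equipartition; ~10⁴ MC sweeps for toy occupancies and umbrella profiles;
250 basin crossings and 400 shots per interface for the double-well FFS;
5-bp duplexes over 1.5–2 × 10⁴ Langevin steps for the stability contrast;
and 12-shot commitment probabilities for the 2-bp → full-duplex zippering
of a native-only 5-mer at 300 K and 500 K. Full-size hybridization-rate
campaigns (14-mers, many temperatures, thousands of shots) are
cluster-scale computations by design and are outside the validation suite;
the commitment probabilities and the direction of their temperature
dependence are the scaled stand-ins.

## Known limitations

* The smooth angular envelopes make the model somewhat softer in
  orientation space than the reference piecewise parameterizations;
  absolute melting temperatures and absolute rates are not comparable to
  the reference code or to experiment, only the model's own ratios and
  directions are.
* Cross-stacking is identity-independent; only hydrogen bonding and
  stacking carry sequence dependence.
* The Monte Carlo cluster scheme rejects decomposition-changing moves, so
  binding/unbinding transitions are carried by single-particle moves only;
  this is correct but slows mixing across the bound/unbound boundary at
  low temperature.
* The pseudoknot descriptor reports exactly two registers; structures with
  three or more simultaneous register blocks are labelled by their two
  most-populated registers.
* `Configuration.angmom` stores lab-frame angular momentum; with the
  isotropic inertia used throughout this is equivalent to the body frame up
  to rotation.
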