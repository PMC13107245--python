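# Methods

`mncat` is a desk-scale modelling toolkit for enzyme–Mn synergistic
catalysis.  It implements, on toy systems whose ground truth is known by
construction, the full computational workflow such a study runs at
production scale: model geometry and metal-coordination analysis, a toy
molecular-mechanics force field with Verlet dynamics and weak coupling,
climbing-image elastic-band transition-state search with normal-mode
validation, umbrella sampling with WHAM unbiasing, hydrogen-bond network
statistics, and the table-level analytics of the accompanying reference
dataset of quinazolinone substrates (QD-01…QD-15).  No electronic-structure
computation is performed anywhere: analytic surfaces and toy force fields
stand in for the quantum-chemical energies, which keeps every result
checkable against an independent oracle.

## Unit system

One coherent unit system is used throughout: Å, fs, amu, K, kcal/mol, and
elementary charges.  Constants (`mncat.units`):

* kB = 1.987204e-3 kcal/(mol·K)
* Coulomb constant 1/(4πε0) = 332.0637 kcal·Å/(mol·e²)
* acceleration conversion 1 kcal/(mol·Å·amu) = 4.184e-4 Å/fs²
* 1 eV = 23.0609 kcal/mol (for externally quoted chain-of-states settings)
* vibrational conversion ω[cm⁻¹] = 108.593·√(λ[kcal/(mol·Å²)]/m[amu]),
  derived from SI constants at import time and cross-checked in the tests
  against `scipy.constants`.  (A commonly quoted constant 1302.79 belongs to
  force constants in mdyn/Å, not kcal/(mol·Å²); the two differ by √143.94.)

## Geometry and coordination models

Distances, angles (arccos of the normalized dot product) and signed torsions
(atan2 convention, cis = 0°, 180° = trans) are standard.  The coordination
number of the Mn centre is the Gaussian-smoothed ligand count
Σᵢ exp(−(Rᵢ−R₀)²/2σ²) with R₀ = 2.08 Å and σ = 0.05 Å by default: each
ligand contributes 1 at the ideal bond length and is discounted as its bond
stretches or compresses.  Note a statistical consequence the tests exercise:
when the bond-length *noise* equals the smoothing width, the expected
per-ligand contribution is 1/√2, so a realistic noisy four-coordinate
cluster scores ≈2.9, while a spread-free cluster scores exactly 4.  A raw
sum of −(Rᵢ−R₀)²/2σ² without the exponential is unbounded below and cannot
produce near-integer counts, which is why the smoothed form is the
implemented one.

The effective charge of the metal centre is the screened Coulomb sum
k_e·Σᵢ Zᵢ·e^(−k·rᵢ)/rᵢ with attenuation k = 1.2 Å⁻¹ and ligand partial
charges on the scale of the reference charge table (O ≈ −0.40 e,
Mn ≈ +1.82 e).  Its physical units are those of a screened potential; the
quantity is exposed as the stated formula in the declared unit system and
used as a relative polarization index, not an observable charge.

## Force field, solvation and synergy bookkeeping

The toy force field is the CHARMM-style sum of harmonic bond and angle
terms (no ½ factor — supply force constants accordingly), periodic torsions
Kφ(1+cos(nφ−δ)), and 12-6 Lennard-Jones A/r¹²−B/r⁶ plus point-charge
Coulomb over nonbonded pairs.  1-2 and 1-3 pairs are excluded, 1-4 pairs
interact at full strength (configurable).  Forces are analytic for every
term; the torsion gradient uses the plane-normal formulas for the end atoms
with the interior atoms fixed by translation invariance, and the whole
gradient is validated against central finite differences in the tests.

Born solvation is implemented in its standard stabilizing (negative) form
−½(1−1/ε)q²k_e/R_cav with ε = 78.39 by default; the four-component
solvation decomposition (electrostatic, cavity, dispersion, repulsion) is
bookkeeping over supplied components, since continuum-model internals are
out of scope at toy scale.  Binding energy is the usual supermolecular
difference.  The synergy energy E(EMS) − E(ES) − E(MS) + E(S) isolates the
enzyme–metal coupling: it is identically zero for pairwise-additive
energies with no direct enzyme–metal term, equals that term when present,
and recovers an explicitly planted three-body coupling exactly — all three
identities are asserted in the tests.

## Dynamics

The integrator is position (Størmer) Verlet,
r(t+Δt) = 2r(t) − r(t−Δt) + (F/m)Δt², bootstrapped with a second-order
Taylor step.  There are no stored velocities: the thermostat uses
backward-difference effective velocities, while recorded frames carry
central-difference velocities (O(Δt²)), which is what makes the measured
total-energy fluctuation of a harmonic dimer ~1e-5 relative over 10⁴ steps
instead of the O(ωΔt) artifact a one-sided difference would show.  The
final frame's velocity comes from one virtual extra step.

Temperature control is Berendsen-style weak coupling:
T(t+Δt) = T + (Δt/τ)(T_target − T), realized as velocity rescaling by
√(T_new/T) applied to the position history; instantaneous temperature uses
3N−3 degrees of freedom.  On a force-free gas the relaxation is exactly the
discrete exponential (1−Δt/τ)ⁿ, which the tests compare to exp(−t/τ).  The
mechanism choice (deterministic rescaling rather than a stochastic
thermostat) is the minimal realization of the prescribed temperature
trajectory.  Pressure control is the isotropic weak-coupling box update
h ← h + (Δt/W)(P_int−P_ext)h with affine coordinate scaling; internal
pressure, when the driver needs it, is the scalar virial estimate.  The
full anisotropic cell-matrix form is an extension point toy systems do not
need.  Maxwell–Boltzmann velocity initialization demands an explicit seed
and removes centre-of-mass motion; a fixed seed makes `run_md`
bit-reproducible.  The production protocol (5000-step steepest-descent
minimisation, NVT, NPT, long production at Δt = 2 fs) is encoded as a named
preset; tests exercise the same machinery at ≤2×10⁴ steps, which is ample
to measure conservation, relaxation and thermostat fidelity on toy systems.

RMSD uses Kabsch superposition (optional — the closed-form oracles for
single-atom displacement hold only without alignment, and the tests check
both modes); RMSF is measured about the mean structure after a two-pass
superposition.

## Transition-state search and validation

The band force is the plain (non-projected) elastic band exactly as the
workflow defines it: Fᵢ = −∇E(Rᵢ) + κ(Rᵢ₊₁ − 2Rᵢ + Rᵢ₋₁), with 10 images,
κ = 5.0 eV/Å² and force tolerances 0.05/0.02 eV/Å (all stored converted to
kcal/mol units).  Once the plain band is within 10× the force tolerance,
the highest interior image switches to the climbing-image force — the true
force with its component along the chord tangent (Rᵢ₊₁−Rᵢ₋₁) inverted and
no springs — and rides uphill to the saddle.  The optimizer is damped
steepest descent with a 0.1 Å per-iteration displacement cap; the step
size halves after ten non-improving iterations, recovers multiplicatively
while improving, and resets when the climbing image activates (the force
norm jumps discontinuously there, and treating that jump as divergence
would freeze the step size).  Improved-tangent NEB is a noted extension,
not implemented.

Saddle validation follows the standard protocol: symmetric
central-difference Hessian (default step 1e-4), mass-weighted
eigendecomposition, imaginary frequencies from negative eigenvalues,
per-mode reduced masses 1/Σ(cᵢ²/mᵢ), and classification as a transition
state only when there is exactly one imaginary mode whose displacement
overlaps the declared reaction coordinate by at least 0.5.  Descent paths
launched at saddle ± ε·mode must terminate in the two connected basins;
ε must exceed the positional uncertainty of the saddle estimate (grid
resolution for grid-located saddles, the force tolerance's positional slack
for band-located ones), and callers choose it accordingly.

## Umbrella sampling and WHAM

Window sampling runs Metropolis-adjusted overdamped Langevin (MALA) on the
biased potential V(R) + ½kᵢ(R−Rᵢ)²: the Euler–Maruyama proposal is
accepted/rejected so the stationary distribution is the exact biased
Boltzmann measure — plain Euler–Maruyama leaves an O(step) bias in the PMF
that is visible at the 0.05 kcal/mol level.  A plain Metropolis random walk
is available for non-differentiable surfaces.  Defaults: mobility
(Δt/γ) = 2e-3 Å²·mol/kcal per step, 1000 burn-in steps, one sample kept
every 4 steps to shorten autocorrelation.

WHAM is the standard self-consistent iteration over window free-energy
constants in log space, with the bias *subtracted* in the unbiasing step —
the only sign convention under which a planted profile is recovered, which
is the testable contract of the estimator.  Histograms use left-closed,
right-open bins on a grid aligned to multiples of the bin width; adjacent
windows with disjoint histograms raise an error, weak overlap (<5% of the
smaller window) warns.  The profile is anchored at its minimum; per-bin
uncertainties are the Poisson-counting estimate kBT/√n.  For barrier
recovery on the 5 kcal/mol quartic well the package's validation runs use
20 windows spanning ±1.2 Å with bias constant 100 kcal/(mol·Å²) and
0.05 Å bins: the window spacing (0.126 Å) then matches the window width
(√(kBT/k) ≈ 0.077 Å) for healthy histogram overlap, and the bin width
resolves the barrier top to well under the 0.1 kcal/mol comparison level.
A 1000 kcal/(mol·Å²) bias with 20 windows over the same range would leave
0.024 Å-wide, non-overlapping histograms — stiff biases of that size need
proportionally more windows.

TST rates are k = A·exp(−ΔG‡/kBT) with A = kBT/h (Eyring) or a supplied
empirical prefactor.  The reference proton-transfer table's rates (~10³
s⁻¹ at 3–4 kcal/mol barriers) imply prefactors more than six orders of
magnitude below kBT/h and are therefore reproduced only through the
configurable prefactor, never derived.

## Hydrogen bonds

A donor–hydrogen–acceptor triple is bonded in a frame iff the
donor–acceptor distance ≤ 3.5 Å and the D-H…A angle, measured at the
hydrogen with 180° linear, is ≥ 150°; both boundaries inclusive.
Occupancy is the per-triple fraction of frames satisfying the criterion.

## Synthetic data: what it emulates and what it does not

Every generator takes an explicit seed (no global RNG state) and returns a
truth record sufficient to score the downstream analysis.

* **Mn clusters** — Mn at the origin, O ligands on tetrahedral/octahedral/
  random directions, radial Gaussian noise (defaults 2.08 ± 0.05 Å),
  charges on the reference-table scale.
* **Reaction surfaces** — 1-D quartic a(x²−1)² + bx with closed-form
  stationary points, or two 2-D Gaussian wells.  The 2-D saddle truth comes
  from an independent dense-grid percolation search (bisecting the energy
  threshold at which the sublevel set connects the basins, via
  connected-component labelling; default 1001² grid, the saddle *location*
  is the bottleneck cell adjacent to both basin components), never from the
  band search it scores.  A Dijkstra widest-path search in the tests
  cross-checks the percolation oracle itself.
* **H-bond trajectories** — per-frame Bernoulli toggling between a bonded
  state (≈2.85 Å / ≈165°, clipped to lie strictly inside the criterion) and
  an unbonded state (>4 Å and <140°, strictly outside), so the measured
  occupancy equals the realized planted fraction exactly.
* **Substrate series** — enzyme-only activation energies uniform on
  27.6–32.4 kcal/mol, additive metal-only drops of 5.1 ± 0.4 kcal/mol, and
  multiplicative synergistic reductions uniform on 32.6–40.9%, all matching
  the spans of the reference activation-energy table, plus optional
  Gaussian noise (0.2 kcal/mol in the noisy tests).

None of these emulate real conformational ensembles, solvent, or electronic
structure; passing tests demonstrate that the *estimators* (band search,
WHAM, occupancy, reduction statistics) recover planted truth under
controlled conditions, not that the toy systems predict real chemistry.

## Reference tables and their audit

The printed reference tables ship as CSV fixtures (activation energies and
reductions, synergy decompositions, calculation-vs-experiment errors, IR
deviations, and the four sensitivity grids), and every derived cell is
recomputed from raw columns with half-away-from-zero rounding to one
decimal — the convention that reproduces all printed cells.  The audit
(`report.audit_tables`) flags the inconsistencies the source data carries:
the headline 36.5% average reduction versus the recomputed column mean of
36.9%; the synergy table's "Average value" row versus its own column means
(−15.225/−8.1/−3.9/−27.225); a functional-sensitivity row (QD-07) spanning
1.1 kcal/mol where the accompanying text claims a 1.0 maximum; and the
"approximately sevenfold" cyclability improvement, which has no supporting
table and is reported as non-recomputable rather than assumed.  The
synergy "Average value" row is stored but excluded from consistency
assertions.

## Known limitations

* Plain elastic band (no tangent projection) can corner-cut on strongly
  curved 2-D paths; the climbing image corrects the saddle energy but the
  interior path is not a minimum-energy path in the improved-tangent sense.
* The barostat is isotropic; no constraint algorithms, Ewald summation or
  periodic minimum-image conventions (toy systems are non-periodic by
  default, and the box is used only for pressure bookkeeping).
* WHAM is 1-D with Poisson error bars; no MBAR, no autocorrelation-aware
  uncertainties, no 2-D profiles, no tunneling corrections.
* PDB reading is coordinates-and-elements only (first model, via gemmi);
  no altloc/occupancy/CONECT semantics.
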