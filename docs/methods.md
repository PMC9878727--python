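# Methods

This note documents the models, numerical choices and known limitations
of `cgmotor`, in the order the pipeline uses them.

## Units and conventions

Lengths are nm, energies kJ mol⁻¹, time ps, temperature K.  Angles are
degrees at every I/O boundary (topology files, distribution tables,
reports) and radians internally.  k_B = 0.0083145 kJ mol⁻¹ K⁻¹.
Atom and bead indices are 1-based in files, 0-based in memory.

## Bonded potential

The energy of a configuration is the sum over terms

* bond: ½k(r−r₀)²; a bond flagged *constrained* contributes no energy
  and is held at exactly r₀ by the sampler;
* angle, harmonic: ½k_f(θ−θ₀)² with θ the 0–π angle at the central bead;
* angle, quartic: Σₙ₌₀⁴ Cₙ(θ−θ₀)ⁿ — the polynomial convention was chosen
  for the quartic form (over restricted-bending variants) because it is
  the minimal form able to represent a double well with adjustable
  asymmetry; C₂<0, C₄>0 gives wells at ±√(−C₂/2C₄) and a barrier
  C₂²/4C₄;
* dihedral: Σₘ k_m(1+cos(n_m φ−φ₀ₘ)) over one or more cosine terms,
  with φ the signed IUPAC dihedral wrapped to (−180°, 180°].

Virtual sites are massless: their positions are rebuilt as (weighted)
means of their constructor beads whenever a constructor moves, and they
enter the energy only through the terms that reference them (dihedrals
may pivot on a v-site; terms over *only* v-sites are rejected).
Default bead radii by Martini size class are regular 0.264, small
0.230, tiny 0.191 nm, overridable per bead.

## Forward mapping

Each real bead is placed at the centre of geometry (default, matching
the Martini heavy-atom convention) or centre of mass of its assigned
atoms, frame by frame; virtual beads are then constructed from the real
beads.  The default excludes no atom class by itself — hydrogen
handling is whatever the scheme lists, so a heavy-atom mapping is
expressed simply by not listing hydrogens.  Atom sharing between beads
is rejected unless the scheme enables it explicitly.

## Distribution statistics and MAE

Histograms use fixed-width bins on aligned grids: 0.001 nm for bonds,
1° for angles and dihedrals (configurable).  Dihedrals use circular
mean/standard deviation; bonds and angles use linear moments.

Modality of angle distributions is detected on a Gaussian-smoothed
histogram (σ = 2 bins): maxima above 10% of the global maximum and
separated by ≥ 15° count as distinct modes; two or more ⇒ bimodal, and
the two highest modes are kept (positions refined by quadratic
interpolation through the peak bins).  Bond-length distributions are
treated as unimodal by construction.

The MAE between two distribution sets is computed over *per-term
distribution means* within each category — the only reading of a
"mean absolute error of bond lengths/angles" that carries units of nm
and degrees — except for bimodal angles, which are compared mode by
mode: each model mode is paired with the nearest reference mode and the
paired |Δ| are averaged.  The comparison convention is recorded in the
JSON report.

## Boltzmann inversion and refinement

Direct inversion of a unimodal distribution gives x₀ = mean and
k = k_BT/σ² (angle σ converted to radians first); σ below 1e-9 is
reported as a constraint recommendation instead of a force constant.

The quartic-angle fit inverts V(θ) = −k_BT ln[p(θ)/sin θ] over bins with
density ≥ 10⁻⁴ of the peak (the density floor avoids log 0), offsets the
minimum to zero, and least-squares fits C₀..C₄ in powers of (θ−θ₀) with
θ₀ the density-weighted circular mean.  The sin θ division is the
standard bond-angle Jacobian correction; without it the planted
potential would be recovered with a small systematic tilt.  Because θ₀
is a gauge choice (the quartic basis includes odd powers), fitted
coefficient vectors are compared through the potential's shape — well
positions and barrier — not coefficient by coefficient.

Dihedral fitting expands −k_BT ln p(φ) on {1+cos(nφ−φ₀ₙ)} with phases
restricted to {0°, 180°}; the fit is linear with phase 0 plus a free
constant, and negative amplitudes are folded to phase 180°
(mathematically identical to a phase grid search).

The refinement loop samples the current topology, extracts its
distributions, and applies the damped update

    x₀ ← x₀ + λ(⟨x⟩_target − ⟨x⟩_model),   k ← k(σ²_model/σ²_target)^λ

to every harmonic bond and angle (λ = 0.7 by default; both sides of the
comparison are produced by the same sampler, so Jacobian shifts cancel
and no correction is needed here).  Quartic angles and dihedrals are set
once by direct inversion and not iterated — refinement adjusts, it never
refits from scratch.  Convergence thresholds default to the MAE levels
the published motor/switch models achieved (0.0025 nm bonds, 5.5°
unimodal angles, 11.4° bimodal angles); non-convergence returns the best
iterate with `converged=False`.

## Monte Carlo sampler

A single-molecule Metropolis chain replaces MD for equilibrium bonded
statistics: one step attempts a Gaussian displacement of one real bead
(cyclic order), evaluates only the energy terms whose support includes
the moved bead (virtual-site dependents included), and accepts with the
Metropolis rule.  The move size adapts toward 40% ± 10% acceptance
during burn-in (default: the first 10% of steps) and is frozen for
production.  Identical configurations give bit-identical ensembles; all
randomness flows through one `numpy.random.Generator`.

Constrained bonds are sampled *on the constraint manifold*: a bead with
a constrained partner is moved by perturbing the bond direction and
renormalising to exactly r₀, so constraint violation is zero by
construction (at the cost of the constrained pair's centre not
diffusing, which is irrelevant for internal statistics).  The direction
proposal is symmetric only to leading order in the step size; the
residual bias is far below sampling noise at production move sizes.
Beads tied into more than one constrained bond are not supported.

The sampled measure is the Cartesian Boltzmann distribution, as in MD.
Its internal-coordinate marginals therefore carry the geometric
Jacobians: p(r) ∝ r² e^(−βV) for a bond, p(θ) ∝ sin θ e^(−βV) for an
angle.  For a bond with k = 1250 kJ mol⁻¹ nm⁻², r₀ = 0.35 nm, T = 300 K
the exact variance of r is 0.969·k_BT/k (Gaussian-weighted moments of
the r² measure), i.e. the naive equipartition value is approached only
in the very stiff limit — a ~3% effect at this stiffness that any
Boltzmann-correct Cartesian sampler must show.

Initial coordinates come from a seeded random placement followed by an
L-BFGS minimisation of the bonded energy (constraints as stiff springs,
then projected exactly).

### Toy drivers

*Enforced rotation.*  The rotor group is coupled by an isotropic
harmonic restraint (no mass weighting) to reference positions that
rotate rigidly about the axle direction at a fixed rate; the reference
is centred on the group's *instantaneous* centroid (pivot-free), so the
restraint exerts no net translational force.  MC sweeps carry a
fictitious timestep (0.002 ps per sweep) so rates in °/ps are
meaningful; this is a toy-model convention for qualitative studies, not
dynamics — at 80°/ps the reference completes a turn in exactly 4.5 ps
and a well-restrained rotor tracks it with a bounded steady lag.  The
exact functional form of the engine-native pivot-free potential is not
public; the simplified isotropic restraint is a stated approximation.

*Topology switching.*  Photo-isomerisation of a switch is mimicked by
continuing a chain — same coordinates, move size and random stream —
under the bonded topology of the other stereoisomer, recording the
bonded-energy relaxation.  Switching to an identical topology is
bit-identical to an uninterrupted chain, which pins down the state
hand-off.

## Free-energy estimators

*TI*: trapezoidal quadrature of per-λ means; uncertainty propagates
per-λ standard errors through the quadrature weights.  Soft-core path
details belong to the engine that produced the series and are out of
scope.

*BAR*: solves Σ_F f(β(W_F−ΔG+M)) = Σ_R f(β(W_R+ΔG−M)), f the logistic
function, M = ln(n_F/n_R)/β, by bracketed root finding (bracket grown
geometrically; non-overlapping work distributions raise a diagnostic).
The reported uncertainty is the standard asymptotic variance from the
fluctuations of the Fermi weights in both directions.

*WHAM*: standard self-consistent iteration in log space
(`logsumexp`), converged to 1e-7 relative tolerance on the window free
energies; bins span the sampled range (default 300).  Uncertainty: 100
bootstrap replicates, each resampling every window's own time series
with replacement (the window is the resampling block — conservative for
correlated samples); the profile and each replicate are anchored at
zero minimum, which also fixes the gauge freedom of adding a constant
to all window free energies.

*log P* = (ΔG_water→vac − ΔG_octanol→vac)/(ln 10 · R T), T = 310 K by
default; uncertainties add in quadrature.  The sign convention makes a
hydrophobic solute (easier to pull out of water than out of octanol)
positive, matching the hydrophobicity ordering of published motor
models.  Both transfer directions are supported by swapping arguments.

## SASA

Shrake–Rupley with a deterministic Fibonacci-sphere point set (default
960 points) on each particle's probe-inflated sphere (default probe
0.14 nm, the water-probe convention); a point is buried if it falls
inside any other inflated sphere.  Atomic radii use the Rowland–Taylor
values (H 0.110, C 0.177, N 0.164, O 0.158, S 0.181 nm …); bead radii
default to the Martini class values.  Virtual sites are excluded by
default (they are interaction constructs, not volume) but can be
included by flag.  Isolated spheres are exact by construction; the
two-sphere case agrees with the spherical-cap closed form to < 1% at
960 points.  The AA/CG comparison reports
100·|⟨A_CG⟩−⟨A_AA⟩|/⟨A_AA⟩ per molecule plus the average and maximum.

## Synthetic generators and what they do (not) show

The generators plant a known truth and emulate only the statistical
shape of real inputs:

* the **toy motor** (8 real beads, one virtual pivot, a bimodal quartic
  axle angle with modes near 80° and 130° and a ~4 kJ/mol barrier, an
  n = 2 stator–rotor dihedral through the v-site) exercises every term
  type the real motor/switch topologies use, at a fraction of their
  size;
* **pseudo-atomistic decoration** dresses each bead with a cloud of
  atoms whose per-frame centre of geometry equals the bead position to
  machine precision, so mapping correctness and fitting correctness are
  testable independently; a `cog_noise` mode breaks the exactness for
  integration tests;
* **umbrella windows** are drawn exactly (inverse-CDF on a fine grid)
  from e^(−β(F+bias)) for an analytic F — the default double well has a
  6 kJ/mol barrier between minima at 0.4 and 1.0 nm, sampled with the
  partitioning protocol's window spacing (0.1 nm) and spring constant
  (1500 kJ mol⁻¹ nm⁻²);
* **work samples** are Gaussians satisfying the Crooks relation
  (forward N(ΔG+σ²β/2, σ²), reverse N(−ΔG+σ²β/2, σ²)), so the planted
  ΔG is exactly right.

Passing on these fixtures demonstrates that the estimators and the
fitting loop are self-consistent and correct against planted truths; it
does not demonstrate transferability of any particular CG model to real
chemistry — no solvent, no nonbonded interactions (the Martini
interaction matrix is deliberately out of scope), no conformational
heterogeneity beyond what the planted bonded terms generate, and
MC "time" is not physical time.

## Problem sizes

Defaults were chosen as the smallest sizes at which the statistical
checks are comfortably resolved: reference ensembles of 10⁶ MC moves
(~9×10⁴ frames), refinement iterations of 3×10⁵ moves, WHAM with 11
windows × 2000 points, BAR at n = 10⁴ per direction.  The closed-loop
recovery experiment converges in 3–4 refinement iterations and lands
its bond/angle MAEs an order of magnitude inside the published
acceptance levels.

## Known limitations

* Nonbonded energies, solvents, thermostats/barostats and bilayer or
  surface systems are out of scope; bead *types* are recorded but not
  interpreted.
* The sampler supports at most one constrained bond per bead (no
  constraint networks).
* The circular mean of a symmetric bimodal dihedral (e.g. the n = 2
  profile at ±90°) is ill-conditioned; the dihedral MAE is reported for
  completeness but the fitted-profile comparison is the meaningful
  check there.
* Multi-frame trajectories are stored as XYZ (Å on disk, the format's
  convention); `.gro` files hold single frames.
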