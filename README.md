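# cgmotor

Coarse-grained (CG) model building for synthetic molecular motors and
switches — the desk-scale half of a Martini-style parameterization
workflow, runnable end-to-end without an external MD engine.

Light-driven molecular motors (overcrowded-alkene "stator/rotor"
compounds) and photoswitches are increasingly simulated at the Martini CG
level, where 2–4 heavy atoms become one bead and fused aromatic rings
become "tiny" (T) beads, often with massless *virtual sites* constructed
geometrically from real beads (e.g. the central bead of a naphthalene
moiety, or a pivot used to define the stator–rotor dihedral).  Deriving
the bonded part of such a model is an iterative distribution-matching
exercise: forward-map an atomistic ensemble onto the beads, Boltzmann-
invert the resulting bond/angle/dihedral distributions, re-simulate,
compare, adjust, repeat.  `cgmotor` packages every step of that loop, the
validation statistics used to judge it, and the free-energy machinery
used to check the resulting models — with seeded synthetic generators so
the whole pipeline is testable on a laptop.

## What it does

* **Topology model** — beads (with Martini size classes and radii),
  harmonic/constrained bonds, harmonic and *quartic* angles (the quartic
  polynomial `V(θ) = Σₙ Cₙ(θ−θ₀)ⁿ`, n ≤ 4, represents bimodal angle
  distributions), multi-term proper dihedrals `Σ k_φ(1+cos(nφ−φ₀))`, and
  COG/weighted virtual sites; read/write of a GROMACS-dialect `.itp`
  subset with exact round-tripping.
* **Forward mapping** — per-bead centre-of-geometry (or centre-of-mass)
  projection of atomistic ensembles, plus scheme/topology consistency
  checks.
* **Distribution statistics** — per-term histograms, linear and circular
  moments, bimodality detection, and the cross-resolution mean-absolute-
  error (MAE) report over per-term means (bonds in nm, angles in degrees,
  bimodal angles compared mode-by-mode).
* **Fitting** — direct Boltzmann inversion (`k = k_BT/σ²`), quartic-angle
  and cosine-series dihedral fits of `−k_BT ln p`, and an iterative
  refinement loop `x₀ ← x₀ + λ(⟨x⟩_target − ⟨x⟩_model)`,
  `k ← k(σ²_model/σ²_target)^λ` against the built-in sampler.
* **Sampler** — a fast (numba) single-molecule Metropolis Monte Carlo
  chain over the bonded potential, with exact constraint handling,
  virtual-site re-placement, seed-deterministic output, and two toy
  drivers: *enforced rotation* (isotropic, pivot-free harmonic restraint
  to a reference rotating at a fixed rate, e.g. 80°/ps with
  k = 280 kJ mol⁻¹ nm⁻², giving a full turn in 4.5 ps) and *topology
  switching* (E/Z photo-isomerisation mimicked by continuing a chain
  under the other stereoisomer's bonded terms).
* **Free energies** — thermodynamic integration over λ, Bennett's
  acceptance ratio, WHAM for umbrella windows (default 300 bins, 100
  bootstrap resamples), and the octanol–water partition coefficient
  `log P = (ΔG_w→vac − ΔG_oct→vac)/(2.303 R T)`.
* **SASA validation** — Shrake–Rupley solvent-accessible surface area
  with Martini bead-class radii (0.264/0.230/0.191 nm) or Rowland–Taylor
  atomic radii, and the AA-vs-CG percent-difference report.
* **Synthetic fixtures** — seeded generators with planted ground truth
  for every input class: a toy-motor molecule (8 beads + a virtual
  pivot, one bimodal axle angle, an n=2 stator–rotor dihedral through
  the v-site), pseudo-atomistic decorations whose per-bead COG is exact,
  umbrella windows drawn from an analytic PMF, and Crooks-consistent
  Gaussian work samples.

## Worked example

```python
from cgmotor import SamplerConfig, sample, extract_distributions, invert_harmonic
from cgmotor.fixtures import toy_motor

spec = toy_motor()
ens = sample(spec.topology, SamplerConfig(n_steps=400_000, stride=10, seed=1))
dists = extract_distributions(ens, spec.topology)

d = dists["bond:0-1"]
fit = invert_harmonic(d, T=300.0)
print(f"bond 0-1: mean {d.mean:.4f} nm, sigma {d.std:.4f} nm")
print(f"Boltzmann inversion: r0 = {fit.x0:.4f} nm, k = {fit.k:.0f} kJ/mol/nm^2")
a = dists["angle:3-4-5"]
print(f"axle angle: {a.modality}, modes at {a.modes[0]:.1f} and {a.modes[1]:.1f} degrees")
```

prints

```
bond 0-1: mean 0.3527 nm, sigma 0.0204 nm
Boltzmann inversion: r0 = 0.3527 nm, k = 5981 kJ/mol/nm^2
axle angle: bimodal, modes at 80.3 and 128.7 degrees
```

The planted bond had r₀ = 0.35 nm and k = 6000 kJ mol⁻¹ nm⁻²: the
sampled mean sits slightly above r₀ (the radial Jacobian of a bond in
3-D) and the inverted force constant lands within noise of the truth.
The planted axle angle is a quartic double well with minima 25° either
side of 105°, and the extracted modes land on them.

Free energies and partitioning, on synthetic work samples with planted
ΔG of 30 (water) and 10 (octanol) kJ/mol at 310 K:

```python
from cgmotor import gen_work_samples, bar_estimate, log_p
w_wat = gen_work_samples(dG=30.0, sigma=2.0, n=10_000, T=310.0, seed=2)
w_oct = gen_work_samples(dG=10.0, sigma=2.0, n=10_000, T=310.0, seed=3)
gw, go = bar_estimate(w_wat), bar_estimate(w_oct)
lp, err = log_p(gw, go, T=310.0)
print(f"log P = {lp:.2f} +/- {err:.2f}")
# log P = 3.37 +/- 0.00    (planted: 20/5.935 = 3.37)
```

The same operations are available from the shell via the `cgmotor`
command (`generate`, `map`, `extract`, `fit`, `sample`, `validate`,
`sasa`, `wham`, `bar`, `ti`, `logp`, `rotate`, `switch`); every run
writes a provenance manifest alongside its outputs.

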