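"""Seeded synthetic-data generators with planted ground truth.

Everything the toolkit consumes can be generated here without any
external simulation engine: pseudo-atomistic conformer ensembles whose
forward-mapped statistics follow a known CG topology, umbrella-window
time series drawn from a known PMF, and forward/reverse work samples
satisfying the Gaussian fluctuation relation for a chosen Delta G.
Planted truths are returned alongside the data so every downstream stage
(mapping, fitting, WHAM, BAR) can be closed-loop tested.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import KB
from .ensemble import ConformerEnsemble
from .free_energy import UmbrellaSet, UmbrellaWindow, WorkSamples
from .mapping import MappingScheme
from .sampler import SamplerConfig, build_initial_coords, sample
from .topology import AngleTerm, BeadDef, BondTerm, CGTopology, DihedralTerm, VirtualSiteDef

__all__ = [
    "ToyMoleculeSpec",
    "toy_motor",
    "decorate_ensemble",
    "gen_reference_ensemble",
    "gen_umbrella_data",
    "gen_work_samples",
    "double_well_pmf",
]


@dataclass
class ToyMoleculeSpec:
    """A planted-truth CG molecule plus its pseudo-AA decoration rule."""

    topology: CGTopology
    atoms_per_bead: int = 3
    spread: float = 0.08  # nm; size of the decoration atom cloud

    def __post_init__(self) -> None:
        if self.atoms_per_bead < 1:
            raise ValueError("need at least one atom per bead")
        if self.spread < 0:
            raise ValueError("spread must be >= 0")
        self.topology.validate()


def toy_motor(bimodal: bool = True) -> ToyMoleculeSpec:
    """The default toy molecular-motor fixture.

    Eight real beads (a four-bead "stator" 0-3 and a four-bead "rotor"
    4-7 joined by the 3-4 axle bond) plus one virtual pivot bead (9th,
    cog of the stator core) used to define the stator-rotor dihedral —
    the minimal architecture exhibiting every bonded term type the CG
    motor/switch models use: harmonic bonds, unimodal harmonic angles,
    one bimodal quartic angle at the axle, and an n=2 dihedral through
    the v-site.

    The quartic angle (C2 = -42, C4 = 110.4 kJ/mol/rad^n about
    theta0 = 105 deg) has wells ~25 deg either side of theta0, i.e. modes
    near 80 and 130 degrees with a ~4 kJ/mol barrier.
    """
    beads = [BeadDef(name=f"B{i+1}", bead_class="tiny", type_code="TC5")
             for i in range(8)]
    beads.append(BeadDef(name="V1", bead_class="tiny", type_code="TC5",
                         is_virtual=True))
    bonds = [
        BondTerm(0, 1, r0=0.35, k=6000.0),
        BondTerm(1, 2, r0=0.40, k=4000.0),
        BondTerm(2, 3, r0=0.36, k=7000.0),
        BondTerm(3, 4, r0=0.38, k=5000.0),  # the axle
        BondTerm(4, 5, r0=0.34, k=6500.0),
        BondTerm(5, 6, r0=0.42, k=3500.0),
        BondTerm(6, 7, r0=0.37, k=5500.0),
    ]
    angles = [
        AngleTerm(0, 1, 2, theta0=120.0, kf=150.0),
        AngleTerm(1, 2, 3, theta0=105.0, kf=200.0),
        AngleTerm(4, 5, 6, theta0=130.0, kf=120.0),
        AngleTerm(5, 6, 7, theta0=115.0, kf=180.0),
    ]
    if bimodal:
        angles.append(AngleTerm(
            3, 4, 5, theta0=105.0, form="quartic",
            quartic_coeffs=(0.0, 0.0, -42.0, 0.0, 110.4)))
    else:
        angles.append(AngleTerm(3, 4, 5, theta0=105.0, kf=160.0))
    dihedrals = [DihedralTerm(8, 3, 4, 5, [(2, 0.0, 5.0)])]
    vsites = [VirtualSiteDef(site=8, constructors=(0, 1, 2), rule="cog")]
    top = CGTopology(name="toymotor", beads=beads, bonds=bonds, angles=angles,
                     dihedrals=dihedrals, virtual_sites=vsites)
    return ToyMoleculeSpec(topology=top)


def decorate_ensemble(
    cg: ConformerEnsemble,
    spec: ToyMoleculeSpec,
    seed: int = 0,
    cog_noise: float = 0.0,
) -> tuple[ConformerEnsemble, MappingScheme]:
    """Dress each real CG bead with a cloud of pseudo-atoms.

    The per-frame atom offsets are mean-centred, so the centre of
    geometry of every bead's atoms equals the bead position *exactly*
    and forward mapping recovers the CG frames bit-for-bit; a nonzero
    ``cog_noise`` (nm) breaks that exactness for integration tests.
    Virtual beads receive no atoms.  Returns the pseudo-AA ensemble and
    the matching mapping scheme.
    """
    rng = np.random.default_rng(seed)
    top = spec.topology
    real = top.real_indices
    app = spec.atoms_per_bead
    n_atoms = len(real) * app
    frames = np.empty((cg.n_frames, n_atoms, 3))
    assignments = []
    for bi, bead in enumerate(real):
        lo = bi * app
        offsets = rng.normal(scale=spec.spread, size=(cg.n_frames, app, 3))
        if app == 1:
            offsets[:] = 0.0
        else:
            offsets -= offsets.mean(axis=1, keepdims=True)
        if cog_noise > 0:
            offsets += rng.normal(scale=cog_noise, size=(cg.n_frames, 1, 3))
        frames[:, lo:lo + app, :] = cg.frames[:, bead, None, :] + offsets
        assignments.append(
            (top.beads[bead].name, tuple(range(lo, lo + app)), "cog"))
    aa = ConformerEnsemble(
        frames=frames, resolution="AA",
        metadata={**cg.metadata, "generator": "cgmotor.fixtures.decorate_ensemble",
                  "decoration_seed": seed, "atoms_per_bead": app,
                  "spread_nm": spec.spread, "cog_noise_nm": cog_noise},
    )
    scheme = MappingScheme(
        molecule=top.name,
        bead_assignments=assignments,
        virtual_beads=[top.beads[i].name for i in sorted(top.virtual_indices)],
    )
    return aa, scheme


def gen_reference_ensemble(
    spec: ToyMoleculeSpec,
    n_frames: int = 20_000,
    T: float = 300.0,
    seed: int = 0,
    n_steps: int | None = None,
    stride: int = 10,
):
    """Planted-truth reference: sample the spec's topology, decorate.

    Returns ``(aa_ensemble, scheme, truth_topology)``; the CG skeleton
    that generated the pseudo-AA frames is also stashed in the AA
    ensemble's metadata for closed-loop assertions.
    """
    top = spec.topology
    if n_steps is None:
        production = n_frames * stride
        burn = max(production // 10, 10 * stride)
        n_steps = burn + production
    else:
        burn = None
    cfg = SamplerConfig(temperature=T, n_steps=n_steps, stride=stride,
                        seed=seed, burn_in=burn)
    start = build_initial_coords(top, seed=seed)
    cg = sample(top, cfg, start=start)
    aa, scheme = decorate_ensemble(cg, spec, seed=seed + 1)
    aa.metadata["cg_skeleton"] = cg
    return aa, scheme, top.copy()


# -- free-energy fixtures ----------------------------------------------

def double_well_pmf(barrier: float = 6.0, minima: tuple[float, float] = (0.4, 1.0)):
    """Symmetric quartic double-well PMF along a 1-D coordinate (nm);
    zero at both minima, ``barrier`` kJ/mol at the midpoint."""
    a, b = minima
    m = 0.5 * (a + b)
    w = 0.5 * (b - a)

    def F(x):
        x = np.asarray(x, dtype=float)
        return barrier * ((x - m) ** 2 - w**2) ** 2 / w**4

    F.barrier = barrier
    F.minima = minima
    return F


def gen_umbrella_data(
    pmf,
    window_centers,
    k: float = 1500.0,
    n_per_window: int = 2000,
    T: float = 300.0,
    seed: int = 0,
) -> UmbrellaSet:
    """Umbrella-window samples drawn exactly from the biased Boltzmann
    density exp(-beta (F(xi) + k/2 (xi - xi0)^2)) by inverse-CDF sampling
    on a fine grid.  Defaults follow the umbrella protocol used for the
    partitioning PMFs (0.1 nm window spacing works well with
    k = 1500 kJ/mol/nm^2)."""
    rng = np.random.default_rng(seed)
    beta = 1.0 / (KB * T)
    sigma = np.sqrt(1.0 / (beta * k)) if k > 0 else None
    windows = []
    for xi0 in window_centers:
        if sigma is not None:
            lo, hi = xi0 - 8 * sigma, xi0 + 8 * sigma
        else:
            lo, hi = min(window_centers) - 0.2, max(window_centers) + 0.2
        grid = np.linspace(lo, hi, 4001)
        u = pmf(grid) + 0.5 * k * (grid - xi0) ** 2
        if not np.all(np.isfinite(u)):
            raise ValueError("PMF is unbounded on the sampled range")
        logp = -beta * (u - u.min())
        p = np.exp(logp)
        cdf = np.concatenate([[0.0], np.cumsum(0.5 * (p[1:] + p[:-1]) * np.diff(grid))])
        cdf /= cdf[-1]
        series = np.interp(rng.random(n_per_window), cdf, grid)
        windows.append(UmbrellaWindow(xi0=float(xi0), k=float(k), series=series))
    return UmbrellaSet(windows=windows, temperature=T)


def gen_work_samples(
    dG: float,
    sigma: float,
    n: int = 10_000,
    T: float = 300.0,
    seed: int = 0,
) -> WorkSamples:
    """Gaussian forward/reverse work obeying the Crooks fluctuation
    relation: forward ~ N(dG + sigma^2 beta / 2, sigma^2) and reverse ~
    N(-dG + sigma^2 beta / 2, sigma^2), so the planted ``dG`` is the
    exact answer."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    rng = np.random.default_rng(seed)
    beta = 1.0 / (KB * T)
    shift = 0.5 * sigma**2 * beta
    fwd = dG + shift + sigma * rng.standard_normal(n)
    rev = -dG + shift + sigma * rng.standard_normal(n)
    return WorkSamples(forward=fwd, reverse=rev, temperature=T)
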