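"""Bonded-potential fitting by Boltzmann inversion and iterative refinement.

The parameterization loop mirrors the standard CG workflow: invert the
mapped atomistic distributions for an initial guess (direct Boltzmann
inversion, ``V = -kB T ln p``), sample the resulting model with the MC
sampler, compare distributions, and nudge the harmonic parameters until
the model's distributions match the targets:

    x0 <- x0 + damping * (mean_target - mean_model)
    k  <- k * (var_model / var_target) ** damping

Angle distributions are divided by sin(theta) (and bond distributions by
r^2) before log-inversion where a potential of the *internal* coordinate
is wanted; the iterative loop itself needs no Jacobian handling because
both sides of the comparison are sampled by the same machinery.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import KB
from .diststats import DistributionSet, MAEReport, TermDistribution, extract_distributions, mae_between
from .sampler import SamplerConfig, sample
from .topology import CGTopology

__all__ = [
    "FitConfig",
    "FitReport",
    "HarmonicFit",
    "DegenerateFitError",
    "invert_harmonic",
    "fit_quartic_angle",
    "fit_dihedral",
    "initial_guess",
    "refine",
]

#: density floor for log-inversion, as a fraction of the peak density
DENSITY_FLOOR = 1e-4

#: convergence thresholds defaulting to the achieved cross-resolution MAEs
#: of the published motor/switch models (nm, degrees, degrees)
DEFAULT_THRESHOLDS = {"bonds": 0.0025, "angles_unimodal": 5.5, "angles_bimodal": 11.4}


class DegenerateFitError(ValueError):
    pass


@dataclass
class FitConfig:
    temperature: float = 300.0
    max_iterations: int = 12
    thresholds: dict = field(default_factory=lambda: dict(DEFAULT_THRESHOLDS))
    damping: float = 0.7
    seed: int = 0
    sampler_steps: int = 300_000
    sampler_stride: int = 20

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0")
        if not 0 < self.damping <= 1:
            raise ValueError("damping must lie in (0, 1]")
        if any(v <= 0 for v in self.thresholds.values()):
            raise ValueError("thresholds must be > 0")


@dataclass
class FitReport:
    converged: bool
    n_iterations: int
    trace: list[MAEReport]  # one comparison per iteration
    final_mae: MAEReport | None = None

    def trace_values(self, category: str) -> list[float]:
        attr = {"bonds": "mae_bonds", "angles_unimodal": "mae_angles_unimodal",
                "angles_bimodal": "mae_angles_bimodal"}[category]
        return [getattr(r, attr) for r in self.trace]


@dataclass
class HarmonicFit:
    x0: float  # nm (bond) or degrees (angle)
    k: float | None  # kJ/mol/nm^2 or kJ/mol/rad^2; None when constrained
    constrained: bool = False


def invert_harmonic(dist: TermDistribution, T: float = 300.0) -> HarmonicFit:
    """Gaussian Boltzmann inversion: x0 = mean, k = kB T / sigma^2.

    A vanishing sigma signals a fixed length: the term should be a
    constraint, and no force constant is returned.
    """
    if dist.std <= 1e-9:  # numerically rigid (nm or degrees)
        return HarmonicFit(x0=dist.mean, k=None, constrained=True)
    sigma = dist.std
    if dist.kind in ("angle", "dihedral"):
        sigma = np.deg2rad(sigma)
    return HarmonicFit(x0=dist.mean, k=float(KB * T / sigma**2))


def _occupied(dist: TermDistribution, floor: float = DENSITY_FLOOR):
    mask = dist.density >= floor * dist.density.max()
    return dist.centers[mask], dist.density[mask]


def fit_quartic_angle(
    dist: TermDistribution,
    T: float = 300.0,
    jacobian: bool = True,
) -> tuple[float, tuple[float, float, float, float, float]]:
    """Fit a quartic angle potential to a (typically bimodal) distribution.

    The free energy ``-kB T ln p`` over occupied bins (``p`` divided by
    sin(theta) when ``jacobian``), offset so its minimum is zero, is
    least-squares fitted by ``sum_n C_n (theta - theta0)^n`` with theta0
    the density-weighted circular mean.  Returns ``(theta0 degrees,
    (C0..C4))`` with coefficients in kJ/mol/rad^n.
    """
    centers, density = _occupied(dist)
    if len(centers) < 6:
        raise DegenerateFitError(
            "quartic fit needs at least 6 occupied bins "
            f"(got {len(centers)}); distribution is too narrow"
        )
    th = np.deg2rad(centers)
    p = density.copy()
    if jacobian:
        p = p / np.sin(np.clip(th, 1e-6, np.pi - 1e-6))
    v = -KB * T * np.log(p)
    v -= v.min()
    # density-weighted circular mean of the angle
    z = np.sum(dist.density * np.exp(1j * np.deg2rad(dist.centers)))
    theta0 = float(np.angle(z)) % (2 * np.pi)
    x = th - theta0
    basis = np.vander(x, 5, increasing=True)  # columns x^0..x^4
    coeffs, *_ = np.linalg.lstsq(basis, v, rcond=None)
    return float(np.rad2deg(theta0)), tuple(float(c) for c in coeffs)


def fit_dihedral(
    dist: TermDistribution,
    T: float = 300.0,
    multiplicities: list[int] = (1, 2, 3),
) -> list[tuple[int, float, float]]:
    """Fit proper-dihedral cosine terms to a dihedral distribution.

    ``-kB T ln p(phi)`` is expanded on the basis ``{1 + cos(n phi - phi0_n)}``
    with phases restricted to {0, 180} degrees: the fit is linear with
    phase 0 and negative amplitudes are folded to phase 180.  Returns
    ``[(n, phase_deg, k_phi), ...]``.
    """
    if len(multiplicities) == 0:
        raise ValueError("need at least one multiplicity")
    centers, density = _occupied(dist)
    if len(centers) == 0:
        raise DegenerateFitError("empty dihedral histogram")
    phi = np.deg2rad(centers)
    v = -KB * T * np.log(density)
    v -= v.min()
    cols = [np.ones_like(phi)]  # free constant (gauge of the potential)
    for n in multiplicities:
        cols.append(1.0 + np.cos(n * phi))
    basis = np.column_stack(cols)
    coeffs, *_ = np.linalg.lstsq(basis, v, rcond=None)
    terms = []
    for n, k in zip(multiplicities, coeffs[1:]):
        if k >= 0:
            terms.append((int(n), 0.0, float(k)))
        else:
            terms.append((int(n), 180.0, float(-k)))
    return terms


def initial_guess(
    template: CGTopology,
    target: DistributionSet,
    T: float = 300.0,
    dihedral_multiplicities: list[int] = (1, 2, 3),
) -> CGTopology:
    """Direct Boltzmann inversion of every target distribution, keeping the
    template's connectivity, bead definitions and term forms."""
    top = template.copy()
    for b in top.bonds:
        d = target[f"bond:{b.i}-{b.j}"]
        fit = invert_harmonic(d, T)
        b.r0 = fit.x0
        if fit.constrained:
            b.constrained = True
        else:
            b.k = fit.k
    for a in top.angles:
        d = target[f"angle:{a.i}-{a.j}-{a.k}"]
        if a.form == "quartic" or d.modality == "bimodal":
            theta0, coeffs = fit_quartic_angle(d, T)
            a.form = "quartic"
            a.theta0 = theta0
            a.quartic_coeffs = coeffs
            a.kf = 0.0
        else:
            fit = invert_harmonic(d, T)
            a.theta0 = fit.x0
            a.kf = fit.k
    for dh in top.dihedrals:
        d = target[f"dihedral:{dh.i}-{dh.j}-{dh.k}-{dh.l}"]
        mults = [t[0] for t in dh.terms] or list(dihedral_multiplicities)
        dh.terms = fit_dihedral(d, T, mults)
    return top


def refine(
    top0: CGTopology,
    target: DistributionSet,
    cfg: FitConfig,
    start_coords: np.ndarray | None = None,
) -> tuple[CGTopology, FitReport]:
    """Iterative distribution matching of the harmonic bonded terms.

    Each iteration samples the current topology, extracts its
    distributions, compares them with the target and applies the damped
    mean/variance update to every harmonic bond and angle.  Quartic angles
    and dihedral profiles are set once by direct inversion and are not
    re-fitted.  Stops when the category MAEs drop below ``cfg.thresholds``
    or after ``cfg.max_iterations``; if the loop never meets the
    thresholds the best iterate seen is returned with ``converged=False``.
    """
    missing = {f"bond:{b.i}-{b.j}" for b in top0.bonds} \
        | {f"angle:{a.i}-{a.j}-{a.k}" for a in top0.angles} \
        | {f"dihedral:{d.i}-{d.j}-{d.k}-{d.l}" for d in top0.dihedrals}
    missing -= set(target.terms)
    if missing:
        raise ValueError(f"target lacks distributions for terms: {sorted(missing)}")

    current = top0.copy()
    trace: list[MAEReport] = []
    best_top = current.copy()
    best_score = np.inf

    for it in range(cfg.max_iterations):
        scfg = SamplerConfig(
            temperature=cfg.temperature, n_steps=cfg.sampler_steps,
            stride=cfg.sampler_stride, seed=cfg.seed + it,
        )
        ens = sample(current, scfg, start=start_coords)
        model = extract_distributions(ens, current)
        report = mae_between(target, model, thresholds=cfg.thresholds)
        trace.append(report)

        score = 0.0
        for cat, thr in cfg.thresholds.items():
            val = {"bonds": report.mae_bonds,
                   "angles_unimodal": report.mae_angles_unimodal,
                   "angles_bimodal": report.mae_angles_bimodal}.get(cat)
            if val is not None:
                score += val / thr
        if score < best_score:
            best_score = score
            best_top = current.copy()
        if report.passed():
            return current, FitReport(converged=True, n_iterations=it + 1,
                                      trace=trace, final_mae=report)

        # damped update of harmonic terms
        for b in current.bonds:
            if b.constrained:
                continue
            tid = f"bond:{b.i}-{b.j}"
            tgt, mod = target[tid], model[tid]
            b.r0 = max(b.r0 + cfg.damping * (tgt.mean - mod.mean), 1e-3)
            if tgt.std > 0 and mod.std > 0:
                b.k *= (mod.std**2 / tgt.std**2) ** cfg.damping
        for a in current.angles:
            if a.form != "harmonic":
                continue
            tid = f"angle:{a.i}-{a.j}-{a.k}"
            tgt, mod = target[tid], model[tid]
            a.theta0 = float(np.clip(a.theta0 + cfg.damping * (tgt.mean - mod.mean),
                                     1.0, 179.0))
            if tgt.std > 0 and mod.std > 0:
                a.kf *= (mod.std**2 / tgt.std**2) ** cfg.damping

    return best_top, FitReport(converged=False, n_iterations=cfg.max_iterations,
                               trace=trace, final_mae=trace[-1] if trace else None)
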