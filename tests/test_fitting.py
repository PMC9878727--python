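"""Boltzmann inversion and iterative distribution-matching."""

import numpy as np
import pytest

from cgmotor.constants import KB
from cgmotor.diststats import _make_distribution, extract_distributions
from cgmotor.fitting import (
    DegenerateFitError,
    FitConfig,
    fit_dihedral,
    fit_quartic_angle,
    invert_harmonic,
    refine,
)
from cgmotor.sampler import SamplerConfig, sample
from cgmotor.topology import BeadDef, BondTerm, CGTopology


def _dist_from_samples(samples, kind, bin_width=None):
    if bin_width is None:
        bin_width = 0.001 if kind == "bond" else 1.0
    return _make_distribution(f"{kind}:x", kind, np.asarray(samples, float), bin_width)


class TestInvertHarmonic:
    def test_bond_sigma_001(self, rng):
        d = _dist_from_samples(rng.normal(0.35, 0.01, 400_000), "bond")
        fit = invert_harmonic(d, T=300.0)
        assert fit.k == pytest.approx(KB * 300 / 0.01**2, rel=0.02)  # 24943.5
        assert fit.x0 == pytest.approx(d.mean)

    def test_angle_sigma_5deg(self, rng):
        d = _dist_from_samples(rng.normal(110.0, 5.0, 400_000), "angle")
        fit = invert_harmonic(d, T=300.0)
        assert fit.k == pytest.approx(KB * 300 / np.deg2rad(5.0) ** 2, rel=0.02)  # ~327.5

    def test_x0_is_mean_exactly(self, rng):
        d = _dist_from_samples(rng.normal(0.42, 0.02, 1000), "bond")
        assert invert_harmonic(d).x0 == d.mean

    def test_zero_sigma_suggests_constraint(self):
        d = _dist_from_samples(np.full(100, 0.35), "bond")
        fit = invert_harmonic(d)
        assert fit.constrained and fit.k is None

    def test_gaussian_stats_identity_round_trip(self, rng):
        """invert_harmonic on exact-Gaussian samples recovers (x0, k)."""
        k_true, x0_true = 5000.0, 0.38
        sigma = np.sqrt(KB * 300 / k_true)
        d = _dist_from_samples(rng.normal(x0_true, sigma, 100_000), "bond")
        fit = invert_harmonic(d, T=300.0)
        assert fit.x0 == pytest.approx(x0_true, rel=0.02)
        assert fit.k == pytest.approx(k_true, rel=0.02)


class TestQuarticAngle:
    def _sample_quartic(self, c2, c4, theta0_deg, n, rng):
        """Exact Boltzmann draws of the angle marginal sin(th) exp(-beta V)."""
        grid = np.linspace(1e-3, np.pi - 1e-3, 4000)
        x = grid - np.deg2rad(theta0_deg)
        V = c2 * x**2 + c4 * x**4
        p = np.sin(grid) * np.exp(-(V - V.min()) / (KB * 300))
        cdf = np.concatenate([[0], np.cumsum((p[1:] + p[:-1]) / 2 * np.diff(grid))])
        cdf /= cdf[-1]
        return np.rad2deg(np.interp(rng.random(n), cdf, grid))

    def test_recover_planted_double_well(self, rng):
        """The fitted quartic reproduces the planted well positions and
        barrier (the expansion point theta0 is a fit-internal gauge, so the
        comparison is on the potential's shape, not raw coefficients)."""
        samples = self._sample_quartic(-42.0, 110.4, 105.0, 300_000, rng)
        theta0, coeffs = fit_quartic_angle(_dist_from_samples(samples, "angle"), T=300.0)
        grid = np.deg2rad(np.linspace(55.0, 155.0, 2001))
        x = grid - np.deg2rad(theta0)
        v = sum(c * x**n for n, c in enumerate(coeffs))
        minima_idx = [i for i in range(1, len(grid) - 1)
                      if v[i] < v[i - 1] and v[i] < v[i + 1]]
        assert len(minima_idx) == 2
        lo, hi = np.rad2deg(grid[minima_idx])
        assert lo == pytest.approx(80.0, abs=2.5)
        assert hi == pytest.approx(130.0, abs=2.5)
        barrier = v[minima_idx[0]:minima_idx[1]].max() - v[minima_idx].mean()
        assert barrier == pytest.approx(42.0**2 / (4 * 110.4), rel=0.25)

    def test_gaussian_input_reduces_to_harmonic(self, rng):
        sigma_deg = 5.0
        samples = rng.normal(100.0, sigma_deg, 500_000)
        theta0, coeffs = fit_quartic_angle(
            _dist_from_samples(samples, "angle"), T=300.0, jacobian=False)
        k_expect = KB * 300 / np.deg2rad(sigma_deg) ** 2
        assert 2 * coeffs[2] == pytest.approx(k_expect, rel=0.15)
        # C3, C4 contribute little over the sampled support (+-3 sigma)
        x3 = np.deg2rad(3 * sigma_deg)
        assert abs(coeffs[3]) * x3**3 < 0.2 * 0.5 * k_expect * x3**2
        assert abs(coeffs[4]) * x3**4 < 0.2 * 0.5 * k_expect * x3**2

    def test_density_floor_masks_empty_bins(self, rng):
        samples = rng.normal(100.0, 4.0, 50_000)
        d = _dist_from_samples(samples, "angle")
        theta0, coeffs = fit_quartic_angle(d, T=300.0)
        assert np.isfinite(coeffs).all()

    def test_all_density_in_one_bin_degenerate(self):
        d = _dist_from_samples(np.full(100, 100.0), "angle")
        with pytest.raises(DegenerateFitError):
            fit_quartic_angle(d)


class TestDihedral:
    def _sample_dihedral(self, terms, n, rng):
        grid = np.linspace(-np.pi, np.pi, 4001)
        V = sum(k * (1 + np.cos(m * grid - np.deg2rad(p))) for m, p, k in terms)
        p = np.exp(-(V - V.min()) / (KB * 300))
        cdf = np.concatenate([[0], np.cumsum((p[1:] + p[:-1]) / 2 * np.diff(grid))])
        cdf /= cdf[-1]
        return np.rad2deg(np.interp(rng.random(n), cdf, grid))

    def test_single_n2_term_recovery(self, rng):
        samples = self._sample_dihedral([(2, 0.0, 5.0)], 400_000, rng)
        terms = fit_dihedral(_dist_from_samples(samples, "dihedral"), T=300.0,
                             multiplicities=[2])
        n, phase, k = terms[0]
        assert (n, phase) == (2, 0.0)
        assert k == pytest.approx(5.0, rel=0.10)

    def test_uniform_density_gives_zero_amplitudes(self, rng):
        samples = rng.uniform(-180, 180, 400_000)
        terms = fit_dihedral(_dist_from_samples(samples, "dihedral"), T=300.0,
                             multiplicities=[1, 2, 3])
        for _, _, k in terms:
            assert abs(k) < 0.1

    def test_two_term_beats_single_term(self, rng):
        planted = [(1, 0.0, 2.0), (2, 0.0, 4.0)]
        samples = self._sample_dihedral(planted, 400_000, rng)
        d = _dist_from_samples(samples, "dihedral")

        def residual(terms):
            centers, density = d.centers, d.density
            mask = density >= 1e-4 * density.max()
            phi = np.deg2rad(centers[mask])
            v = -KB * 300 * np.log(density[mask])
            v -= v.min()
            pred = sum(k * (1 + np.cos(n * phi - np.deg2rad(p))) for n, p, k in terms)
            # allow the free gauge constant
            return np.sum((v - pred - np.mean(v - pred)) ** 2)

        r2 = residual(fit_dihedral(d, multiplicities=[1, 2]))
        r1 = residual(fit_dihedral(d, multiplicities=[2]))
        assert r2 < r1

    def test_negative_amplitude_folds_to_phase_180(self, rng):
        # a well at phi=0 needs k(1+cos(phi-180)) i.e. phase 180 with k>0
        samples = self._sample_dihedral([(1, 180.0, 6.0)], 200_000, rng)
        terms = fit_dihedral(_dist_from_samples(samples, "dihedral"),
                             multiplicities=[1])
        n, phase, k = terms[0]
        assert phase == 180.0 and k > 0


class TestRefine:
    def _bond_top(self, r0, k):
        return CGTopology("b2", [BeadDef("A"), BeadDef("B"), BeadDef("C")],
                          bonds=[BondTerm(0, 1, r0=r0, k=k),
                                 BondTerm(1, 2, r0=r0 + 0.04, k=k * 0.8)])

    @pytest.fixture(scope="class")
    def bond_target(self):
        top = self._bond_top(0.35, 6000.0)
        ens = sample(top, SamplerConfig(n_steps=400_000, stride=10, seed=21))
        return top, extract_distributions(ens, top)

    def test_fixpoint_converges_at_iteration_zero(self, bond_target):
        top, target = bond_target
        cfg = FitConfig(seed=22, max_iterations=5, sampler_steps=200_000)
        fitted, report = refine(top, target, cfg)
        assert report.converged
        assert report.n_iterations == 1  # passed on the first comparison
        assert fitted.bonds[0].r0 == top.bonds[0].r0  # never updated

    def test_perturbed_start_recovers(self, bond_target):
        top, target = bond_target
        start = self._bond_top(0.36, 7200.0)  # +0.01 nm, +20% k
        cfg = FitConfig(seed=23, max_iterations=10, sampler_steps=200_000)
        fitted, report = refine(start, target, cfg)
        assert report.converged
        assert report.final_mae.mae_bonds <= 0.0025
        for fb, tb in zip(fitted.bonds, top.bonds):
            assert fb.r0 == pytest.approx(tb.r0, abs=0.005)
            assert fb.k == pytest.approx(tb.k, rel=0.25)

    def test_damping_path_independence(self, bond_target):
        top, target = bond_target
        start = self._bond_top(0.36, 7200.0)
        fits = []
        for damping, seed in ((1.0, 31), (0.5, 32)):
            cfg = FitConfig(seed=seed, max_iterations=12, damping=damping,
                            sampler_steps=200_000)
            fitted, report = refine(start, target, cfg)
            assert report.converged
            fits.append(fitted)
        for b1, b2 in zip(fits[0].bonds, fits[1].bonds):
            assert b1.r0 == pytest.approx(b2.r0, abs=0.004)
            assert b1.k == pytest.approx(b2.k, rel=0.3)

    def test_missing_target_terms_rejected(self, bond_target):
        top, target = bond_target
        bigger = CGTopology("b3", [BeadDef("A"), BeadDef("B"), BeadDef("C"),
                                   BeadDef("D")],
                            bonds=[BondTerm(0, 1, 0.35, 6000.0),
                                   BondTerm(1, 2, 0.39, 4800.0),
                                   BondTerm(2, 3, 0.40, 4000.0)])
        with pytest.raises(ValueError, match="bond:2-3"):
            refine(bigger, target, FitConfig(seed=1))


class TestStiffBondRoundTrip:
    def test_k_recovered_within_5_percent(self):
        """Sampling + Gaussian inversion recovers a stiff bond force
        constant despite the radial Jacobian (k r0^2 / kBT ~ 400)."""
        k_true = 8000.0
        top = CGTopology("s", [BeadDef("A"), BeadDef("B")],
                         bonds=[BondTerm(0, 1, r0=0.35, k=k_true)])
        start = np.array([[0.0, 0.0, 0.0], [0.35, 0.0, 0.0]])
        ens = sample(top, SamplerConfig(n_steps=1_000_000, stride=10, seed=41),
                     start=start)
        d = extract_distributions(ens, top)["bond:0-1"]
        fit = invert_harmonic(d, T=300.0)
        assert fit.k == pytest.approx(k_true, rel=0.05)
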