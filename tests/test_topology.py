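"""Topology model: bonded energies, virtual sites, validation."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from cgmotor.topology import (
    AngleTerm,
    BeadDef,
    BondTerm,
    CGTopology,
    DihedralTerm,
    GeometryError,
    TopologyError,
    VirtualSiteDef,
    bonded_energy,
    dihedral_values,
    place_virtual_sites,
)


def _chain_top(n=4, **kw):
    return CGTopology(
        "chain", [BeadDef(f"B{i}") for i in range(n)],
        bonds=[BondTerm(i, i + 1, r0=0.35, k=1000.0) for i in range(n - 1)],
        **kw,
    )


class TestBondedEnergy:
    def test_single_bond_closed_form(self):
        top = CGTopology("b", [BeadDef("A"), BeadDef("B")],
                         bonds=[BondTerm(0, 1, r0=0.35, k=1250.0)])
        coords = np.array([[0.0, 0.0, 0.0], [0.40, 0.0, 0.0]])
        e, br = bonded_energy(top, coords)
        assert e == pytest.approx(0.5 * 1250.0 * 0.05**2)  # 1.5625 kJ/mol
        assert br["bonds"][0] == pytest.approx(1.5625)

    def test_equilibrium_geometry_is_zero(self):
        top = CGTopology(
            "eq", [BeadDef(f"B{i}") for i in range(3)],
            bonds=[BondTerm(0, 1, r0=0.35, k=5000.0), BondTerm(1, 2, r0=0.35, k=5000.0)],
            angles=[AngleTerm(0, 1, 2, theta0=90.0, kf=100.0,)],
        )
        coords = np.array([[0.35, 0.0, 0.0], [0.0, 0.0, 0.0], [0.0, 0.35, 0.0]])
        e, _ = bonded_energy(top, coords)
        assert e == pytest.approx(0.0, abs=1e-12)

    def test_quartic_c0_zero_minimum(self):
        top = CGTopology(
            "q", [BeadDef(f"B{i}") for i in range(3)],
            bonds=[BondTerm(0, 1, r0=0.35, k=5000.0), BondTerm(1, 2, r0=0.35, k=5000.0)],
            angles=[AngleTerm(0, 1, 2, theta0=120.0, form="quartic",
                              quartic_coeffs=(0.0, 0.0, 50.0, 0.0, 10.0))],
        )
        th = np.deg2rad(120.0)
        coords = np.array([[0.35, 0.0, 0.0], [0.0, 0.0, 0.0],
                           [0.35 * np.cos(th), 0.35 * np.sin(th), 0.0]])
        assert bonded_energy(top, coords)[0] == pytest.approx(0.0, abs=1e-12)

    def test_constrained_bond_contributes_zero(self):
        top = CGTopology("c", [BeadDef("A"), BeadDef("B")],
                         bonds=[BondTerm(0, 1, r0=0.35, constrained=True)])
        coords = np.array([[0.0, 0.0, 0.0], [0.9, 0.0, 0.0]])
        assert bonded_energy(top, coords)[0] == 0.0

    def test_random_seven_bead_brute_force(self, rng):
        """Total equals an independent term-by-term hand evaluation."""
        top = CGTopology(
            "seven", [BeadDef(f"B{i}") for i in range(7)],
            bonds=[BondTerm(0, 1, 0.33, 900.0), BondTerm(1, 2, 0.41, 1500.0),
                   BondTerm(2, 3, 0.37, 700.0), BondTerm(3, 4, 0.35, 2000.0),
                   BondTerm(4, 5, 0.36, 1100.0), BondTerm(5, 6, 0.39, 1300.0)],
            angles=[AngleTerm(0, 1, 2, 110.0, kf=90.0),
                    AngleTerm(2, 3, 4, 95.0, form="quartic",
                              quartic_coeffs=(1.0, -2.0, 30.0, 4.0, 60.0))],
            dihedrals=[DihedralTerm(0, 1, 2, 3, [(1, 0.0, 3.0), (2, 180.0, 1.5)])],
        )
        coords = rng.normal(scale=0.4, size=(7, 3))

        def brute(c):
            e = 0.0
            for b in top.bonds:
                r = np.linalg.norm(c[b.j] - c[b.i])
                e += 0.5 * b.k * (r - b.r0) ** 2
            for a in top.angles:
                u, v = c[a.i] - c[a.j], c[a.k] - c[a.j]
                th = np.arccos(np.dot(u, v) / np.linalg.norm(u) / np.linalg.norm(v))
                x = th - np.deg2rad(a.theta0)
                if a.form == "harmonic":
                    e += 0.5 * a.kf * x**2
                else:
                    e += sum(cn * x**n for n, cn in enumerate(a.quartic_coeffs))
            for d in top.dihedrals:
                phi = dihedral_values(c, [d])[0]
                for n, p, kp in d.terms:
                    e += kp * (1 + np.cos(n * phi - np.deg2rad(p)))
            return e

        e, _ = bonded_energy(top, coords)
        assert e == pytest.approx(brute(coords), rel=1e-12)

    def test_rigid_motion_invariance(self, rng):
        top = CGTopology(
            "inv", [BeadDef(f"B{i}") for i in range(5)],
            bonds=[BondTerm(i, i + 1, 0.35, 1000.0) for i in range(4)],
            angles=[AngleTerm(0, 1, 2, 120.0, kf=80.0),
                    AngleTerm(1, 2, 3, 100.0, kf=120.0)],
            dihedrals=[DihedralTerm(0, 1, 2, 3, [(2, 0.0, 4.0)])],
        )
        for _ in range(10):
            coords = rng.normal(scale=0.4, size=(5, 3))
            e0 = bonded_energy(top, coords)[0]
            R = Rotation.random(random_state=rng).as_matrix()
            t = rng.normal(scale=2.0, size=3)
            e1 = bonded_energy(top, coords @ R.T + t)[0]
            assert e1 == pytest.approx(e0, abs=1e-9)

    def test_quartic_with_c2_half_kf_equals_harmonic(self, rng):
        kf = 137.0
        mk = lambda form, coeffs=None: CGTopology(
            "a", [BeadDef(f"B{i}") for i in range(3)],
            bonds=[BondTerm(0, 1, 0.35, 1.0), BondTerm(1, 2, 0.35, 1.0)],
            angles=[AngleTerm(0, 1, 2, 105.0, kf=kf, form=form,
                              quartic_coeffs=coeffs)],
        )
        th_harm = mk("harmonic")
        th_quart = mk("quartic", (0.0, 0.0, kf / 2.0, 0.0, 0.0))
        for _ in range(20):
            coords = rng.normal(scale=0.4, size=(3, 3))
            assert bonded_energy(th_quart, coords)[0] == pytest.approx(
                bonded_energy(th_harm, coords)[0], abs=1e-10)

    def test_degenerate_angle_geometry_raises(self):
        top = CGTopology(
            "bad", [BeadDef(f"B{i}") for i in range(3)],
            bonds=[BondTerm(0, 1, 0.35, 1.0), BondTerm(1, 2, 0.35, 1.0)],
            angles=[AngleTerm(0, 1, 2, 100.0, kf=10.0)],
        )
        coords = np.array([[0.0, 0.0, 0.0], [0.0, 0.0, 0.0], [0.3, 0.0, 0.0]])
        with pytest.raises(GeometryError):
            bonded_energy(top, coords)


class TestVirtualSites:
    def test_cog_equilateral_triangle_centroid(self):
        top = CGTopology(
            "v", [BeadDef("A"), BeadDef("B"), BeadDef("C"),
                  BeadDef("V", is_virtual=True)],
            bonds=[BondTerm(0, 1, 0.35, 1.0), BondTerm(1, 2, 0.35, 1.0)],
            virtual_sites=[VirtualSiteDef(3, (0, 1, 2), rule="cog")],
        )
        tri = np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0], [0.5, np.sqrt(3) / 2, 0.0],
                        [9.0, 9.0, 9.0]])
        out = place_virtual_sites(top, tri)
        assert out[3] == pytest.approx(tri[:3].mean(axis=0))

    def test_weighted_midpoint(self):
        top = CGTopology(
            "v", [BeadDef("A"), BeadDef("B"), BeadDef("V", is_virtual=True)],
            bonds=[BondTerm(0, 1, 0.35, 1.0)],
            virtual_sites=[VirtualSiteDef(2, (0, 1), rule="weighted",
                                          weights=(0.5, 0.5))],
        )
        coords = np.array([[0.0, 0.0, 0.0], [1.0, 2.0, 3.0], [0.0, 0.0, 0.0]])
        out = place_virtual_sites(top, coords)
        assert out[2] == pytest.approx([0.5, 1.0, 1.5])

    def test_four_constructors_match_explicit_mean(self, rng):
        top = CGTopology(
            "v", [*(BeadDef(f"B{i}") for i in range(4)), BeadDef("V", is_virtual=True)],
            bonds=[BondTerm(i, i + 1, 0.35, 1.0) for i in range(3)],
            virtual_sites=[VirtualSiteDef(4, (0, 1, 2, 3), rule="cog")],
        )
        coords = np.vstack([rng.normal(size=(4, 3)), np.zeros(3)])
        out = place_virtual_sites(top, coords)
        assert out[4] == pytest.approx(coords[:4].mean(axis=0))
        # idempotent
        assert place_virtual_sites(top, out)[4] == pytest.approx(out[4])

    def test_empty_constructors_rejected(self):
        with pytest.raises(TopologyError):
            VirtualSiteDef(2, (), rule="cog")

    def test_weights_must_sum_to_one(self):
        with pytest.raises(TopologyError):
            VirtualSiteDef(2, (0, 1), rule="weighted", weights=(0.7, 0.6))


class TestValidation:
    def test_out_of_range_index(self):
        with pytest.raises(TopologyError, match="99"):
            CGTopology("bad", [BeadDef(f"B{i}") for i in range(5)],
                       bonds=[BondTerm(0, 99, 0.35, 100.0)])

    def test_virtual_bead_needs_rule(self):
        with pytest.raises(TopologyError):
            CGTopology("bad", [BeadDef("A"), BeadDef("V", is_virtual=True)],
                       bonds=[BondTerm(0, 1, 0.35, 1.0)])

    def test_dihedral_through_vsite_allowed(self, toy_spec):
        # stator-rotor dihedral pivoting on the virtual bead is legal
        assert any(8 in (d.i, d.j, d.k, d.l) for d in toy_spec.topology.dihedrals)

    def test_bead_class_radius_defaults(self):
        assert BeadDef("r").radius == pytest.approx(0.264)
        assert BeadDef("s", bead_class="small").radius == pytest.approx(0.230)
        assert BeadDef("t", bead_class="tiny").radius == pytest.approx(0.191)

    def test_frame_length_mismatch(self):
        top = _chain_top(4)
        with pytest.raises(ValueError):
            bonded_energy(top, np.zeros((3, 3)))
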