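"""Monte Carlo sampler: Boltzmann correctness, determinism, constraints,
and the rotation / topology-switch drivers."""

import numpy as np
import pytest
from scipy import stats as sps

from cgmotor.constants import KB
from cgmotor.diststats import dihedral_series, extract_distributions
from cgmotor.sampler import (
    RotationDriver,
    SamplerConfig,
    StuckChainError,
    build_initial_coords,
    enforced_rotation,
    sample,
    switch_topology,
)
from cgmotor.topology import (
    AngleTerm,
    BeadDef,
    BondTerm,
    CGTopology,
    DihedralTerm,
    TopologyError,
)

BOND_START = np.array([[0.0, 0.0, 0.0], [0.35, 0.0, 0.0]])


def _bond_top(k=1250.0, r0=0.35, constrained=False):
    return CGTopology("b", [BeadDef("A"), BeadDef("B")],
                      bonds=[BondTerm(0, 1, r0=r0, k=k, constrained=constrained)])


class TestEquilibrium:
    def test_seed_determinism(self, toy_spec, toy_start):
        cfg = SamplerConfig(n_steps=30_000, stride=10, seed=7)
        e1 = sample(toy_spec.topology, cfg, start=toy_start)
        e2 = sample(toy_spec.topology, cfg, start=toy_start)
        assert np.array_equal(e1.frames, e2.frames)

    def test_different_seeds_differ(self, toy_spec, toy_start):
        e1 = sample(toy_spec.topology, SamplerConfig(n_steps=30_000, seed=7),
                    start=toy_start)
        e2 = sample(toy_spec.topology, SamplerConfig(n_steps=30_000, seed=8),
                    start=toy_start)
        assert not np.array_equal(e1.frames, e2.frames)

    def test_constrained_bond_exact_length(self):
        top = _bond_top(constrained=True)
        ens = sample(top, SamplerConfig(n_steps=50_000, stride=10, seed=5),
                     start=BOND_START)
        r = np.linalg.norm(ens.frames[:, 1] - ens.frames[:, 0], axis=1)
        assert np.max(np.abs(r - 0.35)) < 1e-12

    def test_detailed_balance_bond_length_ks(self):
        """Sampled bond-length density matches the analytic Boltzmann
        marginal p(r) ~ r^2 exp(-beta k (r-r0)^2 / 2)."""
        top = _bond_top(k=1250.0)
        ens = sample(top, SamplerConfig(n_steps=1_000_000, stride=10, seed=0),
                     start=BOND_START)
        r = np.linalg.norm(ens.frames[:, 1] - ens.frames[:, 0], axis=1)
        beta = 1.0 / (KB * 300.0)
        grid = np.linspace(0.05, 0.8, 4000)
        p = grid**2 * np.exp(-beta * 0.5 * 1250.0 * (grid - 0.35) ** 2)
        cdf_y = np.concatenate([[0], np.cumsum((p[1:] + p[:-1]) / 2 * np.diff(grid))])
        cdf_y /= cdf_y[-1]
        stat = sps.kstest(r, lambda x: np.interp(x, grid, cdf_y)).statistic
        assert stat < 0.02

    def test_acceptance_adaptation_targets_40_percent(self, toy_spec, toy_start):
        cfg = SamplerConfig(n_steps=200_000, stride=10, seed=3)
        ens = sample(toy_spec.topology, cfg, start=toy_start)
        assert 0.25 <= ens.metadata["acceptance_rate"] <= 0.55

    def test_virtual_site_follows_constructors(self, toy_spec, toy_start):
        ens = sample(toy_spec.topology, SamplerConfig(n_steps=30_000, seed=2),
                     start=toy_start)
        cog = ens.frames[:, [0, 1, 2]].mean(axis=1)
        assert np.allclose(ens.frames[:, 8], cog, atol=1e-12)

    def test_stuck_chain_error(self):
        top = _bond_top(k=1e8)
        cfg = SamplerConfig(n_steps=30_000, stride=10, seed=1, move_sigma=5.0,
                            adapt=False, temperature=1.0)
        with pytest.raises(StuckChainError):
            sample(top, cfg, start=BOND_START)

    def test_constraint_network_rejected(self):
        # a bead tied into two constrained bonds has no supported move
        chain = CGTopology(
            "cc", [BeadDef("A"), BeadDef("B"), BeadDef("C")],
            bonds=[BondTerm(0, 1, 0.3, constrained=True),
                   BondTerm(1, 2, 0.3, constrained=True)])
        with pytest.raises(TopologyError, match="constrained"):
            sample(chain, SamplerConfig(n_steps=100, stride=1, seed=1),
                   start=np.array([[0, 0, 0], [0.3, 0, 0], [0.6, 0, 0.0]]))


class TestEnforcedRotation:
    @pytest.fixture(scope="class")
    def rotation_run(self, toy_spec, toy_start):
        drv = RotationDriver(rotation_group=(5, 6, 7), axis_beads=(3, 4),
                             rate=80.0, k_rot=280.0)
        cfg = SamplerConfig(n_steps=1000, stride=5, seed=2, move_sigma=0.02)
        return enforced_rotation(toy_spec.topology, drv, duration=9.0, cfg=cfg,
                                 start=toy_start)

    def test_full_turn_in_4_5_ps(self, rotation_run):
        """At 80 deg/ps the rotor completes 360 degrees in ~4.5 ps."""
        _, trace = rotation_run
        t, ref, rot = trace[:, 0], trace[:, 1], trace[:, 2]
        rate_fit = np.polyfit(t, rot, 1)[0]
        assert 360.0 / rate_fit == pytest.approx(4.5, abs=0.15)
        # the driving reference is exact: 360 deg at exactly 4.5 ps
        assert np.interp(4.5, t, ref) == pytest.approx(360.0, abs=1.0)

    def test_rotor_lag_bounded(self, rotation_run):
        """The restrained follower shows a bounded steady lag, not a
        secular drift away from the reference."""
        _, trace = rotation_run
        lag = trace[:, 1] - trace[:, 2]
        assert abs(lag.mean()) < 90.0  # stays locked within a quarter turn
        assert np.max(np.abs(lag)) < 180.0  # never slips a half-turn
        # steady state: the late-time mean lag matches the mid-run mean
        half = len(lag) // 2
        assert abs(lag[half:].mean() - lag[:half].mean()) < 45.0

    def test_zero_rate_reference_static(self, toy_spec, toy_start):
        drv = RotationDriver(rotation_group=(5, 6, 7), axis_beads=(3, 4),
                             rate=0.0, k_rot=280.0)
        cfg = SamplerConfig(n_steps=1000, stride=5, seed=2, move_sigma=0.02)
        _, trace = enforced_rotation(toy_spec.topology, drv, duration=5.0, cfg=cfg,
                                     start=toy_start)
        assert np.all(trace[:, 1] == 0.0)
        assert abs(trace[:, 2].mean()) < 15.0

    def test_degenerate_axis_rejected(self, toy_spec, toy_start):
        drv = RotationDriver(rotation_group=(5, 6, 7), axis_beads=(3, 4))
        coords = toy_start.copy()
        coords[4] = coords[3]
        cfg = SamplerConfig(n_steps=1000, stride=5, seed=2)
        with pytest.raises(ValueError, match="axis"):
            enforced_rotation(toy_spec.topology, drv, 1.0, cfg, start=coords)

    def test_axis_beads_not_in_rotor(self):
        with pytest.raises(ValueError):
            RotationDriver(rotation_group=(3, 4), axis_beads=(3, 4))


def _dihedral_top(phase):
    return CGTopology(
        "sw", [BeadDef(f"B{i}") for i in range(4)],
        bonds=[BondTerm(0, 1, 0.35, 8000.0), BondTerm(1, 2, 0.35, 8000.0),
               BondTerm(2, 3, 0.35, 8000.0)],
        angles=[AngleTerm(0, 1, 2, 110.0, kf=250.0),
                AngleTerm(1, 2, 3, 110.0, kf=250.0)],
        dihedrals=[DihedralTerm(0, 1, 2, 3, [(1, phase, 15.0)])],
    )


class TestSwitchTopology:
    def test_noop_switch_matches_uninterrupted_chain(self):
        top = _dihedral_top(0.0)
        start = build_initial_coords(top, seed=3)
        n_mobile, stride = 4, 10
        burn, leg = 20_000, 40_000
        # uninterrupted: burn + 2 legs
        full = sample(top, SamplerConfig(n_steps=burn + 2 * leg, stride=stride,
                                         seed=9, burn_in=burn), start=start)
        # interrupted at the same point, same seed stream
        first, state = sample(
            top, SamplerConfig(n_steps=burn + leg, stride=stride, seed=9,
                               burn_in=burn),
            start=start, return_state=True)
        second, _ = switch_topology(
            state, top, SamplerConfig(n_steps=leg, stride=stride, seed=0))
        rejoined = np.concatenate([first.frames, second.frames])
        assert np.array_equal(rejoined, full.frames)

    def test_ez_flip_recentres_dihedral(self):
        """Flipping the dihedral phase 0 -> 180 (E<->Z mimic) moves the
        post-switch dihedral population from 180 to 0 degrees."""
        top_z, top_e = _dihedral_top(0.0), _dihedral_top(180.0)
        cfg = SamplerConfig(n_steps=300_000, stride=10, seed=13)
        ens_z, state = sample(top_z, cfg, return_state=True)
        d_z = extract_distributions(ens_z, top_z)["dihedral:0-1-2-3"]
        assert min(abs(d_z.mean - 180), abs(d_z.mean + 180)) < 10.0
        ens_e, state2 = switch_topology(state, top_e, cfg)
        # discard the relaxation transient
        late = ens_e.frames[ens_e.n_frames // 4:]
        phi = dihedral_series(late, 0, 1, 2, 3)
        mean_e = np.rad2deg(np.angle(np.mean(np.exp(1j * np.deg2rad(phi)))))
        assert abs(mean_e) < 10.0
        # switching back recovers the original equilibrium
        ens_back, _ = switch_topology(state2, top_z, cfg)
        phi_b = dihedral_series(ens_back.frames[ens_back.n_frames // 4:], 0, 1, 2, 3)
        mean_b = np.rad2deg(np.angle(np.mean(np.exp(1j * np.deg2rad(phi_b)))))
        assert min(abs(mean_b - 180), abs(mean_b + 180)) < 10.0

    def test_relaxation_trace_recorded(self):
        top = _dihedral_top(0.0)
        cfg = SamplerConfig(n_steps=50_000, stride=10, seed=4)
        _, state = sample(top, cfg, return_state=True)
        ens, _ = switch_topology(state, _dihedral_top(180.0), cfg)
        trace = ens.metadata["energy_trace_kJ_per_mol"]
        assert len(trace) == ens.n_frames
        assert np.all(np.isfinite(trace))

    def test_bead_count_mismatch(self):
        top = _dihedral_top(0.0)
        cfg = SamplerConfig(n_steps=20_000, stride=10, seed=4)
        _, state = sample(top, cfg, return_state=True)
        small = CGTopology("s", [BeadDef("A"), BeadDef("B")],
                           bonds=[BondTerm(0, 1, 0.35, 100.0)])
        with pytest.raises(ValueError, match="mismatch"):
            switch_topology(state, small, cfg)
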