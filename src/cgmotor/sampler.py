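"""Desk-scale Metropolis Monte Carlo sampling of bonded CG potentials.

This module is the package's stand-in for molecular-dynamics production
runs: a single-molecule Metropolis chain on bead coordinates under the
bonded energy, producing equilibrium :class:`ConformerEnsemble` objects at
a set temperature.  It also hosts the two toy drivers used to mimic the
behaviour of light-driven molecular machines:

* *enforced rotation* — an isotropic harmonic restraint couples a rotor
  group to a reference that rotates rigidly about an axle at a fixed rate
  (pivot-free: the reference is centred on the group's instantaneous
  centroid, no mass weighting);
* *topology switching* — an E/Z photo-isomerisation mimic in which the
  chain simply continues from its current coordinates under a different
  bonded topology.

MC sweeps carry a fictitious timestep (default 0.002 ps per sweep) so that
rates expressed in degrees/ps are meaningful for the rotation driver; this
is a toy-model convention, not dynamics.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import minimize

from . import _kernel
from .constants import KB
from .ensemble import ConformerEnsemble
from .topology import CGTopology, TopologyError, bonded_energy, place_virtual_sites

__all__ = [
    "SamplerConfig",
    "RotationDriver",
    "ChainState",
    "StuckChainError",
    "sample",
    "enforced_rotation",
    "switch_topology",
    "build_initial_coords",
    "rotation_angle_trace",
]


class StuckChainError(RuntimeError):
    pass


@dataclass
class SamplerConfig:
    temperature: float = 300.0  # K
    n_steps: int = 100_000  # attempted single-bead moves
    stride: int = 10  # record a frame every `stride` moves
    move_sigma: float = 0.05  # nm; adapted during burn-in
    seed: int = 0
    burn_in: int | None = None  # default: n_steps // 10
    adapt: bool = True
    timestep: float = 0.002  # ps per MC sweep (toy-time convention)

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0")
        if not self.n_steps >= self.stride >= 1:
            raise ValueError("need n_steps >= stride >= 1")

    @property
    def effective_burn_in(self) -> int:
        return self.n_steps // 10 if self.burn_in is None else self.burn_in


@dataclass
class RotationDriver:
    rotation_group: tuple[int, ...]  # rotor bead indices
    axis_beads: tuple[int, int]  # the axle: axis direction from these two beads
    rate: float = 80.0  # degrees / ps
    k_rot: float = 280.0  # kJ mol^-1 nm^-2
    timestep: float = 0.002  # ps per MC sweep

    def __post_init__(self) -> None:
        self.rotation_group = tuple(int(i) for i in self.rotation_group)
        if self.rate < 0 or self.k_rot < 0:
            raise ValueError("rate and k_rot must be >= 0")
        if set(self.axis_beads) & set(self.rotation_group):
            raise ValueError("axis beads must not be part of the rotation group")


@dataclass
class ChainState:
    """Velocity-free state of a chain: coordinates, move size and the live
    random-number stream, enough to continue sampling seamlessly."""

    coords: np.ndarray  # (n_beads, 3), virtual sites placed
    move_sigma: float
    rng: np.random.Generator
    temperature: float


# -- topology packing ---------------------------------------------------

@dataclass
class _Packed:
    mobile: np.ndarray
    cons_partner: np.ndarray
    cons_r0: np.ndarray
    arrays: tuple = field(default=())


def _csr(n_beads: int, per_bead: list[list[int]]) -> tuple[np.ndarray, np.ndarray]:
    ptr = np.zeros(n_beads + 1, dtype=np.int64)
    for b in range(n_beads):
        ptr[b + 1] = ptr[b] + len(per_bead[b])
    idx = np.array([i for lst in per_bead for i in lst], dtype=np.int64)
    return ptr, idx


def _pack(top: CGTopology):
    """Flatten a topology into the arrays the numba kernels consume."""
    n = top.n_beads
    virt = top.virtual_indices
    mobile = np.array(top.real_indices, dtype=np.int64)
    if mobile.size == 0:
        raise TopologyError("topology has no real (non-virtual) beads to sample")

    # constrained-bond structure: each bead may pivot about at most one partner
    cons_partner = np.full(n, -1, dtype=np.int64)
    cons_r0 = np.zeros(n)
    for b in top.bonds:
        if b.constrained:
            for this, other in ((b.i, b.j), (b.j, b.i)):
                if cons_partner[this] != -1:
                    raise TopologyError(
                        f"bead {this} participates in more than one constrained "
                        "bond; constraint networks are not supported by the sampler"
                    )
                cons_partner[this] = other
                cons_r0[this] = b.r0

    b_i = np.array([b.i for b in top.bonds], dtype=np.int64)
    b_j = np.array([b.j for b in top.bonds], dtype=np.int64)
    b_r0 = np.array([b.r0 for b in top.bonds])
    b_k = np.array([b.k for b in top.bonds])
    b_cons = np.array([b.constrained for b in top.bonds], dtype=np.bool_)

    a_i = np.array([a.i for a in top.angles], dtype=np.int64)
    a_j = np.array([a.j for a in top.angles], dtype=np.int64)
    a_k = np.array([a.k for a in top.angles], dtype=np.int64)
    a_th0 = np.deg2rad([a.theta0 for a in top.angles]) if top.angles else np.zeros(0)
    a_kf = np.array([a.kf for a in top.angles])
    a_form = np.array([0 if a.form == "harmonic" else 1 for a in top.angles],
                      dtype=np.int64)
    a_coeffs = np.zeros((len(top.angles), 5))
    for t, a in enumerate(top.angles):
        if a.form == "quartic":
            a_coeffs[t] = a.quartic_coeffs

    # dihedrals flattened to one cosine term per row
    rows = [(d.i, d.j, d.k, d.l, n_, p_, k_)
            for d in top.dihedrals for n_, p_, k_ in d.terms]
    d_i = np.array([r[0] for r in rows], dtype=np.int64)
    d_j = np.array([r[1] for r in rows], dtype=np.int64)
    d_k = np.array([r[2] for r in rows], dtype=np.int64)
    d_l = np.array([r[3] for r in rows], dtype=np.int64)
    d_n = np.array([r[4] for r in rows], dtype=np.float64)
    d_phi0 = np.deg2rad([r[5] for r in rows]) if rows else np.zeros(0)
    d_kp = np.array([r[6] for r in rows])

    vs_site = np.array([v.site for v in top.virtual_sites], dtype=np.int64)
    vs_cons_lists = []
    vs_w_lists = []
    for v in top.virtual_sites:
        vs_cons_lists.append(list(v.constructors))
        if v.rule == "cog":
            vs_w_lists.append([1.0 / len(v.constructors)] * len(v.constructors))
        else:
            vs_w_lists.append(list(v.weights))
    vs_ptr, vs_cons = _csr(len(top.virtual_sites), vs_cons_lists) if top.virtual_sites \
        else (np.zeros(1, dtype=np.int64), np.zeros(0, dtype=np.int64))
    vs_w = np.array([w for lst in vs_w_lists for w in lst])

    # a real bead "controls" itself plus every v-site it constructs
    controls: list[set[int]] = [set() for _ in range(n)]
    for b in range(n):
        if b not in virt:
            controls[b].add(b)
    for v in top.virtual_sites:
        for c in v.constructors:
            controls[c].add(v.site)

    def _dependents(term_beads: tuple[int, ...]) -> set[int]:
        dep = set()
        for b in range(n):
            if controls[b] & set(term_beads):
                dep.add(b)
        return dep

    bead_bonds: list[list[int]] = [[] for _ in range(n)]
    for t, b in enumerate(top.bonds):
        for dep in _dependents((b.i, b.j)):
            bead_bonds[dep].append(t)
    bead_angs: list[list[int]] = [[] for _ in range(n)]
    for t, a in enumerate(top.angles):
        for dep in _dependents((a.i, a.j, a.k)):
            bead_angs[dep].append(t)
    bead_dhs: list[list[int]] = [[] for _ in range(n)]
    for t, r in enumerate(rows):
        for dep in _dependents(r[:4]):
            bead_dhs[dep].append(t)
    bead_vss: list[list[int]] = [[] for _ in range(n)]
    for t, v in enumerate(top.virtual_sites):
        for c in v.constructors:
            bead_vss[c].append(t)

    bead_bond_ptr, bead_bond_idx = _csr(n, bead_bonds)
    bead_ang_ptr, bead_ang_idx = _csr(n, bead_angs)
    bead_dh_ptr, bead_dh_idx = _csr(n, bead_dhs)
    bead_vs_ptr, bead_vs_idx = _csr(n, bead_vss)

    term_arrays = (b_i, b_j, b_r0, b_k, b_cons,
                   a_i, a_j, a_k, a_th0, a_kf, a_form, a_coeffs,
                   d_i, d_j, d_k, d_l, d_n, d_phi0, d_kp,
                   vs_site, vs_ptr, vs_cons, vs_w,
                   bead_bond_ptr, bead_bond_idx, bead_ang_ptr, bead_ang_idx,
                   bead_dh_ptr, bead_dh_idx, bead_vs_ptr, bead_vs_idx)
    return mobile, cons_partner, cons_r0, term_arrays


# -- initial coordinates ------------------------------------------------

def build_initial_coords(top: CGTopology, seed: int = 0) -> np.ndarray:
    """Deterministic low-energy starting frame: random placement followed by
    a bonded-energy minimisation (constraints handled as stiff springs, then
    projected exactly)."""
    rng = np.random.default_rng(seed)
    n = top.n_beads
    # minimisation topology: constraints become stiff harmonic bonds
    mintop = top.copy()
    for b in mintop.bonds:
        if b.constrained:
            b.constrained = False
            b.k = 50_000.0

    scale = 0.35 * max(n, 2) ** (1.0 / 3.0)
    best = None
    best_e = np.inf
    for _attempt in range(3):
        x0 = rng.normal(scale=scale, size=(n, 3))

        def objective(flat: np.ndarray) -> float:
            c = place_virtual_sites(mintop, flat.reshape(n, 3))
            return bonded_energy(mintop, c)[0]

        res = minimize(objective, x0.ravel(), method="L-BFGS-B",
                       options={"maxiter": 500})
        if res.fun < best_e:
            best_e = res.fun
            best = res.x.reshape(n, 3)
    coords = place_virtual_sites(top, best)
    # exact constraint projection
    for _ in range(20):
        for b in top.bonds:
            if b.constrained:
                d = coords[b.j] - coords[b.i]
                coords[b.j] = coords[b.i] + b.r0 * d / np.linalg.norm(d)
    return place_virtual_sites(top, coords)


# -- public sampling API ------------------------------------------------

def _run(top, cfg: SamplerConfig, coords: np.ndarray, rng: np.random.Generator,
         burn_in: int, adapt: bool, sigma: float):
    mobile, cons_partner, cons_r0, term_arrays = _pack(top)
    n_frames = max((cfg.n_steps - burn_in) // cfg.stride, 0)
    frames = np.empty((n_frames, top.n_beads, 3))
    beta = 1.0 / (KB * cfg.temperature)
    status, sigma_out, n_acc = _kernel.run_chain(
        coords, rng, cfg.n_steps, cfg.stride, burn_in, sigma, beta, adapt,
        mobile, cons_partner, cons_r0, *term_arrays, frames)
    if status == _kernel.STATUS_STUCK:
        raise StuckChainError(
            f"all moves rejected for {_kernel.STUCK_LIMIT} consecutive steps "
            f"(move_sigma={sigma_out:.3g} nm, T={cfg.temperature} K, "
            f"accepted {n_acc} of attempted moves); the potential may be "
            "pathological or the move size unrecoverable"
        )
    return frames, sigma_out, n_acc


def sample(
    top: CGTopology,
    cfg: SamplerConfig,
    start: np.ndarray | None = None,
    return_state: bool = False,
):
    """Equilibrium ensemble of the bonded potential at ``cfg.temperature``.

    Identical configurations (including the seed) give bit-identical
    ensembles.  With ``return_state=True`` also returns a
    :class:`ChainState` from which :func:`switch_topology` can continue.
    """
    rng = np.random.default_rng(cfg.seed)
    if start is None:
        coords = build_initial_coords(top, seed=cfg.seed)
    else:
        coords = place_virtual_sites(top, np.array(start, dtype=float))
    frames, sigma_out, n_acc = _run(
        top, cfg, coords, rng, cfg.effective_burn_in, cfg.adapt, cfg.move_sigma)
    ens = ConformerEnsemble(
        frames=frames, resolution="CG",
        names=[b.name for b in top.beads],
        metadata={
            "generator": "cgmotor.sampler.sample",
            "seed": cfg.seed,
            "temperature_K": cfg.temperature,
            "n_steps": cfg.n_steps,
            "stride": cfg.stride,
            "acceptance_rate": n_acc / cfg.n_steps,
            "final_move_sigma_nm": sigma_out,
        },
    )
    if return_state:
        state = ChainState(coords=coords, move_sigma=sigma_out, rng=rng,
                           temperature=cfg.temperature)
        return ens, state
    return ens


def switch_topology(
    state: ChainState,
    new_top: CGTopology,
    cfg: SamplerConfig,
    old_names: list[str] | None = None,
):
    """Continue a chain under a new topology (E/Z switching mimic).

    The chain keeps its coordinates, move size and random stream; no
    burn-in or re-adaptation happens, so switching to an identical topology
    is statistically indistinguishable from an uninterrupted chain.
    Returns ``(ensemble, new_state)``; the ensemble's metadata carries the
    post-switch relaxation trace (bonded energy per recorded frame).
    """
    if state.coords.shape[0] != new_top.n_beads:
        raise ValueError(
            f"bead-count mismatch: chain has {state.coords.shape[0]} beads, "
            f"new topology {new_top.n_beads}"
        )
    if old_names is not None:
        new_names = [b.name for b in new_top.beads]
        if new_names != old_names:
            raise ValueError("bead names differ between old and new topology")
    cont = replace(cfg, temperature=state.temperature)
    coords = place_virtual_sites(new_top, state.coords)
    frames, sigma_out, n_acc = _run(
        new_top, cont, coords, state.rng, burn_in=0, adapt=False,
        sigma=state.move_sigma)
    energy_trace = np.array([bonded_energy(new_top, f)[0] for f in frames])
    ens = ConformerEnsemble(
        frames=frames, resolution="CG",
        names=[b.name for b in new_top.beads],
        metadata={
            "generator": "cgmotor.sampler.switch_topology",
            "temperature_K": state.temperature,
            "acceptance_rate": n_acc / cont.n_steps,
            "energy_trace_kJ_per_mol": energy_trace,
        },
    )
    new_state = ChainState(coords=coords, move_sigma=sigma_out, rng=state.rng,
                           temperature=state.temperature)
    return ens, new_state


# -- enforced rotation --------------------------------------------------

def rotation_angle_trace(
    frames: np.ndarray, rotor: tuple[int, ...], axis: np.ndarray,
    ref_frame: np.ndarray,
) -> np.ndarray:
    """Cumulative rotor angle (degrees) per frame.

    For each frame the in-plane rotation angle about ``axis`` that best
    aligns the rotor's centroid-relative positions with those of
    ``ref_frame`` is measured and unwrapped over frames.
    """
    rotor = list(rotor)
    u = axis / np.linalg.norm(axis)
    y0 = ref_frame[rotor] - ref_frame[rotor].mean(axis=0)
    y0p = y0 - np.outer(y0 @ u, u)  # project out the axis component
    angles = np.empty(frames.shape[0])
    for f, frame in enumerate(frames):
        y = frame[rotor] - frame[rotor].mean(axis=0)
        yp = y - np.outer(y @ u, u)
        s = np.sum(np.cross(y0p, yp) @ u)
        c = np.sum(y0p * yp)
        angles[f] = np.arctan2(s, c)
    return np.rad2deg(np.unwrap(angles))


def enforced_rotation(
    top: CGTopology,
    drv: RotationDriver,
    duration: float,
    cfg: SamplerConfig,
    start: np.ndarray | None = None,
):
    """Drive the rotor group about the axle for ``duration`` ps.

    Returns ``(ensemble, trace)`` where ``trace`` has columns
    (time ps, reference angle deg, cumulative rotor angle deg).
    """
    if duration <= 0:
        raise ValueError("duration must be > 0")
    a, b = drv.axis_beads
    rng = np.random.default_rng(cfg.seed)
    if start is None:
        coords = build_initial_coords(top, seed=cfg.seed)
    else:
        coords = place_virtual_sites(top, np.array(start, dtype=float))
    axis = coords[b] - coords[a]
    norm = np.linalg.norm(axis)
    if norm < 1e-9:
        raise ValueError("degenerate rotation axis: axle beads coincide")
    axis = axis / norm

    mobile, cons_partner, cons_r0, term_arrays = _pack(top)
    in_rotor = np.zeros(top.n_beads, dtype=np.bool_)
    in_rotor[list(drv.rotation_group)] = True
    rotor = np.array(drv.rotation_group, dtype=np.int64)
    ref_rel0 = coords[rotor] - coords[rotor].mean(axis=0)

    n_sweeps = max(int(round(duration / drv.timestep)), 1)
    stride = max(cfg.stride, 1)
    n_frames = n_sweeps // stride
    frames = np.empty((n_frames, top.n_beads, 3))
    ref_angles = np.empty(n_frames)
    beta = 1.0 / (KB * cfg.temperature)
    start_frame = coords.copy()

    _kernel.run_rotation(
        coords, rng, n_sweeps, stride, cfg.move_sigma, beta,
        mobile, in_rotor, cons_partner, cons_r0, *term_arrays,
        rotor, ref_rel0, axis, np.deg2rad(drv.rate), drv.timestep, drv.k_rot,
        frames, ref_angles)

    times = drv.timestep * stride * (np.arange(n_frames) + 1) - drv.timestep
    rotor_angle = rotation_angle_trace(frames, drv.rotation_group, axis, start_frame)
    trace = np.column_stack([times, np.rad2deg(ref_angles), rotor_angle])
    ens = ConformerEnsemble(
        frames=frames, resolution="CG",
        names=[bd.name for bd in top.beads],
        metadata={
            "generator": "cgmotor.sampler.enforced_rotation",
            "seed": cfg.seed,
            "temperature_K": cfg.temperature,
            "rate_deg_per_ps": drv.rate,
            "k_rot": drv.k_rot,
            "timestep_ps": drv.timestep,
        },
    )
    return ens, trace
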