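"""Coarse-grained topology data model and bonded-energy evaluation.

A :class:`CGTopology` holds beads plus bonded terms (bonds, angles,
dihedrals) and virtual-site construction rules, mirroring the subset of a
GROMACS molecule definition that a bonded-only CG model needs.  Angle and
dihedral reference values are stored in degrees (the file convention);
quartic angle coefficients are in kJ mol^-1 rad^-n and all trigonometry is
done in radians internally.

Functional forms:

* bond:      V(r) = 1/2 k (r - r0)^2               (constrained bonds: fixed length, zero energy)
* angle:     V(th) = 1/2 kf (th - th0)^2            (harmonic)
             V(th) = sum_{n=0..4} C_n (th - th0)^n  (quartic; represents bimodal angles)
* dihedral:  V(phi) = sum_m k_m (1 + cos(n_m phi - phi0_m))
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .constants import BEAD_CLASS_RADII

__all__ = [
    "BeadDef",
    "BondTerm",
    "AngleTerm",
    "DihedralTerm",
    "VirtualSiteDef",
    "CGTopology",
    "TopologyError",
    "GeometryError",
    "bond_lengths",
    "angle_values",
    "dihedral_values",
    "bonded_energy",
    "place_virtual_sites",
]


class TopologyError(ValueError):
    """Raised for invalid topology definitions (bad indices, bad terms)."""


class GeometryError(ValueError):
    """Raised when a frame's geometry makes a bonded term undefined."""


@dataclass
class BeadDef:
    """One CG interaction site.

    ``bead_class`` is the Martini size class (regular / small / tiny) and
    sets the default radius; ``type_code`` is the chemical bead type label
    (e.g. "TC5", "SP4") which this package records but does not interpret
    (nonbonded interactions are out of scope).
    """

    name: str
    bead_class: str = "regular"
    type_code: str = ""
    charge: float = 0.0
    radius: float | None = None
    is_virtual: bool = False

    def __post_init__(self) -> None:
        if self.bead_class not in BEAD_CLASS_RADII:
            raise TopologyError(
                f"unknown bead class {self.bead_class!r}; "
                f"expected one of {sorted(BEAD_CLASS_RADII)}"
            )
        if self.radius is None:
            self.radius = BEAD_CLASS_RADII[self.bead_class]
        if self.radius <= 0:
            raise TopologyError(f"bead {self.name!r}: radius must be > 0")


@dataclass
class BondTerm:
    i: int
    j: int
    r0: float
    k: float = 0.0
    constrained: bool = False

    def __post_init__(self) -> None:
        if self.i == self.j:
            raise TopologyError("bond indices must differ")
        if self.r0 <= 0:
            raise TopologyError("bond r0 must be > 0")
        if self.k < 0:
            raise TopologyError("bond force constant must be >= 0")


@dataclass
class AngleTerm:
    i: int
    j: int
    k: int
    theta0: float  # degrees
    kf: float = 0.0  # kJ/mol/rad^2 (harmonic)
    form: str = "harmonic"
    quartic_coeffs: tuple[float, ...] | None = None  # C0..C4, kJ/mol/rad^n

    def __post_init__(self) -> None:
        if len({self.i, self.j, self.k}) != 3:
            raise TopologyError("angle indices must be distinct")
        if self.form not in ("harmonic", "quartic"):
            raise TopologyError(f"unknown angle form {self.form!r}")
        if self.form == "harmonic":
            if not 0.0 < self.theta0 < 180.0:
                raise TopologyError("harmonic angle theta0 must lie in (0, 180) degrees")
        else:
            if self.quartic_coeffs is None or len(self.quartic_coeffs) != 5:
                raise TopologyError("quartic angle requires 5 coefficients C0..C4")
            self.quartic_coeffs = tuple(float(c) for c in self.quartic_coeffs)


@dataclass
class DihedralTerm:
    i: int
    j: int
    k: int
    l: int
    #: list of (multiplicity n, phase phi0 in degrees, amplitude k_phi in kJ/mol)
    terms: list[tuple[int, float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len({self.i, self.j, self.k, self.l}) != 4:
            raise TopologyError("dihedral indices must be distinct")
        for n, _phi, _k in self.terms:
            if int(n) < 1:
                raise TopologyError("dihedral multiplicity must be >= 1")
        self.terms = [(int(n), float(p), float(kp)) for n, p, kp in self.terms]


@dataclass
class VirtualSiteDef:
    """Geometric construction of a massless site from real beads."""

    site: int
    constructors: tuple[int, ...]
    rule: str = "cog"
    weights: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        self.constructors = tuple(int(c) for c in self.constructors)
        if len(self.constructors) == 0:
            raise TopologyError("virtual site needs at least one constructor bead")
        if self.site in self.constructors:
            raise TopologyError("virtual site cannot construct itself")
        if self.rule not in ("cog", "weighted"):
            raise TopologyError(f"unknown virtual-site rule {self.rule!r}")
        if self.rule == "weighted":
            if self.weights is None or len(self.weights) != len(self.constructors):
                raise TopologyError("weighted virtual site needs one weight per constructor")
            self.weights = tuple(float(w) for w in self.weights)
            if abs(sum(self.weights) - 1.0) > 1e-8:
                raise TopologyError("virtual-site weights must sum to 1")


@dataclass
class CGTopology:
    name: str
    beads: list[BeadDef]
    bonds: list[BondTerm] = field(default_factory=list)
    angles: list[AngleTerm] = field(default_factory=list)
    dihedrals: list[DihedralTerm] = field(default_factory=list)
    virtual_sites: list[VirtualSiteDef] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    # -- validation -----------------------------------------------------
    def validate(self) -> None:
        n = len(self.beads)
        virt = self.virtual_indices
        for b in self.bonds:
            self._check_indices((b.i, b.j), n, "bond")
            if b.i in virt and b.j in virt:
                raise TopologyError("bond between two virtual sites is not allowed")
        for a in self.angles:
            self._check_indices((a.i, a.j, a.k), n, "angle")
            if {a.i, a.j, a.k} <= virt:
                raise TopologyError("angle over only virtual sites is not allowed")
        for d in self.dihedrals:
            self._check_indices((d.i, d.j, d.k, d.l), n, "dihedral")
            # dihedrals may pivot through a v-site (stator/rotor dihedral),
            # but not consist purely of v-sites
            if {d.i, d.j, d.k, d.l} <= virt:
                raise TopologyError("dihedral over only virtual sites is not allowed")
        for v in self.virtual_sites:
            self._check_indices((v.site, *v.constructors), n, "virtual site")
            if not self.beads[v.site].is_virtual:
                raise TopologyError(
                    f"bead {v.site} has a virtual-site rule but is not flagged virtual"
                )
        ruled = {v.site for v in self.virtual_sites}
        for idx in virt:
            if idx not in ruled:
                raise TopologyError(f"virtual bead {idx} has no construction rule")

    @staticmethod
    def _check_indices(idx: Sequence[int], n: int, what: str) -> None:
        for i in idx:
            if not 0 <= i < n:
                raise TopologyError(f"{what} references bead {i}, but topology has {n} beads")

    # -- convenience ----------------------------------------------------
    @property
    def n_beads(self) -> int:
        return len(self.beads)

    @property
    def virtual_indices(self) -> set[int]:
        return {i for i, b in enumerate(self.beads) if b.is_virtual}

    @property
    def real_indices(self) -> list[int]:
        return [i for i, b in enumerate(self.beads) if not b.is_virtual]

    def copy(self) -> "CGTopology":
        return CGTopology(
            name=self.name,
            beads=[replace(b) for b in self.beads],
            bonds=[replace(b) for b in self.bonds],
            angles=[replace(a) for a in self.angles],
            dihedrals=[
                DihedralTerm(d.i, d.j, d.k, d.l, list(d.terms)) for d in self.dihedrals
            ],
            virtual_sites=[replace(v) for v in self.virtual_sites],
        )

    def radii(self, include_virtual: bool = True) -> np.ndarray:
        r = np.array([b.radius for b in self.beads], dtype=float)
        if not include_virtual:
            r = r[self.real_indices]
        return r


# -- geometry helpers ---------------------------------------------------

def _as_frame(coords: np.ndarray) -> np.ndarray:
    c = np.asarray(coords, dtype=float)
    if c.ndim != 2 or c.shape[1] != 3:
        raise ValueError("coords must be an (n_beads, 3) array")
    return c


def bond_lengths(coords: np.ndarray, bonds: Sequence[BondTerm]) -> np.ndarray:
    c = _as_frame(coords)
    return np.array([np.linalg.norm(c[b.j] - c[b.i]) for b in bonds])


def angle_values(coords: np.ndarray, angles: Sequence[AngleTerm]) -> np.ndarray:
    """Angle at the central bead j, in radians."""
    c = _as_frame(coords)
    out = np.empty(len(angles))
    for t, a in enumerate(angles):
        u = c[a.i] - c[a.j]
        v = c[a.k] - c[a.j]
        nu, nv = np.linalg.norm(u), np.linalg.norm(v)
        if nu == 0.0 or nv == 0.0:
            raise GeometryError(f"angle ({a.i},{a.j},{a.k}): coincident beads")
        out[t] = np.arccos(np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0))
    return out


def dihedral_values(coords: np.ndarray, dihedrals: Sequence[DihedralTerm]) -> np.ndarray:
    """Signed dihedral angle in radians, IUPAC convention, in (-pi, pi]."""
    c = _as_frame(coords)
    out = np.empty(len(dihedrals))
    for t, d in enumerate(dihedrals):
        b1 = c[d.j] - c[d.i]
        b2 = c[d.k] - c[d.j]
        b3 = c[d.l] - c[d.k]
        n1 = np.cross(b1, b2)
        n2 = np.cross(b2, b3)
        nb2 = np.linalg.norm(b2)
        if np.linalg.norm(n1) == 0.0 or np.linalg.norm(n2) == 0.0 or nb2 == 0.0:
            raise GeometryError(
                f"dihedral ({d.i},{d.j},{d.k},{d.l}): degenerate (collinear) geometry"
            )
        out[t] = np.arctan2(np.dot(np.cross(n1, n2), b2) / nb2, np.dot(n1, n2))
    return out


# -- energies -----------------------------------------------------------

def bonded_energy(top: CGTopology, coords: np.ndarray) -> tuple[float, dict]:
    """Total bonded energy of one frame, kJ/mol, plus a per-term breakdown.

    Virtual sites must already be placed (see :func:`place_virtual_sites`);
    constrained bonds contribute zero energy.
    """
    c = _as_frame(coords)
    if c.shape[0] != top.n_beads:
        raise ValueError(
            f"frame has {c.shape[0]} coordinates but topology has {top.n_beads} beads"
        )
    breakdown: dict[str, np.ndarray] = {}

    e_bonds = np.zeros(len(top.bonds))
    if top.bonds:
        r = bond_lengths(c, top.bonds)
        for t, b in enumerate(top.bonds):
            if not b.constrained:
                e_bonds[t] = 0.5 * b.k * (r[t] - b.r0) ** 2
    breakdown["bonds"] = e_bonds

    e_angles = np.zeros(len(top.angles))
    if top.angles:
        th = angle_values(c, top.angles)
        for t, a in enumerate(top.angles):
            dth = th[t] - np.deg2rad(a.theta0)
            if a.form == "harmonic":
                e_angles[t] = 0.5 * a.kf * dth**2
            else:
                e_angles[t] = sum(cn * dth**n for n, cn in enumerate(a.quartic_coeffs))
    breakdown["angles"] = e_angles

    e_dih = np.zeros(len(top.dihedrals))
    if top.dihedrals:
        phi = dihedral_values(c, top.dihedrals)
        for t, d in enumerate(top.dihedrals):
            e_dih[t] = sum(
                kp * (1.0 + np.cos(n * phi[t] - np.deg2rad(p))) for n, p, kp in d.terms
            )
    breakdown["dihedrals"] = e_dih

    total = float(e_bonds.sum() + e_angles.sum() + e_dih.sum())
    return total, breakdown


def place_virtual_sites(top: CGTopology, coords: np.ndarray) -> np.ndarray:
    """Return a copy of ``coords`` with virtual-site positions rebuilt.

    cog rule: unweighted mean of the constructor positions; weighted rule:
    weighted mean.  Idempotent because constructors are always real beads.
    """
    c = _as_frame(coords).copy()
    for v in top.virtual_sites:
        pos = c[list(v.constructors)]
        if v.rule == "cog":
            c[v.site] = pos.mean(axis=0)
        else:
            c[v.site] = np.average(pos, axis=0, weights=v.weights)
    return c
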