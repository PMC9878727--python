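"""Forward mapping of atomistic ensembles onto CG beads.

A :class:`MappingScheme` assigns groups of atoms to beads; each real bead
is placed at the centre of geometry (cog, the default, following the
Martini heavy-atom convention) or centre of mass (com) of its atoms, and
virtual beads are then constructed geometrically from the real beads.

Scheme files are JSON::

    {
      "molecule": "toy",
      "beads": [
        {"name": "B1", "atoms": [1, 2, 3], "rule": "cog"},
        {"name": "B2", "atoms": [4, 5], "rule": "com"}
      ],
      "virtual_beads": ["V1"],
      "atom_masses": {"1": 12.011, ...}   // needed only for com beads
    }

Atom indices are 1-based in the file (matching coordinate-file order) and
0-based in memory.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .ensemble import ConformerEnsemble
from .topology import CGTopology, place_virtual_sites

__all__ = ["MappingScheme", "MappingError", "map_ensemble", "check_scheme",
           "read_scheme", "write_scheme"]


class MappingError(ValueError):
    pass


@dataclass
class MappingScheme:
    molecule: str
    #: (bead label, 0-based atom indices, "cog" | "com")
    bead_assignments: list[tuple[str, tuple[int, ...], str]]
    #: bead labels that are virtual (no direct atom assignment)
    virtual_beads: list[str] = field(default_factory=list)
    #: per-atom masses (amu), indexed by 0-based atom index; only needed
    #: when any bead uses the com rule
    atom_masses: dict[int, float] = field(default_factory=dict)
    allow_shared_atoms: bool = False

    def __post_init__(self) -> None:
        seen: set[int] = set()
        norm = []
        for label, atoms, rule in self.bead_assignments:
            atoms = tuple(int(a) for a in atoms)
            if len(atoms) == 0:
                raise MappingError(f"bead {label!r} has no atoms assigned")
            if len(set(atoms)) != len(atoms):
                raise MappingError(f"bead {label!r} lists an atom twice")
            if rule not in ("cog", "com"):
                raise MappingError(f"bead {label!r}: unknown weight rule {rule!r}")
            if rule == "com":
                missing = [a for a in atoms if a not in self.atom_masses]
                if missing:
                    raise MappingError(
                        f"bead {label!r} uses com but lacks masses for atoms {missing}"
                    )
            if not self.allow_shared_atoms and seen & set(atoms):
                raise MappingError(
                    f"bead {label!r} shares atoms with an earlier bead "
                    "(set allow_shared_atoms to permit this explicitly)"
                )
            seen |= set(atoms)
            norm.append((label, atoms, rule))
        self.bead_assignments = norm

    @property
    def n_real_beads(self) -> int:
        return len(self.bead_assignments)

    @property
    def bead_labels(self) -> list[str]:
        """Real bead labels followed by virtual bead labels."""
        return [lab for lab, _, _ in self.bead_assignments] + list(self.virtual_beads)

    @property
    def assigned_atoms(self) -> set[int]:
        out: set[int] = set()
        for _, atoms, _ in self.bead_assignments:
            out |= set(atoms)
        return out

    @property
    def max_atom_index(self) -> int:
        return max(self.assigned_atoms)


def map_ensemble(
    scheme: MappingScheme,
    aa: ConformerEnsemble,
    top: CGTopology | None = None,
) -> ConformerEnsemble:
    """Project an atomistic ensemble onto CG bead coordinates, frame by frame.

    Real beads are group means (cog/com) of their atoms; if ``top`` is given
    its virtual sites are then placed, so the output has
    ``scheme.n_real_beads + len(scheme.virtual_beads)`` particles.
    """
    if scheme.max_atom_index >= aa.n_particles:
        raise MappingError(
            f"scheme references atom index {scheme.max_atom_index + 1} but the "
            f"ensemble has only {aa.n_particles} atoms"
        )
    n_cg = scheme.n_real_beads + len(scheme.virtual_beads)
    if top is not None and top.n_beads != n_cg:
        raise MappingError(
            f"topology has {top.n_beads} beads but scheme defines {n_cg}"
        )
    out = np.zeros((aa.n_frames, n_cg, 3))
    for b, (_label, atoms, rule) in enumerate(scheme.bead_assignments):
        sel = aa.frames[:, list(atoms), :]  # (F, na, 3)
        if rule == "cog":
            out[:, b, :] = sel.mean(axis=1)
        else:
            masses = np.array([scheme.atom_masses[a] for a in atoms])
            out[:, b, :] = np.einsum("fai,a->fi", sel, masses) / masses.sum()
    if top is not None and top.virtual_sites:
        for f in range(out.shape[0]):
            out[f] = place_virtual_sites(top, out[f])
    return ConformerEnsemble(
        frames=out,
        resolution="CG",
        box=aa.box,
        names=scheme.bead_labels,
        metadata={**aa.metadata, "mapped_from": aa.resolution,
                  "mapping_molecule": scheme.molecule},
    )


def check_scheme(scheme: MappingScheme, top: CGTopology, n_atoms: int | None = None) -> dict:
    """Cross-validate a mapping scheme against a CG topology.

    Returns a machine-readable report ``{"findings": [...], "ok": bool}``;
    problems are reported, never raised.
    """
    findings: list[dict] = []
    n_scheme = scheme.n_real_beads + len(scheme.virtual_beads)
    if n_scheme != top.n_beads:
        findings.append({
            "kind": "bead-count-mismatch",
            "detail": f"scheme defines {n_scheme} beads, topology {top.n_beads}",
        })
    top_virtual = {top.beads[i].name for i in top.virtual_indices}
    scheme_virtual = set(scheme.virtual_beads)
    for name in sorted(top_virtual - scheme_virtual):
        findings.append({
            "kind": "unconstructible v-site",
            "detail": f"topology bead {name!r} is virtual but the scheme does not list it",
        })
    for name in sorted(scheme_virtual - top_virtual):
        findings.append({
            "kind": "virtual-flag-mismatch",
            "detail": f"scheme lists {name!r} as virtual but the topology does not",
        })
    if n_atoms is not None:
        unassigned = sorted(set(range(n_atoms)) - scheme.assigned_atoms)
        if unassigned:
            findings.append({
                "kind": "unassigned-atoms",
                "detail": "atoms not mapped to any bead (1-based): "
                          + ", ".join(str(a + 1) for a in unassigned),
                "atoms": [a + 1 for a in unassigned],
            })
    return {"ok": not findings, "findings": findings}


def read_scheme(path: str | Path) -> MappingScheme:
    data = json.loads(Path(path).read_text())
    beads = [
        (b["name"], tuple(int(a) - 1 for a in b["atoms"]), b.get("rule", "cog"))
        for b in data["beads"]
    ]
    masses = {int(k) - 1: float(v) for k, v in data.get("atom_masses", {}).items()}
    return MappingScheme(
        molecule=data.get("molecule", "molecule"),
        bead_assignments=beads,
        virtual_beads=list(data.get("virtual_beads", [])),
        atom_masses=masses,
        allow_shared_atoms=bool(data.get("allow_shared_atoms", False)),
    )


def write_scheme(scheme: MappingScheme, path: str | Path) -> None:
    data = {
        "molecule": scheme.molecule,
        "beads": [
            {"name": lab, "atoms": [a + 1 for a in atoms], "rule": rule}
            for lab, atoms, rule in scheme.bead_assignments
        ],
        "virtual_beads": list(scheme.virtual_beads),
        "atom_masses": {str(k + 1): v for k, v in scheme.atom_masses.items()},
        "allow_shared_atoms": scheme.allow_shared_atoms,
    }
    Path(path).write_text(json.dumps(data, indent=2) + "\n")
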