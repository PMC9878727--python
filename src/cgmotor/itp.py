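"""Read and write a GROMACS-dialect .itp subset for bonded CG topologies.

Supported directives: ``[moleculetype]``, ``[atoms]``, ``[bonds]``,
``[constraints]``, ``[angles]``, ``[dihedrals]``, ``[virtual_sitesn]``.
Lines are whitespace separated, ``;`` starts a comment, atom indices are
1-based in the file and 0-based in memory.

Function-type mapping (recorded verbatim in the file):

===========  =====  ==========================================================
directive    funct  internal form
===========  =====  ==========================================================
bonds          1    harmonic bond ``i j 1 r0 k``
constraints    1    fixed-length bond ``i j 1 r0``
angles         1    harmonic angle ``i j k 1 theta0 kf``
angles         6    quartic polynomial angle ``i j k 6 theta0 C0 C1 C2 C3 C4``
                    (dialect extension of this package; GROMACS itself has no
                    polynomial angle type)
dihedrals     1/9   proper dihedral ``i j k l f phi0 kphi n`` (type 9 lines
                    with identical indices accumulate into one multi-term
                    dihedral)
virtual_sitesn  1   centre of geometry ``site 1 c1 c2 ...``
virtual_sitesn  3   weighted centre ``site 3 c1 w1 c2 w2 ...``
===========  =====  ==========================================================

Bead size class is inferred from the type code prefix ("T" tiny, "S" small,
otherwise regular), which also sets the default radius; the virtual flag is
inferred from membership in ``[virtual_sitesn]``.  ``write_topology`` after
``read_topology`` is an exact textual fixpoint on files this module wrote.
"""

from __future__ import annotations

import io
from pathlib import Path

from .topology import (
    AngleTerm,
    BeadDef,
    BondTerm,
    CGTopology,
    DihedralTerm,
    VirtualSiteDef,
)

__all__ = ["read_topology", "write_topology", "ItpParseError"]

_DIRECTIVES = {
    "moleculetype",
    "atoms",
    "bonds",
    "constraints",
    "angles",
    "dihedrals",
    "virtual_sitesn",
}


class ItpParseError(ValueError):
    """Raised with the offending line number when a file cannot be parsed."""


def _bead_class_from_type(type_code: str) -> str:
    if type_code.startswith("T"):
        return "tiny"
    if type_code.startswith("S"):
        return "small"
    return "regular"


def read_topology(path: str | Path) -> CGTopology:
    """Parse a topology file; raises :class:`ItpParseError` on unknown
    directives or malformed lines and ``TopologyError`` on invalid indices."""
    text = Path(path).read_text()
    name = "molecule"
    beads: list[BeadDef] = []
    bonds: list[BondTerm] = []
    constraint_bonds: list[BondTerm] = []
    angles: list[AngleTerm] = []
    dihedrals: list[DihedralTerm] = []
    vsites: list[VirtualSiteDef] = []
    section = None

    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split(";", 1)[0].strip()
        if not line:
            continue
        if line.startswith("["):
            section = line.strip("[] \t").lower()
            if section not in _DIRECTIVES:
                raise ItpParseError(f"line {lineno}: unknown directive [{section}]")
            continue
        if section is None:
            raise ItpParseError(f"line {lineno}: content before any directive")
        tok = line.split()
        try:
            if section == "moleculetype":
                name = tok[0]
            elif section == "atoms":
                # nr type resnr residue atom cgnr charge
                type_code = tok[1]
                beads.append(
                    BeadDef(
                        name=tok[4],
                        bead_class=_bead_class_from_type(type_code),
                        type_code=type_code,
                        charge=float(tok[6]) if len(tok) > 6 else 0.0,
                    )
                )
            elif section == "bonds":
                i, j, funct = int(tok[0]) - 1, int(tok[1]) - 1, int(tok[2])
                if funct != 1:
                    raise ItpParseError(f"line {lineno}: unsupported bond funct {funct}")
                bonds.append(BondTerm(i, j, r0=float(tok[3]), k=float(tok[4])))
            elif section == "constraints":
                i, j, funct = int(tok[0]) - 1, int(tok[1]) - 1, int(tok[2])
                if funct != 1:
                    raise ItpParseError(
                        f"line {lineno}: unsupported constraint funct {funct}"
                    )
                constraint_bonds.append(BondTerm(i, j, r0=float(tok[3]), constrained=True))
            elif section == "angles":
                i, j, k = (int(t) - 1 for t in tok[:3])
                funct = int(tok[3])
                if funct == 1:
                    angles.append(
                        AngleTerm(i, j, k, theta0=float(tok[4]), kf=float(tok[5]))
                    )
                elif funct == 6:
                    coeffs = tuple(float(t) for t in tok[5:10])
                    angles.append(
                        AngleTerm(
                            i, j, k,
                            theta0=float(tok[4]),
                            form="quartic",
                            quartic_coeffs=coeffs,
                        )
                    )
                else:
                    raise ItpParseError(f"line {lineno}: unsupported angle funct {funct}")
            elif section == "dihedrals":
                i, j, k, l = (int(t) - 1 for t in tok[:4])
                funct = int(tok[4])
                if funct not in (1, 9):
                    raise ItpParseError(
                        f"line {lineno}: unsupported dihedral funct {funct}"
                    )
                phi0, kphi, n = float(tok[5]), float(tok[6]), int(tok[7])
                term = (n, phi0, kphi)
                if (
                    funct == 9
                    and dihedrals
                    and (dihedrals[-1].i, dihedrals[-1].j, dihedrals[-1].k, dihedrals[-1].l)
                    == (i, j, k, l)
                ):
                    dihedrals[-1].terms.append(term)
                    dihedrals[-1].__post_init__()
                else:
                    dihedrals.append(DihedralTerm(i, j, k, l, [term]))
            elif section == "virtual_sitesn":
                site, funct = int(tok[0]) - 1, int(tok[1])
                if funct == 1:
                    cons = tuple(int(t) - 1 for t in tok[2:])
                    vsites.append(VirtualSiteDef(site, cons, rule="cog"))
                elif funct == 3:
                    rest = tok[2:]
                    if len(rest) % 2 != 0:
                        raise ItpParseError(
                            f"line {lineno}: weighted v-site needs index/weight pairs"
                        )
                    cons = tuple(int(t) - 1 for t in rest[0::2])
                    weights = tuple(float(t) for t in rest[1::2])
                    vsites.append(
                        VirtualSiteDef(site, cons, rule="weighted", weights=weights)
                    )
                else:
                    raise ItpParseError(
                        f"line {lineno}: unsupported virtual_sitesn funct {funct}"
                    )
        except ItpParseError:
            raise
        except (IndexError, ValueError) as exc:
            raise ItpParseError(f"line {lineno}: malformed [{section}] entry: {raw!r}") from exc

    for v in vsites:
        beads[v.site].is_virtual = True
    # canonical order (regular bonds, then constraints) so that
    # read -> write -> read is an exact fixpoint whatever the file order
    bonds = bonds + constraint_bonds
    return CGTopology(
        name=name, beads=beads, bonds=bonds, angles=angles,
        dihedrals=dihedrals, virtual_sites=vsites,
    )


def _fmt(x: float) -> str:
    return f"{x:.6g}"


def write_topology(top: CGTopology, path: str | Path | None = None) -> str:
    """Serialize a topology; returns the text and optionally writes it."""
    buf = io.StringIO()
    w = buf.write
    w("[ moleculetype ]\n; name  nrexcl\n")
    w(f"{top.name}  1\n\n")

    w("[ atoms ]\n; nr  type  resnr  residue  atom  cgnr  charge\n")
    for idx, b in enumerate(top.beads, start=1):
        w(f"{idx}  {b.type_code or b.name}  1  {top.name}  {b.name}  {idx}  {_fmt(b.charge)}\n")

    real_bonds = [b for b in top.bonds if not b.constrained]
    constraints = [b for b in top.bonds if b.constrained]
    if real_bonds:
        w("\n[ bonds ]\n; i  j  funct  r0  k\n")
        for b in real_bonds:
            w(f"{b.i + 1}  {b.j + 1}  1  {_fmt(b.r0)}  {_fmt(b.k)}\n")
    if constraints:
        w("\n[ constraints ]\n; i  j  funct  r0\n")
        for b in constraints:
            w(f"{b.i + 1}  {b.j + 1}  1  {_fmt(b.r0)}\n")
    if top.angles:
        w("\n[ angles ]\n; i  j  k  funct  theta0  params\n")
        for a in top.angles:
            if a.form == "harmonic":
                w(f"{a.i + 1}  {a.j + 1}  {a.k + 1}  1  {_fmt(a.theta0)}  {_fmt(a.kf)}\n")
            else:
                cs = "  ".join(_fmt(c) for c in a.quartic_coeffs)
                w(f"{a.i + 1}  {a.j + 1}  {a.k + 1}  6  {_fmt(a.theta0)}  {cs}\n")
    if top.dihedrals:
        w("\n[ dihedrals ]\n; i  j  k  l  funct  phi0  kphi  n\n")
        for d in top.dihedrals:
            funct = 9 if len(d.terms) > 1 else 1
            for n, phi0, kphi in d.terms:
                w(
                    f"{d.i + 1}  {d.j + 1}  {d.k + 1}  {d.l + 1}  {funct}  "
                    f"{_fmt(phi0)}  {_fmt(kphi)}  {n}\n"
                )
    if top.virtual_sites:
        w("\n[ virtual_sitesn ]\n; site  funct  constructors\n")
        for v in top.virtual_sites:
            if v.rule == "cog":
                cons = "  ".join(str(c + 1) for c in v.constructors)
                w(f"{v.site + 1}  1  {cons}\n")
            else:
                pairs = "  ".join(
                    f"{c + 1}  {_fmt(wt)}" for c, wt in zip(v.constructors, v.weights)
                )
                w(f"{v.site + 1}  3  {pairs}\n")

    text = buf.getvalue()
    if path is not None:
        Path(path).write_text(text)
    return text
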