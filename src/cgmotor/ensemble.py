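"""Conformer ensembles (sets of coordinate frames) and their file I/O.

Coordinates are held in nm as a ``(n_frames, n_particles, 3)`` array.  On
disk, multi-frame ensembles are stored as XYZ trajectories (read and written
through MDAnalysis, with the XYZ ecosystem's Angstrom convention converted
at the boundary) and single frames may also be stored as GROMACS .gro files
(natively in nm).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["ConformerEnsemble", "read_ensemble", "write_ensemble"]

_NM_PER_ANGSTROM = 0.1


@dataclass
class ConformerEnsemble:
    """A stack of coordinate frames at one resolution (AA or CG)."""

    frames: np.ndarray  # (n_frames, n_particles, 3), nm
    resolution: str = "CG"  # "AA" or "CG"
    box: np.ndarray | None = None  # (3,) box lengths, nm
    names: list[str] | None = None  # per-particle labels
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValueError("frames must have shape (n_frames, n_particles, 3)")
        if self.frames.shape[0] < 1:
            raise ValueError("an ensemble needs at least one frame")
        if self.resolution not in ("AA", "CG"):
            raise ValueError("resolution must be 'AA' or 'CG'")
        if self.names is not None and len(self.names) != self.n_particles:
            raise ValueError("names length must match particle count")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_particles(self) -> int:
        return self.frames.shape[1]

    def particle_names(self) -> list[str]:
        return self.names or [f"X{i + 1}" for i in range(self.n_particles)]


def write_ensemble(ens: ConformerEnsemble, path: str | Path) -> None:
    """Write an ensemble to .xyz (any frame count) or .gro (one frame)."""
    import MDAnalysis as mda

    path = Path(path)
    suffix = path.suffix.lower()
    u = mda.Universe.empty(ens.n_particles, trajectory=True)
    u.add_TopologyAttr("names", ens.particle_names())
    if suffix == ".xyz":
        u.add_TopologyAttr("elements", ens.particle_names())
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            with mda.Writer(str(path), n_atoms=ens.n_particles) as w:
                for frame in ens.frames:
                    u.atoms.positions = frame / _NM_PER_ANGSTROM
                    w.write(u.atoms)
    elif suffix == ".gro":
        if ens.n_frames != 1:
            raise ValueError(
                ".gro holds a single frame; write multi-frame ensembles as .xyz"
            )
        u.add_TopologyAttr("resnames", ["MOL"])
        u.atoms.positions = ens.frames[0] / _NM_PER_ANGSTROM
        if ens.box is not None:
            u.dimensions = [*(ens.box / _NM_PER_ANGSTROM), 90.0, 90.0, 90.0]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            u.atoms.write(str(path))
    else:
        raise ValueError(f"unsupported ensemble format {suffix!r} (use .xyz or .gro)")


def read_ensemble(path: str | Path, resolution: str = "CG") -> ConformerEnsemble:
    """Read a .xyz trajectory or a .gro frame into a nm-unit ensemble."""
    import MDAnalysis as mda

    path = Path(path)
    suffix = path.suffix.lower()
    if suffix not in (".xyz", ".gro"):
        raise ValueError(f"unsupported ensemble format {suffix!r} (use .xyz or .gro)")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(path))
        frames = np.array(
            [u.atoms.positions * _NM_PER_ANGSTROM for _ in u.trajectory], dtype=float
        )
        box = None
        if suffix == ".gro" and u.dimensions is not None:
            box = np.asarray(u.dimensions[:3], dtype=float) * _NM_PER_ANGSTROM
        names = list(u.atoms.names) if hasattr(u.atoms, "names") else None
    return ConformerEnsemble(
        frames=frames, resolution=resolution, box=box, names=names,
        metadata={"source": str(path)},
    )
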