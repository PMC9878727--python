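"""Bonded-term distributions and cross-resolution comparison statistics.

For every bonded term of a topology, :func:`extract_distributions` collects
the per-frame geometric values over an ensemble (bond lengths in nm, angles
and dihedrals in degrees, dihedrals wrapped to (-180, 180] with circular
statistics) into normalized histograms with summary statistics and a
uni-/bimodality flag.  :func:`mae_between` compares two such sets term by
term and averages the absolute differences of the per-term means within
each category — the mean-absolute-error statistic used to judge how well a
CG model reproduces its mapped atomistic reference.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats as sps
from scipy.ndimage import gaussian_filter1d
from scipy.signal import find_peaks

from .ensemble import ConformerEnsemble
from .topology import CGTopology

__all__ = [
    "TermDistribution",
    "DistributionSet",
    "MAEReport",
    "InsufficientDataError",
    "ComparisonError",
    "extract_distributions",
    "bond_length_series",
    "angle_series",
    "dihedral_series",
    "mae_between",
    "find_modes",
    "write_distribution_tables",
]

#: default histogram bin widths: bonds in nm, angles/dihedrals in degrees
DEFAULT_BOND_BIN = 0.001
DEFAULT_ANGLE_BIN = 1.0

#: modality detector: peaks above this fraction of the global maximum ...
MODE_HEIGHT_FRACTION = 0.10
#: ... separated by at least this many degrees count as distinct modes
MODE_MIN_SEPARATION_DEG = 15.0


class InsufficientDataError(ValueError):
    pass


class ComparisonError(ValueError):
    pass


@dataclass
class TermDistribution:
    term_id: str
    kind: str  # bond | angle | dihedral
    edges: np.ndarray  # bin edges (nm or degrees)
    density: np.ndarray  # normalized: sum(density * widths) == 1
    mean: float  # linear mean (bond, angle) or circular mean (dihedral)
    std: float  # linear or circular std, same units
    modality: str = "unimodal"  # unimodal | bimodal
    modes: tuple[float, ...] = ()  # mode positions (same units as mean)

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])


@dataclass
class DistributionSet:
    terms: dict[str, TermDistribution] = field(default_factory=dict)

    def __getitem__(self, term_id: str) -> TermDistribution:
        return self.terms[term_id]

    def __iter__(self):
        return iter(self.terms.values())

    def ids(self, kind: str | None = None) -> list[str]:
        return [t.term_id for t in self if kind is None or t.kind == kind]


@dataclass
class MAEReport:
    mae_bonds: float | None  # nm
    mae_angles_unimodal: float | None  # degrees
    mae_angles_bimodal: float | None  # degrees
    mae_dihedrals: float | None  # degrees (circular means)
    per_term: dict[str, float] = field(default_factory=dict)
    thresholds: dict[str, float] = field(default_factory=dict)

    def passed(self) -> bool:
        checks = {
            "bonds": self.mae_bonds,
            "angles_unimodal": self.mae_angles_unimodal,
            "angles_bimodal": self.mae_angles_bimodal,
        }
        for key, value in checks.items():
            thr = self.thresholds.get(key)
            if thr is not None and value is not None and value > thr:
                return False
        return True

    def to_json(self, path: str | Path | None = None) -> str:
        data = {
            "mae_bonds_nm": self.mae_bonds,
            "mae_angles_unimodal_deg": self.mae_angles_unimodal,
            "mae_angles_bimodal_deg": self.mae_angles_bimodal,
            "mae_dihedrals_deg": self.mae_dihedrals,
            "per_term_abs_diff": self.per_term,
            "thresholds": self.thresholds,
            "passed": self.passed(),
            "convention": "MAE over per-term distribution means; "
                          "bimodal angles compared mode-by-mode (nearest pairing)",
        }
        text = json.dumps(data, indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


def _grid_edges(lo: float, hi: float, width: float) -> np.ndarray:
    """Bin edges of the given width on a grid aligned to multiples of width."""
    start = np.floor(lo / width) * width
    stop = np.ceil(hi / width) * width
    n = max(int(round((stop - start) / width)), 1)
    return start + width * np.arange(n + 1)


def find_modes(
    centers: np.ndarray,
    density: np.ndarray,
    min_separation: float = MODE_MIN_SEPARATION_DEG,
    height_fraction: float = MODE_HEIGHT_FRACTION,
    smooth_bins: float = 2.0,
) -> tuple[float, ...]:
    """Mode positions of a histogram density by kernel smoothing + peak picking.

    Peaks above ``height_fraction`` of the global maximum and separated by at
    least ``min_separation`` (same units as ``centers``) are kept; peak
    positions are refined by quadratic interpolation through the three bins
    around each maximum.
    """
    if len(centers) < 3:
        return (float(centers[np.argmax(density)]),)
    width = centers[1] - centers[0]
    smooth = gaussian_filter1d(density.astype(float), smooth_bins, mode="nearest")
    if np.isfinite(min_separation):
        distance = max(int(round(min_separation / width)), 1)
    else:
        distance = len(centers)
    idx, _ = find_peaks(smooth, height=height_fraction * smooth.max(), distance=distance)
    if len(idx) == 0:
        idx = np.array([int(np.argmax(smooth))])
    modes = []
    for i in idx:
        if 0 < i < len(smooth) - 1:
            y0, y1, y2 = smooth[i - 1], smooth[i], smooth[i + 1]
            denom = y0 - 2 * y1 + y2
            shift = 0.0 if denom == 0 else 0.5 * (y0 - y2) / denom
            modes.append(float(centers[i] + np.clip(shift, -1, 1) * width))
        else:
            modes.append(float(centers[i]))
    # keep the two highest if more than two survive
    if len(modes) > 2:
        heights = [smooth[np.argmin(np.abs(centers - m))] for m in modes]
        order = np.argsort(heights)[::-1][:2]
        modes = [modes[i] for i in sorted(order)]
    return tuple(sorted(modes))


def _make_distribution(
    term_id: str, kind: str, samples: np.ndarray, bin_width: float
) -> TermDistribution:
    if kind == "dihedral":
        samples = -(np.mod(-samples + 180.0, 360.0) - 180.0)  # wrap to (-180, 180]
        edges = _grid_edges(-180.0, 180.0, bin_width)
        mean = float(sps.circmean(samples, high=180.0, low=-180.0))
        std = float(sps.circstd(samples, high=180.0, low=-180.0))
    elif kind == "angle":
        edges = _grid_edges(0.0, 180.0, bin_width)
        mean = float(np.mean(samples))
        std = float(np.std(samples))
    else:
        lo, hi = float(samples.min()), float(samples.max())
        pad = max(3 * bin_width, 0.05 * (hi - lo))
        edges = _grid_edges(max(lo - pad, 0.0), hi + pad, bin_width)
        mean = float(np.mean(samples))
        std = float(np.std(samples))
    density, edges = np.histogram(samples, bins=edges, density=True)
    centers = 0.5 * (edges[:-1] + edges[1:])
    if kind in ("angle", "dihedral"):
        modes = find_modes(centers, density)
    else:
        # bond-length distributions are treated as unimodal by construction
        modes = find_modes(centers, density, min_separation=np.inf)
    modality = "bimodal" if len(modes) >= 2 else "unimodal"
    return TermDistribution(
        term_id=term_id, kind=kind, edges=edges, density=density,
        mean=mean, std=std, modality=modality,
        modes=modes if modality == "bimodal" else (modes[0],),
    )


def bond_length_series(frames: np.ndarray, i: int, j: int) -> np.ndarray:
    """Per-frame i-j distance, nm; ``frames`` is (F, N, 3)."""
    return np.linalg.norm(frames[:, j] - frames[:, i], axis=1)


def angle_series(frames: np.ndarray, i: int, j: int, k: int) -> np.ndarray:
    """Per-frame angle at bead j, degrees."""
    u = frames[:, i] - frames[:, j]
    v = frames[:, k] - frames[:, j]
    cos = np.einsum("fi,fi->f", u, v) / (
        np.linalg.norm(u, axis=1) * np.linalg.norm(v, axis=1))
    return np.rad2deg(np.arccos(np.clip(cos, -1.0, 1.0)))


def dihedral_series(frames: np.ndarray, i: int, j: int, k: int, l: int) -> np.ndarray:
    """Per-frame signed dihedral, degrees, wrapped to (-180, 180]."""
    b1 = frames[:, j] - frames[:, i]
    b2 = frames[:, k] - frames[:, j]
    b3 = frames[:, l] - frames[:, k]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    y = np.einsum("fi,fi->f", np.cross(n1, n2), b2) / np.linalg.norm(b2, axis=1)
    x = np.einsum("fi,fi->f", n1, n2)
    deg = np.rad2deg(np.arctan2(y, x))
    return -(np.mod(-deg + 180.0, 360.0) - 180.0)


def extract_distributions(
    ens: ConformerEnsemble,
    top: CGTopology,
    bond_bin: float = DEFAULT_BOND_BIN,
    angle_bin: float = DEFAULT_ANGLE_BIN,
) -> DistributionSet:
    """One distribution per bonded term of ``top`` over all frames of ``ens``."""
    if ens.n_frames < 2:
        raise InsufficientDataError(
            f"need at least 2 frames to extract distributions, got {ens.n_frames}"
        )
    if ens.n_particles != top.n_beads:
        raise ValueError(
            f"ensemble has {ens.n_particles} particles, topology {top.n_beads} beads"
        )
    out = DistributionSet()
    frames = ens.frames
    for b in top.bonds:
        tid = f"bond:{b.i}-{b.j}"
        out.terms[tid] = _make_distribution(
            tid, "bond", bond_length_series(frames, b.i, b.j), bond_bin)
    for a in top.angles:
        tid = f"angle:{a.i}-{a.j}-{a.k}"
        out.terms[tid] = _make_distribution(
            tid, "angle", angle_series(frames, a.i, a.j, a.k), angle_bin)
    for d in top.dihedrals:
        tid = f"dihedral:{d.i}-{d.j}-{d.k}-{d.l}"
        out.terms[tid] = _make_distribution(
            tid, "dihedral", dihedral_series(frames, d.i, d.j, d.k, d.l), angle_bin)
    return out


def _circular_abs_diff(a: float, b: float) -> float:
    d = abs(a - b) % 360.0
    return min(d, 360.0 - d)


def _bimodal_abs_diff(ref: TermDistribution, model: TermDistribution) -> float:
    """Mode-by-mode |difference|, pairing each model mode with the nearest
    reference mode, averaged over the pairs."""
    ref_modes = ref.modes or (ref.mean,)
    model_modes = model.modes or (model.mean,)
    diffs = [min(abs(m - r) for r in ref_modes) for m in model_modes]
    return float(np.mean(diffs))


def mae_between(
    ref: DistributionSet,
    model: DistributionSet,
    thresholds: dict[str, float] | None = None,
) -> MAEReport:
    """Category-wise mean absolute error of per-term means (modes for
    bimodal angles) between a reference and a model distribution set."""
    if set(ref.terms) != set(model.terms):
        missing = set(ref.terms) ^ set(model.terms)
        raise ComparisonError(f"term lists differ; unmatched ids: {sorted(missing)}")
    per_term: dict[str, float] = {}
    cats: dict[str, list[float]] = {"bonds": [], "uni": [], "bi": [], "dih": []}
    for tid, r in ref.terms.items():
        m = model.terms[tid]
        if r.kind == "bond":
            d = abs(m.mean - r.mean)
            cats["bonds"].append(d)
        elif r.kind == "angle":
            if r.modality == "bimodal" or m.modality == "bimodal":
                d = _bimodal_abs_diff(r, m)
                cats["bi"].append(d)
            else:
                d = abs(m.mean - r.mean)
                cats["uni"].append(d)
        else:
            d = _circular_abs_diff(m.mean, r.mean)
            cats["dih"].append(d)
        per_term[tid] = float(d)

    def _mae(vals: list[float]) -> float | None:
        return float(np.mean(vals)) if vals else None

    return MAEReport(
        mae_bonds=_mae(cats["bonds"]),
        mae_angles_unimodal=_mae(cats["uni"]),
        mae_angles_bimodal=_mae(cats["bi"]),
        mae_dihedrals=_mae(cats["dih"]),
        per_term=per_term,
        thresholds=thresholds or {},
    )


def write_distribution_tables(dset: DistributionSet, path: str | Path) -> None:
    """Whitespace-delimited table: term id, bin center, density."""
    lines = ["# term_id  bin_center  density"]
    for t in dset:
        for c, d in zip(t.centers, t.density):
            lines.append(f"{t.term_id}  {c:.6g}  {d:.8g}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_distribution_tables(path: str | Path) -> DistributionSet:
    """Rebuild a :class:`DistributionSet` from a table written by
    :func:`write_distribution_tables` (summary statistics are recomputed
    from the histograms)."""
    rows: dict[str, list[tuple[float, float]]] = {}
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        tid, center, density = line.split()
        rows.setdefault(tid, []).append((float(center), float(density)))
    out = DistributionSet()
    for tid, data in rows.items():
        data.sort()
        centers = np.array([c for c, _ in data])
        density = np.array([d for _, d in data])
        width = centers[1] - centers[0] if len(centers) > 1 else 1.0
        edges = np.concatenate([centers - 0.5 * width, [centers[-1] + 0.5 * width]])
        kind = tid.split(":", 1)[0]
        w = density * width
        w = w / w.sum()
        if kind == "dihedral":
            z = np.sum(w * np.exp(1j * np.deg2rad(centers)))
            mean = float(np.rad2deg(np.angle(z)))
            r = min(abs(z), 1.0)
            std = float(np.rad2deg(np.sqrt(-2.0 * np.log(r)))) if r > 0 else 180.0
        else:
            mean = float(np.sum(w * centers))
            std = float(np.sqrt(max(np.sum(w * centers**2) - mean**2, 0.0)))
        if kind in ("angle", "dihedral"):
            modes = find_modes(centers, density)
        else:
            modes = find_modes(centers, density, min_separation=np.inf)
        modality = "bimodal" if len(modes) >= 2 else "unimodal"
        out.terms[tid] = TermDistribution(
            term_id=tid, kind=kind, edges=edges, density=density,
            mean=mean, std=std, modality=modality,
            modes=modes if modality == "bimodal" else (modes[0],),
        )
    return out
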