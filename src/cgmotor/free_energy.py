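"""Free-energy estimators: TI over an alchemical path, Bennett's acceptance
ratio, WHAM for umbrella windows, and octanol-water log P assembly.

These implement the analysis half of a solvation / partitioning free-energy
protocol: per-window or per-lambda samples come in (from simulation output
files or from the synthetic generators), and a Delta G or a potential of
mean force with uncertainties comes out.

Conventions: energies kJ/mol, reaction coordinate nm, temperatures K.
log P uses the solvation free-energy difference between water and
(hydrated) octanol,

    log P = (dG_water->vac - dG_octanol->vac) / (ln(10) R T),

so a hydrophobic solute (easier to pull out of water than out of octanol)
gets a positive log P.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit, logsumexp

from .constants import KB

__all__ = [
    "LambdaSeries",
    "WorkSamples",
    "UmbrellaSet",
    "PMFProfile",
    "FreeEnergyResult",
    "OverlapError",
    "ti_integrate",
    "bar_estimate",
    "wham",
    "log_p",
    "read_lambda_series",
    "read_work_samples",
    "read_umbrella_set",
]

LN10 = float(np.log(10.0))


class OverlapError(RuntimeError):
    pass


@dataclass
class LambdaSeries:
    """Per-lambda samples of dH/dlambda along an alchemical path."""

    lambdas: np.ndarray  # strictly increasing, endpoints 0 and 1
    samples: list[np.ndarray]  # per-lambda dH/dlambda samples, kJ/mol

    def __post_init__(self) -> None:
        self.lambdas = np.asarray(self.lambdas, dtype=float)
        if len(self.lambdas) != len(self.samples):
            raise ValueError("one sample array per lambda required")
        if np.any(np.diff(self.lambdas) <= 0):
            raise ValueError("lambda values must be strictly increasing")
        if abs(self.lambdas[0]) > 1e-12 or abs(self.lambdas[-1] - 1.0) > 1e-12:
            raise ValueError("lambda path must include both endpoints 0 and 1")
        self.samples = [np.atleast_1d(np.asarray(s, dtype=float)) for s in self.samples]


@dataclass
class WorkSamples:
    forward: np.ndarray  # kJ/mol
    reverse: np.ndarray  # kJ/mol
    temperature: float = 300.0

    def __post_init__(self) -> None:
        self.forward = np.atleast_1d(np.asarray(self.forward, dtype=float))
        self.reverse = np.atleast_1d(np.asarray(self.reverse, dtype=float))
        if self.forward.size == 0 or self.reverse.size == 0:
            raise ValueError("BAR needs work samples in both directions")


@dataclass
class UmbrellaWindow:
    xi0: float  # reference position, nm
    k: float  # spring constant, kJ/mol/nm^2
    series: np.ndarray  # sampled reaction-coordinate values, nm

    def __post_init__(self) -> None:
        self.series = np.atleast_1d(np.asarray(self.series, dtype=float))


@dataclass
class UmbrellaSet:
    windows: list[UmbrellaWindow]
    temperature: float = 300.0

    def __post_init__(self) -> None:
        if len(self.windows) < 1:
            raise ValueError("need at least one umbrella window")


@dataclass
class PMFProfile:
    centers: np.ndarray  # nm
    free_energy: np.ndarray  # kJ/mol, min-anchored at 0
    errors: np.ndarray  # bootstrap standard errors, kJ/mol
    occupied: np.ndarray | None = None  # bins with any samples

    def write(self, path: str | Path) -> None:
        lines = ["# xi_nm  F_kJ_per_mol  bootstrap_se"]
        for c, f, e in zip(self.centers, self.free_energy, self.errors):
            lines.append(f"{c:.6g}  {f:.6g}  {e:.6g}")
        Path(path).write_text("\n".join(lines) + "\n")


@dataclass
class FreeEnergyResult:
    dG: float  # kJ/mol
    uncertainty: float  # kJ/mol
    method: str  # TI | BAR | WHAM-difference
    extra: dict = field(default_factory=dict)


# -- thermodynamic integration -----------------------------------------

def ti_integrate(series: LambdaSeries) -> FreeEnergyResult:
    """Trapezoidal integral of <dH/dlambda> over lambda; the uncertainty
    propagates the per-lambda standard errors through the trapezoid
    weights."""
    lam = series.lambdas
    if len(lam) < 2:
        raise ValueError("TI needs at least two lambda points")
    means = np.array([s.mean() for s in series.samples])
    sems = np.array([
        s.std(ddof=1) / np.sqrt(len(s)) if len(s) > 1 else 0.0
        for s in series.samples
    ])
    # trapezoid quadrature weights
    w = np.zeros_like(lam)
    dl = np.diff(lam)
    w[:-1] += 0.5 * dl
    w[1:] += 0.5 * dl
    dG = float(np.dot(w, means))
    err = float(np.sqrt(np.dot(w**2, sems**2)))
    return FreeEnergyResult(dG=dG, uncertainty=err, method="TI",
                            extra={"n_lambda": len(lam)})


# -- Bennett's acceptance ratio -----------------------------------------

def bar_estimate(w: WorkSamples) -> FreeEnergyResult:
    """Self-consistent Bennett estimate from forward and reverse work.

    Solves  sum_F f(beta(W_F - dG + M)) = sum_R f(beta(W_R + dG - M)),
    f the logistic function, M = ln(n_F/n_R)/beta, by bracketed root
    finding; reports the standard asymptotic variance.
    """
    beta = 1.0 / (KB * w.temperature)
    n_f, n_r = len(w.forward), len(w.reverse)
    M = np.log(n_f / n_r) / beta

    def imbalance(dG: float) -> float:
        lhs = expit(-beta * (w.forward - dG + M)).sum()
        rhs = expit(-beta * (w.reverse + dG - M)).sum()
        return lhs - rhs

    lo = min(w.forward.min(), -w.reverse.max()) - 1.0
    hi = max(w.forward.max(), -w.reverse.min()) + 1.0
    for _ in range(60):
        if imbalance(lo) * imbalance(hi) <= 0:
            break
        span = hi - lo
        lo -= span
        hi += span
    else:
        raise OverlapError(
            "BAR root not bracketed: forward and reverse work distributions "
            f"do not overlap (forward range [{w.forward.min():.3g}, "
            f"{w.forward.max():.3g}], reverse range [{w.reverse.min():.3g}, "
            f"{w.reverse.max():.3g}] kJ/mol)"
        )
    dG = brentq(imbalance, lo, hi, xtol=1e-12, rtol=8.9e-16)

    # asymptotic variance (Bennett 1976): fluctuations of the Fermi weights
    f_f = expit(-beta * (w.forward - dG + M))
    f_r = expit(-beta * (w.reverse + dG - M))
    with np.errstate(divide="ignore"):
        var_beta_dG = (
            f_f.var() / (n_f * f_f.mean() ** 2)
            + f_r.var() / (n_r * f_r.mean() ** 2)
        )
    err = float(np.sqrt(var_beta_dG) / beta) if np.isfinite(var_beta_dG) else 0.0
    return FreeEnergyResult(dG=float(dG), uncertainty=err, method="BAR",
                            extra={"n_forward": n_f, "n_reverse": n_r})


# -- WHAM ----------------------------------------------------------------

def wham(
    us: UmbrellaSet,
    n_bins: int = 300,
    n_bootstrap: int = 100,
    seed: int = 0,
    tol: float = 1e-7,
    max_iter: int = 100_000,
) -> PMFProfile:
    """Self-consistent WHAM unbiasing of umbrella-window histograms.

    Iterates the standard coupled equations for the unbiased bin
    probabilities and window free energies to relative tolerance ``tol``
    on the window free energies.  Uncertainty comes from ``n_bootstrap``
    replicates in which every window's own time series is resampled with
    replacement (the window is the resampling block).  The profile is
    anchored so its minimum over occupied bins is zero.
    """
    if len(us.windows) >= 2:
        order = np.argsort([w.xi0 for w in us.windows])
        sorted_w = [us.windows[i] for i in order]
        for a, b in zip(sorted_w[:-1], sorted_w[1:]):
            if a.series.max() < b.series.min():
                raise OverlapError(
                    f"umbrella windows at xi0={a.xi0:.3g} and {b.xi0:.3g} nm have "
                    f"disjoint sampled ranges (gap {b.series.min() - a.series.max():.3g} nm); "
                    "WHAM cannot connect them"
                )
    beta = 1.0 / (KB * us.temperature)
    all_xi = np.concatenate([w.series for w in us.windows])
    lo, hi = float(all_xi.min()), float(all_xi.max())
    edges = np.linspace(lo, hi, n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    widths = np.diff(edges)
    # bias energies, (n_windows, n_bins)
    bias = np.array([0.5 * w.k * (centers - w.xi0) ** 2 for w in us.windows])
    log_boltz = -beta * bias
    n_samples = np.array([len(w.series) for w in us.windows], dtype=float)

    def solve(series_list: list[np.ndarray], f_init: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        hist = np.array([np.histogram(s, bins=edges)[0] for s in series_list],
                        dtype=float)
        counts = hist.sum(axis=0)
        log_counts = np.where(counts > 0, np.log(np.maximum(counts, 1e-300)), -np.inf)
        f = f_init.copy()  # dimensionless window free energies, beta*F_w
        for _ in range(max_iter):
            # log denominator: ln sum_w N_w exp(f_w - beta U_w(x))
            log_den = logsumexp(
                f[:, None] + log_boltz + np.log(n_samples)[:, None], axis=0)
            log_p = log_counts - log_den  # unnormalised ln P(x_b)
            new_f = -logsumexp(log_p[None, :] + log_boltz, axis=1)
            new_f -= new_f[0]
            delta = np.max(np.abs(new_f - f))
            scale = max(np.max(np.abs(new_f)), 1.0)
            f = new_f
            if delta <= tol * scale:
                break
        else:
            raise OverlapError("WHAM iteration failed to converge")
        with np.errstate(divide="ignore"):
            F = -np.log(np.exp(log_p) / widths) / beta
        return F, f

    f0 = np.zeros(len(us.windows))
    F_raw, f_conv = solve([w.series for w in us.windows], f0)
    occupied = np.isfinite(F_raw)
    F = F_raw - np.nanmin(F_raw[occupied])

    rng = np.random.default_rng(seed)
    boot = np.full((n_bootstrap, n_bins), np.nan)
    for b in range(n_bootstrap):
        resampled = [
            w.series[rng.integers(0, len(w.series), size=len(w.series))]
            for w in us.windows
        ]
        Fb, _ = solve(resampled, f_conv)
        occ = np.isfinite(Fb)
        boot[b] = Fb - np.nanmin(Fb[occ & occupied])
    with np.errstate(invalid="ignore"):
        errors = np.nanstd(boot, axis=0, ddof=1)
    errors = np.where(np.isfinite(errors), errors, 0.0)
    F = np.where(occupied, F, np.nan)
    return PMFProfile(centers=centers, free_energy=F, errors=errors,
                      occupied=occupied)


# -- partition coefficient ----------------------------------------------

def log_p(
    dG_water: FreeEnergyResult,
    dG_octanol: FreeEnergyResult,
    T: float = 310.0,
) -> tuple[float, float]:
    """Octanol-water partition coefficient from the two solvent->vacuum
    transfer free energies; returns (log P, uncertainty in log units)."""
    if dG_water.extra.get("temperature") is not None \
            and dG_octanol.extra.get("temperature") is not None \
            and dG_water.extra["temperature"] != dG_octanol.extra["temperature"]:
        raise ValueError("inputs were computed at different temperatures")
    denom = LN10 * KB * T
    value = (dG_water.dG - dG_octanol.dG) / denom
    err = float(np.hypot(dG_water.uncertainty, dG_octanol.uncertainty) / denom)
    return float(value), err


# -- file readers (whitespace-delimited text) ---------------------------

def read_lambda_series(path: str | Path) -> LambdaSeries:
    """Columns: lambda, dH/dlambda sample (one sample per row)."""
    data = np.loadtxt(path, ndmin=2)
    lams = np.unique(data[:, 0])
    samples = [data[data[:, 0] == l, 1] for l in lams]
    return LambdaSeries(lambdas=lams, samples=samples)


def read_work_samples(path: str | Path, temperature: float = 300.0) -> WorkSamples:
    """Columns: direction (+1 forward / -1 reverse), work kJ/mol."""
    data = np.loadtxt(path, ndmin=2)
    fwd = data[data[:, 0] > 0, 1]
    rev = data[data[:, 0] < 0, 1]
    return WorkSamples(forward=fwd, reverse=rev, temperature=temperature)


def read_umbrella_set(
    meta_path: str | Path, temperature: float = 300.0
) -> UmbrellaSet:
    """Metadata file rows: series_file  xi0_nm  k; series files have the
    reaction coordinate in their last column (time may precede it)."""
    meta_path = Path(meta_path)
    windows = []
    for line in meta_path.read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        fname, xi0, k = line.split()[:3]
        series = np.loadtxt(meta_path.parent / fname, ndmin=2)[:, -1]
        windows.append(UmbrellaWindow(xi0=float(xi0), k=float(k), series=series))
    return UmbrellaSet(windows=windows, temperature=temperature)
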