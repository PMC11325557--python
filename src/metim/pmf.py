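"""Potential-of-mean-force assembly from umbrella windows.

WHAM (weighted histogram analysis method) unbiases overlapping
harmonically restrained windows into a single 1-D free-energy profile
G(r) along the ion-ligand distance.  From the profile, the binding free
energy is extracted by a volume-corrected Boltzmann integral over the
bound region referenced to the bulk plateau and to a standard-state
concentration (1 M by default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .toysim import KB, DistanceSeries

__all__ = [
    "PMFProfile",
    "WhamSolution",
    "EstimationError",
    "ConvergenceError",
    "AnalysisError",
    "wham",
    "remove_radial_entropy",
    "binding_free_energy",
    "stationary_points",
    "StationaryPoint",
    "bootstrap_profile",
]


class EstimationError(ValueError):
    """Window set cannot support a joint estimate (e.g. a coverage gap)."""


class ConvergenceError(RuntimeError):
    """Self-consistent iteration exceeded max_iter; carries the residual."""

    def __init__(self, message: str, residual: float) -> None:
        super().__init__(message)
        self.residual = residual


class AnalysisError(ValueError):
    """Profile does not meet the assumptions of the requested analysis."""


@dataclass
class PMFProfile:
    """Binned free-energy profile, normalized so min(G) = 0.

    The profile is interpreted as piecewise constant over bins of width
    ``bin_width`` centred on ``grid``.
    """

    grid: np.ndarray  # Å bin centers, strictly increasing
    free_energy: np.ndarray  # kcal/mol
    bin_width: float
    reference: str = "min-zero"
    se: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.free_energy = np.asarray(self.free_energy, dtype=float)
        if np.any(np.diff(self.grid) <= 0):
            raise ValueError("grid must be strictly increasing")
        if not np.all(np.isfinite(self.free_energy)):
            raise ValueError("profile contains undefined bins inside the sampled range")


@dataclass
class WhamSolution:
    """Per-window free-energy offsets (f_0 ≡ 0) and convergence metadata."""

    offsets: np.ndarray  # kcal/mol
    n_iterations: int
    residual: float
    converged: bool


def _window_bias_matrix(windows, grid):
    w = np.empty((len(windows), len(grid)))
    for i, series in enumerate(windows):
        r = series.restraint
        w[i] = 0.5 * r.spring_constant * (grid - r.center) ** 2
    return w


def _check_overlap(windows, min_overlap: int = 5) -> None:
    order = np.argsort([w.restraint.center for w in windows])
    for a, b in zip(order[:-1], order[1:]):
        lo = max(windows[a].values.min(), windows[b].values.min())
        hi = min(windows[a].values.max(), windows[b].values.max())
        if hi <= lo:
            raise EstimationError(
                f"no histogram overlap between windows centred at "
                f"{windows[a].restraint.center:.3f} and "
                f"{windows[b].restraint.center:.3f} Å (gap {lo - hi:.3f} Å)"
            )
        n_shared = min(
            int(np.sum((windows[a].values >= lo) & (windows[a].values <= hi))),
            int(np.sum((windows[b].values >= lo) & (windows[b].values <= hi))),
        )
        if n_shared < min_overlap:
            warnings.warn(
                f"adjacent windows at {windows[a].restraint.center:.3f} and "
                f"{windows[b].restraint.center:.3f} Å share only {n_shared} samples",
                stacklevel=3,
            )


def wham(
    windows: list[DistanceSeries],
    n_bins: int = 200,
    tol: float = 1e-7,
    max_iter: int = 100_000,
    temperature: float = 300.0,
    min_counts: int = 10,
) -> tuple[PMFProfile, WhamSolution]:
    """Self-consistent WHAM on 1-D histograms with harmonic biases.

    Iterates the coupled equations

        P(b) ∝ Σ_i n_i(b) / Σ_i N_i exp(-β (w_i(b) - f_i))
        f_i  = -k_B T ln Σ_b exp(-β w_i(b)) P(b)

    by direct (unaccelerated) fixed-point iteration until
    max_i |Δf_i| < ``tol`` (kcal/mol).  Offsets are reported relative to
    window 0; the profile G = -k_B T ln P is shifted to min 0.  Edge bins
    holding fewer than ``min_counts`` total samples are trimmed (their G
    estimates are dominated by extreme-tail noise of the outermost windows).
    """
    if len(windows) == 0:
        raise EstimationError("at least one window required")
    if len(windows) > 1:
        _check_overlap(windows)
    beta = 1.0 / (KB * temperature)
    lo = min(w.values.min() for w in windows)
    hi = max(w.values.max() for w in windows)
    edges = np.linspace(lo, hi, n_bins + 1)
    grid = 0.5 * (edges[:-1] + edges[1:])
    counts = np.array([np.histogram(w.values, bins=edges)[0] for w in windows], dtype=float)
    n_tot = counts.sum(axis=1)  # N_i
    numer = counts.sum(axis=0)  # Σ_i n_i(b)
    bias = _window_bias_matrix(windows, grid)  # (n_win, n_bins)
    boltz = np.exp(-beta * bias)

    f = np.zeros(len(windows))
    residual = np.inf
    for iteration in range(1, max_iter + 1):
        denom = (n_tot * np.exp(beta * f)) @ boltz
        with np.errstate(divide="ignore", invalid="ignore"):
            p = np.where(denom > 0, numer / denom, 0.0)
        z = boltz @ p
        f_new = -KB * temperature * np.log(z)
        f_new -= f_new[0]
        residual = float(np.max(np.abs(f_new - f)))
        f = f_new
        if residual < tol:
            break
    else:
        raise ConvergenceError(
            f"WHAM did not converge in {max_iter} iterations "
            f"(residual {residual:.3e} kcal/mol)",
            residual,
        )

    occupied = numer > 0
    g = np.full_like(grid, np.nan)
    g[occupied] = -KB * temperature * np.log(p[occupied])
    # trim thin edges, keep the contiguously well-sampled range
    idx = np.where(numer >= min_counts)[0]
    if idx.size == 0:
        idx = np.where(occupied)[0]
    first, last = idx[0], idx[-1]
    interior = occupied[first : last + 1]
    if not interior.all():
        n_empty = int((~interior).sum())
        warnings.warn(
            f"{n_empty} empty interior bins inside the sampled range; "
            "filled by linear interpolation",
            stacklevel=2,
        )
        inner = np.arange(first, last + 1)
        g[first : last + 1] = np.interp(
            grid[first : last + 1], grid[first : last + 1][interior], g[first : last + 1][interior]
        )
    grid = grid[first : last + 1]
    g = g[first : last + 1]
    g -= g.min()
    profile = PMFProfile(grid=grid, free_energy=g, bin_width=float(edges[1] - edges[0]))
    solution = WhamSolution(
        offsets=f, n_iterations=iteration, residual=residual, converged=True
    )
    return profile, solution


# ---------------------------------------------------------------------------
# Binding free energy from the profile
# ---------------------------------------------------------------------------

#: Å³ per molecule at 1 mol/L.
_STANDARD_VOLUME_1M = 1e27 / 6.02214076e23


def remove_radial_entropy(profile: PMFProfile, temperature: float = 300.0) -> PMFProfile:
    """Subtract the radial-shell entropy from a distance PMF.

    A PMF estimated from raw distance histograms in 3-D carries the
    -2 k_B T ln r term of the spherical-shell Jacobian, so it drifts
    downward at large r instead of plateauing.  This returns the centred
    profile G(r) + 2 k_B T ln r (re-normalized to min 0), whose tail is
    flat for a short-ranged interaction; use it before
    :func:`binding_free_energy`, whose 4πr² bound-volume integral supplies
    the Jacobian explicitly.
    """
    g = profile.free_energy + 2.0 * KB * temperature * np.log(profile.grid)
    g = g - g.min()
    return PMFProfile(
        grid=profile.grid.copy(),
        free_energy=g,
        bin_width=profile.bin_width,
        reference="min-zero, radial entropy removed",
    )


def _plateau(profile: PMFProfile, fraction: float = 0.2, max_slope: float = 0.05):
    """Mean plateau level over the outermost ``fraction`` of the range;
    raises AnalysisError if the tail slope exceeds ``max_slope`` kcal/mol/Å."""
    n = len(profile.grid)
    n_tail = max(int(np.ceil(fraction * n)), 3)
    r = profile.grid[-n_tail:]
    g = profile.free_energy[-n_tail:]
    slope = float(np.polyfit(r, g, 1)[0])
    if abs(slope) > max_slope:
        raise AnalysisError(
            f"no plateau: tail slope {slope:.3f} kcal/mol/Å exceeds {max_slope}"
        )
    return float(g.mean())


def binding_free_energy(
    profile: PMFProfile,
    bound_cutoff: float,
    concentration_standard: float = 1.0,
    temperature: float = 300.0,
    method: str = "volume",
    plateau_max_slope: float = 0.05,
) -> float:
    """Standard-state binding free energy from a distance PMF.

    ``method="volume"`` (default) evaluates

        ΔG = -k_B T ln( ∫_bound 4π r² exp(-G(r)/k_B T) dr / V° )

    with G referenced to the bulk plateau and V° the volume per molecule at
    ``concentration_standard`` mol/L.  The integral treats the profile as
    piecewise constant per bin (exact for bin-aligned square wells).
    ``method="well_depth"`` returns min(G) − plateau, a cruder estimator for
    sensitivity checks.  ``plateau_max_slope`` (kcal/mol/Å) is the tail-slope
    gate of the plateau test; raise it for noisy toy-engine profiles.
    """
    if bound_cutoff <= profile.grid[0]:
        raise AnalysisError("bound region not sampled: cutoff below the grid")
    plateau = _plateau(profile, max_slope=plateau_max_slope)
    g_ref = profile.free_energy - plateau
    if method == "well_depth":
        return float(g_ref.min())
    if method != "volume":
        raise ValueError(f"unknown method {method!r}")
    beta = 1.0 / (KB * temperature)
    h = profile.bin_width
    lo_edges = profile.grid - 0.5 * h
    hi_edges = np.minimum(profile.grid + 0.5 * h, bound_cutoff)
    inside = hi_edges > lo_edges
    shell = (4.0 * np.pi / 3.0) * (hi_edges[inside] ** 3 - lo_edges[inside] ** 3)
    integral = float(np.sum(shell * np.exp(-beta * g_ref[inside])))
    v0 = _STANDARD_VOLUME_1M / concentration_standard
    return float(-KB * temperature * np.log(integral / v0))


# ---------------------------------------------------------------------------
# Stationary points
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StationaryPoint:
    position: float  # Å
    value: float  # kcal/mol
    kind: str  # "min" | "max"
    barrier: float | None = None  # max minus adjacent min, maxima only


def stationary_points(
    profile: PMFProfile,
    smooth_window: int | None = None,
    min_prominence: float = 0.0,
) -> list[StationaryPoint]:
    """Local minima and maxima of the profile.

    ``smooth_window`` applies a reflection-padded moving average first
    (default none); ``min_prominence`` (kcal/mol) prunes adjacent
    extremum pairs whose free-energy contrast is smaller — useful for
    suppressing sampling wiggles on noisy profiles.  Maxima carry the
    barrier height relative to the lower adjacent minimum.
    """
    if len(profile.grid) < 5:
        raise ValueError("profile needs at least 5 bins")
    g = profile.free_energy
    if smooth_window is not None and smooth_window > 1:
        w = min(smooth_window, len(g) - 1)
        padded = np.pad(g, w, mode="reflect")
        kernel = np.ones(w) / w
        g = np.convolve(padded, kernel, mode="same")[w:-w]
    points: list[tuple[float, float, str]] = []
    for i in range(1, len(g) - 1):
        if g[i] < g[i - 1] and g[i] <= g[i + 1]:
            points.append((float(profile.grid[i]), float(g[i]), "min"))
        elif g[i] > g[i - 1] and g[i] >= g[i + 1]:
            points.append((float(profile.grid[i]), float(g[i]), "max"))
    # prune low-contrast neighbouring pairs, weakest first
    while min_prominence > 0 and len(points) >= 2:
        contrasts = [abs(points[j + 1][1] - points[j][1]) for j in range(len(points) - 1)]
        j = int(np.argmin(contrasts))
        if contrasts[j] >= min_prominence:
            break
        del points[j : j + 2]
    out: list[StationaryPoint] = []
    for j, (pos, val, kind) in enumerate(points):
        if kind == "max":
            neighbours = [
                q[1] for q in (points[j - 1 : j] + points[j + 1 : j + 2]) if q[2] == "min"
            ]
            barrier = val - min(neighbours) if neighbours else None
            out.append(StationaryPoint(pos, val, "max", barrier))
        else:
            out.append(StationaryPoint(pos, val, "min"))
    return out


# ---------------------------------------------------------------------------
# Block-bootstrap uncertainties
# ---------------------------------------------------------------------------

def _iact(x: np.ndarray, max_lag: int | None = None) -> float:
    """Integrated autocorrelation time (in samples) by initial-positive-sum."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 4 or x.std() == 0:
        return 1.0
    xc = x - x.mean()
    if max_lag is None:
        max_lag = min(n // 4, 1000)
    acf = np.correlate(xc, xc, mode="full")[n - 1 : n - 1 + max_lag + 1]
    acf /= acf[0]
    tau = 1.0
    for k in range(1, max_lag + 1):
        if acf[k] <= 0:
            break
        tau += 2.0 * acf[k]
    return max(tau, 1.0)


def bootstrap_profile(
    windows: list[DistanceSeries],
    n_boot: int = 50,
    seed: int = 0,
    **wham_kwargs,
) -> tuple[PMFProfile, np.ndarray]:
    """Per-window block bootstrap of the WHAM profile.

    Block length per window is its integrated autocorrelation time estimate.
    Returns the point-estimate profile and the bootstrap SE interpolated
    onto its grid.
    """
    profile, _ = wham(windows, **wham_kwargs)
    rng = np.random.default_rng(seed)
    block_lens = [max(1, int(round(_iact(w.values)))) for w in windows]
    samples = []
    for _ in range(n_boot):
        resampled = []
        for w, bl in zip(windows, block_lens):
            n = len(w.values)
            n_blocks = int(np.ceil(n / bl))
            starts = rng.integers(0, max(n - bl, 1), size=n_blocks)
            vals = np.concatenate([w.values[s : s + bl] for s in starts])[:n]
            resampled.append(
                DistanceSeries(values=vals, sampling_interval=w.sampling_interval, restraint=w.restraint)
            )
        try:
            p, _ = wham(resampled, **wham_kwargs)
        except (EstimationError, ConvergenceError):
            continue
        samples.append(np.interp(profile.grid, p.grid, p.free_energy))
    se = np.std(np.array(samples), axis=0, ddof=1) if len(samples) > 1 else np.zeros_like(profile.grid)
    profile.se = se
    return profile, se
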