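"""Exact-density synthetic umbrella windows for testing PMF assembly.

Instead of running dynamics, windows are drawn directly from the biased
Boltzmann density ∝ exp(−[G(r) + k/2 (r−r₀)²]/k_BT) of an analytic
profile G(r), by inverse-CDF sampling on a fine grid.  Exact sampling
removes sampler convergence as a confound: any disagreement between the
recovered and analytic profile is attributable to WHAM itself.

Profile families: ``double_well`` (two Gaussian wells), ``well_plus_shoulder``
(deep bound well plus a shallow outer shoulder, the cation-π-intermediate
analogue), and ``flat``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .toysim import KB, DistanceSeries, UmbrellaRestraint

__all__ = [
    "AnalyticProfile",
    "double_well",
    "well_plus_shoulder",
    "flat_profile",
    "SyntheticPmfSpec",
    "generate_windows",
    "sample_biased_density",
]


@dataclass(frozen=True)
class AnalyticProfile:
    """A closed-form free-energy profile G(r) with a stated validity range."""

    fn: Callable[[np.ndarray], np.ndarray]
    r_min: float
    r_max: float
    name: str = "analytic"

    def __call__(self, r):
        return self.fn(np.asarray(r, dtype=float))


def double_well(
    depth1: float = 4.0,
    pos1: float = 2.1,
    width1: float = 0.25,
    depth2: float = 1.5,
    pos2: float = 4.0,
    width2: float = 0.4,
    r_min: float = 1.5,
    r_max: float = 6.5,
) -> AnalyticProfile:
    """Two Gaussian wells: G(r) = −d₁ e^{−(r−p₁)²/2w₁²} − d₂ e^{−(r−p₂)²/2w₂²}."""

    def g(r):
        return -depth1 * np.exp(-((r - pos1) ** 2) / (2 * width1**2)) - depth2 * np.exp(
            -((r - pos2) ** 2) / (2 * width2**2)
        )

    return AnalyticProfile(g, r_min, r_max, "double_well")


def well_plus_shoulder(
    depth: float = 5.0,
    pos: float = 2.1,
    width: float = 0.25,
    shoulder_depth: float = 0.8,
    shoulder_pos: float = 4.5,
    shoulder_width: float = 0.5,
    r_min: float = 1.5,
    r_max: float = 7.0,
) -> AnalyticProfile:
    """Bound well plus a shallow outer minimum near the second shell."""
    p = double_well(depth, pos, width, shoulder_depth, shoulder_pos, shoulder_width, r_min, r_max)
    return AnalyticProfile(p.fn, r_min, r_max, "well_plus_shoulder")


def flat_profile(r_min: float = 1.5, r_max: float = 6.5) -> AnalyticProfile:
    return AnalyticProfile(lambda r: np.zeros_like(r), r_min, r_max, "flat")


@dataclass(frozen=True)
class SyntheticPmfSpec:
    """Window layout + sampling plan over an analytic profile.

    Defaults: 20 windows with k = 20 kcal/mol/Å² and 5000 samples each,
    spanning the profile's validity range.
    """

    profile: AnalyticProfile
    n_windows: int = 20
    spring_constant: float = 20.0  # kcal/mol/Å²
    samples_per_window: int = 5000
    temperature: float = 300.0
    seed: int = 0
    centers: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.samples_per_window < 100:
            raise ValueError("samples_per_window must be >= 100")
        if self.n_windows < 1:
            raise ValueError("need at least one window")

    def window_centers(self) -> np.ndarray:
        if self.centers is not None:
            return np.asarray(self.centers, dtype=float)
        return np.linspace(self.profile.r_min, self.profile.r_max, self.n_windows)


def sample_biased_density(
    profile: AnalyticProfile,
    restraint: UmbrellaRestraint,
    n_samples: int,
    temperature: float,
    rng: np.random.Generator,
    grid_resolution: float = 1e-3,
) -> np.ndarray:
    """Inverse-CDF draw from ∝ exp(−[G(r) + bias(r)]/k_BT).

    The grid covers the restraint center ± 5σ (σ = √(k_BT/k)) intersected
    with the profile's validity range, at ``grid_resolution`` Å.
    """
    kt = KB * temperature
    sigma = np.sqrt(kt / restraint.spring_constant)
    lo = max(profile.r_min, restraint.center - 5 * sigma)
    hi = min(profile.r_max, restraint.center + 5 * sigma)
    if hi <= lo:
        raise ValueError(
            f"window at {restraint.center} Å does not intersect the profile "
            f"range [{profile.r_min}, {profile.r_max}]"
        )
    grid = np.arange(lo, hi + grid_resolution, grid_resolution)
    u = profile(grid) + restraint.energy(grid)
    u = u - u.min()
    density = np.exp(-u / kt)
    total = np.trapezoid(density, grid)
    if total <= 0 or not np.isfinite(total):
        raise ValueError(f"biased density numerically zero across window at {restraint.center} Å")
    cdf = np.concatenate([[0.0], np.cumsum((density[1:] + density[:-1]) / 2) * grid_resolution])
    cdf /= cdf[-1]
    # strictly increasing section for interpolation
    return np.interp(rng.random(n_samples), cdf, grid)


def generate_windows(spec: SyntheticPmfSpec) -> list[DistanceSeries]:
    """Materialize every window of ``spec`` as a DistanceSeries.

    Per-window RNG streams are spawned from the spec seed, so the result is
    reproducible and windows are mutually independent.
    """
    centers = spec.window_centers()
    ss = np.random.SeedSequence(spec.seed)
    children = ss.spawn(len(centers))
    out = []
    for center, child in zip(centers, children):
        restraint = UmbrellaRestraint(center=float(center), spring_constant=spec.spring_constant)
        rng = np.random.default_rng(child)
        values = sample_biased_density(
            spec.profile, restraint, spec.samples_per_window, spec.temperature, rng
        )
        out.append(DistanceSeries(values=values, sampling_interval=1.0, restraint=restraint))
    return out
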