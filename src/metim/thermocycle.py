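"""Thermodynamic-cycle bookkeeping for relative metal-binding free energies.

A cycle joins two absolute binding legs (PMF: ion A and ion B binding the
same ligand set) with two alchemical mutation legs (TI: A→B in the bound
complex and A→B free in solution).  Free energy being a state function,
the signed sum around the cycle — the closure ΔΔG — should vanish; its
magnitude, and the mean absolute error (MAE) over a set of cycles,
diagnose parameter inconsistency.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CycleLegs",
    "CycleReport",
    "cycle_closure",
    "mae",
    "triplicate_stats",
    "build_report",
]

#: Leg orientation: binding legs point into the complex, mutation legs A→B;
#: closure = dg1 + dg2 − dg3 − dg4.
SIGN_CONVENTION = "closure = dg1(bind A) + dg2(TI A->B bound) - dg3(bind B) - dg4(TI A->B aqueous)"


@dataclass(frozen=True)
class CycleLegs:
    """Four legs of one mutation cycle (kcal/mol).

    dg1: PMF binding of ion A; dg2: TI A→B in the bound complex;
    dg3: PMF binding of ion B; dg4: TI A→B in aqueous solution.
    """

    dg1: float
    dg2: float
    dg3: float
    dg4: float
    se: tuple[float, float, float, float] = (0.0, 0.0, 0.0, 0.0)
    ion_pair: str = ""
    n_ligands: int = 1

    def __post_init__(self) -> None:
        for name in ("dg1", "dg2", "dg3", "dg4"):
            v = getattr(self, name)
            if v is None or not np.isfinite(v):
                raise ValueError(f"missing or non-finite leg {name}")
        if any(s < 0 for s in self.se):
            raise ValueError("leg standard errors must be >= 0")


@dataclass
class CycleReport:
    """Per-cycle closures and their aggregate MAE."""

    closures: list[float]
    ses: list[float]
    within_uncertainty: list[bool]
    labels: list[str]
    mae: float
    sigma_level: float = 1.0
    sign_convention: str = SIGN_CONVENTION

    def table(self) -> str:
        lines = [
            f"# {self.sign_convention}",
            f"{'cycle':<20s}{'closure':>10s}{'SE':>8s}{'within':>8s}",
        ]
        for lbl, c, s, w in zip(self.labels, self.closures, self.ses, self.within_uncertainty):
            lines.append(f"{lbl:<20s}{c:>10.3f}{s:>8.3f}{str(w):>8s}")
        lines.append(f"{'MAE':<20s}{self.mae:>10.3f}")
        return "\n".join(lines)


def cycle_closure(legs: CycleLegs) -> tuple[float, float]:
    """Closure ΔΔG = dg1 + dg2 − dg3 − dg4 and its quadrature-summed SE."""
    ddg = legs.dg1 + legs.dg2 - legs.dg3 - legs.dg4
    se = float(np.sqrt(sum(s * s for s in legs.se)))
    return float(ddg), se


def mae(closures) -> float:
    """Mean absolute closure over a cycle set."""
    closures = np.asarray(closures, dtype=float)
    if closures.size == 0:
        raise ValueError("empty closure list")
    return float(np.mean(np.abs(closures)))


def triplicate_stats(replicates) -> tuple[float, float]:
    """Sample mean and standard error (n−1 denominator) of replicate ΔΔG."""
    replicates = np.asarray(replicates, dtype=float)
    if replicates.size < 2:
        raise ValueError("at least 2 replicates required")
    mean = float(replicates.mean())
    se = float(replicates.std(ddof=1) / np.sqrt(replicates.size))
    return mean, se


def build_report(cycles: list[CycleLegs], sigma_level: float = 1.0) -> CycleReport:
    """Closure, SE and |closure| ≤ σ·SE flag per cycle, plus the set MAE."""
    closures, ses, within, labels = [], [], [], []
    for legs in cycles:
        ddg, se = cycle_closure(legs)
        closures.append(ddg)
        ses.append(se)
        within.append(abs(ddg) <= sigma_level * se)
        labels.append(legs.ion_pair or f"{legs.n_ligands}-ligand")
    return CycleReport(
        closures=closures,
        ses=ses,
        within_uncertainty=within,
        labels=labels,
        mae=mae(closures),
        sigma_level=sigma_level,
    )
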