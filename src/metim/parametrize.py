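"""Free-energy-matched polarizability calibration.

The ligating nitrogen's polarizability α₀ (hence its C4 coefficient) is
adjusted until the simulated metal-imidazole binding free energy lies
within a tolerance (±0.1 kcal/mol by default) of the experimental value.
Assuming an approximately linear α₀ → ΔG relation, each non-accepted
iterate proposes the next α₀ by linear extrapolation through the two most
recent points (the secant method), clamped to α₀ ≥ 0, with a bisection
fallback when the secant slope degenerates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from typing import Callable

from .forcefield import IonSpec, c4_from_polarizability
from .io import packaged_data_path, read_csv_registry

__all__ = [
    "IterationRecord",
    "ExperimentalTarget",
    "NonConvergenceError",
    "optimize_polarizability",
    "load_targets",
    "write_iteration_log",
]

_DEGENERATE_SLOPE = 1e-6  # kcal/mol; |ΔΔG| below this means no usable secant


@dataclass(frozen=True)
class IterationRecord:
    """One step of the calibration loop: the trial α₀, its C4, the simulated
    ΔG with uncertainty, and whether it met the acceptance band."""

    iteration: int
    alpha0: float  # Å³
    c4: float  # kcal/mol·Å⁴
    dg_sim: float  # kcal/mol
    dg_uncertainty: float  # kcal/mol
    accepted: bool


@dataclass(frozen=True)
class ExperimentalTarget:
    """An ion's experimental imidazole binding free energy (kcal/mol)."""

    ion: str
    dg_exp: float
    source: str = ""
    alpha_seed: float | None = None


class NonConvergenceError(RuntimeError):
    """Loop hit max_iter; ``best`` carries the closest record seen."""

    def __init__(self, message: str, records: list[IterationRecord], best: IterationRecord) -> None:
        super().__init__(message)
        self.records = records
        self.best = best


def _evaluate(evaluator, alpha: float) -> tuple[float, float]:
    out = evaluator(alpha)
    if isinstance(out, tuple):
        return float(out[0]), float(out[1])
    return float(out), 0.0


def optimize_polarizability(
    target: ExperimentalTarget,
    evaluator: Callable[[float], float | tuple[float, float]],
    ion: IonSpec,
    alpha_init: float,
    alpha_second: float | None = None,
    tol: float = 0.1,
    max_iter: int = 25,
) -> list[IterationRecord]:
    """Run the secant calibration loop; returns the full audit trail.

    ``evaluator`` maps α₀ to ΔG (or ``(ΔG, SE)``).  A record is accepted when
    |ΔG − target| ≤ ``tol``; otherwise the next α₀ comes from the secant line
    through the two most recent (α₀, ΔG) points, clamped to α₀ ≥ 0.  When the
    two most recent ΔG values are indistinguishable (slope degenerate) the
    loop bisects against a bracketing pair, and errors out if none exists.
    For stochastic evaluators whose SE exceeds ``tol`` a warning is issued:
    the acceptance criterion is then statistically unresolvable.
    """
    import warnings

    if tol <= 0:
        raise ValueError("tol must be positive")
    if alpha_second is None:
        alpha_second = 1.1 * alpha_init if alpha_init > 0 else 0.1
    if alpha_second == alpha_init:
        raise ValueError("alpha_init and alpha_second must differ")

    records: list[IterationRecord] = []
    history: list[tuple[float, float]] = []  # (alpha, dg)

    def record(alpha: float) -> IterationRecord:
        dg, se = _evaluate(evaluator, alpha)
        if se > tol:
            warnings.warn(
                f"evaluator SE {se:.3f} exceeds tolerance {tol}; "
                "acceptance is statistically unresolvable",
                stacklevel=3,
            )
        rec = IterationRecord(
            iteration=len(records),
            alpha0=alpha,
            c4=c4_from_polarizability(alpha, ion),
            dg_sim=dg,
            dg_uncertainty=se,
            accepted=abs(dg - target.dg_exp) <= tol,
        )
        records.append(rec)
        history.append((alpha, dg))
        return rec

    rec = record(alpha_init)
    if rec.accepted:
        return records

    next_alpha = alpha_second
    while len(records) < max_iter:
        rec = record(next_alpha)
        if rec.accepted:
            return records
        (a0, g0), (a1, g1) = history[-2], history[-1]
        if abs(g1 - g0) < _DEGENERATE_SLOPE:
            next_alpha = _bisect_fallback(history, target.dg_exp)
        else:
            # secant: root of the line through the last two iterates
            next_alpha = a1 + (target.dg_exp - g1) * (a1 - a0) / (g1 - g0)
        next_alpha = max(next_alpha, 0.0)
        if any(abs(next_alpha - a) < 1e-12 for a, _ in history):
            next_alpha = _bisect_fallback(history, target.dg_exp)

    best = min(records, key=lambda r: abs(r.dg_sim - target.dg_exp))
    raise NonConvergenceError(
        f"no α₀ within {tol} kcal/mol of {target.dg_exp} after {max_iter} "
        f"evaluations (best |ΔG-target| = {abs(best.dg_sim - target.dg_exp):.3f})",
        records,
        best,
    )


def _bisect_fallback(history: list[tuple[float, float]], target: float) -> float:
    """Midpoint of the tightest bracketing (α, ΔG) pair around the target."""
    below = [(a, g) for a, g in history if g < target]
    above = [(a, g) for a, g in history if g > target]
    if not below or not above:
        raise NonConvergenceError(
            "degenerate secant slope and no bracketing pair around the target",
            [],
            None,  # type: ignore[arg-type]
        )
    a_lo = max(below, key=lambda t: t[1])[0]
    a_hi = min(above, key=lambda t: t[1])[0]
    return 0.5 * (a_lo + a_hi)


def load_targets(registry=None) -> list[ExperimentalTarget]:
    """Load experimental targets; default is the packaged 11-ion registry."""
    path = packaged_data_path("experimental_targets.csv") if registry is None else registry
    try:
        df = read_csv_registry(path)
    except ValueError:
        raise
    if len(df) == 0:
        return []
    required = {"ion", "dg_exp_kcal_mol"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"registry {path} missing columns: {sorted(missing)}")
    targets = []
    for _, row in df.iterrows():
        targets.append(
            ExperimentalTarget(
                ion=str(row["ion"]),
                dg_exp=float(row["dg_exp_kcal_mol"]),
                source=str(row.get("source", "")),
                alpha_seed=float(row["alpha_seed_A3"]) if "alpha_seed_A3" in df.columns else None,
            )
        )
    return targets


def write_iteration_log(records: list[IterationRecord], path) -> None:
    """Persist the audit trail as JSON-lines (one record per line)."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(json.dumps(asdict(rec)) + "\n")
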