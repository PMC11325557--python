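"""C4 coefficients from SAPT induction energies.

The induction component of a SAPT energy decomposition behaves as −C4/r⁴
at long range, so C4 can be read off either at a single (equilibrium)
distance, C4 = −E_ind·r⁴, or by least squares over a distance scan
(typically 1.7–3.0 Å).  Short-range contamination (charge transfer,
overlap effects) makes scan fits sit below single-point values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .io import packaged_data_path, read_csv_registry

__all__ = [
    "InductionScan",
    "C4Estimate",
    "c4_at_equilibrium",
    "c4_fit_scan",
    "average_c4",
    "load_packaged_zn_estimates",
]


@dataclass(frozen=True)
class InductionScan:
    """(r, E_ind) pairs for one complex, r strictly increasing (Å),
    induction energies in kcal/mol (attractive induction ⇒ E_ind ≤ 0)."""

    r: np.ndarray
    e_ind: np.ndarray
    system: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "r", np.asarray(self.r, dtype=float))
        object.__setattr__(self, "e_ind", np.asarray(self.e_ind, dtype=float))
        if self.r.shape != self.e_ind.shape:
            raise ValueError("r and e_ind must have matching shapes")
        if np.any(np.diff(self.r) <= 0):
            raise ValueError("scan distances must be strictly increasing")
        if np.any(self.r <= 0):
            raise ValueError("scan distances must be positive")
        if np.any(self.e_ind > 0):
            warnings.warn(
                f"scan {self.system!r} has positive induction energies; "
                "attractive induction is expected to be <= 0",
                stacklevel=2,
            )


@dataclass(frozen=True)
class C4Estimate:
    """A derived C4 value (kcal/mol·Å⁴) tagged by how it was obtained."""

    value: float
    method: str  # "at_equilibrium" | "scan_fit"
    residual: float | None = None  # RMS of fit, scan_fit only

    def __post_init__(self) -> None:
        if not np.isfinite(self.value):
            raise ValueError("C4 estimate must be finite")
        if self.residual is not None and self.residual < 0:
            raise ValueError("residual must be >= 0")


def c4_at_equilibrium(e_ind: float, r_eq: float) -> C4Estimate:
    """Single-point evaluation C4 = −E_ind·r_eq⁴."""
    if r_eq <= 0:
        raise ValueError(f"equilibrium distance must be positive, got {r_eq}")
    return C4Estimate(value=float(-e_ind * r_eq**4), method="at_equilibrium")


def c4_fit_scan(scan: InductionScan, weight_r4: bool = False) -> C4Estimate:
    """Least-squares fit of E_ind(r) ≈ −C4/r⁴ over the scan.

    Unweighted in E_ind by default, with the closed-form solution
    C4 = −Σ E_i r_i⁻⁴ / Σ r_i⁻⁸; ``weight_r4=True`` weights residuals by
    r⁴ (equivalently fits −E·r⁴ against a constant).  Residual is the RMS
    of the (unweighted) fit.
    """
    if len(scan.r) < 3:
        raise ValueError("scan fit requires at least 3 points")
    x = scan.r**-4
    if weight_r4:
        c4 = float(np.mean(-scan.e_ind * scan.r**4))
    else:
        c4 = float(-(scan.e_ind @ x) / (x @ x))
    resid = float(np.sqrt(np.mean((scan.e_ind + c4 * x) ** 2)))
    return C4Estimate(value=c4, method="scan_fit", residual=resid)


def average_c4(estimates: list[C4Estimate]) -> float:
    """Arithmetic mean of a homogeneous-method estimate set (kcal/mol·Å⁴);
    mixing single-point and scan-fit estimates is disallowed."""
    if not estimates:
        raise ValueError("empty estimate list")
    methods = {e.method for e in estimates}
    if len(methods) > 1:
        raise ValueError(f"cannot average across methods: {sorted(methods)}")
    return float(np.mean([e.value for e in estimates]))


def load_packaged_zn_estimates(path=None) -> dict[str, list[C4Estimate]]:
    """The packaged Zn(imidazole)₆₋ₙ(H₂O)ₙ C4 table as estimate lists keyed
    ``"at_equilibrium"`` / ``"scan_fit"`` (row order preserved)."""
    src = packaged_data_path("sapt_c4_zn.csv") if path is None else path
    df = read_csv_registry(src)
    return {
        "at_equilibrium": [
            C4Estimate(value=float(v), method="at_equilibrium")
            for v in df["c4_equilibrium_kcal_mol_A4"]
        ],
        "scan_fit": [
            C4Estimate(value=float(v), method="scan_fit", residual=0.0)
            for v in df["c4_scan_fit_kcal_mol_A4"]
        ],
    }
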