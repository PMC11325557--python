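"""12-6-4 nonbonded model for metal ions coordinating imidazole-like ligands.

The pairwise potential between an ion *i* and a ligand atom *j* is

    U(r) = A/r^12 - B/r^6 - C4/r^4 + k_e * Q_i * Q_j / r

i.e. the classic 12-6 Lennard-Jones plus Coulomb form augmented with an
attractive r^-4 term describing the ion-induced-dipole interaction.  The
C4 coefficient (kcal/mol·Å⁴) is either tabulated per (ion, atom type) or
derived from the atom type's polarizability α₀ (Å³) via the induced-dipole
closed form

    C4 = (k_e / 2) * Q_i**2 * α₀ * cos²θ,   θ = 0 here,

with k_e the Coulomb constant in kcal·Å/(mol·e²).  Units are fixed
globally: Å, kcal/mol, elementary charges, fs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "COULOMB_CONSTANT",
    "IonSpec",
    "AtomType",
    "LigandTopology",
    "Configuration",
    "c4_from_polarizability",
    "lj_pair_coefficients",
    "pair_energy",
    "pair_force",
    "total_nonbonded",
]

#: Coulomb constant in kcal·Å/(mol·e²), the AMBER convention.
COULOMB_CONSTANT = 332.0637

#: Charge-sum consistency tolerance for ligand topologies, in e.
_CHARGE_TOL = 1e-6


@dataclass(frozen=True)
class IonSpec:
    """Force-field description of a metal ion.

    Parameters
    ----------
    label : str
        Ion name, e.g. ``"Zn2+"``.
    charge : int
        Formal charge in elementary charges; +1 or +2.
    lj_rmin_half : float
        Lennard-Jones Rmin/2 in Å.
    lj_epsilon : float
        Lennard-Jones well depth in kcal/mol; must be positive.
    c4_by_atom_type : dict
        Pair-specific C4 values keyed by atom-type name, kcal/mol·Å⁴.
    """

    label: str
    charge: int
    lj_rmin_half: float
    lj_epsilon: float
    c4_by_atom_type: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.charge not in (1, 2):
            raise ValueError(f"ion charge must be +1 or +2, got {self.charge}")
        if self.lj_epsilon <= 0:
            raise ValueError("lj_epsilon must be positive")
        for name, c4 in self.c4_by_atom_type.items():
            if c4 < 0:
                raise ValueError(f"C4 for atom type {name!r} must be >= 0, got {c4}")

    def c4_for(self, atype: "AtomType") -> float:
        """C4 against ``atype``: the tabulated pair value if present, else
        derived from the atom type's polarizability (0 if α₀ is absent)."""
        if atype.name in self.c4_by_atom_type:
            return self.c4_by_atom_type[atype.name]
        if atype.polarizability is not None and atype.polarizability > 0:
            return c4_from_polarizability(atype.polarizability, self)
        return 0.0


@dataclass(frozen=True)
class AtomType:
    """A ligand atom type with LJ parameters and optional polarizability.

    Names follow the AMBER convention for the HID tautomer of imidazole:
    NA is the protonated δ-nitrogen, NB the metal-ligating ε-nitrogen,
    CC the carbon bridging them.
    """

    name: str
    lj_rmin_half: float
    lj_epsilon: float
    polarizability: float | None = None  # α₀ in Å³

    def __post_init__(self) -> None:
        if self.lj_epsilon <= 0:
            raise ValueError("lj_epsilon must be positive")
        if self.polarizability is not None and self.polarizability < 0:
            raise ValueError("polarizability must be >= 0")


@dataclass(frozen=True)
class LigandTopology:
    """Rigid ligand: atom names, types, partial charges and reference geometry.

    ``atoms`` is a list of ``(name, atom_type_name, charge_e, xyz)`` tuples
    with ``xyz`` the reference coordinates in Å; ``bonds`` holds 0-based
    atom index pairs.  Partial charges must sum to ``formal_charge`` within
    1e-6 e, and every atom type name must resolve in ``atom_types``.
    """

    atoms: tuple[tuple[str, str, float, tuple[float, float, float]], ...]
    bonds: tuple[tuple[int, int], ...]
    atom_types: dict[str, AtomType]
    formal_charge: float = 0.0
    name: str = "LIG"

    def __post_init__(self) -> None:
        total = sum(a[2] for a in self.atoms)
        if abs(total - self.formal_charge) > _CHARGE_TOL:
            raise ValueError(
                f"partial charges sum to {total:.8f} e, expected formal charge "
                f"{self.formal_charge:+.4f} e"
            )
        for name, tname, _, _ in self.atoms:
            if tname not in self.atom_types:
                raise KeyError(f"atom {name!r}: unknown atom type {tname!r}")
        n = len(self.atoms)
        for i, j in self.bonds:
            if not (0 <= i < n and 0 <= j < n):
                raise IndexError(f"bond ({i}, {j}) out of range for {n} atoms")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def reference_coords(self) -> np.ndarray:
        return np.array([a[3] for a in self.atoms], dtype=float)

    def charges(self) -> np.ndarray:
        return np.array([a[2] for a in self.atoms], dtype=float)

    def types(self) -> list[AtomType]:
        return [self.atom_types[a[1]] for a in self.atoms]

    def atom_index(self, atom_name: str) -> int:
        for i, a in enumerate(self.atoms):
            if a[0] == atom_name:
                return i
        raise KeyError(f"no atom named {atom_name!r} in ligand {self.name!r}")


@dataclass
class Configuration:
    """Cartesian snapshot: ion position plus per-ligand atom positions (Å)."""

    ion_position: np.ndarray
    ligand_positions: list[np.ndarray]
    box: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        self.ion_position = np.asarray(self.ion_position, dtype=float).reshape(3)
        self.ligand_positions = [
            np.asarray(p, dtype=float).reshape(-1, 3) for p in self.ligand_positions
        ]


def c4_from_polarizability(alpha0: float, ion: IonSpec) -> float:
    """Map an atom-type polarizability to a C4 coefficient.

    Implements the ion-induced-dipole relation C4 = (k_e/2)·Q_i²·α₀·cos²θ
    with the induced dipole aligned along the ion-ligand axis (θ = 0).

    Parameters
    ----------
    alpha0 : float
        Atom-type polarizability in Å³; must be >= 0.
    ion : IonSpec
        Supplies the ionic charge Q_i.

    Returns
    -------
    float
        C4 in kcal/mol·Å⁴; linear and homogeneous in ``alpha0``.
    """
    if alpha0 < 0:
        raise ValueError(f"polarizability must be >= 0, got {alpha0}")
    return 0.5 * COULOMB_CONSTANT * ion.charge**2 * alpha0


def lj_pair_coefficients(ion: IonSpec, atype: AtomType) -> tuple[float, float]:
    """A and B of A/r^12 - B/r^6 from Lorentz-Berthelot combining.

    Rmin combines arithmetically (Rmin = Rmin/2_ion + Rmin/2_atom) and ε
    geometrically, the AMBER convention; this is the only supported rule.
    """
    rmin = ion.lj_rmin_half + atype.lj_rmin_half
    eps = np.sqrt(ion.lj_epsilon * atype.lj_epsilon)
    a = eps * rmin**12
    b = 2.0 * eps * rmin**6
    return a, b


def pair_energy(r, ion: IonSpec, atype: AtomType, q_j: float):
    """12-6-4 plus Coulomb pair energy U(r) in kcal/mol.

    ``r`` may be a scalar or array of distances in Å (all > 0).  C4 is
    resolved through :meth:`IonSpec.c4_for`.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("pair distance must be positive")
    a, b = lj_pair_coefficients(ion, atype)
    c4 = ion.c4_for(atype)
    inv_r = 1.0 / r
    u = (
        a * inv_r**12
        - b * inv_r**6
        - c4 * inv_r**4
        + COULOMB_CONSTANT * ion.charge * q_j * inv_r
    )
    return u if u.ndim else float(u)


def pair_force(r, ion: IonSpec, atype: AtomType, q_j: float):
    """Radial pair force -dU/dr in kcal/mol/Å (positive = repulsive)."""
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("pair distance must be positive")
    a, b = lj_pair_coefficients(ion, atype)
    c4 = ion.c4_for(atype)
    inv_r = 1.0 / r
    f = (
        12.0 * a * inv_r**13
        - 6.0 * b * inv_r**7
        - 4.0 * c4 * inv_r**5
        + COULOMB_CONSTANT * ion.charge * q_j * inv_r**2
    )
    return f if f.ndim else float(f)


def total_nonbonded(
    config: Configuration,
    ion: IonSpec,
    topologies: LigandTopology | list[LigandTopology],
    cutoff: float = 10.0,
) -> float:
    """Sum of ion-atom 12-6-4 pair energies within ``cutoff`` (Å).

    Ligand-ligand intramolecular terms are excluded (ligands are rigid);
    the cutoff is a hard truncation with no switching.  Overlapping
    positions raise a ``ValueError``.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    topos = topologies if isinstance(topologies, list) else [topologies]
    if len(topos) != len(config.ligand_positions):
        raise ValueError("one coordinate block per ligand topology required")
    total = 0.0
    for topo, pos in zip(topos, config.ligand_positions):
        dr = pos - config.ion_position
        dist = np.linalg.norm(dr, axis=1)
        if np.any(dist == 0):
            raise ValueError("overlapping ion/atom positions (r = 0)")
        for (name, tname, q, _), r in zip(topo.atoms, dist):
            if r <= cutoff:
                total += pair_energy(r, ion, topo.atom_types[tname], q)
    return float(total)
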