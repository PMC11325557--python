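"""Plain-text formats: mol2 (subset), frcmod-style parameter blocks, umbrella
window series, and the CSV registries for targets, cycle legs and SAPT scans.

All numeric files carry units in their headers.  Supported records round-trip
losslessly.
"""

from __future__ import annotations

import io as _stdio
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .forcefield import AtomType, LigandTopology

__all__ = [
    "read_mol2",
    "write_mol2",
    "read_frcmod",
    "write_frcmod",
    "FrcmodData",
    "write_window_series",
    "read_window_series",
    "packaged_data_path",
]

_DATA_DIR = Path(__file__).parent / "data"


def packaged_data_path(name: str) -> Path:
    """Path to a packaged data file (experimental targets, SAPT tables...)."""
    p = _DATA_DIR / name
    if not p.exists():
        raise FileNotFoundError(f"no packaged data file {name!r}")
    return p


# ---------------------------------------------------------------------------
# mol2 (subset: MOLECULE / ATOM / BOND, charges required)
# ---------------------------------------------------------------------------

def read_mol2(path, atom_types: dict[str, AtomType], formal_charge: float | None = None):
    """Parse a TRIPOS mol2 file (MOLECULE/ATOM/BOND subset) into a
    :class:`LigandTopology`.

    The charge column is required.  ``atom_types`` supplies the LJ/polarizability
    table the topology's type names must resolve against.  If ``formal_charge``
    is None it is taken as the charge sum rounded to the nearest integer.
    """
    text = Path(path).read_text()
    section = None
    name = "LIG"
    atoms: list[tuple[str, str, float, tuple[float, float, float]]] = []
    bonds: list[tuple[int, int]] = []
    mol_lines = 0
    for raw in text.splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if line.startswith("@<TRIPOS>"):
            section = line[len("@<TRIPOS>"):].upper()
            mol_lines = 0
            continue
        if section == "MOLECULE":
            mol_lines += 1
            if mol_lines == 1:
                name = line
        elif section == "ATOM":
            parts = line.split()
            if len(parts) < 9:
                raise ValueError(f"mol2 ATOM record lacks a charge column: {raw!r}")
            aname = parts[1]
            x, y, z = (float(v) for v in parts[2:5])
            tname = parts[5]
            q = float(parts[8])
            atoms.append((aname, tname, q, (x, y, z)))
        elif section == "BOND":
            parts = line.split()
            bonds.append((int(parts[1]) - 1, int(parts[2]) - 1))
    if not atoms:
        raise ValueError(f"no @<TRIPOS>ATOM records found in {path}")
    if formal_charge is None:
        formal_charge = float(round(sum(a[2] for a in atoms)))
    return LigandTopology(
        atoms=tuple(atoms),
        bonds=tuple(bonds),
        atom_types=atom_types,
        formal_charge=formal_charge,
        name=name,
    )


def write_mol2(topo: LigandTopology, path) -> None:
    """Write a topology back out as TRIPOS mol2 (MOLECULE/ATOM/BOND)."""
    buf = _stdio.StringIO()
    buf.write("@<TRIPOS>MOLECULE\n")
    buf.write(f"{topo.name}\n")
    buf.write(f"{topo.n_atoms:d} {len(topo.bonds):d} 1 0 0\n")
    buf.write("SMALL\nUSER_CHARGES\n")
    buf.write("@<TRIPOS>ATOM\n")
    for i, (aname, tname, q, (x, y, z)) in enumerate(topo.atoms, start=1):
        buf.write(
            f"{i:7d} {aname:<8s}{x:10.4f}{y:10.4f}{z:10.4f} "
            f"{tname:<6s}{1:4d} {topo.name:<8s}{q:10.6f}\n"
        )
    buf.write("@<TRIPOS>BOND\n")
    for i, (a, b) in enumerate(topo.bonds, start=1):
        buf.write(f"{i:6d}{a + 1:6d}{b + 1:6d} 1\n")
    Path(path).write_text(buf.getvalue())


# ---------------------------------------------------------------------------
# frcmod-style parameter block: NONBON (Rmin/2, epsilon) + C4 block
# ---------------------------------------------------------------------------

@dataclass
class FrcmodData:
    """Supported frcmod records: a title, NONBON LJ lines and a C4 block.

    ``nonbon`` maps atom-type name -> (rmin_half Å, epsilon kcal/mol);
    ``c4`` maps (ion label, atom-type name) -> C4 kcal/mol·Å⁴.
    """

    title: str
    nonbon: dict[str, tuple[float, float]]
    c4: dict[tuple[str, str], float]


def read_frcmod(path) -> FrcmodData:
    """Parse the NONBON and C4 blocks of an frcmod-style file."""
    lines = Path(path).read_text().splitlines()
    title = lines[0].strip() if lines else ""
    section = None
    nonbon: dict[str, tuple[float, float]] = {}
    c4: dict[tuple[str, str], float] = {}
    for raw in lines[1:]:
        stripped = raw.strip()
        if not stripped:
            section = None
            continue
        upper = stripped.upper()
        if upper.startswith(("NONBON", "NONB")):
            section = "NONBON"
            continue
        if upper.startswith("C4"):
            section = "C4"
            continue
        if upper.startswith(("MASS", "BOND", "ANGLE", "DIHE", "IMPROPER")):
            section = "SKIP"
            continue
        if section == "NONBON":
            parts = stripped.split()
            nonbon[parts[0]] = (float(parts[1]), float(parts[2]))
        elif section == "C4":
            parts = stripped.split()
            c4[(parts[0], parts[1])] = float(parts[2])
    return FrcmodData(title=title, nonbon=nonbon, c4=c4)


def write_frcmod(data: FrcmodData, path) -> None:
    buf = _stdio.StringIO()
    buf.write(data.title + "\n")
    buf.write("NONBON\n")
    for name, (rmin_half, eps) in data.nonbon.items():
        buf.write(f"  {name:<4s}{rmin_half:12.6f}{eps:14.8f}\n")
    buf.write("\n")
    buf.write("C4  (ion  atom_type  C4_kcal_mol_A4)\n")
    for (ion, tname), value in data.c4.items():
        buf.write(f"  {ion:<6s}{tname:<6s}{value:14.6f}\n")
    buf.write("\n")
    Path(path).write_text(buf.getvalue())


# ---------------------------------------------------------------------------
# Umbrella window series: two-column text, header names center and k
# ---------------------------------------------------------------------------

def write_window_series(series, path) -> None:
    """Write a :class:`~metim.toysim.DistanceSeries` as two-column text
    (time_fs, distance_angstrom); the header records the restraint."""
    r = series.restraint
    header = (
        f"# umbrella window: center_angstrom={r.center:.6f} "
        f"spring_constant_kcal_mol_A2={r.spring_constant:.6f}\n"
        f"# sampling_interval_fs={series.sampling_interval:.6f}\n"
        f"# time_fs  distance_angstrom\n"
    )
    t = np.arange(len(series.values)) * series.sampling_interval
    body = "\n".join(f"{ti:.3f} {v:.8f}" for ti, v in zip(t, series.values))
    Path(path).write_text(header + body + "\n")


def read_window_series(path):
    """Read a window file written by :func:`write_window_series`."""
    from .toysim import DistanceSeries, UmbrellaRestraint

    center = spring = interval = None
    values = []
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            for token in line[1:].split():
                if token.startswith("center_angstrom="):
                    center = float(token.split("=")[1])
                elif token.startswith("spring_constant_kcal_mol_A2="):
                    spring = float(token.split("=")[1])
                elif token.startswith("sampling_interval_fs="):
                    interval = float(token.split("=")[1])
            continue
        parts = line.split()
        values.append(float(parts[1]))
    if center is None or spring is None:
        raise ValueError(f"window file {path} lacks restraint header")
    restraint = UmbrellaRestraint(center=center, spring_constant=spring)
    return DistanceSeries(
        values=np.asarray(values, dtype=float),
        sampling_interval=interval if interval is not None else 1.0,
        restraint=restraint,
    )


# ---------------------------------------------------------------------------
# CSV registries
# ---------------------------------------------------------------------------

def read_csv_registry(path) -> pd.DataFrame:
    """Read a CSV registry, skipping '#' comment lines; errors carry context."""
    try:
        return pd.read_csv(path, comment="#", skip_blank_lines=True)
    except Exception as exc:  # noqa: BLE001 - reraise with the offending file
        raise ValueError(f"malformed registry {path}: {exc}") from exc
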