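import numpy as np
import pytest

from metim.fixtures import SyntheticPmfSpec, double_well, generate_windows
from metim.forcefield import AtomType, IonSpec, LigandTopology
from metim.io import packaged_data_path, read_frcmod, read_mol2


@pytest.fixture(scope="session")
def zn_ion():
    return IonSpec("Zn2+", 2, lj_rmin_half=1.395, lj_epsilon=0.014917,
                   c4_by_atom_type={"NB": 424.0})


@pytest.fixture(scope="session")
def nb_type():
    return AtomType("NB", lj_rmin_half=1.824, lj_epsilon=0.17, polarizability=0.53)


@pytest.fixture(scope="session")
def single_site_ligand():
    types = {"L": AtomType("L", 1.7, 0.15)}
    return LigandTopology(
        atoms=(("L1", "L", 0.0, (0.0, 0.0, 0.0)),), bonds=(), atom_types=types
    )


@pytest.fixture(scope="session")
def imidazole_topology():
    frc = read_frcmod(packaged_data_path("parameters_synthetic.frcmod"))
    types = {
        name: AtomType(name, rmh, eps, polarizability=0.53 if name == "NB" else None)
        for name, (rmh, eps) in frc.nonbon.items()
    }
    return read_mol2(packaged_data_path("imidazole_hid_synthetic.mol2"), types)


@pytest.fixture(scope="session")
def analytic_double_well():
    return double_well()


@pytest.fixture(scope="session")
def double_well_windows(analytic_double_well):
    """Exact-density umbrella windows over the analytic double well:
    20 windows, k = 20 kcal/mol/Å², 5000 samples each, fixed seed."""
    spec = SyntheticPmfSpec(
        profile=analytic_double_well, n_windows=20, spring_constant=20.0,
        samples_per_window=5000, seed=1,
    )
    return generate_windows(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
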