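"""Pair potential, polarizability→C4 mapping, and total nonbonded energy."""

import numpy as np
import pytest
from scipy.optimize import minimize_scalar

from metim.forcefield import (
    COULOMB_CONSTANT,
    AtomType,
    Configuration,
    IonSpec,
    LigandTopology,
    c4_from_polarizability,
    lj_pair_coefficients,
    pair_energy,
    pair_force,
    total_nonbonded,
)


class TestC4FromPolarizability:
    def test_zero_polarizability_gives_zero(self, zn_ion):
        assert c4_from_polarizability(0.0, zn_ion) == 0.0

    @pytest.mark.parametrize("alpha", [0.1, 0.53, 1.5, 7.0])
    def test_linearity(self, alpha, zn_ion):
        assert c4_from_polarizability(2 * alpha, zn_ion) == pytest.approx(
            2 * c4_from_polarizability(alpha, zn_ion), rel=1e-14
        )

    def test_value_against_independent_transcription(self, zn_ion):
        # hand evaluation of (k_e/2)·Q²·α with θ = 0: 332.0637/2 · 4 · 1.5
        assert c4_from_polarizability(1.5, zn_ion) == pytest.approx(996.1911, abs=1e-10)

    def test_monovalent_scaling(self):
        cu1 = IonSpec("Cu+", 1, 1.2, 0.01)
        zn2 = IonSpec("Zn2+", 2, 1.2, 0.01)
        # C4 ∝ Q², so a divalent ion polarizes four times as strongly
        assert c4_from_polarizability(1.0, zn2) == pytest.approx(
            4 * c4_from_polarizability(1.0, cu1)
        )

    def test_negative_polarizability_rejected(self, zn_ion):
        with pytest.raises(ValueError):
            c4_from_polarizability(-0.1, zn_ion)


class TestPairEnergy:
    def test_pure_lj_minimum_closed_form(self):
        # atom type without polarizability: no C4 fallback, pure 12-6
        nb_type = AtomType("NB", 1.824, 0.17)
        ion = IonSpec("Zn2+", 2, 1.395, 0.014917)  # no C4
        rmin = ion.lj_rmin_half + nb_type.lj_rmin_half
        depth = -np.sqrt(ion.lj_epsilon * nb_type.lj_epsilon)
        assert pair_energy(rmin, ion, nb_type, 0.0) == pytest.approx(depth, rel=1e-12)
        res = minimize_scalar(lambda r: pair_energy(r, ion, nb_type, 0.0),
                              bounds=(1.0, 8.0), method="bounded",
                              options={"xatol": 1e-10})
        assert res.x == pytest.approx(rmin, abs=1e-6)

    def test_decay_at_large_distance(self, zn_ion, nb_type):
        assert abs(pair_energy(1e6, zn_ion, nb_type, 0.0)) < 1e-12

    def test_minimum_location_matches_grid_scan(self, zn_ion, nb_type):
        """Zn²⁺–NB with C4 = 424: analytic force zero agrees with a dense
        1e-4 Å grid scan of the energy."""
        grid = np.arange(1.5, 4.0, 1e-4)
        u = pair_energy(grid, zn_ion, nb_type, 0.0)
        r_grid = grid[np.argmin(u)]
        res = minimize_scalar(lambda r: pair_energy(r, zn_ion, nb_type, 0.0),
                              bounds=(1.5, 4.0), method="bounded",
                              options={"xatol": 1e-12})
        assert abs(res.x - r_grid) <= 1e-4
        assert abs(pair_force(res.x, zn_ion, nb_type, 0.0)) < 1e-6

    def test_c4_deepens_well_and_pulls_minimum_inward(self, nb_type):
        plain_nb = AtomType("NB", 1.824, 0.17)
        grid = np.arange(1.5, 5.0, 1e-4)
        prev_min_r, prev_u = np.inf, None
        for c4 in (0.0, 200.0, 424.0):
            ion = IonSpec("M2+", 2, 1.395, 0.014917, {"NB": c4})
            u = pair_energy(grid, ion, plain_nb, 0.0)
            if prev_u is not None:
                well = (grid > 2.5) & (grid < 4.0)
                assert np.all(u[well] < prev_u[well])
            r_min = grid[np.argmin(u)]
            assert r_min < prev_min_r or prev_min_r == np.inf
            prev_min_r, prev_u = r_min, u
        # the polarizability fallback engages only without a tabulated entry
        base = IonSpec("M2+", 2, 1.395, 0.014917)
        assert base.c4_for(nb_type) == pytest.approx(
            c4_from_polarizability(nb_type.polarizability, base)
        )

    def test_c4_zero_reduces_to_lj_plus_coulomb(self):
        nb_type = AtomType("NB", 1.824, 0.17)
        ion = IonSpec("Zn2+", 2, 1.395, 0.014917)
        q_j = -0.56
        for r in (1.8, 2.5, 3.219, 5.0, 9.9):
            a, b = lj_pair_coefficients(ion, nb_type)
            lj = a / r**12 - b / r**6
            coulomb = COULOMB_CONSTANT * ion.charge * q_j / r
            assert pair_energy(r, ion, nb_type, q_j) == pytest.approx(
                lj + coulomb, rel=1e-14
            )

    def test_nonpositive_distance_rejected(self, zn_ion, nb_type):
        for fn in (pair_energy, pair_force):
            with pytest.raises(ValueError):
                fn(0.0, zn_ion, nb_type, 0.0)
            with pytest.raises(ValueError):
                fn(-1.0, zn_ion, nb_type, 0.0)


class TestPairForce:
    @pytest.mark.parametrize("r", [2.0, 3.0, 5.0])
    def test_matches_finite_difference(self, r, zn_ion, nb_type):
        h = 1e-6
        fd = -(pair_energy(r + h, zn_ion, nb_type, -0.56)
               - pair_energy(r - h, zn_ion, nb_type, -0.56)) / (2 * h)
        f = pair_force(r, zn_ion, nb_type, -0.56)
        assert f == pytest.approx(fd, rel=1e-6)

    def test_zero_at_lj_minimum(self):
        nb_type = AtomType("NB", 1.824, 0.17)
        ion = IonSpec("Zn2+", 2, 1.395, 0.014917)
        rmin = ion.lj_rmin_half + nb_type.lj_rmin_half
        assert pair_force(rmin, ion, nb_type, 0.0) == pytest.approx(0.0, abs=1e-12)


class TestTotalNonbonded:
    def _random_topology(self, rng, n=5):
        types = {"T": AtomType("T", 1.7, 0.1)}
        atoms = tuple(
            (f"A{i}", "T", 0.1 * (-1) ** i, tuple(rng.uniform(2.0, 6.0, 3)))
            for i in range(n)
        )
        charge = sum(a[2] for a in atoms)
        return LigandTopology(atoms=atoms, bonds=(), atom_types=types, formal_charge=charge)

    def test_beyond_cutoff_is_zero(self, zn_ion):
        types = {"T": AtomType("T", 1.7, 0.1)}
        topo = LigandTopology(atoms=(("A", "T", 0.0, (15.0, 0.0, 0.0)),),
                              bonds=(), atom_types=types)
        cfg = Configuration(np.zeros(3), [topo.reference_coords()])
        assert total_nonbonded(cfg, zn_ion, topo, cutoff=10.0) == 0.0

    def test_two_equal_atoms_additivity(self, zn_ion):
        types = {"T": AtomType("T", 1.7, 0.1)}
        one = LigandTopology(atoms=(("A", "T", 0.1, (3.0, 0.0, 0.0)),),
                             bonds=(), atom_types=types, formal_charge=0.1)
        two = LigandTopology(
            atoms=(("A", "T", 0.1, (3.0, 0.0, 0.0)), ("B", "T", 0.1, (0.0, 3.0, 0.0))),
            bonds=(), atom_types=types, formal_charge=0.2,
        )
        c1 = Configuration(np.zeros(3), [one.reference_coords()])
        c2 = Configuration(np.zeros(3), [two.reference_coords()])
        assert total_nonbonded(c2, zn_ion, two, 10.0) == pytest.approx(
            2 * total_nonbonded(c1, zn_ion, one, 10.0), rel=1e-12
        )

    def test_matches_explicit_pairwise_sum(self, zn_ion, rng):
        topo = self._random_topology(rng)
        cfg = Configuration(np.zeros(3), [topo.reference_coords()])
        # independent recomputation from the raw 12-6-4 formula
        expected = 0.0
        for (name, tname, q, xyz) in topo.atoms:
            r = float(np.linalg.norm(xyz))
            atype = topo.atom_types[tname]
            rmin = zn_ion.lj_rmin_half + atype.lj_rmin_half
            eps = np.sqrt(zn_ion.lj_epsilon * atype.lj_epsilon)
            expected += (
                eps * rmin**12 / r**12
                - 2 * eps * rmin**6 / r**6
                + COULOMB_CONSTANT * zn_ion.charge * q / r
            )
        assert total_nonbonded(cfg, zn_ion, topo, 10.0) == pytest.approx(expected, rel=1e-12)

    def test_overlap_rejected(self, zn_ion):
        types = {"T": AtomType("T", 1.7, 0.1)}
        topo = LigandTopology(atoms=(("A", "T", 0.0, (0.0, 0.0, 0.0)),),
                              bonds=(), atom_types=types)
        cfg = Configuration(np.zeros(3), [topo.reference_coords()])
        with pytest.raises(ValueError):
            total_nonbonded(cfg, zn_ion, topo, 10.0)


class TestValidation:
    def test_ion_charge_domain(self):
        with pytest.raises(ValueError):
            IonSpec("X", 3, 1.0, 0.1)
        with pytest.raises(ValueError):
            IonSpec("X", 2, 1.0, -0.1)

    def test_negative_c4_rejected(self):
        with pytest.raises(ValueError):
            IonSpec("X", 2, 1.0, 0.1, {"NB": -5.0})

    def test_ligand_charge_sum_enforced(self):
        types = {"T": AtomType("T", 1.7, 0.1)}
        with pytest.raises(ValueError):
            LigandTopology(atoms=(("A", "T", 0.5, (0, 0, 0)),), bonds=(),
                           atom_types=types, formal_charge=0.0)

    def test_unresolvable_atom_type_rejected(self):
        with pytest.raises(KeyError):
            LigandTopology(atoms=(("A", "ZZ", 0.0, (0, 0, 0)),), bonds=(),
                           atom_types={"T": AtomType("T", 1.7, 0.1)})
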