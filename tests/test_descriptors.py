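import math

import numpy as np
import pytest
from rdkit import Chem
from rdkit.Chem import rdPartialCharges

from barrierkit import constants as C
from barrierkit import descriptors as D
from barrierkit.fixtures import build_ma
from barrierkit.qm_io import Structure
from oracles import buried_volume_mc, estate_oracle, sterimol_scan


def structure(symbols, coords, **kw):
    return Structure(symbols=tuple(symbols), coords=tuple(tuple(c) for c in coords), **kw)


def rdkit_graph(smiles):
    """(symbols, bond pairs, bond orders, mol) for a hydrogen-explicit mol."""
    mol = Chem.AddHs(Chem.MolFromSmiles(smiles))
    symbols = tuple(a.GetSymbol() for a in mol.GetAtoms())
    pairs = tuple((b.GetBeginAtomIdx(), b.GetEndAtomIdx()) for b in mol.GetBonds())
    orders = tuple(b.GetBondTypeAsDouble() for b in mol.GetBonds())
    return symbols, pairs, orders, mol


def graph_structure(symbols):
    # coordinates are irrelevant for graph-derived descriptors
    coords = [(float(i), 0.1 * i, 0.0) for i in range(len(symbols))]
    return structure(symbols, coords)


class TestPerceiveBonds:
    def test_cc_single_bond_distance(self):
        s = structure(["C", "C"], [(0, 0, 0), (1.54, 0, 0)])
        assert D.perceive_bonds(s, tolerance=1.2).pairs == ((0, 1),)

    def test_cc_far_apart(self):
        s = structure(["C", "C"], [(0, 0, 0), (3.0, 0, 0)])
        assert D.perceive_bonds(s).pairs == ()

    def test_fixture_ground_truth_graph(self):
        # all-H substituents give acrolein-like C3H4O: 7 bonds
        ma, info = build_ma(("H", "H", "H", "H"))
        bonds = D.perceive_bonds(ma)
        expected = {(0, 1), (1, 2), (2, 3), (0, 4), (0, 5), (1, 6), (2, 7)}
        assert {tuple(sorted(p)) for p in bonds.pairs} == expected

    def test_no_self_bonds_and_symmetric(self):
        ma, _ = build_ma(("Me", "F", "H", "Cl"))
        for i, j in D.perceive_bonds(ma).pairs:
            assert i != j


class TestPEOE:
    def test_homonuclear_diatomic_zero(self):
        s = structure(["C", "C"], [(0, 0, 0), (1.54, 0, 0)])
        q = D.peoe_charges(s)
        np.testing.assert_allclose(q, 0.0, atol=1e-14)

    def test_charge_conservation(self):
        ma, _ = build_ma(("Me", "F", "H", "Cl"))
        q = D.peoe_charges(ma)
        assert q.sum() == pytest.approx(0.0, abs=1e-6)

    @pytest.mark.parametrize("smiles", ["C=O", "CC=O", "CO", "CC(C)=O"])
    def test_matches_reference_implementation(self, smiles):
        symbols, pairs, orders, mol = rdkit_graph(smiles)
        rdPartialCharges.ComputeGasteigerCharges(mol, nIter=12)
        reference = np.array(
            [a.GetDoubleProp("_GasteigerCharge") for a in mol.GetAtoms()]
        )
        s = graph_structure(symbols)
        bonds = D.Connectivity(n_atoms=len(symbols), pairs=pairs, orders=orders)
        mine = D.peoe_charges(s, bonds, n_iterations=12)
        np.testing.assert_allclose(mine, reference, atol=1e-3)

    def test_carbonyl_polarity(self):
        symbols, pairs, orders, _ = rdkit_graph("C=O")
        s = graph_structure(symbols)
        bonds = D.Connectivity(n_atoms=len(symbols), pairs=pairs, orders=orders)
        q = D.peoe_charges(s, bonds)
        assert q[1] < 0 < q[0]  # O negative, C positive

    def test_unparameterised_element_error(self):
        s = structure(["K"], [(0, 0, 0)])
        with pytest.raises(ValueError, match="K"):
            D.peoe_charges(s, D.Connectivity(n_atoms=1, pairs=()))

    def test_graph_invariance_under_coordinates(self):
        symbols, pairs, orders, _ = rdkit_graph("CC=O")
        bonds = D.Connectivity(n_atoms=len(symbols), pairs=pairs, orders=orders)
        q1 = D.peoe_charges(graph_structure(symbols), bonds)
        other = structure(symbols, [(0.5 * i, -i, 2.0) for i in range(len(symbols))])
        q2 = D.peoe_charges(other, bonds)
        np.testing.assert_array_equal(q1, q2)


class TestEState:
    def test_ethane_symmetry(self):
        symbols, pairs, orders, _ = rdkit_graph("CC")
        s = graph_structure(symbols)
        bonds = D.Connectivity(n_atoms=len(symbols), pairs=pairs, orders=orders)
        idx = D.estate_indices(s, bonds)
        assert idx[0] == pytest.approx(idx[1], abs=1e-12)

    def test_perturbation_sum_is_zero(self):
        # sum over atoms of the pairwise (I_i - I_j)/d^2 terms cancels, so
        # the EState total equals the intrinsic-state total
        symbols, pairs, orders, _ = rdkit_graph("CCC=O")
        s = graph_structure(symbols)
        bonds = D.Connectivity(n_atoms=len(symbols), pairs=pairs, orders=orders)
        values = D.estate_indices(s, bonds)
        heavy = [i for i, sym in enumerate(symbols) if sym != "H"]
        h_counts = []
        heavy_bonds = []
        pos = {a: k for k, a in enumerate(heavy)}
        for k, a in enumerate(heavy):
            h_counts.append(
                sum(1 for i, j in pairs if (i == a and symbols[j] == "H") or (j == a and symbols[i] == "H"))
            )
        for i, j in pairs:
            if symbols[i] != "H" and symbols[j] != "H":
                heavy_bonds.append((pos[i], pos[j]))
        oracle = estate_oracle(
            [symbols[a] for a in heavy], heavy_bonds, h_counts,
            C.PRINCIPAL_QUANTUM_NUMBER, C.VALENCE_ELECTRONS, C.ATOMIC_NUMBER,
        )
        assert sum(values.values()) == pytest.approx(sum(oracle), abs=1e-10)

    def test_propanal_matches_independent_oracle(self):
        symbols, pairs, orders, _ = rdkit_graph("CCC=O")
        s = graph_structure(symbols)
        bonds = D.Connectivity(n_atoms=len(symbols), pairs=pairs, orders=orders)
        values = D.estate_indices(s, bonds)
        heavy = [i for i, sym in enumerate(symbols) if sym != "H"]
        pos = {a: k for k, a in enumerate(heavy)}
        h_counts = [
            sum(1 for i, j in pairs if (i == a and symbols[j] == "H") or (j == a and symbols[i] == "H"))
            for a in heavy
        ]
        heavy_bonds = [
            (pos[i], pos[j]) for i, j in pairs if symbols[i] != "H" and symbols[j] != "H"
        ]
        oracle = estate_oracle(
            [symbols[a] for a in heavy], heavy_bonds, h_counts,
            C.PRINCIPAL_QUANTUM_NUMBER, C.VALENCE_ELECTRONS, C.ATOMIC_NUMBER,
        )
        for k, a in enumerate(heavy):
            assert values[a] == pytest.approx(oracle[k], abs=1e-10)

    def test_isolated_heavy_atom_fallback(self, caplog):
        import logging

        s = structure(["C"], [(0.0, 0.0, 0.0)])
        with caplog.at_level(logging.INFO, logger="barrierkit.descriptors"):
            values = D.estate_indices(s, D.Connectivity(n_atoms=1, pairs=()))
        # free-atom intrinsic state: ((2/2)^2 * 4 + 1) / 1
        assert values[0] == pytest.approx(5.0)
        assert any("isolated heavy atom" in r.message for r in caplog.records)

    def test_matches_rdkit(self):
        from rdkit.Chem.EState import EStateIndices

        symbols, pairs, orders, mol = rdkit_graph("CCC=O")
        heavy_mol = Chem.RemoveHs(mol)
        reference = EStateIndices(heavy_mol)
        s = graph_structure(symbols)
        bonds = D.Connectivity(n_atoms=len(symbols), pairs=pairs, orders=orders)
        values = D.estate_indices(s, bonds)
        heavy = [i for i, sym in enumerate(symbols) if sym != "H"]
        mine = [values[a] for a in heavy]
        np.testing.assert_allclose(mine, reference, atol=1e-6)


class TestSterimol:
    def test_single_atom_substituent(self):
        s = structure(["C", "H"], [(0, 0, 0), (1.09, 0, 0)])
        l_val, b1, b5 = D.sterimol(s, 0, 1)
        r = C.VDW_RADII["H"]
        assert l_val == pytest.approx(1.09 + r, abs=1e-10)
        assert b1 == pytest.approx(r, abs=1e-6)
        assert b5 == pytest.approx(r, abs=1e-10)

    def test_b1_le_b5_random_fixtures(self, rng):
        for _ in range(200):
            n = int(rng.integers(2, 7))
            coords = np.vstack([[0.0, 0.0, 0.0], rng.normal(0, 1.5, (n, 3))])
            coords[1] += [1.5, 0, 0]  # keep axis well-defined
            symbols = ["C"] + list(rng.choice(["C", "H", "O", "N"], n))
            pairs = tuple((i, i + 1) for i in range(n))  # chain through substituent
            s = structure(symbols, coords)
            bonds = D.Connectivity(n_atoms=n + 1, pairs=tuple((0, 1),) if n == 1 else ((0, 1),) + tuple((i, i + 1) for i in range(1, n)))
            _, b1, b5 = D.sterimol(s, 0, 1, bonds=bonds)
            assert b1 <= b5 + 1e-9

    def test_tert_butyl_matches_scan_oracle(self):
        # tert-butyl-like substituent: central C with three offset methyls
        coords = [
            (0.0, 0.0, 0.0),      # attach (H-like anchor)
            (1.53, 0.0, 0.0),     # quaternary C
            (2.2, 1.3, 0.4),
            (2.2, -1.1, 0.8),
            (2.2, -0.2, -1.35),
        ]
        symbols = ["C", "C", "C", "C", "C"]
        s = structure(symbols, coords)
        bonds = D.Connectivity(n_atoms=5, pairs=((0, 1), (1, 2), (1, 3), (1, 4)))
        l_val, b1, b5 = D.sterimol(s, 0, 1, bonds=bonds)
        radii = np.array([C.VDW_RADII[x] for x in symbols])
        ol, ob1, ob5 = sterimol_scan(np.array(coords), radii, 0, [1, 2, 3, 4])
        assert l_val == pytest.approx(ol, abs=1e-9)
        assert b5 == pytest.approx(ob5, abs=1e-9)
        assert b1 == pytest.approx(ob1, abs=0.01)

    def test_empty_substituent_error(self):
        s = structure(["C", "C"], [(0, 0, 0), (0, 0, 0)])
        with pytest.raises(ValueError):
            D.sterimol(s, 0, 1, bonds=D.Connectivity(n_atoms=2, pairs=((0, 1),)))


class TestBuriedVolume:
    def test_isolated_atom_analytic(self):
        s = structure(["C"], [(0, 0, 0)])
        r = C.VDW_RADII["C"]
        R = 3.5
        expected = 100.0 * (r / R) ** 3
        got = D.percent_buried_volume(s, 0, sphere_radius=R, radii_scale=1.0)
        assert got == pytest.approx(expected, abs=0.5)

    def test_remote_atom_no_effect(self):
        s1 = structure(["C"], [(0, 0, 0)])
        s2 = structure(["C", "C"], [(0, 0, 0), (10.0, 0, 0)])
        a = D.percent_buried_volume(s1, 0)
        b = D.percent_buried_volume(s2, 0)
        assert a == b

    def test_crowded_matches_monte_carlo(self):
        ma, _ = build_ma(("Me", "Me", "H", "Me"))
        got = D.percent_buried_volume(ma, 0, sphere_radius=3.5, radii_scale=1.17)
        radii = np.array([C.VDW_RADII[x] for x in ma.symbols]) * 1.17
        oracle = buried_volume_mc(
            ma.positions(), radii, ma.positions()[0], 3.5, n_points=2_000_000, seed=3
        )
        assert got == pytest.approx(oracle, abs=0.5)

    def test_bounds(self, small_reactions):
        ts = small_reactions[0].record.get("DFT", "TS").structure
        v = D.percent_buried_volume(ts, 0)
        assert 0.0 <= v <= 100.0

    def test_nonpositive_radius_error(self):
        s = structure(["C"], [(0, 0, 0)])
        with pytest.raises(ValueError):
            D.percent_buried_volume(s, 0, sphere_radius=0.0)


class TestSASA:
    def test_isolated_atom_sphere_area(self):
        s = structure(["C"], [(0, 0, 0)])
        areas, total = D.sasa(s, probe=1.4, n_points=960)
        expected = 4.0 * math.pi * (C.VDW_RADII["C"] + 1.4) ** 2
        assert total == pytest.approx(expected, rel=0.01)

    def test_disjoint_additivity(self):
        s1 = structure(["C"], [(0, 0, 0)])
        s2 = structure(["O"], [(0, 0, 0)])
        both = structure(["C", "O"], [(0, 0, 0), (50.0, 0, 0)])
        _, t1 = D.sasa(s1)
        _, t2 = D.sasa(s2)
        _, t = D.sasa(both)
        assert t == pytest.approx(t1 + t2, abs=1e-9)

    def test_enclosed_atom_zero(self):
        shell = D.golden_spiral_points(32)
        coords = [(0.0, 0.0, 0.0)] + [tuple(p) for p in shell * 1.0]
        s = structure(["C"] + ["O"] * 32, coords)
        areas, _ = D.sasa(s)
        assert areas[0] == 0.0

    def test_per_atom_sums_to_total(self, small_reactions):
        ma = small_reactions[0].record.get("DFT", "MA").structure
        areas, total = D.sasa(ma)
        assert total == pytest.approx(areas.sum(), abs=1e-9)
        assert (areas >= 0).all()

    def test_too_few_points_error(self):
        s = structure(["C"], [(0, 0, 0)])
        with pytest.raises(ValueError):
            D.sasa(s, n_points=5)


class TestRigidMotionInvariance:
    @staticmethod
    def _random_rigid(coords, rng):
        from scipy.spatial.transform import Rotation

        rot = Rotation.random(random_state=int(rng.integers(1 << 31))).as_matrix()
        shift = rng.normal(0, 5, 3)
        return np.asarray(coords) @ rot.T + shift

    def test_geometric_descriptors_invariant(self, rng):
        ma, info = build_ma(("Me", "F", "H", "Me"))
        bonds = D.perceive_bonds(ma)
        attach, sub = 1, info["rgroup_attachments"][2]
        base = (
            D.sterimol(ma, 0, 4, bonds=bonds),
            D.percent_buried_volume(ma, 0),
            D.sasa(ma)[1],
        )
        for _ in range(3):
            moved = structure(ma.symbols, self._random_rigid(ma.positions(), rng))
            got = (
                D.sterimol(moved, 0, 4, bonds=bonds),
                D.percent_buried_volume(moved, 0),
                D.sasa(moved)[1],
            )
            np.testing.assert_allclose(got[0], base[0], atol=1e-6)
            # grid integration is grid-aligned: small translational jitter only
            assert got[1] == pytest.approx(base[1], abs=0.3)
            assert got[2] == pytest.approx(base[2], rel=1e-2)


class TestDescriptorSet:
    def test_compute_block(self, small_reactions):
        gen = small_reactions[0]
        rec = gen.record.get("DFT", "MA")
        ka = gen.record.key_atoms
        dset = D.compute_descriptor_set(
            rec.structure,
            key_atom_map={"beta_carbon": ka.beta_carbon, "carbonyl_oxygen": ka.carbonyl_oxygen},
            mulliken=rec.mulliken,
            level="DFT",
        )
        v = dset.values
        assert "peoe_beta_carbon" in v and "sasa_total" in v
        assert "mulliken_carbonyl_oxygen" in v
        assert all(np.isfinite(x) for x in v.values())

    def test_dispersion_hook_passthrough(self, small_reactions):
        gen = small_reactions[0]
        rec = gen.record.get("DFT", "MA")
        dset = D.compute_descriptor_set(
            rec.structure,
            key_atom_map={"beta_carbon": 0},
            dispersion={0: 3.14},
        )
        assert dset.values["dispersion_experimental_beta_carbon"] == 3.14
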