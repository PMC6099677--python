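"""Structure I/O, property assignment, activity conversion, alignment, splits."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from rdkit import Chem
from rdkit.Chem import AllChem

from qsar3d.structures import (
    ActivityRecord,
    AlignedDataset,
    Atom,
    Molecule,
    assign_atom_properties,
    ec50_to_pec50,
    kabsch_align,
    read_structures,
    split_train_test,
)
from qsar3d.synthetic import GeneratorSpec, generate_dataset, write_structures


def _rdkit_3d(smiles: str) -> Molecule:
    rdmol = Chem.AddHs(Chem.MolFromSmiles(smiles))
    AllChem.EmbedMolecule(rdmol, randomSeed=7)
    conf = rdmol.GetConformer()
    atoms = [
        Atom(a.GetSymbol(), np.array(conf.GetAtomPosition(i)), vdw_radius=1.5)
        for i, a in enumerate(rdmol.GetAtoms())
    ]
    return Molecule(id=smiles, atoms=atoms, rdkit_mol=rdmol)


class TestEc50Conversion:
    @pytest.mark.parametrize(
        "ec50_um, expected",
        [(0.062, 7.208), (130.0, 3.886), (1.0, 6.000)],
    )
    def test_reference_values(self, ec50_um, expected):
        assert ec50_to_pec50(ec50_um) == pytest.approx(expected, abs=5e-4)

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            ec50_to_pec50(0.0)
        with pytest.raises(ValueError):
            ec50_to_pec50(-1.0)

    @given(st.floats(min_value=1e-6, max_value=1e6))
    @settings(max_examples=50, deadline=None)
    def test_decade_shift_and_monotonicity(self, ec50):
        assert ec50_to_pec50(10 * ec50) == pytest.approx(ec50_to_pec50(ec50) - 1.0, abs=1e-9)
        assert ec50_to_pec50(2 * ec50) < ec50_to_pec50(ec50)

    def test_all_table6_rows_reproduce(self, tables):
        t6 = tables["table6"]
        computed = ec50_to_pec50(t6["ec50_uM"].to_numpy())
        assert np.allclose(np.round(computed, 3), t6["pec50"].to_numpy(), atol=1e-9)

    def test_activity_record_consistency_guard(self):
        with pytest.raises(ValueError):
            ActivityRecord(molecule_id="x", pec50=5.0, ec50=1.0)  # implies 6.0


class TestStructureIO:
    def test_sdf_round_trip_from_generator(self, tmp_path, synthetic_study):
        dataset, _ = synthetic_study
        path = tmp_path / "mols.sdf"
        write_structures(dataset.molecules, path, fmt="sdf")
        back = read_structures(path)
        assert len(back) == len(dataset.molecules)
        assert [m.id for m in back] == dataset.ids
        for orig, rt in zip(dataset.molecules, back):
            assert np.allclose(rt.coords, orig.coords, atol=1e-4)
            for a, b in zip(orig.atoms, rt.atoms):
                assert b.partial_charge == pytest.approx(a.partial_charge, abs=1e-6)
                assert b.vdw_radius == pytest.approx(a.vdw_radius, abs=1e-4)
                assert (b.is_donor, b.is_acceptor) == (a.is_donor, a.is_acceptor)

    def test_mol2_round_trip_keeps_charges(self, tmp_path, synthetic_study):
        dataset, _ = synthetic_study
        path = tmp_path / "mols.mol2"
        write_structures(dataset.molecules[:5], path, fmt="mol2")
        back = read_structures(path)
        assert len(back) == 5
        for orig, rt in zip(dataset.molecules[:5], back):
            assert np.allclose(rt.coords, orig.coords, atol=1e-4)
            assert np.allclose(
                [a.partial_charge for a in rt.atoms],
                [a.partial_charge for a in orig.atoms],
                atol=1e-4,
            )

    def test_methane_sdf(self, tmp_path):
        rdmol = Chem.AddHs(Chem.MolFromSmiles("C"))
        AllChem.EmbedMolecule(rdmol, randomSeed=1)
        path = tmp_path / "methane.sdf"
        w = Chem.SDWriter(str(path))
        w.write(rdmol)
        w.close()
        mols = read_structures(path)
        assert len(mols) == 1
        assert len(mols[0].atoms) == 5

    def test_empty_file_errors(self, tmp_path):
        path = tmp_path / "empty.sdf"
        path.write_text("")
        with pytest.raises(ValueError):
            read_structures(path)

    def test_external_parser_reads_our_sdf(self, tmp_path, synthetic_study):
        """Cross-parser check: openbabel accepts the generated SDF."""
        import shutil
        import subprocess

        if shutil.which("obabel") is None:
            pytest.skip("openbabel CLI not on PATH")
        dataset, _ = synthetic_study
        path = tmp_path / "mols.sdf"
        write_structures(dataset.molecules[:3], path, fmt="sdf")
        out = subprocess.run(
            ["obabel", str(path), "-osmi"], capture_output=True, text=True, timeout=120
        )
        assert out.returncode == 0
        assert len([l for l in out.stdout.splitlines() if l.strip()]) == 3


class TestPropertyAssignment:
    def test_water_flags(self):
        mol = assign_atom_properties(_rdkit_3d("O"))
        o = next(a for a in mol.atoms if a.element == "O")
        hs = [a for a in mol.atoms if a.element == "H"]
        assert o.is_donor and o.is_acceptor
        assert all(h.is_donor for h in hs)

    def test_benzene_carbons_have_no_hbond_flags(self):
        mol = assign_atom_properties(_rdkit_3d("c1ccccc1"))
        for a in mol.atoms:
            if a.element == "C":
                assert not a.is_donor and not a.is_acceptor

    def test_ethanol_gasteiger_charges_conserve_total_charge(self):
        mol = assign_atom_properties(_rdkit_3d("CCO"))
        assert sum(a.partial_charge for a in mol.atoms) == pytest.approx(0.0, abs=0.01)
        # hydrophobicity populated from atomic logP contributions
        assert any(a.hydrophobicity != 0 for a in mol.atoms)
        assert all(a.vdw_radius > 0 for a in mol.atoms)

    def test_requires_connection_table(self):
        bare = Molecule(id="m", atoms=[Atom("C", np.zeros(3))])
        with pytest.raises(ValueError):
            assign_atom_properties(bare)


class TestKabschAlign:
    def _triangle(self):
        pts = np.array([[0.0, 0, 0], [1.5, 0, 0], [0, 2.0, 0], [1.0, 1.0, 1.0]])
        atoms = [Atom("C", p, vdw_radius=1.7) for p in pts]
        return Molecule(id="ref", atoms=atoms)

    def test_identity_alignment_is_exact(self):
        ref = self._triangle()
        aligned, rmsd = kabsch_align(ref, ref, [(i, i) for i in range(4)])
        assert rmsd <= 1e-6
        assert np.allclose(aligned.coords, ref.coords, atol=1e-9)

    def test_recovers_known_rotation_translation(self):
        ref = self._triangle()
        theta = np.pi / 2
        R = np.array(
            [[np.cos(theta), -np.sin(theta), 0], [np.sin(theta), np.cos(theta), 0], [0, 0, 1]]
        )
        moved = Molecule(
            id="mob",
            atoms=[Atom("C", R @ a.position + np.array([3.0, -1.0, 2.0])) for a in ref.atoms],
        )
        aligned, rmsd = kabsch_align(moved, ref, [(i, i) for i in range(4)])
        assert rmsd == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(aligned.coords, ref.coords, atol=1e-8)

    def test_matches_brute_force_rotation_search(self):
        """Perturb one atom; optimal RMSD must match a grid search over rotations."""
        ref = self._triangle()
        pts = ref.coords.copy()
        pts[1, 0] += 0.1
        mob = Molecule(id="mob", atoms=[Atom("C", p) for p in pts])
        _, rmsd = kabsch_align(mob, ref, [(i, i) for i in range(4)])

        # oracle: exhaustive search over Euler angles after centroid match
        P = pts - pts.mean(axis=0)
        Q = ref.coords - ref.coords.mean(axis=0)
        best = np.inf
        angles = np.linspace(-0.2, 0.2, 41)  # perturbation is small, optimum near identity
        for a in angles:
            for b in angles:
                for c in angles:
                    ca, sa, cb, sb, cc, sc = np.cos(a), np.sin(a), np.cos(b), np.sin(b), np.cos(c), np.sin(c)
                    Rz = np.array([[ca, -sa, 0], [sa, ca, 0], [0, 0, 1]])
                    Ry = np.array([[cb, 0, sb], [0, 1, 0], [-sb, 0, cb]])
                    Rx = np.array([[1, 0, 0], [0, cc, -sc], [0, sc, cc]])
                    R = Rz @ Ry @ Rx
                    best = min(best, np.sqrt(np.mean(np.sum((P @ R.T - Q) ** 2, axis=1))))
        assert rmsd == pytest.approx(best, abs=5e-3)
        assert rmsd <= best + 1e-12  # closed form never worse than the search

    def test_rejects_degenerate_maps(self):
        ref = self._triangle()
        with pytest.raises(ValueError):
            kabsch_align(ref, ref, [(0, 0), (1, 1)])
        line = Molecule(id="l", atoms=[Atom("C", np.array([float(i), 0, 0])) for i in range(4)])
        with pytest.raises(ValueError):
            kabsch_align(line, line, [(i, i) for i in range(3)])


class TestSplit:
    def test_counts_match_fraction(self):
        data = [(str(i), 5.0 + 0.3 * i) for i in range(10)]
        roles = split_train_test(data, 0.7, seed=3)
        assert sum(r == "train" for r in roles.values()) == 7
        assert sum(r == "test" for r in roles.values()) == 3

    def test_same_seed_reproduces(self):
        data = [(str(i), 4.0 + 0.1 * i) for i in range(20)]
        assert split_train_test(data, 0.7, seed=11) == split_train_test(data, 0.7, seed=11)

    def test_manual_split_reproduces_study_assignment(self, table3):
        test_ids = table3.loc[table3.is_test == 1, "id"].astype(str).tolist()
        data = list(zip(table3["id"].astype(str), table3["experimental_pec50"]))
        roles = split_train_test(data, 29 / 41, strategy="manual", manual_test_ids=test_ids)
        assert sum(r == "test" for r in roles.values()) == 12
        assert sum(r == "train" for r in roles.values()) == 29
        assert all(roles[i] == "test" for i in test_ids)

    def test_manual_unknown_id_errors(self):
        data = [(str(i), 5.0) for i in range(6)]
        with pytest.raises(ValueError):
            split_train_test(data, 0.7, strategy="manual", manual_test_ids=["nope"])

    def test_stratified_draws_from_both_activity_bins(self):
        low = [(f"lo{i}", 4.5 + 0.05 * i) for i in range(10)]
        high = [(f"hi{i}", 6.5 + 0.05 * i) for i in range(30)]
        roles = split_train_test(low + high, 0.7, seed=5)
        test_ids = [i for i, r in roles.items() if r == "test"]
        assert any(i.startswith("lo") for i in test_ids)
        assert any(i.startswith("hi") for i in test_ids)


def test_dataset_requires_complete_bookkeeping():
    atoms = [Atom("C", np.zeros(3))]
    mols = [Molecule(id="a", atoms=atoms), Molecule(id="b", atoms=atoms)]
    acts = {"a": ActivityRecord("a", 5.0), "b": ActivityRecord("b", 6.0)}
    with pytest.raises(ValueError):
        AlignedDataset(molecules=mols, activities=acts, roles={"a": "train"})
    with pytest.raises(ValueError):
        AlignedDataset(molecules=mols, activities={"a": acts["a"]}, roles={"a": "train", "b": "test"})
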