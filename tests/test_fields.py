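"""Grid construction and CoMFA/CoMSIA field kernels against closed-form oracles."""

import numpy as np
import pytest

from qsar3d.fields import (
    COULOMB_CONSTANT,
    LJ_EPSILON,
    PROBE_EPSILON,
    FieldBlock,
    GridSpec,
    assemble_descriptors,
    build_grid,
    comfa_fields,
    comfa_probe,
    comsia_fields,
    comsia_probe,
)
from qsar3d.structures import Atom, Molecule


def _atom_mol(mid="m", element="C", pos=(0, 0, 0), charge=0.0, radius=1.70,
              hydro=0.0, donor=False, acceptor=False):
    return Molecule(
        id=mid,
        atoms=[Atom(element, np.array(pos, dtype=float), partial_charge=charge,
                    vdw_radius=radius, hydrophobicity=hydro,
                    is_donor=donor, is_acceptor=acceptor)],
    )


def _grid_single_point(pos):
    """Degenerate 2-point-per-axis grid whose first point is ``pos``."""
    return GridSpec(origin=tuple(pos), spacing=50.0, dims=(2, 2, 2))


class TestBuildGrid:
    def test_single_atom_padding(self):
        g = build_grid([_atom_mol()], spacing=2.0, padding=4.0)
        pts = g.points()
        assert pts[:, 0].min() <= -4 and pts[:, 0].max() >= 4
        assert all(d >= 5 for d in g.dims)

    def test_minimum_dims_enforced(self):
        g = build_grid([_atom_mol()], spacing=2.0, padding=0.0)
        assert all(d >= 2 for d in g.dims)

    def test_empty_list_errors(self):
        with pytest.raises(ValueError):
            build_grid([], spacing=2.0)

    def test_doubling_spacing_halves_points_per_axis(self):
        mols = [_atom_mol(pos=(0, 0, 0)), _atom_mol("m2", pos=(11.0, 7.0, 5.0))]
        g1 = build_grid(mols, spacing=1.0, padding=3.0)
        g2 = build_grid(mols, spacing=2.0, padding=3.0)
        for n1, n2 in zip(g1.dims, g2.dims):
            assert abs(n2 - ((n1 - 1) // 2 + 1)) <= 1

    def test_lattice_translation_gives_identical_descriptors(self):
        """Shifting all molecules rigidly leaves every field value bit-identical."""
        mols = [
            _atom_mol("a", charge=0.3, hydro=0.5),
            _atom_mol("b", pos=(2.0, 1.0, 0.0), charge=-0.2, radius=1.55, donor=True),
        ]
        shift = np.array([4.0, -2.0, 6.0])  # multiple of the spacing
        moved = [m.translated(shift) for m in mols]
        g1 = build_grid(mols, spacing=2.0, padding=4.0)
        g2 = build_grid(moved, spacing=2.0, padding=4.0)
        assert g1.dims == g2.dims
        for b1, b2 in zip(comfa_fields(mols, g1), comfa_fields(moved, g2)):
            assert np.array_equal(b1.values, b2.values)
        for b1, b2 in zip(comsia_fields(mols, g1), comsia_fields(moved, g2)):
            assert np.array_equal(b1.values, b2.values)


class TestComfaKernels:
    @pytest.mark.parametrize("r", [3.0, 3.22, 4.0, 5.5, 8.0])
    def test_steric_matches_lennard_jones_closed_form(self, r):
        mol = _atom_mol(charge=0.0)
        grid = _grid_single_point((r, 0, 0))
        steric, _ = comfa_fields([mol], grid)
        eps = np.sqrt(LJ_EPSILON["C"] * PROBE_EPSILON)
        rm = 1.70 + 1.52
        expected = eps * ((rm / r) ** 12 - 2 * (rm / r) ** 6)
        assert steric.values[0, 0] == pytest.approx(np.clip(expected, -30, 30), abs=1e-10)

    @pytest.mark.parametrize("r", [2.0, 3.0, 4.5, 6.0, 10.0])
    def test_electrostatic_matches_coulomb_closed_form(self, r):
        mol = _atom_mol(charge=0.25)
        grid = _grid_single_point((0, r, 0))
        _, electro = comfa_fields([mol], grid)
        expected = COULOMB_CONSTANT * 0.25 * 1.0 / (r * r)  # dielectric eps(r) = r
        assert electro.values[0, 0] == pytest.approx(np.clip(expected, -30, 30), abs=1e-10)

    def test_far_point_steric_negligible(self):
        mol = _atom_mol()
        grid = _grid_single_point((12.0, 0, 0))
        steric, _ = comfa_fields([mol], grid)
        assert abs(steric.values[0, 0]) < 0.01

    def test_steric_clips_at_cutoff_at_atom_center(self):
        mol = _atom_mol()
        grid = _grid_single_point((0.0, 0.0, 0.0))
        steric, _ = comfa_fields([mol], grid)
        assert steric.values[0, 0] == 30.0

    def test_electrostatic_masked_inside_steric_envelope(self):
        """Where one molecule's steric clips, its electrostatic entry takes the
        column mean of the unclipped molecules."""
        inside = _atom_mol("in", pos=(0, 0, 0), charge=0.4)
        far1 = _atom_mol("f1", pos=(30, 0, 0), charge=0.2)
        far2 = _atom_mol("f2", pos=(30, 0, 0), charge=-0.2)
        grid = _grid_single_point((0.0, 0.0, 0.0))
        steric, electro = comfa_fields([inside, far1, far2], grid)
        assert steric.values[0, 0] == 30.0
        assert electro.mask[0, 0]
        expected_fill = (electro.values[1, 0] + electro.values[2, 0]) / 2
        assert electro.values[0, 0] == pytest.approx(expected_fill, abs=1e-12)

    def test_missing_radius_errors(self):
        bad = Molecule(id="bad", atoms=[Atom("C", np.zeros(3), vdw_radius=0.0)])
        with pytest.raises(ValueError):
            comfa_fields([bad], _grid_single_point((3, 0, 0)))


class TestComsiaKernels:
    def test_value_at_atom_center_is_minus_weight(self):
        mol = _atom_mol(hydro=1.0)
        grid = _grid_single_point((0.0, 0.0, 0.0))
        blocks = {b.field_type: b for b in comsia_fields([mol], grid)}
        assert blocks["comsia_hydrophobic"].values[0, 0] == pytest.approx(-1.0, abs=1e-12)

    def test_gaussian_attenuation_at_one_angstrom(self):
        mol = _atom_mol(hydro=1.0)
        grid = _grid_single_point((1.0, 0.0, 0.0))
        blocks = {b.field_type: b for b in comsia_fields([mol], grid, alpha=0.3)}
        assert blocks["comsia_hydrophobic"].values[0, 0] == pytest.approx(-np.exp(-0.3), abs=1e-10)
        assert blocks["comsia_hydrophobic"].values[0, 0] == pytest.approx(-0.74082, abs=1e-5)

    def test_two_equidistant_atoms_double_the_value(self):
        single = _atom_mol(hydro=1.0, pos=(0, 0, 1.0))
        double = Molecule(
            id="d",
            atoms=[
                Atom("C", np.array([0.0, 0, 1.0]), vdw_radius=1.7, hydrophobicity=1.0),
                Atom("C", np.array([0.0, 0, -1.0]), vdw_radius=1.7, hydrophobicity=1.0),
            ],
        )
        grid = _grid_single_point((0.0, 0.0, 0.0))
        v1 = {b.field_type: b for b in comsia_fields([single], grid)}["comsia_hydrophobic"]
        v2 = {b.field_type: b for b in comsia_fields([double], grid)}["comsia_hydrophobic"]
        assert v2.values[0, 0] == pytest.approx(2 * v1.values[0, 0], abs=1e-12)

    def test_matches_brute_force_double_loop(self):
        """Vectorized kernels agree with a literal atoms × points loop."""
        rng = np.random.default_rng(42)
        mols = []
        for m in range(3):
            atoms = [
                Atom(
                    "C",
                    rng.normal(scale=2.0, size=3),
                    partial_charge=rng.normal(scale=0.2),
                    vdw_radius=rng.uniform(1.2, 1.9),
                    hydrophobicity=rng.normal(scale=0.4),
                    is_donor=bool(rng.integers(2)),
                    is_acceptor=bool(rng.integers(2)),
                )
                for _ in range(5)
            ]
            mols.append(Molecule(id=f"m{m}", atoms=atoms))
        grid = build_grid(mols, spacing=2.0, padding=2.0)
        points = grid.points()
        probe = comsia_probe()
        blocks = {b.field_type: b for b in comsia_fields(mols, grid, probe, alpha=0.3)}
        weights = {
            "comsia_steric": lambda a: a.vdw_radius**3,
            "comsia_electrostatic": lambda a: a.partial_charge,
            "comsia_hydrophobic": lambda a: a.hydrophobicity,
            "comsia_donor": lambda a: float(a.is_donor),
            "comsia_acceptor": lambda a: float(a.is_acceptor),
        }
        pw = {
            "comsia_steric": probe.vdw_radius**3,
            "comsia_electrostatic": probe.charge,
            "comsia_hydrophobic": probe.hydrophobicity,
            "comsia_donor": probe.donor_weight,
            "comsia_acceptor": probe.acceptor_weight,
        }
        for ft, wfun in weights.items():
            for i, mol in enumerate(mols):
                for j, q in enumerate(points):
                    expected = -pw[ft] * sum(
                        wfun(a) * np.exp(-0.3 * np.sum((a.position - q) ** 2))
                        for a in mol.atoms
                    )
                    assert blocks[ft].values[i, j] == pytest.approx(expected, abs=1e-10)

    def test_positive_weights_bound_values(self):
        mol = _atom_mol(hydro=0.8)
        grid = build_grid([mol], spacing=2.0, padding=4.0)
        blocks = {b.field_type: b for b in comsia_fields([mol], grid)}
        vals = blocks["comsia_hydrophobic"].values
        assert np.all(vals <= 0) and np.all(vals >= -0.8)

    def test_alpha_must_be_positive(self):
        with pytest.raises(ValueError):
            comsia_fields([_atom_mol()], _grid_single_point((1, 0, 0)), alpha=0.0)


class TestAssemble:
    def test_concatenates_blocks_with_metadata(self):
        b1 = FieldBlock("comfa_steric", np.arange(12.0).reshape(3, 4), "kcal/mol")
        b2 = FieldBlock("comfa_electrostatic", np.ones((3, 4)), "kcal/mol")
        mat = assemble_descriptors([b1, b2], ["a", "b", "c"])
        assert mat.X.shape == (3, 8)
        assert len(mat.field_types) == 8
        assert list(mat.field_types[:4]) == ["comfa_steric"] * 4

    def test_empty_and_mismatched_inputs_error(self):
        with pytest.raises(ValueError):
            assemble_descriptors([], ["a"])
        b1 = FieldBlock("comfa_steric", np.ones((3, 2)), "kcal/mol")
        b2 = FieldBlock("comfa_electrostatic", np.ones((2, 2)), "kcal/mol")
        with pytest.raises(ValueError):
            assemble_descriptors([b1, b2], ["a", "b", "c"])

    def test_block_order_does_not_change_pls_predictions(self):
        from qsar3d.pls import PLSModel

        rng = np.random.default_rng(5)
        b1 = FieldBlock("comfa_steric", rng.normal(size=(10, 6)), "kcal/mol")
        b2 = FieldBlock("comfa_electrostatic", rng.normal(size=(10, 6)), "kcal/mol")
        y = rng.normal(size=10)
        m1 = assemble_descriptors([b1, b2], [str(i) for i in range(10)])
        m2 = assemble_descriptors([b2, b1], [str(i) for i in range(10)])
        p1 = PLSModel(3).fit(m1.X, y).predict(m1.X)
        p2 = PLSModel(3).fit(m2.X, y).predict(m2.X)
        assert np.allclose(p1, p2, atol=1e-8)
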