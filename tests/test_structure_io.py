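"""Trajectory/energy I/O round-trips and the atom-selection grammar."""

import numpy as np
import pytest

from cyp51var.structure_io import (
    AtomRecord,
    EnergySeries,
    Frame,
    ParseError,
    SelectionError,
    StructuralError,
    Topology,
    Trajectory,
    read_energy_csv,
    read_multimodel_pdb,
    read_xyz_trajectory,
    select_atoms,
    write_energy_csv,
    write_multimodel_pdb,
    write_xyz_trajectory,
)

from conftest import random_trajectory

SINGLE_MODEL_PDB = """\
ATOM      1  FE  HEM A 500       1.000   2.000   3.000  1.00  0.00          FE
ATOM      2  C30 LAN L   1       4.000   5.000   6.500  1.00  0.00           C
END
"""


class TestMultiModelPDB:
    def test_single_model_file(self, tmp_path):
        path = tmp_path / "single.pdb"
        path.write_text(SINGLE_MODEL_PDB)
        traj = read_multimodel_pdb(path)
        assert traj.n_frames == 1
        assert traj.n_atoms == 2
        atom = traj.topology.atoms[0]
        assert (atom.atom_name, atom.residue_name, atom.residue_number) == ("FE", "HEM", 500)
        assert np.allclose(traj.frames[0].coords[1], [4.0, 5.0, 6.5])

    def test_round_trip_preserves_coordinates_to_pdb_precision(self, tmp_path):
        rng = np.random.default_rng(3)
        traj = random_trajectory(rng, n_atoms=7, n_frames=5, box=99.0)
        path = tmp_path / "traj.pdb"
        write_multimodel_pdb(traj, path)
        back = read_multimodel_pdb(path)
        assert back.n_frames == traj.n_frames
        assert back.n_atoms == traj.n_atoms
        for fa, fb in zip(traj.frames, back.frames):
            np.testing.assert_allclose(fb.coords, np.round(fa.coords, 3), atol=5e-4)
        for a, b in zip(traj.topology, back.topology):
            assert (a.atom_name, a.residue_name, a.chain_id, a.residue_number) == (
                b.atom_name, b.residue_name, b.chain_id, b.residue_number)

    def test_model_atom_count_mismatch_names_offender(self, tmp_path):
        lines = ["MODEL        1"]
        for i in range(3):
            lines.append(f"ATOM  {i+1:>5d}  CA  ALA A{i+1:>4d}    {1.0:8.3f}{2.0:8.3f}{3.0:8.3f}  1.00  0.00           C")
        lines += ["ENDMDL", "MODEL        2"]
        for i in range(2):
            lines.append(f"ATOM  {i+1:>5d}  CA  ALA A{i+1:>4d}    {1.0:8.3f}{2.0:8.3f}{3.0:8.3f}  1.00  0.00           C")
        lines += ["ENDMDL", "END"]
        path = tmp_path / "bad.pdb"
        path.write_text("\n".join(lines) + "\n")
        with pytest.raises(StructuralError, match="MODEL 2"):
            read_multimodel_pdb(path)

    def test_empty_file_is_parse_error(self, tmp_path):
        path = tmp_path / "empty.pdb"
        path.write_text("")
        with pytest.raises(ParseError):
            read_multimodel_pdb(path)

    def test_agrees_with_mdanalysis_reader(self, tmp_path):
        """Independent cross-check: MDAnalysis reads our multi-model PDB the same."""
        mda = pytest.importorskip("MDAnalysis")
        rng = np.random.default_rng(11)
        traj = random_trajectory(rng, n_atoms=6, n_frames=4, box=50.0)
        path = tmp_path / "xcheck.pdb"
        write_multimodel_pdb(traj, path)
        u = mda.Universe(str(path))
        assert len(u.trajectory) == traj.n_frames
        for ours, ts in zip(read_multimodel_pdb(path).frames, u.trajectory):
            np.testing.assert_allclose(ours.coords, u.atoms.positions, atol=5e-4)


class TestXYZ:
    def test_minimal_single_frame(self, tmp_path):
        topo = Topology((AtomRecord(1, "FE", "HEM", "A", 1),))
        path = tmp_path / "one.xyz"
        path.write_text("1\nt=0\nFE 0.0 0.0 0.0\n")
        traj = read_xyz_trajectory(path, topo)
        assert traj.n_frames == 1
        np.testing.assert_array_equal(traj.frames[0].coords, [[0.0, 0.0, 0.0]])

    def test_round_trip(self, tmp_path):
        rng = np.random.default_rng(5)
        traj = random_trajectory(rng, n_atoms=4, n_frames=3)
        path = tmp_path / "t.xyz"
        write_xyz_trajectory(traj, path, decimals=6)
        back = read_xyz_trajectory(path, traj.topology)
        for fa, fb in zip(traj.frames, back.frames):
            np.testing.assert_allclose(fb.coords, fa.coords, atol=5e-7)
            assert fb.time_ps == pytest.approx(fa.time_ps)

    def test_truncated_final_frame_reports_frame_index(self, tmp_path):
        topo = Topology((AtomRecord(1, "FE", "HEM", "A", 1), AtomRecord(2, "C30", "LAN", "L", 1)))
        path = tmp_path / "trunc.xyz"
        path.write_text("2\nt=0\nFE 0 0 0\nC30 1 1 1\n2\nt=1\nFE 0 0 0\n")
        with pytest.raises(ParseError, match="frame 1"):
            read_xyz_trajectory(path, topo)

    def test_atom_count_mismatch(self, tmp_path):
        topo = Topology((AtomRecord(1, "FE", "HEM", "A", 1),))
        path = tmp_path / "m.xyz"
        path.write_text("2\nt=0\nFE 0 0 0\nC30 1 1 1\n")
        with pytest.raises(StructuralError):
            read_xyz_trajectory(path, topo)

    def test_missing_time_comment_defaults_to_frame_index(self, tmp_path):
        topo = Topology((AtomRecord(1, "FE", "HEM", "A", 1),))
        path = tmp_path / "nt.xyz"
        path.write_text("1\nno time here\nFE 0 0 0\n1\nstill none\nFE 1 0 0\n")
        traj = read_xyz_trajectory(path, topo)
        assert [f.time_ps for f in traj.frames] == [0.0, 1.0]


class TestEnergyCSV:
    def test_two_rows(self, tmp_path):
        path = tmp_path / "e.csv"
        path.write_text("frame,energy\n0,-100.0\n1,-101.0\n")
        series = read_energy_csv(path)
        assert len(series) == 2
        assert series.mean() == pytest.approx(-100.5)

    def test_empty_data_section_raises(self, tmp_path):
        path = tmp_path / "e.csv"
        path.write_text("frame,energy\n")
        with pytest.raises(ParseError):
            read_energy_csv(path)

    def test_non_numeric_cell_reports_row(self, tmp_path):
        path = tmp_path / "e.csv"
        path.write_text("frame,energy\n0,-1.0\n1,oops\n")
        with pytest.raises(ParseError, match="row 3"):
            read_energy_csv(path)

    def test_round_trip_bit_identical(self, tmp_path):
        rng = np.random.default_rng(9)
        series = EnergySeries("other", rng.normal(-100, 5, 64), np.arange(64))
        path = tmp_path / "rt.csv"
        write_energy_csv(series, path)
        back = read_energy_csv(path)
        np.testing.assert_array_equal(back.values, series.values)
        np.testing.assert_array_equal(back.frame_indices, series.frame_indices)


class TestSelectAtoms:
    def test_unique_heme_iron(self, tripeptide_topology):
        atoms = list(tripeptide_topology.atoms) + [AtomRecord(99, "FE", "HEM", "A", 500)]
        topo = Topology(tuple(atoms))
        sel = select_atoms(topo, "atom_name=FE and residue_name=HEM")
        assert sel.indices == (len(atoms) - 1,)

    def test_missing_chain_is_empty_with_warning(self, tripeptide_topology):
        with pytest.warns(UserWarning, match="matched no atoms"):
            sel = select_atoms(tripeptide_topology, "chain=Z")
        assert sel.is_empty

    def test_grammar_error_quotes_unparsed_token(self, tripeptide_topology):
        with pytest.raises(SelectionError, match="bogus"):
            select_atoms(tripeptide_topology, "bogus=FE")
        with pytest.raises(SelectionError):
            select_atoms(tripeptide_topology, "atom_name=FE extra_token")

    def test_parentheses_and_precedence(self, tripeptide_topology):
        topo = tripeptide_topology
        # and binds tighter than or
        sel = select_atoms(topo, "atom_name=N and residue_name=MET or atom_name=O1",
                           warn_empty=False)
        expected = tuple(
            i for i, a in enumerate(topo)
            if (a.atom_name == "N" and a.residue_name == "MET") or a.atom_name == "O1"
        )
        assert sel.indices == expected
        grouped = select_atoms(topo, "atom_name=N and (residue_name=MET or atom_name=O1)",
                               warn_empty=False)
        assert grouped.indices == tuple(
            i for i, a in enumerate(topo) if a.atom_name == "N" and a.residue_name == "MET"
        )

    @pytest.mark.parametrize("seed", range(10))
    def test_random_specs_equal_brute_force(self, seed):
        """Parsed selections match direct predicate evaluation over all atoms."""
        rng = np.random.default_rng(seed)
        traj = random_trajectory(rng, n_atoms=20, n_frames=1)
        topo = traj.topology
        fields = {
            "chain": lambda a: a.chain_id,
            "residue_name": lambda a: a.residue_name,
            "residue_number": lambda a: str(a.residue_number),
            "atom_name": lambda a: a.atom_name,
        }

        def random_ast(depth=0):
            if depth >= 2 or rng.random() < 0.4:
                fname = list(fields)[int(rng.integers(len(fields)))]
                atom = topo.atoms[int(rng.integers(len(topo)))]
                value = fields[fname](atom)
                return ("test", fname, value)
            op = "and" if rng.random() < 0.5 else "or"
            return (op, random_ast(depth + 1), random_ast(depth + 1))

        def render(node):
            if node[0] == "test":
                return f"{node[1]}={node[2]}"
            return f"({render(node[1])} {node[0]} {render(node[2])})"

        def evaluate(node, atom):
            if node[0] == "test":
                return fields[node[1]](atom) == node[2]
            left, right = evaluate(node[1], atom), evaluate(node[2], atom)
            return (left and right) if node[0] == "and" else (left or right)

        for _ in range(20):
            ast = random_ast()
            sel = select_atoms(topo, render(ast), warn_empty=False)
            brute = tuple(i for i, a in enumerate(topo) if evaluate(ast, a))
            assert sel.indices == brute


class TestInvariants:
    def test_frame_count_mismatch_with_topology_raises(self):
        topo = Topology((AtomRecord(1, "FE", "HEM", "A", 1),))
        frame = Frame(0, 0.0, np.zeros((2, 3)))
        with pytest.raises(StructuralError):
            Trajectory(topo, (frame,))

    def test_nonfinite_coordinates_rejected(self):
        with pytest.raises(ValueError, match="non-finite"):
            Frame(0, 0.0, np.array([[np.nan, 0.0, 0.0]]))

    def test_duplicate_serials_rejected(self):
        with pytest.raises(ValueError, match="unique"):
            Topology((AtomRecord(1, "FE", "HEM", "A", 1), AtomRecord(1, "C30", "LAN", "L", 1)))
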