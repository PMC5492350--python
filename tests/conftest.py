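import numpy as np
import pytest

from cyp51var.structure_io import AtomRecord, Frame, Topology, Trajectory


@pytest.fixture
def tripeptide_topology() -> Topology:
    """Three standard residues (backbone N/CA/C/O each) plus a ligand hydroxyl."""
    atoms = [AtomRecord(1, "O1", "LAN", "L", 1, element="O")]
    serial = 2
    for res_num, res_name in ((10, "MET"), (11, "ILE"), (12, "TRP")):
        for atom_name in ("N", "CA", "C", "O"):
            atoms.append(AtomRecord(serial, atom_name, res_name, "A", res_num))
            serial += 1
    return Topology(tuple(atoms))


def random_trajectory(rng: np.random.Generator, n_atoms: int = 8, n_frames: int = 6,
                      box: float = 10.0) -> Trajectory:
    """Small random trajectory over a mixed protein/ligand topology."""
    res_names = ["MET", "ILE", "TRP", "LAN", "HEM"]
    atom_names = ["N", "CA", "C", "O", "O1", "FE", "C30", "CB"]
    # first two atoms fixed so a ligand hydroxyl and one backbone amide
    # partner always exist; the rest are random
    atoms = [
        AtomRecord(1, "O1", "LAN", "L", 1),
        AtomRecord(2, "N", "MET", "A", 2),
    ]
    for i in range(2, n_atoms):
        atoms.append(
            AtomRecord(
                serial=i + 1,
                atom_name=atom_names[int(rng.integers(len(atom_names)))],
                residue_name=res_names[int(rng.integers(len(res_names)))],
                chain_id="AB"[int(rng.integers(2))],
                residue_number=int(rng.integers(1, 5)),
            )
        )
    topo = Topology(tuple(atoms))
    frames = tuple(
        Frame(index=t, time_ps=float(t), coords=rng.uniform(-box, box, size=(n_atoms, 3)))
        for t in range(n_frames)
    )
    return Trajectory(topo, frames)
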