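"""Rank candidate two-chain complex poses by key interface-residue contacts.

The CYP51A1-POR interface is characterised by a small set of key interacting
residues on each partner (for CYP51A1: K127, A172, K175, K364, K442, R452,
N459; for POR: residues 92, 93, 142).  A docking pose is scored by how many
cross-chain key-residue pairs are in contact — minimum heavy-atom distance
within a cutoff (default 5.0 angstrom) — with the summed minimum distances
breaking ties.  This reproduces a positional pose-selection step: the pose
placing the known interface residues against each other wins.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .structure_io import Trajectory

__all__ = [
    "KeyResidueSet",
    "Pose",
    "PoseScore",
    "ResolutionError",
    "contact_score",
    "rank_poses",
    "CYP51A1_KEY_RESIDUES",
    "POR_KEY_RESIDUES",
]

WILDCARD = "*"

DEFAULT_CONTACT_CUTOFF = 5.0  # angstrom, heavy-atom minimum distance


class ResolutionError(KeyError):
    """A key residue could not be found in a pose."""


@dataclass(frozen=True)
class KeyResidueSet:
    """Key interface residues on one chain.

    ``residues`` pairs each residue number with its expected one-letter
    residue name, or ``"*"`` where the identity is not asserted.
    """

    chain_id: str
    residues: tuple[tuple[int, str], ...]

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError("key residue set must be non-empty")
        if any(num <= 0 for num, _ in self.residues):
            raise ValueError("residue numbers must be positive")

    def __len__(self) -> int:
        return len(self.residues)


#: One-letter to three-letter residue-name map for expected-name checks.
_ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}

#: CYP51A1 key residues predicted to interact with POR.
CYP51A1_KEY_RESIDUES = KeyResidueSet(
    chain_id="A",
    residues=((127, "K"), (172, "A"), (175, "K"), (364, "K"), (442, "K"),
              (452, "R"), (459, "N")),
)

#: POR key residues; identity asserted only for E92.
POR_KEY_RESIDUES = KeyResidueSet(
    chain_id="B",
    residues=((92, "E"), (93, WILDCARD), (142, WILDCARD)),
)


@dataclass(frozen=True)
class Pose:
    """One candidate rigid arrangement: a single-frame, two-chain structure."""

    label: str
    structure: Trajectory

    def __post_init__(self) -> None:
        if self.structure.n_frames != 1:
            raise ValueError(f"pose {self.label!r}: structure must have exactly one frame")


@dataclass(frozen=True)
class PoseScore:
    """Contacts and distances over the cross-chain key-residue pairs."""

    contacts: int
    sum_min_distances: float
    per_pair: dict[tuple[str, str], float]

    def __post_init__(self) -> None:
        if self.contacts < 0 or self.contacts > len(self.per_pair):
            raise ValueError("contacts must lie in [0, number of key pairs]")


def _heavy_atom_indices_by_residue(
    pose: Pose, key_set: KeyResidueSet
) -> dict[int, tuple[str, np.ndarray]]:
    """Map residue number -> (residue name, heavy-atom indices) for one chain."""
    topo = pose.structure.topology
    wanted = {num: name for num, name in key_set.residues}
    found: dict[int, tuple[str, list[int]]] = {}
    for i, atom in enumerate(topo):
        if atom.chain_id != key_set.chain_id:
            continue
        if atom.residue_number not in wanted:
            continue
        if atom.element.upper() == "H" or atom.atom_name.startswith("H"):
            continue  # heavy atoms only
        name, idxs = found.setdefault(atom.residue_number, (atom.residue_name, []))
        idxs.append(i)
    missing = sorted(set(wanted) - set(found))
    if missing:
        raise ResolutionError(
            f"pose {pose.label!r}: chain {key_set.chain_id} is missing key residue(s) "
            f"{missing}"
        )
    out: dict[int, tuple[str, np.ndarray]] = {}
    for num, (res_name, idxs) in found.items():
        expected = wanted[num]
        if expected != WILDCARD and _ONE_TO_THREE.get(expected, expected) != res_name:
            warnings.warn(
                f"pose {pose.label!r}: chain {key_set.chain_id} residue {num} is "
                f"{res_name}, expected {expected}",
                stacklevel=3,
            )
        out[num] = (res_name, np.array(idxs, dtype=int))
    return out


def contact_score(
    pose: Pose,
    set_a: KeyResidueSet,
    set_b: KeyResidueSet,
    contact_cutoff: float = DEFAULT_CONTACT_CUTOFF,
) -> PoseScore:
    """Score one pose: per cross-chain key pair, the minimum heavy-atom
    distance; ``contacts`` counts pairs at or under ``contact_cutoff``."""
    if contact_cutoff <= 0:
        raise ValueError("contact_cutoff must be positive")
    res_a = _heavy_atom_indices_by_residue(pose, set_a)
    res_b = _heavy_atom_indices_by_residue(pose, set_b)
    coords = pose.structure.frames[0].coords
    per_pair: dict[tuple[str, str], float] = {}
    contacts = 0
    total = 0.0
    for num_a, (name_a, idx_a) in sorted(res_a.items()):
        for num_b, (name_b, idx_b) in sorted(res_b.items()):
            diff = coords[idx_a][:, None, :] - coords[idx_b][None, :, :]
            dmin = float(np.sqrt(np.sum(diff * diff, axis=-1)).min())
            key = (f"{name_a}{num_a}", f"{name_b}{num_b}")
            per_pair[key] = dmin
            total += dmin
            if dmin <= contact_cutoff:
                contacts += 1
    return PoseScore(contacts=contacts, sum_min_distances=total, per_pair=per_pair)


def rank_poses(
    poses: list[Pose],
    set_a: KeyResidueSet,
    set_b: KeyResidueSet,
    cutoff: float = DEFAULT_CONTACT_CUTOFF,
) -> list[tuple[str, PoseScore]]:
    """Rank poses: contacts descending, then sum of minimum distances
    ascending, then label — fully deterministic."""
    if not poses:
        raise ValueError("rank_poses requires at least one pose")
    scored = [(p.label, contact_score(p, set_a, set_b, cutoff)) for p in poses]
    scored.sort(key=lambda ls: (-ls[1].contacts, ls[1].sum_min_distances, ls[0]))
    return scored
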