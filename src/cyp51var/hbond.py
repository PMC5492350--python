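"""Hydrogen-bond detection and per-residue relative occupation times.

A hydrogen bond between the ligand hydroxyl and a candidate partner atom is
declared whenever their distance falls within a cutoff (default 2.4 angstrom,
inclusive) — a pure distance criterion with no angular term.  The default
``donor_acceptor`` mode measures the hydroxyl's heavy (oxygen) atom against
partner heavy atoms; ``hydrogen_acceptor`` mode is available for the reading
where the cutoff applies to the hydroxyl hydrogen instead.

The summary statistic is the relative occupation time tau_HB/tau_0 of each
partner residue: the percentage of analysed frames in which at least one of
that residue's partner atoms is hydrogen-bonded to the hydroxyl.  Occupancies
need not sum to 100 — the hydroxyl may be unbonded, or bonded to several
residues, in any one frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .structure_io import (
    AtomSelection,
    Frame,
    SelectionError,
    Topology,
    Trajectory,
    select_atoms,
)

__all__ = [
    "HBondCriterion",
    "OccupancyEntry",
    "OccupancyTable",
    "hbond_present",
    "candidate_partners",
    "occupancy_table",
    "default_window",
    "STANDARD_RESIDUES",
]

#: Three-letter codes of the twenty standard amino acids.
STANDARD_RESIDUES = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR TRP TYR VAL".split()
)

_MODES = ("donor_acceptor", "hydrogen_acceptor")


@dataclass(frozen=True)
class HBondCriterion:
    """Distance-only hydrogen-bond criterion.

    Parameters
    ----------
    cutoff_angstrom:
        Maximum partner distance, default 2.4 angstrom.
    mode:
        ``donor_acceptor`` (heavy-atom pair, default) or ``hydrogen_acceptor``.
    inclusive:
        Whether a distance exactly at the cutoff counts as bonded.
    """

    cutoff_angstrom: float = 2.4
    mode: str = "donor_acceptor"
    inclusive: bool = True

    def __post_init__(self) -> None:
        if self.cutoff_angstrom <= 0:
            raise ValueError("cutoff_angstrom must be positive")
        if self.mode not in _MODES:
            raise ValueError(f"mode must be one of {_MODES}")

    def bonded(self, distance: float) -> bool:
        if self.inclusive:
            return distance <= self.cutoff_angstrom
        return distance < self.cutoff_angstrom


@dataclass(frozen=True)
class OccupancyEntry:
    residue_name: str
    residue_number: int
    occupancy_percent: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.occupancy_percent <= 100.0:
            raise ValueError("occupancy_percent must lie in [0, 100]")


@dataclass(frozen=True)
class OccupancyTable:
    """Per-residue relative occupation times over an analysis window.

    ``entries`` are sorted by descending occupancy; residues with zero
    occupancy are omitted from ``entries`` but counted in ``n_zero_residues``.
    """

    structure_label: str
    entries: tuple[OccupancyEntry, ...]
    n_frames_analyzed: int
    window: tuple[int, int]
    n_zero_residues: int = 0

    def __post_init__(self) -> None:
        occ = [e.occupancy_percent for e in self.entries]
        if any(b > a for a, b in zip(occ, occ[1:])):
            raise ValueError("entries must be sorted by descending occupancy")
        start, end = self.window
        if self.n_frames_analyzed != end - start:
            raise ValueError("n_frames_analyzed must equal window length")

    def as_rows(self) -> list[tuple[str, str, float]]:
        """Rows (structure_label, residue, occupancy rounded to 1 decimal)."""
        return [
            (self.structure_label, f"{e.residue_name}{e.residue_number}",
             round(e.occupancy_percent, 1))
            for e in self.entries
        ]


def hbond_present(
    frame: Frame,
    partner_atom_index: int,
    hydroxyl_atom_index: int,
    criterion: HBondCriterion = HBondCriterion(),
) -> bool:
    """True iff the partner-hydroxyl distance satisfies the criterion."""
    n = frame.coords.shape[0]
    for idx in (partner_atom_index, hydroxyl_atom_index):
        if not 0 <= idx < n:
            raise IndexError(f"atom index {idx} out of range for frame with {n} atoms")
    d = float(
        np.linalg.norm(frame.coords[partner_atom_index] - frame.coords[hydroxyl_atom_index])
    )
    return criterion.bonded(d)


def candidate_partners(
    topology: Topology,
    partner_spec: str | None = None,
    extra_spec: str | None = None,
) -> AtomSelection:
    """Candidate hydrogen-bond partner atoms.

    By default: the backbone amide nitrogen ("N") and carbonyl oxygen ("O")
    of every standard amino-acid residue.  ``extra_spec`` adds further atoms
    (e.g. a tryptophan indole nitrogen) via the selection grammar;
    ``partner_spec`` replaces the default outright.
    """
    if partner_spec is not None:
        sel = select_atoms(topology, partner_spec, warn_empty=False)
        indices = set(sel.indices)
        spec = partner_spec
    else:
        indices = {
            i
            for i, a in enumerate(topology)
            if a.atom_name in ("N", "O") and a.residue_name in STANDARD_RESIDUES
        }
        spec = "<default backbone amide N/O>"
    if extra_spec is not None:
        extra = select_atoms(topology, extra_spec, warn_empty=False)
        indices |= set(extra.indices)
        spec = f"{spec} + {extra_spec}"
    return AtomSelection(spec=spec, indices=tuple(sorted(indices)))


def default_window(traj: Trajectory) -> tuple[int, int]:
    """Second half of the trajectory — the production-window convention."""
    n = traj.n_frames
    return (n // 2, n)


def occupancy_table(
    traj: Trajectory,
    hydroxyl_sel: AtomSelection,
    partner_sel: AtomSelection,
    criterion: HBondCriterion = HBondCriterion(),
    window: tuple[int, int] | None = None,
    structure_label: str = "",
) -> OccupancyTable:
    """Per-residue hydrogen-bond occupancies over ``window``.

    For each residue owning at least one partner atom,
    ``occupancy_percent = 100 * (frames in window with >=1 bonded partner
    atom of that residue) / n_frames_analyzed``.  A frame with several bonded
    atoms of the same residue counts once for that residue.

    ``hydroxyl_sel`` must resolve at least one atom; if it resolves several
    (e.g. both O and H of the hydroxyl), a bond exists when any of them is
    within the cutoff of the partner atom.
    """
    if window is None:
        window = default_window(traj)
    start, end = window
    if not (0 <= start < end <= traj.n_frames):
        raise ValueError(
            f"window {window} is empty or outside trajectory of {traj.n_frames} frames"
        )
    if hydroxyl_sel.is_empty:
        raise SelectionError(f"hydroxyl selection {hydroxyl_sel.spec!r} resolved no atoms")
    n_frames = end - start
    hyd_idx = np.array(hydroxyl_sel.indices, dtype=int)
    part_idx = np.array(partner_sel.indices, dtype=int)

    # residue key for each partner atom
    atoms = traj.topology.atoms
    residue_keys = [
        (atoms[i].chain_id, atoms[i].residue_name, atoms[i].residue_number) for i in part_idx
    ]
    unique_keys = sorted(set(residue_keys))
    key_pos = {k: j for j, k in enumerate(unique_keys)}
    atom_residue = np.array([key_pos[k] for k in residue_keys], dtype=int)

    bonded_frames = np.zeros(len(unique_keys), dtype=int)
    for frame in traj.frames[start:end]:
        if part_idx.size == 0:
            continue
        # distances: partners x hydroxyl atoms
        diff = frame.coords[part_idx][:, None, :] - frame.coords[hyd_idx][None, :, :]
        dists = np.sqrt(np.sum(diff * diff, axis=-1))
        dmin = dists.min(axis=1)
        bonded = dmin <= criterion.cutoff_angstrom if criterion.inclusive else dmin < criterion.cutoff_angstrom
        if bonded.any():
            bonded_residues = np.unique(atom_residue[bonded])
            bonded_frames[bonded_residues] += 1

    entries = []
    n_zero = 0
    for key, count in zip(unique_keys, bonded_frames):
        if count == 0:
            n_zero += 1
            continue
        _, res_name, res_num = key
        entries.append(
            OccupancyEntry(
                residue_name=res_name,
                residue_number=res_num,
                occupancy_percent=100.0 * count / n_frames,
            )
        )
    entries.sort(key=lambda e: (-e.occupancy_percent, e.residue_number, e.residue_name))
    return OccupancyTable(
        structure_label=structure_label,
        entries=tuple(entries),
        n_frames_analyzed=n_frames,
        window=(start, end),
        n_zero_residues=n_zero,
    )
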