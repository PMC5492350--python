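"""Coordinate, trajectory and energy-series I/O plus atom selection.

The trajectory carrier is deliberately simple: a :class:`Topology` (an
ordered list of :class:`AtomRecord`) shared by every :class:`Frame` of a
:class:`Trajectory`.  Multi-model PDB is the canonical on-disk trajectory
format (human-inspectable, fixed-column, three-decimal angstrom precision);
a minimal XYZ trajectory format is supported as a lighter-weight carrier.
Per-frame internal energies travel as two-column CSV files.

Atom selections use a tiny grammar of equality tests
(``atom_name=FE and residue_name=HEM``) combined with ``and``/``or`` and
parentheses — enough to resolve the heme iron, the ligand hydroxyl and
backbone amide partners without a full selection language.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AtomRecord",
    "Topology",
    "Frame",
    "Trajectory",
    "EnergySeries",
    "AtomSelection",
    "ParseError",
    "StructuralError",
    "SelectionError",
    "read_multimodel_pdb",
    "write_multimodel_pdb",
    "read_xyz_trajectory",
    "write_xyz_trajectory",
    "read_energy_csv",
    "write_energy_csv",
    "select_atoms",
]


class ParseError(ValueError):
    """A file could not be parsed as the declared format."""


class StructuralError(ValueError):
    """File parsed, but its structure is internally inconsistent."""


class SelectionError(ValueError):
    """An atom-selection spec is malformed or resolves unexpectedly."""


@dataclass(frozen=True)
class AtomRecord:
    """One atom's identity within a topology.

    ``atom_name`` follows PDB conventions ("FE", "C30", "O1", "N");
    ``residue_number`` is 1-based as in PDB records.
    """

    serial: int
    atom_name: str
    residue_name: str
    chain_id: str
    residue_number: int
    element: str = ""

    def __post_init__(self) -> None:
        if self.serial <= 0:
            raise ValueError(f"atom serial must be positive, got {self.serial}")
        if not self.atom_name:
            raise ValueError("atom_name must be non-empty")


@dataclass(frozen=True)
class Topology:
    """Ordered atom list; order matches the coordinate order of every frame."""

    atoms: tuple[AtomRecord, ...]

    def __post_init__(self) -> None:
        if not self.atoms:
            raise ValueError("topology must contain at least one atom")
        serials = [a.serial for a in self.atoms]
        if len(set(serials)) != len(serials):
            raise ValueError("atom serials must be unique within a topology")

    def __len__(self) -> int:
        return len(self.atoms)

    def __iter__(self):
        return iter(self.atoms)


@dataclass(frozen=True)
class Frame:
    """One snapshot: coordinates in angstrom, time in picoseconds."""

    index: int
    time_ps: float
    coords: np.ndarray  # shape (n_atoms, 3)

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise ValueError(f"coords must have shape (n, 3), got {coords.shape}")
        if not np.all(np.isfinite(coords)):
            raise ValueError(f"frame {self.index}: non-finite coordinates")
        if self.index < 0:
            raise ValueError("frame index must be non-negative")
        object.__setattr__(self, "coords", coords)


@dataclass(frozen=True)
class Trajectory:
    """A topology plus an ordered sequence of frames over it."""

    topology: Topology
    frames: tuple[Frame, ...]

    def __post_init__(self) -> None:
        n = len(self.topology)
        for f in self.frames:
            if f.coords.shape[0] != n:
                raise StructuralError(
                    f"frame {f.index} has {f.coords.shape[0]} atoms, topology has {n}"
                )
        indices = [f.index for f in self.frames]
        if any(b <= a for a, b in zip(indices, indices[1:])):
            raise ValueError("frame indices must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def n_atoms(self) -> int:
        return len(self.topology)


_SERIES_LABELS = ("complex", "component1", "component2", "other")


@dataclass(frozen=True)
class EnergySeries:
    """Per-frame internal energies from one simulation.

    Units are configuration metadata (default kcal/mol); all operations are
    unit-agnostic.
    """

    label: str
    values: np.ndarray
    frame_indices: np.ndarray
    units: str = "kcal/mol"

    def __post_init__(self) -> None:
        if self.label not in _SERIES_LABELS:
            raise ValueError(f"label must be one of {_SERIES_LABELS}, got {self.label!r}")
        values = np.asarray(self.values, dtype=float)
        idx = np.asarray(self.frame_indices, dtype=int)
        if values.size == 0:
            raise ValueError("energy series must be non-empty")
        if not np.all(np.isfinite(values)):
            raise ValueError("energy series contains non-finite values")
        if idx.shape != values.shape:
            raise ValueError("frame_indices must match values in length")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "frame_indices", idx)

    def __len__(self) -> int:
        return len(self.values)

    def mean(self) -> float:
        return float(np.mean(self.values))


@dataclass(frozen=True)
class AtomSelection:
    """A resolved selection: the spec string and the topology indices it matched."""

    spec: str
    indices: tuple[int, ...]

    def __len__(self) -> int:
        return len(self.indices)

    @property
    def is_empty(self) -> bool:
        return not self.indices


# ---------------------------------------------------------------------------
# Multi-model PDB

def _parse_pdb_atom_line(line: str, lineno: int) -> tuple[AtomRecord, tuple[float, float, float]]:
    try:
        serial = int(line[6:11])
        atom_name = line[12:16].strip()
        residue_name = line[17:20].strip()
        chain_id = line[21].strip() or " "
        residue_number = int(line[22:26])
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
        element = line[76:78].strip() if len(line) >= 78 else ""
    except (ValueError, IndexError) as exc:
        raise ParseError(f"line {lineno}: malformed ATOM/HETATM record: {line.rstrip()!r}") from exc
    return (
        AtomRecord(serial, atom_name, residue_name, chain_id, residue_number, element),
        (x, y, z),
    )


def read_multimodel_pdb(path: str | Path) -> Trajectory:
    """Read a (possibly multi-MODEL) PDB file as a trajectory.

    A file without MODEL records is read as a single-frame trajectory.  The
    topology is taken from the first MODEL; every subsequent MODEL must have
    the same atom count or a :class:`StructuralError` names the offender.
    """
    path = Path(path)
    text = path.read_text()
    models: list[tuple[int, list[AtomRecord], list[tuple[float, float, float]]]] = []
    current_atoms: list[AtomRecord] = []
    current_coords: list[tuple[float, float, float]] = []
    current_model: int | None = None
    for lineno, line in enumerate(text.splitlines(), start=1):
        record = line[:6].strip()
        if record == "MODEL":
            if current_atoms:
                models.append((current_model if current_model is not None else len(models) + 1,
                               current_atoms, current_coords))
                current_atoms, current_coords = [], []
            try:
                current_model = int(line.split()[1])
            except (IndexError, ValueError):
                current_model = len(models) + 1
        elif record in ("ATOM", "HETATM"):
            atom, xyz = _parse_pdb_atom_line(line, lineno)
            current_atoms.append(atom)
            current_coords.append(xyz)
        elif record == "ENDMDL":
            if current_atoms:
                models.append((current_model if current_model is not None else len(models) + 1,
                               current_atoms, current_coords))
                current_atoms, current_coords = [], []
            current_model = None
    if current_atoms:
        models.append((current_model if current_model is not None else len(models) + 1,
                       current_atoms, current_coords))
    if not models:
        raise ParseError(f"{path}: no ATOM/HETATM records found")
    first_model_id, first_atoms, _ = models[0]
    n = len(first_atoms)
    for model_id, atoms, _ in models[1:]:
        if len(atoms) != n:
            raise StructuralError(
                f"{path}: MODEL {model_id} has {len(atoms)} atoms, "
                f"MODEL {first_model_id} has {n}"
            )
    topology = Topology(tuple(first_atoms))
    frames = tuple(
        Frame(index=i, time_ps=float(i), coords=np.array(coords, dtype=float))
        for i, (_, _, coords) in enumerate(models)
    )
    return Trajectory(topology, frames)


def write_multimodel_pdb(traj: Trajectory, path: str | Path) -> None:
    """Write a trajectory as a multi-MODEL PDB (fixed columns, 3 decimals)."""
    lines: list[str] = []
    for frame in traj.frames:
        lines.append(f"MODEL {frame.index + 1:>8d}")
        for atom, (x, y, z) in zip(traj.topology, frame.coords):
            name = atom.atom_name
            # PDB alignment: names of <4 chars start in column 14
            name_field = f" {name:<3s}" if len(name) < 4 else name[:4]
            lines.append(
                f"ATOM  {atom.serial:>5d} {name_field}"
                f" {atom.residue_name:<3s} {atom.chain_id}{atom.residue_number:>4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          "
                f"{atom.element:>2s}"
            )
        lines.append("ENDMDL")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# XYZ trajectory

_TIME_RE = re.compile(r"t\s*=\s*([0-9.eE+-]+)")


def read_xyz_trajectory(path: str | Path, topology: Topology) -> Trajectory:
    """Read an XYZ trajectory (count line, comment line ``t=<ps>``, atom lines).

    Frames are returned in file order.  A comment line without a parseable
    time defaults ``time_ps`` to the frame index.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    n_top = len(topology)
    frames: list[Frame] = []
    pos = 0
    frame_idx = 0
    while pos < len(lines):
        if not lines[pos].strip():
            pos += 1
            continue
        try:
            count = int(lines[pos].strip())
        except ValueError as exc:
            raise ParseError(f"{path}: line {pos + 1}: expected atom count") from exc
        if count != n_top:
            raise StructuralError(
                f"{path}: frame {frame_idx} declares {count} atoms, topology has {n_top}"
            )
        comment = lines[pos + 1] if pos + 1 < len(lines) else ""
        m = _TIME_RE.search(comment)
        time_ps = float(m.group(1)) if m else float(frame_idx)
        coords = np.empty((count, 3), dtype=float)
        for i in range(count):
            lineno = pos + 2 + i
            if lineno >= len(lines):
                raise ParseError(f"{path}: frame {frame_idx} truncated")
            parts = lines[lineno].split()
            if len(parts) < 4:
                raise ParseError(
                    f"{path}: frame {frame_idx}, line {lineno + 1}: expected 'name x y z'"
                )
            try:
                coords[i] = [float(parts[1]), float(parts[2]), float(parts[3])]
            except ValueError as exc:
                raise ParseError(
                    f"{path}: frame {frame_idx}, line {lineno + 1}: non-numeric coordinate"
                ) from exc
        frames.append(Frame(index=frame_idx, time_ps=time_ps, coords=coords))
        pos += 2 + count
        frame_idx += 1
    if not frames:
        raise ParseError(f"{path}: empty XYZ trajectory")
    return Trajectory(topology, tuple(frames))


def write_xyz_trajectory(traj: Trajectory, path: str | Path, decimals: int = 6) -> None:
    """Write a trajectory in XYZ format, ``decimals`` digits after the point."""
    lines: list[str] = []
    for frame in traj.frames:
        lines.append(str(traj.n_atoms))
        lines.append(f"t={frame.time_ps:.6g}")
        for atom, (x, y, z) in zip(traj.topology, frame.coords):
            lines.append(
                f"{atom.atom_name} {x:.{decimals}f} {y:.{decimals}f} {z:.{decimals}f}"
            )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Energy CSV

def read_energy_csv(path: str | Path, label: str = "other", units: str = "kcal/mol") -> EnergySeries:
    """Read a two-column ``frame,energy`` CSV (header required)."""
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise ParseError(f"{path}: empty CSV") from exc
    if df.shape[1] < 2:
        raise ParseError(f"{path}: expected two columns 'frame,energy'")
    if df.shape[0] == 0:
        raise ParseError(f"{path}: no data rows")
    frames = np.empty(len(df), dtype=int)
    values = np.empty(len(df), dtype=float)
    for i, (f, v) in enumerate(zip(df.iloc[:, 0], df.iloc[:, 1])):
        try:
            frames[i] = int(str(f))
            values[i] = float(str(v))
        except ValueError as exc:
            # +2: header is row 1
            raise ParseError(f"{path}: row {i + 2}: non-numeric cell") from exc
    return EnergySeries(label=label, values=values, frame_indices=frames, units=units)


def write_energy_csv(series: EnergySeries, path: str | Path) -> None:
    lines = ["frame,energy"]
    for f, v in zip(series.frame_indices, series.values):
        lines.append(f"{int(f)},{float(v)!r}")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Atom selection grammar
#
#   expr     := term ('or' term)*
#   term     := factor ('and' factor)*
#   factor   := test | '(' expr ')'
#   test     := field '=' value
#   field    := chain | residue_name | residue_number | atom_name | element

_FIELDS: dict[str, Callable[[AtomRecord], str]] = {
    "chain": lambda a: a.chain_id,
    "chain_id": lambda a: a.chain_id,
    "residue_name": lambda a: a.residue_name,
    "residue_number": lambda a: str(a.residue_number),
    "atom_name": lambda a: a.atom_name,
    "element": lambda a: a.element,
}

_TOKEN_RE = re.compile(r"\(|\)|=|[^\s()=]+")


class _SpecParser:
    def __init__(self, spec: str):
        self.tokens = _TOKEN_RE.findall(spec)
        self.pos = 0
        self.spec = spec

    def peek(self) -> str | None:
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def take(self) -> str:
        tok = self.peek()
        if tok is None:
            raise SelectionError(f"unexpected end of selection spec: {self.spec!r}")
        self.pos += 1
        return tok

    def parse(self) -> Callable[[AtomRecord], bool]:
        pred = self.expr()
        if self.peek() is not None:
            raise SelectionError(
                f"unparsed token {self.peek()!r} in selection spec {self.spec!r}"
            )
        return pred

    def expr(self) -> Callable[[AtomRecord], bool]:
        preds = [self.term()]
        while self.peek() == "or":
            self.take()
            preds.append(self.term())
        if len(preds) == 1:
            return preds[0]
        return lambda a: any(p(a) for p in preds)

    def term(self) -> Callable[[AtomRecord], bool]:
        preds = [self.factor()]
        while self.peek() == "and":
            self.take()
            preds.append(self.factor())
        if len(preds) == 1:
            return preds[0]
        return lambda a: all(p(a) for p in preds)

    def factor(self) -> Callable[[AtomRecord], bool]:
        tok = self.take()
        if tok == "(":
            pred = self.expr()
            closing = self.take()
            if closing != ")":
                raise SelectionError(f"expected ')', got {closing!r} in {self.spec!r}")
            return pred
        if tok in ("and", "or", ")", "="):
            raise SelectionError(f"unexpected token {tok!r} in selection spec {self.spec!r}")
        field = tok
        if field not in _FIELDS:
            raise SelectionError(
                f"unknown field {field!r} in selection spec {self.spec!r}; "
                f"known fields: {sorted(set(_FIELDS))}"
            )
        eq = self.take()
        if eq != "=":
            raise SelectionError(f"expected '=' after {field!r}, got {eq!r}")
        value = self.take()
        getter = _FIELDS[field]
        return lambda a: getter(a) == value


def select_atoms(topology: Topology, spec: str, warn_empty: bool = True) -> AtomSelection:
    """Resolve a selection spec against a topology.

    Empty selections are allowed but emit a warning (they usually signal a
    typo in a residue or atom name).
    """
    pred = _SpecParser(spec).parse()
    indices = tuple(i for i, atom in enumerate(topology) if pred(atom))
    if not indices and warn_empty:
        import warnings

        warnings.warn(f"selection {spec!r} matched no atoms", stacklevel=2)
    return AtomSelection(spec=spec, indices=indices)
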