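"""Synthetic trajectories, energy series, pose sets and table fixtures.

Cluster-scale molecular dynamics is out of reach on a desk machine, so every
analysis stage is exercised instead on generated data with known ground
truth:

* hydrogen-bond trajectories — each target residue's partner atom hops
  between a bonded and an unbonded distance from a fixed ligand hydroxyl
  under a two-state Markov chain whose stationary probability is the target
  occupancy (``persistence`` controls autocorrelation; 0 means i.i.d.);
* stationary AR(1) series for internal energies and distance processes;
* docking pose sets with one planted near-native pose (a chosen number of
  key residue pairs within contact range) among randomly displaced decoys;
* TSV fixtures transcribing the study's variant and occupancy tables.

All generators are seed-deterministic: identical inputs give byte-identical
outputs.  None of this emulates physics — no force field, no sterics — only
the statistical structure the analysis layer consumes.
"""

from __future__ import annotations

import math
import shutil
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from .pose_ranking import WILDCARD, KeyResidueSet, Pose, _ONE_TO_THREE
from .structure_io import AtomRecord, EnergySeries, Frame, Topology, Trajectory
from .variants import packaged_table_path

__all__ = [
    "HBondScenario",
    "SeriesScenario",
    "GenerationError",
    "make_hbond_topology",
    "gen_hbond_trajectory",
    "gen_ar1_series",
    "gen_distance_trajectory",
    "gen_pose_set",
    "scenario_from_config",
    "write_fixtures",
    "FIXTURE_NAMES",
    "paper_like_occupancy_targets",
    "paper_like_fe_c30_means",
    "paper_like_lanosterol_binding",
    "paper_like_por_binding",
]


class GenerationError(RuntimeError):
    """A generator could not satisfy the requested geometry."""


# ---------------------------------------------------------------------------
# Hydrogen-bond trajectories


@dataclass(frozen=True)
class HBondScenario:
    """Ground truth for a hydrogen-bond occupancy trajectory.

    ``residue_targets`` maps (residue_name, residue_number) to the stationary
    probability that the residue's backbone amide partner sits at
    ``bonded_distance`` from the ligand hydroxyl in any one frame.
    ``persistence`` is the extra stay-probability of the two-state Markov
    chain (0 = i.i.d. Bernoulli frames).
    """

    residue_targets: dict[tuple[str, int], float]
    n_frames: int
    bonded_distance: float = 2.2
    unbonded_distance: float = 6.0
    persistence: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.residue_targets:
            raise ValueError("at least one residue target required")
        for key, p in self.residue_targets.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"occupancy target for {key} outside [0, 1]: {p}")
        if not 0.0 <= self.persistence < 1.0:
            raise ValueError("persistence must lie in [0, 1)")
        if self.n_frames <= 0:
            raise ValueError("n_frames must be positive")
        if not self.bonded_distance < self.unbonded_distance:
            raise ValueError("bonded_distance must be below unbonded_distance")


HYDROXYL_ATOM_SPEC = "residue_name=LAN and atom_name=O1"


def _residue_directions(n: int) -> np.ndarray:
    """n well-separated unit vectors (golden-spiral points on the sphere)."""
    idx = np.arange(n, dtype=float) + 0.5
    phi = math.pi * (3.0 - math.sqrt(5.0)) * idx
    z = 1.0 - 2.0 * idx / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=1)


def make_hbond_topology(residue_targets: dict[tuple[str, int], float]) -> Topology:
    """Template topology for :func:`gen_hbond_trajectory`.

    One ligand residue LAN (hydroxyl oxygen O1, chain L) plus, per target
    residue on chain A, backbone atoms N / CA / C / O.  The N is the mobile
    hydrogen-bond partner; the rest stay far from the hydroxyl.
    """
    atoms: list[AtomRecord] = [AtomRecord(1, "O1", "LAN", "L", 1)]
    serial = 2
    for res_name, res_num in sorted(residue_targets, key=lambda k: k[1]):
        for atom_name in ("N", "CA", "C", "O"):
            atoms.append(AtomRecord(serial, atom_name, res_name, "A", res_num))
            serial += 1
    return Topology(tuple(atoms))


def gen_hbond_trajectory(
    scenario: HBondScenario, topology_template: Topology | None = None
) -> Trajectory:
    """Generate a trajectory realising the scenario's occupancy targets.

    Each residue's bonded/unbonded state evolves independently as a two-state
    Markov chain with stationary probability equal to its target and
    transition probabilities P(bond | no bond) = (1 - persistence) p,
    P(stay bonded) = persistence + (1 - persistence) p.
    """
    if topology_template is None:
        topology_template = make_hbond_topology(scenario.residue_targets)
    atoms = topology_template.atoms
    hydroxyl_idx = [
        i for i, a in enumerate(atoms) if a.residue_name == "LAN" and a.atom_name == "O1"
    ]
    if len(hydroxyl_idx) != 1:
        raise ValueError("template must contain exactly one LAN O1 hydroxyl atom")
    partner_idx: dict[tuple[str, int], int] = {}
    for key in scenario.residue_targets:
        res_name, res_num = key
        matches = [
            i
            for i, a in enumerate(atoms)
            if a.residue_name == res_name and a.residue_number == res_num
            and a.atom_name == "N"
        ]
        if len(matches) != 1:
            raise ValueError(
                f"template must contain exactly one backbone N for residue "
                f"{res_name}{res_num}, found {len(matches)}"
            )
        partner_idx[key] = matches[0]

    keys = sorted(scenario.residue_targets, key=lambda k: k[1])
    probs = np.array([scenario.residue_targets[k] for k in keys])
    rng = np.random.default_rng(scenario.seed)
    rho = scenario.persistence

    # static base coordinates: hydroxyl at origin, residues spread on a sphere
    n_atoms = len(atoms)
    base = np.zeros((n_atoms, 3))
    dirs = _residue_directions(len(keys))
    static_offsets = {"N": 0.0, "CA": 20.0, "C": 21.5, "O": 23.0}
    for k, key in enumerate(keys):
        res_name, res_num = key
        for i, a in enumerate(atoms):
            if a.residue_name == res_name and a.residue_number == res_num:
                if a.atom_name == "N":
                    continue  # set per frame
                base[i] = dirs[k] * static_offsets.get(a.atom_name, 25.0)

    state = (rng.random(len(keys)) < probs).astype(bool)
    frames = []
    for t in range(scenario.n_frames):
        if t > 0:
            u = rng.random(len(keys))
            p_bond = np.where(state, rho + (1.0 - rho) * probs, (1.0 - rho) * probs)
            state = u < p_bond
        coords = base.copy()
        for k, key in enumerate(keys):
            d = scenario.bonded_distance if state[k] else scenario.unbonded_distance
            coords[partner_idx[key]] = dirs[k] * d
        frames.append(Frame(index=t, time_ps=float(t), coords=coords))
    return Trajectory(topology_template, tuple(frames))


# ---------------------------------------------------------------------------
# AR(1) series


@dataclass(frozen=True)
class SeriesScenario:
    """Stationary AR(1) ground truth: stationary mean and sd as stated."""

    mean: float
    sd: float
    ar1_phi: float = 0.0
    n: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be non-negative")
        if not 0.0 <= self.ar1_phi < 1.0:
            raise ValueError("ar1_phi must lie in [0, 1)")
        if self.n <= 0:
            raise ValueError("n must be positive")


def gen_ar1_series(scenario: SeriesScenario, label: str = "other") -> EnergySeries:
    """x_0 = mean; x_t = mean + phi (x_{t-1} - mean) + eps_t with
    Var(eps) = sd^2 (1 - phi^2), so the stationary mean/sd equal the
    scenario's.  Also used for synthetic distance processes."""
    rng = np.random.default_rng(scenario.seed)
    phi = scenario.ar1_phi
    innov_sd = scenario.sd * math.sqrt(1.0 - phi * phi)
    eps = rng.normal(0.0, innov_sd, size=scenario.n)
    x = np.empty(scenario.n)
    x[0] = scenario.mean
    dev = 0.0
    for t in range(1, scenario.n):
        dev = phi * dev + eps[t]
        x[t] = scenario.mean + dev
    return EnergySeries(label=label, values=x, frame_indices=np.arange(scenario.n))


def gen_distance_trajectory(scenario: SeriesScenario) -> Trajectory:
    """Two-atom trajectory (heme FE fixed at origin, ligand C30 on the x
    axis) whose FE-C30 distance follows the AR(1) scenario.

    Negative excursions of the AR(1) process are clipped at zero (distances
    cannot be negative); keep mean >> sd to avoid clipping in practice.
    """
    series = gen_ar1_series(scenario)
    distances = np.maximum(series.values, 0.0)
    topology = Topology(
        (
            AtomRecord(1, "FE", "HEM", "A", 500, element="FE"),
            AtomRecord(2, "C30", "LAN", "L", 1, element="C"),
        )
    )
    frames = tuple(
        Frame(index=t, time_ps=float(t),
              coords=np.array([[0.0, 0.0, 0.0], [d, 0.0, 0.0]]))
        for t, d in enumerate(distances)
    )
    return Trajectory(topology, frames)


def scenario_from_config(path: str | Path) -> HBondScenario | SeriesScenario:
    """Load a scenario from a YAML or JSON config file.

    The config carries a ``kind`` ("hbond" or "series"), a ``seed`` and the
    scenario's fields; hydrogen-bond targets are a list of
    ``{name, number, probability}`` mappings.  YAML is a superset of JSON, so
    both formats go through one loader.
    """
    data = yaml.safe_load(Path(path).read_text())
    if not isinstance(data, dict) or "kind" not in data:
        raise ValueError(f"{path}: scenario config must be a mapping with a 'kind' key")
    kind = data.pop("kind")
    if "seed" not in data:
        raise ValueError(f"{path}: scenario config must declare a seed")
    if kind == "hbond":
        targets = {
            (str(t["name"]), int(t["number"])): float(t["probability"])
            for t in data.pop("residue_targets")
        }
        return HBondScenario(residue_targets=targets, **data)
    if kind == "series":
        return SeriesScenario(**data)
    raise ValueError(f"{path}: unknown scenario kind {kind!r}")


# ---------------------------------------------------------------------------
# Pose sets

_PLANTED_CONTACT_DISTANCE = 4.0  # < 4.5 per the near-native definition
_DECOY_MIN_SEPARATION = 15.0
_RESIDUE_SPACING = 50.0


def _three_letter(name: str) -> str:
    if name == WILDCARD:
        return "GLY"
    return _ONE_TO_THREE.get(name, name)


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix from a normalised quaternion."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def _build_chain(
    key_set: KeyResidueSet, origin: np.ndarray, serial_start: int
) -> tuple[list[AtomRecord], list[np.ndarray]]:
    atoms: list[AtomRecord] = []
    coords: list[np.ndarray] = []
    serial = serial_start
    offsets = {"N": (0.0, 0.0, 0.0), "CA": (1.5, 0.0, 0.0),
               "C": (0.0, 1.5, 0.0), "O": (0.0, 0.0, 1.5)}
    for i, (num, name) in enumerate(sorted(key_set.residues)):
        site = origin + np.array([_RESIDUE_SPACING * i, 0.0, 0.0])
        for atom_name, off in offsets.items():
            atoms.append(
                AtomRecord(serial, atom_name, _three_letter(name), key_set.chain_id, num)
            )
            coords.append(site + np.array(off))
            serial += 1
    return atoms, coords


def gen_pose_set(
    n_decoys: int,
    planted_contacts: int,
    set_a: KeyResidueSet,
    set_b: KeyResidueSet,
    seed: int = 0,
    max_retries: int = 50,
) -> list[Pose]:
    """One planted near-native pose plus ``n_decoys`` displaced decoys.

    The planted pose (label ``"planted"``) has exactly ``planted_contacts``
    cross-chain key-residue pairs with minimum heavy-atom distance 4.0
    angstrom; every other pair is tens of angstroms apart.  Decoys
    (``"decoy_01"``...) carry chain B randomly rotated and translated to at
    least 15 angstrom interface separation.  Deterministic given the seed.
    """
    if n_decoys < 1:
        raise ValueError("n_decoys must be >= 1")
    n_pairs = len(set_a) * len(set_b)
    if not 0 <= planted_contacts <= n_pairs:
        raise GenerationError(
            f"planted_contacts {planted_contacts} infeasible for "
            f"{len(set_a)}x{len(set_b)} key pairs"
        )
    rng = np.random.default_rng(seed)

    atoms_a, coords_a = _build_chain(set_a, np.zeros(3), serial_start=1)
    atoms_b, coords_b = _build_chain(
        set_b, np.array([0.0, 300.0, 0.0]), serial_start=len(atoms_a) + 1
    )
    nums_a = [num for num, _ in sorted(set_a.residues)]
    nums_b = [num for num, _ in sorted(set_b.residues)]
    names_b = {num: _three_letter(name) for num, name in set_b.residues}

    # plant contacts: extra chain-B atoms parked next to chosen chain-A sites
    all_pairs = [(i, j) for i in range(len(nums_a)) for j in range(len(nums_b))]
    chosen = rng.choice(len(all_pairs), size=planted_contacts, replace=False)
    extra_atoms: list[AtomRecord] = []
    extra_coords: list[np.ndarray] = []
    serial = len(atoms_a) + len(atoms_b) + 1
    for m, pair_idx in enumerate(sorted(int(c) for c in chosen)):
        i, j = all_pairs[pair_idx]
        site_a = np.array([_RESIDUE_SPACING * i, 0.0, 0.0])
        extra_atoms.append(
            AtomRecord(serial, f"C{m + 1}", names_b[nums_b[j]], set_b.chain_id, nums_b[j])
        )
        extra_coords.append(site_a + np.array([_PLANTED_CONTACT_DISTANCE, 0.0, 0.0]))
        serial += 1

    topology = Topology(tuple(atoms_a + atoms_b + extra_atoms))
    a_block = np.array(coords_a)
    b_block = np.array(coords_b + extra_coords)
    n_a = len(atoms_a)

    def make_pose(label: str, b_coords: np.ndarray) -> Pose:
        coords = np.vstack([a_block, b_coords])
        frame = Frame(index=0, time_ps=0.0, coords=coords)
        return Pose(label=label, structure=Trajectory(topology, (frame,)))

    poses = [make_pose("planted", b_block)]
    a_extent = float(np.linalg.norm(a_block, axis=1).max())
    for d in range(n_decoys):
        for attempt in range(max_retries):
            rot = _random_rotation(rng)
            centroid = b_block.mean(axis=0)
            rotated = (b_block - centroid) @ rot.T
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            b_extent = float(np.linalg.norm(rotated, axis=1).max())
            radius = a_extent + b_extent + _DECOY_MIN_SEPARATION + 100.0 * rng.random()
            candidate = rotated + direction * radius
            dmin = float(
                np.sqrt(
                    ((a_block[:, None, :] - candidate[None, :, :]) ** 2).sum(-1)
                ).min()
            )
            if dmin >= _DECOY_MIN_SEPARATION:
                poses.append(make_pose(f"decoy_{d + 1:02d}", candidate))
                break
        else:
            raise GenerationError(
                f"could not place decoy {d + 1} with >= {_DECOY_MIN_SEPARATION} A "
                f"separation in {max_retries} attempts"
            )
    return poses


# ---------------------------------------------------------------------------
# Table fixtures

FIXTURE_NAMES = (
    "table1_phenotypes.tsv",
    "table2_invitro_pairs.tsv",
    "table3_damaging.tsv",
    "table4_conserved_regions.tsv",
    "table5_occupancy.tsv",
)


def write_fixtures(outdir: str | Path) -> list[Path]:
    """Emit the five packaged TSV fixtures into ``outdir``.

    Re-running is byte-identical (the packaged tables are static
    transcriptions of the study's printed tables).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for name in FIXTURE_NAMES:
        src = packaged_table_path(name)
        dst = outdir / name
        shutil.copyfile(src, dst)
        written.append(dst)
    return written


# ---------------------------------------------------------------------------
# "Paper-like" presets
#
# These define the study conditions for the qualitative-reproduction checks:
# occupancy targets mirror the printed occupancy table (percent / 100); the
# Fe-C30 levels put the wild type at a catalytically competent ~5 A with the
# two displaced variants ~4 A further out; binding-enthalpy means reproduce
# the reported favorability ordering with a near-zero D152G-POR enthalpy.


def paper_like_occupancy_targets() -> dict[str, dict[tuple[str, int], float]]:
    """Per-structure hydrogen-bond occupancy targets (probability scale)."""
    return {
        "WT": {("MET", 384): 0.245, ("ILE", 385): 0.659, ("ILE", 383): 0.015},
        "R277L": {("MET", 384): 0.127, ("ILE", 385): 0.301, ("ILE", 383): 0.008},
        "R431H": {("MET", 493): 0.063, ("ILE", 494): 0.012},
        "D152G": {("TRP", 245): 0.108, ("MET", 493): 0.016, ("PHE", 240): 0.008},
    }


def paper_like_fe_c30_means() -> dict[str, float]:
    """Mean Fe-C30 distances (angstrom): WT-like pair vs ~4 A displaced pair."""
    return {"WT": 5.0, "R277L": 5.4, "R431H": 9.0, "D152G": 9.0}


def paper_like_lanosterol_binding() -> dict[str, float]:
    """True lanosterol binding enthalpies (kcal/mol), most favorable first."""
    return {"WT": -45.0, "R277L": -38.0, "R431H": -18.0, "D152G": -12.0}


def paper_like_por_binding() -> dict[str, float]:
    """True CYP51A1-POR binding enthalpies (kcal/mol); D152G near zero."""
    return {"WT": -60.0, "R431H": -40.0, "R277L": -20.0, "D152G": 0.0}
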