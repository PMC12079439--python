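"""Catalytic-competence audit of a candidate enzyme + docked substrate pose.

For a serine hydrolase to attack an ester, four things must hold: the
substrate's carbonyl carbon must sit close enough to the Ser nucleophile
(attack distance < 4 Å), backbone amide NH groups must be positioned to
stabilize the developing oxyanion, the Ser–His–Asp triad must be
hydrogen-bond connected, and the docked pose must fall inside a plausible
binding-energy window.  All criteria use heavy-atom geometry only — no
hydrogens are required.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .model_io import StructureModel, StructureError, read_structure

__all__ = [
    "LigandPose",
    "TriadAssignment",
    "AuditResult",
    "attack_distance",
    "find_oxyanion_donors",
    "triad_geometry",
    "energy_window_filter",
    "audit_active_site",
    "parse_pose_table",
    "annotate_ester_groups",
]

# heavy-atom covalent-bond cutoffs used for ester-group auto-annotation
_CO_BOND_MAX = 1.6  # Å, any C–O bond
_CARBONYL_MAX = 1.30  # Å, C=O double bond is ~1.23 Å; single C–O is ~1.34 Å


@dataclass
class LigandPose:
    """Docked small-molecule pose with annotated ester groups.

    ``ester_groups`` holds (carbonyl_C, carbonyl_O, ester_O) atom indices;
    ``binding_energy`` is the docking score in kcal/mol when available.
    """

    atoms: list[tuple[str, str, np.ndarray]]  # (label, element, coords Å)
    ester_groups: list[tuple[int, int, int]] = field(default_factory=list)
    binding_energy: float | None = None
    pose_id: str = ""

    def __post_init__(self) -> None:
        self.atoms = [(lab, el, np.asarray(xyz, dtype=float))
                      for lab, el, xyz in self.atoms]
        n = len(self.atoms)
        for ci, oi, ei in self.ester_groups:
            if not all(0 <= i < n for i in (ci, oi, ei)):
                raise ValueError(f"ester group ({ci},{oi},{ei}) indexes out of range")
            d = float(np.linalg.norm(self.atoms[ci][2] - self.atoms[oi][2]))
            if d >= _CO_BOND_MAX:
                raise ValueError(
                    f"ester group ({ci},{oi},{ei}): carbonyl C–O distance "
                    f"{d:.2f} Å is not a bond")

    def coords(self) -> np.ndarray:
        return np.array([xyz for _, _, xyz in self.atoms], dtype=float)


@dataclass
class TriadAssignment:
    """Residue keys and atom names for the Ser–His–Asp triad.

    The canonical arrangement is assumed: His NE2 faces the Ser nucleophile,
    His ND1 faces the Asp carboxylate.
    """

    ser: tuple[str, int]          # (chain, resnum)
    his: tuple[str, int]
    asp: tuple[str, int]
    ser_atom: str = "OG"
    his_atoms: tuple[str, str] = ("NE2", "ND1")  # (faces Ser, faces Asp)
    asp_atoms: tuple[str, str] = ("OD1", "OD2")

    def __post_init__(self) -> None:
        if len({tuple(self.ser), tuple(self.his), tuple(self.asp)}) != 3:
            raise ValueError("triad residues must be distinct")


@dataclass
class AuditResult:
    attack_distance: float
    oxyanion_donors: list[tuple[tuple[str, int, str], float]]
    triad_distances: dict[str, float]
    passes: dict[str, bool]

    @property
    def all_pass(self) -> bool:
        return all(self.passes.values())


def _ser_og(model: StructureModel, triad: TriadAssignment):
    chain, num = triad.ser
    return model.residue(chain, num).atom(triad.ser_atom)


def attack_distance(model: StructureModel, triad: TriadAssignment,
                    pose: LigandPose) -> float:
    """Minimum Ser Oγ → carbonyl-carbon distance over the pose's ester groups.

    The mechanism criterion passes when the value is strictly below 4 Å.
    """
    if not pose.ester_groups:
        raise ValueError("pose has no annotated ester groups")
    og = _ser_og(model, triad).coords
    dists = [float(np.linalg.norm(og - pose.atoms[ci][2]))
             for ci, _, _ in pose.ester_groups]
    return min(dists)


def find_oxyanion_donors(model: StructureModel, pose: LigandPose,
                         group_index: int = 0,
                         max_NO_dist: float = 3.5) -> list[tuple[tuple[str, int, str], float]]:
    """Backbone amide nitrogens close enough to the carbonyl O to form an oxyanion hole.

    Returns (residue key, N–O distance) pairs sorted by distance for every
    residue whose backbone N lies within ``max_NO_dist`` of the carbonyl
    oxygen of the selected ester group.
    """
    if not 0 <= group_index < len(pose.ester_groups):
        raise ValueError(f"invalid ester group index {group_index}")
    _, oi, _ = pose.ester_groups[group_index]
    carbonyl_o = pose.atoms[oi][2]
    donors = []
    for res in model.residues:
        if res.has_atom("N"):
            d = float(np.linalg.norm(res.atom("N").coords - carbonyl_o))
            if d <= max_NO_dist:
                donors.append((res.key, d))
    donors.sort(key=lambda x: x[1])
    return donors


def triad_geometry(model: StructureModel, triad: TriadAssignment,
                   hbond_max: float = 3.5) -> dict:
    """Ser Oγ–His NE2 and His ND1–Asp carboxylate distances with H-bond flags.

    The Asp side uses the nearer of the two carboxylate oxygens; a contact
    counts as hydrogen-bonded at ≤ ``hbond_max`` Å (heavy-atom criterion).
    """
    og = _ser_og(model, triad).coords
    hc, hn = triad.his
    his = model.residue(hc, hn)
    ne2 = his.atom(triad.his_atoms[0]).coords
    nd1 = his.atom(triad.his_atoms[1]).coords
    ac, an = triad.asp
    asp = model.residue(ac, an)
    d_asp = min(
        float(np.linalg.norm(nd1 - asp.atom(name).coords))
        for name in triad.asp_atoms if asp.has_atom(name)
    )
    d_ser = float(np.linalg.norm(og - ne2))
    return {
        "ser_OG_his_NE2": d_ser,
        "his_ND1_asp_O": d_asp,
        "hbonded": d_ser <= hbond_max and d_asp <= hbond_max,
    }


def energy_window_filter(energy: float, window: tuple[float, float] = (-4.0, 0.0)) -> bool:
    """True iff the docking energy lies in [low, high], inclusive at both ends."""
    low, high = window
    if not low < high:
        raise ValueError("window low must be < high")
    return low <= energy <= high


def audit_active_site(model: StructureModel, triad: TriadAssignment,
                      pose: LigandPose, *,
                      attack_dist_max: float = 4.0,
                      oxyanion_max_NO: float = 3.5,
                      min_donors: int = 2,
                      energy_window: tuple[float, float] = (-4.0, 0.0),
                      hbond_max: float = 3.5) -> AuditResult:
    """Full mechanism audit: attack distance, oxyanion hole, triad, energy."""
    d_attack = attack_distance(model, triad, pose)
    donors = find_oxyanion_donors(model, pose, 0, oxyanion_max_NO)
    triad_d = triad_geometry(model, triad, hbond_max)
    passes = {
        "attack_distance": d_attack < attack_dist_max,
        "oxyanion_hole": len(donors) >= min_donors,
        "triad_hbonds": bool(triad_d["hbonded"]),
    }
    if pose.binding_energy is not None:
        passes["energy_window"] = energy_window_filter(pose.binding_energy,
                                                       energy_window)
    return AuditResult(
        attack_distance=d_attack,
        oxyanion_donors=donors,
        triad_distances={k: triad_d[k] for k in ("ser_OG_his_NE2", "his_ND1_asp_O")},
        passes=passes,
    )


# ---------------------------------------------------------------------------
# Pose tables

def annotate_ester_groups(atoms: list[tuple[str, str, np.ndarray]]) -> list[tuple[int, int, int]]:
    """Detect ester groups C(=O)–O–C from element identities and distances.

    A carbon is an ester carbonyl carbon when it bonds one short C=O oxygen
    (< 1.30 Å) and one longer C–O oxygen (< 1.6 Å) that itself bonds another
    carbon.
    """
    coords = np.array([xyz for _, _, xyz in atoms], dtype=float)
    elements = [el.upper() for _, el, _ in atoms]
    groups: list[tuple[int, int, int]] = []
    for ci, el in enumerate(elements):
        if el != "C":
            continue
        o_neighbors = [(j, float(np.linalg.norm(coords[ci] - coords[j])))
                       for j, e in enumerate(elements)
                       if e == "O" and j != ci
                       and np.linalg.norm(coords[ci] - coords[j]) < _CO_BOND_MAX]
        carbonyls = [(j, d) for j, d in o_neighbors if d < _CARBONYL_MAX]
        singles = [(j, d) for j, d in o_neighbors if d >= _CARBONYL_MAX]
        if not carbonyls or not singles:
            continue
        carbonyl_o = min(carbonyls, key=lambda x: x[1])[0]
        for ester_o, _ in singles:
            # the bridging O must continue to a second carbon
            has_second_c = any(
                e == "C" and j != ci
                and np.linalg.norm(coords[ester_o] - coords[j]) < _CO_BOND_MAX
                for j, e in enumerate(elements))
            if has_second_c:
                groups.append((ci, carbonyl_o, ester_o))
                break
    return groups


def parse_pose_table(path: str | Path) -> list[LigandPose]:
    """Read a docking pose table (TSV: pose_id, energy_kcal_mol, ligand_pdb_path).

    Ligand coordinates are read from each pose's companion PDB (HETATM
    records); ester groups are auto-annotated from connectivity.  Poses are
    returned sorted by energy, most favourable first.
    """
    path = Path(path)
    poses: list[LigandPose] = []
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            ligand_path = Path(row["ligand_pdb_path"])
            if not ligand_path.is_absolute():
                ligand_path = path.parent / ligand_path
            if not ligand_path.exists():
                raise FileNotFoundError(
                    f"pose {row['pose_id']}: companion coordinates "
                    f"{ligand_path} not found")
            models = read_structure(ligand_path)
            atoms = [(a.name, a.element, a.coords)
                     for res in models[0].residues for a in res.atoms]
            groups = annotate_ester_groups(atoms)
            if not groups:
                import warnings
                warnings.warn(f"pose {row['pose_id']}: no ester pattern found; "
                              "annotation left empty")
            poses.append(LigandPose(
                atoms=atoms,
                ester_groups=groups,
                binding_energy=float(row["energy_kcal_mol"]),
                pose_id=row["pose_id"],
            ))
    poses.sort(key=lambda p: p.binding_energy)
    return poses
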