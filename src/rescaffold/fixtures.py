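"""Synthetic structures, poses, trajectories, sequences, and rate data.

Every screening operation in this package is testable without downloading
anything: the generators here build toy scaffolds with planted catalytic
triads at prescribed geometries, perturb structures to an exact target
RMSD, synthesize drifting trajectories, place ester ligands at controlled
attack distances, and draw Michaelis–Menten rate data with known truth.
All generators are pure functions of their parameters and a seed.

The toy scaffold is an ideal helical backbone with pseudo side-chain
atoms — geometrically well-formed but not physically realistic; it
exercises the screening arithmetic, not molecular mechanics.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .model_io import AtomRecord, ResidueRecord, StructureModel, write_fasta
from .active_site_audit import LigandPose, TriadAssignment, annotate_ester_groups
from .kinetics import KineticsDataset
from .motif_scaffold import kabsch_superpose, DEFAULT_BACKBONE_ATOMS
from .screening_pipeline import CandidateRecord

__all__ = [
    "ToyScaffoldParams",
    "make_toy_scaffold",
    "default_triad",
    "perturb_to_rmsd",
    "make_drift_trajectory",
    "make_pose_at_distance",
    "make_mm_dataset",
    "make_candidate_batch",
    "random_sequence",
]

_POLAR_RESNAMES = ("SER", "THR", "ASN", "GLN", "GLU", "LYS", "ARG", "GLY")

# helix geometry: 100°/residue turn, 1.5 Å rise, 2.3 Å Cα radius
_TURN = np.deg2rad(100.0)
_RISE = 1.5
_RADIUS = 2.3


@dataclass
class ToyScaffoldParams:
    """Parameters for the toy scaffold generator.

    ``triad_targets`` are the planted Ser Oγ–His NE2 and His ND1–Asp O
    distances in Å; ``planted_patch`` optionally converts a run of surface
    residues to a hydrophobic type (size, 3-letter resname).
    """

    n_residues: int = 30
    triad_targets: tuple[float, float] = (3.0, 2.8)
    planted_patch: tuple[int, str] | None = None
    seed: int = 0
    bfactor: float = 90.0

    def __post_init__(self) -> None:
        if self.n_residues < 20:
            raise ValueError("toy scaffold needs at least 20 residues")
        for t in self.triad_targets:
            if not 2.4 < t < 6.0:
                raise ValueError(f"triad target {t} Å outside (2.4, 6.0)")


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _helix_frames(n: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Cα positions, chain tangents, and outward radial unit vectors."""
    i = np.arange(n)
    ca = np.column_stack([_RADIUS * np.cos(_TURN * i),
                          _RADIUS * np.sin(_TURN * i),
                          _RISE * i])
    radial = np.column_stack([np.cos(_TURN * i), np.sin(_TURN * i),
                              np.zeros(n)])
    tangent = np.empty_like(ca)
    tangent[1:-1] = ca[2:] - ca[:-2]
    tangent[0] = ca[1] - ca[0]
    tangent[-1] = ca[-1] - ca[-2]
    tangent /= np.linalg.norm(tangent, axis=1, keepdims=True)
    return ca, tangent, radial


def _triad_indices(n: int) -> tuple[int, int, int]:
    return n // 6, n // 2, (5 * n) // 6


def make_toy_scaffold(params: ToyScaffoldParams) -> StructureModel:
    """Helical toy scaffold with a planted Ser–His–Asp pseudo-triad.

    Backbone N/CA/C/O atoms are placed on an ideal helix; Cβ pseudo-atoms
    point radially outward.  The triad side-chain atoms (Ser OG, His
    NE2/ND1, Asp OD1/OD2) are positioned so that triad_geometry recovers
    ``params.triad_targets`` exactly.  Deterministic under ``params.seed``.
    """
    rng = np.random.default_rng(params.seed)
    n = params.n_residues
    ca, tangent, radial = _helix_frames(n)
    si, hi, ai = _triad_indices(n)
    resnames = [str(rng.choice(_POLAR_RESNAMES)) for _ in range(n)]
    resnames[si], resnames[hi], resnames[ai] = "SER", "HIS", "ASP"
    if params.planted_patch is not None:
        size, patch_res = params.planted_patch
        start = min(n - size, ai + 2) if ai + 2 + size <= n else 1
        for k in range(start, start + size):
            if k not in (si, hi, ai):
                resnames[k] = patch_res

    residues: list[ResidueRecord] = []
    serial = 1

    def add(res_atoms, name, element, xyz):
        nonlocal serial
        res_atoms.append(AtomRecord(serial=serial, name=name, element=element,
                                    coords=np.asarray(xyz, dtype=float),
                                    bfactor=params.bfactor))
        serial += 1

    side_chain: dict[int, list[tuple[str, str, np.ndarray]]] = {}
    og = ca[si] + 2.4 * radial[si]
    u = _unit(ca[hi] - og)
    d1, d2 = params.triad_targets
    ne2 = og + d1 * u
    nd1 = ne2 + 2.2 * _unit(ca[ai] - ne2)
    w = _unit(radial[ai] + np.array([0.0, 0.0, 0.3]))
    od1 = nd1 + d2 * w
    od2 = nd1 + (d2 + 0.6) * _unit(w + 0.4 * tangent[ai])
    side_chain[si] = [("OG", "O", og)]
    side_chain[hi] = [("NE2", "N", ne2), ("ND1", "N", nd1)]
    side_chain[ai] = [("OD1", "O", od1), ("OD2", "O", od2)]

    for i in range(n):
        atoms: list[AtomRecord] = []
        add(atoms, "N", "N", ca[i] - 1.2 * tangent[i] - 0.5 * radial[i])
        add(atoms, "CA", "C", ca[i])
        add(atoms, "C", "C", ca[i] + 1.2 * tangent[i] - 0.4 * radial[i])
        add(atoms, "O", "O", ca[i] + 1.2 * tangent[i] - 0.4 * radial[i]
            + 1.23 * _unit(-radial[i] + 0.2 * tangent[i]))
        if resnames[i] != "GLY":
            add(atoms, "CB", "C", ca[i] + 1.53 * radial[i])
        for name, element, xyz in side_chain.get(i, []):
            add(atoms, name, element, xyz)
        residues.append(ResidueRecord(chain_id="A", resnum=i + 1, icode=" ",
                                      resname=resnames[i], atoms=atoms))
    return StructureModel(model_index=1, residues=residues,
                          provenance="synthetic")


def default_triad(model: StructureModel) -> TriadAssignment:
    """Triad assignment matching :func:`make_toy_scaffold`'s planted residues."""
    si, hi, ai = _triad_indices(len(model))
    return TriadAssignment(ser=("A", si + 1), his=("A", hi + 1),
                           asp=("A", ai + 1))


# ---------------------------------------------------------------------------
# Controlled-RMSD perturbation

def _copy_model(model: StructureModel) -> StructureModel:
    residues = []
    for r in model.residues:
        atoms = [AtomRecord(serial=a.serial, name=a.name, element=a.element,
                            coords=a.coords.copy(), bfactor=a.bfactor,
                            occupancy=a.occupancy) for a in r.atoms]
        residues.append(ResidueRecord(chain_id=r.chain_id, resnum=r.resnum,
                                      icode=r.icode, resname=r.resname,
                                      atoms=atoms))
    return StructureModel(model_index=model.model_index, residues=residues,
                          provenance=model.provenance)


def _measured_rmsd(model: StructureModel, displaced: StructureModel,
                   atoms: tuple[str, ...]) -> float:
    A = model.coords(atoms)
    B = displaced.coords(atoms)
    return kabsch_superpose(A, B).rmsd


def perturb_to_rmsd(model: StructureModel, target_rmsd: float, seed: int = 0,
                    atoms: tuple[str, ...] = DEFAULT_BACKBONE_ATOMS) -> StructureModel:
    """Displace a structure so its post-superposition RMSD hits a target.

    A random per-atom displacement field is projected orthogonal to the six
    rigid-body modes (net translation and infinitesimal rotation) and then
    scaled — with a bisection refinement on the actual post-superposition
    RMSD over ``atoms`` — until the measured value matches ``target_rmsd``
    within 1e-4 Å.  ``target_rmsd = 0`` returns an identical copy.
    """
    if target_rmsd < 0:
        raise ValueError("target RMSD must be non-negative")
    new = _copy_model(model)
    if target_rmsd == 0:
        return new
    rng = np.random.default_rng(seed)
    all_atoms = [a for r in new.residues for a in r.atoms]
    X = np.array([a.coords for a in all_atoms])
    D = rng.normal(size=X.shape)
    # remove rigid-body content: translations and infinitesimal rotations
    D -= D.mean(axis=0)
    Xc = X - X.mean(axis=0)
    for axis in np.eye(3):
        mode = np.cross(axis, Xc)
        mode_flat = mode.ravel()
        norm2 = mode_flat @ mode_flat
        if norm2 > 0:
            D -= ((D.ravel() @ mode_flat) / norm2) * mode
    scale_unit = float(np.sqrt((D ** 2).sum() / len(D)))
    D /= scale_unit  # unit "raw" RMSD over all atoms

    def apply(s: float) -> StructureModel:
        trial = _copy_model(model)
        for a, d in zip((a for r in trial.residues for a in r.atoms), D):
            a.coords = a.coords + s * d
        return trial

    def f(s: float) -> float:
        return _measured_rmsd(model, apply(s), atoms)

    lo, hi = 0.0, target_rmsd
    while f(hi) < target_rmsd:
        hi *= 2.0
        if hi > 1e4:
            raise RuntimeError("failed to bracket the target RMSD")
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if f(mid) < target_rmsd:
            lo = mid
        else:
            hi = mid
        if hi - lo < 1e-7:
            break
    s_final = 0.5 * (lo + hi)
    return apply(s_final)


def make_drift_trajectory(model: StructureModel, rmsd_schedule: list[float],
                          seed: int = 0) -> list[StructureModel]:
    """Trajectory whose frame-i Cα RMSD versus frame 0 follows a schedule.

    ``rmsd_schedule[0]`` must be 0 (the reference frame is unperturbed).
    """
    if not rmsd_schedule or rmsd_schedule[0] != 0:
        raise ValueError("rmsd_schedule must start at 0")
    frames = [_copy_model(model)]
    for i, r in enumerate(rmsd_schedule[1:], start=1):
        frame = perturb_to_rmsd(model, r, seed=seed + 7919 * i, atoms=("CA",))
        frame.model_index = i + 1
        frames.append(frame)
    return frames


# ---------------------------------------------------------------------------
# Ligand poses

# minimal ester fragment C3–C1(=O1)–O2–C2–C4 in a local frame (Å)
_ESTER_TEMPLATE: tuple[tuple[str, str, tuple[float, float, float]], ...] = (
    ("C1", "C", (0.00, 0.00, 0.00)),    # carbonyl carbon
    ("O1", "O", (0.00, 0.00, 1.23)),    # carbonyl oxygen
    ("O2", "O", (1.27, 0.00, -0.45)),   # bridging ester oxygen
    ("C2", "C", (2.47, 0.00, 0.25)),    # alkoxy carbon
    ("C3", "C", (-1.30, 0.60, -0.50)),  # acyl substituent
    ("C4", "C", (3.47, 1.00, 0.25)),    # alkoxy chain continuation
)


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
        [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
        [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
    ])


def make_pose_at_distance(model: StructureModel, triad: TriadAssignment,
                          d: float, seed: int = 0,
                          binding_energy: float | None = None,
                          clash_dist: float = 2.4,
                          max_attempts: int = 1000) -> LigandPose:
    """Place a 6-atom ester fragment with its carbonyl carbon exactly ``d`` Å
    from the Ser nucleophile oxygen, clash-free against the protein.

    The fragment is dropped along the outward direction from the protein
    centroid through the Ser Oγ (randomly re-oriented per attempt) until no
    protein heavy atom other than the targeted Oγ comes within
    ``clash_dist`` of any ligand atom.
    """
    if d <= 1.5:
        raise ValueError("attack distance must exceed 1.5 Å")
    chain, num = triad.ser
    og = model.residue(chain, num).atom(triad.ser_atom).coords
    prot = model.coords()
    centroid = prot.mean(axis=0)
    out_dir = _unit(og - centroid)
    template = np.array([xyz for _, _, xyz in _ESTER_TEMPLATE])
    rng = np.random.default_rng(seed)
    for attempt in range(max_attempts):
        direction = _unit(out_dir + 0.3 * rng.normal(size=3)) \
            if attempt else out_dir
        c1_target = og + d * direction
        R = _random_rotation(rng)
        coords = (template - template[0]) @ R.T + c1_target
        dists = np.linalg.norm(prot[None, :, :] - coords[:, None, :], axis=2)
        # exclude the intended C1–OG contact from the clash check
        og_idx = int(np.argmin(np.linalg.norm(prot - og, axis=1)))
        mask = np.ones_like(dists, dtype=bool)
        mask[0, og_idx] = False
        if dists[mask].min() >= clash_dist:
            atoms = [(label, el, coords[k])
                     for k, (label, el, _) in enumerate(_ESTER_TEMPLATE)]
            groups = annotate_ester_groups(atoms)
            return LigandPose(atoms=atoms, ester_groups=groups,
                              binding_energy=binding_energy,
                              pose_id=f"synthetic-d{d:g}")
    raise RuntimeError(f"no clash-free placement found in {max_attempts} attempts")


# ---------------------------------------------------------------------------
# Kinetics and sequences

def make_mm_dataset(vmax: float, km: float, substrate_grid,
                    noise_sd_frac: float = 0.0, seed: int = 0) -> KineticsDataset:
    """Michaelis–Menten rate data with multiplicative Gaussian noise.

    rates = vmax·S/(km+S) · (1 + ε), ε ~ N(0, noise_sd_frac²).  The
    generating truth is attached as ``dataset.truth``.
    """
    if vmax <= 0 or km <= 0:
        raise ValueError("vmax and km must be positive")
    S = np.asarray(substrate_grid, dtype=float)
    rng = np.random.default_rng(seed)
    v = vmax * S / (km + S)
    if noise_sd_frac > 0:
        v = np.clip(v * (1.0 + rng.normal(0.0, noise_sd_frac, size=S.shape)),
                    0.0, None)
    ds = KineticsDataset(substrate=S, rate=v)
    ds.truth = {"vmax": vmax, "km": km, "noise_sd_frac": noise_sd_frac,
                "seed": seed}
    return ds


def random_sequence(length: int, seed: int = 0,
                    alphabet: str = "ACDEFGHIKLMNPQRSTVWY") -> str:
    rng = np.random.default_rng(seed)
    return "".join(rng.choice(list(alphabet), size=length))


# ---------------------------------------------------------------------------
# Candidate batches with planted failures

def make_candidate_batch(seed: int = 0, n_pass: int = 6, n_low_plddt: int = 5,
                         n_high_rmsd: int = 4, n_bad_energy: int = 3,
                         n_unstable: int = 2,
                         n_pathology: int = 0) -> list[CandidateRecord]:
    """Candidate records with scores planted to fail specific screen stages.

    Passing candidates draw pLDDT in (75, 95), pTM in (0.75, 0.95), motif
    RMSD in (0.5, 2.0) Å, binding energy in (−3.5, −0.5) kcal/mol, attack
    distance in (3.0, 3.8) Å, two oxyanion donors, and trajectory RMSD in
    (2, 4) Å; each planted-failure group violates exactly one criterion.
    """
    rng = np.random.default_rng(seed)
    records: list[CandidateRecord] = []

    def base_scores() -> dict:
        return {
            "mean_plddt": float(rng.uniform(75, 95)),
            "ptm": float(rng.uniform(0.75, 0.95)),
            "motif_rmsd": float(rng.uniform(0.5, 2.0)),
            "binding_energy": float(rng.uniform(-3.5, -0.5)),
            "attack_distance": float(rng.uniform(3.0, 3.8)),
            "n_donors": 2,
            "traj_max_rmsd": float(rng.uniform(2.0, 4.0)),
        }

    def clean_seq() -> str:
        # alternating polar/hydrophobic pattern: no runs of any kind
        return "".join("LS"[i % 2] for i in range(150))

    def add(tag: str, count: int, mutate, sequence=None) -> None:
        for k in range(count):
            scores = base_scores()
            mutate(scores, rng)
            records.append(CandidateRecord(
                id=f"{tag}{k:02d}",
                sequence=sequence() if sequence else clean_seq(),
                scores=scores,
            ))

    add("ok", n_pass, lambda s, r: None)
    add("lowplddt", n_low_plddt,
        lambda s, r: s.update(mean_plddt=float(r.uniform(40, 65))))
    add("highrmsd", n_high_rmsd,
        lambda s, r: s.update(motif_rmsd=float(r.uniform(3.0, 6.0))))
    add("badenergy", n_bad_energy,
        lambda s, r: s.update(binding_energy=float(r.uniform(0.5, 3.0))))
    add("unstable", n_unstable,
        lambda s, r: s.update(traj_max_rmsd=float(r.uniform(5.5, 9.0))))
    add("repeats", n_pathology, lambda s, r: None,
        sequence=lambda: clean_seq()[:60] + "L" * 8 + clean_seq()[68:])
    return records


def write_fixture_set(out_dir: str | Path, seed: int = 0) -> dict[str, str]:
    """Write a complete on-disk fixture set (PDB/FASTA/CSV/TSV) for demos."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    from .model_io import write_structure
    written: dict[str, str] = {}

    scaffold = make_toy_scaffold(ToyScaffoldParams(n_residues=40, seed=seed))
    write_structure(scaffold, out_dir / "template.pdb")
    written["template"] = "template.pdb"

    design = perturb_to_rmsd(scaffold, 2.0, seed=seed + 1)
    write_structure(design, out_dir / "design_rmsd2.pdb")
    written["design"] = "design_rmsd2.pdb"

    frames = make_drift_trajectory(scaffold, [0, 1, 2, 3, 4], seed=seed + 2)
    write_structure(frames, out_dir / "trajectory.pdb")
    written["trajectory"] = "trajectory.pdb"

    pose = make_pose_at_distance(scaffold, default_triad(scaffold), 3.0,
                                 seed=seed + 3, binding_energy=-2.78)
    _write_pose(pose, out_dir / "pose.pdb")
    with open(out_dir / "poses.tsv", "w") as fh:
        fh.write("pose_id\tenergy_kcal_mol\tligand_pdb_path\n")
        fh.write(f"{pose.pose_id}\t{pose.binding_energy}\tpose.pdb\n")
    written["poses"] = "poses.tsv"

    seqs = {
        "clean": random_sequence(150, seed=seed + 4),
        "with_saar": random_sequence(60, seed=seed + 5) + "L" * 7
        + random_sequence(60, seed=seed + 6),
    }
    write_fasta(seqs, out_dir / "sequences.fasta")
    written["sequences"] = "sequences.fasta"

    ds = make_mm_dataset(0.55, 0.72, np.linspace(0.1, 5.0, 8),
                         noise_sd_frac=0.05, seed=seed + 7)
    with open(out_dir / "kinetics.csv", "w") as fh:
        fh.write("substrate_g_per_L,rate_uM_per_min\n")
        for s, v in zip(ds.substrate, ds.rate):
            fh.write(f"{s:.4f},{v:.6f}\n")
    written["kinetics"] = "kinetics.csv"
    return written


def _write_pose(pose: LigandPose, path: str | Path) -> None:
    """Write ligand atoms as PDB HETATM records."""
    with open(path, "w") as fh:
        for i, (label, el, xyz) in enumerate(pose.atoms, start=1):
            fh.write(
                f"HETATM{i:5d} {label:<4s} LIG A   1    "
                f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
                f"{1.00:6.2f}{0.00:6.2f}          {el:>2s}\n")
        fh.write("END\n")
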