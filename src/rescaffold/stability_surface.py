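"""Trajectory stability screening and surface hydrophobicity diagnostics.

Two screens live here.  The first tracks the global Cα RMSD of a candidate
along a molecular-dynamics trajectory (supplied as a multi-model PDB) and
discards designs that drift beyond a cutoff within the simulated horizon.
The second computes solvent-accessible surface area by Shrake–Rupley sphere
sampling and clusters exposed hydrophobic residues into surface patches —
the patches that, when large, mark a design as aggregation-prone and in
need of sequence refinement.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .model_io import StructureModel, StructureError
from .motif_scaffold import kabsch_superpose

__all__ = [
    "TrajectorySeries",
    "SASAResult",
    "HydrophobicPatch",
    "ca_rmsd_timecourse",
    "stability_filter",
    "shrake_rupley_sasa",
    "hydrophobic_patches",
    "VDW_RADII",
    "MAX_SASA",
    "HYDROPHOBIC_RESNAMES",
]

#: van der Waals radii (Å) by element symbol.
VDW_RADII: dict[str, float] = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80,
    "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98, "SE": 1.90,
}

#: Theoretical maximum SASA (Å²) per residue type (Tien et al. 2013,
#: theoretical values), used as the denominator for relative exposure.
MAX_SASA: dict[str, float] = {
    "ALA": 129.0, "ARG": 274.0, "ASN": 195.0, "ASP": 193.0, "CYS": 167.0,
    "GLN": 225.0, "GLU": 223.0, "GLY": 104.0, "HIS": 224.0, "ILE": 197.0,
    "LEU": 201.0, "LYS": 236.0, "MET": 224.0, "PHE": 240.0, "PRO": 159.0,
    "SER": 155.0, "THR": 172.0, "TRP": 285.0, "TYR": 263.0, "VAL": 174.0,
}

#: Aliphatic/aromatic residues counted as hydrophobic for patch detection.
#: Cys is excluded: its surface behaviour is dominated by disulfide chemistry.
HYDROPHOBIC_RESNAMES: frozenset[str] = frozenset(
    {"ALA", "VAL", "LEU", "ILE", "MET", "PHE", "TRP"})


@dataclass
class TrajectorySeries:
    """Cα RMSD vs a reference frame along a trajectory."""

    times: np.ndarray  # ns, strictly increasing
    rmsd: np.ndarray   # Å
    reference_index: int = 0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.rmsd = np.asarray(self.rmsd, dtype=float)
        if self.times.shape != self.rmsd.shape:
            raise ValueError("times and rmsd must have equal length")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if abs(self.rmsd[self.reference_index]) > 1e-8:
            raise ValueError("RMSD at the reference frame must be zero")


@dataclass
class SASAResult:
    """Per-residue solvent-accessible areas and relative exposures."""

    residue_keys: list[tuple[str, int, str]]
    per_residue_area: np.ndarray      # Å²
    relative_exposure: np.ndarray     # observed / theoretical max

    @property
    def total(self) -> float:
        return float(self.per_residue_area.sum())


@dataclass
class HydrophobicPatch:
    members: list[tuple[str, int, str]]
    total_area: float
    centroid: np.ndarray

    def __len__(self) -> int:
        return len(self.members)


# ---------------------------------------------------------------------------
# Trajectory stability

def ca_rmsd_timecourse(frames: list[StructureModel], reference_index: int = 0,
                       superpose: bool = True,
                       times: np.ndarray | None = None,
                       duration: float | None = None) -> TrajectorySeries:
    """Per-frame Cα RMSD against a reference frame.

    Frames must share residue count and ordering.  With ``superpose`` each
    frame is optimally superposed onto the reference before the RMSD is
    taken, so rigid tumbling does not register as drift.  Frame times come
    from ``times`` if given, else are spaced uniformly over ``duration``
    (default 20 ns).
    """
    if not frames:
        raise ValueError("empty trajectory")
    n_res = len(frames[0])
    cas = []
    for i, frame in enumerate(frames):
        if len(frame) != n_res:
            raise StructureError(
                f"frame {i} has {len(frame)} residues, expected {n_res}")
        ca = frame.coords(("CA",))
        if ca.shape[0] != n_res:
            raise StructureError(f"frame {i}: missing Cα atoms")
        cas.append(ca)
    ref = cas[reference_index]
    rmsds = np.empty(len(frames))
    for i, ca in enumerate(cas):
        if superpose:
            rmsds[i] = kabsch_superpose(ref, ca).rmsd
        else:
            rmsds[i] = float(np.sqrt(((ref - ca) ** 2).sum() / n_res))
    if times is None:
        total = 20.0 if duration is None else float(duration)
        times = np.linspace(0.0, total, len(frames))
    return TrajectorySeries(times=np.asarray(times, dtype=float), rmsd=rmsds,
                            reference_index=reference_index)


def stability_filter(series: TrajectorySeries, max_rmsd: float = 5.0,
                     horizon: float = 20.0) -> dict:
    """Stability gate: fail iff RMSD strictly exceeds ``max_rmsd`` at any
    time ≤ ``horizon`` ns.  Excursions after the horizon are ignored."""
    within = series.times <= horizon
    max_within = float(series.rmsd[within].max()) if within.any() else 0.0
    ok = max_within <= max_rmsd
    return {"pass": ok, "max_rmsd_within_horizon": max_within,
            "max_rmsd": max_rmsd, "horizon": horizon}


# ---------------------------------------------------------------------------
# SASA

def _sphere_points(n: int) -> np.ndarray:
    """Near-uniform points on the unit sphere (golden-spiral lattice)."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + 5.0 ** 0.5) * i
    return np.column_stack([np.sin(phi) * np.cos(theta),
                            np.sin(phi) * np.sin(theta),
                            np.cos(phi)])


def shrake_rupley_sasa(model: StructureModel, probe_radius: float = 1.4,
                       n_points: int = 960) -> SASAResult:
    """Solvent-accessible surface area by Shrake–Rupley sphere sampling.

    Each atom is expanded to radius r_vdw + probe and sampled with
    ``n_points`` near-uniform surface points; points falling inside any
    neighbouring expanded sphere are occluded.  The accessible area of an
    atom is the unoccluded fraction of its expanded-sphere area; residue
    areas are sums over their atoms.
    """
    coords = []
    radii = []
    res_index = []
    for ri, res in enumerate(model.residues):
        for a in res.atoms:
            r = VDW_RADII.get(a.element.upper())
            if r is None:
                raise StructureError(
                    f"no van der Waals radius for element {a.element!r}")
            coords.append(a.coords)
            radii.append(r + probe_radius)
            res_index.append(ri)
    coords = np.asarray(coords)
    radii = np.asarray(radii)
    res_index = np.asarray(res_index)

    unit = _sphere_points(n_points)
    tree = cKDTree(coords)
    rmax = radii.max()
    per_atom = np.empty(len(coords))
    for i in range(len(coords)):
        pts = coords[i] + radii[i] * unit
        neighbors = [j for j in tree.query_ball_point(coords[i], radii[i] + rmax)
                     if j != i]
        accessible = np.ones(n_points, dtype=bool)
        for j in neighbors:
            d2 = ((pts - coords[j]) ** 2).sum(axis=1)
            accessible &= d2 > radii[j] ** 2
        per_atom[i] = accessible.mean() * 4.0 * np.pi * radii[i] ** 2

    n_res = len(model.residues)
    per_res = np.zeros(n_res)
    np.add.at(per_res, res_index, per_atom)
    exposure = np.array([
        per_res[ri] / MAX_SASA[res.resname.upper()]
        if res.resname.upper() in MAX_SASA else np.nan
        for ri, res in enumerate(model.residues)
    ])
    return SASAResult(
        residue_keys=[r.key for r in model.residues],
        per_residue_area=per_res,
        relative_exposure=exposure,
    )


# ---------------------------------------------------------------------------
# Hydrophobic patches

def _linkage_atom(res) -> np.ndarray | None:
    """Side-chain-facing anchor: Cβ, falling back to Cα for glycine."""
    if res.has_atom("CB"):
        return res.atom("CB").coords
    if res.has_atom("CA"):
        return res.atom("CA").coords
    return None


def hydrophobic_patches(model: StructureModel, sasa: SASAResult,
                        hydrophobic_set: frozenset[str] = HYDROPHOBIC_RESNAMES,
                        exposure_min: float = 0.25,
                        link_dist: float = 8.0) -> list[HydrophobicPatch]:
    """Cluster exposed hydrophobic residues into surface patches.

    Residues whose type is hydrophobic and whose relative exposure is at
    least ``exposure_min`` are clustered by single linkage on Cβ–Cβ (Cα for
    Gly) distance ≤ ``link_dist``.  Patches are returned sorted by total
    area, largest first; each exposed residue belongs to exactly one patch.
    """
    if sasa.residue_keys != [r.key for r in model.residues]:
        raise ValueError("SASA result does not match the model")
    candidates = []
    for ri, res in enumerate(model.residues):
        if (res.resname.upper() in hydrophobic_set
                and np.isfinite(sasa.relative_exposure[ri])
                and sasa.relative_exposure[ri] >= exposure_min):
            anchor = _linkage_atom(res)
            if anchor is not None:
                candidates.append((ri, anchor))
    if not candidates:
        return []
    anchors = np.array([a for _, a in candidates])
    tree = cKDTree(anchors)
    pairs = tree.query_pairs(link_dist)
    # union-find single linkage
    parent = list(range(len(candidates)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in pairs:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb
    clusters: dict[int, list[int]] = {}
    for k in range(len(candidates)):
        clusters.setdefault(find(k), []).append(k)
    patches = []
    for members in clusters.values():
        res_ids = [candidates[m][0] for m in members]
        area = float(sasa.per_residue_area[res_ids].sum())
        centroid = anchors[members].mean(axis=0)
        patches.append(HydrophobicPatch(
            members=[model.residues[ri].key for ri in res_ids],
            total_area=area,
            centroid=centroid,
        ))
    patches.sort(key=lambda p: p.total_area, reverse=True)
    return patches
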