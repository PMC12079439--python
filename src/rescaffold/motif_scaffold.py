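"""Catalytic-motif extraction, contig specification, and motif-fidelity RMSD.

A design campaign keeps a handful of disconnected template segments — each
carrying one residue of the Ser–His–Asp catalytic triad — and asks a
generative model to rebuild everything in between.  This module defines the
kept-segment specification, emits the contig strings that drive external
inpainting, and measures how faithfully a design recapitulates the kept
motif backbone via optimal rigid-body (Kabsch) superposition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model_io import StructureModel, StructureError

__all__ = [
    "MotifSpec",
    "MotifCorrespondence",
    "SuperpositionResult",
    "extract_motif",
    "spec_summary",
    "kabsch_superpose",
    "motif_rmsd",
    "contig_string",
    "parse_contig",
    "static_quality_filter",
    "DEFAULT_BACKBONE_ATOMS",
]

DEFAULT_BACKBONE_ATOMS: tuple[str, ...] = ("N", "CA", "C", "O")

CATALYTIC_ROLES = ("nucleophile", "base", "acid")


@dataclass
class MotifSpec:
    """Kept template segments plus catalytic-triad role assignments.

    ``segments`` are inclusive (chain, start, end) residue ranges in author
    numbering; ``catalytic`` assigns each triad role (nucleophile = Ser,
    base = His, acid = Asp) to one residue inside some segment.
    """

    segments: list[tuple[str, int, int]]
    catalytic: list[tuple[str, str, int]]  # (role, chain, resnum)
    backbone_atoms: tuple[str, ...] = DEFAULT_BACKBONE_ATOMS

    def __post_init__(self) -> None:
        self.segments = [tuple(s) for s in self.segments]
        self.catalytic = [tuple(c) for c in self.catalytic]
        self.backbone_atoms = tuple(self.backbone_atoms)
        prev_end: dict[str, int] = {}
        for chain, start, end in self.segments:
            if end < start:
                raise ValueError(f"segment ({chain}, {start}, {end}) has end < start")
            if chain in prev_end and start <= prev_end[chain]:
                raise ValueError("segments must be sorted and non-overlapping")
            prev_end[chain] = end
        roles = [c[0] for c in self.catalytic]
        if sorted(roles) != sorted(CATALYTIC_ROLES):
            raise ValueError(
                f"catalytic roles must be exactly {CATALYTIC_ROLES}, got {roles}")
        for role, chain, resnum in self.catalytic:
            if not any(c == chain and s <= resnum <= e
                       for c, s, e in self.segments):
                raise ValueError(
                    f"catalytic residue ({role}) {chain}{resnum} lies outside "
                    "every kept segment")

    @property
    def retained_count(self) -> int:
        return sum(end - start + 1 for _, start, end in self.segments)

    def residue_keys(self) -> list[tuple[str, int, str]]:
        """All (chain, resnum, icode) keys covered by the segments, in order."""
        return [(chain, num, " ")
                for chain, start, end in self.segments
                for num in range(start, end + 1)]

    @classmethod
    def from_dict(cls, d: dict) -> "MotifSpec":
        return cls(
            segments=[tuple(s) for s in d["segments"]],
            catalytic=[tuple(c) for c in d["catalytic"]],
            backbone_atoms=tuple(d.get("backbone_atoms", DEFAULT_BACKBONE_ATOMS)),
        )

    def to_dict(self) -> dict:
        return {
            "segments": [list(s) for s in self.segments],
            "catalytic": [list(c) for c in self.catalytic],
            "backbone_atoms": list(self.backbone_atoms),
        }


@dataclass
class MotifCorrespondence:
    """Paired (template residue key, design residue key) lists, segment-ordered."""

    pairs: list[tuple[tuple[str, int, str], tuple[str, int, str]]]

    @classmethod
    def identity(cls, spec: MotifSpec) -> "MotifCorrespondence":
        """Design residues share the template's numbering (e.g. a perturbed copy)."""
        return cls([(k, k) for k in spec.residue_keys()])

    @classmethod
    def positional(cls, spec: MotifSpec,
                   design_segments: list[tuple[str, int, int]]) -> "MotifCorrespondence":
        """Map kept segments onto design segments of identical lengths, in order."""
        t_keys = spec.residue_keys()
        d_keys = [(chain, num, " ")
                  for chain, start, end in design_segments
                  for num in range(start, end + 1)]
        if len(t_keys) != len(d_keys):
            raise ValueError(
                f"design segments cover {len(d_keys)} residues, "
                f"template motif covers {len(t_keys)}")
        return cls(list(zip(t_keys, d_keys)))

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass
class SuperpositionResult:
    rotation: np.ndarray   # (3, 3), proper rotation (det = +1)
    translation: np.ndarray  # (3,), Å
    rmsd: float

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


def extract_motif(model: StructureModel, spec: MotifSpec) -> np.ndarray:
    """Backbone coordinates of the motif, one row per (residue, backbone atom).

    Rows are ordered by (segment, residue, backbone_atoms order), so two
    extractions with the same spec are in direct correspondence.
    """
    return _extract_keys(model, spec.residue_keys(), spec.backbone_atoms)


def _extract_keys(model: StructureModel, keys: list[tuple[str, int, str]],
                  atom_names: tuple[str, ...]) -> np.ndarray:
    rows = []
    missing = []
    for chain, num, icode in keys:
        try:
            res = model.residue(chain, num, icode)
        except StructureError:
            missing.append((chain, num, "residue absent"))
            continue
        for name in atom_names:
            if res.has_atom(name):
                rows.append(res.atom(name).coords)
            else:
                missing.append((chain, num, f"atom {name} absent"))
    if missing:
        raise StructureError(f"motif extraction failed: {missing}")
    return np.array(rows, dtype=float)


def spec_summary(spec: MotifSpec, template_length: int) -> dict:
    """Retained residue count and its integer percentage of the template length."""
    if template_length <= 0:
        raise ValueError("template_length must be positive")
    count = spec.retained_count
    if count > template_length:
        raise ValueError("motif covers more residues than the template has")
    return {
        "retained_count": count,
        "retained_percent": int(round(100.0 * count / template_length)),
    }


def kabsch_superpose(A: np.ndarray, B: np.ndarray) -> SuperpositionResult:
    """Optimal least-squares rigid superposition of B onto A (Kabsch).

    Returns the proper rotation R and translation t minimizing
    ``RMS(A - (R·B + t))`` together with that minimal RMSD.
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    if A.shape != B.shape or A.ndim != 2 or A.shape[1] != 3:
        raise ValueError(f"coordinate sets must share shape (n, 3); "
                         f"got {A.shape} vs {B.shape}")
    n = A.shape[0]
    if n < 3:
        raise ValueError("need at least 3 points for a unique superposition")
    ca, cb = A.mean(axis=0), B.mean(axis=0)
    A0, B0 = A - ca, B - cb
    H = B0.T @ A0
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = ca - R @ cb
    diff = A0 - B0 @ R.T
    rmsd = float(np.sqrt((diff ** 2).sum() / n))
    return SuperpositionResult(rotation=R, translation=t, rmsd=rmsd)


def motif_rmsd(template: StructureModel, design: StructureModel,
               spec: MotifSpec,
               correspondence: MotifCorrespondence | None = None) -> float:
    """Backbone RMSD between the kept template motif and its design counterpart.

    The correspondence defaults to identity numbering (design residues keep
    the template's keys); supply a positional correspondence when the design
    renumbers the kept segments.
    """
    if correspondence is None:
        correspondence = MotifCorrespondence.identity(spec)
    t_keys = [p[0] for p in correspondence.pairs]
    d_keys = [p[1] for p in correspondence.pairs]
    A = _extract_keys(template, t_keys, spec.backbone_atoms)
    B = _extract_keys(design, d_keys, spec.backbone_atoms)
    return kabsch_superpose(A, B).rmsd


# ---------------------------------------------------------------------------
# Contig strings

def contig_string(spec: MotifSpec, template_length: int,
                  target_length: tuple[int, int]) -> str:
    """Contig map for inpainting: kept segments alternating with gap ranges.

    Grammar: segment tokens ``A<start>-<end>`` (chain-letter prefixed) and
    gap tokens ``<gmin>-<gmax>``, joined by ``/``.  Gap ranges are sized so
    that the total design length over all minimal (maximal) gap choices
    equals ``target_length[0]`` (``target_length[1]``).  Gap budget is split
    across the template's intervening regions proportionally to their
    lengths, with a largest-remainder correction so the totals are exact.
    """
    tmin, tmax = target_length
    kept = spec.retained_count
    if tmin < kept:
        raise ValueError(
            f"infeasible budget: target min {tmin} < retained residues {kept}")
    if tmax < tmin:
        raise ValueError("target max must be >= target min")
    if tmax >= template_length:
        raise ValueError("target max must be shorter than the template")

    # gap slots: before first segment, between segments, after last
    slots: list[int] = []  # template lengths of each intervening region
    first_chain, first_start, _ = spec.segments[0]
    slots.append(first_start - 1)
    for (c1, s1, e1), (c2, s2, e2) in zip(spec.segments, spec.segments[1:]):
        slots.append(max(s2 - e1 - 1, 0))
    _, _, last_end = spec.segments[-1]
    slots.append(template_length - last_end)

    gmin = _apportion(tmin - kept, slots)
    gmax = _apportion(tmax - kept, slots)
    # a slot absent in the template never receives residues
    tokens: list[str] = []
    for i, (chain, start, end) in enumerate(spec.segments):
        if gmax[i] > 0:
            tokens.append(f"{gmin[i]}-{gmax[i]}")
        tokens.append(f"{chain}{start}-{end}")
    if gmax[-1] > 0:
        tokens.append(f"{gmin[-1]}-{gmax[-1]}")
    return "/".join(tokens)


def _apportion(total: int, weights: list[int]) -> list[int]:
    """Split ``total`` into integer parts proportional to ``weights`` (largest remainder)."""
    if total < 0:
        raise ValueError("cannot apportion a negative total")
    wsum = sum(weights)
    if wsum == 0:
        if total:
            raise ValueError("no gap slots available for a nonzero budget")
        return [0] * len(weights)
    raw = [total * w / wsum for w in weights]
    parts = [int(np.floor(x)) for x in raw]
    rem = total - sum(parts)
    order = sorted(range(len(raw)), key=lambda i: raw[i] - parts[i], reverse=True)
    for i in order[:rem]:
        parts[i] += 1
    return parts


def parse_contig(text: str) -> dict:
    """Parse a contig string back into segments and gap ranges.

    Returns ``{"segments": [(chain, start, end)], "gaps": [(gmin, gmax)],
    "min_total": int, "max_total": int}``.
    """
    segments: list[tuple[str, int, int]] = []
    gaps: list[tuple[int, int]] = []
    min_total = 0
    max_total = 0
    for token in text.split("/"):
        token = token.strip()
        if not token:
            continue
        if token[0].isalpha():
            chain = token[0]
            start_s, end_s = token[1:].split("-")
            start, end = int(start_s), int(end_s)
            segments.append((chain, start, end))
            min_total += end - start + 1
            max_total += end - start + 1
        else:
            lo_s, hi_s = token.split("-")
            lo, hi = int(lo_s), int(hi_s)
            gaps.append((lo, hi))
            min_total += lo
            max_total += hi
    return {"segments": segments, "gaps": gaps,
            "min_total": min_total, "max_total": max_total}


# ---------------------------------------------------------------------------
# Static quality gate

def static_quality_filter(candidate, config) -> dict:
    """Prediction-quality and motif-fidelity gate.

    A candidate passes iff mean pLDDT > ``plddt_min`` (strict), pTM >
    ``ptm_min`` (strict), and motif RMSD ≤ ``motif_rmsd_max`` (inclusive:
    designs are discarded only when the RMSD exceeds the cutoff).  The
    candidate may be any object with a ``scores`` mapping, or a mapping
    itself, carrying ``mean_plddt``, ``ptm``, and ``motif_rmsd``.
    """
    scores = candidate.scores if hasattr(candidate, "scores") else candidate
    required = ("mean_plddt", "ptm", "motif_rmsd")
    missing = [k for k in required if scores.get(k) is None]
    if missing:
        raise ValueError(f"incomplete candidate: missing scores {missing}")
    reasons = []
    if not scores["mean_plddt"] > config.plddt_min:
        reasons.append("plddt")
    if not scores["ptm"] > config.ptm_min:
        reasons.append("ptm")
    if not scores["motif_rmsd"] <= config.motif_rmsd_max:
        reasons.append("motif_rmsd")
    return {"pass": not reasons, "reasons": reasons}
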