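"""Multi-criteria triage of candidate enzyme designs.

Candidates move through the screen in the order the design campaign applies
them: static structural quality (prediction confidence + motif fidelity),
docking energy and active-site geometry, trajectory stability, and finally
sequence-pathology flags.  Each candidate accumulates a per-criterion
decision ledger and a terminal stage; the report tallies survivors per
stage.  By default a candidate that fails a stage is not evaluated further
(short-circuit); exhaustive mode scores everything for diagnostics.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from .model_io import StructureModel
from .motif_scaffold import (MotifSpec, kabsch_superpose, static_quality_filter,
                             DEFAULT_BACKBONE_ATOMS)
from .sequence_pathology import find_pathologies, HYDROPHOBIC_LETTERS

__all__ = [
    "ScreenConfig",
    "CandidateRecord",
    "ScreenReport",
    "run_screen",
    "size_metrics",
    "compare_backbones",
    "rank_candidates",
    "write_report",
]

STAGES = ("generated", "static_pass", "docked_pass", "stable_pass",
          "pathology_flagged", "accepted")


@dataclass
class ScreenConfig:
    """All thresholds of the screen, with the campaign's defaults.

    Prediction gates are strict (pLDDT > 70, pTM > 0.7); the motif-fidelity
    gate discards designs whose motif RMSD exceeds 2.5 Å; docked poses must
    fall in the −4 to 0 kcal/mol window with the scissile carbonyl carbon
    under 4 Å from the Ser nucleophile and at least two backbone NH oxyanion
    donors; trajectories may not exceed 5 Å Cα RMSD within 20 ns.
    """

    plddt_min: float = 70.0
    ptm_min: float = 0.7
    motif_rmsd_max: float = 2.5          # Å
    energy_window: tuple[float, float] = (-4.0, 0.0)  # kcal/mol
    attack_dist_max: float = 4.0         # Å
    min_oxyanion_donors: int = 2
    traj_rmsd_max: float = 5.0           # Å
    traj_horizon: float = 20.0           # ns
    # pathology parameters
    min_run: int = 5
    hydrophobic_set: frozenset[str] = HYDROPHOBIC_LETTERS
    exposure_min: float = 0.25
    link_dist: float = 8.0               # Å
    flank: int = 2
    # template metadata (for size metrics and motif comparison)
    template_path: str | None = None
    template_spec: MotifSpec | None = None
    template_length: int | None = None
    template_mw: float | None = None     # kDa
    exhaustive: bool = False

    def __post_init__(self) -> None:
        low, high = self.energy_window
        if not low < high:
            raise ValueError("energy window low must be < high")
        for name in ("plddt_min", "ptm_min", "motif_rmsd_max", "attack_dist_max",
                     "traj_rmsd_max", "traj_horizon"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        self.hydrophobic_set = frozenset(self.hydrophobic_set)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["hydrophobic_set"] = sorted(self.hydrophobic_set)
        d["energy_window"] = list(self.energy_window)
        if self.template_spec is not None:
            d["template_spec"] = self.template_spec.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ScreenConfig":
        d = dict(d)
        if "hydrophobic_set" in d:
            d["hydrophobic_set"] = frozenset(d["hydrophobic_set"])
        if "energy_window" in d:
            d["energy_window"] = tuple(d["energy_window"])
        if d.get("template_spec") is not None and not isinstance(
                d["template_spec"], MotifSpec):
            d["template_spec"] = MotifSpec.from_dict(d["template_spec"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ScreenConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class CandidateRecord:
    """One candidate design: its sequence, scores, and screening decisions."""

    id: str
    sequence: str = ""
    structure_path: str | None = None
    scores: dict[str, float | None] = field(default_factory=dict)
    decisions: dict[str, dict] = field(default_factory=dict)
    stage: str = "generated"
    error: str | None = None

    SCORE_KEYS = ("mean_plddt", "ptm", "motif_rmsd", "binding_energy",
                  "attack_distance", "n_donors", "traj_max_rmsd")


@dataclass
class ScreenReport:
    candidates: list[CandidateRecord]
    summary: dict[str, int]
    provenance: dict[str, Any]

    def accepted_ids(self) -> list[str]:
        return [c.id for c in self.candidates if c.stage == "accepted"]


def _stage_static(c: CandidateRecord, config: ScreenConfig) -> bool:
    decision = static_quality_filter(c, config)
    c.decisions["static"] = decision
    return decision["pass"]


def _stage_docking(c: CandidateRecord, config: ScreenConfig) -> bool:
    reasons = []
    e = c.scores.get("binding_energy")
    if e is None:
        raise ValueError(f"candidate {c.id}: missing binding_energy")
    low, high = config.energy_window
    if not low <= e <= high:
        reasons.append("energy_window")
    d = c.scores.get("attack_distance")
    if d is not None and not d < config.attack_dist_max:
        reasons.append("attack_distance")
    nd = c.scores.get("n_donors")
    if nd is not None and not nd >= config.min_oxyanion_donors:
        reasons.append("oxyanion_hole")
    decision = {"pass": not reasons, "reasons": reasons}
    c.decisions["docking"] = decision
    return decision["pass"]


def _stage_stability(c: CandidateRecord, config: ScreenConfig) -> bool:
    r = c.scores.get("traj_max_rmsd")
    if r is None:
        raise ValueError(f"candidate {c.id}: missing traj_max_rmsd")
    ok = r <= config.traj_rmsd_max
    c.decisions["stability"] = {
        "pass": ok, "reasons": [] if ok else ["traj_rmsd"]}
    return ok


def _stage_pathology(c: CandidateRecord, config: ScreenConfig) -> bool:
    runs = find_pathologies(c.sequence, config.hydrophobic_set, config.min_run) \
        if c.sequence else []
    clean = not runs
    c.decisions["pathology"] = {
        "pass": clean,
        "reasons": [] if clean else [f"{r.kind}:{r.start}-{r.end}" for r in runs],
    }
    return clean


_STAGE_FUNCS = (
    ("static", _stage_static, "static_pass"),
    ("docking", _stage_docking, "docked_pass"),
    ("stability", _stage_stability, "stable_pass"),
    ("pathology", _stage_pathology, "accepted"),
)


def run_screen(candidates: list[CandidateRecord],
               config: ScreenConfig) -> ScreenReport:
    """Apply the full screen to a candidate batch.

    Candidates are expected to carry their scores (computed upstream from
    structures, docking tables, and trajectories).  A candidate that raises
    at any stage is recorded as an errored row; the batch never aborts.
    A candidate surviving static, docking, and stability stages ends at
    ``accepted`` if its sequence is pathology-free, else at
    ``pathology_flagged`` (flagged designs are redesign inputs, not
    rejects).
    """
    for c in candidates:
        c.stage = "generated"
        c.decisions = {}
        c.error = None
        try:
            survived = True
            for name, func, stage_on_pass in _STAGE_FUNCS:
                ok = func(c, config)
                if ok and survived:
                    c.stage = stage_on_pass
                if not ok:
                    if name == "pathology" and survived:
                        c.stage = "pathology_flagged"
                    survived = False
                    if not config.exhaustive:
                        break
        except Exception as exc:  # noqa: BLE001 — errored rows must not abort the batch
            c.error = str(exc)
            c.stage = "generated"
    summary = {stage: sum(1 for c in candidates if _reached(c.stage, stage))
               for stage in STAGES}
    summary["errored"] = sum(1 for c in candidates if c.error is not None)
    return ScreenReport(
        candidates=list(candidates),
        summary=summary,
        provenance={"config_hash": config.hash(), "config": config.to_dict(),
                    "n_candidates": len(candidates)},
    )


def _reached(stage: str, query: str) -> bool:
    """Did a candidate at ``stage`` reach ``query``?

    ``pathology_flagged`` counts as having reached ``stable_pass`` (it
    survived the first three stages) but not ``accepted``.
    """
    order = {s: i for i, s in enumerate(
        ("generated", "static_pass", "docked_pass", "stable_pass", "accepted"))}
    eff = "stable_pass" if stage == "pathology_flagged" else stage
    if query == "pathology_flagged":
        return stage == "pathology_flagged"
    return order[eff] >= order[query]


def size_metrics(template_length: float, template_mw: float | None,
                 design_length: float, design_mw: float | None) -> dict:
    """Integer percent reductions in chain length and molecular weight.

    Percentages are rounded half away from zero.  A design larger than the
    template yields a negative (unrounded) reduction and a warning flag.
    """
    out: dict[str, float | int | bool] = {}

    def reduction(t: float, d: float) -> float:
        if t <= 0 or d <= 0:
            raise ValueError("sizes must be positive")
        return 100.0 * (t - d) / t

    def round_half_away(x: float) -> int:
        return int(np.sign(x) * np.floor(abs(x) + 0.5))

    r_len = reduction(template_length, design_length)
    out["len_reduction_pct"] = (round_half_away(r_len) if r_len >= 0 else r_len)
    out["len_grew"] = r_len < 0
    if template_mw is not None and design_mw is not None:
        r_mw = reduction(template_mw, design_mw)
        out["mw_reduction_pct"] = (round_half_away(r_mw) if r_mw >= 0 else r_mw)
        out["mw_grew"] = r_mw < 0
    return out


def compare_backbones(before: StructureModel, after: StructureModel,
                      atoms: tuple[str, ...] = DEFAULT_BACKBONE_ATOMS) -> float:
    """Full-chain backbone RMSD after optimal superposition.

    Used to check that a fixed-backbone sequence redesign did not move the
    fold: acceptance requires the value to stay at or below 1.0 Å.
    """
    if len(before) != len(after):
        raise ValueError(
            f"residue count mismatch: {len(before)} vs {len(after)}")
    A = before.coords(atoms)
    B = after.coords(atoms)
    if A.shape != B.shape:
        raise ValueError("backbone topology mismatch")
    return kabsch_superpose(A, B).rmsd


def rank_candidates(report: ScreenReport) -> list[str]:
    """Deterministic ranking: accepted first, then by motif RMSD ascending,
    binding energy ascending, mean pLDDT descending, id lexicographic."""
    def key(c: CandidateRecord):
        s = c.scores
        return (
            0 if c.stage == "accepted" else 1,
            s.get("motif_rmsd") if s.get("motif_rmsd") is not None else np.inf,
            s.get("binding_energy") if s.get("binding_energy") is not None else np.inf,
            -(s.get("mean_plddt") if s.get("mean_plddt") is not None else -np.inf),
            c.id,
        )
    return [c.id for c in sorted(report.candidates, key=key)]


def write_report(report: ScreenReport, out_dir: str | Path) -> None:
    """Write the report as a TSV table plus a JSON twin (thresholds included)."""
    import pandas as pd
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for c in report.candidates:
        row: dict[str, Any] = {"id": c.id, "stage": c.stage, "error": c.error}
        for k in CandidateRecord.SCORE_KEYS:
            row[k] = c.scores.get(k)
        for stage_name, d in c.decisions.items():
            row[f"{stage_name}_pass"] = d["pass"]
            row[f"{stage_name}_reasons"] = ";".join(d.get("reasons", []))
        rows.append(row)
    pd.DataFrame(rows).to_csv(out_dir / "screen_report.tsv", sep="\t",
                              index=False)
    payload = {
        "summary": report.summary,
        "provenance": report.provenance,
        "ranking": rank_candidates(report),
        "candidates": rows,
    }
    with open(out_dir / "screen_report.json", "w") as fh:
        json.dump(payload, fh, indent=2, default=str)
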