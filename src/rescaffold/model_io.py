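"""Structure and sequence I/O.

Parses PDB files into lightweight in-memory models, exposes per-residue
prediction confidence (pLDDT stored in the B-factor column of predicted
models), and computes basic sequence properties.  PDB parsing and writing
are delegated to :mod:`gemmi`; this module only defines the containers the
rest of the package operates on.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import gemmi
import numpy as np
from Bio.SeqUtils import molecular_weight

__all__ = [
    "AtomRecord",
    "ResidueRecord",
    "StructureModel",
    "ProteinSequence",
    "StructureError",
    "read_structure",
    "write_structure",
    "extract_sequence",
    "mean_plddt",
    "sequence_mass",
    "read_fasta",
    "write_fasta",
    "THREE_TO_ONE",
]

#: Standard 3-letter -> 1-letter amino-acid codes; anything else maps to "X".
THREE_TO_ONE: Mapping[str, str] = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}


class StructureError(ValueError):
    """Raised for malformed, empty, or internally inconsistent structures."""


@dataclass
class AtomRecord:
    """A single atom; ``bfactor`` carries per-residue pLDDT in predicted models."""

    serial: int
    name: str
    element: str
    coords: np.ndarray  # shape (3,), Å
    bfactor: float = 0.0
    occupancy: float = 1.0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise StructureError(f"atom {self.name!r}: coords must be a finite 3-vector")
        if not self.name:
            raise StructureError("atom name must be non-empty")


@dataclass
class ResidueRecord:
    chain_id: str
    resnum: int
    icode: str
    resname: str
    atoms: list[AtomRecord] = field(default_factory=list)

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.resnum, self.icode)

    @property
    def one_letter(self) -> str:
        return THREE_TO_ONE.get(self.resname.upper(), "X")

    def atom(self, name: str) -> AtomRecord:
        for a in self.atoms:
            if a.name == name:
                return a
        raise StructureError(
            f"residue {self.chain_id}{self.resnum}{self.icode.strip()} "
            f"({self.resname}) has no atom {name!r}"
        )

    def has_atom(self, name: str) -> bool:
        return any(a.name == name for a in self.atoms)


@dataclass
class StructureModel:
    """One atomic model: an ordered list of residues grouped by chain.

    ``provenance`` is one of ``{"predicted", "experimental", "synthetic"}``;
    only predicted models promise a meaningful pLDDT in the B-factor column.
    """

    model_index: int
    residues: list[ResidueRecord]
    provenance: str = "experimental"

    def __post_init__(self) -> None:
        if not self.residues:
            raise StructureError("a model must contain at least one residue")
        seen: set[tuple[str, int, str]] = set()
        for r in self.residues:
            if r.key in seen:
                raise StructureError(f"duplicate residue {r.key}")
            seen.add(r.key)

    def __len__(self) -> int:
        return len(self.residues)

    def chains(self) -> list[str]:
        out: list[str] = []
        for r in self.residues:
            if r.chain_id not in out:
                out.append(r.chain_id)
        return out

    def residue(self, chain_id: str, resnum: int, icode: str = " ") -> ResidueRecord:
        for r in self.residues:
            if r.key == (chain_id, resnum, icode):
                return r
        raise StructureError(f"residue ({chain_id}, {resnum}, {icode!r}) not found")

    def coords(self, atom_names: Iterable[str] | None = None) -> np.ndarray:
        """Stacked coordinates, optionally restricted to the named atoms."""
        rows = []
        names = tuple(atom_names) if atom_names is not None else None
        for r in self.residues:
            for a in r.atoms:
                if names is None or a.name in names:
                    rows.append(a.coords)
        return np.array(rows, dtype=float)


@dataclass
class ProteinSequence:
    """One-letter sequence plus a position -> (chain, resnum, icode) mapping."""

    letters: str
    numbering: list[tuple[str, int, str]]

    def __post_init__(self) -> None:
        if len(self.letters) != len(self.numbering):
            raise StructureError("letters and numbering must have equal length")

    def __len__(self) -> int:
        return len(self.letters)

    def position_of(self, chain_id: str, resnum: int, icode: str = " ") -> int:
        return self.numbering.index((chain_id, resnum, icode))


# ---------------------------------------------------------------------------
# PDB reading / writing

def _pick_altloc(atoms: list[gemmi.Atom]) -> gemmi.Atom:
    # highest occupancy wins; ties resolve to the first conformer encountered
    return max(atoms, key=lambda a: a.occ)


def read_structure(path: str | Path, format: str = "pdb",
                   provenance: str = "experimental") -> list[StructureModel]:
    """Read a (possibly multi-model) PDB file into StructureModel objects.

    One model is returned per MODEL/ENDMDL block; a file without MODEL
    records yields a single model.  B-factors are preserved verbatim.
    """
    if format != "pdb":
        raise ValueError(f"unsupported format {format!r}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        st = gemmi.read_pdb(str(path), split_chain_on_ter=False)
    except (RuntimeError, ValueError) as exc:
        raise StructureError(f"failed to parse {path}: {exc}") from exc

    models: list[StructureModel] = []
    for mi, gmodel in enumerate(st, start=1):
        residues: list[ResidueRecord] = []
        for chain in gmodel:
            for gres in chain:
                # group by name so an altloc pair collapses to one conformer
                by_name: dict[str, list[gemmi.Atom]] = {}
                for atom in gres:
                    by_name.setdefault(atom.name, []).append(atom)
                atoms = []
                for name, group in by_name.items():
                    a = _pick_altloc(group)
                    atoms.append(AtomRecord(
                        serial=a.serial,
                        name=name,
                        element=a.element.name,
                        coords=np.array([a.pos.x, a.pos.y, a.pos.z]),
                        bfactor=a.b_iso,
                        occupancy=a.occ,
                    ))
                icode = gres.seqid.icode if gres.seqid.icode.strip() else " "
                residues.append(ResidueRecord(
                    chain_id=chain.name,
                    resnum=gres.seqid.num,
                    icode=icode,
                    resname=gres.name,
                    atoms=atoms,
                ))
        if residues:
            models.append(StructureModel(model_index=mi, residues=residues,
                                         provenance=provenance))
    if not models:
        raise StructureError(f"{path}: no residues found")
    return models


def write_structure(models: StructureModel | list[StructureModel],
                    path: str | Path) -> None:
    """Write one or more models as a (multi-model) PDB file."""
    if isinstance(models, StructureModel):
        models = [models]
    st = gemmi.Structure()
    st.name = "rescaffold"
    for model in models:
        gmodel = gemmi.Model(model.model_index)
        chain_map: dict[str, gemmi.Chain] = {}
        for res in model.residues:
            if res.chain_id not in chain_map:
                chain_map[res.chain_id] = gemmi.Chain(res.chain_id)
            gres = gemmi.Residue()
            gres.name = res.resname
            gres.seqid = gemmi.SeqId(res.resnum, res.icode if res.icode.strip() else " ")
            for a in res.atoms:
                ga = gemmi.Atom()
                ga.name = a.name
                ga.serial = a.serial
                ga.element = gemmi.Element(a.element)
                ga.pos = gemmi.Position(*a.coords)
                ga.b_iso = a.bfactor
                ga.occ = a.occupancy
                gres.add_atom(ga)
            chain_map[res.chain_id].add_residue(gres)
        for chain in chain_map.values():
            gmodel.add_chain(chain)
        st.add_model(gmodel)
    st.setup_entities()
    st.write_pdb(str(path))


# ---------------------------------------------------------------------------
# Sequence operations

def extract_sequence(model: StructureModel, chain: str) -> ProteinSequence:
    """One-letter sequence of a chain in author residue order.

    Non-standard residues become ``"X"``; the numbering mapping is invertible
    because residue keys are unique within a model.
    """
    letters = []
    numbering = []
    for r in model.residues:
        if r.chain_id == chain:
            letters.append(r.one_letter)
            numbering.append(r.key)
    if not letters:
        raise StructureError(f"chain {chain!r} not found "
                             f"(have {model.chains()})")
    return ProteinSequence("".join(letters), numbering)


def mean_plddt(model: StructureModel) -> float:
    """Model-level pLDDT: arithmetic mean of Cα B-factors over all residues.

    Only meaningful for ``provenance == "predicted"`` models, where the
    B-factor column stores the per-residue confidence in [0, 100].
    """
    if model.provenance != "predicted":
        raise StructureError(
            f"mean_plddt requires a predicted model, got {model.provenance!r}")
    missing = [r.key for r in model.residues if not r.has_atom("CA")]
    if missing:
        raise StructureError(f"residues lacking a Cα atom: {missing}")
    return float(np.mean([r.atom("CA").bfactor for r in model.residues]))


def sequence_mass(seq: ProteinSequence | str) -> float:
    """Average molecular mass (Da) of a protein sequence: residue masses + one water."""
    letters = seq.letters if isinstance(seq, ProteinSequence) else seq
    if "X" in letters:
        raise StructureError("mass undefined: sequence contains 'X' residues")
    return float(molecular_weight(letters, seq_type="protein"))


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ordered {id: sequence} mapping."""
    from Bio import SeqIO
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(records: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i:i + 60] + "\n")
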