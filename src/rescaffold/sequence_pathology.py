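"""Detection of generative-model sequence artifacts and redesign masking.

Inpainting models tend to emit low-complexity stretches that native
proteins avoid: single-amino-acid repeats (SAAR, e.g. ``LLLLLLL``) and
uninterrupted hydrophobic runs (CHAA, e.g. ``LVVLV``).  Both correlate with
misfolding and poor expression.  This module finds such runs, summarizes
sequence hydrophobicity, and converts flagged positions — together with
surface-patch positions — into a redesign mask and contig string so the
offending stretches can be regenerated while the catalytic motif stays
untouched.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .model_io import ProteinSequence

__all__ = [
    "RunAnnotation",
    "RedesignMask",
    "find_saar",
    "find_chaa",
    "find_pathologies",
    "redesign_mask",
    "hydrophobic_fraction",
    "HYDROPHOBIC_LETTERS",
]

#: One-letter codes counted as hydrophobic (matches the residue-name set
#: used for surface-patch detection; Cys excluded).
HYDROPHOBIC_LETTERS: frozenset[str] = frozenset("AVLIMFW")

DEFAULT_MIN_RUN = 5


@dataclass
class RunAnnotation:
    """A maximal problematic run: half-open interval [start, end) of ``seq``."""

    kind: str  # "SAAR" or "CHAA"
    start: int
    end: int
    subsequence: str

    def __post_init__(self) -> None:
        if self.kind not in ("SAAR", "CHAA"):
            raise ValueError(f"unknown run kind {self.kind!r}")
        if len(self.subsequence) != self.end - self.start:
            raise ValueError("subsequence length does not match interval")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class RedesignMask:
    """Per-position keep/redesign decision plus the derived contig string."""

    keep: list[bool]
    contig: str
    protected: frozenset[int]
    warnings: list[str] = field(default_factory=list)


def _letters(seq: ProteinSequence | str) -> str:
    return seq.letters if isinstance(seq, ProteinSequence) else seq


def find_saar(seq: ProteinSequence | str,
              min_run: int = DEFAULT_MIN_RUN) -> list[RunAnnotation]:
    """Maximal single-amino-acid repeats of length ≥ ``min_run``."""
    if min_run < 2:
        raise ValueError("min_run must be at least 2")
    s = _letters(seq)
    runs = []
    i = 0
    while i < len(s):
        j = i
        while j < len(s) and s[j] == s[i]:
            j += 1
        if j - i >= min_run:
            runs.append(RunAnnotation("SAAR", i, j, s[i:j]))
        i = j
    return runs


def find_chaa(seq: ProteinSequence | str,
              hydrophobic_set: frozenset[str] = HYDROPHOBIC_LETTERS,
              min_run: int = DEFAULT_MIN_RUN) -> list[RunAnnotation]:
    """Maximal consecutive-hydrophobic runs of length ≥ ``min_run``.

    A run whose span is a homopolymer is reported by :func:`find_saar`
    instead and omitted here, so the two detectors never double-report the
    same interval.
    """
    if min_run < 2:
        raise ValueError("min_run must be at least 2")
    s = _letters(seq)
    runs = []
    i = 0
    while i < len(s):
        if s[i] in hydrophobic_set:
            j = i
            while j < len(s) and s[j] in hydrophobic_set:
                j += 1
            if j - i >= min_run and len(set(s[i:j])) > 1:
                runs.append(RunAnnotation("CHAA", i, j, s[i:j]))
            i = j
        else:
            i += 1
    return runs


def find_pathologies(seq: ProteinSequence | str,
                     hydrophobic_set: frozenset[str] = HYDROPHOBIC_LETTERS,
                     min_run: int = DEFAULT_MIN_RUN) -> list[RunAnnotation]:
    """All SAAR and CHAA runs, position-sorted, SAAR taking precedence."""
    runs = find_saar(seq, min_run) + find_chaa(seq, hydrophobic_set, min_run)
    runs.sort(key=lambda r: (r.start, r.end))
    return runs


def hydrophobic_fraction(seq: ProteinSequence | str,
                         hydrophobic_set: frozenset[str] = HYDROPHOBIC_LETTERS) -> float:
    """Fraction of positions carrying a hydrophobic letter."""
    s = _letters(seq)
    if not s:
        raise ValueError("empty sequence")
    return sum(c in hydrophobic_set for c in s) / len(s)


def redesign_mask(length: int, runs: list[RunAnnotation],
                  patch_positions: set[int] | frozenset[int] = frozenset(),
                  protected: set[int] | frozenset[int] = frozenset(),
                  flank: int = 2) -> RedesignMask:
    """Build a keep/redesign mask from flagged runs and surface patches.

    Every run interval and patch position, widened by ``flank`` on both
    sides and clipped to the sequence, is marked for redesign — except
    positions inside the protected (motif) set, which are always kept.  The
    derived contig uses fixed-length gaps (gap min = gap max = replaced
    stretch length) so regeneration preserves overall length.
    """
    bad = [i for i in patch_positions if not 0 <= i < length]
    bad += [i for i in protected if not 0 <= i < length]
    if bad:
        raise IndexError(f"positions out of range: {sorted(set(bad))}")
    keep = [True] * length
    for run in runs:
        if run.start < 0 or run.end > length:
            raise IndexError(f"run [{run.start}, {run.end}) out of range")
        for i in range(max(run.start - flank, 0), min(run.end + flank, length)):
            keep[i] = False
    for p in patch_positions:
        for i in range(max(p - flank, 0), min(p + flank + 1, length)):
            keep[i] = False
    warnings = []
    for p in sorted(protected):
        if not keep[p]:
            keep[p] = True
            warnings.append(
                f"position {p} flagged for redesign but protected by the motif")
    contig = _mask_to_contig(keep)
    return RedesignMask(keep=keep, contig=contig,
                        protected=frozenset(protected), warnings=warnings)


def _mask_to_contig(keep: list[bool]) -> str:
    """Alternating kept segments (1-based, chain A) and fixed-length gaps."""
    tokens = []
    i = 0
    n = len(keep)
    while i < n:
        j = i
        while j < n and keep[j] == keep[i]:
            j += 1
        if keep[i]:
            tokens.append(f"A{i + 1}-{j}")
        else:
            tokens.append(f"{j - i}-{j - i}")
        i = j
    return "/".join(tokens)
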