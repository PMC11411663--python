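"""Reading PDB structures and reducing residues to effective atoms.

The model operates on one pseudo-atom per residue — the *effective atom* —
placed at the unweighted mean position of the residue's heavy atoms
(backbone and side chain alike).  This module parses PDB text, selects a
structural unit (a chain, or a CATH-style author-numbered residue range
within a chain) and produces the ordered list of effective-atom centroids
together with the one-letter sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import gemmi
import numpy as np

__all__ = [
    "AtomRecord",
    "UnitSelector",
    "ResidueCentroid",
    "EffectiveAtomSet",
    "PdbParseError",
    "SelectionError",
    "THREE_TO_ONE",
    "read_structure",
    "effective_atoms",
    "extract_sequence",
]


class PdbParseError(ValueError):
    """Raised when PDB text cannot be parsed into polymer atoms."""


class SelectionError(ValueError):
    """Raised when a unit selector does not resolve to a usable residue set."""


#: Standard 20 amino acids, three-letter -> one-letter.
THREE_TO_ONE: Mapping[str, str] = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}


@dataclass(frozen=True)
class AtomRecord:
    """One heavy-atom coordinate record from a PDB ATOM line."""

    chain_id: str
    residue_number: int
    insertion_code: str  # "" when absent
    residue_name: str
    atom_name: str
    element: str
    position: np.ndarray  # shape (3,), Angstrom

    @property
    def is_standard(self) -> bool:
        return self.residue_name in THREE_TO_ONE


@dataclass(frozen=True)
class UnitSelector:
    """Structural-unit selector: a chain, optionally restricted to an
    author-numbered inclusive residue range (CATH convention)."""

    chain_id: str
    residue_range: Optional[tuple[int, int]] = None

    def __post_init__(self) -> None:
        if self.residue_range is not None:
            start, end = self.residue_range
            if start > end:
                raise ValueError(f"selector range start {start} > end {end}")

    @classmethod
    def parse(cls, text: str) -> "UnitSelector":
        """Parse ``"A"`` or ``"A:12-58"`` selector strings."""
        text = text.strip()
        if ":" not in text:
            if not text:
                raise ValueError("empty selector")
            return cls(chain_id=text)
        chain, _, rng = text.partition(":")
        if not chain:
            raise ValueError(f"selector {text!r}: missing chain id")
        try:
            start_s, _, end_s = rng.partition("-")
            start, end = int(start_s), int(end_s)
        except ValueError as exc:
            raise ValueError(f"selector {text!r}: bad range {rng!r}") from exc
        return cls(chain_id=chain, residue_range=(start, end))

    def __str__(self) -> str:
        if self.residue_range is None:
            return self.chain_id
        return f"{self.chain_id}:{self.residue_range[0]}-{self.residue_range[1]}"


@dataclass(frozen=True)
class ResidueCentroid:
    residue_id: str  # e.g. "A:17" or "A:17B" with insertion code
    one_letter: str
    centroid: np.ndarray  # shape (3,)


@dataclass
class EffectiveAtomSet:
    """Ordered per-residue effective atoms of one structural unit."""

    residues: list[ResidueCentroid]
    unit_label: str = ""

    def __post_init__(self) -> None:
        if len(self.residues) < 2:
            raise ValueError("an effective-atom set needs at least 2 residues")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite centroid coordinates")

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def coords(self) -> np.ndarray:
        """(N, 3) array of centroid coordinates in chain order."""
        return np.asarray([r.centroid for r in self.residues], dtype=float)

    @property
    def sequence(self) -> str:
        return "".join(r.one_letter for r in self.residues)


def read_structure(pdb_text: str) -> list[AtomRecord]:
    """Parse PDB text into heavy-atom records of the first model.

    HETATM records and waters are excluded; alternate locations are
    resolved to the highest-occupancy conformer (ties broken by file
    order).  Raises :class:`PdbParseError` on empty or garbled input,
    naming the first offending line.
    """
    lines = [ln for ln in pdb_text.splitlines() if ln.strip()]
    if not lines:
        raise PdbParseError("empty PDB text")
    if not any(ln.startswith("ATOM") for ln in lines):
        if any(ln.startswith("HETATM") for ln in lines):
            raise PdbParseError("no polymer atoms (only HETATM records present)")
        raise PdbParseError(f"not PDB format; first line: {lines[0][:60]!r}")

    try:
        structure = gemmi.read_pdb_string(pdb_text)
    except (RuntimeError, ValueError) as exc:  # gemmi reports the line itself
        raise PdbParseError(f"PDB parse failure: {exc}") from exc
    if len(structure) == 0:
        raise PdbParseError("no models in structure")

    records: list[AtomRecord] = []
    model = structure[0]  # first model only (NMR ensembles)
    for chain in model:
        for residue in chain:
            if residue.het_flag != "A" or residue.is_water():
                continue
            # altloc: keep highest occupancy per atom name, ties -> first seen
            best: dict[str, gemmi.Atom] = {}
            for atom in residue:
                if atom.is_hydrogen():
                    continue
                prev = best.get(atom.name)
                if prev is None or atom.occ > prev.occ:
                    best[atom.name] = atom
            for atom in best.values():
                records.append(AtomRecord(
                    chain_id=chain.name,
                    residue_number=residue.seqid.num,
                    insertion_code=(residue.seqid.icode or "").strip(),
                    residue_name=residue.name,
                    atom_name=atom.name,
                    element=atom.element.name,
                    position=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                ))
    if not records:
        raise PdbParseError("no polymer atoms")
    return records


def effective_atoms(atoms: Sequence[AtomRecord], sel: UnitSelector,
                    nonstandard_letters: Optional[Mapping[str, str]] = None,
                    ) -> EffectiveAtomSet:
    """Reduce the selected residues to effective atoms.

    Each selected residue contributes one centroid: the unweighted mean of
    its heavy-atom positions.  Residues are ordered by
    (residue_number, insertion_code).  ``nonstandard_letters`` may extend
    the residue-name mapping (e.g. ``{"MSE": "M"}``); unmapped
    non-standard residues become ``'X'``.
    """
    mapping = dict(THREE_TO_ONE)
    if nonstandard_letters:
        mapping.update(nonstandard_letters)

    groups: dict[tuple[int, str], list[AtomRecord]] = {}
    for atom in atoms:
        if atom.chain_id != sel.chain_id:
            continue
        if sel.residue_range is not None:
            lo, hi = sel.residue_range
            if not (lo <= atom.residue_number <= hi):
                continue
        groups.setdefault((atom.residue_number, atom.insertion_code), []).append(atom)

    if len(groups) < 2:
        raise SelectionError(
            f"selector {sel} matches {len(groups)} residue(s); need at least 2")

    residues = []
    for (num, icode) in sorted(groups):
        members = groups[(num, icode)]
        if not members:
            raise SelectionError(f"residue {sel.chain_id}:{num}{icode} has no heavy atoms")
        centroid = np.mean([a.position for a in members], axis=0)
        letter = mapping.get(members[0].residue_name, "X")
        residues.append(ResidueCentroid(
            residue_id=f"{sel.chain_id}:{num}{icode}",
            one_letter=letter,
            centroid=centroid,
        ))
    return EffectiveAtomSet(residues=residues, unit_label=str(sel))


def extract_sequence(eas: EffectiveAtomSet) -> str:
    """One-letter sequence of the unit, 'X' for non-standard residues."""
    return eas.sequence
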