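"""Intrinsic residue hydrophobicity scales.

The model is scale-agnostic: any table mapping the 20 standard amino
acids to non-negative intrinsic hydrophobicities works, because both the
observed and theoretical profiles are normalized to probability
distributions.  The packaged default is the Kyte–Doolittle hydropathy
index min–max rescaled to [0, 1] (so arginine, the most polar residue,
sits at 0 and isoleucine at 1).  Custom scales load from a two-column
TSV (one-letter code, value; '#' comments).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

__all__ = ["HydrophobicityScale", "kyte_doolittle_normalized", "load_scale_tsv"]

STANDARD_LETTERS = "ACDEFGHIKLMNPQRSTVWY"

_KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}


@dataclass(frozen=True)
class HydrophobicityScale:
    """Residue type -> intrinsic hydrophobicity H^r (dimensionless, >= 0)."""

    values: Mapping[str, float]
    name: str = "custom"
    default: float = 0.0  # used for non-standard residues ('X')

    def __post_init__(self) -> None:
        missing = [a for a in STANDARD_LETTERS if a not in self.values]
        if missing:
            raise ValueError(f"scale {self.name!r} missing residues: {missing}")
        arr = np.array(list(self.values.values()), dtype=float)
        if not np.all(np.isfinite(arr)) or np.any(arr < 0):
            raise ValueError(f"scale {self.name!r} has negative or non-finite values")

    def __getitem__(self, letter: str) -> float:
        return float(self.values.get(letter, self.default))

    def lookup(self, sequence: str) -> np.ndarray:
        """Per-residue H^r vector for a one-letter sequence."""
        return np.array([self[a] for a in sequence], dtype=float)


def kyte_doolittle_normalized() -> HydrophobicityScale:
    """Kyte–Doolittle hydropathy rescaled linearly onto [0, 1]."""
    lo = min(_KYTE_DOOLITTLE.values())
    hi = max(_KYTE_DOOLITTLE.values())
    values = {a: (v - lo) / (hi - lo) for a, v in _KYTE_DOOLITTLE.items()}
    return HydrophobicityScale(values=values, name="kyte-doolittle-01")


def load_scale_tsv(path: str | Path, name: str | None = None) -> HydrophobicityScale:
    """Load a scale from a 2-column TSV (one-letter code, value)."""
    path = Path(path)
    values: dict[str, float] = {}
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 2 or len(parts[0]) != 1:
            raise ValueError(f"{path}:{lineno}: expected '<letter>\\t<value>', got {raw!r}")
        values[parts[0].upper()] = float(parts[1])
    return HydrophobicityScale(values=values, name=name or path.stem)
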