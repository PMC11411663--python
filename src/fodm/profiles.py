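"""The three per-residue hydrophobicity distributions of the model.

* **T** (theoretical): a 3D Gaussian spanning the oriented molecule,
  evaluated at each effective atom — the idealized micelle-like field
  with a central hydrophobic core decaying to zero at the surface.
* **O** (observed): the hydrophobicity actually collected at each
  residue from pairwise hydrophobic interactions with its neighbours,
  using Levitt's polynomial contact function with a 9 A cutoff.
* **R** (random/uniform): 1/N per residue — no core at all.

All three are normalized to sum to one so they can be compared with
divergence entropy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .orientation import GaussianSigmas, OrientedSet
from .scales import HydrophobicityScale
from .structure_io import EffectiveAtomSet

__all__ = [
    "Profile",
    "DegenerateProfileError",
    "DEFAULT_CUTOFF",
    "levitt_g",
    "normalize",
    "theoretical_profile",
    "observed_profile",
    "uniform_profile",
]

#: Levitt's hydrophobic-interaction cutoff, Angstrom.
DEFAULT_CUTOFF = 9.0


class DegenerateProfileError(ValueError):
    """Raised when a raw profile sums to zero (no information content)."""


@dataclass(frozen=True)
class Profile:
    """Non-negative per-residue vector normalized to sum 1.

    ``role`` records which distribution it is: "T", "O", "R" or "M".
    """

    values: np.ndarray
    role: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.ndim != 1 or len(v) < 2:
            raise ValueError("a profile needs at least 2 entries")
        if np.any(v < 0) or not np.all(np.isfinite(v)):
            raise ValueError("profile values must be finite and non-negative")
        if abs(v.sum() - 1.0) > 1e-12:
            raise ValueError(f"profile ({self.role}) sums to {v.sum()}, expected 1")

    def __len__(self) -> int:
        return len(self.values)

    def __array__(self, dtype=None, copy=None) -> np.ndarray:
        return np.asarray(self.values, dtype=dtype)


def normalize(raw: np.ndarray, role: str = "") -> Profile:
    """Normalize a non-negative raw vector to a probability profile."""
    raw = np.asarray(raw, dtype=float)
    if np.any(raw < 0):
        raise ValueError("raw profile has negative entries")
    total = raw.sum()
    if total <= 0:
        raise DegenerateProfileError(f"degenerate {role or 'profile'}: sum is zero")
    v = raw / total
    return Profile(values=v / v.sum(), role=role)  # second pass pins sum at 1


def levitt_g(x: np.ndarray | float) -> np.ndarray | float:
    """Levitt's interaction fall-off on the scaled distance x = r/c.

    g(x) = 1 - 1/2 (7x^2 - 9x^4 + 5x^6 - x^8); g(0) = 1, g(1) = 0,
    and g = 0 beyond the cutoff (x > 1).
    """
    x = np.asarray(x, dtype=float)
    x2 = x * x
    g = 1.0 - 0.5 * (7.0 * x2 - 9.0 * x2**2 + 5.0 * x2**3 - x2**4)
    return np.where(x <= 1.0, g, 0.0)


def theoretical_profile(os_: OrientedSet, s: GaussianSigmas) -> Profile:
    """Micelle-like reference T: the 3D Gaussian at each effective atom."""
    z = os_.coords / s.as_array()
    raw = np.exp(-0.5 * np.sum(z * z, axis=1))
    return normalize(raw, role="T")


def observed_profile(eas: EffectiveAtomSet | OrientedSet,
                     scale: HydrophobicityScale | np.ndarray,
                     cutoff_c: float = DEFAULT_CUTOFF) -> Profile:
    """Observed hydrophobicity O from pairwise Levitt interactions.

    raw_i = sum over j != i with r_ij <= c of (H_i + H_j) * g(r_ij / c).
    ``scale`` is either a :class:`HydrophobicityScale` (looked up on the
    unit's sequence) or a ready per-residue H^r array.
    """
    if cutoff_c <= 0:
        raise ValueError("cutoff must be positive")
    if isinstance(scale, HydrophobicityScale):
        h = scale.lookup(eas.sequence)
    else:
        h = np.asarray(scale, dtype=float)
        if h.shape != (len(eas),):
            raise ValueError(f"per-residue hydrophobicity length {h.shape} != {len(eas)} residues")
    d = squareform(pdist(eas.coords))
    g = np.asarray(levitt_g(d / cutoff_c))
    np.fill_diagonal(g, 0.0)  # self-term excluded: interactions are pairwise
    raw = np.sum((h[:, None] + h[None, :]) * g, axis=1)
    return normalize(raw, role="O")


def uniform_profile(n: int) -> Profile:
    """Uniform reference R: every residue equally likely hydrophobic."""
    if n < 2:
        raise ValueError("uniform profile needs n >= 2")
    return Profile(values=np.full(n, 1.0 / n), role="R")
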