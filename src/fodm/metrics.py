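"""Divergence statistics: D_KL, RD, the K-modified field M, and RD_FR.

The accordance of the observed distribution O with the micelle-like
reference T is judged against a second, structure-free reference R
(uniform) through the relative distance

    RD = D_KL(O|T) / (D_KL(O|T) + D_KL(O|R)),

with RD < 0.5 read as the presence of a hydrophobic core.  Environments
other than bulk water are modelled by blending T with its complement:

    M_i ∝ T_i + K (T_max − T_i),

where K >= 0 measures how far the effective folding field departs from
the aqueous one; K is estimated by minimizing D_KL(O|M) over a grid.
Fragment status (RD_FR) repeats the RD computation on a contiguous
slice of O and T, each renormalized, against a uniform reference of the
fragment's length.

Divergences are reported in bits (base-2 logarithm).  RD and the fitted
K are invariant to the logarithm base.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .profiles import Profile, normalize, uniform_profile

__all__ = [
    "FodResult",
    "FragmentSpec",
    "kl_divergence",
    "relative_distance",
    "m_profile",
    "fit_k",
    "fragment_rd",
    "DEFAULT_K_MAX",
    "DEFAULT_K_STEP",
]

DEFAULT_K_MAX = 5.0
DEFAULT_K_STEP = 0.01


@dataclass(frozen=True)
class FodResult:
    """Unit-level outcome of the analysis."""

    rd: float
    dkl_ot: float
    dkl_or: float
    k_hat: float
    dkl_om: float
    unit_label: str = ""
    n_residues: int = 0

    def to_dict(self) -> dict:
        return {
            "unit": self.unit_label,
            "n_residues": self.n_residues,
            "rd": self.rd,
            "dkl_ot": self.dkl_ot,
            "dkl_or": self.dkl_or,
            "k_hat": self.k_hat,
            "dkl_om": self.dkl_om,
        }


@dataclass(frozen=True)
class FragmentSpec:
    """A contiguous fragment: 0-based half-open [start, end) positions
    into the unit's residue order, with an optional expected sequence."""

    start: int
    end: int
    sequence: Optional[str] = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"bad fragment bounds [{self.start}, {self.end})")
        if self.end - self.start < 2:
            raise ValueError("fragment must span at least 2 residues")

    def __len__(self) -> int:
        return self.end - self.start


def kl_divergence(p: Profile | np.ndarray, q: Profile | np.ndarray) -> float:
    """Divergence entropy D_KL(p|q) = sum p_i log2(p_i / q_i), in bits.

    0 * log(0/q) is taken as 0; p_i > 0 where q_i = 0 is an error
    (unsupported support).
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError(f"length mismatch: {p.shape} vs {q.shape}")
    mask = p > 0
    if np.any(q[mask] <= 0):
        raise ValueError("unsupported support: p_i > 0 where q_i = 0")
    return float(np.sum(p[mask] * np.log2(p[mask] / q[mask])))


def relative_distance(o: Profile, t: Profile, r: Profile) -> float:
    """RD = D(o|t) / (D(o|t) + D(o|r)); 0.5 (with warning) when both vanish."""
    d_ot = kl_divergence(o, t)
    d_or = kl_divergence(o, r)
    denom = d_ot + d_or
    if denom == 0.0:
        warnings.warn("o, t and r coincide; RD undefined, reporting 0.5")
        return 0.5
    return d_ot / denom


def m_profile(t: Profile, k: float) -> Profile:
    """Environment-modified field: normalize(T_i + K (T_max − T_i))."""
    if k < 0:
        raise ValueError("K must be non-negative")
    t_arr = np.asarray(t, dtype=float)
    raw = t_arr + k * (t_arr.max() - t_arr)
    return normalize(raw, role="M")


def fit_k(o: Profile, t: Profile,
          k_max: float = DEFAULT_K_MAX,
          k_step: float = DEFAULT_K_STEP) -> tuple[float, float]:
    """Grid search for the K minimizing D_KL(O|M).

    Returns (k_hat, attained D_KL(O|M)).  Ties resolve to the smallest K;
    a minimum attained at k_max triggers a truncation warning.
    """
    if k_max <= 0 or k_step <= 0:
        raise ValueError("k_max and k_step must be positive")
    grid = np.arange(0.0, k_max + 0.5 * k_step, k_step)
    if len(grid) == 0:
        raise ValueError("empty K grid")
    o_arr = np.asarray(o, dtype=float)
    t_arr = np.asarray(t, dtype=float)
    # raw M for every grid point at once; rows indexed by K
    raw = t_arr[None, :] + grid[:, None] * (t_arr.max() - t_arr)[None, :]
    m = raw / raw.sum(axis=1, keepdims=True)
    mask = o_arr > 0
    with np.errstate(divide="ignore"):
        div = np.sum(o_arr[mask] * np.log2(o_arr[mask] / m[:, mask]), axis=1)
    idx = int(np.argmin(div))  # first occurrence == smallest K
    k_hat = float(grid[idx])
    if idx == len(grid) - 1:
        warnings.warn(f"K fit hit the grid bound k_max={k_max}; possibly truncated")
    return k_hat, float(max(div[idx], 0.0))  # clamp -0.0 rounding residue


def fragment_rd(o: Profile, t: Profile, fr: FragmentSpec) -> float:
    """RD of a renormalized contiguous fragment of the O and T profiles.

    The O and T slices are each renormalized to sum 1 and compared
    against a uniform reference over the fragment length.
    """
    n = len(o)
    if len(t) != n:
        raise ValueError("o and t must be aligned")
    if fr.end > n:
        raise ValueError(f"fragment [{fr.start}, {fr.end}) exceeds unit length {n}")
    o_slice = np.asarray(o)[fr.start:fr.end]
    t_slice = np.asarray(t)[fr.start:fr.end]
    o_fr = normalize(o_slice, role="O")
    t_fr = normalize(t_slice, role="T")
    r_fr = uniform_profile(len(fr))
    return relative_distance(o_fr, t_fr, r_fr)
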