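"""Seedable synthetic structures with controlled hydrophobicity geometry.

These generators make every statistic in the package testable without
structure downloads.  Each fixture is a cloud of single-pseudo-atom
residues (so the effective atom coincides with the written atom) with a
known relation between position and intrinsic hydrophobicity:

* ``micelle``  — hydrophobic residues concentrated at the center, polar
  at the shell: the textbook aqueous-folding arrangement, expected
  RD < 0.5;
* ``inverted`` — hydrophobicity placement swapped (polar core,
  hydrophobic surface), as for a membrane-exposed unit: RD > 0.5;
* ``uniform``  — every residue gets the same intrinsic hydrophobicity;
* ``gaussian_exact`` — per-residue hydrophobicities solved from a linear
  system so the observed profile reproduces the theoretical Gaussian
  profile essentially exactly (RD ≈ 0, fitted K = 0).

Also provided: a generator of ordered (hi, lo) scatter points with
planted outliers, for exercising the screening/pruning logic, and a
PDB writer so fixtures can round-trip through the normal reading path.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np

from .orientation import orient, sigmas
from .pairs import OrderedPoint
from .profiles import DEFAULT_CUTOFF, levitt_g, theoretical_profile
from .scales import STANDARD_LETTERS, HydrophobicityScale, kyte_doolittle_normalized
from .structure_io import THREE_TO_ONE, EffectiveAtomSet, ResidueCentroid

__all__ = ["FixtureSpec", "Fixture", "generate", "write_pdb", "screening_points"]

_ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}

MODES = ("micelle", "inverted", "uniform", "gaussian_exact")


@dataclass(frozen=True)
class FixtureSpec:
    n_residues: int = 60
    mode: str = "micelle"
    seed: int = 0
    radius: float = 12.0  # Angstrom

    def __post_init__(self) -> None:
        if self.n_residues < 10:
            raise ValueError("fixtures need n_residues >= 10")
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        if self.mode not in MODES:
            raise ValueError(f"unknown mode {self.mode!r}; choose from {MODES}")


@dataclass
class Fixture:
    """A generated structure plus its hydrophobicity assignment.

    ``hydrophobicity`` is always the per-residue H^r vector actually
    intended for the observed profile; ``scale`` is the letter-level
    scale behind it when one exists (None for gaussian_exact, whose
    values are continuous and residue-specific).
    """

    eas: EffectiveAtomSet
    hydrophobicity: np.ndarray
    scale: Optional[HydrophobicityScale]
    spec: FixtureSpec


def _ball_points(rng: np.random.Generator, n: int, radius: float) -> np.ndarray:
    """n points uniformly distributed in a ball of the given radius."""
    direction = rng.normal(size=(n, 3))
    direction /= np.linalg.norm(direction, axis=1, keepdims=True)
    r = radius * rng.random(n) ** (1.0 / 3.0)
    return direction * r[:, None]


def _gaussian_cloud(rng: np.random.Generator, n: int, radius: float) -> np.ndarray:
    """n points from an isotropic Gaussian with most mass inside ``radius``.

    A centrally dense cloud mimics a globular protein better than a
    uniform ball for profile purposes: the residue density then tracks
    the micelle-like reference field itself.
    """
    return rng.normal(scale=radius / 2.5, size=(n, 3))


def _letters_by_radius(coords: np.ndarray, scale: HydrophobicityScale,
                       invert: bool) -> list[str]:
    """Assign letters so H^r decreases (or increases) with distance from
    the geometric center, using the scale's own 20-letter spread.

    The radial rank is pushed through a sigmoid toward the scale's
    extremes, so the core/shell hydrophobicity contrast dominates the
    quantization noise of a 20-letter alphabet.
    """
    center = coords.mean(axis=0)
    radial = np.linalg.norm(coords - center, axis=1)
    order = np.argsort(radial)  # innermost first
    ranked = sorted(STANDARD_LETTERS, key=lambda a: scale[a],
                    reverse=not invert)
    n = len(coords)
    letters = [""] * n
    for rank, idx in enumerate(order):
        frac = rank / (n - 1)
        frac = 0.5 * (1.0 + np.tanh(4.0 * (frac - 0.5)) / np.tanh(2.0))
        letters[idx] = ranked[min(int(frac * 20), 19)]
    return letters


def _as_eas(coords: np.ndarray, letters: list[str], label: str) -> EffectiveAtomSet:
    residues = [ResidueCentroid(residue_id=f"A:{i + 1}", one_letter=letters[i],
                                centroid=coords[i].copy())
                for i in range(len(coords))]
    return EffectiveAtomSet(residues=residues, unit_label=label)


def _gaussian_exact_hydrophobicity(eas: EffectiveAtomSet,
                                   cutoff: float) -> np.ndarray:
    """Per-residue H making the observed profile reproduce T.

    The observed raw profile is linear in H: O_raw = (diag(s) + G) H,
    with G the Levitt kernel matrix (zero diagonal) and s its row sums.
    An unconstrained solve can go negative at extreme shell points, so
    H >= 0 is found by minimizing D_KL(O|T) (non-negative least squares
    as the starting point) under the side constraint sum_i O_i/T_i <= N:
    that sum is exactly N at O == T and its excess is what makes
    dD_KL(O|M(k))/dk negative at k = 0, so the constraint pins the
    fitted K of the finished fixture at zero.
    """
    from scipy.optimize import minimize, nnls
    from scipy.spatial.distance import pdist, squareform

    oriented = orient(eas)
    t = np.asarray(theoretical_profile(oriented, sigmas(oriented)))
    d = squareform(pdist(eas.coords))
    g = np.asarray(levitt_g(d / cutoff))
    np.fill_diagonal(g, 0.0)
    a = np.diag(g.sum(axis=1)) + g
    n = len(t)
    h0, _ = nnls(a, t)

    def profile(h: np.ndarray) -> np.ndarray:
        raw = a @ h
        return raw / raw.sum()

    def kl(h: np.ndarray) -> float:
        o = profile(h)
        m = o > 0
        return float(np.sum(o[m] * np.log(o[m] / t[m])))

    def kl_grad(h: np.ndarray) -> np.ndarray:
        o = profile(h)
        s = (a @ h).sum()
        lg = np.where(o > 0, np.log(np.where(o > 0, o, 1.0) / t), 0.0)
        return a @ ((lg - float(np.sum(o * lg))) / s)

    margin = 0.05

    def slack(h: np.ndarray) -> float:
        return float(np.sum(profile(h) / t)) - n

    def slack_grad(h: np.ndarray) -> np.ndarray:
        o = profile(h)
        s = (a @ h).sum()
        w = 1.0 / t
        return a @ ((w - float(np.sum(o * w))) / s)

    res = minimize(kl, h0 + 1e-8, jac=kl_grad, bounds=[(0.0, None)] * n,
                   constraints=[{"type": "ineq",
                                 "fun": lambda h: -(slack(h) + margin),
                                 "jac": lambda h: -slack_grad(h)}],
                   method="SLSQP", options={"maxiter": 300, "ftol": 1e-12})
    return np.clip(res.x, 0.0, None)


def generate(spec: FixtureSpec, cutoff: float = DEFAULT_CUTOFF) -> Fixture:
    """Generate a fixture; byte-identical output for identical specs."""
    rng = np.random.default_rng(spec.seed)
    label = f"{spec.mode}-n{spec.n_residues}-seed{spec.seed}"
    default_scale = kyte_doolittle_normalized()

    if spec.mode == "gaussian_exact":
        # a uniform ball keeps every point connected through the kernel
        # at the default radius, which the constrained solve needs
        coords = _ball_points(rng, spec.n_residues, spec.radius)
        eas = _as_eas(coords, ["X"] * spec.n_residues, label)
        h = _gaussian_exact_hydrophobicity(eas, cutoff)
        return Fixture(eas=eas, hydrophobicity=h, scale=None, spec=spec)

    coords = _gaussian_cloud(rng, spec.n_residues, spec.radius)
    if spec.mode == "uniform":
        letters = ["A"] * spec.n_residues
    else:
        letters = _letters_by_radius(coords, default_scale,
                                     invert=(spec.mode == "inverted"))
    eas = _as_eas(coords, letters, label)
    h = default_scale.lookup(eas.sequence)
    return Fixture(eas=eas, hydrophobicity=h, scale=default_scale, spec=spec)


def write_pdb(eas: EffectiveAtomSet, path: str | Path,
              chain_id: str = "A") -> None:
    """Write one CA pseudo-atom per residue, wwPDB v3.3 columns.

    Round-trips through ``read_structure``/``effective_atoms`` to the
    same centroids within the format's 1e-3 A coordinate precision.
    """
    lines = []
    for serial, res in enumerate(eas.residues, start=1):
        resname = _ONE_TO_THREE.get(res.one_letter, "UNK")
        x, y, z = res.centroid
        lines.append(
            f"ATOM  {serial:5d}  CA  {resname:>3s} {chain_id}{serial:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}          "
            f"{'C':>2s}"
        )
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def screening_points(n_inliers: int = 35, n_outliers: int = 15,
                     seed: int = 0, slope: float = 0.85,
                     intercept: float = 0.05, noise: float = 0.005,
                     outlier_shift: float = 0.15) -> list[OrderedPoint]:
    """Ordered (hi, lo) scatter with near-collinear inliers and planted
    outliers displaced well off the trend line.

    Inliers sit on lo = slope*hi + intercept with Gaussian noise;
    outliers are shifted downward by ``outlier_shift`` (plus jitter), at
    least an order of magnitude beyond the inlier noise by default.
    Sources are tagged "inlier-i" / "outlier-i"; the list is shuffled
    deterministically by the seed.
    """
    rng = np.random.default_rng(seed)
    points = []
    hi_in = rng.uniform(0.55, 0.99, size=n_inliers)
    for i, hi in enumerate(hi_in):
        lo = slope * hi + intercept + rng.normal(0.0, noise)
        lo = float(np.clip(lo, 0.0, hi))
        points.append(OrderedPoint(hi=float(hi), lo=lo, source=f"inlier-{i}"))
    hi_out = rng.uniform(0.55, 0.99, size=n_outliers)
    for i, hi in enumerate(hi_out):
        lo = slope * hi + intercept - outlier_shift - 0.05 * rng.random()
        lo = float(np.clip(lo, 0.0, hi))
        points.append(OrderedPoint(hi=float(hi), lo=lo, source=f"outlier-{i}"))
    return [points[i] for i in rng.permutation(len(points))]
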