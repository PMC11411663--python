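"""Canonical orientation of a structural unit and Gaussian sigma derivation.

Before the idealized micelle-like field can be evaluated, the molecule is
brought to a reproducible frame:

1. the geometric center of the effective atoms is moved to the origin;
2. the pair of effective atoms with the greatest mutual distance is found
   and the molecule rotated so the line through that pair runs along the
   X axis;
3. among all pairs projected onto the YZ plane, the longest projected
   line is rotated onto the Y axis.

The three Gaussian standard deviations are then read off the oriented
coordinates by the three-sigma rule: the molecule's extent along each
axis spans three standard deviations, i.e. sigma_a = max_i |a_i| / 3.

Sign conventions (the Gaussian is even, so these only fix reproducible
output coordinates): the difference vector from the first-in-chain member
of the maximal pair to the second is aligned with +X, and likewise with
+Y for the projected pair.  Ties in the maximal-distance searches are
broken by lexicographic residue order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .structure_io import EffectiveAtomSet, ResidueCentroid

__all__ = ["OrientedSet", "GaussianSigmas", "orient", "sigmas"]

#: Floor applied to a degenerate (zero-extent) axis, in Angstrom.
SIGMA_FLOOR = 1.0


@dataclass
class OrientedSet:
    """An EffectiveAtomSet in the canonical frame, with the rigid-body
    transform that produced it (rotated = rotation @ (original + translation))."""

    residues: list[ResidueCentroid]
    rotation: np.ndarray     # (3, 3), proper orthonormal
    translation: np.ndarray  # (3,), applied before rotation
    unit_label: str = ""

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def coords(self) -> np.ndarray:
        return np.asarray([r.centroid for r in self.residues], dtype=float)

    @property
    def sequence(self) -> str:
        return "".join(r.one_letter for r in self.residues)


@dataclass(frozen=True)
class GaussianSigmas:
    sigma_x: float
    sigma_y: float
    sigma_z: float

    def __post_init__(self) -> None:
        if not (self.sigma_x > 0 and self.sigma_y > 0 and self.sigma_z > 0):
            raise ValueError("sigmas must be strictly positive")

    def as_array(self) -> np.ndarray:
        return np.array([self.sigma_x, self.sigma_y, self.sigma_z])


def _max_distance_pair(coords: np.ndarray) -> tuple[int, int]:
    """Indices (i, j), i < j in chain order, of the farthest pair.

    Ties broken lexicographically on (i, j)."""
    d = squareform(pdist(coords))
    dmax = d.max()
    # first (i, j) attaining the max, row-major scan == lexicographic order
    i, j = np.argwhere((d == dmax) & (np.tri(len(coords), k=-1).T > 0))[0]
    return int(i), int(j)


def _rotation_aligning(v: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Proper rotation sending unit vector v onto unit vector target."""
    v = v / np.linalg.norm(v)
    c = float(np.dot(v, target))
    axis = np.cross(v, target)
    s = np.linalg.norm(axis)
    if s < 1e-12:
        if c > 0:
            return np.eye(3)
        # antiparallel: rotate pi about any axis perpendicular to v
        perp = np.cross(v, [1.0, 0.0, 0.0])
        if np.linalg.norm(perp) < 1e-6:
            perp = np.cross(v, [0.0, 1.0, 0.0])
        perp /= np.linalg.norm(perp)
        return 2.0 * np.outer(perp, perp) - np.eye(3)
    axis = axis / s
    K = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + s * K + (1 - c) * (K @ K)


def orient(eas: EffectiveAtomSet | OrientedSet) -> OrientedSet:
    """Center the unit at the origin and rotate it to the canonical frame."""
    coords = eas.coords
    if np.allclose(coords, coords[0]):
        raise ValueError("all effective atoms coincide; orientation undefined")
    translation = -coords.mean(axis=0)
    centered = coords + translation

    i, j = _max_distance_pair(centered)
    r1 = _rotation_aligning(centered[i] - centered[j], np.array([1.0, 0.0, 0.0]))
    stage1 = centered @ r1.T

    # longest line in the YZ projection -> Y axis (rotation about X)
    yz = stage1[:, 1:]
    k, l = _max_distance_pair(np.column_stack([yz, np.zeros(len(yz))]))
    dyz = yz[k] - yz[l]
    norm = np.linalg.norm(dyz)
    if norm < 1e-9:
        warnings.warn("all points collinear along X; YZ orientation step skipped")
        r2 = np.eye(3)
    else:
        cos_t, sin_t = dyz[0] / norm, dyz[1] / norm
        # rotate about X so (y, z) = (cos, sin) maps onto (1, 0)
        r2 = np.array([[1.0, 0.0, 0.0],
                       [0.0, cos_t, sin_t],
                       [0.0, -sin_t, cos_t]])
    rotation = r2 @ r1
    final = centered @ rotation.T

    residues = [ResidueCentroid(r.residue_id, r.one_letter, final[idx].copy())
                for idx, r in enumerate(eas.residues)]
    return OrientedSet(residues=residues, rotation=rotation,
                       translation=translation,
                       unit_label=getattr(eas, "unit_label", ""))


def sigmas(os_: OrientedSet) -> GaussianSigmas:
    """Three-sigma-rule standard deviations of the oriented unit.

    sigma_a = max_i |coordinate_a(i)| / 3 per axis; an axis with zero
    extent (e.g. a perfectly planar set) gets the 1 A floor, with a
    warning.
    """
    extents = np.abs(os_.coords).max(axis=0) / 3.0
    out = []
    for axis, value in zip("xyz", extents):
        if value <= 0.0:
            warnings.warn(f"zero extent along {axis}; sigma_{axis} floored at {SIGMA_FLOOR} A")
            value = SIGMA_FLOOR
        out.append(float(value))
    return GaussianSigmas(*out)
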