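"""Pair-level screening of chameleon fragments.

A chameleon sequence is an identical amino-acid subsequence (typically
6–12 residues) that folds as a helix in one protein and as β-structure
in another.  Given per-unit results and fragment RD_FR values for both
members of each pair, this module:

* locates the shared fragment in each unit's sequence,
* classifies pairs by the unit-level RD (both core-forming, both
  core-less, or mixed),
* orders each pair's two RD_FR values as (higher, lower) irrespective of
  secondary structure,
* computes the Pearson correlation of the ordered scatter, and
* prunes outliers stepwise until the correlation exceeds a target.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .metrics import FodResult

__all__ = [
    "PairRecord",
    "OrderedPoint",
    "PruneResult",
    "locate_fragment",
    "categorize_pair",
    "order_points",
    "pearson",
    "prune_outliers",
]


@dataclass(frozen=True)
class PairRecord:
    """One chameleon pair: two units' results plus their fragment status."""

    unit_a: FodResult
    unit_b: FodResult
    rd_fr_a: float
    rd_fr_b: float
    ss_label_a: str = "helix"   # user-supplied metadata, not computed
    ss_label_b: str = "beta"
    fragment_sequence: str = ""
    pair_id: str = ""

    @property
    def category(self) -> int:
        return categorize_pair(self.unit_a.rd, self.unit_b.rd)


@dataclass(frozen=True)
class OrderedPoint:
    """A pair's RD_FR values ordered as (higher, lower)."""

    hi: float
    lo: float
    source: str = ""

    def __post_init__(self) -> None:
        if self.hi < self.lo:
            raise ValueError("hi must be >= lo")


@dataclass
class PruneResult:
    kept: list[OrderedPoint]
    removed: list[OrderedPoint]
    r_final: float
    converged: bool

    @property
    def fraction_removed(self) -> float:
        total = len(self.kept) + len(self.removed)
        return len(self.removed) / total if total else 0.0


def locate_fragment(sequence: str, subseq: str) -> list[int]:
    """All 0-based start positions of exact (possibly overlapping) matches."""
    if len(subseq) < 2:
        raise ValueError("fragment sequence must have length >= 2")
    hits = []
    start = sequence.find(subseq)
    while start != -1:
        hits.append(start)
        start = sequence.find(subseq, start + 1)
    return hits


def categorize_pair(rd_a: float, rd_b: float) -> int:
    """Pair category by unit-level RD.

    1: both units core-forming (RD < 0.5); 2: both core-less (RD > 0.5);
    3: mixed.  Exactly 0.5 counts as not-greater, hence mixed.
    """
    for rd in (rd_a, rd_b):
        if not (0.0 <= rd <= 1.0):
            raise ValueError(f"RD {rd} outside [0, 1]")
    if rd_a < 0.5 and rd_b < 0.5:
        return 1
    if rd_a > 0.5 and rd_b > 0.5:
        return 2
    return 3


def order_points(pairs: Sequence[PairRecord]) -> list[OrderedPoint]:
    """Per pair, (hi, lo) = (max, min) of the two RD_FR values, in input order."""
    return [OrderedPoint(hi=max(p.rd_fr_a, p.rd_fr_b),
                         lo=min(p.rd_fr_a, p.rd_fr_b),
                         source=p.pair_id)
            for p in pairs]


def pearson(points: Sequence[OrderedPoint]) -> float:
    """Pearson product–moment correlation of the (hi, lo) scatter."""
    if len(points) < 3:
        raise ValueError("need at least 3 points for a correlation")
    x = np.array([p.hi for p in points])
    y = np.array([p.lo for p in points])
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("degenerate variance; correlation undefined")
    return float(stats.pearsonr(x, y).statistic)


def _residuals_to_ls_line(points: Sequence[OrderedPoint]) -> np.ndarray:
    x = np.array([p.hi for p in points])
    y = np.array([p.lo for p in points])
    slope, intercept = np.polyfit(x, y, 1)
    return np.abs(y - (slope * x + intercept))


def prune_outliers(points: Sequence[OrderedPoint],
                   r_target: float = 0.9) -> PruneResult:
    """Greedy stepwise outlier elimination.

    Repeatedly removes the single point whose removal maximizes the
    recomputed Pearson r, until r > ``r_target`` or fewer than 4 points
    would remain for the next step.  Ties resolve to the point with the
    larger absolute residual to the current least-squares line, then to
    the earlier input position.  The result is flagged unconverged if
    the target was not reached.
    """
    if len(points) < 4:
        raise ValueError("need at least 4 points to prune")
    current = list(points)
    removed: list[OrderedPoint] = []
    r = pearson(current)
    while r <= r_target and len(current) >= 4:
        residuals = _residuals_to_ls_line(current)
        best = None  # (-r_after, -residual, index)
        for idx in range(len(current)):
            trial = current[:idx] + current[idx + 1:]
            try:
                r_after = pearson(trial)
            except ValueError:
                continue
            key = (-r_after, -residuals[idx], idx)
            if best is None or key < best[0]:
                best = (key, idx)
        if best is None:
            break
        _, drop = best
        removed.append(current.pop(drop))
        r = pearson(current)
    return PruneResult(kept=current, removed=removed, r_final=r,
                       converged=r > r_target)
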