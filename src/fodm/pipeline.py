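"""High-level orchestration: one-call analyses used by the CLI, the
examples and batch screening.

``analyze_unit`` runs the whole chain for one structural unit:
effective atoms -> orientation -> sigmas -> T/O/R profiles -> RD and the
fitted K.  ``analyze_fragment`` adds the RD_FR of a contiguous fragment,
and ``analyze_pairs`` drives a manifest of chameleon pairs through to
ordered points, correlation and outlier pruning.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from . import metrics, pairs as pairs_mod, profiles as profiles_mod
from .metrics import FodResult, FragmentSpec
from .orientation import orient, sigmas
from .pairs import PairRecord, PruneResult, locate_fragment, order_points, pearson, prune_outliers
from .profiles import DEFAULT_CUTOFF, Profile, observed_profile, theoretical_profile, uniform_profile
from .scales import HydrophobicityScale, kyte_doolittle_normalized, load_scale_tsv
from .structure_io import EffectiveAtomSet, UnitSelector, effective_atoms, read_structure

__all__ = ["RunConfig", "UnitAnalysis", "FragmentAnalysis", "PairScreen",
           "analyze_unit", "analyze_fragment", "analyze_pairs", "load_unit"]

log = logging.getLogger("fodm")


@dataclass
class RunConfig:
    """Knobs shared by every analysis entry point."""

    scale: Optional[HydrophobicityScale] = None  # None -> packaged default
    cutoff_c: float = DEFAULT_CUTOFF
    k_max: float = metrics.DEFAULT_K_MAX
    k_step: float = metrics.DEFAULT_K_STEP

    def __post_init__(self) -> None:
        if self.cutoff_c <= 0:
            raise ValueError("cutoff must be positive")
        if self.k_step <= 0 or self.k_max <= 0:
            raise ValueError("K grid parameters must be positive")

    @classmethod
    def with_scale_path(cls, scale_path: Optional[str] = None, **kw) -> "RunConfig":
        scale = load_scale_tsv(scale_path) if scale_path else None
        return cls(scale=scale, **kw)

    def resolve_scale(self) -> HydrophobicityScale:
        return self.scale if self.scale is not None else kyte_doolittle_normalized()


@dataclass
class UnitAnalysis:
    result: FodResult
    t: Profile
    o: Profile
    r: Profile
    m: Profile
    eas: EffectiveAtomSet

    def profile_table(self) -> list[dict]:
        rows = []
        for idx, res in enumerate(self.eas.residues):
            rows.append({
                "residue_id": res.residue_id,
                "one_letter": res.one_letter,
                "T": float(self.t.values[idx]),
                "O": float(self.o.values[idx]),
                "R": float(self.r.values[idx]),
                "M": float(self.m.values[idx]),
            })
        return rows


@dataclass
class FragmentAnalysis:
    rd_fr: float
    fragment: FragmentSpec
    sequence: str
    t_slice: np.ndarray  # renormalized
    o_slice: np.ndarray  # renormalized


@dataclass
class PairScreen:
    records: list[PairRecord]
    failures: list[tuple[str, str]]  # (pair_id, message)
    category_counts: dict[int, int]
    r_initial: Optional[float]
    prune: Optional[PruneResult]


def load_unit(pdb_path: str | Path, selector: str | UnitSelector) -> EffectiveAtomSet:
    """Read a PDB file and reduce the selected unit to effective atoms."""
    sel = UnitSelector.parse(selector) if isinstance(selector, str) else selector
    atoms = read_structure(Path(pdb_path).read_text())
    eas = effective_atoms(atoms, sel)
    eas.unit_label = f"{Path(pdb_path).stem}:{sel}"
    return eas


def analyze_unit(eas: EffectiveAtomSet,
                 config: Optional[RunConfig] = None,
                 hydrophobicity: Optional[np.ndarray] = None) -> UnitAnalysis:
    """Full unit-level analysis.

    ``hydrophobicity`` overrides the letter-level scale with an explicit
    per-residue H^r vector (used by the exact synthetic fixtures).
    """
    config = config or RunConfig()
    oriented = orient(eas)
    sig = sigmas(oriented)
    t = theoretical_profile(oriented, sig)
    h = hydrophobicity if hydrophobicity is not None else config.resolve_scale()
    o = observed_profile(eas, h, cutoff_c=config.cutoff_c)
    r = uniform_profile(len(eas))
    rd = metrics.relative_distance(o, t, r)
    k_hat, dkl_om = metrics.fit_k(o, t, k_max=config.k_max, k_step=config.k_step)
    result = FodResult(
        rd=rd,
        dkl_ot=metrics.kl_divergence(o, t),
        dkl_or=metrics.kl_divergence(o, r),
        k_hat=k_hat,
        dkl_om=dkl_om,
        unit_label=eas.unit_label,
        n_residues=len(eas),
    )
    return UnitAnalysis(result=result, t=t, o=o, r=r,
                        m=metrics.m_profile(t, k_hat), eas=eas)


def resolve_fragment(eas: EffectiveAtomSet,
                     fragment: str | FragmentSpec) -> FragmentSpec:
    """Turn a fragment request (sequence or spec) into positions.

    A sequence with several occurrences is ambiguous: the caller must
    give an explicit range; the first occurrence is used with a warning
    otherwise (mirrored by the CLI, which refuses instead).
    """
    if isinstance(fragment, FragmentSpec):
        if fragment.sequence:
            actual = eas.sequence[fragment.start:fragment.end]
            if actual != fragment.sequence:
                raise ValueError(
                    f"fragment range sequence {actual!r} != expected {fragment.sequence!r}")
        return fragment
    hits = locate_fragment(eas.sequence, fragment)
    if not hits:
        raise ValueError(f"fragment {fragment!r} not found in unit sequence")
    if len(hits) > 1:
        log.warning("fragment %r occurs at %s; using first occurrence", fragment, hits)
    start = hits[0]
    return FragmentSpec(start=start, end=start + len(fragment), sequence=fragment)


def analyze_fragment(ua: UnitAnalysis,
                     fragment: str | FragmentSpec) -> FragmentAnalysis:
    """RD_FR of a fragment of an analyzed unit, with renormalized slices."""
    fr = resolve_fragment(ua.eas, fragment)
    rd_fr = metrics.fragment_rd(ua.o, ua.t, fr)
    o_slice = np.asarray(ua.o)[fr.start:fr.end]
    t_slice = np.asarray(ua.t)[fr.start:fr.end]
    return FragmentAnalysis(
        rd_fr=rd_fr, fragment=fr,
        sequence=ua.eas.sequence[fr.start:fr.end],
        t_slice=t_slice / t_slice.sum(),
        o_slice=o_slice / o_slice.sum(),
    )


def _parse_optional_range(text: str) -> Optional[tuple[int, int]]:
    text = (text or "").strip()
    if not text:
        return None
    start_s, _, end_s = text.partition("-")
    return int(start_s), int(end_s)


def analyze_pairs(manifest_path: str | Path,
                  config: Optional[RunConfig] = None,
                  r_target: float = 0.9) -> PairScreen:
    """Run a chameleon-pair manifest end to end.

    Manifest CSV columns: pair_id, pdb_a, selector_a, ss_a, pdb_b,
    selector_b, ss_b, fragment_sequence, and optional frag_range_a /
    frag_range_b ("start-end", 0-based half-open positions into the
    unit) to disambiguate repeated fragments.  Per-row failures are
    logged and the run continues.
    """
    config = config or RunConfig()
    manifest_path = Path(manifest_path)
    records: list[PairRecord] = []
    failures: list[tuple[str, str]] = []
    with manifest_path.open(newline="") as fh:
        rows = list(csv.DictReader(fh))
    base = manifest_path.parent
    for row in rows:
        pair_id = (row.get("pair_id") or "").strip() or f"row{len(records) + len(failures) + 1}"
        try:
            sides = []
            for suffix in ("a", "b"):
                pdb = Path(row[f"pdb_{suffix}"])
                if not pdb.is_absolute():
                    pdb = base / pdb
                eas = load_unit(pdb, row[f"selector_{suffix}"])
                ua = analyze_unit(eas, config)
                rng = _parse_optional_range(row.get(f"frag_range_{suffix}", ""))
                frag = (FragmentSpec(rng[0], rng[1], row["fragment_sequence"].strip() or None)
                        if rng else row["fragment_sequence"].strip())
                fa = analyze_fragment(ua, frag)
                sides.append((ua, fa))
            (ua_a, fa_a), (ua_b, fa_b) = sides
            records.append(PairRecord(
                unit_a=ua_a.result, unit_b=ua_b.result,
                rd_fr_a=fa_a.rd_fr, rd_fr_b=fa_b.rd_fr,
                ss_label_a=(row.get("ss_a") or "").strip(),
                ss_label_b=(row.get("ss_b") or "").strip(),
                fragment_sequence=row["fragment_sequence"].strip(),
                pair_id=pair_id,
            ))
        except Exception as exc:  # per-row isolation is the contract
            log.error("pair %s failed: %s", pair_id, exc)
            failures.append((pair_id, str(exc)))

    counts = {1: 0, 2: 0, 3: 0}
    for rec in records:
        counts[rec.category] += 1
    r_initial = None
    prune = None
    points = order_points(records)
    if len(points) >= 3:
        try:
            r_initial = pearson(points)
        except ValueError:
            r_initial = None
    if len(points) >= 4 and r_initial is not None:
        prune = prune_outliers(points, r_target=r_target)
    return PairScreen(records=records, failures=failures,
                      category_counts=counts, r_initial=r_initial, prune=prune)
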