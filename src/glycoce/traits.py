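"""Glycosylation traits from a normalized peak-area profile.

A :class:`GlycoProfile` holds relative peak areas (fractions of total assigned
area, summing to one).  Traits are sums of relative areas over the peaks whose
dominant structure belongs to a class:

* ``G0``  -- agalactosylated (A2 + A2B + FA2 + FA2B)
* ``G1``  -- monogalactosylated, sialylated forms included
* ``G2``  -- digalactosylated
* ``g0_g1_ratio = G0 / G1`` and ``g0_percent = 100 * G0`` summarize
  hypogalactosylation; the ratio is undefined (NaN, flagged) when G1 = 0.

Fucosylation, bisecting and sialylation traits sum the peaks whose dominant
structure carries F, B, or at least one S respectively; a degree-weighted
sialylation variant (S2 counted twice) is available behind a flag.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import pandas as pd

from .reference import ReferenceTable, build_reference_table

__all__ = ["GlycoProfile", "TraitVector", "ProfileError", "compute_traits", "traits_for_cohort"]

_SUM_TOL = 1e-9

TRAIT_COLUMNS = [
    "G0",
    "G1",
    "G2",
    "g0_g1_ratio",
    "g0_percent",
    "fucosylation",
    "bisecting",
    "sialylation",
]


class ProfileError(ValueError):
    """Raised for invalid or empty glycan profiles."""


@dataclass(frozen=True)
class GlycoProfile:
    """Normalized relative peak areas keyed by reference peak id."""

    relative_areas: Mapping[int, float]
    reference: str = "default-22"
    unassigned_fraction: float = 0.0

    def __post_init__(self) -> None:
        if not self.relative_areas:
            raise ProfileError("profile has no assigned peaks")
        if any(v < 0 for v in self.relative_areas.values()):
            raise ProfileError("relative areas must be non-negative")
        total = sum(self.relative_areas.values()) + self.unassigned_fraction
        if abs(total - 1.0) > _SUM_TOL:
            raise ProfileError(f"relative areas must sum to 1, got {total!r}")

    def area(self, peak_id: int) -> float:
        return float(self.relative_areas.get(peak_id, 0.0))


@dataclass(frozen=True)
class TraitVector:
    """Derived glycosylation traits for one sample."""

    G0: float
    G1: float
    G2: float
    g0_g1_ratio: float  # NaN when undefined
    g0_percent: float
    fucosylation: float
    bisecting: float
    sialylation: float
    ratio_defined: bool = True

    def as_dict(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in TRAIT_COLUMNS}


def compute_traits(
    profile: GlycoProfile,
    ref: Optional[ReferenceTable] = None,
    degree_weighted_sialylation: bool = False,
) -> TraitVector:
    """Compute the trait vector of a profile against a reference table.

    Each peak contributes its full relative area to the class of its dominant
    structure (comigration resolved by dominance).  ``g0_g1_ratio`` is NaN with
    ``ratio_defined=False`` when the G1 sum is zero.
    """
    if ref is None:
        ref = build_reference_table()
    known = {p.peak_id for p in ref.peaks}
    extra = set(profile.relative_areas) - known
    if extra:
        raise ProfileError(f"profile references unknown peak ids: {sorted(extra)}")

    sums = {"G0": 0.0, "G1": 0.0, "G2": 0.0, "other": 0.0}
    fuc = bis = sia = 0.0
    for peak in ref.peaks:
        a = profile.area(peak.peak_id)
        if a == 0.0:
            continue
        sums[peak.trait_class] += a
        dom = peak.dominant
        if dom.core_fucose:
            fuc += a
        if dom.bisecting:
            bis += a
        if dom.sialic_acids > 0:
            sia += a * (dom.sialic_acids if degree_weighted_sialylation else 1)

    g0, g1 = sums["G0"], sums["G1"]
    defined = g1 > 0.0
    ratio = g0 / g1 if defined else math.nan
    return TraitVector(
        G0=g0,
        G1=g1,
        G2=sums["G2"],
        g0_g1_ratio=ratio,
        g0_percent=100.0 * g0,
        fucosylation=fuc,
        bisecting=bis,
        sialylation=sia,
        ratio_defined=defined,
    )


def traits_for_cohort(
    profiles: Mapping[str, GlycoProfile] | Iterable[tuple[str, GlycoProfile]],
    ref: Optional[ReferenceTable] = None,
) -> pd.DataFrame:
    """Trait table for a cohort: one row per subject, indexed by subject_id.

    Row order follows input order.  Duplicate subject ids are an error.
    """
    if ref is None:
        ref = build_reference_table()
    items = list(profiles.items()) if isinstance(profiles, Mapping) else list(profiles)
    ids = [sid for sid, _ in items]
    if len(ids) != len(set(ids)):
        dupes = sorted({s for s in ids if ids.count(s) > 1})
        raise ValueError(f"duplicate subject ids: {dupes}")
    rows = [compute_traits(p, ref).as_dict() for _, p in items]
    df = pd.DataFrame(rows, index=pd.Index(ids, name="subject_id"), columns=TRAIT_COLUMNS)
    return df
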