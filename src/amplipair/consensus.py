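"""Weighted consensus of taxonomic profiles from two sequencing experiments.

Two experiments targeting different V-region pairs produce two abundance
profiles of the same community.  Because each target resolves each taxon
with different accuracy, the refined abundance of taxon *i* is the
weighted average

    T_i(xy) = (W_i(x) * T_i(x) + W_i(y) * T_i(y)) / (W_i(x) + W_i(y))

where the weights are each experiment's per-taxon share of correct
assignments.  The combined profile is then renormalized to percent and
can be scored against a reference profile by the cumulated deviation
``Σ_i |T_i(est) − T_i(ref)|`` (percentage points).
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

logger = logging.getLogger(__name__)

COUNTS = "counts"
PERCENT = "percent"


@dataclass(frozen=True)
class TaxonomicProfile:
    """Ordered taxon → abundance map, in counts or percent units."""

    abundances: Mapping[str, float]
    unit: str = COUNTS

    def __post_init__(self) -> None:
        if self.unit not in (COUNTS, PERCENT):
            raise ValueError(f"unit must be {COUNTS!r} or {PERCENT!r}")
        object.__setattr__(self, "abundances", dict(self.abundances))
        for taxon, value in self.abundances.items():
            if value < 0:
                raise ValueError(f"negative abundance for {taxon!r}: {value}")
        if self.unit == PERCENT:
            total = sum(self.abundances.values())
            if abs(total - 100.0) > 0.5:  # tolerate printed rounding
                raise ValueError(f"percent profile sums to {total:.3f}, expected 100")

    @property
    def n(self) -> int:
        return len(self.abundances)

    @property
    def taxa(self) -> list[str]:
        return list(self.abundances)

    def get(self, taxon: str) -> float:
        return self.abundances.get(taxon, 0.0)

    @classmethod
    def from_counts(cls, counts: Mapping[str, int]) -> "TaxonomicProfile":
        return cls(dict(counts), COUNTS)

    @classmethod
    def from_assignments(cls, assignments: Iterable[str]) -> "TaxonomicProfile":
        """Count profile from assigned taxon names, ignoring 'unclassified'."""
        from .classifier import UNCLASSIFIED

        return cls.from_counts(Counter(a for a in assignments if a != UNCLASSIFIED))

    @classmethod
    def from_tsv(cls, path: str | Path, unit: str = PERCENT) -> "TaxonomicProfile":
        frame = pd.read_csv(path, sep="\t", comment="#")
        taxon_col, value_col = frame.columns[:2]
        return cls(dict(zip(frame[taxon_col], frame[value_col].astype(float))), unit)

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"taxon": self.taxa, "abundance": list(self.abundances.values())}
        ).to_csv(path, sep="\t", index=False)


def normalize_profile(profile: TaxonomicProfile) -> TaxonomicProfile:
    """Scale a profile to percent (sums to 100)."""
    total = sum(profile.abundances.values())
    if total <= 0:
        raise ValueError("cannot normalize an all-zero profile")
    return TaxonomicProfile(
        {t: 100.0 * v / total for t, v in profile.abundances.items()}, PERCENT
    )


def combine_profiles(
    px: TaxonomicProfile,
    py: TaxonomicProfile,
    wx: Mapping[str, float],
    wy: Mapping[str, float],
    return_table: bool = False,
) -> TaxonomicProfile | tuple[TaxonomicProfile, pd.DataFrame]:
    """Weighted per-taxon combination of two profiles.

    The taxon universe is the union of both profiles and both weight
    tables; a missing abundance or weight is treated as 0.  When both
    weights vanish for a taxon with nonzero abundance, the unweighted mean
    is used instead (flagged in the provenance table and logged).  The raw
    combined profile is returned un-normalized; apply
    :func:`normalize_profile` for percent output.
    """
    if px.unit != py.unit:
        raise ValueError(f"unit mismatch: {px.unit!r} vs {py.unit!r}")
    taxa = sorted(set(px.taxa) | set(py.taxa) | set(wx) | set(wy))
    combined: dict[str, float] = {}
    rows = []
    n_fallback = 0
    for taxon in taxa:
        tx, ty = px.get(taxon), py.get(taxon)
        wxi, wyi = wx.get(taxon, 0.0), wy.get(taxon, 0.0)
        if wxi < 0 or wyi < 0:
            raise ValueError(f"negative weight for taxon {taxon!r}")
        if wxi + wyi > 0:
            txy = (wxi * tx + wyi * ty) / (wxi + wyi)
            fallback = False
        else:
            txy = 0.5 * (tx + ty)
            fallback = txy > 0
            n_fallback += fallback
        combined[taxon] = txy
        rows.append(
            {"taxon": taxon, "T_x": tx, "T_y": ty, "W_x": wxi, "W_y": wyi,
             "T_xy": txy, "zero_weight_fallback": fallback}
        )
    if n_fallback:
        logger.warning(
            "%d taxa had zero weight in both experiments; used unweighted mean",
            n_fallback,
        )
    profile = TaxonomicProfile(combined, COUNTS) if px.unit == COUNTS else _as_raw_percent(combined)
    if return_table:
        return profile, pd.DataFrame(rows)
    return profile


def _as_raw_percent(values: dict[str, float]) -> TaxonomicProfile:
    # A raw combination of percent profiles need not sum to 100; keep it in
    # counts units until the caller normalizes.
    return TaxonomicProfile(values, COUNTS)


def cumulated_deviation(est: TaxonomicProfile, ref: TaxonomicProfile) -> float:
    """Cumulated percentage deviation ``Σ_i |est_i − ref_i|`` between two
    percent profiles (taxon universe = union, missing = 0)."""
    for p, name in ((est, "estimate"), (ref, "reference")):
        if p.unit != PERCENT:
            raise ValueError(f"{name} profile must be in percent units")
    taxa = set(est.taxa) | set(ref.taxa)
    return float(sum(abs(est.get(t) - ref.get(t)) for t in taxa))
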