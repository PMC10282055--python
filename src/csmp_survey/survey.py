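"""Survey-level analytics for the mask-wearing campaign.

Operations over the campaign's record types: stacked-pair collection
efficiency, CsMP share of whole-mask activity, particle accounting,
CsMP frequency by mask-activity class, and the inverse-square distance
regression of mask activity on residence distance from the source.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.stats

from .nuclides import Activity, CensoredActivityError

__all__ = [
    "MaskRecord",
    "ParticleRecord",
    "MaskPair",
    "ResidenceRecord",
    "EfficiencyResult",
    "EfficiencySummary",
    "FractionResult",
    "ParticleCounts",
    "RegressionFit",
    "UndefinedEfficiencyError",
    "collection_efficiency",
    "efficiency_summary",
    "csmp_fraction",
    "count_particles",
    "frequency_by_activity_class",
    "distance_regression",
]

MASK_TYPES = ("single", "inner", "outer", "n95")
CONSTRUCTIONS = ("wood", "light_steel", "reinforced_concrete")


class UndefinedEfficiencyError(ValueError):
    """Collection efficiency with a censored or zero outer-mask activity."""


@dataclass(frozen=True)
class MaskRecord:
    """One worn mask with its radiocesium activities and survey metadata."""

    mask_id: str
    residence_id: str
    person_id: str
    worn_date: datetime.date
    mask_type: str
    a134: Activity
    a137: Activity

    def __post_init__(self) -> None:
        if self.mask_type not in MASK_TYPES:
            raise ValueError(f"mask_type must be one of {MASK_TYPES}, got {self.mask_type!r}")


@dataclass(frozen=True)
class ParticleRecord:
    """One isolated CsMP, linked to the mask it was recovered from."""

    particle_id: str
    mask_id: str
    a134: Activity
    a137: Activity
    previously_reported: bool = False

    def __post_init__(self) -> None:
        if self.a137.censored:
            raise ValueError("a particle record requires a measured cs137 activity")


@dataclass(frozen=True)
class MaskPair:
    """Outer and inner masks worn stacked by one person on one visit."""

    outer: MaskRecord
    inner: MaskRecord

    def __post_init__(self) -> None:
        if (
            self.outer.residence_id != self.inner.residence_id
            or self.outer.person_id != self.inner.person_id
            or self.outer.worn_date != self.inner.worn_date
        ):
            raise ValueError("paired masks must share residence, person, and worn date")


@dataclass(frozen=True)
class ResidenceRecord:
    residence_id: str
    distance_km: float
    construction: str = "wood"

    def __post_init__(self) -> None:
        if self.distance_km <= 0:
            raise ValueError("distance_km must be > 0")
        if self.construction not in CONSTRUCTIONS:
            raise ValueError(f"construction must be one of {CONSTRUCTIONS}")


@dataclass(frozen=True)
class EfficiencyResult:
    """Collection efficiency in percent; significant when positive.

    The efficiency is reported exactly as defined,
    (1 - inner/outer) * 100, although it overstates the true filtration:
    the outer mask pre-filters the airstream reaching the inner one, so
    the true efficiency is at or below this value.
    """

    efficiency: float
    significant: bool

    def __post_init__(self) -> None:
        if self.efficiency > 100.0:
            raise ValueError("efficiency cannot exceed 100%")


@dataclass(frozen=True)
class EfficiencySummary:
    n_total: int
    n_significant: int
    max_pct: float | None
    min_pct: float | None
    mean_pct: float | None


@dataclass(frozen=True)
class FractionResult:
    """CsMP share of whole-mask Cs-137 activity, in percent."""

    percent: float
    upper_bound: bool = False


@dataclass(frozen=True)
class ParticleCounts:
    n_total: int
    n_new: int
    n_masks_with_new: int


@dataclass(frozen=True)
class RegressionFit:
    slope: float
    intercept: float
    r_squared: float
    slope_stderr: float | None = None


def collection_efficiency(pair: MaskPair) -> EfficiencyResult:
    """Collection efficiency of a stacked pair: (1 - inner/outer) * 100.

    Negative values arise when the inner mask caught more activity than
    the outer one (counting noise, leakage) and are flagged not
    significant.
    """
    if pair.outer.a137.censored or pair.inner.a137.censored:
        raise UndefinedEfficiencyError("both masks of a pair need measured cs137 activities")
    outer = pair.outer.a137.value
    inner = pair.inner.a137.value
    if outer <= 0:
        raise UndefinedEfficiencyError("outer-mask cs137 activity must be positive")
    eff = (1.0 - inner / outer) * 100.0
    return EfficiencyResult(efficiency=eff, significant=eff > 0.0)


def efficiency_summary(results: Iterable[EfficiencyResult]) -> EfficiencySummary:
    """Summarise pair efficiencies over the significant (positive) cases."""
    results = list(results)
    if not results:
        raise ValueError("efficiency_summary requires at least one result")
    sig = [r.efficiency for r in results if r.significant]
    if not sig:
        return EfficiencySummary(len(results), 0, None, None, None)
    return EfficiencySummary(
        n_total=len(results),
        n_significant=len(sig),
        max_pct=max(sig),
        min_pct=min(sig),
        mean_pct=float(np.mean(sig)),
    )


def csmp_fraction(particle: ParticleRecord, mask: MaskRecord) -> FractionResult:
    """Percent of a mask's Cs-137 activity carried by one of its particles.

    Both activities must share the worn-date reference. A censored
    particle numerator yields an upper bound computed at its detection
    limit.
    """
    if mask.a137.censored or mask.a137.value <= 0:
        raise CensoredActivityError("mask cs137 activity must be measured and positive")
    if particle.a137.reference_date != mask.a137.reference_date:
        raise ValueError(
            "particle and mask activities must share a reference date; "
            f"got {particle.a137.reference_date} vs {mask.a137.reference_date}"
        )
    if particle.a137.censored:
        return FractionResult(
            percent=100.0 * particle.a137.detection_limit / mask.a137.value,
            upper_bound=True,
        )
    return FractionResult(percent=100.0 * particle.a137.value / mask.a137.value)


def count_particles(particles: Iterable[ParticleRecord]) -> ParticleCounts:
    """Total particles, newly discovered ones, and masks hosting new ones."""
    particles = list(particles)
    n_total = len(particles)
    new = [p for p in particles if not p.previously_reported]
    return ParticleCounts(
        n_total=n_total,
        n_new=len(new),
        n_masks_with_new=len({p.mask_id for p in new}),
    )


def frequency_by_activity_class(
    masks: Iterable[MaskRecord],
    particles: Iterable[ParticleRecord],
    class_edges: Sequence[float],
) -> pd.DataFrame:
    """CsMP occurrence frequency per mask Cs-137 activity class.

    ``class_edges`` are strictly increasing bin boundaries; bins are
    half-open [lo, hi). Censored masks are placed by their detection
    limit. Returns one row per bin with mask counts and the percentage
    of masks hosting at least one CsMP; the percentage is reported as
    observed, not forced monotone.
    """
    edges = list(class_edges)
    if len(edges) < 2 or any(b <= a for a, b in zip(edges, edges[1:])):
        raise ValueError("class_edges must be strictly increasing with >= 2 entries")
    masks = list(masks)
    hosts = {p.mask_id for p in particles}
    rows = []
    for lo, hi in zip(edges, edges[1:]):
        in_bin = [
            m
            for m in masks
            if lo <= (m.a137.detection_limit if m.a137.censored else m.a137.value) < hi
        ]
        n = len(in_bin)
        n_with = sum(1 for m in in_bin if m.mask_id in hosts)
        rows.append(
            {
                "class_lo_bq": lo,
                "class_hi_bq": hi,
                "n_masks": n,
                "n_masks_with_csmp": n_with,
                "percent_with_csmp": 100.0 * n_with / n if n else 0.0,
            }
        )
    return pd.DataFrame(rows)


def distance_regression(
    residence_activities: Sequence[tuple[float, float]],
    fixed_slope: float | None = None,
) -> RegressionFit:
    """Log-log regression of mask activity on distance from the source.

    Ordinary least squares of log10(activity) on log10(distance); an
    undisturbed inverse-square deposition law appears as slope -2. With
    ``fixed_slope`` the slope is held (e.g. at -2) and only the intercept
    is fitted; R^2 is then reported for that constrained model and may be
    negative if the fixed slope fits worse than a constant.
    """
    pts = list(residence_activities)
    if len(pts) < 3:
        raise ValueError("distance_regression requires at least 3 points")
    d = np.asarray([p[0] for p in pts], dtype=float)
    a = np.asarray([p[1] for p in pts], dtype=float)
    if np.any(d <= 0) or np.any(a <= 0):
        raise ValueError("distances and activities must be positive")
    x = np.log10(d)
    y = np.log10(a)
    if fixed_slope is None:
        fit = scipy.stats.linregress(x, y)
        return RegressionFit(
            slope=float(fit.slope),
            intercept=float(fit.intercept),
            r_squared=float(fit.rvalue**2),
            slope_stderr=float(fit.stderr),
        )
    intercept = float(np.mean(y - fixed_slope * x))
    resid = y - (fixed_slope * x + intercept)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else (1.0 if np.allclose(resid, 0) else 0.0)
    return RegressionFit(slope=float(fixed_slope), intercept=intercept, r_squared=r2)
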