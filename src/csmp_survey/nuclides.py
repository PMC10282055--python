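"""Radiocesium nuclide constants, decay correction, and isotope ratios.

Every activity in a survey carries a calendar reference date: the date the
mask was worn, the date of the gamma measurement, or the accident date
(2011-03-11) to which all source-attribution quantities are normalised.
This module moves censored measurements (value, 1-sigma) between reference
dates with the exponential decay law and propagates counting uncertainty
to first order.

Half-lives are not survey observables; the registry carries evaluated
nuclear-data values (30.08 y for Cs-137, 2.0652 y for Cs-134). The decay
factor itself is treated as exact: its relative uncertainty is orders of
magnitude below the counting sigma of any mask or particle measurement.
"""

from __future__ import annotations

import datetime
import math
from dataclasses import dataclass, replace

__all__ = [
    "Nuclide",
    "Activity",
    "ValueWithSigma",
    "CensoredActivityError",
    "UndefinedRatioError",
    "NUCLIDES",
    "CS134",
    "CS137",
    "ACCIDENT_DATE",
    "get_nuclide",
    "parse_date",
    "elapsed_years",
    "decay_factor",
    "decay_correct",
    "isotope_ratio",
]

#: mean Julian year, used for day-count -> year conversion
DAYS_PER_YEAR = 365.25

#: reference date to which source-attribution quantities are decay-corrected
ACCIDENT_DATE = datetime.date(2011, 3, 11)


class CensoredActivityError(ValueError):
    """An operation that needs a measured value received a censored one."""


class UndefinedRatioError(ZeroDivisionError):
    """Isotope ratio with a zero denominator activity."""


@dataclass(frozen=True)
class Nuclide:
    """A registered radionuclide with its physical half-life in years."""

    name: str
    half_life_years: float

    def __post_init__(self) -> None:
        if self.half_life_years <= 0:
            raise ValueError(f"half-life must be positive, got {self.half_life_years}")

    @property
    def decay_constant(self) -> float:
        """Decay constant lambda in 1/years."""
        return math.log(2.0) / self.half_life_years


CS134 = Nuclide("cs134", 2.0652)
CS137 = Nuclide("cs137", 30.08)

#: built-in registry; override half-lives by constructing Nuclide directly
NUCLIDES: dict[str, Nuclide] = {n.name: n for n in (CS134, CS137)}


def get_nuclide(name: str | Nuclide) -> Nuclide:
    if isinstance(name, Nuclide):
        return name
    try:
        return NUCLIDES[name.lower()]
    except KeyError:
        raise KeyError(f"unknown nuclide {name!r}; registered: {sorted(NUCLIDES)}") from None


@dataclass(frozen=True)
class Activity:
    """A (possibly censored) activity measurement in Bq at a reference date.

    For a detected value, ``value`` and ``sigma`` hold the measurement and
    its 1-sigma counting uncertainty. For a censored one (below the
    detection limit, printed "LDL" in survey tables) ``value``/``sigma``
    are ``None`` and ``detection_limit`` carries the limit, which is itself
    decay-corrected when the record changes reference date.
    """

    nuclide: Nuclide
    reference_date: datetime.date
    value: float | None = None
    sigma: float | None = None
    censored: bool = False
    detection_limit: float | None = None

    def __post_init__(self) -> None:
        if self.censored:
            if self.detection_limit is None or self.detection_limit <= 0:
                raise ValueError("censored activity requires a positive detection_limit")
            if self.sigma is not None:
                raise ValueError("censored activity carries no sigma")
        else:
            if self.value is None or self.value < 0:
                raise ValueError(f"activity value must be >= 0, got {self.value}")
            if self.sigma is None or self.sigma < 0:
                raise ValueError(f"activity sigma must be >= 0, got {self.sigma}")

    def require_value(self) -> float:
        if self.censored or self.value is None:
            raise CensoredActivityError(
                f"{self.nuclide.name} activity at {self.reference_date} is censored "
                f"(< {self.detection_limit} Bq)"
            )
        return self.value


@dataclass(frozen=True)
class ValueWithSigma:
    """A derived scalar with first-order propagated 1-sigma uncertainty."""

    value: float
    sigma: float

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")


def parse_date(text: str | datetime.date) -> datetime.date:
    """Parse ISO-8601 ``YYYY-MM-DD`` or the survey-table ``YYYY/M/D`` dialect."""
    if isinstance(text, datetime.date):
        return text
    s = str(text).strip()
    for fmt in ("%Y-%m-%d", "%Y/%m/%d"):
        try:
            return datetime.datetime.strptime(s, fmt).date()
        except ValueError:
            continue
    raise ValueError(f"unparseable date {text!r} (expected YYYY-MM-DD or YYYY/M/D)")


def elapsed_years(from_date: datetime.date, to_date: datetime.date) -> float:
    """Signed elapsed time in years: whole-day difference divided by 365.25.

    Antisymmetric in its arguments; dates carry no time of day.
    """
    return ((parse_date(to_date) - parse_date(from_date)).days) / DAYS_PER_YEAR


def decay_factor(nuclide: str | Nuclide, from_date: datetime.date, to_date: datetime.date) -> float:
    """Multiplicative factor taking an activity from ``from_date`` to ``to_date``.

    ``exp(-ln2 * dt / T_half)``; < 1 going forward in time, > 1 going back,
    and ``factor(a, b) * factor(b, a) == 1``.
    """
    nuc = get_nuclide(nuclide)
    return math.exp(-math.log(2.0) * elapsed_years(from_date, to_date) / nuc.half_life_years)


def decay_correct(a: Activity, target_date: datetime.date) -> Activity:
    """Re-reference an activity to ``target_date``.

    Value and sigma scale by the same (exact) decay factor, so the relative
    uncertainty is unchanged. A censored activity stays censored with its
    detection limit scaled by the factor.
    """
    target = parse_date(target_date)
    f = decay_factor(a.nuclide, a.reference_date, target)
    if a.censored:
        return replace(a, reference_date=target, detection_limit=a.detection_limit * f)
    return replace(
        a,
        reference_date=target,
        value=a.value * f,
        sigma=a.sigma * f,
        detection_limit=None if a.detection_limit is None else a.detection_limit * f,
    )


def isotope_ratio(a134: Activity, a137: Activity, at_date: datetime.date = ACCIDENT_DATE) -> ValueWithSigma:
    """Cs-134/Cs-137 activity ratio at a common reference date.

    Both inputs are decay-corrected to ``at_date`` internally, then
    R = A134/A137 with (sigma_R/R)^2 = (s134/A134)^2 + (s137/A137)^2.
    The ratio at 2011-03-11 attributes material to a reactor unit
    (about 0.94 / 1.08 / 1.05 for Units 1/2/3).
    """
    if a134.censored:
        raise CensoredActivityError("cannot form isotope ratio: cs134 activity is censored")
    if a137.censored:
        raise CensoredActivityError("cannot form isotope ratio: cs137 activity is censored")
    n = decay_correct(a134, at_date)
    d = decay_correct(a137, at_date)
    if d.value == 0:
        raise UndefinedRatioError("cs137 activity is zero; ratio undefined")
    r = n.value / d.value
    rel2 = 0.0
    if n.value > 0:
        rel2 += (n.sigma / n.value) ** 2
    rel2 += (d.sigma / d.value) ** 2
    return ValueWithSigma(value=r, sigma=abs(r) * math.sqrt(rel2))
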