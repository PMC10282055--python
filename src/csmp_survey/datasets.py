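"""Packaged reference tables from the published mask-wearing campaign.

Four small CSVs transcribe the campaign's printed results: worn-date
activities of the 48 isolated CsMPs with measurement metadata, the same
particles decay-corrected to 2011-03-11 with estimated volumes and
diameters, the 51 stacked-pair collection efficiencies, and the CsMP
share of each host mask's activity with worn dates. Censored Cs-134
entries are recorded as ``LDL`` with an empty sigma, exactly as printed.

Two tables disagree on a handful of particle IDs (one mask renamed, two
particle series swapped between sibling masks); ``match_worn_to_2011``
reconciles them by ID where possible and by closest activity otherwise,
reporting every non-identity match so the reconciliation is auditable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources

import pandas as pd

__all__ = [
    "load_worn_activities",
    "load_activities_2011",
    "load_pair_efficiencies",
    "load_mask_fractions",
    "printed_ulp",
    "matches_printed",
    "match_worn_to_2011",
]

_NUMERIC_SENTINELS = {"LDL", "-", "–", ""}


def _read(name: str, numeric: list[str], raw: bool) -> pd.DataFrame:
    path = resources.files("csmp_survey.data").joinpath(name)
    with resources.as_file(path) as p:
        df = pd.read_csv(p, dtype=str, keep_default_na=False)
    if raw:
        return df
    out = df.copy()
    for col in numeric:
        out[col] = pd.to_numeric(df[col].where(~df[col].isin(_NUMERIC_SENTINELS)), errors="raise")
    return out


def load_worn_activities(raw: bool = False) -> pd.DataFrame:
    """Isolated-CsMP activities referenced to the worn date (48 rows).

    Columns include measurement date and live time; ``previously_reported``
    marks the four particles already known before this campaign. With
    ``raw=True`` every cell is returned as its printed string (``LDL`` for
    censored Cs-134), which the last-digit reproduction sweeps need.
    """
    df = _read(
        "csmp_worn_activities.csv",
        ["live_time_s", "a134_bq", "a134_sigma", "a137_bq", "a137_sigma"],
        raw,
    )
    if not raw:
        df["previously_reported"] = df["previously_reported"].map({"true": True, "false": False})
    return df


def load_activities_2011(raw: bool = False) -> pd.DataFrame:
    """Particle activities at 2011-03-11 with estimated volume/diameter (45 rows).

    The three non-spherical particles of one mask are excluded from this
    table by the original sizing analysis, hence 45 rows rather than 48.
    """
    return _read(
        "csmp_activities_2011.csv",
        ["a134_2011_bq", "a134_2011_sigma", "a137_2011_bq", "a137_2011_sigma", "volume_cm3", "diameter_um"],
        raw,
    )


def load_pair_efficiencies(raw: bool = False) -> pd.DataFrame:
    """Stacked-pair collection efficiencies with outer-mask activity (51 rows)."""
    return _read("pair_collection_efficiency.csv", ["a137_outer_bq", "efficiency_pct"], raw)


def load_mask_fractions(raw: bool = False) -> pd.DataFrame:
    """CsMP and host-mask worn-date activities with the percent share (48 rows)."""
    return _read(
        "csmp_mask_fractions.csv",
        [
            "a134_bq",
            "a134_sigma",
            "a137_bq",
            "a137_sigma",
            "mask_a134_bq",
            "mask_a134_sigma",
            "mask_a137_bq",
            "mask_a137_sigma",
            "fraction_pct",
        ],
        raw,
    )


def printed_ulp(printed: str) -> float:
    """One unit in the last printed digit of a decimal or e-notation string.

    ``"1.15" -> 0.01``, ``"0.0170" -> 0.0001``, ``"2.51e-12" -> 0.01e-12``,
    ``"102" -> 1``. This is the natural tolerance when checking that a
    recomputed value reproduces a rounded printed one.
    """
    s = printed.strip().lower()
    if "e" in s:
        mantissa, exp = s.split("e")
        return printed_ulp(mantissa) * 10.0 ** int(exp)
    if "." in s:
        return 10.0 ** -(len(s) - s.index(".") - 1)
    return 1.0


def matches_printed(computed: float, printed: str) -> bool:
    """Does a recomputed value reproduce a rounded printed one?

    Printed tables were computed from unrounded inputs and then rounded;
    recomputing from the rounded printed inputs can land one last-digit
    unit away even when both chains agree. The check therefore rounds the
    recomputed value to the printed precision and allows one unit in the
    last digit, i.e. |computed - printed| <= 1.5 ulp.
    """
    return abs(computed - float(printed)) <= 1.5 * printed_ulp(printed) * (1.0 + 1e-9)


@dataclass(frozen=True)
class IdMatch:
    worn_id: str
    id_2011: str
    by_activity: bool


def match_worn_to_2011() -> list[IdMatch]:
    """Pair worn-date particle rows with 2011-reference rows.

    Exact ID matches first; leftovers (the known typo cluster) are paired
    greedily by closest worn-date Cs-137 activity against the fraction
    table, whose IDs agree with the 2011 table and which carries the same
    worn-date measurements. Matches made by activity are flagged.
    """
    worn = load_worn_activities()
    t2011 = load_activities_2011()
    frac = load_mask_fractions().set_index("particle_id")

    ids_2011 = set(t2011["particle_id"])
    matches: list[IdMatch] = []
    unmatched_worn = []
    for row in worn.itertuples():
        if row.particle_id in ids_2011:
            matches.append(IdMatch(row.particle_id, row.particle_id, by_activity=False))
        else:
            unmatched_worn.append(row)
    taken = {m.id_2011 for m in matches}
    free_2011 = [pid for pid in t2011["particle_id"] if pid not in taken]
    for row in unmatched_worn:
        candidates = [pid for pid in free_2011 if pid in frac.index]
        if not candidates:
            continue
        best = min(
            candidates,
            key=lambda pid: abs(math.log(frac.loc[pid, "a137_bq"] / row.a137_bq)),
        )
        # particles absent from the 2011 table (non-spherical, not sized)
        # must not steal a slot: require activity agreement within 20%
        if abs(math.log(frac.loc[best, "a137_bq"] / row.a137_bq)) > math.log(1.2):
            continue
        matches.append(IdMatch(row.particle_id, best, by_activity=True))
        free_2011.remove(best)
    return matches
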