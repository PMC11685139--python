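"""Cohort construction: target-drug matching, demographics, 2x2 tables.

Counting conventions
--------------------
The counting unit for adverse events is the distinct (case, PT) pair;
"patients" are distinct deduplicated cases.  ``N`` for a contingency
table is the total number of case-PT pairs in the deduplicated
universe.  At SOC level a case contributes one unit to a SOC if any of
its PTs maps there under the primary-SOC mapping (distinct case-SOC
pairs).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, Mapping, Optional, Set, Tuple, Union

import numpy as np
import pandas as pd

__all__ = [
    "Cohort",
    "ContingencyTable",
    "PTSOCMap",
    "DEFAULT_TARGET_DICTIONARY",
    "DEFAULT_TARGET_ROLES",
    "normalize_drug_name",
    "match_target_drug",
    "normalize_age",
    "build_cohort",
    "summarize_cohort",
    "build_contingency",
    "contingency_all",
    "count_concomitants",
]

#: seed dictionary for the default target drug (generic, salt and brand names)
DEFAULT_TARGET_DICTIONARY = frozenset({"SORAFENIB", "SORAFENIB TOSYLATE", "NEXAVAR"})
#: suspect-drug roles used to attribute a report to the target drug
DEFAULT_TARGET_ROLES = frozenset({"PS", "SS"})

AGE_BANDS = ["<18", "18-44", "45-64", ">=65"]

#: divisor converting each age code to years
_AGE_FACTORS = {"DEC": 0.1, "YR": 1.0, "MON": 12.0, "WK": 52.143, "DY": 365.25, "HR": 8766.0}


def normalize_drug_name(name: str) -> str:
    """Upper-case, trim, and collapse internal whitespace."""
    return re.sub(r"\s+", " ", str(name).strip().upper())


@dataclass(frozen=True)
class ContingencyTable:
    """The 2x2 table of one drug-event pair against the database universe.

    ``a``: target-drug case-term pairs with the event, ``b``: without;
    ``c``/``d``: the same for all other reports.
    """

    a: int
    b: int
    c: int
    d: int

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def expected(self) -> float:
        """Expected count under independence, (a+b)(a+c)/N."""
        return (self.a + self.b) * (self.a + self.c) / self.n


@dataclass(frozen=True)
class Cohort:
    """Target-drug reports and the counting universe they sit in."""

    target_primaryids: frozenset
    n_target_patients: int
    n_target_events: int
    n_universe_patients: int
    n_universe_events: int


class PTSOCMap:
    """Mapping from MedDRA Preferred Term to its primary System Organ Class."""

    def __init__(self, mapping: Mapping[str, str]):
        self._map: Dict[str, str] = dict(mapping)

    def soc_of(self, pt: str) -> Optional[str]:
        return self._map.get(pt)

    def socs(self) -> Set[str]:
        return set(self._map.values())

    def __len__(self) -> int:
        return len(self._map)

    def map_events(self, events: pd.DataFrame) -> pd.DataFrame:
        """Aggregate case-PT pairs to distinct case-SOC pairs."""
        soc = events["pt"].map(self._map)
        out = pd.DataFrame({"primaryid": events["primaryid"], "soc": soc}).dropna()
        return out.drop_duplicates().reset_index(drop=True)

    @classmethod
    def from_tsv(cls, path: Union[str, Path]) -> "PTSOCMap":
        """Load a 3-column TSV (pt, soc, primary_flag); keeps primary rows."""
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        df.columns = [c.strip().lower() for c in df.columns]
        primary = df[df["primary_flag"].str.strip().isin(["1", "Y", "y", "true", "True"])]
        dup = primary["pt"].duplicated()
        if dup.any():
            raise ValueError(f"PT with more than one primary SOC: {sorted(primary['pt'][dup])[:5]}")
        return cls(dict(zip(primary["pt"], primary["soc"])))


def match_target_drug(
    drugs: pd.DataFrame,
    name_dictionary: Iterable[str] = DEFAULT_TARGET_DICTIONARY,
    roles: Iterable[str] = DEFAULT_TARGET_ROLES,
) -> Set[int]:
    """Select report ids with a dictionary-matching drug in an accepted role.

    Matching is exact on the normalized string (upper-case, trimmed,
    whitespace collapsed) against either the verbatim drug name or the
    active-ingredient field.
    """
    dictionary = {normalize_drug_name(n) for n in name_dictionary}
    if not dictionary:
        raise ValueError("target drug dictionary is empty")
    roles = set(roles)
    names = drugs["name"].map(normalize_drug_name)
    ingredients = drugs["active_ingredient"].map(normalize_drug_name)
    hit = (names.isin(dictionary) | ingredients.isin(dictionary)) & drugs["role"].isin(roles)
    return set(drugs.loc[hit, "primaryid"])


def normalize_age(value, code) -> float:
    """Convert an (age value, age code) pair to years; NaN means unknown.

    Codes: DEC decades, YR years, MON months, WK weeks, DY days, HR
    hours.  Negative values and unknown codes yield NaN.
    """
    factor = _AGE_FACTORS.get(str(code).upper())
    if factor is None or value is None:
        return float("nan")
    value = float(value)
    if np.isnan(value) or value < 0:
        return float("nan")
    return value / factor if factor >= 1 else value * 10.0


def age_years_column(cases: pd.DataFrame) -> pd.Series:
    """Vectorized :func:`normalize_age` over a case table."""
    years = pd.Series(np.nan, index=cases.index)
    for code, factor in _AGE_FACTORS.items():
        mask = cases["age_code"] == code
        if factor >= 1:
            years[mask] = cases.loc[mask, "age_value"] / factor
        else:
            years[mask] = cases.loc[mask, "age_value"] * 10.0
    years[years < 0] = np.nan
    return years


def age_band_column(years: pd.Series) -> pd.Series:
    """Assign the standard age bands; NaN ages map to 'unknown'."""
    band = pd.Series("unknown", index=years.index)
    band[years < 18] = "<18"
    band[(years >= 18) & (years < 45)] = "18-44"
    band[(years >= 45) & (years < 65)] = "45-64"
    band[years >= 65] = ">=65"
    return band


def distinct_case_events(events: pd.DataFrame, kept_primaryids: Iterable[int]) -> pd.DataFrame:
    """Restrict reactions to surviving reports and drop within-case PT repeats."""
    kept = set(kept_primaryids)
    out = events[events["primaryid"].isin(kept)]
    return out.drop_duplicates(subset=["primaryid", "pt"]).reset_index(drop=True)


def build_cohort(
    kept_cases: pd.DataFrame,
    events: pd.DataFrame,
    target_primaryids: Iterable[int],
) -> Tuple[Cohort, pd.DataFrame]:
    """Assemble the analysis cohort and the distinct case-PT event table.

    Returns the cohort bookkeeping plus the deduplicated event table
    (one row per case-PT pair in the universe).
    """
    universe_ids = set(kept_cases["primaryid"])
    target = frozenset(set(target_primaryids) & universe_ids)
    ev = distinct_case_events(events, universe_ids)
    is_target = ev["primaryid"].isin(target)
    cohort = Cohort(
        target_primaryids=target,
        n_target_patients=len(target),
        n_target_events=int(is_target.sum()),
        n_universe_patients=len(universe_ids),
        n_universe_events=len(ev),
    )
    return cohort, ev


def summarize_cohort(cohort: Cohort, cases: pd.DataFrame) -> Dict[str, pd.DataFrame]:
    """Demographic summary of the target cohort.

    Counts and percentages (denominator = target patients) for sex, age
    band, reporter, seriousness and outcome codes; mean +/- SD of age
    over reports with known age; mean events per patient.
    """
    if cohort.n_target_patients == 0:
        raise ValueError("cohort has zero target patients")
    sub = cases[cases["primaryid"].isin(cohort.target_primaryids)]
    n = cohort.n_target_patients

    def _freq(series: pd.Series, order=None) -> pd.DataFrame:
        counts = series.value_counts()
        if order is not None:
            counts = counts.reindex(order, fill_value=0)
        return pd.DataFrame(
            {"count": counts, "percent": (100.0 * counts / n).round(2)}
        )

    years = age_years_column(sub)
    bands = age_band_column(years)

    outcome_counts = pd.Series(
        [c for codes in sub["outcomes"] for c in codes], dtype="object"
    ).value_counts()
    outcomes = pd.DataFrame(
        {"count": outcome_counts, "percent": (100.0 * outcome_counts / n).round(2)}
    )

    known = years.dropna()
    age_stats = pd.DataFrame(
        {
            "n_known": [len(known)],
            "mean": [round(float(known.mean()), 2) if len(known) else np.nan],
            "sd": [round(float(known.std(ddof=1)), 2) if len(known) > 1 else np.nan],
        }
    )

    return {
        "sex": _freq(sub["sex"], order=["F", "M", "UNK"]),
        "age_band": _freq(bands, order=AGE_BANDS + ["unknown"]),
        "reporter": _freq(sub["reporter"]),
        "serious": _freq(sub["serious"].map({True: "serious", False: "non-serious"})),
        "outcomes": outcomes,
        "age": age_stats,
        "events_per_patient": pd.DataFrame(
            {
                "n_patients": [n],
                "n_events": [cohort.n_target_events],
                "mean_events_per_patient": [round(cohort.n_target_events / n, 1)],
            }
        ),
    }


def build_contingency(
    term: str,
    level: str,
    cohort: Cohort,
    events: pd.DataFrame,
    ptsoc: Optional[PTSOCMap] = None,
) -> ContingencyTable:
    """Build the 2x2 table for one PT or SOC against the universe.

    At PT level the margins are the case-PT pair totals of the cohort;
    at SOC level events are first aggregated to distinct case-SOC pairs.
    A term absent from the universe yields an a=0 table, not an error.
    """
    if level == "PT":
        ev = events
        term_col = "pt"
        n_target, n_universe = cohort.n_target_events, cohort.n_universe_events
    elif level == "SOC":
        if ptsoc is None:
            raise ValueError("SOC-level table requires a PT->SOC map")
        ev = ptsoc.map_events(events)
        term_col = "soc"
        is_t = ev["primaryid"].isin(cohort.target_primaryids)
        n_target, n_universe = int(is_t.sum()), len(ev)
    else:
        raise ValueError(f"level must be 'PT' or 'SOC', got {level!r}")

    with_term = ev[ev[term_col] == term]
    in_target = with_term["primaryid"].isin(cohort.target_primaryids)
    a = int(in_target.sum())
    c = len(with_term) - a
    return ContingencyTable(a=a, b=n_target - a, c=c, d=n_universe - n_target - c)


def contingency_all(
    cohort: Cohort, events: pd.DataFrame, level: str = "PT", ptsoc: Optional[PTSOCMap] = None
) -> pd.DataFrame:
    """Vectorized 2x2 cells for every term at once.

    Returns a DataFrame indexed by term with columns a, b, c, d —
    identical to calling :func:`build_contingency` per term.
    """
    if level == "PT":
        ev, term_col = events, "pt"
        n_target, n_universe = cohort.n_target_events, cohort.n_universe_events
    else:
        if ptsoc is None:
            raise ValueError("SOC-level tables require a PT->SOC map")
        ev, term_col = ptsoc.map_events(events), "soc"
        is_t = ev["primaryid"].isin(cohort.target_primaryids)
        n_target, n_universe = int(is_t.sum()), len(ev)

    is_target = ev["primaryid"].isin(cohort.target_primaryids)
    a = ev[is_target].groupby(term_col).size()
    total = ev.groupby(term_col).size()
    out = pd.DataFrame({"a": a.reindex(total.index, fill_value=0), "total": total})
    out["c"] = out["total"] - out["a"]
    out["b"] = n_target - out["a"]
    out["d"] = n_universe - n_target - out["c"]
    return out[["a", "b", "c", "d"]].rename_axis(term_col)


def count_concomitants(
    drugs: pd.DataFrame,
    target_primaryids: Iterable[int],
    target_dictionary: Iterable[str] = DEFAULT_TARGET_DICTIONARY,
    top: Optional[int] = None,
) -> pd.DataFrame:
    """Rank non-target drugs by the number of distinct target reports naming them.

    A report listing the same base name twice counts once.  Ties are
    broken alphabetically.
    """
    target = set(target_primaryids)
    dictionary = {normalize_drug_name(s) for s in target_dictionary}
    sub = drugs[drugs["primaryid"].isin(target)].copy()
    sub["base_name"] = sub["name"].map(normalize_drug_name)
    sub = sub[~sub["base_name"].isin(dictionary) & (sub["base_name"] != "")]
    counts = (
        sub.drop_duplicates(subset=["primaryid", "base_name"])
        .groupby("base_name")
        .size()
        .rename("reports")
        .reset_index()
        .sort_values(["reports", "base_name"], ascending=[False, True], kind="mergesort")
        .reset_index(drop=True)
    )
    return counts.head(top) if top else counts
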