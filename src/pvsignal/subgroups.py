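"""Stratified disproportionality: ROR and BCPNN IC within subgroups.

The comparator is the within-stratum universe — the 2x2 table for a
term inside, say, the female stratum counts female target reports
against female non-target reports.  This avoids confounding by stratum
size; summing the within-stratum cells over all strata of a factor
reproduces the marginal table exactly.
"""

from __future__ import annotations

from typing import Iterable, Optional

import pandas as pd

from .cohort import (
    Cohort,
    age_band_column,
    age_years_column,
    build_cohort,
    contingency_all,
)
from .stats import bcpnn_ic, ror_stat
from .cohort import ContingencyTable

__all__ = ["FACTORS", "stratify", "subgroup_scores", "stratified_analysis"]

FACTORS = ("year", "sex", "age_band", "reporter", "serious")


def stratify(cases: pd.DataFrame, factor: str) -> pd.Series:
    """Assign each report to exactly one stratum of the given factor.

    Returns a Series of labels indexed by primaryid; missing values map
    to an ``unknown`` stratum.  Report year is taken from FDA_DT.
    """
    if factor == "year":
        labels = cases["fda_dt"].map(lambda d: str(d.year))
    elif factor == "sex":
        labels = cases["sex"].map({"F": "female", "M": "male"}).fillna("unknown")
    elif factor == "age_band":
        labels = age_band_column(age_years_column(cases))
    elif factor == "reporter":
        labels = cases["reporter"]
    elif factor == "serious":
        labels = cases["serious"].map({True: "serious", False: "non-serious"})
    else:
        raise ValueError(f"unsupported factor {factor!r}; choose from {FACTORS}")
    return pd.Series(labels.values, index=cases["primaryid"].values, name=factor)


def subgroup_scores(
    stratum_cases: pd.DataFrame,
    events: pd.DataFrame,
    target_primaryids: Iterable[int],
    terms: Optional[Iterable[str]] = None,
) -> pd.DataFrame:
    """ROR and IC per PT computed entirely within one stratum.

    A stratum with zero target events yields NaN scores (undefined,
    flagged by the caller), never an exception.
    """
    cohort, ev = build_cohort(stratum_cases, events, target_primaryids)
    if cohort.n_target_events == 0 or cohort.n_universe_events == 0:
        terms = list(terms) if terms is not None else []
        return pd.DataFrame(
            {"a": 0, "ror": float("nan"), "ror_lo": float("nan"), "ror_hi": float("nan"),
             "ic": float("nan"), "ic_lo": float("nan"), "ic_hi": float("nan")},
            index=pd.Index(terms, name="pt"),
        )
    cont = contingency_all(cohort, ev, level="PT")
    if terms is not None:
        terms = [t for t in terms]
        cont = cont.reindex(terms)
        cont["a"] = cont["a"].fillna(0).astype(int)
        cont["c"] = cont["c"].fillna(0).astype(int)
        cont["b"] = cohort.n_target_events - cont["a"]
        cont["d"] = cohort.n_universe_events - cohort.n_target_events - cont["c"]
    rows = []
    for term, r in cont.iterrows():
        t = ContingencyTable(int(r["a"]), int(r["b"]), int(r["c"]), int(r["d"]))
        ror, lo, hi = ror_stat(t)
        ic, ic_lo, ic_hi = bcpnn_ic(t)
        rows.append(
            {"pt": term, "a": t.a, "ror": ror, "ror_lo": lo, "ror_hi": hi,
             "ic": ic, "ic_lo": ic_lo, "ic_hi": ic_hi}
        )
    return pd.DataFrame(rows).set_index("pt")


def stratified_analysis(
    cases: pd.DataFrame,
    events: pd.DataFrame,
    target_primaryids: Iterable[int],
    factor: str,
    terms: Optional[Iterable[str]] = None,
) -> pd.DataFrame:
    """Long-format subgroup table over every stratum of one factor."""
    labels = stratify(cases, factor)
    frames = []
    for stratum in sorted(labels.unique()):
        ids = set(labels.index[labels == stratum])
        sub_cases = cases[cases["primaryid"].isin(ids)]
        scores = subgroup_scores(sub_cases, events, target_primaryids, terms=terms)
        scores = scores.reset_index()
        scores.insert(0, "stratum", stratum)
        scores.insert(0, "factor", factor)
        frames.append(scores)
    return pd.concat(frames, ignore_index=True)
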