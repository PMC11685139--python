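"""Time-to-onset (TTO) analysis: event date minus therapy start.

Only day-precise date pairs are usable; partial dates and negative
intervals are excluded with an explicit reason so that usable +
excluded always equals the total, per reason.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Dict, Iterable, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .dates import PartialDate

__all__ = [
    "OnsetRecord",
    "TTO_BINS",
    "compute_tto",
    "onset_records",
    "bin_tto",
    "median_tto",
    "rank_sum_test",
]

#: histogram bins in days, closed on both ends (same-day onset falls in 0-30)
TTO_BINS = ["0-30", "31-60", "61-90", "91-180", "181-360", ">360"]
_BIN_EDGES = [(0, 30), (31, 60), (61, 90), (91, 180), (181, 360)]


@dataclass(frozen=True)
class OnsetRecord:
    primaryid: int
    tto_days: Optional[int]
    usable: bool
    reason: str = ""


def compute_tto(
    primaryid: int,
    event_dt: Optional[PartialDate],
    therapy_start: Optional[PartialDate],
) -> OnsetRecord:
    """Days from (earliest) therapy start to the adverse event.

    Unusable when either date is missing or lacks day precision, or
    when the event precedes the start; the reason is recorded instead
    of raising.
    """
    if event_dt is None or therapy_start is None:
        return OnsetRecord(primaryid, None, False, "missing date")
    if event_dt.precision != "day" or therapy_start.precision != "day":
        return OnsetRecord(primaryid, None, False, "partial date")
    days = (event_dt.to_date() - therapy_start.to_date()).days
    if days < 0:
        return OnsetRecord(primaryid, None, False, "negative")
    return OnsetRecord(primaryid, days, True)


def onset_records(
    cases: pd.DataFrame,
    drugs: pd.DataFrame,
    target_primaryids: Iterable[int],
    target_dictionary: Iterable[str],
) -> pd.DataFrame:
    """One onset record per target report.

    The therapy start is the earliest start among the report's
    target-drug mentions (a report may list several therapy episodes).
    """
    from .cohort import normalize_drug_name

    target = set(target_primaryids)
    dictionary = {normalize_drug_name(s) for s in target_dictionary}
    sub = drugs[drugs["primaryid"].isin(target)].copy()
    names = sub["name"].map(normalize_drug_name)
    ingredients = sub["active_ingredient"].map(normalize_drug_name)
    sub = sub[names.isin(dictionary) | ingredients.isin(dictionary)]

    starts: Dict[int, PartialDate] = {}
    for pid, start in zip(sub["primaryid"], sub["therapy_start"]):
        if start is None:
            continue
        prev = starts.get(pid)
        if prev is None or start.sort_key() < prev.sort_key():
            starts[pid] = start

    events = dict(zip(cases["primaryid"], cases["event_dt"]))
    records = [
        compute_tto(pid, events.get(pid), starts.get(pid)) for pid in sorted(target)
    ]
    return pd.DataFrame(
        {
            "primaryid": [r.primaryid for r in records],
            "tto_days": [r.tto_days for r in records],
            "usable": [r.usable for r in records],
            "reason": [r.reason for r in records],
        }
    )


def bin_tto(records: pd.DataFrame) -> pd.DataFrame:
    """Histogram of usable TTO values over the standard day bins."""
    tto = records.loc[records["usable"], "tto_days"].astype(int)
    counts = {}
    for label, (lo, hi) in zip(TTO_BINS, _BIN_EDGES):
        counts[label] = int(((tto >= lo) & (tto <= hi)).sum())
    counts[">360"] = int((tto > 360).sum())
    out = pd.DataFrame({"count": pd.Series(counts).reindex(TTO_BINS)})
    total = out["count"].sum()
    out["percent"] = (100.0 * out["count"] / total).round(2) if total else 0.0
    return out


def median_tto(records: pd.DataFrame, stratifier: Optional[pd.Series] = None) -> pd.DataFrame:
    """Median and IQR of usable TTO, overall or per stratum.

    Even-sized strata use the midpoint rule; empty strata are omitted.
    """
    usable = records[records["usable"]].copy()
    usable["tto_days"] = usable["tto_days"].astype(float)
    if stratifier is None:
        usable["stratum"] = "all"
    else:
        usable["stratum"] = usable["primaryid"].map(stratifier).fillna("unknown")
    rows = []
    for label, grp in usable.groupby("stratum"):
        v = grp["tto_days"]
        rows.append(
            {
                "stratum": label,
                "n": len(v),
                "median": float(v.median()),
                "q1": float(v.quantile(0.25)),
                "q3": float(v.quantile(0.75)),
            }
        )
    return pd.DataFrame(rows).set_index("stratum")


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum / Mann-Whitney U


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """U for the first sample, counting ties as half wins."""
    gt = (x[:, None] > y[None, :]).sum()
    eq = (x[:, None] == y[None, :]).sum()
    return float(gt + 0.5 * eq)


def rank_sum_test(x: Sequence[float], y: Sequence[float]) -> Tuple[float, float, float]:
    """Two-sided Mann-Whitney U test.

    Returns ``(U, z, p)`` with U oriented to the first sample (large U
    means x tends to exceed y).  The p-value comes from exhaustive
    enumeration of all pooled splits when both samples have at most 8
    observations, otherwise from the tie-corrected normal approximation
    with a 0.5 continuity correction.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = len(x), len(y)
    n = n1 + n2
    u = _u_statistic(x, y)
    mu = n1 * n2 / 2.0

    pooled = np.concatenate([x, y])
    _, tie_counts = np.unique(pooled, return_counts=True)
    if len(tie_counts) == 1:  # everything tied
        return u, 0.0, 1.0

    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    sigma = math.sqrt(n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1))))
    diff = u - mu
    z = (diff - 0.5 * np.sign(diff)) / sigma if sigma > 0 else 0.0
    from scipy.stats import norm

    if n1 <= 8 and n2 <= 8:
        # exact permutation null: every split of the pooled sample
        obs = abs(diff)
        extreme = total = 0
        idx = range(n)
        for comb in itertools.combinations(idx, n1):
            mask = np.zeros(n, dtype=bool)
            mask[list(comb)] = True
            u_perm = _u_statistic(pooled[mask], pooled[~mask])
            total += 1
            if abs(u_perm - mu) >= obs - 1e-12:
                extreme += 1
        p = extreme / total
    else:
        p = float(min(1.0, 2.0 * norm.sf(abs(z))))
    return u, float(z), p
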