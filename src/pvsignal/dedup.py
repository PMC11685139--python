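"""FDA-recommended deduplication of spontaneous reports.

A safety case (CASEID) accrues versions (PRIMARYID) as follow-up
information arrives.  The FDA-recommended cleaning keeps, per CASEID,
the version with the largest FDA_DT, breaking FDA_DT ties by the
largest PRIMARYID; cases appearing on any quarterly deleted-report list
are then excluded entirely.  Both steps are deterministic and
order-invariant.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Set

import pandas as pd

__all__ = ["DedupResult", "deduplicate", "apply_deletions"]


@dataclass(frozen=True)
class DedupResult:
    """Outcome of deduplication: surviving report versions and drop counts."""

    kept: pd.DataFrame  # one row per surviving primaryid (case columns preserved)
    dropped_duplicates: int
    dropped_deleted: int = 0

    @property
    def kept_primaryids(self) -> Set[int]:
        return set(self.kept["primaryid"])


def deduplicate(cases: pd.DataFrame) -> DedupResult:
    """Keep one report version per case: max (FDA_DT, then PRIMARYID).

    FDA_DT values of partial precision compare via their padded sort
    key (unknown month/day as 01), so a fully dated revision outranks a
    partial one from the same year.
    """
    if cases.empty:
        return DedupResult(kept=cases.copy(), dropped_duplicates=0)
    ordered = cases.sort_values(
        ["caseid", "fda_dt_key", "primaryid"], kind="mergesort"
    )
    kept = ordered.drop_duplicates(subset="caseid", keep="last").reset_index(drop=True)
    return DedupResult(kept=kept, dropped_duplicates=len(cases) - len(kept))


def apply_deletions(result: DedupResult, deleted: Iterable[int]) -> DedupResult:
    """Exclude cases whose CASEID is on a deleted-report list.

    Quarterly deleted lists are applied cumulatively: pass the union of
    all lists (a case deleted in any later quarter is excluded).
    Idempotent.
    """
    deleted = set(deleted)
    if not deleted or result.kept.empty:
        return result
    mask = result.kept["caseid"].isin(deleted)
    return replace(
        result,
        kept=result.kept[~mask].reset_index(drop=True),
        dropped_deleted=result.dropped_deleted + int(mask.sum()),
    )
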