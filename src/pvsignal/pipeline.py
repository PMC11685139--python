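"""End-to-end orchestration: files in, ranked signal tables out."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence, Set, Union

import pandas as pd

from . import dedup as _dedup
from .cohort import (
    Cohort,
    DEFAULT_TARGET_DICTIONARY,
    DEFAULT_TARGET_ROLES,
    PTSOCMap,
    build_cohort,
    contingency_all,
    match_target_drug,
)
from .io import QuarterData, concat_quarters, read_deleted_list, read_quarter
from .stats import GPSPrior, score_table
from .synthetic import _quarter_tag

__all__ = ["load_quarters", "AnalysisResult", "run_analysis"]


def load_quarters(
    directory: Union[str, Path], quarters: Sequence[str]
) -> tuple[QuarterData, Set[int]]:
    """Read a quarterly file set plus the union of its deleted lists.

    Files follow the packet naming convention (``DEMO19Q1.txt`` etc.,
    ``DELETED19Q1.txt``); deleted lists are optional per quarter and
    applied cumulatively.
    """
    directory = Path(directory)
    packets = []
    deleted: Set[int] = set()
    for label in quarters:
        tag = _quarter_tag(label)
        paths = {
            table: directory / f"{table.upper()}{tag}.txt"
            for table in ("demo", "drug", "reac", "ther", "outc")
        }
        paths = {k: v for k, v in paths.items() if v.exists()}
        packets.append(read_quarter(paths))
        del_path = directory / f"DELETED{tag}.txt"
        if del_path.exists():
            deleted |= read_deleted_list(del_path)
    return concat_quarters(packets), deleted


@dataclass
class AnalysisResult:
    """Everything the downstream reporting stages consume."""

    dedup: _dedup.DedupResult
    cohort: Cohort
    events: pd.DataFrame  # distinct case-PT pairs of the universe
    scores: pd.DataFrame  # per-PT disproportionality table
    soc_scores: Optional[pd.DataFrame] = None


def run_analysis(
    data: QuarterData,
    deleted: Iterable[int] = (),
    name_dictionary: Iterable[str] = DEFAULT_TARGET_DICTIONARY,
    roles: Iterable[str] = DEFAULT_TARGET_ROLES,
    ptsoc: Optional[PTSOCMap] = None,
    prior: Optional[GPSPrior] = None,
) -> AnalysisResult:
    """Deduplicate, build the cohort, and score every PT (and SOC).

    The MGPS prior is fitted across all PT-level pairs unless one is
    supplied.
    """
    result = _dedup.apply_deletions(_dedup.deduplicate(data.cases), deleted)
    target = match_target_drug(data.drugs, name_dictionary, roles)
    cohort, events = build_cohort(result.kept, data.events, target)
    scores = score_table(contingency_all(cohort, events, level="PT"), prior=prior)
    soc_scores = None
    if ptsoc is not None:
        soc_scores = score_table(
            contingency_all(cohort, events, level="SOC", ptsoc=ptsoc), prior=prior
        )
    return AnalysisResult(
        dedup=result, cohort=cohort, events=events, scores=scores, soc_scores=soc_scores
    )
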