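"""Readers for FAERS-style quarterly ASCII extracts.

A quarterly packet contains five "$"-delimited tables with one header
line (DEMO, DRUG, REAC, THER, OUTC) plus a plain-text list of deleted
case ids.  The readers are deliberately lenient at field level — an
unparseable date or age becomes "unknown", never a rejected record —
but strict about structure: every input line is accounted for either as
a parsed record or as a quarantine entry carrying a reason.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Union

import pandas as pd

from .dates import PartialDate, parse_partial_date

log = logging.getLogger(__name__)

__all__ = [
    "QuarterData",
    "FormatError",
    "read_quarter",
    "read_deleted_list",
    "write_table",
    "SERIOUS_OUTCOMES",
    "OUTCOME_CODES",
]

#: outcome codes whose presence makes a report "serious"; OT alone does not
SERIOUS_OUTCOMES = frozenset({"DE", "LT", "HO", "DS", "CA", "RI"})
OUTCOME_CODES = frozenset({"DE", "LT", "HO", "DS", "CA", "RI", "OT"})

DRUG_ROLES = frozenset({"PS", "SS", "C", "I"})
AGE_CODES = frozenset({"DEC", "YR", "MON", "WK", "DY", "HR"})

_REPORTER_MAP = {
    "MD": "physician",
    "PH": "pharmacist",
    "OT": "other health-professional",
    "HP": "other health-professional",
    "LW": "lawyer",
    "CN": "consumer",
}

REQUIRED_COLUMNS = {
    "demo": ["primaryid", "caseid", "fda_dt"],
    "drug": ["primaryid", "drug_seq", "role_cod", "drugname"],
    "reac": ["primaryid", "pt"],
    "ther": ["primaryid", "dsg_drug_seq", "start_dt"],
    "outc": ["primaryid", "outc_cod"],
}


class FormatError(ValueError):
    """A table header is missing a mandatory column."""


@dataclass
class QuarterData:
    """Typed contents of one quarterly packet.

    ``cases``/``drugs``/``events`` correspond to the deduplicatable
    report records, their drug mentions, and their MedDRA-coded
    reactions.  ``quarantine`` lists every input line (or field) that
    could not be used, with a reason, so that parsed + quarantined
    always accounts for the full input.
    """

    cases: pd.DataFrame
    drugs: pd.DataFrame
    events: pd.DataFrame
    quarantine: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["table", "primaryid", "field", "reason"])
    )

    def quarantine_csv(self, path) -> None:
        self.quarantine.to_csv(path, index=False)


def _read_table(path, table: str, quarantined: list) -> pd.DataFrame:
    """Read one "$"-delimited table with a single header line."""
    bad_lines: list = []

    def _collect(line):
        bad_lines.append(line)
        return None

    df = pd.read_csv(
        path,
        sep="$",
        dtype=str,
        keep_default_na=False,
        engine="python",
        on_bad_lines=_collect,
    )
    df.columns = [c.strip().lower() for c in df.columns]
    for col in REQUIRED_COLUMNS[table]:
        if col not in df.columns:
            raise FormatError(f"{table.upper()} table {path}: missing mandatory column {col!r}")
    for line in bad_lines:
        quarantined.append((table, None, "<line>", f"malformed line with {len(line)} fields"))
    return df


def _numeric_id(series: pd.Series) -> pd.Series:
    return pd.to_numeric(series.str.strip(), errors="coerce")


def read_quarter(paths: Mapping[str, Union[str, Path]]) -> QuarterData:
    """Read one quarterly packet into typed records.

    Parameters
    ----------
    paths
        Mapping with keys ``demo``, ``drug``, ``reac`` and optionally
        ``ther`` and ``outc``, each naming one ASCII table file.

    Returns
    -------
    QuarterData
        Cases (one row per report version, with seriousness/outcomes
        merged from OUTC), drug mentions (therapy start merged from
        THER), reaction mentions, and the quarantine log.

    Raises
    ------
    FormatError
        If a table header lacks a mandatory column.
    """
    quarantined: list = []

    demo = _read_table(paths["demo"], "demo", quarantined)
    drug = _read_table(paths["drug"], "drug", quarantined)
    reac = _read_table(paths["reac"], "reac", quarantined)
    ther = _read_table(paths["ther"], "ther", quarantined) if "ther" in paths else None
    outc = _read_table(paths["outc"], "outc", quarantined) if "outc" in paths else None

    cases = _build_cases(demo, outc, quarantined)
    drugs = _build_drugs(drug, ther, quarantined)
    events = _build_events(reac, quarantined)

    quarantine = pd.DataFrame(quarantined, columns=["table", "primaryid", "field", "reason"])
    return QuarterData(cases=cases, drugs=drugs, events=events, quarantine=quarantine)


def _build_cases(demo: pd.DataFrame, outc: Optional[pd.DataFrame], quarantined: list) -> pd.DataFrame:
    pid = _numeric_id(demo["primaryid"])
    cid = _numeric_id(demo["caseid"])
    fda = demo["fda_dt"].map(parse_partial_date)

    # structural failures quarantine the whole record
    bad_pid = pid.isna()
    bad_cid = ~bad_pid & cid.isna()
    missing_fda = ~bad_pid & ~bad_cid & fda.isna()
    for idx in demo.index[bad_pid]:
        quarantined.append(("demo", demo.at[idx, "primaryid"], "primaryid", "non-numeric primaryid"))
    for idx in demo.index[bad_cid]:
        quarantined.append(("demo", demo.at[idx, "primaryid"], "caseid", "non-numeric caseid"))
    for idx in demo.index[missing_fda]:
        quarantined.append(("demo", demo.at[idx, "primaryid"], "fda_dt", "missing or unparseable fda_dt"))
    keep = ~(bad_pid | bad_cid | missing_fda)

    demo = demo[keep]
    out = pd.DataFrame(
        {
            "primaryid": pid[keep].astype("int64"),
            "caseid": cid[keep].astype("int64"),
            "fda_dt": fda[keep],
        },
        index=demo.index,
    )
    out["fda_dt_key"] = out["fda_dt"].map(PartialDate.sort_key).astype("int64")
    out["event_dt"] = (
        demo["event_dt"].map(parse_partial_date) if "event_dt" in demo.columns else None
    )

    sex = demo["sex"].str.strip().str.upper() if "sex" in demo.columns else pd.Series("", index=demo.index)
    out["sex"] = sex.where(sex.isin(["F", "M"]), "UNK")

    if "age" in demo.columns:
        age_val = pd.to_numeric(demo["age"].str.strip(), errors="coerce")
        age_cod = demo.get("age_cod", pd.Series("", index=demo.index)).str.strip().str.upper()
        out["age_value"] = age_val
        out["age_code"] = age_cod.where(age_cod.isin(AGE_CODES), "UNK")
        out.loc[out["age_value"].isna(), "age_code"] = "UNK"
    else:
        out["age_value"] = float("nan")
        out["age_code"] = "UNK"

    occp = demo.get("occp_cod", pd.Series("", index=demo.index)).str.strip().str.upper()
    out["reporter"] = occp.map(_REPORTER_MAP).fillna("unknown")

    # seriousness from OUTC: serious iff any code in {DE,LT,HO,DS,CA,RI}
    if outc is not None and len(outc):
        opid = _numeric_id(outc["primaryid"])
        codes = outc["outc_cod"].str.strip().str.upper()
        valid = opid.notna() & codes.isin(OUTCOME_CODES)
        for idx in outc.index[~valid]:
            quarantined.append(("outc", outc.at[idx, "primaryid"], "outc_cod", "unknown outcome code or id"))
        grouped = (
            pd.DataFrame({"primaryid": opid[valid].astype("int64"), "code": codes[valid]})
            .drop_duplicates()
            .groupby("primaryid")["code"]
            .agg(lambda s: tuple(sorted(s)))
        )
        out["outcomes"] = out["primaryid"].map(grouped)
    else:
        out["outcomes"] = None
    out["outcomes"] = out["outcomes"].apply(lambda v: v if isinstance(v, tuple) else ())
    out["serious"] = out["outcomes"].apply(lambda codes: bool(SERIOUS_OUTCOMES.intersection(codes)))

    return out.reset_index(drop=True)


def _build_drugs(drug: pd.DataFrame, ther: Optional[pd.DataFrame], quarantined: list) -> pd.DataFrame:
    pid = _numeric_id(drug["primaryid"])
    seq = _numeric_id(drug["drug_seq"])
    role = drug["role_cod"].str.strip().str.upper()
    ok = pid.notna() & seq.notna() & role.isin(DRUG_ROLES)
    for idx in drug.index[~ok]:
        quarantined.append(("drug", drug.at[idx, "primaryid"], "role_cod/id", "bad id or role code"))
    out = pd.DataFrame(
        {
            "primaryid": pid[ok].astype("int64"),
            "drug_seq": seq[ok].astype("int64"),
            "name": drug.loc[ok, "drugname"].str.strip(),
            "active_ingredient": drug.loc[ok, "prod_ai"].str.strip()
            if "prod_ai" in drug.columns
            else "",
            "role": role[ok],
        }
    )
    if ther is not None and len(ther):
        tpid = _numeric_id(ther["primaryid"])
        tseq = _numeric_id(ther["dsg_drug_seq"])
        tok = tpid.notna() & tseq.notna()
        starts = pd.DataFrame(
            {
                "primaryid": tpid[tok].astype("int64"),
                "drug_seq": tseq[tok].astype("int64"),
                "therapy_start": ther.loc[tok, "start_dt"].map(parse_partial_date),
            }
        ).drop_duplicates(subset=["primaryid", "drug_seq"])
        out = out.merge(starts, on=["primaryid", "drug_seq"], how="left")
    else:
        out["therapy_start"] = None
    out["therapy_start"] = out["therapy_start"].where(out["therapy_start"].notna(), None)
    return out.reset_index(drop=True)


def _build_events(reac: pd.DataFrame, quarantined: list) -> pd.DataFrame:
    pid = _numeric_id(reac["primaryid"])
    pt = reac["pt"].str.strip()
    ok = pid.notna() & (pt != "")
    for idx in reac.index[~ok]:
        quarantined.append(("reac", reac.at[idx, "primaryid"], "pt", "empty PT or bad id"))
    return pd.DataFrame(
        {"primaryid": pid[ok].astype("int64"), "pt": pt[ok]}
    ).reset_index(drop=True)


def read_deleted_list(path: Union[str, Path]) -> set:
    """Read a deleted-case list: one CASEID per line, blanks ignored.

    Non-numeric tokens are logged and skipped rather than raising.
    """
    out: set = set()
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        tok = line.strip()
        if not tok:
            continue
        if not tok.isdigit():
            log.warning("deleted list %s line %d: non-numeric token %r skipped", path, lineno, tok)
            continue
        out.add(int(tok))
    return out


def write_table(df: pd.DataFrame, path: Union[str, Path]) -> None:
    """Write a table in the FAERS ASCII dialect ("$"-delimited, one header line)."""
    df.to_csv(path, sep="$", index=False)


def concat_quarters(quarters: Iterable[QuarterData]) -> QuarterData:
    """Concatenate several quarterly packets into one dataset."""
    quarters = list(quarters)
    return QuarterData(
        cases=pd.concat([q.cases for q in quarters], ignore_index=True),
        drugs=pd.concat([q.drugs for q in quarters], ignore_index=True),
        events=pd.concat([q.events for q in quarters], ignore_index=True),
        quarantine=pd.concat([q.quarantine for q in quarters], ignore_index=True),
    )
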