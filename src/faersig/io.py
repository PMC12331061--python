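"""Reading FAERS-dialect quarterly tables, deduplication and record linkage.

FAERS distributes each quarter as '$'-delimited ASCII files (DEMO, DRUG,
REAC, THER, OUTC).  A case (CASEID) may appear as several report versions
(PRIMARYID); the FDA-recommended deduplication keeps, within a CASEID, the
version with the largest FDA_DT and, among those, the largest PRIMARYID.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SchemaError", "EmptyTableError", "read_table", "deduplicate",
    "select_primary_suspect", "link_onset", "cohort_frame", "parse_faers_date",
    "OnsetTallies", "REQUIRED_COLUMNS",
]

REQUIRED_COLUMNS = {
    "DEMO": ["primaryid", "caseid", "fda_dt"],
    "DRUG": ["primaryid", "role_cod", "drugname"],
    "REAC": ["primaryid", "pt"],
    "THER": ["primaryid", "start_dt"],
    "OUTC": ["primaryid", "outc_cod"],
}


class SchemaError(ValueError):
    """A mandatory column is missing from a FAERS table."""


class EmptyTableError(ValueError):
    """The file contains a header but no data rows (or nothing at all)."""


def read_table(path: str | Path, table_kind: str) -> pd.DataFrame:
    """Read one '$'-delimited FAERS table as strings.

    Empty fields become ``NaN``; nothing is coerced to dates or numbers at
    this stage so that partial dates survive verbatim.  Column names are
    lower-cased.
    """
    kind = table_kind.upper()
    if kind not in REQUIRED_COLUMNS:
        raise ValueError(f"unknown table kind {table_kind!r}")
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="$", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise EmptyTableError(f"{path} is empty") from None
    df.columns = [c.strip().lower() for c in df.columns]
    for col in REQUIRED_COLUMNS[kind]:
        if col not in df.columns:
            raise SchemaError(f"{kind} table {path} lacks mandatory column {col!r}")
    if len(df) == 0:
        raise EmptyTableError(f"{path} contains no data rows")
    return df.mask(df == "")


def parse_faers_date(value: object) -> tuple[_dt.date | None, bool]:
    """Parse an 8-digit YYYYMMDD field.

    Returns ``(date, partial)``.  4- or 6-digit values (YYYY / YYYYMM) and
    anything unparseable yield ``(None, True)``; missing yields
    ``(None, False)``.
    """
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None, False
    s = str(value).strip()
    if not s or s.lower() == "nan":
        return None, False
    if len(s) == 8 and s.isdigit():
        try:
            return _dt.date(int(s[:4]), int(s[4:6]), int(s[6:8])), False
        except ValueError:
            return None, True
    return None, True


def deduplicate(demo: pd.DataFrame) -> pd.DataFrame:
    """One row per CASEID: keep max (FDA_DT, PRIMARYID) lexicographically.

    Output is sorted by ascending caseid.  Idempotent; an empty frame passes
    through unchanged.
    """
    if len(demo) == 0:
        return demo.copy()
    df = demo.copy()
    key_fda = pd.to_numeric(df["fda_dt"], errors="coerce").fillna(-1)
    key_pid = pd.to_numeric(df["primaryid"], errors="coerce").fillna(-1)
    key_case = pd.to_numeric(df["caseid"], errors="coerce")
    order = np.lexsort((key_pid.to_numpy(), key_fda.to_numpy()))
    df = df.iloc[order]
    df = df.groupby("caseid", sort=False).tail(1)
    df = df.iloc[np.argsort(key_case.loc[df.index].to_numpy(), kind="stable")]
    return df.reset_index(drop=True)


def select_primary_suspect(
    drug: pd.DataFrame, name_patterns: Sequence[str]
) -> set[str]:
    """PRIMARYIDs whose DRUG rows match a name pattern with role PS.

    Matching is case-insensitive substring over ``drugname`` and, when
    present, ``prod_ai``.
    """
    if not name_patterns:
        raise ValueError("name_patterns must contain at least one pattern")
    pats = [p.lower() for p in name_patterns]
    name_cols = [c for c in ("drugname", "prod_ai") if c in drug.columns]
    matched = np.zeros(len(drug), dtype=bool)
    for col in name_cols:
        names = drug[col].fillna("").str.lower()
        for p in pats:
            matched |= names.str.contains(p, regex=False).to_numpy()
    is_ps = drug["role_cod"].fillna("").str.upper().eq("PS").to_numpy()
    return set(drug.loc[matched & is_ps, "primaryid"].astype(str))


@dataclass
class OnsetTallies:
    """Attrition accounting for onset-time linkage."""

    n_candidates: int = 0
    n_missing_event: int = 0
    n_partial_or_missing_start: int = 0
    n_negative: int = 0
    n_used: int = 0

    def as_dict(self) -> dict[str, int]:
        return dict(self.__dict__)


def link_onset(
    demo: pd.DataFrame,
    ther: pd.DataFrame,
    index_ids: Iterable[str],
    drug: pd.DataFrame | None = None,
    name_patterns: Sequence[str] | None = None,
    zero_day_value: float = 0.5,
) -> tuple[pd.DataFrame, OnsetTallies]:
    """Onset times (event date minus therapy start, whole days) per report.

    ``demo`` must already be deduplicated.  When ``drug`` and
    ``name_patterns`` are given, THER rows are restricted to those whose
    ``dsg_drug_seq`` links to a matching drug row; with several eligible
    THER rows per report the earliest complete start date is used (first
    exposure defines time at risk).  Records with a partial or missing date
    on either side are excluded and tallied, as are negative intervals;
    zero-day onsets are set to ``zero_day_value`` so that a positive-support
    onset model remains applicable.

    Returns ``(frame with primaryid, onset_days, sex; tallies)``.
    """
    ids = set(map(str, index_ids))
    cases = demo.loc[demo["primaryid"].astype(str).isin(ids)].copy()
    t = OnsetTallies(n_candidates=len(cases))

    th = ther.loc[ther["primaryid"].astype(str).isin(ids)].copy()
    if drug is not None and name_patterns is not None and "dsg_drug_seq" in th.columns:
        pats = [p.lower() for p in name_patterns]
        name_cols = [c for c in ("drugname", "prod_ai") if c in drug.columns]
        m = np.zeros(len(drug), dtype=bool)
        for col in name_cols:
            names = drug[col].fillna("").str.lower()
            for p in pats:
                m |= names.str.contains(p, regex=False).to_numpy()
        if "drug_seq" in drug.columns:
            keys = set(zip(drug.loc[m, "primaryid"].astype(str),
                           drug.loc[m, "drug_seq"].astype(str)))
            th = th[[(pid, seq) in keys for pid, seq in
                     zip(th["primaryid"].astype(str), th["dsg_drug_seq"].astype(str))]]

    starts: dict[str, _dt.date] = {}
    partial_start_ids: set[str] = set()
    for pid, grp in th.groupby(th["primaryid"].astype(str)):
        parsed = [parse_faers_date(v) for v in grp["start_dt"]]
        complete = [d for d, part in parsed if d is not None]
        if complete:
            starts[pid] = min(complete)
        else:
            partial_start_ids.add(pid)

    rows = []
    for pid, ev in zip(cases["primaryid"].astype(str),
                       cases.get("event_dt", pd.Series(index=cases.index, dtype=object))):
        ev_date, ev_partial = parse_faers_date(ev)
        if ev_date is None:
            t.n_missing_event += 1
            continue
        start = starts.get(pid)
        if start is None:
            t.n_partial_or_missing_start += 1
            continue
        days = (ev_date - start).days
        if days < 0:
            t.n_negative += 1
            continue
        rows.append((pid, float(days) if days > 0 else zero_day_value))
    t.n_used = len(rows)

    out = pd.DataFrame(rows, columns=["primaryid", "onset_days"])
    sex_map = {"F": "female", "M": "male"}
    sex = (cases.set_index(cases["primaryid"].astype(str))["sex"]
           if "sex" in cases.columns else pd.Series(dtype=object))
    out["sex"] = [sex_map.get(str(sex.get(pid, "")), "unknown") for pid in out["primaryid"]]
    return out, t


_CONTINENT = {
    "US": "North America", "CA": "North America", "MX": "North America",
    "JP": "Asia", "CN": "Asia", "IN": "Asia", "KR": "Asia",
    "FR": "Europe", "DE": "Europe", "GB": "Europe", "PL": "Europe",
    "IT": "Europe", "ES": "Europe",
    "CO": "South America", "BR": "South America", "AR": "South America",
    "AU": "Oceania", "NZ": "Oceania",
}

_REPORTER = {"CN": "consumer", "PH": "pharmacist", "MD": "physician", "OT": "other"}


def _age_years(age: object, cod: object) -> float:
    try:
        v = float(age)
    except (TypeError, ValueError):
        return np.nan
    c = str(cod).upper() if isinstance(cod, str) else "YR"
    if c in ("", "YR", "NAN"):
        return v
    if c == "DEC":
        return v * 10.0
    if c == "MON":
        return v / 12.0
    if c == "WK":
        return v / 52.18
    if c == "DY":
        return v / 365.25
    return np.nan


def cohort_frame(demo: pd.DataFrame, outc: pd.DataFrame | None = None) -> pd.DataFrame:
    """Tidy per-report cohort frame for descriptive summaries.

    Maps FAERS codes to readable categories, derives age in years, report
    year from FDA_DT, continents from country codes, and per-report outcome
    lists; a report is 'serious' when it carries at least one OUTC row.
    """
    df = pd.DataFrame({"primaryid": demo["primaryid"].astype(str)})
    sex_map = {"F": "female", "M": "male"}
    df["sex"] = [sex_map.get(str(v), "unknown") if pd.notna(v) else "unknown"
                 for v in demo.get("sex", np.nan)]
    ages = [_age_years(a, c) for a, c in
            zip(demo.get("age", np.nan), demo.get("age_cod", "YR"))]
    df["age_years"] = ages
    df["reporter"] = [_REPORTER.get(str(v).upper(), "unknown") if pd.notna(v) else "unknown"
                      for v in demo.get("occp_cod", np.nan)]
    df["year"] = [str(v)[:4] if pd.notna(v) else "unknown" for v in demo["fda_dt"]]
    for src, dst in (("occr_country", "occurrence_country"),
                     ("reporter_country", "reporting_country")):
        vals = [str(v).upper() if pd.notna(v) else "unknown" for v in demo.get(src, np.nan)]
        df[dst] = vals
        df[dst.replace("country", "continent")] = [
            _CONTINENT.get(v, "Unknown") for v in vals]

    outcomes: dict[str, list[str]] = {}
    if outc is not None and len(outc):
        for pid, grp in outc.groupby(outc["primaryid"].astype(str)):
            outcomes[pid] = sorted(set(grp["outc_cod"].dropna().astype(str)))
    df["outcomes"] = [outcomes.get(pid, []) for pid in df["primaryid"]]
    df["serious"] = [len(o) > 0 for o in df["outcomes"]]
    return df
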