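"""2x2 contingency construction for drug-event disproportionality.

The counting unit throughout is the unique (report, PT) pair: a report
contributes at most once to a given event term but may contribute to many
terms, so a cohort of ~1,000 reports typically yields several thousand
adverse-event pairs.  For one event label against the index drug,

    a = index-drug reports mentioning the event
    b = (total index-drug pairs) - a
    c = other-drug reports mentioning the event
    d = (total other-drug pairs) - c
    E = (a+b)(a+c)/N,   N = a+b+c+d.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "build_pt_tables", "aggregate_soc", "build_drug_event_cells",
    "read_pt_soc_map", "CELL_COLUMNS",
]

CELL_COLUMNS = ["label", "a", "b", "c", "d", "expected"]


def _unique_pairs(events: pd.DataFrame) -> pd.DataFrame:
    ev = events[["primaryid", "pt"]].astype(str)
    return ev.drop_duplicates(ignore_index=True)


def build_pt_tables(events: pd.DataFrame, index_ids: Iterable[str]) -> pd.DataFrame:
    """One 2x2 cell per PT, index drug vs all other reports.

    ``events`` needs columns ``primaryid`` and ``pt``; repeated identical
    PTs within one report are collapsed first.
    """
    if len(events) == 0:
        raise ValueError("event set is empty")
    ev = _unique_pairs(events)
    ids = set(map(str, index_ids))
    is_idx = ev["primaryid"].isin(ids)
    n_index_pairs = int(is_idx.sum())
    n_total = len(ev)
    n_other_pairs = n_total - n_index_pairs

    a = ev.loc[is_idx, "pt"].value_counts()
    pt_tot = ev["pt"].value_counts()
    out = pd.DataFrame({"label": pt_tot.index})
    out["a"] = a.reindex(pt_tot.index).fillna(0).astype(int).to_numpy()
    out["c"] = (pt_tot - a.reindex(pt_tot.index).fillna(0)).astype(int).to_numpy()
    out["b"] = n_index_pairs - out["a"]
    out["d"] = n_other_pairs - out["c"]
    out["expected"] = (out["a"] + out["b"]) * (out["a"] + out["c"]) / n_total
    out = out.sort_values("label", ignore_index=True)[CELL_COLUMNS]
    return out


def aggregate_soc(pt_cells: pd.DataFrame, pt_to_soc: Mapping[str, str]) -> pd.DataFrame:
    """Sum member-PT cells to the system-organ-class level.

    Counting stays at the event (pair) level: SOC counts are plain sums of
    the member PT counts, without re-deduplicating reports that contribute
    several PTs inside one SOC.  PTs absent from the map are collected under
    ``unmapped``.  A ``proportion_pct`` column gives 100*a/sum(a).
    """
    df = pt_cells.copy()
    df["soc"] = [pt_to_soc.get(pt, "unmapped") for pt in df["label"]]
    n_index_pairs = int((df["a"] + df["b"]).iloc[0]) if len(df) else 0
    n_total = int((df[["a", "b", "c", "d"]].iloc[0]).sum()) if len(df) else 0
    g = df.groupby("soc", sort=True)[["a", "c"]].sum().reset_index()
    g = g.rename(columns={"soc": "label"})
    g["b"] = n_index_pairs - g["a"]
    g["d"] = (n_total - n_index_pairs) - g["c"]
    g["expected"] = (g["a"] + g["b"]) * (g["a"] + g["c"]) / n_total
    total_a = g["a"].sum()
    g["proportion_pct"] = 100.0 * g["a"] / total_a
    return g[CELL_COLUMNS + ["proportion_pct"]]


def build_drug_event_cells(
    events: pd.DataFrame, drug_of_report: Mapping[str, str] | pd.Series
) -> pd.DataFrame:
    """Observed and expected counts for every (drug, PT) cell of the corpus.

    This is the cell set an empirical-Bayes prior is fitted on: for each
    drug D and term P, ``a`` counts unique reports of D mentioning P, and
    ``E = (pairs of D)(pairs of P)/N`` is the independence expectation.
    Only cells with ``a >= 1`` are returned unless ``include_zero``.
    """
    ev = _unique_pairs(events)
    d = pd.Series(drug_of_report)
    d.index = d.index.astype(str)
    ev["drug"] = ev["primaryid"].map(d).fillna("UNKNOWN")
    n_total = len(ev)
    row = ev.groupby("drug").size()
    col = ev.groupby("pt").size()
    cells = ev.groupby(["drug", "pt"]).size().rename("a").reset_index()
    cells["expected"] = (row.loc[cells["drug"]].to_numpy()
                         * col.loc[cells["pt"]].to_numpy()) / n_total
    return cells


def read_pt_soc_map(path: str | Path) -> dict[str, str]:
    """Two-column CSV (pt, soc) -> mapping."""
    df = pd.read_csv(path, dtype=str)
    cols = [c.strip().lower() for c in df.columns]
    df.columns = cols
    if "pt" not in cols or "soc" not in cols:
        raise ValueError(f"PT->SOC map {path} must have columns pt,soc")
    return dict(zip(df["pt"], df["soc"]))
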