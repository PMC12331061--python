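"""Table-1-style clinical-characteristics summary of a deduplicated cohort.

Percentages use the deduplicated report count as denominator, are rounded
half-up to two decimals, and always surface missingness as explicit
``Not specified`` rows — in spontaneous-report data the missingness itself
(>80% unknown sex and age is typical) is a finding, not a nuisance.
Outcome rows count report-outcome pairs: a report may carry several
outcomes or none, so the outcome column need not sum to 100%.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

__all__ = ["round_half_up", "pct", "summarize_cases", "CohortSummary"]

_OUTCOME_LABELS = {
    "LT": "Life-threatening",
    "HO": "Hospitalization - initial or prolonged",
    "DS": "Disability",
    "DE": "Death",
    "OT": "Other",
}
_AGE_BINS = [(-np.inf, 18, "<18"), (18, 45, "18-44"), (45, 65, "45-64"),
             (65, np.inf, ">=65")]


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal round-half-up (the convention of clinical tables; numpy's
    banker's rounding would turn e.g. 0.125 into 0.12)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def pct(count: float, denom: float, ndigits: int = 2) -> float:
    """Percentage with half-up rounding."""
    if denom <= 0:
        raise ValueError("denominator must be positive")
    return round_half_up(100.0 * count / denom, ndigits)


@dataclass
class CohortSummary:
    table: pd.DataFrame            # group, label, count, percent
    age_stats: dict
    n: int

    def to_text(self) -> str:
        lines = [f"Clinical characteristics of the cohort (N = {self.n})", ""]
        for group, sub in self.table.groupby("group", sort=False):
            lines.append(group)
            for _, r in sub.iterrows():
                lines.append(f"  {r['label']:<42s} {r['count']:>6d} ({r['percent']:.2f})")
        a = self.age_stats
        lines += ["", "Age (years, quantitative)",
                  f"  N (missing)      {a['n']} ({a['missing']})"]
        if a["n"]:
            lines += [
                f"  Mean (SD)        {a['mean']:.2f} ({a['sd']:.2f})",
                f"  Median (Q1, Q3)  {a['median']:.2f} ({a['q1']:.2f}, {a['q3']:.2f})",
                f"  Min, Max         {a['min']:.2f}, {a['max']:.2f}",
            ]
        return "\n".join(lines)


def _freq_rows(rows, group, series, order=None, top_n=None, denom=None):
    counts = series.value_counts()
    if order is not None:
        labels = [l for l in order if l in counts.index]
        labels += [l for l in counts.index if l not in labels]
    else:
        labels = list(counts.sort_values(ascending=False).index)
    if top_n is not None:
        labels = [l for l in labels if l != "Not specified"][:top_n] + (
            ["Not specified"] if "Not specified" in labels else [])
    for lab in labels:
        c = int(counts[lab])
        rows.append((group, lab, c, pct(c, denom)))


def summarize_cases(cases: pd.DataFrame, top_n_countries: int = 5) -> CohortSummary:
    """Frequency table plus quantitative age statistics for a cohort frame.

    ``cases`` is the tidy frame from :func:`faersig.io.cohort_frame`
    (columns sex, age_years, reporter, year, occurrence/reporting
    country and continent, serious, outcomes).
    """
    n = len(cases)
    if n == 0:
        raise ValueError("empty cohort")
    rows: list[tuple] = []

    sex = cases["sex"].map({"female": "Female", "male": "Male"}).fillna("Not specified")
    _freq_rows(rows, "Gender", sex, order=["Female", "Male", "Not specified"], denom=n)

    age = pd.to_numeric(cases["age_years"], errors="coerce")
    age_grp = pd.Series("Not specified", index=cases.index)
    for lo, hi, lab in _AGE_BINS:
        age_grp[(age >= lo) & (age < hi)] = lab
    _freq_rows(rows, "Age", age_grp,
               order=[b[2] for b in _AGE_BINS] + ["Not specified"], denom=n)

    _freq_rows(rows, "Year of report", cases["year"].astype(str),
               order=sorted(cases["year"].astype(str).unique()), denom=n)

    rep = cases["reporter"].map({"consumer": "Consumer", "pharmacist": "Pharmacist",
                                 "physician": "Physician", "other": "Other"}
                                ).fillna("Not specified")
    _freq_rows(rows, "Reporter",
               rep, order=["Consumer", "Pharmacist", "Physician", "Other",
                           "Not specified"], denom=n)

    for col, group in (("occurrence_continent", "Continent of occurrence"),
                       ("occurrence_country", "Country of occurrence"),
                       ("reporting_continent", "Continent of the reporting country"),
                       ("reporting_country", "Reporting country")):
        if col in cases.columns:
            _freq_rows(rows, group, cases[col],
                       top_n=top_n_countries if "country" in col else None, denom=n)

    sev = cases["serious"].map({True: "Serious", False: "Non-serious"})
    _freq_rows(rows, "Severity", sev, order=["Serious", "Non-serious"], denom=n)

    # outcomes: per (report, outcome) pair; multi-valued and non-exhaustive
    outc = [o for lst in cases["outcomes"] for o in lst]
    for code, label in _OUTCOME_LABELS.items():
        c = outc.count(code)
        if c:
            rows.append(("Outcome", label, c, pct(c, n)))

    table = pd.DataFrame(rows, columns=["group", "label", "count", "percent"])

    obs = age.dropna()
    age_stats: dict = {"n": int(obs.size), "missing": int(n - obs.size)}
    if obs.size:
        q1, med, q3 = np.percentile(obs, [25, 50, 75])  # linear interpolation
        age_stats.update(
            mean=round_half_up(obs.mean()), sd=round_half_up(obs.std(ddof=1)),
            median=round_half_up(med), q1=round_half_up(q1), q3=round_half_up(q3),
            min=round_half_up(obs.min()), max=round_half_up(obs.max()),
        )
    return CohortSummary(table=table, age_stats=age_stats, n=n)
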