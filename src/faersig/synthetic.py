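"""Synthetic FAERS-like data generation with known ground truth.

Emits the five quarterly ASCII tables (DEMO, DRUG, REAC, THER, OUTC) in the
'$'-delimited FAERS dialect, together with a per-report ground-truth ledger.
The generator plants drug-event association signals of known strength for a
single index drug against a background of drug-independent events, injects
duplicate report versions (same CASEID, increasing FDA_DT/PRIMARYID),
missing demographics, and Weibull-distributed therapy-to-event onset times,
so that every downstream stage of the pipeline can be validated against a
recorded truth without any external download.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = ["SyntheticConfig", "SyntheticBundle", "generate_dataset", "default_vocabulary"]

_EPOCH = np.datetime64("1970-01-01")

# Marginal composition emulating a typical spontaneous-report cohort for a
# recently approved specialty drug: heavy missingness of demographics,
# consumer-dominated reporting, US-dominated geography, report volume
# growing over the post-approval years.
_SEX_PROBS = {"F": 0.735, "M": 0.265}
_YEAR_WEIGHTS = {2020: 0.1354, 2021: 0.1039, 2022: 0.1725, 2023: 0.2013, 2024: 0.3869}
_OCCP_PROBS = {"CN": 0.7829, "PH": 0.0724, "MD": 0.1447}
_COUNTRY_PROBS = {
    "US": 0.8609, "JP": 0.0436, "FR": 0.0353, "CO": 0.0148, "PL": 0.0111,
    "DE": 0.0130, "GB": 0.0120, "AU": 0.0083, "BR": 0.0010,
}
_OUTCOME_PROBS = {"LT": 0.0139, "HO": 0.2959, "DS": 0.0028, "DE": 0.0993, "OT": 0.3219}


def default_vocabulary(n_pts: int = 50, n_socs: int = 10) -> dict[str, str]:
    """Synthetic PT->SOC map: ``pt_001``..``pt_NNN`` spread over ``soc_01``...

    MedDRA itself is licensed and is never shipped; real analyses supply
    their own two-column mapping.
    """
    return {f"pt_{i + 1:03d}": f"soc_{i % n_socs + 1:02d}" for i in range(n_pts)}


def _default_rates(vocabulary: Mapping[str, str], mean_events: float = 3.5) -> dict[str, float]:
    """Power-law decaying per-PT marginal probabilities summing to ``mean_events``."""
    pts = list(vocabulary)
    w = np.arange(1, len(pts) + 1, dtype=float) ** -0.7
    r = mean_events * w / w.sum()
    if (r >= 1).any():
        r = np.clip(r, None, 0.95)
    return dict(zip(pts, r))


@dataclass(frozen=True)
class SyntheticConfig:
    """Generative conditions for one synthetic FAERS corpus.

    Defaults emulate the structure of a real post-marketing cohort: ~83%
    missing sex and ~85% missing age, onset times Weibull with scale ~187
    days and shape 0.73 (decreasing reporting hazard, i.e. early failure),
    a male/female onset-scale gap, and a handful of index-drug event terms
    reported at ten times their background rate.
    """

    n_reports: int = 2000
    index_fraction: float = 0.10
    duplicate_fraction: float = 0.15
    sex_missing_rate: float = 0.8284
    age_missing_rate: float = 0.8544
    vocabulary: Mapping[str, str] = field(default_factory=default_vocabulary)
    background_event_rates: Mapping[str, float] | None = None
    planted_signals: Mapping[str, float] = field(
        default_factory=lambda: {"pt_030": 10.0, "pt_040": 10.0, "pt_048": 10.0}
    )
    index_drug: str = "OSILODROSTAT"
    n_background_drugs: int = 20
    tto_scale_by_sex: Mapping[str, float] = field(
        default_factory=lambda: {"F": 187.21, "M": 82.5, "U": 187.21}
    )
    tto_shape_by_sex: Mapping[str, float] = field(
        default_factory=lambda: {"F": 0.73, "M": 0.73, "U": 0.73}
    )
    event_date_missing_rate: float = 0.45
    partial_start_fraction: float = 0.10
    negative_onset_fraction: float = 0.01
    seed: int = 0

    def rates(self) -> dict[str, float]:
        if self.background_event_rates is None:
            return _default_rates(self.vocabulary)
        return dict(self.background_event_rates)

    def validate(self) -> None:
        if not (isinstance(self.n_reports, (int, np.integer)) and self.n_reports > 0):
            raise ValueError("n_reports must be a positive integer")
        for name in (
            "index_fraction", "duplicate_fraction", "sex_missing_rate",
            "age_missing_rate", "event_date_missing_rate",
            "partial_start_fraction", "negative_onset_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if not self.vocabulary:
            raise ValueError("vocabulary must contain at least one PT")
        rates = self.rates()
        for pt, r in rates.items():
            if pt not in self.vocabulary:
                raise ValueError(f"background_event_rates: unknown PT {pt!r}")
            if not 0.0 < r < 1.0:
                raise ValueError(f"background_event_rates[{pt!r}] must lie in (0, 1), got {r}")
        for pt, lam in self.planted_signals.items():
            if pt not in self.vocabulary:
                raise ValueError(f"planted_signals: unknown PT {pt!r}")
            if not lam > 0:
                raise ValueError(f"planted_signals[{pt!r}] must be > 0, got {lam}")
        for name in ("tto_scale_by_sex", "tto_shape_by_sex"):
            m = getattr(self, name)
            for s in ("F", "M", "U"):
                if s not in m:
                    raise ValueError(f"{name} must define sexes F, M and U")
                if not m[s] > 0:
                    raise ValueError(f"{name}[{s!r}] must be > 0, got {m[s]}")
        if self.n_background_drugs < 1:
            raise ValueError("n_background_drugs must be >= 1")


@dataclass
class SyntheticBundle:
    """Raw tables plus the ground-truth ledger for one generated corpus."""

    tables: dict[str, pd.DataFrame]
    ledger: pd.DataFrame
    config: SyntheticConfig

    def write(self, out_dir: str | Path, quarter: str = "24Q3") -> dict[str, Path]:
        """Write '$'-delimited FAERS-dialect files plus ledger.csv / truth.json."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}
        for kind, df in self.tables.items():
            p = out / f"{kind}{quarter}.txt"
            df.to_csv(p, sep="$", index=False, lineterminator="\n")
            paths[kind] = p
        lp = out / "ledger.csv"
        self.ledger.to_csv(lp, index=False, lineterminator="\n")
        paths["LEDGER"] = lp
        tp = out / "truth.json"
        cfg = dataclasses.asdict(self.config)
        cfg["vocabulary"] = dict(self.config.vocabulary)
        for k in ("planted_signals", "tto_scale_by_sex", "tto_shape_by_sex"):
            cfg[k] = dict(cfg[k])
        cfg["background_event_rates"] = self.config.rates()
        tp.write_text(json.dumps(cfg, indent=1, sort_keys=True) + "\n")
        paths["TRUTH"] = tp
        return paths


def _fmt_dates(days: np.ndarray) -> np.ndarray:
    """Days-since-epoch -> YYYYMMDD strings."""
    d = _EPOCH + days.astype("timedelta64[D]")
    return np.char.replace(np.datetime_as_string(d, unit="D"), "-", "")


def generate_dataset(config: SyntheticConfig) -> SyntheticBundle:
    """Generate one corpus. Deterministic: same config and seed, same bytes."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_reports
    pts = list(config.vocabulary)
    rates = config.rates()
    p_bg = np.array([rates[pt] for pt in pts])

    caseid = 100000001 + np.arange(n)
    is_index = rng.random(n) < config.index_fraction
    sex_true = rng.choice(["F", "M"], size=n, p=[_SEX_PROBS["F"], _SEX_PROBS["M"]])
    sex_obs = np.where(rng.random(n) < config.sex_missing_rate, "", sex_true)
    age_true = np.clip(np.round(rng.normal(49.66, 16.23, size=n)), 16, 87)
    age_obs = np.where(rng.random(n) < config.age_missing_rate, "",
                       age_true.astype(int).astype(str))

    years = rng.choice(list(_YEAR_WEIGHTS), size=n, p=list(_YEAR_WEIGHTS.values()))
    year_start = (np.array([f"{y}-01-01" for y in years], dtype="datetime64[D]")
                  - _EPOCH).astype(int)
    start_day = year_start + rng.integers(0, 330, size=n)

    # Onset: continuous Weibull draw per sex stratum, then whole-day arithmetic.
    sex_key = np.where(sex_obs == "", "U", sex_obs)  # observability drives the stratum label
    scale = np.array([config.tto_scale_by_sex[s] for s in sex_key])
    shape = np.array([config.tto_shape_by_sex[s] for s in sex_key])
    onset_true = scale * rng.weibull(shape, size=n)
    onset_int = np.floor(onset_true).astype(int)
    event_day = start_day + onset_int

    # Data-quality defects: missing event dates, partial therapy start dates,
    # and a small rate of impossible (negative) intervals from entry errors.
    u = rng.random(n)
    missing_event = u < config.event_date_missing_rate
    negative = (~missing_event) & (u < config.event_date_missing_rate
                                   + config.negative_onset_fraction)
    event_day = np.where(negative, start_day - rng.integers(1, 60, size=n), event_day)
    partial_start = rng.random(n) < config.partial_start_fraction
    partial_kind = rng.choice(["YYYYMM", "YYYY"], size=n)

    fda_day = np.maximum(event_day, start_day) + rng.integers(5, 120, size=n)

    # Duplicate versions: same CASEID, larger FDA_DT and PRIMARYID for later
    # versions; ~30% of duplicate groups share FDA_DT so only the PRIMARYID
    # tie-break distinguishes the survivor.
    n_versions = np.where(rng.random(n) < config.duplicate_fraction,
                          rng.integers(2, 4, size=n), 1)
    fda_tied = rng.random(n) < 0.3

    # Drug assignment; ~1% of background reports also carry the index drug as
    # a concomitant (role C), exercising the primary-suspect filter.
    bg_w = np.arange(1, config.n_background_drugs + 1, dtype=float) ** -0.5
    bg_drugs = np.array([f"DRUG_{i + 1:02d}" for i in range(config.n_background_drugs)])
    drug = np.where(is_index, config.index_drug,
                    rng.choice(bg_drugs, size=n, p=bg_w / bg_w.sum()))
    concomitant_index = (~is_index) & (rng.random(n) < 0.01)

    # Event terms: independent Bernoulli per PT; planted PTs are reported by
    # index cases at rate min(lambda * p, 0.95).
    prob = np.tile(p_bg, (n, 1))
    for pt, lam in config.planted_signals.items():
        j = pts.index(pt)
        prob[is_index, j] = min(lam * p_bg[j], 0.95)
    has_pt = rng.random((n, len(pts))) < prob
    none_mask = ~has_pt.any(axis=1)
    if none_mask.any():  # every report mentions at least one event
        fallback = rng.choice(len(pts), size=int(none_mask.sum()), p=p_bg / p_bg.sum())
        has_pt[np.flatnonzero(none_mask), fallback] = True

    outc_draw = rng.random((n, len(_OUTCOME_PROBS)))
    has_outc = outc_draw < np.array(list(_OUTCOME_PROBS.values()))

    country = rng.choice(list(_COUNTRY_PROBS), size=n, p=list(_COUNTRY_PROBS.values()))
    rep_country = np.where(rng.random(n) < 0.01, "FR", country)
    occp = rng.choice(list(_OCCP_PROBS), size=n, p=list(_OCCP_PROBS.values()))

    start_full = _fmt_dates(start_day)
    start_str = np.where(partial_start,
                         np.where(partial_kind == "YYYY", [s[:4] for s in start_full],
                                  [s[:6] for s in start_full]),
                         start_full)
    event_str = np.where(missing_event, "", _fmt_dates(event_day))

    exclude_reason = np.where(missing_event, "missing_event",
                              np.where(partial_start, "partial_start",
                                       np.where(negative, "negative", "")))
    onset_expected = np.where(onset_int == 0, 0.5, onset_int.astype(float))
    onset_expected = np.where(exclude_reason == "", onset_expected, np.nan)

    # Expand versions (python loop over reports only for the id/date columns;
    # row tables below are built from the per-version frame).
    rep = np.repeat(np.arange(n), n_versions)
    ver = np.concatenate([np.arange(1, k + 1) for k in n_versions])
    primaryid = caseid[rep] * 10 + ver
    kmax = n_versions[rep]
    fda_v = np.where(fda_tied[rep], fda_day[rep],
                     fda_day[rep] + 30 * (ver - 1))
    final = ver == kmax

    demo = pd.DataFrame({
        "primaryid": primaryid.astype(str),
        "caseid": caseid[rep].astype(str),
        "caseversion": ver.astype(str),
        "fda_dt": _fmt_dates(fda_v),
        "event_dt": event_str[rep],
        "age": age_obs[rep],
        "age_cod": np.where(age_obs[rep] == "", "", "YR"),
        "sex": sex_obs[rep],
        "occp_cod": occp[rep],
        "reporter_country": rep_country[rep],
        "occr_country": country[rep],
    })

    drug_rows = [pd.DataFrame({
        "primaryid": primaryid.astype(str),
        "caseid": caseid[rep].astype(str),
        "drug_seq": "1",
        "role_cod": "PS",
        "drugname": drug[rep],
        "prod_ai": drug[rep],
    })]
    conc = concomitant_index[rep]
    if conc.any():
        drug_rows.append(pd.DataFrame({
            "primaryid": primaryid[conc].astype(str),
            "caseid": caseid[rep][conc].astype(str),
            "drug_seq": "2",
            "role_cod": "C",
            "drugname": config.index_drug,
            "prod_ai": config.index_drug,
        }))
    drug_df = pd.concat(drug_rows, ignore_index=True)
    drug_df = drug_df.sort_values(["primaryid", "drug_seq"], kind="stable",
                                  ignore_index=True)

    case_pts = [np.flatnonzero(row) for row in has_pt]
    n_pts_case = np.array([len(x) for x in case_pts])
    reac = pd.DataFrame({
        "primaryid": np.repeat(primaryid, n_pts_case[rep]).astype(str),
        "caseid": np.repeat(caseid[rep], n_pts_case[rep]).astype(str),
        "pt": np.array(pts, dtype=object)[np.concatenate(
            [case_pts[i] for i in rep])],
    })

    ther = pd.DataFrame({
        "primaryid": primaryid.astype(str),
        "caseid": caseid[rep].astype(str),
        "dsg_drug_seq": "1",
        "start_dt": start_str[rep],
        "end_dt": "",
    })

    n_outc_case = has_outc.sum(axis=1)
    outc_codes = np.array(list(_OUTCOME_PROBS), dtype=object)
    outc = pd.DataFrame({
        "primaryid": np.repeat(primaryid, n_outc_case[rep]).astype(str),
        "caseid": np.repeat(caseid[rep], n_outc_case[rep]).astype(str),
        "outc_cod": np.concatenate(
            [outc_codes[has_outc[i]] for i in rep]
        ) if (n_outc_case[rep] > 0).any() else np.array([], dtype=object),
    })

    ledger = pd.DataFrame({
        "primaryid": (caseid * 10 + n_versions).astype(str),  # surviving version
        "caseid": caseid.astype(str),
        "n_versions": n_versions,
        "is_index": is_index,
        "drug": drug,
        "true_sex": sex_true,
        "sex_observed": np.where(sex_obs == "", "unknown",
                                 np.where(sex_obs == "F", "female", "male")),
        "true_age": age_true,
        "onset_days_true": onset_true,
        "onset_days": onset_expected,
        "exclude_reason": exclude_reason,
    })

    tables = {"DEMO": demo, "DRUG": drug_df, "REAC": reac, "THER": ther, "OUTC": outc}
    return SyntheticBundle(tables=tables, ledger=ledger, config=config)
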