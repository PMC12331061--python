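"""End-to-end orchestration: simulate -> ingest -> dedup -> contingency ->
signals -> time-to-onset -> descriptives, with ranked output tables.

Every exclusion along the way (duplicate versions removed, partial or
missing dates, negative intervals, cells below the case threshold) is
counted into the manifest so a report's attrition is fully auditable, and
every number in the output bundle is reproducible from the manifest's
config + seed alone.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from . import __version__
from .contingency import (aggregate_soc, build_drug_event_cells,
                          build_pt_tables, read_pt_soc_map)
from .descriptives import summarize_cases
from .io import (cohort_frame, deduplicate, link_onset, read_table,
                 select_primary_suspect)
from .signals import DisproportionalityModel
from .synthetic import SyntheticConfig, generate_dataset
from .tto import DEFAULT_BIN_EDGES, WeibullOnsetModel

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "rank_signals"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Single configuration for the full pipeline.

    Either ``input_dir`` points at existing FAERS-dialect quarter files, or
    ``simulate=True`` generates a synthetic corpus first (using
    ``synthetic`` overrides, seeded from ``seed``).
    """

    out_dir: str = "faersig_out"
    input_dir: str | None = None
    simulate: bool = True
    synthetic: dict = field(default_factory=dict)
    drug_patterns: Sequence[str] = ("osilodrostat",)
    pt_soc_map: str | None = None
    ic_variant: str = "bate"
    min_cases: int = 3
    yates: bool = True
    bins: Sequence[int] = DEFAULT_BIN_EDGES
    top_n: int = 30
    seed: int = 0
    make_plots: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def rank_signals(estimates: pd.DataFrame, by: str = "frequency",
                 n: int = 30) -> pd.DataFrame:
    """Top-n rows among is_signal=True, by case frequency or ROR intensity.

    Ties break deterministically (frequency desc, ROR desc, label asc)."""
    sig = estimates[estimates["is_signal"]].copy()
    if by == "frequency":
        keys, asc = ["a", "ror", "label"], [False, False, True]
    elif by == "ror":
        keys, asc = ["ror", "a", "label"], [False, False, True]
    else:
        raise ValueError("by must be 'frequency' or 'ror'")
    return sig.sort_values(keys, ascending=asc, kind="mergesort",
                           ignore_index=True).head(n)


def _find_table(directory: Path, kind: str) -> Path:
    hits = sorted(directory.glob(f"{kind}*.txt"))
    if not hits:
        raise FileNotFoundError(f"no {kind}*.txt in {directory}")
    return hits[0]


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage; returns the manifest dict.

    Output CSVs land in ``config.out_dir``; a failing stage removes the
    partial outputs it created and raises :class:`PipelineError` naming
    the stage.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    created: list[Path] = []

    def emit(name: str, df: pd.DataFrame) -> None:
        p = out / name
        df.to_csv(p, index=False, lineterminator="\n")
        created.append(p)

    manifest: dict = {"package": "faersig", "version": __version__,
                      "seed": config.seed, "counts": {}}
    stage = "setup"
    try:
        stage = "simulate"
        if config.simulate and config.input_dir is None:
            syn = dict(config.synthetic)
            syn.setdefault("seed", config.seed)
            bundle = generate_dataset(SyntheticConfig(**syn))
            data_dir = out / "raw"
            bundle.write(data_dir)
            pt_map = dict(bundle.config.vocabulary)
        else:
            data_dir = Path(config.input_dir)
            pt_map = read_pt_soc_map(config.pt_soc_map) if config.pt_soc_map else {}

        stage = "ingest"
        demo = read_table(_find_table(data_dir, "DEMO"), "DEMO")
        drug = read_table(_find_table(data_dir, "DRUG"), "DRUG")
        reac = read_table(_find_table(data_dir, "REAC"), "REAC")
        ther = read_table(_find_table(data_dir, "THER"), "THER")
        outc = read_table(_find_table(data_dir, "OUTC"), "OUTC")
        manifest["counts"]["demo_rows_raw"] = len(demo)

        stage = "dedup"
        demo_d = deduplicate(demo)
        survivors = set(demo_d["primaryid"].astype(str))
        manifest["counts"]["cases_after_dedup"] = len(demo_d)
        manifest["counts"]["duplicate_versions_removed"] = len(demo) - len(demo_d)

        stage = "select"
        index_ids = select_primary_suspect(drug, list(config.drug_patterns))
        index_ids &= survivors
        manifest["counts"]["index_cases"] = len(index_ids)

        stage = "contingency"
        events = reac.loc[reac["primaryid"].astype(str).isin(survivors),
                          ["primaryid", "pt"]]
        pt_cells = build_pt_tables(events, index_ids)
        idx_mask = events["primaryid"].astype(str).isin(index_ids)
        manifest["counts"]["index_event_pairs"] = int(
            events[idx_mask].astype(str).drop_duplicates().shape[0])
        manifest["counts"]["total_event_pairs"] = int(
            events.astype(str).drop_duplicates().shape[0])
        soc_cells = aggregate_soc(pt_cells, pt_map)
        emit("soc_table.csv", soc_cells)

        stage = "signals"
        ps = drug[drug["role_cod"].fillna("").str.upper() == "PS"]
        drug_of_report = (ps.drop_duplicates("primaryid")
                          .set_index(ps.drop_duplicates("primaryid")["primaryid"]
                                     .astype(str))["drugname"])
        all_cells = build_drug_event_cells(events, drug_of_report)
        model = DisproportionalityModel(
            pt_cells, all_cells, min_cases=config.min_cases,
            ic_variant=config.ic_variant, yates=config.yates)
        res = model.fit()
        emit("pt_signals.csv", res.estimates)
        emit("pt_by_frequency.csv", res.rank("frequency", config.top_n))
        emit("pt_by_ror.csv", res.rank("ror", config.top_n))
        manifest["counts"]["signal_pts"] = int(res.estimates["is_signal"].sum())
        manifest["counts"]["cells_below_min_cases"] = int(
            (~res.estimates["min_cases_met"]).sum())
        manifest["mgps_prior"] = {
            "alpha1": res.prior.alpha1, "beta1": res.prior.beta1,
            "alpha2": res.prior.alpha2, "beta2": res.prior.beta2,
            "p_mix": res.prior.p_mix, "loglik": res.prior.loglik,
            "converged": res.prior.converged,
        }

        stage = "tto"
        onsets, tallies = link_onset(demo_d, ther, index_ids, drug,
                                     list(config.drug_patterns))
        manifest["counts"]["onset"] = tallies.as_dict()
        emit("onsets.csv", onsets)
        tto_block: dict = {}
        if len(onsets) >= 10:
            tmodel = WeibullOnsetModel.from_dataframe(onsets)
            tres = tmodel.fit()
            bins, curve = tres.distribution(tuple(config.bins))
            emit("tto_bins.csv", bins)
            emit("tto_ecdf.csv", curve)
            emit("tto_summary.csv", pd.DataFrame([{
                "n": tres.n, "scale": tres.scale,
                "scale_lo": tres.scale_ci[0], "scale_hi": tres.scale_ci[1],
                "shape": tres.shape,
                "shape_lo": tres.shape_ci[0], "shape_hi": tres.shape_ci[1],
                "median_days": tres.median_days,
                "q1_days": tres.iqr_days[0], "q3_days": tres.iqr_days[1],
                "failure_type": tres.failure_type, "loglik": tres.loglik,
            }]))
            tto_block = {"n": tres.n, "failure_type": tres.failure_type,
                         "median_days": tres.median_days}
            if (onsets["sex"] == "female").sum() >= 2 and \
                    (onsets["sex"] == "male").sum() >= 2:
                cmp_ = tres.compare_by_sex()
                tto_block["by_sex"] = {
                    "median_female": cmp_.median_female,
                    "median_male": cmp_.median_male,
                    "statistic": cmp_.statistic, "p": cmp_.p_two_sided,
                    "method": cmp_.method,
                }
            if config.make_plots:
                _plots(out, onsets, bins, curve, created)
        manifest["tto"] = tto_block

        stage = "describe"
        cohort = cohort_frame(demo_d, outc)
        summ = summarize_cases(cohort)
        emit("table1.csv", summ.table)
        (out / "table1.txt").write_text(summ.to_text() + "\n")
        created.append(out / "table1.txt")
        manifest["age_stats"] = summ.age_stats

        stage = "manifest"
        (out / "manifest.json").write_text(
            json.dumps(manifest, indent=1, sort_keys=True, default=str) + "\n")
        return manifest
    except Exception as exc:  # noqa: BLE001 - stage accounting, then re-raise
        for p in created:
            p.unlink(missing_ok=True)
        raise PipelineError(stage, exc) from exc


def _plots(out: Path, onsets: pd.DataFrame, bins: pd.DataFrame,
           curve: pd.DataFrame, created: list[Path]) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.bar(bins["bin"], 100 * bins["proportion"], color="#4878a8")
    ax.set_xlabel("time to onset (days)")
    ax.set_ylabel("% of reports")
    fig.tight_layout()
    p = out / "tto_distribution.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    created.append(p)

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.step(curve["days"], curve["cumulative"], where="post")
    ax.set_xlabel("days since therapy start")
    ax.set_ylabel("cumulative proportion of reported events")
    fig.tight_layout()
    p = out / "tto_cumulative.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    created.append(p)

    known = onsets[onsets["sex"].isin(["female", "male"])]
    if len(known) and known["sex"].nunique() == 2:
        fig, ax = plt.subplots(figsize=(5, 4))
        data = [known.loc[known["sex"] == s, "onset_days"] for s in ("female", "male")]
        ax.boxplot(data, tick_labels=["female", "male"])
        ax.set_ylabel("time to onset (days)")
        fig.tight_layout()
        p = out / "tto_by_sex.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        created.append(p)
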