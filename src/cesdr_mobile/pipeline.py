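"""End-to-end pipeline stages: simulate -> score -> latency profile -> model.

These functions are the programmatic counterpart of the command-line
interface; each writes its artifacts to an output directory and returns the
in-memory objects so tests and notebooks can inspect them directly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import psychometrics, rt, scoring, simulate
from .config import PipelineConfig
from .errors import DataIntegrityError
from .schema_model import LatencySchemaModel, SchemaTestResults

logger = logging.getLogger("cesdr_mobile")

REQUIRED_COLUMNS = simulate.SESSION_COLUMNS


def _config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _write_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, sort_keys=True, indent=2) + "\n")


@dataclass
class SimulationArtifacts:
    sessions_path: Path
    truth_path: Path
    aux_path: Path
    records: pd.DataFrame
    truth: dict
    aux: pd.DataFrame


def run_simulate(config: PipelineConfig, seed: Optional[int], outdir) -> SimulationArtifacts:
    """Generate a cohort and write sessions.csv, truth.json and aux_scales.csv."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cohort_cfg = config.cohort
    if seed is not None:
        cohort_cfg = dataclasses.replace(cohort_cfg, seed=seed)
    records, truth = simulate.simulate_cohort(cohort_cfg)
    aux = simulate.simulate_auxiliary_scales(truth, cohort_cfg)

    sessions_path = outdir / "sessions.csv"
    truth_path = outdir / "truth.json"
    aux_path = outdir / "aux_scales.csv"
    records.to_csv(sessions_path, index=False)
    _write_json(truth, truth_path)
    aux.to_csv(aux_path, index=False)
    _write_json(
        {
            "stage": "simulate",
            "config_hash": _config_hash(config),
            "seed": int(cohort_cfg.seed),
            "n_records": int(len(records)),
            "n_participants": int(cohort_cfg.n_participants),
        },
        outdir / "simulate_manifest.json",
    )
    logger.info("simulated %d records for %d participants", len(records), cohort_cfg.n_participants)
    return SimulationArtifacts(sessions_path, truth_path, aux_path, records, truth, aux)


def load_sessions(path) -> pd.DataFrame:
    """Read and validate a long-format session CSV.

    Schema violations are reported with 1-based file line numbers
    (header is line 1).
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise DataIntegrityError(f"{path}: empty input file") from exc
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise DataIntegrityError(f"{path}: missing column(s) {missing}")
    if len(df) == 0:
        raise DataIntegrityError(f"{path}: no data rows")

    bad = {}
    resp = pd.to_numeric(df["response"], errors="coerce")
    bad["response not in {0,1}"] = df.index[~resp.isin([0, 1])]
    rt_ms = pd.to_numeric(df["rt_ms"], errors="coerce")
    bad["rt_ms not positive"] = df.index[~(rt_ms > 0)]
    day = pd.to_numeric(df["day_index"], errors="coerce")
    bad["day_index not a positive integer"] = df.index[~((day >= 1) & (day % 1 == 0))]
    item = pd.to_numeric(df["item_id"], errors="coerce")
    bad["item_id not a positive integer"] = df.index[~((item >= 1) & (item % 1 == 0))]
    problems = [
        f"{reason} at line(s) {[int(i) + 2 for i in idx[:5]]}"
        for reason, idx in bad.items()
        if len(idx) > 0
    ]
    if problems:
        raise DataIntegrityError(f"{path}: " + "; ".join(problems))
    df["response"] = resp.astype(int)
    df["day_index"] = day.astype(int)
    df["item_id"] = item.astype(int)
    df["participant_id"] = df["participant_id"].astype(str)
    return df


@dataclass
class AnalysisArtifacts:
    scores_path: Path
    rt_path: Path
    statistics_path: Path
    report_path: Path
    residuals_path: Path
    cohort_scores: scoring.CohortScores
    profiles: pd.DataFrame
    statistics: dict
    results: SchemaTestResults

    @property
    def n_excluded(self) -> int:
        return self.cohort_scores.n_excluded


def run_analyze(
    sessions_path,
    config: PipelineConfig,
    outdir,
    aux_path=None,
    make_plots: bool = False,
) -> AnalysisArtifacts:
    """Run scoring -> latency profiling -> psychometrics -> schema model."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    records = load_sessions(sessions_path)

    cohort_scores = scoring.score_cohort(
        records,
        n_items=config.cohort.n_items,
        min_days=config.scoring.min_days,
        cutoff=config.scoring.cutoff,
    )
    summary = cohort_scores.summary
    n_total = len(summary)
    n_excluded = cohort_scores.n_excluded
    logger.info(
        "%d of %d participants excluded by the %d-day adherence rule",
        n_excluded,
        n_total,
        config.scoring.min_days,
    )
    scores_path = outdir / "scores.csv"
    summary.to_csv(scores_path, index=False)

    eligible_ids = summary.loc[summary["eligible"], "participant_id"]
    eligible_records = records[records["participant_id"].isin(eligible_ids)]
    profiles = rt.rt_profiles(
        eligible_records,
        winsorize_ms=config.winsorize_ms,
        expected_items=range(1, config.cohort.n_items + 1),
    )
    rt_path = outdir / "rt_profiles.csv"
    profiles.to_csv(rt_path, index=False)

    totals = summary.loc[summary["eligible"]].set_index("participant_id")["total"].astype(int)
    stats: dict = {
        "n_enrolled": n_total,
        "n_eligible": int(len(eligible_ids)),
        "n_excluded": n_excluded,
        "mobile_total": dataclasses.asdict(psychometrics.describe(totals.to_numpy())),
        "cronbach_alpha_mobile": psychometrics.cronbach_alpha(
            cohort_scores.item_scores.to_numpy()
        ),
        "method_notes": {
            "alpha_input": "converted 0-4 item scores of eligible participants",
            "percentiles": "SPSS HAVERAGE",
            "wilcoxon": "zero differences dropped, midranks, tie-corrected Z, "
            "exact p for n <= 12",
        },
    }

    if aux_path is not None:
        aux = pd.read_csv(aux_path).set_index("participant_id")
        aux = aux.loc[aux.index.intersection(totals.index)]
        merged_idx = totals.index.intersection(aux.index)
        stats["concurrent_validity"] = {}
        for col in aux.columns:
            res = psychometrics.spearman_rho(totals.loc[merged_idx], aux.loc[merged_idx, col])
            stats["concurrent_validity"][col] = {
                "rho": res.rho,
                "p_value": res.p_value,
                "n": res.n,
            }
        if "standard_total" in aux.columns:
            w = psychometrics.wilcoxon_signed_rank(
                aux.loc[merged_idx, "standard_total"], totals.loc[merged_idx]
            )
            stats["standard_vs_mobile_wilcoxon"] = {
                "w": w.w,
                "z": w.z,
                "p_value": w.p_value,
                "n": w.n,
                "exact": w.exact,
            }
            stats["standard_total"] = dataclasses.asdict(
                psychometrics.describe(aux.loc[merged_idx, "standard_total"].to_numpy())
            )

    statistics_path = outdir / "statistics.json"
    _write_json(stats, statistics_path)

    merged = profiles.merge(
        summary.loc[summary["eligible"], ["participant_id", "total"]], on="participant_id"
    )
    merged["total"] = merged["total"].astype(int)
    model = LatencySchemaModel.from_dataframe(merged)
    results = model.fit(alpha=config.alpha)

    report_path = outdir / "schema_report.json"
    _write_json(results.to_dict(), report_path)
    residuals_path = outdir / "residuals.tsv"
    results.residual_table().to_csv(residuals_path, sep="\t", index=False)

    if make_plots:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        ax = results.plot_fit()
        ax.figure.savefig(outdir / "fit_curves.png", dpi=150)
        plt.close(ax.figure)
        axes = results.plot_residuals()
        axes[0].figure.savefig(outdir / "residuals.png", dpi=150)
        plt.close(axes[0].figure)

    _write_json(
        {
            "stage": "analyze",
            "config_hash": _config_hash(config),
            "n_enrolled": n_total,
            "n_excluded": n_excluded,
            "preferred": results.preferred,
        },
        outdir / "analyze_manifest.json",
    )
    return AnalysisArtifacts(
        scores_path=scores_path,
        rt_path=rt_path,
        statistics_path=statistics_path,
        report_path=report_path,
        residuals_path=residuals_path,
        cohort_scores=cohort_scores,
        profiles=profiles,
        statistics=stats,
        results=results,
    )
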