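"""Descriptive outputs and end-to-end orchestration.

Baseline characteristics (counts, mean ± SD, percentages), the yearly
report trend, the sex-by-age pyramid, and :func:`run_pipeline`, which wires
the whole analysis together — ingest/simulate, clean, screen, model, time
to onset, descriptive tables — and records a manifest sufficient to re-run
the pipeline bit-identically.
"""

from __future__ import annotations

import dataclasses
import json
import platform
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, config
from ._util import percentage, round_half_up
from . import disproportionality as dp
from . import onset as onset_mod
from . import risk_modeling as rm
from .report_store import (
    ReportSet,
    clean_cascade,
    load_name_map,
    parse_quarter_files,
    partition_event,
    read_flat,
    write_flat,
    write_provenance,
)
from .synthetic import SimulationConfig, generate_reports


@dataclass(frozen=True)
class BaselineSummary:
    n_total: int
    age_mean: float
    age_sd: float
    weight_mean: float
    weight_sd: float
    sex_counts: dict
    sex_percentages: dict
    outcome_counts: dict
    outcome_percentages: dict
    country_counts: dict
    degenerate_n1: bool = False

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _most_serious(outcomes) -> str:
    for cat in config.OUTCOME_SEVERITY_ORDER:
        if cat in outcomes:
            return cat
    return "missing"


def baseline_table(clean_event_set: ReportSet) -> BaselineSummary:
    """Baseline characteristics of the event reports.

    Continuous variables are mean ± SD (n-1 denominator); categorical
    variables are counts with percentages of the total, rounded half-up to
    two decimals.  Each report contributes its single most serious outcome,
    so outcome counts sum to the total.
    """
    demo = clean_event_set.demo
    n = len(demo)
    if n == 0:
        raise ValueError("baseline table of an empty report set")
    degenerate = n == 1
    age = demo["age_years"].astype(float)
    wt = demo["weight_kg"].astype(float)
    sex_counts = demo["sex"].value_counts().to_dict()
    outcome = demo["outcomes"].map(_most_serious)
    outcome_counts = outcome.value_counts().to_dict()
    country_counts = demo["country"].value_counts().to_dict()
    return BaselineSummary(
        n_total=n,
        age_mean=float(age.mean()),
        age_sd=0.0 if degenerate else float(age.std(ddof=1)),
        weight_mean=float(wt.mean()),
        weight_sd=0.0 if degenerate else float(wt.std(ddof=1)),
        sex_counts={k: int(v) for k, v in sex_counts.items()},
        sex_percentages={k: percentage(v, n) for k, v in sex_counts.items()},
        outcome_counts={k: int(v) for k, v in outcome_counts.items()},
        outcome_percentages={k: percentage(v, n) for k, v in outcome_counts.items()},
        country_counts={k: int(v) for k, v in country_counts.items()},
        degenerate_n1=degenerate,
    )


def yearly_counts(clean_event_set: ReportSet, year_range: tuple[int, int] | None = None) -> pd.Series:
    """Report counts per calendar year, zero-filled across *year_range*
    (default: the observed span)."""
    years = clean_event_set.demo["report_year"].astype(int)
    if year_range is None:
        if len(years) == 0:
            return pd.Series(dtype=int, name="count").rename_axis("year")
        year_range = (int(years.min()), int(years.max()))
    index = pd.RangeIndex(year_range[0], year_range[1] + 1, name="year")
    counts = years.value_counts().reindex(index, fill_value=0).astype(int)
    counts.name = "count"
    return counts


def age_pyramid(clean_event_set: ReportSet, bin_width: int = 5) -> pd.DataFrame:
    """Sex-by-age-bin counts with half-open bins [0,w), [w,2w), ...

    Rows are labelled by the bin's lower edge; columns are female/male."""
    demo = clean_event_set.demo
    if demo["age_years"].isna().any():
        raise ValueError("age pyramid requires complete ages; run apply_demographic_filters")
    lower = (demo["age_years"] // bin_width).astype(int) * bin_width
    table = (
        pd.crosstab(lower, demo["sex"])
        .reindex(columns=["female", "male"], fill_value=0)
        .rename_axis(index="age_bin_lower", columns=None)
    )
    if len(table):
        table = table.reindex(range(0, table.index.max() + bin_width, bin_width), fill_value=0)
    return table.astype(int)


# ---------------------------------------------------------------------------
# End-to-end pipeline
# ---------------------------------------------------------------------------

DEFAULT_PIPELINE_CONFIG: dict = {
    "event_terms": sorted(config.DEFAULT_EVENT_TERMS),
    "exclude_drugs": [],
    "criteria": {},           # SignalCriteria overrides
    "candidate_criteria": {"ror_min": None},  # univariate model-inclusion rule
    "model": {"grid_size": 30, "k_folds": 5, "seed": 0, "run_lasso": True},
    "onset": {"drugs": None},
    "year_range": None,
}


def run_pipeline(cfg: dict, out_dir, seed: int | None = None) -> dict:
    """Execute ingest/simulate -> clean -> signal -> model -> onset ->
    descriptive reports, writing every stage output under *out_dir*.

    ``cfg`` needs either a ``"simulate"`` block (:class:`SimulationConfig`
    fields) or an ``"inputs"`` block naming the five quarterly files or a
    flat TSV.  Returns the run manifest (also written as manifest.json).
    """
    cfg = {**DEFAULT_PIPELINE_CONFIG, **cfg}
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, str] = {}

    def _save(name: str, path: Path) -> Path:
        outputs[name] = str(path)
        return path

    # --- obtain reports ---------------------------------------------------
    if "simulate" in cfg and "inputs" in cfg:
        raise ValueError("config must name either 'simulate' or 'inputs', not both")
    if "simulate" in cfg:
        sim_payload = dict(cfg["simulate"])
        if seed is not None:
            sim_payload["seed"] = seed
        sim_cfg = SimulationConfig.from_dict(sim_payload)
        rs, truth = generate_reports(sim_cfg)
        truth.to_json(_save("truth_ledger", out_dir / "truth_ledger.json"))
    elif "inputs" in cfg:
        inputs = cfg["inputs"]
        if "flat" in inputs:
            rs = read_flat(inputs["flat"])
        else:
            rs = parse_quarter_files(
                inputs["demo"], inputs["drug"], inputs["reac"], inputs["outc"], inputs["ther"]
            )
    else:
        raise ValueError("config must contain a 'simulate' or 'inputs' block")

    name_map = load_name_map(cfg["name_map"]) if cfg.get("name_map") else None
    event_terms = cfg["event_terms"]

    # --- cleaning cascade -------------------------------------------------
    clean = clean_cascade(rs, name_map)
    write_flat(clean, _save("clean", out_dir / "clean.tsv"))
    write_provenance(clean, _save("provenance", out_dir / "provenance.json"))

    # --- disproportionality ----------------------------------------------
    criteria = dp.SignalCriteria(**cfg["criteria"])
    tables = dp.build_contingency_tables(clean, event_terms, cfg["exclude_drugs"])
    signals = dp.compute_signal_stats(tables, criteria)
    signals.to_csv(_save("signals", out_dir / "signals.tsv"), sep="\t", index=False)
    stats = [
        dp.SignalStats(
            drug=r.drug, n_cases=r.a, ror=r.ror, ci_lower=r.ci_lower, ci_upper=r.ci_upper,
            p_raw=r.p_raw, p_adj=r.p_adj, zero_corrected=r.zero_corrected,
        )
        for r in signals.itertuples(index=False)
    ]
    dp.volcano_table(stats).to_csv(_save("volcano", out_dir / "volcano.tsv"), sep="\t", index=False)

    # --- risk modeling ----------------------------------------------------
    cand_criteria = dp.SignalCriteria(**{**cfg["criteria"], **cfg["candidate_criteria"]})
    candidates = [s.drug for s in dp.screen_signals(stats, cand_criteria)]
    model_cfg = {**DEFAULT_PIPELINE_CONFIG["model"], **cfg["model"]}
    model_summary: dict = {"candidates": candidates}
    if candidates:
        dm = rm.build_design_matrix(clean, candidates, event_terms)
        selected = list(dm.drug_columns)
        if model_cfg["run_lasso"] and len(dm.drug_columns) >= 2:
            path = rm.fit_lasso_logistic(
                dm,
                grid_size=model_cfg["grid_size"],
                k_folds=model_cfg["k_folds"],
                seed=model_cfg["seed"],
            )
            path.coefficients.to_csv(_save("lasso_path", out_dir / "lasso_path.tsv"), sep="\t")
            selected = list(path.selected_columns)
            model_summary["lasso_selected"] = selected
            model_summary["selected_lambda"] = path.selected_lambda
        if selected:
            dm_final = rm.build_design_matrix(clean, selected, event_terms)
            fit = rm.fit_logistic_irls(dm_final)
            fit.params.to_csv(_save("model", out_dir / "model.tsv"), sep="\t")
            roc = rm.compute_roc_auc(fit, dm_final)
            pd.DataFrame({"threshold": roc.thresholds, "fpr": roc.fpr, "tpr": roc.tpr}).to_csv(
                _save("roc", out_dir / "roc.tsv"), sep="\t", index=False
            )
            model_summary["auc"] = roc.auc
            model_summary["independent_risk_drugs"] = list(
                fit.params.index[fit.params["flagged_independent"]]
            )

    # --- time to onset ----------------------------------------------------
    event_set, _ = partition_event(clean, event_terms)
    records, excluded = onset_mod.extract_onset(event_set, cfg["onset"].get("drugs"))
    if records:
        summary = onset_mod.summarize_onset(records, excluded_by_reason=excluded)
        Path(_save("onset_summary", out_dir / "onset_summary.json")).write_text(
            json.dumps(
                {
                    "n_used": summary.n_used,
                    "n_excluded": summary.n_excluded,
                    "excluded_by_reason": summary.excluded_by_reason,
                    "median_days": summary.median_days,
                    "q1_days": summary.q1_days,
                    "q3_days": summary.q3_days,
                },
                indent=2,
            )
            + "\n"
        )
        onset_mod.cumulative_curve(records).to_csv(
            _save("onset_curve", out_dir / "onset_curve.tsv"), sep="\t", index=False
        )

    # --- descriptive reports ---------------------------------------------
    baseline = baseline_table(event_set)
    Path(_save("baseline", out_dir / "baseline.json")).write_text(
        json.dumps(baseline.to_dict(), indent=2) + "\n"
    )
    yearly_counts(event_set, cfg["year_range"]).to_csv(
        _save("yearly", out_dir / "yearly.tsv"), sep="\t"
    )
    age_pyramid(event_set).to_csv(_save("pyramid", out_dir / "pyramid.tsv"), sep="\t")

    manifest = {
        "config": _jsonable(cfg),
        "seed": seed,
        "software": {"package": "faersig", "version": __version__, "python": platform.python_version()},
        "provenance": clean.provenance,
        "audit": clean.audit,
        "model": model_summary,
        "outputs": outputs,
        "timestamp_unix": time.time(),
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set, frozenset)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
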