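"""Synthetic spontaneous-report generator with a recoverable ground truth.

The generator emulates the statistical structure a case/non-case
disproportionality analysis assumes: each report carries exactly one
primary-suspect drug sampled from a configurable panel, demographics drawn
from normal/Bernoulli marginals, and a binary event indicator drawn from a
logistic model

    logit P(event) = alpha + beta_drug
                     + beta_age (age - mean_age)
                     + beta_wt  (weight - mean_wt)
                     + beta_sex (female - p_female)

so the per-drug log odds ratio ``beta_drug`` injected into the simulation is
exactly the conditional log-OR a multivariate logistic fit should recover.
Event reports receive a therapy-start-to-onset lag drawn from a log-normal
distribution.  Realistic blemishes — duplicate case versions (earlier-dated,
so keep-latest deduplication provably recovers the truth copy), missing
demographics, and implausible ages/weights — are injected last and recorded
in a :class:`TruthLedger` so every downstream cleaning and estimation stage
has a parameter-recovery test.

Default parameters are chosen to resemble a drug–cataract extraction of a
large spontaneous-report database: demographics centred on age 66.92 ± 11.95
years, 71.16% female, weight 72.44 ± 22.53 kg; a 2% baseline event
probability so that per-drug case counts land in the >100-case screening
regime at the default 200,000 reports; five signal drugs with true odds
ratios 14, 10, 6, 4 and 3 among 25 null drugs; and an onset lag with median
449 days.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from . import config
from ._util import format_faers_date
from .report_store import ReportSet, _empty_demo, _empty_drugs, _empty_reactions

# Background preferred terms given to non-event reports (and occasionally to
# event reports) so reaction sets look report-like.
_BACKGROUND_PTS = np.array(
    ["NAUSEA", "HEADACHE", "DIZZINESS", "RASH", "FATIGUE", "DIARRHOEA",
     "PRURITUS", "VOMITING", "DYSPNOEA", "ARTHRALGIA"]
)

_OUTCOME_NAMES = np.array(
    ["other-serious", "missing", "hospitalization", "death", "disability",
     "life-threatening", "congenital-anomaly", "required-intervention"]
)
# Echoes the outcome mix of a large cataract extraction.
_OUTCOME_PROBS = np.array([0.6205, 0.1982, 0.1476, 0.0128, 0.0147, 0.0055, 0.0004, 0.0003])


@dataclass(frozen=True)
class DrugSpec:
    """One panel drug: ingredient name, probability of being the report's
    primary suspect, and injected conditional log odds ratio."""

    ingredient: str
    exposure_probability: float
    true_log_or: float = 0.0


@dataclass(frozen=True)
class Demographics:
    age_mean: float = 66.92
    age_sd: float = 11.95
    prob_female: float = 0.7116
    weight_mean: float = 72.44
    weight_sd: float = 22.53
    sex_effect_log_or: float = 0.18       # female vs male
    age_effect_per_year: float = 0.02
    weight_effect_per_kg: float = 0.003


@dataclass(frozen=True)
class OnsetModel:
    """Log-normal therapy-start-to-event lag; median = exp(log_median_days)."""

    log_median_days: float = math.log(449.0)
    log_sd: float = 1.33


def default_drug_panel() -> tuple[DrugSpec, ...]:
    """30-drug panel: 5 signal drugs (OR 14, 10, 6, 4, 3) + 25 nulls,
    uniformly exposed."""
    p = 1.0 / 30.0
    signal = [
        ("ALENDRONIC ACID", 14.0),
        ("IBRUTINIB", 10.0),
        ("UPADACITINIB", 6.0),
        ("TIOTROPIUM", 4.0),
        ("ADALIMUMAB", 3.0),
    ]
    nulls = [
        "METFORMIN", "LISINOPRIL", "AMLODIPINE", "OMEPRAZOLE", "LEVOTHYROXINE",
        "ALBUTEROL", "GABAPENTIN", "SERTRALINE", "IBUPROFEN", "PARACETAMOL",
        "WARFARIN", "CLOPIDOGREL", "LOSARTAN", "METOPROLOL", "FUROSEMIDE",
        "INSULIN GLARGINE", "DULOXETINE", "RIVAROXABAN", "APIXABAN", "CELECOXIB",
        "MONTELUKAST", "RANITIDINE", "TAMSULOSIN", "HYDROCHLOROTHIAZIDE", "ESCITALOPRAM",
    ]
    panel = [DrugSpec(name, p, math.log(orr)) for name, orr in signal]
    panel += [DrugSpec(name, p, 0.0) for name in nulls]
    return tuple(panel)


@dataclass(frozen=True)
class SimulationConfig:
    n_reports: int = 200_000
    drugs: tuple[DrugSpec, ...] = field(default_factory=default_drug_panel)
    baseline_event_logit: float = float(logit(0.02))
    demog: Demographics = field(default_factory=Demographics)
    onset: OnsetModel = field(default_factory=OnsetModel)
    duplicate_rate: float = 0.05
    missing_demog_rate: float = 0.10
    implausible_rate: float = 0.01
    year_range: tuple[int, int] = (2004, 2024)
    event_term: str = "CATARACT"
    seed: int = 0

    def validate(self) -> None:
        if self.n_reports < 0:
            raise ValueError("n_reports must be >= 0")
        if not self.drugs:
            raise ValueError("drugs panel must be non-empty")
        for d in self.drugs:
            if not (0.0 < d.exposure_probability < 1.0):
                raise ValueError(f"exposure_probability out of (0,1) for drugs[{d.ingredient}]")
        for name in ("duplicate_rate", "missing_demog_rate", "implausible_rate"):
            v = getattr(self, name)
            if not (0.0 <= v < 1.0):
                raise ValueError(f"{name} must be in [0,1)")
        if self.year_range[0] > self.year_range[1]:
            raise ValueError("year_range must be (first, last) with first <= last")

    @classmethod
    def from_dict(cls, payload: dict) -> "SimulationConfig":
        payload = dict(payload)
        if "drugs" in payload:
            payload["drugs"] = tuple(
                DrugSpec(**d) if isinstance(d, dict) else DrugSpec(*d) for d in payload["drugs"]
            )
        if "demog" in payload and isinstance(payload["demog"], dict):
            payload["demog"] = Demographics(**payload["demog"])
        if "onset" in payload and isinstance(payload["onset"], dict):
            payload["onset"] = OnsetModel(**payload["onset"])
        if "year_range" in payload:
            payload["year_range"] = tuple(payload["year_range"])
        return cls(**payload)


@dataclass
class TruthLedger:
    """Ground truth of one simulation run.

    ``drugs``: ingredient, true_log_or, n_exposed (realized).
    ``reports``: report_id, ingredient, linear predictor, event flag.
    ``duplicate_pairs``: duplicate report_id -> primary report_id.
    ``missing_injected`` / ``implausible_injected``: report_id, field.
    """

    drugs: pd.DataFrame
    reports: pd.DataFrame
    duplicate_pairs: pd.DataFrame
    missing_injected: pd.DataFrame
    implausible_injected: pd.DataFrame

    def to_json(self, path) -> None:
        payload = {
            "drugs": self.drugs.to_dict(orient="records"),
            "reports": self.reports.to_dict(orient="records"),
            "duplicate_pairs": self.duplicate_pairs.to_dict(orient="records"),
            "missing_injected": self.missing_injected.to_dict(orient="records"),
            "implausible_injected": self.implausible_injected.to_dict(orient="records"),
        }
        Path(path).write_text(json.dumps(payload) + "\n")


def generate_reports(cfg: SimulationConfig) -> tuple[ReportSet, TruthLedger]:
    """Draw a full synthetic report set plus its :class:`TruthLedger`.

    Identical configs (including the seed) yield identical output.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_reports
    dg = cfg.demog

    empty_truth = TruthLedger(
        drugs=pd.DataFrame(
            {
                "ingredient": [d.ingredient for d in cfg.drugs],
                "true_log_or": [d.true_log_or for d in cfg.drugs],
                "n_exposed": 0,
            }
        ),
        reports=pd.DataFrame(columns=["report_id", "ingredient", "eta", "event"]),
        duplicate_pairs=pd.DataFrame(columns=["duplicate_report_id", "primary_report_id"]),
        missing_injected=pd.DataFrame(columns=["report_id", "field"]),
        implausible_injected=pd.DataFrame(columns=["report_id", "field"]),
    )
    if n == 0:
        rs = ReportSet(demo=_empty_demo(), drugs=_empty_drugs(), reactions=_empty_reactions())
        rs.record_stage("simulated")
        return rs, empty_truth

    probs = np.array([d.exposure_probability for d in cfg.drugs], dtype=float)
    probs = probs / probs.sum()
    tlor = np.array([d.true_log_or for d in cfg.drugs], dtype=float)
    names = np.array([d.ingredient for d in cfg.drugs])

    drug_idx = rng.choice(len(cfg.drugs), size=n, p=probs)
    age = np.clip(np.round(rng.normal(dg.age_mean, dg.age_sd, n)), 0, 119)
    female = rng.random(n) < dg.prob_female
    weight = np.round(np.clip(rng.normal(dg.weight_mean, dg.weight_sd, n), 2.0, None), 1)

    eta = (
        cfg.baseline_event_logit
        + tlor[drug_idx]
        + dg.age_effect_per_year * (age - dg.age_mean)
        + dg.weight_effect_per_kg * (weight - dg.weight_mean)
        + dg.sex_effect_log_or * (female.astype(float) - dg.prob_female)
    )
    event = rng.random(n) < expit(eta)

    first, last = cfg.year_range
    year = rng.integers(first, last + 1, n)
    start = (
        pd.to_datetime(pd.DataFrame({"year": year, "month": 1, "day": 1}))
        + pd.to_timedelta(rng.integers(0, 365, n), unit="D")
    )
    # lag truncated at ~41 years: keeps the extreme log-normal tail inside
    # the representable date range with negligible effect on the quartiles
    lag = np.clip(np.round(rng.lognormal(cfg.onset.log_median_days, cfg.onset.log_sd, n)), 1, 15_000).astype(int)
    event_date = pd.Series(pd.NaT, index=np.arange(n), dtype="datetime64[ns]")
    event_date[event] = start[event] + pd.to_timedelta(lag[event], unit="D")
    anchor = start.where(~event, event_date)
    version_date = anchor + pd.to_timedelta(rng.integers(7, 180, n), unit="D")

    case_id = np.char.zfill(np.arange(n).astype(str), 8)
    report_id = np.char.add(case_id, "2")  # version 2 = the truth copy

    outcome_idx = rng.choice(len(_OUTCOME_NAMES), size=n, p=_OUTCOME_PROBS)
    _fsets = [frozenset({str(o)}) for o in _OUTCOME_NAMES]
    outcomes = [_fsets[i] for i in outcome_idx]

    demo = pd.DataFrame(
        {
            "report_id": report_id,
            "case_id": case_id,
            "version_date": version_date.values,
            "event_date": event_date.values,
            "report_year": pd.DatetimeIndex(version_date).year,
            "age_years": age.astype(float),
            "sex": np.where(female, "female", "male"),
            "weight_kg": weight,
            "country": "US",
            "outcomes": outcomes,
        }
    ).set_index("report_id")

    has_end = rng.random(n) < 0.7
    therapy_end = pd.Series(pd.NaT, index=np.arange(n), dtype="datetime64[ns]")
    therapy_end[has_end] = start[has_end] + pd.to_timedelta(
        rng.integers(30, 1000, int(has_end.sum())), unit="D"
    )
    drugs = pd.DataFrame(
        {
            "report_id": report_id,
            "name_raw": names[drug_idx],
            "ingredient": names[drug_idx],
            "role": "primary-suspect",
            "therapy_start": start.values,
            "therapy_end": therapy_end.values,
        }
    )

    # Reactions: event reports always carry the event PT; everyone may carry
    # background PTs.
    bg1 = rng.choice(_BACKGROUND_PTS, size=n)
    extra = rng.random(n) < 0.3
    reac_frames = [
        pd.DataFrame({"report_id": report_id[event], "pt": cfg.event_term}),
        pd.DataFrame({"report_id": report_id[~event], "pt": bg1[~event]}),
        pd.DataFrame({"report_id": report_id[extra], "pt": rng.choice(_BACKGROUND_PTS, size=int(extra.sum()))}),
    ]
    reactions = pd.concat(reac_frames, ignore_index=True).drop_duplicates()

    # --- duplicate case versions: earlier-dated re-emissions --------------
    n_dup = int(math.floor(cfg.duplicate_rate * n))
    dup_rows = rng.choice(n, size=n_dup, replace=False) if n_dup else np.array([], dtype=int)
    if n_dup:
        dup_report_id = np.char.add(case_id[dup_rows], "1")
        dup_demo = demo.iloc[dup_rows].copy()
        dup_demo.index = pd.Index(dup_report_id, name="report_id")
        dup_version = pd.DatetimeIndex(dup_demo["version_date"]) - pd.to_timedelta(
            rng.integers(30, 400, n_dup), unit="D"
        )
        dup_demo["version_date"] = dup_version
        dup_demo["report_year"] = dup_version.year
        demo = pd.concat([demo, dup_demo])
        dup_drugs = drugs.iloc[dup_rows].copy()
        dup_drugs["report_id"] = dup_report_id
        drugs = pd.concat([drugs, dup_drugs], ignore_index=True)
        rid_to_dup = dict(zip(report_id[dup_rows], dup_report_id))
        dup_reac = reactions[reactions["report_id"].isin(rid_to_dup)].copy()
        dup_reac["report_id"] = dup_reac["report_id"].map(rid_to_dup)
        reactions = pd.concat([reactions, dup_reac], ignore_index=True)
    duplicate_pairs = pd.DataFrame(
        {
            "duplicate_report_id": np.char.add(case_id[dup_rows], "1") if n_dup else [],
            "primary_report_id": report_id[dup_rows] if n_dup else [],
        }
    )

    # --- missingness and implausible values, injected on the truth copies -
    n_missing = int(math.floor(cfg.missing_demog_rate * n))
    n_impl = int(math.floor(cfg.implausible_rate * n))
    tampered = rng.choice(n, size=n_missing + n_impl, replace=False) if n_missing + n_impl else np.array([], dtype=int)
    miss_rows, impl_rows = tampered[:n_missing], tampered[n_missing:]

    miss_field = rng.choice(["age_years", "sex", "weight_kg"], size=n_missing)
    for f in ("age_years", "weight_kg"):
        rows = report_id[miss_rows[miss_field == f]]
        demo.loc[rows, f] = np.nan
    demo.loc[report_id[miss_rows[miss_field == "sex"]], "sex"] = "unknown"
    missing_injected = pd.DataFrame({"report_id": report_id[miss_rows], "field": miss_field})

    impl_field = rng.choice(["age_years", "weight_kg"], size=n_impl)
    rows_age = report_id[impl_rows[impl_field == "age_years"]]
    demo.loc[rows_age, "age_years"] = rng.integers(121, 140, len(rows_age)).astype(float)
    rows_wt = report_id[impl_rows[impl_field == "weight_kg"]]
    demo.loc[rows_wt, "weight_kg"] = np.round(rng.uniform(401.0, 800.0, len(rows_wt)), 1)
    implausible_injected = pd.DataFrame({"report_id": report_id[impl_rows], "field": impl_field})

    rs = ReportSet(demo=demo, drugs=drugs.reset_index(drop=True), reactions=reactions.reset_index(drop=True))
    rs.record_stage("simulated")

    exposed = pd.Series(drug_idx).value_counts().reindex(range(len(cfg.drugs)), fill_value=0)
    truth = TruthLedger(
        drugs=pd.DataFrame(
            {"ingredient": names, "true_log_or": tlor, "n_exposed": exposed.values}
        ),
        reports=pd.DataFrame(
            {"report_id": report_id, "ingredient": names[drug_idx], "eta": eta, "event": event}
        ),
        duplicate_pairs=duplicate_pairs,
        missing_injected=missing_injected,
        implausible_injected=implausible_injected,
    )
    return rs, truth


def write_quarter_files(rs: ReportSet, out_dir) -> dict[str, Path]:
    """Emit the five "$"-delimited quarterly tables that
    :func:`faersig.report_store.parse_quarter_files` reads.

    The writer serializes report versions as they stand (it never
    deduplicates), so ``parse(write(S))`` reproduces ``S``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {name: out_dir / f"{name}.txt" for name in ("DEMO", "DRUG", "REAC", "OUTC", "THER")}

    demo = rs.demo
    sex_code = demo["sex"].map({"female": "F", "male": "M"}).fillna("")

    def _num(col):
        return demo[col].map(lambda v: "" if pd.isna(v) else f"{float(v):g}")

    pd.DataFrame(
        {
            "primaryid": demo.index,
            "caseid": demo["case_id"],
            "fda_dt": demo["version_date"].map(format_faers_date),
            "event_dt": demo["event_date"].map(format_faers_date),
            "age": _num("age_years"),
            "sex": sex_code,
            "wt": _num("weight_kg"),
            "occr_country": demo["country"],
        }
    ).to_csv(paths["DEMO"], sep="$", index=False)

    drugs = rs.drugs.copy()
    drugs["drug_seq"] = drugs.groupby("report_id").cumcount() + 1
    pd.DataFrame(
        {
            "primaryid": drugs["report_id"],
            "drug_seq": drugs["drug_seq"],
            "drugname": drugs["name_raw"],
            "role_cod": drugs["role"].map(config.ROLE_NAMES),
        }
    ).to_csv(paths["DRUG"], sep="$", index=False)

    ther = drugs[drugs["therapy_start"].notna() | drugs["therapy_end"].notna()]
    pd.DataFrame(
        {
            "primaryid": ther["report_id"],
            "dsg_drug_seq": ther["drug_seq"],
            "start_dt": ther["therapy_start"].map(format_faers_date),
            "end_dt": ther["therapy_end"].map(format_faers_date),
        }
    ).to_csv(paths["THER"], sep="$", index=False)

    rs.reactions.rename(columns={"report_id": "primaryid"}).to_csv(paths["REAC"], sep="$", index=False)

    outc_rows = []
    for rid, outcomes in demo["outcomes"].items():
        for o in sorted(outcomes):
            if o != "missing":
                outc_rows.append((rid, config.OUTCOME_NAMES[o]))
    pd.DataFrame(outc_rows, columns=["primaryid", "outc_cod"]).to_csv(paths["OUTC"], sep="$", index=False)

    return paths
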