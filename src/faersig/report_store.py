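"""Ingestion, normalization, deduplication and filtering of spontaneous reports.

A :class:`ReportSet` is the pipeline's central container.  It is backed by
three pandas DataFrames — one row per report (``demo``), one row per drug
entry (``drugs``) and one row per reaction preferred term (``reactions``) —
so that every cleaning step is vectorized, plus a provenance ledger that
records the report count after each stage of the cleaning cascade.

The cleaning cascade mirrors standard pharmacovigilance practice for
FAERS-style data: parse the five "$"-delimited quarterly tables, normalize
drug names to active ingredients, keep the latest version of each case,
restrict to primary-suspect drug entries, and retain only reports with
complete, plausible demographics.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import json
import logging
import re
from collections.abc import Iterable, Mapping
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import config
from ._util import format_faers_date, parse_faers_date

logger = logging.getLogger(__name__)

DEMO_COLUMNS = ["primaryid", "caseid", "fda_dt", "event_dt", "age", "sex", "wt", "occr_country"]
DRUG_COLUMNS = ["primaryid", "drug_seq", "drugname", "role_cod"]
REAC_COLUMNS = ["primaryid", "pt"]
OUTC_COLUMNS = ["primaryid", "outc_cod"]
THER_COLUMNS = ["primaryid", "dsg_drug_seq", "start_dt", "end_dt"]


# ---------------------------------------------------------------------------
# Record-level domain types (object view of one report)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DrugEntry:
    """One drug row of a report: as-reported name, normalized ingredient,
    FAERS role, and therapy dates."""

    name_raw: str
    ingredient: str
    role: str
    therapy_start: _dt.date | None = None
    therapy_end: _dt.date | None = None

    def __post_init__(self):
        if self.role not in config.ROLE_NAMES:
            raise ValueError(f"unknown drug role: {self.role!r}")


@dataclass(frozen=True)
class SafetyReport:
    """One spontaneous report (one version of one case)."""

    report_id: str
    case_id: str
    version_date: _dt.date
    report_year: int
    drugs: tuple[DrugEntry, ...]
    reactions: frozenset[str]
    event_date: _dt.date | None = None
    age_years: float | None = None
    sex: str = "unknown"
    weight_kg: float | None = None
    country: str = ""
    outcomes: frozenset[str] = frozenset({"missing"})

    def __post_init__(self):
        if self.sex not in config.SEXES:
            raise ValueError(f"unknown sex: {self.sex!r}")
        if self.age_years is not None and self.age_years < 0:
            raise ValueError("age_years must be >= 0")
        if self.weight_kg is not None and self.weight_kg < 0:
            raise ValueError("weight_kg must be >= 0")


# ---------------------------------------------------------------------------
# ReportSet container
# ---------------------------------------------------------------------------

@dataclass
class ReportSet:
    """A collection of spontaneous reports with a cleaning-stage ledger.

    ``demo`` is indexed by ``report_id``; ``drugs`` and ``reactions`` carry a
    ``report_id`` column.  ``provenance`` maps stage name -> report count in
    cascade order; ``audit`` holds auxiliary counters (malformed lines, join
    failures, per-filter drop reasons).
    """

    demo: pd.DataFrame
    drugs: pd.DataFrame
    reactions: pd.DataFrame
    provenance: dict[str, int] = field(default_factory=dict)
    audit: dict[str, int] = field(default_factory=dict)

    @property
    def n_reports(self) -> int:
        return len(self.demo)

    @property
    def report_ids(self) -> pd.Index:
        return self.demo.index

    def record_stage(self, name: str) -> None:
        self.provenance[name] = self.n_reports

    def subset(self, report_ids, stage: str | None = None) -> "ReportSet":
        """New ReportSet restricted to *report_ids* (order preserved)."""
        ids = self.demo.index.intersection(pd.Index(report_ids))
        out = ReportSet(
            demo=self.demo.loc[ids],
            drugs=self.drugs[self.drugs["report_id"].isin(ids)].reset_index(drop=True),
            reactions=self.reactions[self.reactions["report_id"].isin(ids)].reset_index(drop=True),
            provenance=dict(self.provenance),
            audit=dict(self.audit),
        )
        if stage is not None:
            out.record_stage(stage)
        return out

    def copy(self) -> "ReportSet":
        return ReportSet(
            demo=self.demo.copy(),
            drugs=self.drugs.copy(),
            reactions=self.reactions.copy(),
            provenance=dict(self.provenance),
            audit=dict(self.audit),
        )

    def validate(self) -> None:
        """Raise on violated container invariants."""
        if not self.demo.index.is_unique:
            raise ValueError("report_id not unique within ReportSet")
        if self.n_reports:
            with_drug = set(self.drugs["report_id"])
            with_reac = set(self.reactions["report_id"])
            missing = [r for r in self.demo.index if r not in with_drug or r not in with_reac]
            if missing:
                raise ValueError(f"{len(missing)} reports lack a drug or reaction row")
        counts = list(self.provenance.values())
        if any(b > a for a, b in zip(counts, counts[1:])):
            raise ValueError("provenance counters increase along the cascade")

    # -- object view ------------------------------------------------------

    def to_reports(self) -> list[SafetyReport]:
        drugs_by_id: dict[str, list] = {}
        for row in self.drugs.itertuples(index=False):
            drugs_by_id.setdefault(row.report_id, []).append(
                DrugEntry(
                    name_raw=row.name_raw,
                    ingredient=row.ingredient,
                    role=row.role,
                    therapy_start=_to_date(row.therapy_start),
                    therapy_end=_to_date(row.therapy_end),
                )
            )
        reacs_by_id: dict[str, set] = {}
        for row in self.reactions.itertuples(index=False):
            reacs_by_id.setdefault(row.report_id, set()).add(row.pt)
        out = []
        for rid, row in self.demo.iterrows():
            out.append(
                SafetyReport(
                    report_id=rid,
                    case_id=row["case_id"],
                    version_date=_to_date(row["version_date"]),
                    event_date=_to_date(row["event_date"]),
                    report_year=int(row["report_year"]),
                    age_years=None if pd.isna(row["age_years"]) else float(row["age_years"]),
                    sex=row["sex"],
                    weight_kg=None if pd.isna(row["weight_kg"]) else float(row["weight_kg"]),
                    country=row["country"],
                    outcomes=frozenset(row["outcomes"]),
                    drugs=tuple(drugs_by_id.get(rid, ())),
                    reactions=frozenset(reacs_by_id.get(rid, ())),
                )
            )
        return out

    @classmethod
    def from_reports(cls, reports: Iterable[SafetyReport], stage: str = "loaded") -> "ReportSet":
        demo_rows, drug_rows, reac_rows = [], [], []
        for r in reports:
            demo_rows.append(
                dict(
                    report_id=r.report_id,
                    case_id=r.case_id,
                    version_date=pd.Timestamp(r.version_date),
                    event_date=pd.Timestamp(r.event_date) if r.event_date else pd.NaT,
                    report_year=r.report_year,
                    age_years=np.nan if r.age_years is None else float(r.age_years),
                    sex=r.sex,
                    weight_kg=np.nan if r.weight_kg is None else float(r.weight_kg),
                    country=r.country,
                    outcomes=frozenset(r.outcomes),
                )
            )
            for d in r.drugs:
                drug_rows.append(
                    dict(
                        report_id=r.report_id,
                        name_raw=d.name_raw,
                        ingredient=d.ingredient,
                        role=d.role,
                        therapy_start=pd.Timestamp(d.therapy_start) if d.therapy_start else pd.NaT,
                        therapy_end=pd.Timestamp(d.therapy_end) if d.therapy_end else pd.NaT,
                    )
                )
            for pt in r.reactions:
                reac_rows.append(dict(report_id=r.report_id, pt=pt.upper().strip()))
        rs = cls(
            demo=_empty_demo() if not demo_rows else pd.DataFrame(demo_rows).set_index("report_id"),
            drugs=_empty_drugs() if not drug_rows else pd.DataFrame(drug_rows),
            reactions=_empty_reactions() if not reac_rows else pd.DataFrame(reac_rows),
        )
        rs.record_stage(stage)
        return rs


def _to_date(value) -> _dt.date | None:
    if value is None or pd.isna(value):
        return None
    return pd.Timestamp(value).date()


def _empty_demo() -> pd.DataFrame:
    df = pd.DataFrame(
        columns=[
            "report_id", "case_id", "version_date", "event_date", "report_year",
            "age_years", "sex", "weight_kg", "country", "outcomes",
        ]
    )
    return df.set_index("report_id")


def _empty_drugs() -> pd.DataFrame:
    return pd.DataFrame(
        columns=["report_id", "name_raw", "ingredient", "role", "therapy_start", "therapy_end"]
    )


def _empty_reactions() -> pd.DataFrame:
    return pd.DataFrame(columns=["report_id", "pt"])


# ---------------------------------------------------------------------------
# Parsing the quarterly ASCII dialect
# ---------------------------------------------------------------------------

def _read_dollar_file(path, required: list[str], audit: dict, label: str) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"{label} file not found: {path}")

    bad = {"n": 0}

    def _on_bad(line):  # wrong field count -> skip and count
        bad["n"] += 1
        logger.warning("%s: skipping malformed line: %r", label, line[:5])
        return None

    df = pd.read_csv(
        path,
        sep="$",
        dtype=str,
        keep_default_na=False,
        engine="python",
        on_bad_lines=_on_bad,
    )
    df.columns = [c.strip().lower() for c in df.columns]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{label} file {path} lacks required columns {missing}")
    audit[f"malformed_lines_{label.lower()}"] = bad["n"]
    return df


def parse_quarter_files(demo_path, drug_path, reac_path, outc_path, ther_path) -> ReportSet:
    """Parse one quarter's five "$"-delimited tables into a :class:`ReportSet`.

    A report is kept only if its DEMO row joins to at least one DRUG and one
    REAC row; rows failing the join are counted in the audit ledger, never
    silently dropped.  Values are parsed, not judged: an age of 121 survives
    parsing and is removed later by :func:`apply_demographic_filters`.
    """
    audit: dict[str, int] = {}
    demo_raw = _read_dollar_file(demo_path, DEMO_COLUMNS, audit, "DEMO")
    drug_raw = _read_dollar_file(drug_path, DRUG_COLUMNS, audit, "DRUG")
    reac_raw = _read_dollar_file(reac_path, REAC_COLUMNS, audit, "REAC")
    outc_raw = _read_dollar_file(outc_path, OUTC_COLUMNS, audit, "OUTC")
    ther_raw = _read_dollar_file(ther_path, THER_COLUMNS, audit, "THER")

    n_raw = len(demo_raw)

    # DEMO: the version date (fda_dt) anchors deduplication, so a row
    # without one is unusable.
    version_date = demo_raw["fda_dt"].map(parse_faers_date)
    usable = version_date.notna() & demo_raw["primaryid"].str.strip().ne("")
    audit["demo_rows_missing_version_date"] = int((~usable).sum())
    demo_raw = demo_raw[usable]
    version_date = version_date[usable]

    dup_ids = demo_raw["primaryid"].duplicated()
    audit["demo_rows_duplicate_primaryid"] = int(dup_ids.sum())
    demo_raw = demo_raw[~dup_ids]
    version_date = version_date[~dup_ids]

    demo = pd.DataFrame(
        {
            "report_id": demo_raw["primaryid"].str.strip(),
            "case_id": demo_raw["caseid"].str.strip(),
            "version_date": pd.to_datetime(version_date),
            "event_date": pd.to_datetime(demo_raw["event_dt"].map(parse_faers_date)),
            "age_years": pd.to_numeric(demo_raw["age"], errors="coerce"),
            "sex": demo_raw["sex"].str.strip().str.upper().map({"F": "female", "M": "male"}).fillna("unknown"),
            "weight_kg": pd.to_numeric(demo_raw["wt"], errors="coerce"),
            "country": demo_raw["occr_country"].str.strip(),
        }
    ).set_index("report_id")
    demo["report_year"] = demo["version_date"].dt.year
    # negative ages/weights are data errors, not parseable values
    demo.loc[demo["age_years"] < 0, "age_years"] = np.nan
    demo.loc[demo["weight_kg"] < 0, "weight_kg"] = np.nan

    # OUTC: set of outcome names per report; no row -> {missing}
    outc_raw = outc_raw.assign(
        report_id=outc_raw["primaryid"].str.strip(),
        outcome=outc_raw["outc_cod"].str.strip().str.upper().map(config.OUTCOME_CODES),
    )
    n_bad_outc = int(outc_raw["outcome"].isna().sum())
    if n_bad_outc:
        audit["unknown_outcome_codes"] = n_bad_outc
        outc_raw = outc_raw.dropna(subset=["outcome"])
    outcome_sets = outc_raw.groupby("report_id")["outcome"].agg(frozenset)
    demo["outcomes"] = demo.index.map(outcome_sets).where(
        demo.index.isin(outcome_sets.index), frozenset({"missing"})
    )

    # THER: therapy dates join DRUG on (report, drug_seq)
    ther = pd.DataFrame(
        {
            "report_id": ther_raw["primaryid"].str.strip(),
            "drug_seq": ther_raw["dsg_drug_seq"].str.strip(),
            "therapy_start": pd.to_datetime(ther_raw["start_dt"].map(parse_faers_date)),
            "therapy_end": pd.to_datetime(ther_raw["end_dt"].map(parse_faers_date)),
        }
    ).drop_duplicates(subset=["report_id", "drug_seq"])

    role = drug_raw["role_cod"].str.strip().str.upper().map(config.ROLE_CODES)
    n_bad_role = int(role.isna().sum())
    if n_bad_role:
        audit["unknown_role_codes"] = n_bad_role
    drugs = pd.DataFrame(
        {
            "report_id": drug_raw["primaryid"].str.strip(),
            "drug_seq": drug_raw["drug_seq"].str.strip(),
            "name_raw": drug_raw["drugname"].str.strip(),
            "role": role,
        }
    ).dropna(subset=["role"])
    drugs = drugs[drugs["name_raw"] != ""]
    drugs = drugs.merge(ther, on=["report_id", "drug_seq"], how="left")
    drugs["ingredient"] = drugs["name_raw"].map(clean_drug_name)
    drugs = drugs.drop(columns=["drug_seq"])

    reactions = pd.DataFrame(
        {
            "report_id": reac_raw["primaryid"].str.strip(),
            "pt": reac_raw["pt"].str.strip().str.upper(),
        }
    )
    reactions = reactions[reactions["pt"] != ""].drop_duplicates()

    with_drug = set(drugs["report_id"])
    with_reac = set(reactions["report_id"])
    joined = demo.index[[rid in with_drug and rid in with_reac for rid in demo.index]]
    audit["join_failures"] = len(demo) - len(joined)

    rs = ReportSet(
        demo=demo.loc[joined],
        drugs=drugs[drugs["report_id"].isin(joined)].reset_index(drop=True),
        reactions=reactions[reactions["report_id"].isin(joined)].reset_index(drop=True),
        audit=audit,
    )
    rs.provenance["raw"] = n_raw
    rs.record_stage("ingested")
    return rs


# ---------------------------------------------------------------------------
# Drug-name normalization
# ---------------------------------------------------------------------------

_WS = re.compile(r"\s+")


def clean_drug_name(name: str, salt_suffixes: frozenset[str] = config.SALT_SUFFIXES) -> str:
    """Uppercase, trim, collapse whitespace and strip trailing salt tokens."""
    s = _WS.sub(" ", str(name).strip().upper())
    tokens = s.split(" ")
    while len(tokens) > 1 and tokens[-1] in salt_suffixes:
        tokens.pop()
    return " ".join(tokens)


def load_name_map(path) -> dict[str, str]:
    """Read a two-column (brand, ingredient) TSV into a normalization map."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.shape[1] < 2:
        raise ValueError("name map needs two columns: brand, ingredient")
    brand, ingredient = df.columns[:2]
    return {
        clean_drug_name(b): clean_drug_name(i)
        for b, i in zip(df[brand], df[ingredient])
        if str(b).strip() and str(i).strip()
    }


def normalize_drug_names(rs: ReportSet, name_map: Mapping[str, str] | None = None) -> ReportSet:
    """Fill ``ingredient`` from the brand->ingredient map.

    Names absent from the map keep their cleaned raw form; the operation is
    idempotent because the ingredient is always recomputed from ``name_raw``.
    """
    name_map = {clean_drug_name(k): clean_drug_name(v) for k, v in (name_map or {}).items()}
    out = rs.copy()
    # resolve each distinct raw name once
    lookup = {
        raw: clean_drug_name(name_map.get(c, c))
        for raw, c in ((r, clean_drug_name(r)) for r in pd.unique(out.drugs["name_raw"]))
    }
    out.drugs["ingredient"] = out.drugs["name_raw"].map(lookup)
    out.record_stage("normalized")
    return out


# ---------------------------------------------------------------------------
# Cleaning cascade
# ---------------------------------------------------------------------------

def deduplicate(rs: ReportSet) -> ReportSet:
    """Keep one report per case: latest ``version_date``, ties broken by the
    lexicographically greatest ``report_id`` (latest case version supersedes)."""
    if rs.n_reports == 0:
        out = rs.copy()
        out.record_stage("deduplicated")
        return out
    order = rs.demo.reset_index().sort_values(
        ["case_id", "version_date", "report_id"], kind="mergesort"
    )
    keep = order.groupby("case_id", sort=False).tail(1)["report_id"]
    return rs.subset(keep, stage="deduplicated")


def filter_event_reports(rs: ReportSet, event_terms: Iterable[str]) -> ReportSet:
    """Retain reports whose reactions intersect *event_terms*
    (case-insensitive exact PT match)."""
    terms = {str(t).strip().upper() for t in event_terms if str(t).strip()}
    if not terms:
        raise ValueError("event_terms must be non-empty")
    hit = rs.reactions.loc[rs.reactions["pt"].isin(terms), "report_id"].unique()
    return rs.subset(hit, stage="event_reports")


def partition_event(rs: ReportSet, event_terms: Iterable[str]) -> tuple[ReportSet, ReportSet]:
    """Split into (event reports, non-event reports); the two halves
    partition the input."""
    cases = filter_event_reports(rs, event_terms)
    noncase_ids = rs.demo.index.difference(cases.demo.index)
    return cases, rs.subset(noncase_ids, stage="non_event_reports")


def filter_primary_suspect(rs: ReportSet) -> ReportSet:
    """Keep only primary-suspect drug entries.

    An ingredient reported in one report under both the primary-suspect role
    and any other role is excluded from that report entirely; reports left
    without an analysable drug are dropped and counted.
    """
    out = rs.copy()
    if len(out.drugs) == 0:
        out.record_stage("primary_suspect")
        return out
    d = out.drugs
    is_ps = d["role"].eq("primary-suspect")
    flags = (
        d.assign(ps=is_ps, other=~is_ps)
        .groupby(["report_id", "ingredient"], sort=False)[["ps", "other"]]
        .any()
    )
    conflicted = flags.index[flags["ps"] & flags["other"]]
    keep_pairs = pd.MultiIndex.from_frame(d[["report_id", "ingredient"]])
    keep = is_ps & ~keep_pairs.isin(conflicted)
    out.audit["conflicting_role_drug_rows"] = int((keep_pairs.isin(conflicted)).sum())
    kept_drugs = d[keep].reset_index(drop=True)
    surviving = kept_drugs["report_id"].unique()
    out.audit["reports_without_primary_suspect"] = rs.n_reports - len(surviving)
    out = ReportSet(
        demo=out.demo.loc[out.demo.index.intersection(pd.Index(surviving))],
        drugs=kept_drugs,
        reactions=out.reactions[out.reactions["report_id"].isin(surviving)].reset_index(drop=True),
        provenance=out.provenance,
        audit=out.audit,
    )
    out.record_stage("primary_suspect")
    return out


def apply_demographic_filters(
    rs: ReportSet,
    max_age: float = config.MAX_PLAUSIBLE_AGE_YEARS,
    max_weight: float = config.MAX_PLAUSIBLE_WEIGHT_KG,
) -> ReportSet:
    """Completeness and plausibility filter on demographics.

    Retains reports with age and weight present and no greater than the
    plausibility bounds (the boundary values 120 y / 400 kg themselves are
    retained — only strictly larger values are excluded) and sex recorded as
    female or male.
    """
    demo = rs.demo
    ok_age = demo["age_years"].notna() & (demo["age_years"] <= max_age)
    ok_wt = demo["weight_kg"].notna() & (demo["weight_kg"] <= max_weight)
    ok_sex = demo["sex"].isin(["female", "male"])
    out = rs.subset(demo.index[ok_age & ok_wt & ok_sex], stage="demographic_filters")
    out.audit["dropped_age_missing_or_implausible"] = int((~ok_age).sum())
    out.audit["dropped_weight_missing_or_implausible"] = int((~ok_wt).sum())
    out.audit["dropped_sex_unknown"] = int((~ok_sex).sum())
    return out


def clean_cascade(
    rs: ReportSet,
    name_map: Mapping[str, str] | None = None,
) -> ReportSet:
    """normalize -> deduplicate -> primary-suspect -> demographic filters."""
    return apply_demographic_filters(
        filter_primary_suspect(deduplicate(normalize_drug_names(rs, name_map)))
    )


# ---------------------------------------------------------------------------
# Flat TSV dialect (one row per report) and provenance JSON
# ---------------------------------------------------------------------------

_FIELD_SEP = "|"
_ENTRY_SEP = ";"


def write_flat(rs: ReportSet, path) -> None:
    """Write the single-file TSV dialect: one row per report with drug and
    reaction lists serialized inline."""
    drugs_by_id: dict[str, list[str]] = {}
    for row in rs.drugs.itertuples(index=False):
        drugs_by_id.setdefault(row.report_id, []).append(
            _FIELD_SEP.join(
                [
                    row.name_raw,
                    row.ingredient,
                    config.ROLE_NAMES[row.role],
                    format_faers_date(row.therapy_start),
                    format_faers_date(row.therapy_end),
                ]
            )
        )
    reac_by_id = rs.reactions.groupby("report_id")["pt"].agg(lambda s: _ENTRY_SEP.join(sorted(s)))
    rows = []
    for rid, row in rs.demo.iterrows():
        rows.append(
            {
                "report_id": rid,
                "case_id": row["case_id"],
                "version_date": format_faers_date(row["version_date"]),
                "event_date": format_faers_date(row["event_date"]),
                "report_year": int(row["report_year"]),
                "age_years": "" if pd.isna(row["age_years"]) else repr(float(row["age_years"])),
                "sex": row["sex"],
                "weight_kg": "" if pd.isna(row["weight_kg"]) else repr(float(row["weight_kg"])),
                "country": row["country"],
                "outcomes": _ENTRY_SEP.join(sorted(row["outcomes"])),
                "drugs": _ENTRY_SEP.join(drugs_by_id.get(rid, [])),
                "reactions": reac_by_id.get(rid, ""),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_flat(path) -> ReportSet:
    """Read the flat TSV dialect back into a :class:`ReportSet`."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    reports = []
    for row in df.itertuples(index=False):
        drugs = []
        for entry in str(row.drugs).split(_ENTRY_SEP):
            if not entry:
                continue
            name_raw, ingredient, role_code, start, end = entry.split(_FIELD_SEP)
            drugs.append(
                DrugEntry(
                    name_raw=name_raw,
                    ingredient=ingredient,
                    role=config.ROLE_CODES[role_code],
                    therapy_start=parse_faers_date(start),
                    therapy_end=parse_faers_date(end),
                )
            )
        reports.append(
            SafetyReport(
                report_id=row.report_id,
                case_id=row.case_id,
                version_date=parse_faers_date(row.version_date),
                event_date=parse_faers_date(row.event_date),
                report_year=int(row.report_year),
                age_years=float(row.age_years) if row.age_years else None,
                sex=row.sex,
                weight_kg=float(row.weight_kg) if row.weight_kg else None,
                country=row.country,
                outcomes=frozenset(str(row.outcomes).split(_ENTRY_SEP)) if row.outcomes else frozenset({"missing"}),
                drugs=tuple(drugs),
                reactions=frozenset(str(row.reactions).split(_ENTRY_SEP)) if row.reactions else frozenset(),
            )
        )
    return ReportSet.from_reports(reports)


def write_provenance(rs: ReportSet, path) -> None:
    payload = {"stages": rs.provenance, "audit": rs.audit}
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")
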