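"""Time-to-onset analysis: therapy start to adverse-event onset.

One onset record per event report with a primary-suspect drug carrying both
a therapy start date and an event date; the lag is the day difference,
referenced to the earliest therapy start among the report's primary-suspect
entries.  Records with a missing date or a non-positive lag are excluded
and counted by reason.  Quantiles use linear interpolation between order
statistics (the "type 7" convention).
"""

from __future__ import annotations

from collections.abc import Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .report_store import ReportSet


@dataclass(frozen=True)
class OnsetRecord:
    report_id: str
    drug: str
    days: int

    def __post_init__(self):
        if self.days < 1:
            raise ValueError("onset lag must be >= 1 day")


@dataclass(frozen=True)
class OnsetSummary:
    n_used: int
    n_excluded: int
    excluded_by_reason: dict
    median_days: float
    q1_days: float
    q3_days: float
    quantiles: dict  # probability -> days


def extract_onset(clean_set: ReportSet, drugs: Sequence[str] | None = None) -> tuple[list[OnsetRecord], dict]:
    """Onset records for the event-report subset of the cleaned set.

    *drugs*, when given, restricts to those primary-suspect ingredients.
    Returns (records, exclusion counts by reason).
    """
    excluded = {"missing date": 0, "non-positive lag": 0}
    d = clean_set.drugs
    d = d[d["role"] == "primary-suspect"]
    if drugs is not None:
        d = d[d["ingredient"].isin(set(drugs))]
    if len(d) == 0:
        return [], excluded
    # earliest therapy start per (report, ingredient)
    starts = d.groupby(["report_id", "ingredient"], sort=False)["therapy_start"].min().reset_index()
    starts = starts.merge(
        clean_set.demo["event_date"], left_on="report_id", right_index=True, how="left"
    )
    records = []
    for row in starts.itertuples(index=False):
        if pd.isna(row.therapy_start) or pd.isna(row.event_date):
            excluded["missing date"] += 1
            continue
        days = (pd.Timestamp(row.event_date) - pd.Timestamp(row.therapy_start)).days
        if days <= 0:
            excluded["non-positive lag"] += 1
            continue
        records.append(OnsetRecord(report_id=row.report_id, drug=row.ingredient, days=int(days)))
    return records, excluded


def summarize_onset(
    records: Sequence[OnsetRecord],
    probabilities: Sequence[float] = (0.25, 0.5, 0.75),
    excluded_by_reason: dict | None = None,
) -> OnsetSummary:
    """Quantile summary of onset lags (linear / type-7 interpolation)."""
    if not records:
        raise ValueError("no onset records to summarize")
    probs = sorted(set(probabilities) | {0.25, 0.5, 0.75})
    days = np.array([r.days for r in records], dtype=float)
    q = {p: float(np.quantile(days, p, method="linear")) for p in probs}
    excluded_by_reason = dict(excluded_by_reason or {})
    return OnsetSummary(
        n_used=len(records),
        n_excluded=sum(excluded_by_reason.values()),
        excluded_by_reason=excluded_by_reason,
        median_days=q[0.5],
        q1_days=q[0.25],
        q3_days=q[0.75],
        quantiles={p: q[p] for p in probabilities},
    )


def cumulative_curve(records: Sequence[OnsetRecord]) -> pd.DataFrame:
    """Empirical CDF of onset lags: sorted distinct day values with the
    cumulative fraction of records at or below each; the final value is 1."""
    if not records:
        raise ValueError("no onset records for a cumulative curve")
    days = np.sort(np.array([r.days for r in records]))
    values, counts = np.unique(days, return_counts=True)
    cdf = np.cumsum(counts) / len(days)
    return pd.DataFrame({"days": values.astype(int), "cumulative_incidence": cdf})
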