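"""Case/non-case disproportionality analysis: 2x2 tables, reporting odds
ratios, Fisher exact tests, Bonferroni adjustment, signal screening and the
volcano-plot table.

For each drug the cleaned analysis set is cross-classified against the
event of interest:

              event   non-event
    drug        a         b
    other       c         d

ROR = (a/c)/(b/d) = ad/bc, with the log-symmetric Wald interval
exp(ln ROR ± 1.96 sqrt(1/a + 1/b + 1/c + 1/d)).  Two-sided p-values come
from Fisher's exact test on the uncorrected counts; the Haldane–Anscombe
correction (add 0.5 to every cell) is applied to the ROR and its interval
only when a cell is zero, and is flagged.
"""

from __future__ import annotations

import math
from collections.abc import Iterable, Sequence
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact

from . import config
from .report_store import ReportSet


@dataclass(frozen=True)
class ContingencyTable:
    drug: str
    a: int  # event reports with the drug
    b: int  # non-event reports with the drug
    c: int  # event reports without the drug
    d: int  # non-event reports without the drug

    def __post_init__(self):
        for cell in ("a", "b", "c", "d"):
            v = getattr(self, cell)
            if not float(v).is_integer() or v < 0:
                raise ValueError(f"cell {cell} must be a non-negative integer, got {v!r}")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass(frozen=True)
class SignalStats:
    drug: str
    n_cases: int
    ror: float
    ci_lower: float
    ci_upper: float
    p_raw: float | None = None
    p_adj: float | None = None
    zero_corrected: bool = False


@dataclass(frozen=True)
class SignalCriteria:
    """Screening rule: strict inequalities throughout.

    ``ror_min=None`` disables the point-estimate threshold, leaving the
    univariate model-inclusion rule (more than ``min_cases`` reports,
    CI lower bound above ``ci_lower_min``, adjusted p below ``alpha_adj``).
    """

    min_cases: int = 100
    ror_min: float | None = 3.0
    ci_lower_min: float = 1.0
    alpha_adj: float = 0.01

    def __post_init__(self):
        if self.min_cases <= 0 or self.ci_lower_min <= 0 or self.alpha_adj <= 0:
            raise ValueError("criteria must be strictly positive")
        if self.ror_min is not None and self.ror_min <= 0:
            raise ValueError("ror_min must be strictly positive or None")

    def matches(self, s: SignalStats) -> bool:
        if s.p_adj is None:
            raise ValueError("screen requires adjusted p-values")
        ok = s.n_cases > self.min_cases and s.ci_lower > self.ci_lower_min and s.p_adj < self.alpha_adj
        if self.ror_min is not None:
            ok = ok and s.ror > self.ror_min
        return ok


def build_contingency_tables(
    clean_set: ReportSet,
    event_terms: Iterable[str] = config.DEFAULT_EVENT_TERMS,
    exclude_drugs: Iterable[str] = (),
) -> list[ContingencyTable]:
    """One 2x2 table per primary-suspect ingredient in the cleaned set.

    Drugs on *exclude_drugs* (e.g. medications used to treat the event
    itself) are omitted.  All tables share the same margins a+c (event
    reports) and b+d (non-event reports).
    """
    if clean_set.n_reports == 0:
        raise ValueError("no analysable reports")
    terms = {str(t).strip().upper() for t in event_terms if str(t).strip()}
    if not terms:
        raise ValueError("event_terms must be non-empty")
    excluded = {str(d).strip().upper() for d in exclude_drugs}

    event_ids = set(clean_set.reactions.loc[clean_set.reactions["pt"].isin(terms), "report_id"])
    n_event = int(clean_set.demo.index.isin(event_ids).sum())
    n_nonevent = clean_set.n_reports - n_event

    pairs = clean_set.drugs[["report_id", "ingredient"]].drop_duplicates()
    pairs = pairs[~pairs["ingredient"].isin(excluded)]
    is_event = pairs["report_id"].isin(event_ids)
    counts = (
        pairs.assign(event=is_event)
        .groupby("ingredient", sort=True)["event"]
        .agg(a="sum", exposed="count")
    )
    tables = []
    for drug, row in counts.iterrows():
        a = int(row["a"])
        b = int(row["exposed"] - row["a"])
        tables.append(ContingencyTable(drug=drug, a=a, b=b, c=n_event - a, d=n_nonevent - b))
    return tables


def compute_ror_ci(t: ContingencyTable, zero_policy: str = "haldane") -> SignalStats:
    """ROR and 95% Wald CI for one table (p-values filled in separately).

    ``zero_policy='haldane'`` adds 0.5 to all four cells when any cell is
    zero; ``'strict'`` raises instead.  ``n_cases`` always reports the raw
    event-with-drug count.
    """
    a, b, c, d = float(t.a), float(t.b), float(t.c), float(t.d)
    corrected = False
    if min(a, b, c, d) == 0:
        if zero_policy == "strict":
            raise ZeroDivisionError(f"zero cell in contingency table for drug {t.drug!r}")
        if zero_policy != "haldane":
            raise ValueError(f"unknown zero_policy: {zero_policy!r}")
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        corrected = True
    log_ror = math.log(a * d) - math.log(b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return SignalStats(
        drug=t.drug,
        n_cases=t.a,
        ror=math.exp(log_ror),
        ci_lower=math.exp(log_ror - 1.96 * se),
        ci_upper=math.exp(log_ror + 1.96 * se),
        zero_corrected=corrected,
    )


def point_from_ci(ci_lower: float, ci_upper: float) -> float:
    """Point estimate implied by a log-symmetric Wald interval: the
    geometric mean of its bounds.  Useful for checking printed results."""
    if ci_lower <= 0 or ci_upper <= 0:
        raise ValueError("CI bounds must be positive")
    if ci_lower > ci_upper:
        raise ValueError("ci_lower must not exceed ci_upper")
    return math.exp(0.5 * (math.log(ci_lower) + math.log(ci_upper)))


def fisher_exact_two_sided(t: ContingencyTable) -> float:
    """Two-sided Fisher exact p: the total hypergeometric probability of all
    tables with the observed margins no more probable than the observed one.
    Always computed on the uncorrected counts."""
    return float(fisher_exact([[t.a, t.b], [t.c, t.d]], alternative="two-sided")[1])


def adjust_pvalues(p_list: Sequence[float], m: int | None = None) -> list[float]:
    """Bonferroni: p_adj = min(1, m * p).  ``m`` defaults to len(p_list) and
    must be at least that."""
    if m is None:
        m = len(p_list)
    if m < len(p_list):
        raise ValueError("m must be at least the number of p-values")
    for p in p_list:
        if not (0.0 <= p <= 1.0):
            raise ValueError(f"p-value out of [0,1]: {p}")
    return [min(1.0, m * p) for p in p_list]


def screen_signals(stats_list: Sequence[SignalStats], criteria: SignalCriteria | None = None) -> list[SignalStats]:
    """Return the stats flagged by *criteria* (default: the signal rule
    n>100, ROR>3, CI lower bound>1, adjusted p<0.01)."""
    criteria = criteria or SignalCriteria()
    return [s for s in stats_list if criteria.matches(s)]


def compute_signal_stats(
    tables: Sequence[ContingencyTable],
    criteria: SignalCriteria | None = None,
    zero_policy: str = "haldane",
) -> pd.DataFrame:
    """Full per-drug signal table: counts, ROR/CI, Fisher p, Bonferroni
    adjustment and the screening flag.

    The Bonferroni family is the set of drugs meeting ``min_cases`` (drugs
    below it get adjusted p over the same family for reference); the family
    size is stored in ``df.attrs['bonferroni_m']``.
    """
    criteria = criteria or SignalCriteria()
    stats = [compute_ror_ci(t, zero_policy) for t in tables]
    p_raw = [fisher_exact_two_sided(t) for t in tables]
    m = sum(1 for t in tables if t.a > criteria.min_cases)
    m = max(m, 1)
    p_adj = [min(1.0, m * p) for p in p_raw]
    stats = [replace(s, p_raw=p, p_adj=q) for s, p, q in zip(stats, p_raw, p_adj)]
    flagged = {s.drug for s in screen_signals(stats, criteria)}
    df = pd.DataFrame(
        {
            "drug": [t.drug for t in tables],
            "a": [t.a for t in tables],
            "b": [t.b for t in tables],
            "c": [t.c for t in tables],
            "d": [t.d for t in tables],
            "ror": [s.ror for s in stats],
            "ci_lower": [s.ci_lower for s in stats],
            "ci_upper": [s.ci_upper for s in stats],
            "p_raw": p_raw,
            "p_adj": p_adj,
            "zero_corrected": [s.zero_corrected for s in stats],
            "flagged": [t.drug in flagged for t in tables],
        }
    )
    df.attrs["bonferroni_m"] = m
    return df


def volcano_table(
    stats_list: Sequence[SignalStats],
    ror_log_base: float = 2.0,
    p_floor: float = 1e-300,
) -> pd.DataFrame:
    """Plot-ready volcano coordinates: log-ROR on x, -log10 adjusted p on y,
    log10 case count as the colour value.  Log bases are recorded in the
    column names."""
    for s in stats_list:
        if s.p_adj is None:
            raise ValueError("volcano_table requires adjusted p-values")
    x_col = f"log{ror_log_base:g}_ror"
    return pd.DataFrame(
        {
            "drug": [s.drug for s in stats_list],
            x_col: [math.log(s.ror, ror_log_base) for s in stats_list],
            "neg_log10_p_adj": [-math.log10(max(s.p_adj, p_floor)) for s in stats_list],
            "log10_n_cases": [math.log10(s.n_cases) if s.n_cases > 0 else float("-inf") for s in stats_list],
        }
    )
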