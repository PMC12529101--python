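"""Time to onset and Table-1-style descriptive summaries.

Time to onset is EVENT_DT - START_DT + 0.5 days, using the earliest
full-precision start date among the report's drug rows matching the
study drug. The +0.5 keeps same-day onsets strictly positive. Onset
distributions are summarized after trimming to the middle 90%
(values between the 5th and 95th percentiles); all quantiles use
linear interpolation throughout the package.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cases import AnalysisSet, CohortConfig, exposed_drug_rows
from .dates import days_between
from .records import Report

logger = logging.getLogger(__name__)

AGE_BANDS = ((0, 18, "<18"), (18, 45, "18-44"), (45, 65, "45-64"),
             (65, 75, "65-74"), (75, 1000, ">74"))

US_NAMES = frozenset({"US", "USA", "UNITED STATES", "UNITED STATES OF AMERICA"})


@dataclass(frozen=True)
class OnsetRecord:
    caseid: str
    drug: str
    tto_days: float

    def __post_init__(self) -> None:
        if self.tto_days <= 0:
            raise ValueError("time to onset must be positive")


def time_to_onset(
    report: Report, drug: str, config: CohortConfig | None = None
) -> float | None:
    """Days from therapy start to the event, plus 0.5; missing unless
    both dates have day precision and the interval is non-negative.

    Negative intervals are data errors (event before therapy start) and
    are excluded with a log line, not clamped.
    """
    config = config or CohortConfig()
    if report.event_dt is None or report.event_dt.precision != "day":
        return None
    starts = []
    for row in exposed_drug_rows(report, drug, config):
        for ther in report.therapy.get(row.drug_seq, ()):
            if ther.start_dt is not None and ther.start_dt.precision == "day":
                starts.append(ther.start_dt)
    if not starts:
        return None
    start = min(starts, key=lambda d: d.sort_key())
    delta = days_between(start, report.event_dt)
    if delta < 0:
        logger.info(
            "report %s: event %s before start %s; implausible, excluded",
            report.primaryid, report.event_dt, start,
        )
        return None
    return delta + 0.5


def onset_records(
    aset: AnalysisSet, drugs: Iterable[str] | None = None
) -> list[OnsetRecord]:
    """All computable onset times for the exposed reports of each drug."""
    out = []
    for drug in drugs or aset.drug_labels:
        for rep in aset.exposed_reports(drug):
            tto = time_to_onset(rep, drug, aset.config)
            if tto is not None:
                out.append(OnsetRecord(caseid=rep.caseid, drug=drug, tto_days=tto))
    return out


def trim_middle_90(values: Sequence[float]) -> tuple[np.ndarray, float, float]:
    """Keep values within [P5, P95] (linear-interpolation percentiles).

    Returns the kept values and the two cut points.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("trim_middle_90 requires at least one value")
    lo, hi = np.percentile(v, [5.0, 95.0])
    return v[(v >= lo) & (v <= hi)], float(lo), float(hi)


def median_iqr(values: Sequence[float]) -> tuple[float, float, float]:
    """(median, Q1, Q3) by linear interpolation."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("median_iqr requires at least one value")
    med, q1, q3 = np.percentile(v, [50.0, 25.0, 75.0])
    return float(med), float(q1), float(q3)


def binomial_test(k: int, n: int, p0: float = 0.5) -> float:
    """Two-sided exact binomial p-value; NaN when n = 0."""
    if not 0 <= k <= n:
        raise ValueError("need 0 <= k <= n")
    if n == 0:
        return float("nan")
    return float(stats.binomtest(k, n, p0).pvalue)


def summarize_onsets(
    aset: AnalysisSet, drugs: Iterable[str] | None = None
) -> pd.DataFrame:
    """Per-drug onset summary after the middle-90% trim.

    Columns: drug, n_raw, n_kept, cut_low, cut_high, median, q1, q3 —
    the numbers a violin/box onset figure annotates.
    """
    recs = onset_records(aset, drugs)
    rows = []
    for drug in drugs or aset.drug_labels:
        vals = [r.tto_days for r in recs if r.drug == drug]
        if not vals:
            rows.append((drug, 0, 0, np.nan, np.nan, np.nan, np.nan, np.nan))
            continue
        kept, lo, hi = trim_middle_90(vals)
        med, q1, q3 = median_iqr(kept)
        rows.append((drug, len(vals), kept.size, lo, hi, med, q1, q3))
    return pd.DataFrame(
        rows,
        columns=["drug", "n_raw", "n_kept", "cut_low", "cut_high",
                 "median", "q1", "q3"],
    )


def _age_band(age: float) -> str:
    for lo, hi, label in AGE_BANDS:
        if lo <= age < hi:
            return label
    return "missing"


def is_us(country: str | None) -> bool | None:
    if country is None:
        return None
    return country.strip().upper() in US_NAMES


def summarize_characteristics(
    aset: AnalysisSet, drugs: Iterable[str] | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Case-level characteristics per drug, Table-1 style.

    Returns (characteristics, tests). Characteristics is a long table
    (drug, block, category, count, pct) covering sex, age bands, age
    median/IQR, top-3 reporting countries, reporter types, report years
    and outcome codes, with missing counted as its own row and
    percentages over total cases per drug. Tests holds the exact
    binomial p-values: sex F vs M, age >= pooled median vs below,
    US vs non-US, each after excluding missing.
    """
    drugs = list(drugs) if drugs is not None else aset.drug_labels
    pooled_ages = [
        r.age_years
        for d in drugs
        for r in aset.exposed_reports(d)
        if r.age_years is not None
    ]
    pooled_median = float(np.median(pooled_ages)) if pooled_ages else float("nan")

    char_rows = []
    test_rows = []
    for drug in drugs:
        reps = aset.exposed_reports(drug)
        total = len(reps)

        def add(block: str, category: str, count: int) -> None:
            pct = 100.0 * count / total if total else float("nan")
            char_rows.append((drug, block, category, count, pct))

        add("total", "cases", total)

        n_f = sum(1 for r in reps if r.sex == "F")
        n_m = sum(1 for r in reps if r.sex == "M")
        add("sex", "missing", total - n_f - n_m)
        add("sex", "M", n_m)
        add("sex", "F", n_f)
        test_rows.append((drug, "sex_f_vs_m", n_f, n_f + n_m,
                          binomial_test(n_f, n_f + n_m)))

        ages = [r.age_years for r in reps if r.age_years is not None]
        add("age", "missing", total - len(ages))
        for _, _, label in AGE_BANDS:
            add("age", label, sum(1 for a in ages if _age_band(a) == label))
        if ages:
            med, q1, q3 = median_iqr(ages)
            char_rows.append((drug, "age_median_iqr", f"{med:g} ({q1:g}, {q3:g})",
                              len(ages), float("nan")))
        k_old = sum(1 for a in ages if a >= pooled_median)
        test_rows.append((drug, "age_ge_median", k_old, len(ages),
                          binomial_test(k_old, len(ages))))

        countries = pd.Series(
            [r.country.strip().upper() for r in reps if r.country is not None]
        )
        add("country", "missing", total - len(countries))
        for name, count in countries.value_counts().head(3).items():
            add("country", str(name), int(count))
        n_us = int(sum(bool(is_us(c)) for c in countries)) if len(countries) else 0
        test_rows.append((drug, "country_us_vs_other", n_us, len(countries),
                          binomial_test(n_us, len(countries))))

        reporters = [r.reporter for r in reps if r.reporter is not None]
        add("reporter", "missing", total - len(reporters))
        for name, count in pd.Series(reporters).value_counts().items():
            add("reporter", str(name), int(count))

        years = [r.report_year for r in reps if r.report_year is not None]
        add("year", "missing", total - len(years))
        for year, count in sorted(pd.Series(years).value_counts().items()):
            add("year", str(year), int(count))

        outcome_reps = [r for r in reps if r.outcomes]
        add("outcome", "missing", total - len(outcome_reps))
        outc = pd.Series([c for r in outcome_reps for c in sorted(r.outcomes)])
        for code, count in outc.value_counts().items():
            add("outcome", str(code), int(count))

    characteristics = pd.DataFrame(
        char_rows, columns=["drug", "block", "category", "count", "pct"]
    )
    tests = pd.DataFrame(
        test_rows, columns=["drug", "test", "k", "n", "p_value"]
    )
    tests.attrs["pooled_median_age"] = pooled_median
    return characteristics, tests
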