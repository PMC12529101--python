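"""Report-unit disproportionality statistics: ROR and shrinkage IC.

For one drug and one event term at one MedDRA level, the background
reports cross-classify into a 2x2 table

              event   no event
    exposed     a        b
    unexposed   c        d

where every report contributes exactly once (the report unit). The
reporting odds ratio is ROR = ad/bc with a Wald 95% CI on the log scale;
a Haldane–Anscombe +0.5 on all four cells handles zero cells. The
information component is a shrunk log2 observed-to-expected ratio,

    IC = log2((a + 1/2) / (E + 1/2)),   E = (a+b)(a+c)/N,

whose credible bounds are either the standard analytic approximation or
exact gamma quantiles (the internal oracle). A positive signal requires
n = a >= 3, ROR025 > 1 and IC025 > 0 simultaneously.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cases import AnalysisSet
from .meddra import TermMaps, reactions_at_level
from .records import Report

Z95 = 1.96  # conventional two-sided 95% normal quantile
SHRINKAGE = 0.5  # additive offset on observed and expected counts
MIN_REPORTS = 3  # a signal is only evaluated when a >= 3


@dataclass(frozen=True)
class ContingencyTable:
    """The 2x2 cells for one drug x term at one level in a background."""

    a: int
    b: int
    c: int
    d: int
    drug: str = ""
    term: str = ""
    level: str = "PT"

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency cells must be non-negative")

    @property
    def n_background(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def n_exposed(self) -> int:
        return self.a + self.b

    @property
    def n_event(self) -> int:
        return self.a + self.c

    @property
    def expected(self) -> float:
        """Expected a under independence: (a+b)(a+c)/N."""
        if self.n_background == 0:
            raise ValueError("empty background")
        return self.n_exposed * self.n_event / self.n_background


@dataclass(frozen=True)
class SignalEstimate:
    """ROR and IC estimates with interval bounds and classification."""

    drug: str
    term: str
    level: str
    a: int
    b: int
    c: int
    d: int
    ror: float
    ror025: float
    ror975: float
    ic: float
    ic025: float
    ic975: float

    @property
    def n(self) -> int:
        return self.a

    @property
    def evaluated(self) -> bool:
        return self.n >= MIN_REPORTS

    @property
    def positive(self) -> bool:
        return (
            self.evaluated
            and not math.isnan(self.ror025)
            and self.ror025 > 1.0
            and self.ic025 > 0.0
        )


def build_contingency(
    background: Sequence[Report] | AnalysisSet,
    drug: str,
    term: str,
    level: str = "PT",
    maps: TermMaps | None = None,
    exposure: dict[str, dict[str, bool]] | None = None,
) -> ContingencyTable:
    """Count the 2x2 cells over a background, one contribution per report.

    With an :class:`AnalysisSet` the stored exposure flags are used;
    with a bare report sequence an explicit ``exposure`` mapping
    (primaryid -> label -> bool) is required.
    """
    if isinstance(background, AnalysisSet):
        reports = background.reports
        exposure = background.exposure
    else:
        reports = list(background)
        if exposure is None:
            raise ValueError("exposure flags required with a bare report list")
    a = b = c = d = 0
    term_l = term.strip().lower()
    for rep in reports:
        exposed = exposure[rep.primaryid][drug]
        has_term = any(
            t.strip().lower() == term_l for t in reactions_at_level(rep, level, maps)
        )
        if exposed and has_term:
            a += 1
        elif exposed:
            b += 1
        elif has_term:
            c += 1
        else:
            d += 1
    return ContingencyTable(a, b, c, d, drug=drug, term=term, level=level)


def ror_with_ci(table: ContingencyTable, z: float = Z95) -> tuple[float, float, float]:
    """ROR with Wald 95% CI; zero cells get +0.5 on all four cells.

    A table with an entirely empty margin (no exposed reports, no
    reports with the event, ...) has no defined odds ratio and returns
    NaNs rather than raising.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    if (a + b) == 0 or (c + d) == 0 or (a + c) == 0 or (b + d) == 0:
        return (math.nan, math.nan, math.nan)
    if min(a, b, c, d) == 0:
        fa, fb, fc, fd = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    else:
        fa, fb, fc, fd = float(a), float(b), float(c), float(d)
    ror = (fa * fd) / (fb * fc)
    se = math.sqrt(1.0 / fa + 1.0 / fb + 1.0 / fc + 1.0 / fd)
    return (ror, ror * math.exp(-z * se), ror * math.exp(z * se))


def ic_with_ci(
    table: ContingencyTable, method: str = "approx"
) -> tuple[float, float, float]:
    """Shrinkage IC with 95% credible bounds.

    ``approx`` uses the published closed-form bounds

        IC025 = IC - 3.3 (a+1/2)^-1/2 - 2 (a+1/2)^-3/2
        IC975 = IC + 2.4 (a+1/2)^-1/2 - 1/2 (a+1/2)^-3/2

    and ``gamma`` takes log2 of the 2.5%/97.5% quantiles of
    Gamma(shape a+1/2, rate E+1/2) — the exact posterior form the
    approximation was fitted to. The +1/2 offsets make every case
    finite, including a = 0.
    """
    if table.n_background == 0:
        raise ValueError("IC undefined on an empty background")
    a = table.a
    e = table.expected
    ic = math.log2((a + SHRINKAGE) / (e + SHRINKAGE))
    if method == "approx":
        s = a + SHRINKAGE
        lo = ic - 3.3 * s ** -0.5 - 2.0 * s ** -1.5
        hi = ic + 2.4 * s ** -0.5 - 0.5 * s ** -1.5
    elif method == "gamma":
        q = stats.gamma.ppf([0.025, 0.975], a + SHRINKAGE, scale=1.0 / (e + SHRINKAGE))
        lo, hi = math.log2(q[0]), math.log2(q[1])
    else:
        raise ValueError(f"unknown IC method {method!r}")
    return (ic, lo, hi)


def classify_signal(
    table: ContingencyTable, ic_method: str = "approx"
) -> SignalEstimate:
    """Full estimate for one table: ROR, IC, bounds, classification."""
    ror, ror_lo, ror_hi = ror_with_ci(table)
    ic, ic_lo, ic_hi = ic_with_ci(table, method=ic_method)
    return SignalEstimate(
        drug=table.drug,
        term=table.term,
        level=table.level,
        a=table.a,
        b=table.b,
        c=table.c,
        d=table.d,
        ror=ror,
        ror025=ror_lo,
        ror975=ror_hi,
        ic=ic,
        ic025=ic_lo,
        ic975=ic_hi,
    )


SCAN_COLUMNS = [
    "drug", "level", "term", "subgroup", "a", "b", "c", "d",
    "ror", "ror025", "ror975", "ic", "ic025", "ic975",
    "n", "evaluated", "positive",
]


def _membership(
    reports: Sequence[Report], level: str, maps: TermMaps | None
) -> dict[str, np.ndarray]:
    """term -> boolean vector over reports (report-unit membership)."""
    out: dict[str, np.ndarray] = {}
    n = len(reports)
    for i, rep in enumerate(reports):
        for term in reactions_at_level(rep, level, maps):
            vec = out.get(term)
            if vec is None:
                vec = out[term] = np.zeros(n, dtype=bool)
            vec[i] = True
    return out


def run_signal_scan(
    aset: AnalysisSet,
    maps: TermMaps | None = None,
    levels: Iterable[str] = ("PT",),
    subgroups: Iterable[str] = ("all",),
    ic_method: str = "approx",
    drugs: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Scan every drug x term x level x subgroup combination.

    Each subgroup recomputes the background restricted to that
    indication tag. Rows are sorted by IC025 descending within drug
    (ties: n descending, then term) for deterministic output.
    """
    drugs = list(drugs) if drugs is not None else aset.drug_labels
    frames: list[pd.DataFrame] = []
    for subgroup in subgroups:
        sub = aset.subset(subgroup)
        n = len(sub.reports)
        exp_vec = {
            drug: np.fromiter(
                (sub.exposure[r.primaryid][drug] for r in sub.reports),
                dtype=bool,
                count=n,
            )
            for drug in drugs
        }
        for level in levels:
            members = _membership(sub.reports, level, maps)
            rows = []
            for drug in drugs:
                e = exp_vec[drug]
                n_exposed = int(e.sum())
                for term, m in members.items():
                    a = int((e & m).sum())
                    n_event = int(m.sum())
                    table = ContingencyTable(
                        a, n_exposed - a, n_event - a,
                        n - n_exposed - n_event + a,
                        drug=drug, term=term, level=level,
                    )
                    est = classify_signal(table, ic_method=ic_method)
                    rows.append(
                        (drug, level, term, subgroup, est.a, est.b, est.c, est.d,
                         est.ror, est.ror025, est.ror975, est.ic, est.ic025,
                         est.ic975, est.n, est.evaluated, est.positive)
                    )
            frames.append(pd.DataFrame(rows, columns=SCAN_COLUMNS))
    if not frames:
        return pd.DataFrame(columns=SCAN_COLUMNS)
    out = pd.concat(frames, ignore_index=True)
    out = out.sort_values(
        ["subgroup", "level", "drug", "ic025", "n", "term"],
        ascending=[True, True, True, False, False, True],
    ).reset_index(drop=True)
    return out
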