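"""Cohort construction: deduplication, indication restriction, exposure.

Implements the FDA 2014 duplicate-elimination rule (one report per
CASEID: latest FDA_DT, ties broken by largest PRIMARYID), restriction of
the background to reports carrying the study indications (psoriasis /
psoriatic arthropathy by default), and dictionary-driven exposure
flagging of suspect drugs (PS/SS roles).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from . import faers_io
from .records import Report

logger = logging.getLogger(__name__)

#: default generic + brand names of the three study drugs
DEFAULT_DRUG_DICTIONARY: dict[str, frozenset[str]] = {
    "deucravacitinib": frozenset({"deucravacitinib", "sotyktu"}),
    "upadacitinib": frozenset({"upadacitinib", "rinvoq"}),
    "tofacitinib": frozenset({"tofacitinib", "xeljanz"}),
}

#: indication PTs defining the cohort, grouped by subgroup tag
DEFAULT_INDICATION_GROUPS: dict[str, frozenset[str]] = {
    "psoriasis": frozenset({"Psoriasis"}),
    "psa": frozenset({"Psoriatic arthropathy"}),
}

_PUNCT = re.compile(r"[^A-Z0-9]+")


def normalize_drug_name(name: str) -> str:
    """Uppercase, strip punctuation, collapse whitespace."""
    return _PUNCT.sub(" ", name.upper()).strip()


@dataclass(frozen=True)
class CohortConfig:
    """Study-population definition: indications, drug dictionary, roles."""

    indication_groups: Mapping[str, frozenset[str]] = field(
        default_factory=lambda: dict(DEFAULT_INDICATION_GROUPS)
    )
    drug_dictionary: Mapping[str, frozenset[str]] = field(
        default_factory=lambda: dict(DEFAULT_DRUG_DICTIONARY)
    )
    roles_included: frozenset[str] = frozenset({"PS", "SS"})
    year_window: tuple[int, int] | None = None  # inclusive report-year bounds

    def __post_init__(self) -> None:
        if not self.drug_dictionary or any(not v for v in self.drug_dictionary.values()):
            raise ValueError("drug dictionary must be non-empty")
        if not self.indication_groups:
            raise ValueError("indication groups must be non-empty")
        if self.year_window is not None and self.year_window[0] > self.year_window[1]:
            raise ValueError("window start after end")

    @property
    def indication_pts(self) -> frozenset[str]:
        out: set[str] = set()
        for pts in self.indication_groups.values():
            out |= pts
        return frozenset(out)

    def normalized_dictionary(self) -> dict[str, frozenset[str]]:
        return {
            label: frozenset(normalize_drug_name(n) for n in names)
            for label, names in self.drug_dictionary.items()
        }


def _primaryid_key(pid: str) -> tuple[int, int, str]:
    # all-digit ids compare numerically; anything else compares as text
    # after every numeric id (a documented total-order convention)
    if pid.isdigit():
        return (0, int(pid), "")
    return (1, 0, pid)


def dedup_sort_key(report: Report) -> tuple[tuple[int, int, int], tuple[int, int, str]]:
    """Selection key of the FDA rule: (FDA_DT, PRIMARYID), missing date
    components sorting earliest so fuller/later versions win ties."""
    date_key = report.fda_dt.sort_key() if report.fda_dt is not None else (0, 0, 0)
    return (date_key, _primaryid_key(report.primaryid))


def deduplicate(reports: Iterable[Report]) -> list[Report]:
    """One report per CASEID: latest FDA_DT, then largest PRIMARYID.

    A pure max per case, hence idempotent and insensitive to input
    order. The number of removed versions is logged.
    """
    best: dict[str, Report] = {}
    n_in = 0
    for rep in reports:
        n_in += 1
        cur = best.get(rep.caseid)
        if cur is None or dedup_sort_key(rep) > dedup_sort_key(cur):
            best[rep.caseid] = rep
    removed = n_in - len(best)
    if removed:
        logger.info("deduplicate: removed %d duplicate report version(s)", removed)
    return list(best.values())


def indication_tag(report: Report, config: CohortConfig) -> str | None:
    """Subgroup tag from the report's indication PTs, or None if the
    report is outside the cohort. Matching is case-insensitive exact PT."""
    indi = {pt.strip().lower() for pt in report.indications}
    hits = [
        tag
        for tag, pts in config.indication_groups.items()
        if indi & {p.strip().lower() for p in pts}
    ]
    if not hits:
        return None
    return hits[0] if len(hits) == 1 else "both"


def restrict_to_indications(
    reports: Sequence[Report], config: CohortConfig
) -> tuple[list[Report], dict[str, str]]:
    """Keep reports whose indications intersect the cohort PTs.

    Returns the kept reports and a mapping primaryid -> subgroup tag.
    An empty result is a warning, not an error.
    """
    kept: list[Report] = []
    tags: dict[str, str] = {}
    for rep in reports:
        tag = indication_tag(rep, config)
        if tag is not None:
            kept.append(rep)
            tags[rep.primaryid] = tag
    if not kept:
        logger.warning("indication restriction produced an empty cohort")
    return kept, tags


def _name_matches(normalized_field: str, name: str) -> bool:
    if not normalized_field:
        return False
    if normalized_field == name:
        return True
    # dictionary name as a whole word (token subsequence) of the field
    return f" {name} " in f" {normalized_field} "


def flag_exposure(report: Report, config: CohortConfig) -> dict[str, bool]:
    """Per-drug exposure flags: any PS/SS drug row whose DRUGNAME or
    PROD_AI matches the dictionary after normalization."""
    dictionary = config.normalized_dictionary()
    flags = {label: False for label in dictionary}
    for drug in report.drugs:
        if drug.role_cod not in config.roles_included:
            continue
        fields = [normalize_drug_name(drug.drugname)]
        if drug.prod_ai:
            fields.append(normalize_drug_name(drug.prod_ai))
        for label, names in dictionary.items():
            if flags[label]:
                continue
            if any(_name_matches(f, n) for f in fields for n in names):
                flags[label] = True
    return flags


def exposed_drug_rows(report: Report, label: str, config: CohortConfig) -> list:
    """Drug rows (with included roles) matching one dictionary label;
    used to link therapy dates for time-to-onset."""
    names = config.normalized_dictionary()[label]
    rows = []
    for drug in report.drugs:
        if drug.role_cod not in config.roles_included:
            continue
        fields = [normalize_drug_name(drug.drugname)]
        if drug.prod_ai:
            fields.append(normalize_drug_name(drug.prod_ai))
        if any(_name_matches(f, n) for f in fields for n in names):
            rows.append(drug)
    return rows


@dataclass
class AnalysisSet:
    """The indication-restricted, deduplicated background plus per-drug
    exposure flags — the substrate of every downstream analysis."""

    reports: list[Report]
    tags: dict[str, str]  # primaryid -> psoriasis / psa / both
    exposure: dict[str, dict[str, bool]]  # primaryid -> label -> bool
    config: CohortConfig
    flow: dict[str, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.reports)

    @property
    def drug_labels(self) -> list[str]:
        return list(self.config.drug_dictionary)

    def is_exposed(self, report: Report, label: str) -> bool:
        return self.exposure[report.primaryid][label]

    def exposed_reports(self, label: str) -> list[Report]:
        return [r for r in self.reports if self.exposure[r.primaryid][label]]

    def subset(self, subgroup: str) -> "AnalysisSet":
        """Restrict the background to one indication subgroup.

        ``psoriasis`` and ``psa`` each include reports tagged ``both``;
        ``all`` is the identity.
        """
        if subgroup == "all":
            return self
        keep = {
            pid for pid, tag in self.tags.items() if tag == subgroup or tag == "both"
        }
        reports = [r for r in self.reports if r.primaryid in keep]
        return AnalysisSet(
            reports=reports,
            tags={r.primaryid: self.tags[r.primaryid] for r in reports},
            exposure={r.primaryid: self.exposure[r.primaryid] for r in reports},
            config=self.config,
            flow={**self.flow, "subgroup_" + subgroup: len(reports)},
        )


def build_analysis_set(
    source: Sequence[str | Path] | dict[str, list],
    config: CohortConfig | None = None,
) -> AnalysisSet:
    """Full cohort pipeline: join -> window -> dedup -> indication
    restriction -> exposure flags, with stage counts recorded.

    ``source`` is either a list of extract directories or an already
    parsed ``{table kind: records}`` mapping.
    """
    config = config or CohortConfig()
    if isinstance(source, dict):
        tables = source
    else:
        tables = {k: [] for k in faers_io.TABLE_KINDS}
        for directory in source:
            part = faers_io.read_extract(directory)
            for kind in tables:
                tables[kind].extend(part[kind])

    joined = faers_io.join_cases(tables)
    flow = {
        "raw_reports": len(joined.reports),
        "orphan_rows": sum(joined.orphans.values()),
    }

    reports = joined.reports
    if config.year_window is not None:
        lo, hi = config.year_window
        reports = [
            r for r in reports if r.report_year is not None and lo <= r.report_year <= hi
        ]
        flow["in_window"] = len(reports)

    deduped = deduplicate(reports)
    flow["after_dedup"] = len(deduped)
    flow["duplicates_removed"] = len(reports) - len(deduped)

    cohort, tags = restrict_to_indications(deduped, config)
    flow["in_cohort"] = len(cohort)

    exposure = {r.primaryid: flag_exposure(r, config) for r in cohort}
    for label in config.drug_dictionary:
        flow[f"exposed_{label}"] = sum(
            1 for r in cohort if exposure[r.primaryid][label]
        )
    return AnalysisSet(
        reports=cohort, tags=tags, exposure=exposure, config=config, flow=flow
    )
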