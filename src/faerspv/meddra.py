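"""MedDRA-style term hierarchy: PT -> SOC rollup and SMQ membership.

MedDRA itself is licensed, so no dictionary content ships with the
package. This module defines the file contract (two-column mapping
tables) and a synthetic toy ontology used by the test suite and the
synthetic corpus generator. Lookups are case-insensitive; every PT has
exactly one primary SOC; an SMQ is any curated PT set.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

from .records import Report, normalize_ws

logger = logging.getLogger(__name__)

LEVELS = ("PT", "SOC", "SMQ")

#: bucket for PTs with no SOC assignment, so totals are conserved
UNMAPPED = "UNMAPPED"


class TermMapError(ValueError):
    """Conflicting or malformed mapping tables."""


def _key(term: str) -> str:
    return normalize_ws(term).lower()


@dataclass
class TermMaps:
    """PT->primary-SOC mapping and SMQ membership sets."""

    pt_to_soc: dict[str, str] = field(default_factory=dict)  # key: lowered PT
    smq_members: dict[str, frozenset[str]] = field(default_factory=dict)
    pt_version: str = ""
    smq_version: str = ""
    _smq_by_pt: dict[str, set[str]] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        for pts in self.smq_members.values():
            if not pts:
                raise TermMapError("SMQ with empty member set")
        self._smq_by_pt = {}
        for smq, pts in self.smq_members.items():
            for pt in pts:
                self._smq_by_pt.setdefault(_key(pt), set()).add(smq)

    @classmethod
    def from_dicts(
        cls,
        pt_to_soc: Mapping[str, str],
        smq_members: Mapping[str, Iterable[str]] | None = None,
        pt_version: str = "",
        smq_version: str = "",
    ) -> "TermMaps":
        return cls(
            pt_to_soc={_key(pt): soc for pt, soc in pt_to_soc.items()},
            smq_members={
                smq: frozenset(pts) for smq, pts in (smq_members or {}).items()
            },
            pt_version=pt_version,
            smq_version=smq_version,
        )

    def soc_of(self, pt: str) -> str:
        soc = self.pt_to_soc.get(_key(pt))
        if soc is None:
            logger.debug("PT %r has no SOC mapping; bucketed as %s", pt, UNMAPPED)
            return UNMAPPED
        return soc

    def smqs_of(self, pt: str) -> set[str]:
        return set(self._smq_by_pt.get(_key(pt), ()))

    @property
    def socs(self) -> set[str]:
        return set(self.pt_to_soc.values())


def _read_rows(path: str | Path, delimiter: str | None) -> list[list[str]]:
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    if delimiter is None:
        first = text.splitlines()[0] if text.splitlines() else ""
        delimiter = "\t" if "\t" in first else ","
    rows = []
    for row in csv.reader(text.splitlines(), delimiter=delimiter):
        if not row or all(not c.strip() for c in row):
            continue
        rows.append([c.strip() for c in row])
    return rows


def load_term_maps(
    pt_soc_path: str | Path,
    smq_path: str | Path | None = None,
    delimiter: str | None = None,
    scope: str = "both",
) -> TermMaps:
    """Load (PT, SOC) and (SMQ, PT[, scope]) mapping tables.

    Duplicate identical rows collapse; a PT assigned to two different
    SOCs is a configuration error listing every conflict. The optional
    third SMQ column is a narrow/broad scope honored when ``scope`` is
    not ``"both"``.
    """
    pt_rows = _read_rows(pt_soc_path, delimiter)
    if pt_rows and pt_rows[0] and pt_rows[0][0].lower() in ("pt", "preferred_term"):
        pt_rows = pt_rows[1:]
    pt_to_soc: dict[str, str] = {}
    pt_display: dict[str, str] = {}
    conflicts: list[str] = []
    for row in pt_rows:
        if len(row) < 2:
            raise TermMapError(f"PT->SOC row with <2 columns: {row!r}")
        pt, soc = row[0], row[1]
        k = _key(pt)
        if k in pt_to_soc and pt_to_soc[k] != soc:
            conflicts.append(f"{pt_display[k]} -> {pt_to_soc[k]} vs {soc}")
        else:
            pt_to_soc[k] = soc
            pt_display[k] = pt
    if conflicts:
        raise TermMapError(
            "conflicting PT->SOC assignments: " + "; ".join(sorted(conflicts))
        )

    smq_members: dict[str, set[str]] = {}
    if smq_path is not None:
        smq_rows = _read_rows(smq_path, delimiter)
        if smq_rows and smq_rows[0] and smq_rows[0][0].lower() == "smq":
            smq_rows = smq_rows[1:]
        for row in smq_rows:
            if len(row) < 2:
                raise TermMapError(f"SMQ row with <2 columns: {row!r}")
            smq, pt = row[0], row[1]
            row_scope = row[2].lower() if len(row) > 2 and row[2] else "narrow"
            if scope != "both" and row_scope != scope:
                continue
            smq_members.setdefault(smq, set()).add(pt)

    return TermMaps(
        pt_to_soc=pt_to_soc,
        smq_members={smq: frozenset(pts) for smq, pts in smq_members.items()},
    )


def toy_ontology() -> TermMaps:
    """The packaged synthetic toy ontology (not MedDRA content)."""
    data = resources.files("faerspv.data")
    with resources.as_file(data / "toy_pt_soc.tsv") as p1, resources.as_file(
        data / "toy_smq.tsv"
    ) as p2:
        maps = load_term_maps(p1, p2, delimiter="\t")
    maps.pt_version = "toy-1"
    maps.smq_version = "toy-1"
    return maps


def reactions_at_level(
    report: Report | Iterable[str], level: str, maps: TermMaps | None = None
) -> set[str]:
    """The report's reaction terms rolled up to PT, SOC or SMQ level.

    Always a set (the report unit is preserved): SOC is the image of
    the PT set under the primary-SOC map, with unmapped PTs collected
    under ``UNMAPPED``; SMQ is every SMQ whose member set intersects
    the PT set.
    """
    pts = report.reactions if isinstance(report, Report) else set(report)
    if level == "PT":
        return {normalize_ws(pt) for pt in pts}
    if maps is None:
        raise ValueError(f"level {level} requires term maps")
    if level == "SOC":
        return {maps.soc_of(pt) for pt in pts}
    if level == "SMQ":
        out: set[str] = set()
        for pt in pts:
            out |= maps.smqs_of(pt)
        return out
    raise ValueError(f"unknown level {level!r}; expected one of {LEVELS}")
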