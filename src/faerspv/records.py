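"""Typed rows of the FAERS quarterly tables and the joined case report.

One spontaneous report (ICSR) is spread over six "$"-delimited tables
keyed by PRIMARYID (a report version) and CASEID (the underlying case).
These dataclasses mirror the columns the analysis uses; columns present
in a quarter but unknown to the schema are preserved verbatim in
``raw`` so files round-trip.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .dates import PartialDate

DRUG_ROLES = frozenset({"PS", "SS", "C", "I"})
OUTCOME_CODES = frozenset({"DE", "LT", "HO", "DS", "CA", "RI", "OT"})

#: age-unit code -> multiplier to years; DEC is decades.
AGE_UNIT_TO_YEARS = {
    "YR": 1.0,
    "DEC": 10.0,
    "MON": 1.0 / 12.0,
    "WK": 1.0 / 52.18,
    "DY": 1.0 / 365.25,
}


def normalize_ws(s: str) -> str:
    return " ".join(s.split())


@dataclass
class DemoRecord:
    primaryid: str
    caseid: str
    fda_dt: PartialDate | None = None
    event_dt: PartialDate | None = None
    age: float | None = None
    age_cod: str | None = None
    sex: str | None = None  # "M" / "F" / None (unknown or missing)
    reporter_country: str | None = None
    occp_cod: str | None = None
    raw: dict[str, str] = field(default_factory=dict)

    @property
    def age_years(self) -> float | None:
        """Age normalized to years via the unit code.

        A numeric age with a blank unit code is taken to already be in
        years (the common FAERS convention); an unknown unit code makes
        the age missing rather than guessing.
        """
        if self.age is None:
            return None
        cod = (self.age_cod or "YR").strip().upper() or "YR"
        mult = AGE_UNIT_TO_YEARS.get(cod)
        if mult is None:
            return None
        return self.age * mult


@dataclass
class DrugRecord:
    primaryid: str
    drug_seq: int
    role_cod: str | None = None  # PS / SS / C / I
    drugname: str = ""
    prod_ai: str | None = None
    raw: dict[str, str] = field(default_factory=dict)


@dataclass
class ReactionRecord:
    primaryid: str
    pt: str
    raw: dict[str, str] = field(default_factory=dict)


@dataclass
class IndiRecord:
    primaryid: str
    indi_drug_seq: int
    indi_pt: str
    raw: dict[str, str] = field(default_factory=dict)


@dataclass
class TherRecord:
    primaryid: str
    dsg_drug_seq: int
    start_dt: PartialDate | None = None
    end_dt: PartialDate | None = None
    raw: dict[str, str] = field(default_factory=dict)


@dataclass
class OutcRecord:
    primaryid: str
    outc_cod: str = ""
    raw: dict[str, str] = field(default_factory=dict)


@dataclass
class Report:
    """One joined ICSR: demographics plus all drug/reaction/indication/
    therapy/outcome rows sharing a PRIMARYID.

    Reactions and indications are *sets* of whitespace-normalized PT
    strings: a PT mentioned twice in REAC contributes once, which is
    what report-unit contingency counting requires.
    """

    primaryid: str
    caseid: str
    fda_dt: PartialDate | None
    event_dt: PartialDate | None
    age_years: float | None
    sex: str | None
    country: str | None
    reporter: str | None
    drugs: list[DrugRecord] = field(default_factory=list)
    therapy: dict[int, list[TherRecord]] = field(default_factory=dict)
    reactions: set[str] = field(default_factory=set)
    indications: set[str] = field(default_factory=set)
    outcomes: set[str] = field(default_factory=set)

    @property
    def report_year(self) -> int | None:
        return self.fda_dt.year if self.fda_dt is not None else None
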