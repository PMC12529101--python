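"""Reading and writing FAERS quarterly ASCII extracts.

The extracts are plain text, one header line of column names and one
line per row, fields separated by ``$``. FAERS never quotes fields, so
there is no quoting dialect; an embedded ``$`` cannot occur. Columns are
located by (case-insensitive) name, not position, because the schema
drifts across quarters; unknown columns are kept in each record's
``raw`` mapping and written back on serialization.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .dates import PartialDate, parse_partial_date
from .records import (
    DRUG_ROLES,
    OUTCOME_CODES,
    DemoRecord,
    DrugRecord,
    IndiRecord,
    OutcRecord,
    ReactionRecord,
    Report,
    TherRecord,
    normalize_ws,
)

logger = logging.getLogger(__name__)

DELIM = "$"

TABLE_KINDS = ("demo", "drug", "reac", "indi", "ther", "outc")


class FaersFormatError(ValueError):
    """Malformed header: mandatory columns absent."""


@dataclass(frozen=True)
class _Schema:
    columns: tuple[str, ...]  # canonical column order for writing
    mandatory: tuple[str, ...]


SCHEMAS: dict[str, _Schema] = {
    "demo": _Schema(
        columns=(
            "primaryid", "caseid", "fda_dt", "event_dt", "age", "age_cod",
            "sex", "reporter_country", "occp_cod",
        ),
        mandatory=("primaryid", "caseid"),
    ),
    "drug": _Schema(
        columns=("primaryid", "drug_seq", "role_cod", "drugname", "prod_ai"),
        mandatory=("primaryid", "drug_seq"),
    ),
    "reac": _Schema(columns=("primaryid", "pt"), mandatory=("primaryid", "pt")),
    "indi": _Schema(
        columns=("primaryid", "indi_drug_seq", "indi_pt"),
        mandatory=("primaryid", "indi_pt"),
    ),
    "ther": _Schema(
        columns=("primaryid", "dsg_drug_seq", "start_dt", "end_dt"),
        mandatory=("primaryid", "dsg_drug_seq"),
    ),
    "outc": _Schema(columns=("primaryid", "outc_cod"), mandatory=("primaryid", "outc_cod")),
}


def _opt(row: dict[str, str], key: str) -> str | None:
    val = row.pop(key, "").strip()
    return val or None


def _int_or_zero(val: str | None) -> int:
    try:
        return int(val) if val else 0
    except ValueError:
        return 0


def _parse_sex(val: str | None) -> str | None:
    if val is None:
        return None
    val = val.upper()
    return val if val in ("M", "F") else None


def _parse_age(val: str | None) -> float | None:
    if val is None:
        return None
    try:
        return float(val)
    except ValueError:
        logger.warning("unparseable age %r treated as missing", val)
        return None


def _parse_role(val: str | None) -> str | None:
    if val is None:
        return None
    val = val.upper()
    if val not in DRUG_ROLES:
        logger.warning("unknown drug role %r treated as missing", val)
        return None
    return val


def _make_record(kind: str, row: dict[str, str]):
    # row maps lower-cased header name -> stripped field; consumed keys are
    # popped so leftovers land in .raw
    if kind == "demo":
        return DemoRecord(
            primaryid=row.pop("primaryid", "").strip(),
            caseid=row.pop("caseid", "").strip(),
            fda_dt=parse_partial_date(row.pop("fda_dt", "")),
            event_dt=parse_partial_date(row.pop("event_dt", "")),
            age=_parse_age(_opt(row, "age")),
            age_cod=_opt(row, "age_cod"),
            sex=_parse_sex(_opt(row, "sex")),
            reporter_country=_opt(row, "reporter_country"),
            occp_cod=_opt(row, "occp_cod"),
            raw=row,
        )
    if kind == "drug":
        return DrugRecord(
            primaryid=row.pop("primaryid", "").strip(),
            drug_seq=_int_or_zero(row.pop("drug_seq", "")),
            role_cod=_parse_role(_opt(row, "role_cod")),
            drugname=normalize_ws(row.pop("drugname", "")),
            prod_ai=_opt(row, "prod_ai"),
            raw=row,
        )
    if kind == "reac":
        return ReactionRecord(
            primaryid=row.pop("primaryid", "").strip(),
            pt=normalize_ws(row.pop("pt", "")),
            raw=row,
        )
    if kind == "indi":
        return IndiRecord(
            primaryid=row.pop("primaryid", "").strip(),
            indi_drug_seq=_int_or_zero(row.pop("indi_drug_seq", "")),
            indi_pt=normalize_ws(row.pop("indi_pt", "")),
            raw=row,
        )
    if kind == "ther":
        return TherRecord(
            primaryid=row.pop("primaryid", "").strip(),
            dsg_drug_seq=_int_or_zero(row.pop("dsg_drug_seq", "")),
            start_dt=parse_partial_date(row.pop("start_dt", "")),
            end_dt=parse_partial_date(row.pop("end_dt", "")),
            raw=row,
        )
    if kind == "outc":
        code = row.pop("outc_cod", "").strip().upper()
        if code and code not in OUTCOME_CODES:
            logger.warning("unknown outcome code %r kept verbatim", code)
        return OutcRecord(primaryid=row.pop("primaryid", "").strip(), outc_cod=code, raw=row)
    raise ValueError(f"unknown table kind {kind!r}")


def read_table(path: str | Path, kind: str) -> list:
    """Parse one FAERS ASCII table into typed records.

    Lines whose field count does not match the header are logged and
    skipped (never fatal); a header missing mandatory columns raises
    :class:`FaersFormatError`.
    """
    if kind not in SCHEMAS:
        raise ValueError(f"unknown table kind {kind!r}; expected one of {TABLE_KINDS}")
    schema = SCHEMAS[kind]
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        header_line = fh.readline().rstrip("\r\n")
        header = [h.strip().lower() for h in header_line.split(DELIM)]
        missing = [c for c in schema.mandatory if c not in header]
        if missing:
            raise FaersFormatError(
                f"{path.name}: header missing mandatory column(s) {missing}"
            )
        records = []
        skipped = 0
        for lineno, line in enumerate(fh, start=2):
            fields = line.rstrip("\r\n").split(DELIM)
            if len(fields) != len(header):
                skipped += 1
                logger.warning(
                    "%s:%d has %d fields, expected %d; skipped",
                    path.name, lineno, len(fields), len(header),
                )
                continue
            records.append(_make_record(kind, dict(zip(header, fields))))
    if skipped:
        logger.warning("%s: skipped %d malformed line(s)", path.name, skipped)
    return records


def _fmt_date(d: PartialDate | None) -> str:
    return d.format() if d is not None else ""


def _fmt_num(x: float | int | None) -> str:
    if x is None:
        return ""
    if isinstance(x, float) and x == int(x):
        return str(int(x))
    return str(x)


def _serialize(kind: str, rec) -> dict[str, str]:
    if kind == "demo":
        base = {
            "primaryid": rec.primaryid, "caseid": rec.caseid,
            "fda_dt": _fmt_date(rec.fda_dt), "event_dt": _fmt_date(rec.event_dt),
            "age": _fmt_num(rec.age), "age_cod": rec.age_cod or "",
            "sex": rec.sex or "", "reporter_country": rec.reporter_country or "",
            "occp_cod": rec.occp_cod or "",
        }
    elif kind == "drug":
        base = {
            "primaryid": rec.primaryid, "drug_seq": str(rec.drug_seq),
            "role_cod": rec.role_cod or "", "drugname": rec.drugname,
            "prod_ai": rec.prod_ai or "",
        }
    elif kind == "reac":
        base = {"primaryid": rec.primaryid, "pt": rec.pt}
    elif kind == "indi":
        base = {
            "primaryid": rec.primaryid, "indi_drug_seq": str(rec.indi_drug_seq),
            "indi_pt": rec.indi_pt,
        }
    elif kind == "ther":
        base = {
            "primaryid": rec.primaryid, "dsg_drug_seq": str(rec.dsg_drug_seq),
            "start_dt": _fmt_date(rec.start_dt), "end_dt": _fmt_date(rec.end_dt),
        }
    elif kind == "outc":
        base = {"primaryid": rec.primaryid, "outc_cod": rec.outc_cod}
    else:
        raise ValueError(f"unknown table kind {kind!r}")
    base.update(rec.raw)
    return base


def write_table(records: Sequence, path: str | Path, kind: str) -> None:
    """Serialize records to the canonical "$"-delimited form.

    Column order is the schema order followed by any extra raw columns
    (sorted); ``read_table(write_table(...))`` round-trips record for
    record, and re-serializing is byte-identical.
    """
    schema = SCHEMAS[kind]
    extra: list[str] = []
    for rec in records:
        for key in rec.raw:
            if key not in extra:
                extra.append(key)
    columns = list(schema.columns) + sorted(extra)
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        fh.write(DELIM.join(c.upper() for c in columns) + "\n")
        for rec in records:
            row = _serialize(kind, rec)
            fh.write(DELIM.join(row.get(c, "") for c in columns) + "\n")


def read_extract(directory: str | Path) -> dict[str, list]:
    """Read all six tables from one extract directory.

    Files are located case-insensitively by the table name appearing in
    the file stem (``demo.txt``, ``DEMO24Q3.TXT``, ...). A missing table
    yields an empty record list.
    """
    directory = Path(directory)
    tables: dict[str, list] = {k: [] for k in TABLE_KINDS}
    for f in sorted(directory.iterdir()):
        if not f.is_file():
            continue
        stem = f.stem.lower()
        for kind in TABLE_KINDS:
            if stem.startswith(kind):
                tables[kind].extend(read_table(f, kind))
                break
    return tables


@dataclass
class JoinResult:
    reports: list[Report]
    orphans: dict[str, int]  # table kind -> rows with no DEMO parent


def join_cases(tables: dict[str, Iterable]) -> JoinResult:
    """Join the six tables into one :class:`Report` per PRIMARYID.

    Therapy rows attach to drugs through ``dsg_drug_seq == drug_seq``;
    rows in the child tables whose PRIMARYID has no DEMO row are counted
    as orphans and excluded from analysis.
    """
    demo_by_id: dict[str, DemoRecord] = {}
    for d in tables.get("demo", []):
        if d.primaryid in demo_by_id:
            logger.warning("duplicate PRIMARYID %s in DEMO; keeping last", d.primaryid)
        demo_by_id[d.primaryid] = d

    reports = {
        pid: Report(
            primaryid=pid,
            caseid=d.caseid,
            fda_dt=d.fda_dt,
            event_dt=d.event_dt,
            age_years=d.age_years,
            sex=d.sex,
            country=d.reporter_country,
            reporter=d.occp_cod,
        )
        for pid, d in demo_by_id.items()
    }
    orphans = {k: 0 for k in TABLE_KINDS if k != "demo"}

    for r in tables.get("drug", []):
        rep = reports.get(r.primaryid)
        if rep is None:
            orphans["drug"] += 1
        else:
            rep.drugs.append(r)
    for r in tables.get("reac", []):
        rep = reports.get(r.primaryid)
        if rep is None:
            orphans["reac"] += 1
        elif r.pt:
            rep.reactions.add(r.pt)
    for r in tables.get("indi", []):
        rep = reports.get(r.primaryid)
        if rep is None:
            orphans["indi"] += 1
        elif r.indi_pt:
            rep.indications.add(r.indi_pt)
    for r in tables.get("ther", []):
        rep = reports.get(r.primaryid)
        if rep is None:
            orphans["ther"] += 1
        else:
            rep.therapy.setdefault(r.dsg_drug_seq, []).append(r)
    for r in tables.get("outc", []):
        rep = reports.get(r.primaryid)
        if rep is None:
            orphans["outc"] += 1
        elif r.outc_cod:
            rep.outcomes.add(r.outc_cod)

    total_orphans = sum(orphans.values())
    if total_orphans:
        logger.warning("excluded %d orphan child rows with no DEMO parent", total_orphans)
    return JoinResult(reports=list(reports.values()), orphans=orphans)


def join_case(tables: dict[str, Iterable], primaryid: str) -> Report:
    """Join a single PRIMARYID; raises if it has no DEMO row."""
    subset = {
        kind: [r for r in rows if r.primaryid == primaryid]
        for kind, rows in tables.items()
    }
    result = join_cases(subset)
    if not result.reports:
        raise KeyError(f"PRIMARYID {primaryid!r} has no DEMO row")
    return result.reports[0]
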