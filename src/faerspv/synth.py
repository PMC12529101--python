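"""Synthetic spontaneous-reporting corpora with known ground truth.

Emulates the statistical structure of a FAERS extract restricted to a
disease area: each *case* takes one suspect drug (primary or secondary
suspect role), reports each event PT independently with probability
``baseline[pt] * theta[(drug, pt)]`` (theta = 1 is the null), carries
demographics with configurable missingness, indication terms defining
the cohort, therapy/event dates with partial-date degradation, and may
be submitted several times (duplicate versions sharing a CASEID with
later FDA_DT and larger PRIMARYID). The generator writes the exact
"$"-delimited ASCII dialect the reader parses and keeps a ground-truth
ledger of every case, so pipeline output can be checked exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .meddra import TermMaps
from .signals import ContingencyTable

DEMO_COLS = ("primaryid", "caseid", "fda_dt", "event_dt", "age", "age_cod",
             "sex", "reporter_country", "occp_cod")
DRUG_COLS = ("primaryid", "drug_seq", "role_cod", "drugname", "prod_ai")
REAC_COLS = ("primaryid", "pt")
INDI_COLS = ("primaryid", "indi_drug_seq", "indi_pt")
THER_COLS = ("primaryid", "dsg_drug_seq", "start_dt", "end_dt")
OUTC_COLS = ("primaryid", "outc_cod")

#: study drugs with brand aliases, then typical disease-area comparators
DEFAULT_DRUGS: dict[str, tuple[str, ...]] = {
    "deucravacitinib": ("Sotyktu",),
    "upadacitinib": ("Rinvoq",),
    "tofacitinib": ("Xeljanz",),
    "adalimumab": ("Humira",),
    "secukinumab": ("Cosentyx",),
    "ustekinumab": ("Stelara",),
    "apremilast": ("Otezla",),
    "methotrexate": (),
    "etanercept": ("Enbrel",),
    "ixekizumab": ("Taltz",),
}

DEFAULT_WEIGHTS: dict[str, float] = {
    "deucravacitinib": 0.05,
    "upadacitinib": 0.08,
    "tofacitinib": 0.12,
    "adalimumab": 0.20,
    "secukinumab": 0.11,
    "ustekinumab": 0.10,
    "apremilast": 0.10,
    "methotrexate": 0.09,
    "etanercept": 0.08,
    "ixekizumab": 0.07,
}

#: 20-PT toy vocabulary with its ontology (synthetic, not MedDRA content)
DEFAULT_PT_SOC: dict[str, str] = {
    "Acne": "Skin and subcutaneous tissue disorders",
    "Folliculitis": "Skin and subcutaneous tissue disorders",
    "Rash": "Skin and subcutaneous tissue disorders",
    "Pruritus": "Skin and subcutaneous tissue disorders",
    "Mouth ulceration": "Gastrointestinal disorders",
    "Aphthous ulcer": "Gastrointestinal disorders",
    "Nausea": "Gastrointestinal disorders",
    "Diarrhoea": "Gastrointestinal disorders",
    "Nasopharyngitis": "Infections and infestations",
    "Pneumonia": "Infections and infestations",
    "Urinary tract infection": "Infections and infestations",
    "Herpes zoster": "Infections and infestations",
    "Arthralgia": "Musculoskeletal and connective tissue disorders",
    "Myalgia": "Musculoskeletal and connective tissue disorders",
    "Back pain": "Musculoskeletal and connective tissue disorders",
    "Headache": "Nervous system disorders",
    "Dizziness": "Nervous system disorders",
    "Fatigue": "General disorders and administration site conditions",
    "Pyrexia": "General disorders and administration site conditions",
    "Drug ineffective": "General disorders and administration site conditions",
}

DEFAULT_SMQS: dict[str, frozenset[str]] = {
    "Oropharyngeal conditions": frozenset(
        {"Mouth ulceration", "Aphthous ulcer", "Nasopharyngitis"}
    ),
    "Gastrointestinal ulceration": frozenset({"Mouth ulceration", "Aphthous ulcer"}),
    "Herpes viral infections": frozenset({"Herpes zoster"}),
}

DEFAULT_COUNTRIES = {"US": 0.78, "CA": 0.07, "GB": 0.04, "DE": 0.04,
                     "JP": 0.04, "FR": 0.03}
DEFAULT_REPORTERS = {"CN": 0.45, "MD": 0.25, "OT": 0.20, "PH": 0.07, "LW": 0.03}
DEFAULT_OUTCOMES = {"": 0.55, "OT": 0.22, "HO": 0.14, "DE": 0.05, "LT": 0.02,
                    "DS": 0.02}
DEFAULT_INDICATION_MIX = {"psoriasis": 0.43, "psa": 0.52, "both": 0.05}
OFF_INDICATION_PTS = ("Rheumatoid arthritis", "Atopic dermatitis",
                      "Ulcerative colitis")

INDICATION_PT = {"psoriasis": "Psoriasis", "psa": "Psoriatic arthropathy"}


@dataclass
class SynthConfig:
    """Full parameterization of the synthetic reporting system."""

    n_cases: int = 2000
    drugs: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(DEFAULT_DRUGS)
    )
    weights: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_WEIGHTS))
    pt_soc: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_PT_SOC))
    smqs: dict[str, frozenset[str]] = field(default_factory=lambda: dict(DEFAULT_SMQS))
    baseline: Mapping[str, float] | float = 0.02
    filler_pt: str = "Drug ineffective"
    filler_baseline: float = 0.25
    theta: dict[tuple[str, str], float] = field(default_factory=dict)
    # demographics
    sex_female_p: float = 0.65
    sex_missing_p: float = 0.05
    age_mean: float = 56.0
    age_sd: float = 14.0
    age_missing_p: float = 0.20
    age_month_unit_p: float = 0.05
    countries: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_COUNTRIES))
    country_missing_p: float = 0.03
    reporters: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_REPORTERS))
    reporter_missing_p: float = 0.06
    outcomes: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_OUTCOMES))
    # cohort structure
    indication_mix: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_INDICATION_MIX)
    )
    off_indication_rate: float = 0.20
    # dates
    window_start: str = "2014-10-01"
    window_end: str = "2024-09-30"
    onset_median_days: float = 60.0
    onset_sigma: float = 1.0
    report_delay_median_days: float = 30.0
    partial_date_rate: float = 0.10
    event_missing_rate: float = 0.05
    # duplicates and extras
    duplicate_rate: float = 0.10
    max_extra_versions: int = 3
    concomitant_mean: float = 0.7
    suspect_ss_p: float = 0.10
    brand_name_p: float = 0.5
    prod_ai_p: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_cases <= 0:
            raise ValueError("n_cases must be positive")
        if set(self.weights) != set(self.drugs):
            raise ValueError("weights and drugs must list the same names")
        total = sum(self.weights.values())
        if total <= 0:
            raise ValueError("weights must sum to a positive number")
        self.weights = {k: v / total for k, v in self.weights.items()}
        if self.filler_pt not in self.pt_soc:
            raise ValueError("filler_pt must be in the PT vocabulary")
        for (drug, pt), th in self.theta.items():
            if th <= 0:
                raise ValueError(f"theta for {(drug, pt)} must be > 0")
            if drug not in self.drugs or pt not in self.pt_soc:
                raise ValueError(f"theta key {(drug, pt)} outside drug/PT vocabulary")
            if self.event_probability(drug, pt) > 1.0:
                raise ValueError(
                    f"baseline * theta > 1 for {(drug, pt)}: inconsistent config"
                )
        for name, p in [
            ("sex_female_p", self.sex_female_p), ("sex_missing_p", self.sex_missing_p),
            ("age_missing_p", self.age_missing_p),
            ("country_missing_p", self.country_missing_p),
            ("duplicate_rate", self.duplicate_rate),
            ("off_indication_rate", self.off_indication_rate),
            ("partial_date_rate", self.partial_date_rate),
        ]:
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")

    @property
    def pts(self) -> list[str]:
        return list(self.pt_soc)

    @property
    def drug_names(self) -> list[str]:
        return list(self.drugs)

    def baseline_of(self, pt: str) -> float:
        if pt == self.filler_pt:
            return self.filler_baseline
        if isinstance(self.baseline, Mapping):
            return float(self.baseline[pt])
        return float(self.baseline)

    def event_probability(self, drug: str, pt: str) -> float:
        return self.baseline_of(pt) * self.theta.get((drug, pt), 1.0)

    def term_maps(self) -> TermMaps:
        return TermMaps.from_dicts(self.pt_soc, self.smqs,
                                   pt_version="synthetic", smq_version="synthetic")

    def drug_dictionary(self) -> dict[str, frozenset[str]]:
        return {
            name: frozenset({name, *brands})
            for name, brands in self.drugs.items()
        }

    def cohort_config(self):
        """Matching cohort definition (all generated drugs flagged)."""
        from .cases import CohortConfig

        return CohortConfig(drug_dictionary=self.drug_dictionary())


@dataclass
class GroundTruth:
    """Per-case truth recorded at generation time.

    ``cases`` holds one row per CASEID with the attributes of the
    version the FDA deduplication rule retains; ``events`` is the
    realized case x PT boolean matrix.
    """

    cases: pd.DataFrame
    events: pd.DataFrame
    config: SynthConfig

    @property
    def n_raw_reports(self) -> int:
        return int(self.cases["n_versions"].sum())

    @property
    def n_cases(self) -> int:
        return len(self.cases)

    @property
    def n_in_cohort(self) -> int:
        return int(self.cases["in_cohort"].sum())

    def exposed_count(self, drug: str) -> int:
        sel = self.cases["in_cohort"] & (self.cases["drug"] == drug)
        return int(sel.sum())

    def _term_mask(self, term: str, level: str) -> pd.Series:
        maps = self.config.term_maps()
        if level == "PT":
            member_pts = [term]
        elif level == "SOC":
            member_pts = [pt for pt in self.config.pts if maps.soc_of(pt) == term]
        elif level == "SMQ":
            member_pts = sorted(self.config.smqs.get(term, ()))
        else:
            raise ValueError(f"unknown level {level!r}")
        member_pts = [pt for pt in member_pts if pt in self.events.columns]
        if not member_pts:
            return pd.Series(False, index=self.events.index)
        return self.events[member_pts].any(axis=1)

    def cell_counts(
        self, drug: str, term: str, level: str = "PT", subgroup: str = "all"
    ) -> tuple[int, int, int, int]:
        """True 2x2 cells among in-cohort cases (deduplicated units)."""
        mask = self.cases["in_cohort"].copy()
        if subgroup != "all":
            mask &= self.cases["tag"].isin([subgroup, "both"])
        exposed = (self.cases["drug"] == drug) & mask
        has_term = self._term_mask(term, level) & mask
        a = int((exposed & has_term).sum())
        b = int((exposed & ~has_term).sum())
        c = int((~exposed & mask & has_term).sum())
        d = int(mask.sum()) - a - b - c
        return a, b, c, d


@dataclass
class SynthCorpus:
    frames: dict[str, pd.DataFrame]
    ledger: GroundTruth
    config: SynthConfig


def _pick(rng: np.random.Generator, dist: Mapping[str, float], n: int) -> np.ndarray:
    keys = list(dist)
    p = np.array([dist[k] for k in keys], dtype=float)
    return np.array(keys, dtype=object)[rng.choice(len(keys), size=n, p=p / p.sum())]


def _dates_to_str(days: np.ndarray, mask_valid: np.ndarray | None = None) -> np.ndarray:
    """datetime64[D] array -> YYYYMMDD strings ('' where invalid)."""
    s = pd.Series(days).dt.strftime("%Y%m%d").to_numpy(dtype=object)
    if mask_valid is not None:
        s[~mask_valid] = ""
    return s


def generate_corpus(
    config: SynthConfig, out_dir: str | Path | None = None
) -> SynthCorpus:
    """Generate one corpus; optionally write the six ASCII tables.

    Fully deterministic under ``config.seed``: the same config yields
    byte-identical files.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_cases
    idx = np.arange(n)

    caseid = np.array([f"C{i + 1:08d}" for i in idx], dtype=object)
    pid_base = 100000000 + idx * 10

    drug_names = config.drug_names
    w = np.array([config.weights[d] for d in drug_names])
    drug_idx = rng.choice(len(drug_names), size=n, p=w)
    drug = np.array(drug_names, dtype=object)[drug_idx]
    role = np.where(rng.random(n) < config.suspect_ss_p, "SS", "PS").astype(object)

    # events: independent per PT given the suspect drug
    pts = config.pts
    prob_matrix = np.array(
        [[config.event_probability(d, pt) for pt in pts] for d in drug_names]
    )
    events = rng.random((n, len(pts))) < prob_matrix[drug_idx]
    none_mask = ~events.any(axis=1)
    events[none_mask, pts.index(config.filler_pt)] = True  # every report has >=1 PT

    # cohort structure
    off = rng.random(n) < config.off_indication_rate
    tag = _pick(rng, config.indication_mix, n)
    tag[off] = None
    off_pts = rng.choice(len(OFF_INDICATION_PTS), size=n)

    # demographics
    sex = np.where(rng.random(n) < config.sex_female_p, "F", "M").astype(object)
    sex[rng.random(n) < config.sex_missing_p] = ""
    age_years = np.clip(
        np.round(rng.normal(config.age_mean, config.age_sd, n)), 12, 95
    )
    age_missing = rng.random(n) < config.age_missing_p
    month_unit = (rng.random(n) < config.age_month_unit_p) & ~age_missing
    age_val = np.where(month_unit, np.round(age_years * 12), age_years)
    age_str = np.array([f"{v:.0f}" for v in age_val], dtype=object)
    age_str[age_missing] = ""
    age_cod = np.where(month_unit, "MON", "YR").astype(object)
    age_cod[age_missing] = ""
    country = _pick(rng, config.countries, n)
    country[rng.random(n) < config.country_missing_p] = ""
    occp = _pick(rng, config.reporters, n)
    occp[rng.random(n) < config.reporter_missing_p] = ""
    outc = _pick(rng, config.outcomes, n)

    # dates: event uniform in window, therapy start = event - onset,
    # FDA receipt = event + reporting delay (clipped to the window end)
    w_start = np.datetime64(config.window_start)
    w_end = np.datetime64(config.window_end)
    window_days = int((w_end - w_start).astype(int))
    event_day = w_start + rng.integers(0, window_days + 1, n).astype("timedelta64[D]")
    onset = np.round(
        rng.lognormal(math.log(config.onset_median_days), config.onset_sigma, n)
    ).astype(int)
    start_day = event_day - onset.astype("timedelta64[D]")
    delay = np.round(
        rng.lognormal(math.log(config.report_delay_median_days), 0.8, n)
    ).astype(int)
    fda_day = np.minimum(event_day + delay.astype("timedelta64[D]"), w_end)
    duration = np.round(rng.lognormal(math.log(90.0), 0.7, n)).astype(int)
    end_day = start_day + duration.astype("timedelta64[D]")

    event_partial = rng.random(n) < config.partial_date_rate
    start_partial = rng.random(n) < config.partial_date_rate
    event_missing = rng.random(n) < config.event_missing_rate
    end_missing = rng.random(n) < 0.3

    event_str = _dates_to_str(event_day, ~event_missing)
    event_str[event_partial & ~event_missing] = [
        s[:6] for s in event_str[event_partial & ~event_missing]
    ]
    start_str = _dates_to_str(start_day)
    start_str[start_partial] = [s[:6] for s in start_str[start_partial]]
    end_str = _dates_to_str(end_day, ~end_missing)

    # duplicate versions: same CASEID, larger PRIMARYID, later-or-equal FDA_DT
    extra = np.zeros(n, dtype=int)
    dup_mask = rng.random(n) < config.duplicate_rate
    if config.max_extra_versions > 0:
        extra[dup_mask] = rng.integers(1, config.max_extra_versions + 1,
                                       int(dup_mask.sum()))
    n_versions = extra + 1

    case_rep = np.repeat(idx, n_versions)
    version = np.concatenate([np.arange(k) for k in n_versions])
    pid = pid_base[case_rep] + version
    # per-version receipt-date shifts; 0 with prob ~0.3 exercises the
    # PRIMARYID tie-break of the dedup rule
    shift = rng.integers(0, 46, len(case_rep))
    shift[rng.random(len(case_rep)) < 0.3] = 0
    shift[version == 0] = 0
    fda_v = fda_day[case_rep] + pd.Series(shift).groupby(
        pd.Series(case_rep)
    ).cumsum().to_numpy().astype("timedelta64[D]")
    occp_v = occp[case_rep].copy()
    resample = version > 0
    occp_v[resample] = _pick(rng, config.reporters, int(resample.sum()))

    pid_str = pid.astype(str).astype(object)
    demo = pd.DataFrame(
        {
            "primaryid": pid_str,
            "caseid": caseid[case_rep],
            "fda_dt": _dates_to_str(fda_v),
            "event_dt": event_str[case_rep],
            "age": age_str[case_rep],
            "age_cod": age_cod[case_rep],
            "sex": sex[case_rep],
            "reporter_country": country[case_rep],
            "occp_cod": occp_v,
        },
        columns=list(DEMO_COLS),
    )

    # per-case child content, replicated across versions via merge
    versions = pd.DataFrame({"case": case_rep, "primaryid": pid_str})

    brand = rng.random(n) < config.brand_name_p
    drugname = np.empty(n, dtype=object)
    prod_ai = np.empty(n, dtype=object)
    for i in idx:
        name = drug[i]
        brands = config.drugs[name]
        drugname[i] = (brands[0] if brand[i] and brands else name).upper()
        prod_ai[i] = name.upper() if rng.random() < config.prod_ai_p else ""
    drug_rows = [
        pd.DataFrame({"case": idx, "drug_seq": 1, "role_cod": role,
                      "drugname": drugname, "prod_ai": prod_ai})
    ]
    n_conc = np.minimum(rng.poisson(config.concomitant_mean, n), 3)
    for j in range(1, int(n_conc.max()) + 1 if n_conc.size else 1):
        sel = idx[n_conc >= j]
        if not sel.size:
            continue
        conc = rng.choice(len(drug_names), size=sel.size)
        drug_rows.append(
            pd.DataFrame({
                "case": sel, "drug_seq": j + 1, "role_cod": "C",
                "drugname": np.array(drug_names, dtype=object)[conc],
                "prod_ai": "",
            })
        )
    drug_long = pd.concat(drug_rows, ignore_index=True)
    drug_long["drugname"] = drug_long["drugname"].str.upper()

    ev_case, ev_pt = np.nonzero(events)
    reac_long = pd.DataFrame(
        {"case": ev_case, "pt": np.array(pts, dtype=object)[ev_pt]}
    )

    indi_parts = []
    for t, pt_name in INDICATION_PT.items():
        sel = idx[(tag == t) | (tag == "both")]
        indi_parts.append(pd.DataFrame({"case": sel, "indi_pt": pt_name}))
    sel_off = idx[off]
    indi_parts.append(
        pd.DataFrame({
            "case": sel_off,
            "indi_pt": np.array(OFF_INDICATION_PTS, dtype=object)[off_pts[off]],
        })
    )
    indi_long = pd.concat(indi_parts, ignore_index=True)
    upcase = rng.random(len(indi_long)) < 0.3  # exercise case-insensitive match
    indi_long.loc[upcase, "indi_pt"] = indi_long.loc[upcase, "indi_pt"].str.upper()
    indi_long["indi_drug_seq"] = 1

    ther_long = pd.DataFrame(
        {"case": idx, "dsg_drug_seq": 1, "start_dt": start_str, "end_dt": end_str}
    )
    outc_long = pd.DataFrame({"case": idx, "outc_cod": outc})
    outc_long = outc_long[outc_long["outc_cod"] != ""]

    def expand(long: pd.DataFrame, cols: tuple[str, ...]) -> pd.DataFrame:
        out = versions.merge(long, on="case", how="inner")
        for col in cols:
            if col not in out.columns:
                raise KeyError(col)
        out = out[list(cols)].copy()
        for col in cols:
            out[col] = out[col].astype(str)
        return out.sort_values(list(cols), kind="stable").reset_index(drop=True)

    frames = {
        "demo": demo.sort_values("primaryid", kind="stable").reset_index(drop=True),
        "drug": expand(drug_long, DRUG_COLS),
        "reac": expand(reac_long, REAC_COLS),
        "indi": expand(indi_long, INDI_COLS),
        "ther": expand(ther_long, THER_COLS),
        "outc": expand(outc_long, OUTC_COLS),
    }

    # ledger: attributes of the version the FDA rule retains, derived by
    # applying the rule's definition to the generated version arrays
    vkey = pd.DataFrame({
        "case": case_rep,
        "fda": fda_v.astype("datetime64[D]").astype(int),
        "pid": pid,
        "occp": occp_v,
    })
    kept = vkey.sort_values(["case", "fda", "pid"]).groupby("case").tail(1)
    kept = kept.sort_values("case")
    age_years_true = np.where(
        month_unit, np.round(age_years * 12) / 12.0, age_years
    ).astype(float)
    cases_df = pd.DataFrame({
        "caseid": caseid,
        "pid_kept": kept["pid"].to_numpy().astype(str),
        "fda_kept": pd.to_datetime(
            kept["fda"].to_numpy(), unit="D"
        ).strftime("%Y%m%d"),
        "drug": drug,
        "role": role,
        "tag": tag,
        "in_cohort": ~off,
        "sex": np.where(sex == "", None, sex),
        "age_years": np.where(age_missing, np.nan, age_years_true),
        "country": np.where(country == "", None, country),
        "reporter": kept["occp"].to_numpy(),
        "year": pd.to_datetime(kept["fda"].to_numpy(), unit="D").year,
        "onset_days": onset,
        "tto_observable": (~event_missing & ~event_partial & ~start_partial),
        "n_versions": n_versions,
    }).set_index("caseid", drop=False)
    events_df = pd.DataFrame(events, index=cases_df.index, columns=pts)

    corpus = SynthCorpus(
        frames=frames,
        ledger=GroundTruth(cases=cases_df, events=events_df, config=config),
        config=config,
    )
    if out_dir is not None:
        write_corpus(corpus.frames, out_dir)
    return corpus


def frames_to_tables(frames: dict[str, pd.DataFrame]) -> dict[str, list]:
    """Convert generated frames to typed records without file I/O,
    through the same field parser the ASCII reader uses."""
    from .faers_io import _make_record

    out: dict[str, list] = {}
    for kind, df in frames.items():
        cols = list(df.columns)
        out[kind] = [
            _make_record(kind, dict(zip(cols, row)))
            for row in df.itertuples(index=False)
        ]
    return out


def write_corpus(frames: dict[str, pd.DataFrame], out_dir: str | Path) -> None:
    """Write the six tables in the FAERS ASCII dialect."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for kind, df in frames.items():
        path = out_dir / f"{kind}.txt"
        with path.open("w", encoding="utf-8", newline="\n") as fh:
            fh.write("$".join(c.upper() for c in df.columns) + "\n")
            for row in df.itertuples(index=False):
                fh.write("$".join(str(v) for v in row) + "\n")


def inject_duplicates(
    frames: dict[str, pd.DataFrame], rate: float, seed: int,
    max_extra_versions: int = 3,
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """Add duplicate versions to an existing single-version corpus.

    Selected cases gain 1..max extra versions sharing the CASEID with a
    strictly larger PRIMARYID and later-or-equal FDA_DT. Returns the
    augmented frames and a map (caseid, original pid, duplicate pid).
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError("rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    demo = frames["demo"]
    sel = demo[rng.random(len(demo)) < rate]
    dup_rows = []
    dup_map = []
    for row in sel.itertuples(index=False):
        k = int(rng.integers(1, max_extra_versions + 1))
        fda = pd.to_datetime(row.fda_dt, format="%Y%m%d")
        for v in range(1, k + 1):
            new = row._asdict()
            new["primaryid"] = str(int(row.primaryid) + v)
            fda = fda + pd.Timedelta(days=int(rng.integers(0, 30)))
            new["fda_dt"] = fda.strftime("%Y%m%d")
            dup_rows.append(new)
            dup_map.append((row.caseid, row.primaryid, new["primaryid"]))
    if not dup_rows:
        return {k: v.copy() for k, v in frames.items()}, pd.DataFrame(
            columns=["caseid", "original", "duplicate"]
        )
    out = dict(frames)
    out["demo"] = (
        pd.concat([demo, pd.DataFrame(dup_rows)], ignore_index=True)
        .sort_values("primaryid", kind="stable")
        .reset_index(drop=True)
    )
    pid_map = pd.DataFrame(dup_map, columns=["caseid", "original", "duplicate"])
    for kind in ("drug", "reac", "indi", "ther", "outc"):
        df = frames[kind]
        extra = df.merge(
            pid_map.rename(columns={"original": "primaryid"}), on="primaryid"
        )
        extra = extra.drop(columns=["primaryid", "caseid"]).rename(
            columns={"duplicate": "primaryid"}
        )[df.columns.tolist()]
        out[kind] = (
            pd.concat([df, extra], ignore_index=True)
            .sort_values(df.columns.tolist(), kind="stable")
            .reset_index(drop=True)
        )
    return out, pid_map


def expected_ror(config: SynthConfig, drug: str, pt: str) -> float:
    """Analytic odds ratio implied by theta and the exposure mix.

    NaN marks the undefined comparator of a single-drug universe.
    """
    if drug not in config.drugs or pt not in config.pt_soc:
        raise KeyError(f"unknown drug/PT {(drug, pt)}")
    others = [d for d in config.drug_names if d != drug]
    if not others:
        return float("nan")
    w_drug = config.weights[drug]
    pe = config.event_probability(drug, pt)
    pu = sum(
        config.weights[d] * config.event_probability(d, pt) for d in others
    ) / (1.0 - w_drug)
    if pe in (0.0, 1.0) or pu in (0.0, 1.0):
        return float("nan")
    return (pe / (1 - pe)) / (pu / (1 - pu))


def sample_pair_table(
    config: SynthConfig, drug: str, pt: str, rng: np.random.Generator
) -> ContingencyTable:
    """Draw one drug x PT contingency table from the reporting model.

    Samples each case's suspect drug and the target PT's indicator
    exactly as :func:`generate_corpus` does, skipping the unrelated
    corpus plumbing; used for replicated coverage studies.
    """
    names = config.drug_names
    w = np.array([config.weights[d] for d in names])
    assign = rng.choice(len(names), size=config.n_cases, p=w)
    p = np.array([config.event_probability(d, pt) for d in names])
    event = rng.random(config.n_cases) < p[assign]
    exposed = assign == names.index(drug)
    a = int((exposed & event).sum())
    b = int(exposed.sum()) - a
    c = int(event.sum()) - a
    d = config.n_cases - a - b - c
    return ContingencyTable(a, b, c, d, drug=drug, term=pt, level="PT")
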