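"""One-config study runner: corpus -> cohort -> scans -> TTO -> models.

A single YAML config drives a reproducible run; every output table is
written with a manifest carrying the config hash, so identical config
plus identical inputs yields an identical output bundle.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import synth as synth_mod
from .cases import AnalysisSet, CohortConfig, build_analysis_set
from .meddra import LEVELS, TermMaps, load_term_maps, toy_ontology
from .onset import summarize_characteristics, summarize_onsets, onset_records
from .regression import prepare_rows, sensitivity_table
from .signals import run_signal_scan
from .synth import SynthConfig

logger = logging.getLogger(__name__)

DEFAULT_SENSITIVITY_SOCS = [
    "Skin and subcutaneous tissue disorders",
    "Infections and infestations",
    "Gastrointestinal disorders",
]

STUDY_DRUGS = ["deucravacitinib", "upadacitinib", "tofacitinib"]

VALID_SUBGROUPS = ("all", "psoriasis", "psa")


class ConfigError(ValueError):
    """Carries the complete list of config violations, not just the first."""

    def __init__(self, violations: list[str]):
        self.violations = violations
        super().__init__("; ".join(violations))


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {cause}")


@dataclass
class RunConfig:
    out_dir: Path
    synth: SynthConfig | None = None
    quarters: list[Path] = field(default_factory=list)
    term_maps: TermMaps | None = None
    cohort: CohortConfig | None = None
    study_drugs: list[str] = field(default_factory=lambda: list(STUDY_DRUGS))
    levels: list[str] = field(default_factory=lambda: ["PT", "SOC", "SMQ"])
    subgroups: list[str] = field(default_factory=lambda: ["all", "psoriasis", "psa"])
    ic_method: str = "approx"
    sensitivity_socs: list[str] = field(
        default_factory=lambda: list(DEFAULT_SENSITIVITY_SOCS)
    )
    seed: int = 0
    config_hash: str = ""

    def resolved_maps(self) -> TermMaps:
        if self.term_maps is not None:
            return self.term_maps
        if self.synth is not None:
            return self.synth.term_maps()
        return toy_ontology()

    def resolved_cohort(self) -> CohortConfig:
        if self.cohort is not None:
            return self.cohort
        if self.synth is not None:
            return self.synth.cohort_config()
        return CohortConfig()


def validate_config(path: str | Path) -> RunConfig:
    """Parse and validate a YAML run config.

    All violations are collected and reported together in the raised
    :class:`ConfigError`, not first-failure.
    """
    path = Path(path)
    raw_bytes = path.read_bytes()
    try:
        raw = yaml.safe_load(raw_bytes) or {}
    except yaml.YAMLError as exc:
        raise ConfigError([f"not valid YAML: {exc}"]) from exc
    violations: list[str] = []
    if not isinstance(raw, dict):
        raise ConfigError(["top level must be a mapping"])

    has_synth = "synth" in raw
    quarters = [Path(q) for q in raw.get("quarters", [])]
    if not has_synth and not quarters:
        violations.append("one of 'synth' or 'quarters' is required")
    if has_synth and quarters:
        violations.append("'synth' and 'quarters' are mutually exclusive")
    for q in quarters:
        if not q.is_dir():
            violations.append(f"quarters directory does not exist: {q}")

    synth_cfg = None
    if has_synth:
        block = raw.get("synth") or {}
        if not isinstance(block, dict):
            violations.append("'synth' must be a mapping")
        else:
            if "theta" in block:
                block["theta"] = {
                    (k.split("|")[0], k.split("|")[1]): v
                    for k, v in block["theta"].items()
                }
            try:
                synth_cfg = SynthConfig(**block)
            except (TypeError, ValueError) as exc:
                violations.append(f"invalid synth block: {exc}")

    maps = None
    tm = raw.get("term_maps")
    if tm is not None:
        pt_soc = tm.get("pt_soc")
        if pt_soc is None or not Path(pt_soc).is_file():
            violations.append(f"term_maps.pt_soc missing or not a file: {pt_soc}")
        smq = tm.get("smq")
        if smq is not None and not Path(smq).is_file():
            violations.append(f"term_maps.smq is not a file: {smq}")
        if not violations:
            maps = load_term_maps(pt_soc, smq)

    cohort = None
    if "cohort" in raw:
        block = raw["cohort"] or {}
        try:
            cohort = CohortConfig(
                indication_groups={
                    k: frozenset(v)
                    for k, v in block.get(
                        "indication_groups",
                        {"psoriasis": ["Psoriasis"], "psa": ["Psoriatic arthropathy"]},
                    ).items()
                },
                drug_dictionary={
                    k: frozenset(v)
                    for k, v in block["drug_dictionary"].items()
                }
                if "drug_dictionary" in block
                else dict(),
                year_window=tuple(block["year_window"])
                if "year_window" in block
                else None,
            )
        except (KeyError, ValueError) as exc:
            violations.append(f"invalid cohort block: {exc}")

    levels = list(raw.get("levels", ["PT", "SOC", "SMQ"]))
    for lv in levels:
        if lv not in LEVELS:
            violations.append(f"unknown scan level {lv!r}")
    subgroups = list(raw.get("subgroups", ["all", "psoriasis", "psa"]))
    for sg in subgroups:
        if sg not in VALID_SUBGROUPS:
            violations.append(f"unknown subgroup {sg!r}")
    ic_method = raw.get("ic_method", "approx")
    if ic_method not in ("approx", "gamma"):
        violations.append(f"unknown ic_method {ic_method!r}")
    if "out_dir" not in raw:
        violations.append("'out_dir' is required")

    if violations:
        raise ConfigError(violations)
    return RunConfig(
        out_dir=Path(raw["out_dir"]),
        synth=synth_cfg,
        quarters=quarters,
        term_maps=maps,
        cohort=cohort,
        study_drugs=list(raw.get("study_drugs", STUDY_DRUGS)),
        levels=levels,
        subgroups=subgroups,
        ic_method=ic_method,
        sensitivity_socs=list(raw.get("sensitivity_socs", DEFAULT_SENSITIVITY_SOCS)),
        seed=int(raw.get("seed", 0)),
        config_hash=hashlib.sha256(raw_bytes).hexdigest()[:16],
    )


def load_analysis_set(config: RunConfig) -> AnalysisSet:
    """Materialize the cohort from the synthetic generator or extracts."""
    if config.synth is not None:
        corpus = synth_mod.generate_corpus(config.synth)
        tables = synth_mod.frames_to_tables(corpus.frames)
        return build_analysis_set(tables, config.resolved_cohort())
    return build_analysis_set(config.quarters, config.resolved_cohort())


def _write(df: pd.DataFrame, path: Path) -> int:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
    return len(df)


def run_study(config: RunConfig) -> dict:
    """Execute the full study and emit the output bundle.

    Outputs: flow counts, characteristics (+ binomial tests), the
    PT/SOC/SMQ signal scans with indication subgroups, time-to-onset
    values and summaries, the sensitivity model table, and a manifest.
    A failing stage aborts with the stage name; tables already written
    stay on disk.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": config.config_hash,
        "seed": config.seed,
        "tables": {},
    }
    maps = config.resolved_maps()

    stage = "cohort"
    try:
        aset = load_analysis_set(config)
        flow = pd.DataFrame(
            sorted(aset.flow.items()), columns=["stage", "count"]
        )
        manifest["tables"]["flow.tsv"] = _write(flow, out / "flow.tsv")

        stage = "characteristics"
        chars, tests = summarize_characteristics(aset, config.study_drugs)
        manifest["tables"]["characteristics.tsv"] = _write(
            chars, out / "characteristics.tsv"
        )
        manifest["tables"]["binomial_tests.tsv"] = _write(
            tests, out / "binomial_tests.tsv"
        )

        stage = "scan"
        scan = run_signal_scan(
            aset, maps, levels=config.levels, subgroups=config.subgroups,
            ic_method=config.ic_method, drugs=config.study_drugs,
        )
        manifest["tables"]["signal_scan.tsv"] = _write(scan, out / "signal_scan.tsv")

        stage = "tto"
        recs = onset_records(aset, config.study_drugs)
        values = pd.DataFrame(
            [(r.caseid, r.drug, r.tto_days) for r in recs],
            columns=["caseid", "drug", "tto_days"],
        )
        manifest["tables"]["tto_values.tsv"] = _write(values, out / "tto_values.tsv")
        manifest["tables"]["tto_summary.tsv"] = _write(
            summarize_onsets(aset, config.study_drugs), out / "tto_summary.tsv"
        )

        stage = "sensitivity"
        rows, median_age, excl = prepare_rows(
            aset, config.sensitivity_socs, maps, config.study_drugs
        )
        sens = sensitivity_table(rows, config.study_drugs, config.sensitivity_socs)
        manifest["tables"]["sensitivity.tsv"] = _write(sens, out / "sensitivity.tsv")
        manifest["sensitivity"] = {
            "n_cases": len(rows),
            "pooled_median_age": median_age,
            "exclusions": excl,
        }
    except Exception as exc:
        raise StageError(stage, exc) from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    logger.info("run complete: %d tables in %s", len(manifest["tables"]), out)
    return manifest
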