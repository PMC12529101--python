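import random

import pytest

from faerspv.cases import (
    CohortConfig,
    build_analysis_set,
    deduplicate,
    flag_exposure,
    indication_tag,
    normalize_drug_name,
    restrict_to_indications,
)
from faerspv.dates import PartialDate
from faerspv.records import DrugRecord, Report
from faerspv.synth import SynthConfig, frames_to_tables, generate_corpus


def _report(pid, caseid, fda=None, indications=(), drugs=(), sex=None):
    return Report(
        primaryid=pid, caseid=caseid, fda_dt=fda, event_dt=None,
        age_years=None, sex=sex, country=None, reporter=None,
        drugs=list(drugs), indications=set(indications),
    )


class TestDeduplicate:
    def test_latest_fda_dt_wins(self):
        a = _report("1", "C1", PartialDate(2023, 1, 5))
        b = _report("2", "C1", PartialDate(2023, 2, 1))
        assert deduplicate([a, b]) == [b]

    def test_largest_primaryid_breaks_date_ties(self):
        a = _report("1002345", "C1", PartialDate(2023, 1, 5))
        b = _report("1002346", "C1", PartialDate(2023, 1, 5))
        assert deduplicate([b, a]) == [b]

    def test_distinct_caseids_pass_through(self):
        reports = [_report(str(i), f"C{i}") for i in range(5)]
        assert sorted(r.caseid for r in deduplicate(reports)) == sorted(
            r.caseid for r in reports
        )

    def test_missing_date_components_sort_earliest(self):
        partial = _report("9", "C1", PartialDate(2023, 1))
        full = _report("1", "C1", PartialDate(2023, 1, 1))
        assert deduplicate([partial, full]) == [full]

    def test_idempotent_and_order_invariant(self):
        rng = random.Random(0)
        reports = [
            _report(str(1000 + i), f"C{i % 20}",
                    PartialDate(2023, rng.randint(1, 12), rng.randint(1, 28)))
            for i in range(100)
        ]
        once = deduplicate(reports)
        assert {r.caseid for r in once} == {r.caseid for r in reports}
        assert len({r.caseid for r in once}) == len(once)
        assert sorted(r.primaryid for r in deduplicate(once)) == sorted(
            r.primaryid for r in once
        )
        shuffled = reports[:]
        rng.shuffle(shuffled)
        assert sorted(r.primaryid for r in deduplicate(shuffled)) == sorted(
            r.primaryid for r in once
        )


class TestIndicationRestriction:
    def test_match_is_case_insensitive(self):
        rep = _report("1", "C1", indications={"PSORIASIS"})
        assert indication_tag(rep, CohortConfig()) == "psoriasis"

    def test_unrelated_indication_dropped(self):
        rep = _report("1", "C1", indications={"Rheumatoid arthritis"})
        kept, _ = restrict_to_indications([rep], CohortConfig())
        assert kept == []

    def test_both_indications_tagged_both(self):
        rep = _report("1", "C1",
                      indications={"Psoriasis", "Psoriatic arthropathy"})
        assert indication_tag(rep, CohortConfig()) == "both"

    def test_restriction_is_subset_with_tags(self):
        reps = [
            _report("1", "C1", indications={"Psoriasis"}),
            _report("2", "C2", indications={"Asthma"}),
            _report("3", "C3", indications={"psoriatic arthropathy"}),
        ]
        kept, tags = restrict_to_indications(reps, CohortConfig())
        assert [r.primaryid for r in kept] == ["1", "3"]
        assert tags == {"1": "psoriasis", "3": "psa"}


class TestExposure:
    def _drug(self, name, role="PS", prod_ai=None, seq=1):
        return DrugRecord(primaryid="1", drug_seq=seq, role_cod=role,
                          drugname=name, prod_ai=prod_ai)

    def test_brand_name_primary_suspect_matches(self):
        rep = _report("1", "C1", drugs=[self._drug("XELJANZ")])
        assert flag_exposure(rep, CohortConfig())["tofacitinib"]

    def test_concomitant_role_excluded(self):
        rep = _report("1", "C1", drugs=[self._drug("tofacitinib citrate", role="C")])
        assert not flag_exposure(rep, CohortConfig())["tofacitinib"]

    def test_prod_ai_secondary_suspect_matches(self):
        rep = _report("1", "C1",
                      drugs=[self._drug("UNKNOWN BLEND", role="SS",
                                        prod_ai="UPADACITINIB")])
        assert flag_exposure(rep, CohortConfig())["upadacitinib"]

    def test_whole_word_match_inside_salt_name(self):
        rep = _report("1", "C1", drugs=[self._drug("Tofacitinib Citrate")])
        assert flag_exposure(rep, CohortConfig())["tofacitinib"]

    def test_substring_of_longer_token_does_not_match(self):
        rep = _report("1", "C1", drugs=[self._drug("NOTTOFACITINIBX")])
        assert not flag_exposure(rep, CohortConfig())["tofacitinib"]

    def test_normalization_strips_punctuation(self):
        assert normalize_drug_name(" Xeljanz(tofacitinib)! ") == "XELJANZ TOFACITINIB"


class TestBuildAnalysisSet:
    def test_stage_counts_match_generator_ledger(self, analysis_set, small_corpus):
        led = small_corpus.ledger
        flow = analysis_set.flow
        assert flow["raw_reports"] == led.n_raw_reports
        assert flow["after_dedup"] == led.n_cases
        assert flow["in_cohort"] == led.n_in_cohort
        for drug in small_corpus.config.drug_names:
            assert flow[f"exposed_{drug}"] == led.exposed_count(drug)

    def test_duplicate_versions_do_not_change_final_count(self):
        base = SynthConfig(n_cases=300, duplicate_rate=0.0, seed=3)
        noisy = SynthConfig(n_cases=300, duplicate_rate=0.4, seed=3)
        sets = []
        for cfg in (base, noisy):
            corpus = generate_corpus(cfg)
            aset = build_analysis_set(
                frames_to_tables(corpus.frames), cfg.cohort_config()
            )
            sets.append(aset)
        assert sets[0].flow["in_cohort"] == sets[1].flow["in_cohort"]
        assert sets[1].flow["duplicates_removed"] > 0

    def test_empty_input_gives_empty_set(self):
        aset = build_analysis_set(
            {k: [] for k in ("demo", "drug", "reac", "indi", "ther", "outc")},
            CohortConfig(),
        )
        assert len(aset) == 0
        assert aset.flow["raw_reports"] == 0

    def test_subgroup_subsets_include_both_tag(self, analysis_set):
        pso = analysis_set.subset("psoriasis")
        psa = analysis_set.subset("psa")
        n_both = sum(1 for t in analysis_set.tags.values() if t == "both")
        assert len(pso) + len(psa) == len(analysis_set) + n_both
        assert all(analysis_set.tags[r.primaryid] in ("psoriasis", "both")
                   for r in pso.reports)
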