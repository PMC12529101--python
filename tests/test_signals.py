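import math

import numpy as np
import pytest

from faerspv.cases import AnalysisSet, CohortConfig
from faerspv.meddra import reactions_at_level
from faerspv.records import DrugRecord, Report
from faerspv.signals import (
    ContingencyTable,
    build_contingency,
    classify_signal,
    ic_with_ci,
    ror_with_ci,
    run_signal_scan,
)


class TestRor:
    def test_balanced_table_has_unit_ror(self):
        ror, lo, hi = ror_with_ci(ContingencyTable(5, 95, 50, 950))
        assert ror == pytest.approx(1.0)
        assert lo == pytest.approx(
            math.exp(-1.96 * math.sqrt(1 / 5 + 1 / 95 + 1 / 50 + 1 / 950))
        )
        assert lo == pytest.approx(0.389, abs=5e-4)

    def test_zero_cell_continuity_correction(self):
        ror, _, _ = ror_with_ci(ContingencyTable(0, 100, 50, 950))
        assert ror == pytest.approx((0.5 * 950.5) / (100.5 * 50.5))
        assert ror == pytest.approx(0.0936, abs=5e-5)

    @pytest.mark.parametrize("table", [
        ContingencyTable(0, 0, 50, 950),   # no exposed reports
        ContingencyTable(0, 100, 0, 950),  # term absent from background
        ContingencyTable(5, 0, 50, 0),     # everyone has the event
    ])
    def test_degenerate_margin_is_undefined_not_an_exception(self, table):
        assert all(math.isnan(v) for v in ror_with_ci(table))

    def test_inversion_symmetry(self):
        rng = np.random.default_rng(5)
        for a, b, c, d in rng.integers(1, 300, (50, 4)):
            r1, _, _ = ror_with_ci(ContingencyTable(int(a), int(b), int(c), int(d)))
            r2, _, _ = ror_with_ci(ContingencyTable(int(b), int(a), int(d), int(c)))
            assert r1 * r2 == pytest.approx(1.0, rel=1e-12)

    def test_monotone_in_a_with_fixed_margins(self):
        prev_ror, prev_ic = -np.inf, -np.inf
        for a in range(1, 50):
            t = ContingencyTable(a, 50 - a, 100 - a, 850 + a)
            ror, _, _ = ror_with_ci(t)
            ic, _, _ = ic_with_ci(t)
            assert ror > prev_ror and ic > prev_ic
            prev_ror, prev_ic = ror, ic


class TestIc:
    def test_observed_equals_expected_gives_zero(self):
        ic, _, _ = ic_with_ci(ContingencyTable(10, 90, 90, 810))
        assert ic == 0.0

    def test_shrunk_point_and_lower_bound(self):
        ic, lo, _ = ic_with_ci(ContingencyTable(5, 95, 50, 850))
        assert ic == pytest.approx(math.log2(5.5 / 6.0))
        assert lo == pytest.approx(
            ic - 3.3 * 5.5 ** -0.5 - 2 * 5.5 ** -1.5
        )
        assert lo == pytest.approx(-1.688, abs=5e-4)

    def test_zero_count_still_finite(self):
        ic, lo, hi = ic_with_ci(ContingencyTable(0, 100, 50, 850))
        assert np.isfinite([ic, lo, hi]).all()

    def test_shrinkage_pulls_toward_zero(self):
        rng = np.random.default_rng(6)
        for a, b, c, d in rng.integers(1, 400, (100, 4)):
            t = ContingencyTable(int(a), int(b), int(c), int(d))
            e = t.expected
            if a == e:
                continue
            ic, _, _ = ic_with_ci(t)
            assert abs(ic) <= abs(math.log2(a / e)) + 1e-12

    def test_approx_bounds_match_gamma_quantiles_for_a_ge_3(self):
        rng = np.random.default_rng(7)
        for a, b, c, d in rng.integers(0, 500, (200, 4)):
            if a < 3:
                continue
            t = ContingencyTable(int(a), int(b), int(c), int(d))
            _, lo_a, hi_a = ic_with_ci(t, "approx")
            _, lo_g, hi_g = ic_with_ci(t, "gamma")
            assert abs(lo_a - lo_g) < 0.05 and abs(hi_a - hi_g) < 0.05

    def test_empty_background_raises(self):
        with pytest.raises(ValueError):
            ic_with_ci(ContingencyTable(0, 0, 0, 0))


class TestClassification:
    def _estimate(self, a, b, c, d):
        return classify_signal(ContingencyTable(a, b, c, d))

    def test_fewer_than_three_reports_not_evaluated(self):
        est = self._estimate(2, 50, 20, 900)
        assert not est.evaluated and not est.positive

    def test_positive_requires_both_lower_bounds(self):
        strong = self._estimate(40, 60, 50, 850)
        assert strong.ror025 > 1 and strong.ic025 > 0 and strong.positive
        null = self._estimate(5, 95, 50, 950)
        assert not null.positive

    def test_ror_bound_alone_is_not_enough(self):
        # moderate a against a large expected count: the ROR CI excludes
        # 1 while the shrunk IC lower bound stays below 0
        est = self._estimate(9, 91, 390, 9510)
        assert est.ror025 > 1 and est.ic025 <= 0
        assert not est.positive

    def test_interval_ordering_invariants(self):
        rng = np.random.default_rng(8)
        for a, b, c, d in rng.integers(1, 300, (50, 4)):
            est = self._estimate(int(a), int(b), int(c), int(d))
            assert est.ror025 <= est.ror <= est.ror975
            assert est.ic025 <= est.ic <= est.ic975


def _mini_report(pid, tag_pt, drugs, pts):
    return Report(
        primaryid=pid, caseid=f"c{pid}", fda_dt=None, event_dt=None,
        age_years=None, sex=None, country=None, reporter=None,
        drugs=drugs, reactions=set(pts), indications={tag_pt},
    )


def _mini_aset(reports, config):
    from faerspv.cases import flag_exposure, restrict_to_indications

    kept, tags = restrict_to_indications(reports, config)
    exposure = {r.primaryid: flag_exposure(r, config) for r in kept}
    return AnalysisSet(reports=kept, tags=tags, exposure=exposure, config=config)


class TestContingencyCounting:
    def test_duplicate_pt_mention_counts_once(self):
        config = CohortConfig()
        drug = [DrugRecord("1", 1, "PS", "XELJANZ")]
        rep = _mini_report("1", "Psoriasis", drug, ["Acne"])
        rep.reactions = {"Acne"}  # sets collapse duplicate mentions
        other = _mini_report("2", "Psoriasis", [], ["Rash"])
        aset = _mini_aset([rep, other], config)
        t = build_contingency(aset, "tofacitinib", "Acne", "PT")
        assert (t.a, t.b, t.c, t.d) == (1, 0, 0, 1)

    def test_all_reports_exposed_zero_unexposed_cells(self):
        config = CohortConfig()
        reports = [
            _mini_report(str(i), "Psoriasis",
                         [DrugRecord(str(i), 1, "PS", "XELJANZ")], ["Acne"])
            for i in range(4)
        ]
        aset = _mini_aset(reports, config)
        t = build_contingency(aset, "tofacitinib", "Acne", "PT")
        assert (t.c, t.d) == (0, 0)

    def test_scan_cells_match_per_report_recount(self, analysis_set, small_corpus):
        maps = small_corpus.config.term_maps()
        scan = run_signal_scan(analysis_set, maps, levels=("PT", "SOC", "SMQ"))
        n = len(analysis_set.reports)
        for row in scan.sample(n=60, random_state=0).itertuples(index=False):
            a = b = c = d = 0
            for rep in analysis_set.reports:
                exposed = analysis_set.exposure[rep.primaryid][row.drug]
                has = row.term in reactions_at_level(rep, row.level, maps)
                a += exposed and has
                b += exposed and not has
                c += (not exposed) and has
                d += (not exposed) and not has
            assert (row.a, row.b, row.c, row.d) == (a, b, c, d)
            assert row.a + row.b + row.c + row.d == n

    def test_implanted_association_ranks_top_for_its_drug(self, analysis_set):
        scan = run_signal_scan(analysis_set, None, levels=("PT",))
        tofa = scan[scan["drug"] == "tofacitinib"]
        assert tofa.iloc[0]["term"] == "Acne"  # theta = 8 implant

    def test_subgroup_scan_restricts_background(self):
        # implanted signal present only in psoriasis-tagged reports
        config = CohortConfig()
        reports = []
        for i in range(200):
            tag_pt = "Psoriasis" if i < 100 else "Psoriatic arthropathy"
            exposed = i % 10 == 0
            drugs = [DrugRecord(str(i), 1, "PS", "XELJANZ")] if exposed else []
            pts = ["Acne"] if (exposed and i < 100) else ["Rash"]
            reports.append(_mini_report(str(i), tag_pt, drugs, pts))
        aset = _mini_aset(reports, config)
        scan = run_signal_scan(aset, None, levels=("PT",),
                               subgroups=("psoriasis", "psa"))
        pso = scan[(scan["subgroup"] == "psoriasis") & (scan["term"] == "Acne")
                   & (scan["drug"] == "tofacitinib")]
        psa = scan[(scan["subgroup"] == "psa") & (scan["term"] == "Acne")
                   & (scan["drug"] == "tofacitinib")]
        assert bool(pso["positive"].iloc[0])
        assert psa.empty or not bool(psa["positive"].iloc[0])
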