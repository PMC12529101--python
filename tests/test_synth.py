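import numpy as np
import pandas as pd
import pytest

from faerspv.synth import (
    SynthConfig,
    expected_ror,
    frames_to_tables,
    generate_corpus,
    inject_duplicates,
    sample_pair_table,
    write_corpus,
)


class TestDeterminism:
    def test_same_seed_byte_identical_files(self, tmp_path):
        cfg = SynthConfig(n_cases=200, seed=42)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        generate_corpus(SynthConfig(n_cases=200, seed=42), out_dir=d1)
        generate_corpus(cfg, out_dir=d2)
        for f in sorted(d1.iterdir()):
            assert f.read_bytes() == (d2 / f.name).read_bytes()

    def test_different_seed_differs(self):
        a = generate_corpus(SynthConfig(n_cases=200, seed=1)).frames["demo"]
        b = generate_corpus(SynthConfig(n_cases=200, seed=2)).frames["demo"]
        assert not a.equals(b)


class TestLedgerConsistency:
    def test_raw_report_count_matches_demo_rows(self, small_corpus):
        assert small_corpus.ledger.n_raw_reports == len(small_corpus.frames["demo"])

    def test_every_report_has_at_least_one_reaction(self, small_corpus):
        demo_ids = set(small_corpus.frames["demo"]["primaryid"])
        reac_ids = set(small_corpus.frames["reac"]["primaryid"])
        assert demo_ids == reac_ids

    def test_ledger_events_match_reac_rows(self, small_corpus):
        led = small_corpus.ledger
        reac = small_corpus.frames["reac"]
        demo = small_corpus.frames["demo"]
        pid_to_case = dict(zip(demo["primaryid"], demo["caseid"]))
        observed = {
            (pid_to_case[pid], pt) for pid, pt in zip(reac["primaryid"], reac["pt"])
        }
        truth = {
            (case, pt)
            for case, row in led.events.iterrows()
            for pt, flag in row.items()
            if flag
        }
        assert observed == truth

    def test_cell_counts_use_kept_versions_only(self, small_corpus):
        a, b, c, d = small_corpus.ledger.cell_counts("tofacitinib", "Acne")
        assert a + b + c + d == small_corpus.ledger.n_in_cohort


class TestInjectDuplicates:
    def test_rate_zero_is_identity(self, small_corpus):
        frames, dup_map = inject_duplicates(small_corpus.frames, 0.0, seed=1)
        assert dup_map.empty
        for kind, df in frames.items():
            pd.testing.assert_frame_equal(
                df.reset_index(drop=True),
                small_corpus.frames[kind].reset_index(drop=True),
            )

    def test_duplicates_share_caseid_with_larger_pid(self):
        cfg = SynthConfig(n_cases=150, duplicate_rate=0.0, seed=9)
        corpus = generate_corpus(cfg)
        frames, dup_map = inject_duplicates(corpus.frames, 0.5, seed=2)
        assert not dup_map.empty
        demo = frames["demo"].set_index("primaryid")
        for row in dup_map.itertuples(index=False):
            assert int(row.duplicate) > int(row.original)
            assert demo.loc[row.duplicate, "caseid"] == row.caseid
            assert int(demo.loc[row.duplicate, "fda_dt"]) >= int(
                demo.loc[row.original, "fda_dt"]
            )

    def test_dedup_selects_rule_version_from_injected(self):
        from faerspv import faers_io
        from faerspv.cases import deduplicate

        cfg = SynthConfig(n_cases=100, duplicate_rate=0.0, seed=13)
        corpus = generate_corpus(cfg)
        frames, _ = inject_duplicates(corpus.frames, 0.6, seed=3)
        reports = faers_io.join_cases(frames_to_tables(frames)).reports
        deduped = {r.caseid: r.primaryid for r in deduplicate(reports)}
        demo = frames["demo"].assign(
            fda=frames["demo"]["fda_dt"].astype(int),
            pid=frames["demo"]["primaryid"].astype(int),
        )
        want = demo.sort_values(["fda", "pid"]).groupby("caseid").tail(1)
        assert deduped == dict(zip(want["caseid"], want["primaryid"]))


class TestExpectedRor:
    def test_null_theta_gives_unity(self):
        cfg = SynthConfig(n_cases=10)
        assert expected_ror(cfg, "tofacitinib", "Acne") == pytest.approx(1.0)

    def test_rare_events_approach_theta(self):
        cfg = SynthConfig(
            n_cases=10, baseline=0.002, filler_baseline=0.25,
            theta={("tofacitinib", "Acne"): 4.0},
        )
        assert expected_ror(cfg, "tofacitinib", "Acne") == pytest.approx(4.0, rel=0.02)

    def test_single_drug_universe_undefined(self):
        cfg = SynthConfig(
            n_cases=10,
            drugs={"tofacitinib": ("Xeljanz",)},
            weights={"tofacitinib": 1.0},
        )
        assert np.isnan(expected_ror(cfg, "tofacitinib", "Acne"))

    def test_probability_above_one_rejected(self):
        with pytest.raises(ValueError, match="baseline"):
            SynthConfig(n_cases=10, theta={("tofacitinib", "Drug ineffective"): 10.0})

    def test_sample_pair_table_mean_near_expectation(self):
        cfg = SynthConfig(n_cases=30000, theta={("tofacitinib", "Acne"): 4.0},
                          off_indication_rate=0.0, duplicate_rate=0.0)
        target = expected_ror(cfg, "tofacitinib", "Acne")
        rng = np.random.default_rng(0)
        lors = []
        for _ in range(40):
            t = sample_pair_table(cfg, "tofacitinib", "Acne", rng)
            lors.append(np.log(t.a * t.d / (t.b * t.c)))
        assert np.exp(np.mean(lors)) == pytest.approx(target, rel=0.1)


def test_corpus_files_are_parseable_faers_dialect(tmp_path, small_corpus):
    from faerspv import faers_io

    out = tmp_path / "x"
    write_corpus(small_corpus.frames, out)
    tables = faers_io.read_extract(out)
    assert len(tables["demo"]) == len(small_corpus.frames["demo"])
    assert all(r.fda_dt is not None for r in tables["demo"])
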