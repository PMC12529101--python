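"""Build the deduplicated, indication-restricted analysis cohort.

Reads the corpus written by 01_simulate_corpus.py back through the
FAERS ASCII parser (exercising the full ingest path), applies the FDA
deduplication rule and the psoriasis/PsA indication restriction, and
writes the stage-count flow table plus the Table-1-style
characteristics summary under results/study/.
"""

from pathlib import Path

import pandas as pd

from faerspv.cases import build_analysis_set
from faerspv.onset import summarize_characteristics
from faerspv.pipeline import STUDY_DRUGS, validate_config

HERE = Path(__file__).resolve().parent


def main() -> None:
    config = validate_config(HERE / "config.yaml")
    out = Path("results/study")
    out.mkdir(parents=True, exist_ok=True)

    aset = build_analysis_set([Path("results/corpus")],
                              config.synth.cohort_config())
    flow = pd.DataFrame(sorted(aset.flow.items()), columns=["stage", "count"])
    flow.to_csv(out / "flow.tsv", sep="\t", index=False)

    chars, tests = summarize_characteristics(aset, STUDY_DRUGS)
    chars.to_csv(out / "characteristics.tsv", sep="\t", index=False,
                 float_format="%.2f")
    tests.to_csv(out / "binomial_tests.tsv", sep="\t", index=False,
                 float_format="%.4g")

    print("cohort flow:")
    print(flow.to_string(index=False))
    print(f"\npooled median age: {tests.attrs['pooled_median_age']:.1f} years")
    sex = tests[tests["test"] == "sex_f_vs_m"]
    print("female share and binomial p per drug:")
    for row in sex.itertuples(index=False):
        print(f"  {row.drug:16s} {100 * row.k / row.n:5.1f}%  p={row.p_value:.3g}")


if __name__ == "__main__":
    main()
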