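"""Replicated validation studies of the whole pipeline.

Runs the ground-truth recovery studies (statistic oracles, counting,
deduplication, signal-rule calibration, CI coverage, regression
identities, time to onset) at full size and writes their measurements
to results/validation.json.
"""

import json
from pathlib import Path

from faerspv import studies

SEED = 20240901


def main() -> None:
    out = Path("results")
    out.mkdir(exist_ok=True)
    results = {
        "statistic_oracle": studies.statistic_oracle_study(SEED),
        "counting_oracle": studies.counting_oracle_study(SEED),
        "deduplication": studies.dedup_study(SEED),
        "signal_calibration": studies.signal_calibration_study(SEED),
        "ror_coverage": studies.ror_coverage_study(SEED),
        "regression": studies.regression_identity_study(SEED),
        "time_to_onset": studies.tto_study(SEED),
    }
    (out / "validation.json").write_text(json.dumps(results, indent=2))
    for study, vals in results.items():
        print(f"{study}:")
        for k, v in vals.items():
            print(f"  {k}: {v:g}" if isinstance(v, float) else f"  {k}: {v}")


if __name__ == "__main__":
    main()
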