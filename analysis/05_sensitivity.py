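"""Sensitivity analyses: warning-window split and rare-PT exclusion.

Reads results/reports.csv, computes the drug-level pooled-SD ROR in the
pre-warning (2004Q1-2015Q1) and post-warning (2016Q3-2023Q3) windows and
after removing PTs with fewer than 500 dataset-wide mentions, and writes
results/sensitivity_ror.csv.  Prints the pre/post contrast, where the
planted post-2016 ICD reporting surge should be visible.
"""

from pathlib import Path

import pandas as pd

from pvpd.sensitivity import SensitivitySpec, sensitivity_suite
from pvpd.synthetic_faers import read_dataset
from pvpd.termsets import default_termset

OUT = Path("results")


def main() -> None:
    reports = read_dataset(OUT / "reports.csv")
    ts = default_termset()
    drugs = sorted(set(reports.loc[reports["role"] == "PS", "drug"]) - {"other"})
    out = sensitivity_suite(reports, drugs, ts, SensitivitySpec())
    out.to_csv(OUT / "sensitivity_ror.csv", index=False)
    print(f"wrote {OUT/'sensitivity_ror.csv'}")

    wide = out.pivot(index="drug", columns="analysis", values="ror")
    wide["post/pre"] = wide["post_warning"] / wide["pre_warning"]
    print("\ndrug-level pooled-SD ROR by analysis:")
    with pd.option_context("display.float_format", "{:.2f}".format):
        print(wide.to_string())


if __name__ == "__main__":
    main()
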