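"""Disproportionality scan: PT-level and subgroup-level ROR/IC signals.

Reads results/reports.csv (regenerating it if absent), scans every
studied drug against the SD event vocabulary, and writes
results/signals.csv.  Prints the strongest included signals and each
drug's median ROR — the dependent variable of the occupancy regression.
"""

from pathlib import Path

import pandas as pd

from pvpd.disproportionality import median_ror_table, signal_scan
from pvpd.synthetic_faers import read_dataset
from pvpd.termsets import default_termset

OUT = Path("results")


def load_reports() -> pd.DataFrame:
    path = OUT / "reports.csv"
    if not path.exists():
        from pvpd.synthetic_faers import default_study_config, write_dataset

        OUT.mkdir(exist_ok=True)
        write_dataset(default_study_config(n_reports=150_000, seed=0), path)
    return read_dataset(path)


def main() -> None:
    reports = load_reports()
    ts = default_termset()
    drugs = sorted(set(reports.loc[reports["role"] == "PS", "drug"]) - {"other"})
    signals = signal_scan(reports, drugs, ts)
    signals.to_csv(OUT / "signals.csv", index=False)
    print(f"wrote {OUT/'signals.csv'} ({len(signals)} drug-event estimates)")

    inc = signals[(signals["level"] == "pt") & signals["included"]]
    top = inc.sort_values("ror", ascending=False).head(5)
    print("\nstrongest PT-level signals (included pairs):")
    for _, r in top.iterrows():
        print(f"  {r.drug:14s} {r.event:28s} a={r.a:4d} "
              f"ROR={r.ror:7.2f} ({r.ror_lo:.2f}-{r.ror_hi:.2f}) IC={r.ic:5.2f}")

    print("\nper-drug median ROR over included PTs:")
    med = median_ror_table(signals, drugs).dropna().sort_values(ascending=False)
    for drug, m in med.items():
        print(f"  {drug:14s} {m:6.2f}")


if __name__ == "__main__":
    main()
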