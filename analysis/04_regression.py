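"""Regress per-drug median ROR on per-receptor occupancy (all modes).

Reads results/signals.csv and results/occupancy.csv, fits the univariate
per-receptor models in the four predictor modes (raw occupancy,
activity-signed occupancy, pKi, and activity-signed after excluding
impulse-control-disorder PTs), and writes results/regression.csv.
Iloperidone is excluded from the regression stage (sparse reporting).
"""

from pathlib import Path

import pandas as pd

from pvpd.regression import regression_all_modes
from pvpd.termsets import default_termset

OUT = Path("results")


def main() -> None:
    signals = pd.read_csv(OUT / "signals.csv")
    occ = pd.read_csv(OUT / "occupancy.csv")
    fits = regression_all_modes(
        signals, occ, termset=default_termset(), exclude_drugs=("iloperidone",)
    )
    fits.to_csv(OUT / "regression.csv", index=False)
    print(f"wrote {OUT/'regression.csv'} ({len(fits)} receptor x mode fits)")

    sig = fits[fits["p_value"] < 0.05]
    if sig.empty:
        print("\nno receptor reached p < 0.05 in any mode")
    else:
        print("\nfits with p < 0.05:")
        for _, r in sig.iterrows():
            print(f"  {r.receptor:10s} {r['mode']:24s} beta={r.beta:7.3f} "
                  f"p={r.p_value:.3f} R2={r.r2:.3f} n={r.n_points}")


if __name__ == "__main__":
    main()
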