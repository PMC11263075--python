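"""Receptor occupancy for the studied antipsychotics.

Loads the shipped (synthetic, order-of-magnitude-plausible) pharmacology
table, derives the unbound therapeutic concentration per drug and the
occupancy of each of the ten receptors, and writes results/occupancy.csv.
"""

from pathlib import Path

from pvpd.occupancy import load_pharmacology, occupancy_table

OUT = Path("results")


def main() -> None:
    OUT.mkdir(exist_ok=True)
    pharm = load_pharmacology()
    occ = occupancy_table(pharm)
    occ.to_csv(OUT / "occupancy.csv", index=False)
    print(f"wrote {OUT/'occupancy.csv'} ({len(occ)} drug-receptor pairs, "
          f"{occ['drug'].nunique()} drugs)")

    print("\nhighest occupancies:")
    for _, r in occ.sort_values("occupancy_pct", ascending=False).head(6).iterrows():
        print(f"  {r.drug:14s} {r.receptor:10s} C_U={r.c_u_nM:8.2f} nM "
              f"occ={r.occupancy_pct:5.1f}%")
    n_signed = occ["signed_occupancy"].notna().sum()
    print(f"\nactivity known (signed predictor available): {n_signed}/{len(occ)}")


if __name__ == "__main__":
    main()
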