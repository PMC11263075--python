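"""Generate the synthetic spontaneous-report stream under study conditions.

Writes results/reports.csv (flat report x drug x PT layout) plus a JSON
sidecar of the generator configuration, and prints the basic shape of the
stream: report counts, share of antipsychotic primary-suspect reports,
and the size of the planted signal structure.
"""

from pathlib import Path

from pvpd.synthetic_faers import default_study_config, generate_frame, write_dataset

OUT = Path("results")
N_REPORTS = 150_000
SEED = 0


def main() -> None:
    OUT.mkdir(exist_ok=True)
    cfg = default_study_config(n_reports=N_REPORTS, seed=SEED, surge=True)
    path = write_dataset(cfg, OUT / "reports.csv")
    frame = generate_frame(cfg)

    ps = frame[frame["role"] == "PS"].drop_duplicates("report_id")
    aap_share = (ps["drug"] != "other").mean()
    print(f"wrote {path}")
    print(f"reports: {frame['report_id'].nunique():,} "
          f"({len(frame):,} flat rows, quarters {frame['quarter'].min()}..{frame['quarter'].max()})")
    print(f"antipsychotic PS share: {aap_share:.1%}")
    print(f"planted drug-PT effects: {len(cfg.planted_effects)}; "
          f"post-2016Q2 ICD surge x{cfg.warning_surge.multiplier}")


if __name__ == "__main__":
    main()
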