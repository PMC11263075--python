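"""End-to-end orchestration: ingest or generate, scan, regress, report.

``run`` executes every stage of the analysis on one dataset and writes
the full table set (``cohort.csv``, ``signals.csv``, ``occupancy.csv``,
``regression.csv``, ``sensitivity_ror.csv``), advisory figures, and a
``manifest.json`` recording the configuration, seed and library versions.
Every number in the output tables is reproducible by calling the
underlying module function directly; the pipeline adds no math of its
own.  A stage failure aborts the run with a stage-named error and removes
partial outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import shutil
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .disproportionality import report_index, signal_scan
from .occupancy import load_pharmacology, occupancy_table
from .regression import regression_all_modes
from .sensitivity import SensitivitySpec, sensitivity_suite
from .synthetic_faers import (
    GeneratorConfig,
    default_study_config,
    generate_frame,
    read_dataset,
)
from .termsets import TermSet, default_termset, load_termset

logger = logging.getLogger(__name__)

PERIOD_BINS = ((2004, 2008), (2009, 2013), (2014, 2018), (2019, 2023))

_CSV_FLOAT_FORMAT = "%.10g"


@dataclass(frozen=True)
class RunConfig:
    """Configuration for one end-to-end run."""

    drugs: tuple
    input_csv: str | None = None  # mutually exclusive with generator
    generator: GeneratorConfig | None = None
    termset_path: str | None = None
    pharmacology_path: str | None = None
    exclude_drugs: tuple = ("iloperidone",)
    median_over: str = "included"
    sensitivity: SensitivitySpec = field(default_factory=SensitivitySpec)
    out_dir: str = "results/run"
    seed: int = 0
    make_figures: bool = True

    def __post_init__(self) -> None:
        if not self.drugs:
            raise ValueError("drug list must be non-empty")
        if (self.input_csv is None) == (self.generator is None):
            raise ValueError("exactly one of input_csv or generator must be set")
        if self.median_over not in ("included", "significant"):
            raise ValueError(f"invalid median_over {self.median_over!r}")
        for p in (self.input_csv, self.termset_path, self.pharmacology_path):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(p)


def default_run_config(out_dir="results/run", seed: int = 0, n_reports: int = 150_000) -> RunConfig:
    """Demo configuration: synthetic study-condition data, shipped tables."""
    gen = default_study_config(n_reports=n_reports, seed=seed)
    return RunConfig(
        drugs=tuple(sorted(d for d in gen.drugs if d != "other")),
        generator=gen,
        out_dir=out_dir,
        seed=seed,
    )


def load_run_config(path) -> RunConfig:
    """Read a RunConfig from YAML (see ``pvpd/data/demo_config.yaml``)."""
    raw = yaml.safe_load(Path(path).read_text())
    gen = None
    if "generator" in raw:
        g = raw["generator"]
        if g.get("study_defaults", False):
            gen = default_study_config(
                n_reports=int(g.get("n_reports", 150_000)),
                seed=int(raw.get("seed", 0)),
                surge=bool(g.get("surge", True)),
            )
        else:
            from .synthetic_faers import WarningSurge

            surge = g.get("warning_surge")
            gen = GeneratorConfig(
                n_reports=int(g["n_reports"]),
                drugs=dict(g["drugs"]),
                pts=dict(g["pts"]),
                planted_effects={
                    (e["drug"], e["pt"]): float(e["rho"])
                    for e in g.get("planted_effects", [])
                },
                quarter_range=tuple(g.get("quarter_range", ("2004Q1", "2023Q3"))),
                warning_surge=WarningSurge(**surge) if surge else None,
                icd_pts=frozenset(g.get("icd_pts", ())),
                seed=int(raw.get("seed", 0)),
            )
    return RunConfig(
        drugs=tuple(raw["drugs"]),
        input_csv=raw.get("input_csv"),
        generator=gen,
        termset_path=raw.get("termset"),
        pharmacology_path=raw.get("pharmacology"),
        exclude_drugs=tuple(raw.get("exclude_drugs", ("iloperidone",))),
        median_over=raw.get("median_over", "included"),
        out_dir=raw.get("out_dir", "results/run"),
        seed=int(raw.get("seed", 0)),
        make_figures=bool(raw.get("make_figures", True)),
    )


def _age_band(age: pd.Series) -> pd.Series:
    bins = pd.cut(
        age, bins=[18, 40, 65, np.inf], labels=["18-40", "41-65", ">65"], right=True,
        include_lowest=True,
    )
    return bins.astype(object).where(age.notna(), "missing")


def describe_cohort(reports: pd.DataFrame, drugs, termset: TermSet) -> pd.DataFrame:
    """Per-drug descriptive summary of SD case reports.

    One row per drug over its SD cases (PS role, any SD PT): counts by age
    band, mean/SD age, sex, country, indication, outcome, five-year
    period, and mean daily dose with availability.  Structure mirrors a
    standard characteristics table; no hypothesis tests are computed.
    """
    sd_pts = termset.sd_event_pts()
    idx = report_index(reports)
    case_ids = idx[idx["pt"].isin(sd_pts)].groupby("report_id")["ps_drug"].first()
    meta = (
        reports.drop_duplicates("report_id")
        .set_index("report_id")[
            ["age", "sex", "country", "quarter", "indication", "outcome", "daily_dose_mg"]
        ]
    )
    rows = []
    for drug in drugs:
        ids = case_ids[case_ids == drug].index
        sub = meta.loc[meta.index.intersection(ids)]
        n = len(sub)
        band = _age_band(sub["age"]) if n else pd.Series(dtype=object)
        year = sub["quarter"].str.slice(0, 4).astype(int) if n else pd.Series(dtype=int)
        row = {"drug": drug, "n_cases": n}
        for b in ("18-40", "41-65", ">65", "missing"):
            row[f"age_{b}"] = int((band == b).sum()) if n else 0
        row["age_mean"] = float(sub["age"].mean()) if n else np.nan
        row["age_sd"] = float(sub["age"].std()) if n else np.nan
        for s in ("F", "M", "missing"):
            row[f"sex_{s}"] = int((sub["sex"] == s).sum()) if n else 0
        for cc in ("US", "other", "missing"):
            row[f"country_{cc}"] = int((sub["country"] == cc).sum()) if n else 0
        for ind in ("psychotic disorder", "bipolar disorder", "missing"):
            key = "indication_" + ind.replace(" ", "_")
            row[key] = int((sub["indication"] == ind).sum()) if n else 0
        for oc in ("death_lifethreat", "hospitalization", "other", "missing"):
            row[f"outcome_{oc}"] = int((sub["outcome"] == oc).sum()) if n else 0
        for lo, hi in PERIOD_BINS:
            row[f"period_{lo}_{hi}"] = (
                int(((year >= lo) & (year <= hi)).sum()) if n else 0
            )
        dose = sub["daily_dose_mg"].dropna() if n else pd.Series(dtype=float)
        row["dose_mean_mg"] = float(dose.mean()) if len(dose) else np.nan
        row["dose_n_available"] = int(len(dose))
        rows.append(row)
    return pd.DataFrame(rows)


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format=_CSV_FLOAT_FORMAT)


def run(config: RunConfig) -> Path:
    """Execute all stages; returns the output directory.

    Deterministic for a fixed config and seed: re-running produces
    byte-identical CSV outputs.
    """
    out = Path(config.out_dir)
    created = not out.exists()
    out.mkdir(parents=True, exist_ok=True)
    stage = "setup"
    try:
        stage = "ingest"
        if config.generator is not None:
            reports = generate_frame(config.generator)
        else:
            reports = read_dataset(config.input_csv)
        logger.info("ingest: %d rows, %d reports", len(reports), reports["report_id"].nunique())

        stage = "termset"
        ts = (
            load_termset(config.termset_path)
            if config.termset_path
            else default_termset()
        )
        if not ts.sd_event_pts():
            raise ValueError("termset has no SD PTs")

        stage = "cohort"
        cohort = describe_cohort(reports, config.drugs, ts)
        _write_csv(cohort, out / "cohort.csv")

        stage = "signal_scan"
        signals = signal_scan(reports, config.drugs, ts)
        _write_csv(signals, out / "signals.csv")

        stage = "occupancy"
        pharm = load_pharmacology(config.pharmacology_path)
        occ = occupancy_table(pharm)
        _write_csv(occ, out / "occupancy.csv")

        stage = "regression"
        regression = regression_all_modes(
            signals,
            occ,
            termset=ts,
            drugs=list(config.drugs),
            exclude_drugs=config.exclude_drugs,
            median_over=config.median_over,
        )
        _write_csv(regression, out / "regression.csv")

        stage = "sensitivity"
        sens = sensitivity_suite(reports, config.drugs, ts, config.sensitivity)
        _write_csv(sens, out / "sensitivity_ror.csv")

        if config.make_figures:
            stage = "figures"
            from . import plots

            figdir = out / "figures"
            figdir.mkdir(exist_ok=True)
            plots.forest_subgroups(signals, figdir / "forest_subgroups.png")
            plots.occupancy_heatmap(occ, figdir / "occupancy_heatmap.png")
            plots.regression_scatter(
                signals, occ, regression, figdir, exclude_drugs=config.exclude_drugs,
                median_over=config.median_over,
            )

        stage = "manifest"
        manifest = {
            "pvpd_version": __version__,
            "seed": config.seed,
            "config": _config_echo(config),
            "versions": {
                "numpy": np.__version__,
                "pandas": pd.__version__,
            },
            "n_reports": int(reports["report_id"].nunique()),
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    except Exception as exc:
        if created:
            shutil.rmtree(out, ignore_errors=True)
        else:
            for name in (
                "cohort.csv",
                "signals.csv",
                "occupancy.csv",
                "regression.csv",
                "sensitivity_ror.csv",
                "manifest.json",
            ):
                (out / name).unlink(missing_ok=True)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return out


def _config_echo(config: RunConfig) -> dict:
    def enc(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, (frozenset, set)):
            return sorted(obj)
        if isinstance(obj, tuple):
            return [enc(v) for v in obj]
        if isinstance(obj, dict):
            return {str(k): enc(v) for k, v in obj.items()}
        return obj

    return enc(config)
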