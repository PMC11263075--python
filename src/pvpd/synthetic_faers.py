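"""Seedable synthetic spontaneous-report stream with planted associations.

Emulates the shape of a FAERS-style individual-case-safety-report extract:
each report has exactly one primary-suspect (PS) drug, optional concomitant
decoy drugs, one or more reaction PTs, demographic fields with realistic
missingness, and a receipt quarter on a 2004Q1-2023Q3 axis.

The generative model is deliberately simple so that ground truth is
available in closed form: given the PS drug (and quarter), each PT is
included independently with probability ``p_pt * rho(drug, pt)`` (clipped
at 1), where ``rho`` is a planted reporting-rate multiplier (``rho = 1``
means independence).  An optional post-warning surge multiplies the
inclusion probability of impulse-control-disorder (ICD) PTs for quarters
after a cut-off, emulating notoriety bias after a regulatory warning.
:func:`expected_ror` enumerates this mixture exactly and is the oracle for
all recovery tests.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Reserved PT assigned when a report samples no reaction; never configurable.
FALLBACK_PT = "drug ineffective"

FLAT_COLUMNS = [
    "report_id",
    "drug",
    "role",
    "pt",
    "age",
    "sex",
    "country",
    "quarter",
    "indication",
    "outcome",
    "daily_dose_mg",
]

_AGE_BAND_RANGES = {"18-40": (18.0, 40.0), "41-65": (41.0, 65.0), ">65": (66.0, 90.0)}


@dataclass(frozen=True)
class Demographics:
    """Categorical distributions for report-level fields.

    Defaults mirror the broad structure of published antipsychotic
    safety-report cohorts: mostly male, heavy missingness in age and dose,
    roughly half US-origin.
    """

    sex: dict = field(
        default_factory=lambda: {"M": 0.62, "F": 0.28, "missing": 0.10}
    )
    age_band: dict = field(
        default_factory=lambda: {
            "18-40": 0.36,
            "41-65": 0.16,
            ">65": 0.02,
            "missing": 0.46,
        }
    )
    country: dict = field(
        default_factory=lambda: {"US": 0.53, "other": 0.37, "missing": 0.10}
    )
    indication: dict = field(
        default_factory=lambda: {
            "psychotic disorder": 0.33,
            "bipolar disorder": 0.13,
            "missing": 0.54,
        }
    )
    outcome: dict = field(
        default_factory=lambda: {
            "death_lifethreat": 0.04,
            "hospitalization": 0.21,
            "other": 0.65,
            "missing": 0.10,
        }
    )

    def __post_init__(self) -> None:
        for name in ("sex", "age_band", "country", "indication", "outcome"):
            dist = getattr(self, name)
            total = sum(dist.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"demographics.{name} sums to {total}, not 1")
            if any(p < 0 or p > 1 for p in dist.values()):
                raise ValueError(f"demographics.{name} has probability outside [0,1]")


@dataclass(frozen=True)
class WarningSurge:
    """Post-warning reporting surge on ICD PTs.

    ``multiplier`` scales the inclusion probability of every ICD PT for
    reports received strictly after ``cut_quarter``; ``drugs`` restricts
    the surge to specific drugs (``None`` = all drugs, emulating spillover
    of notoriety bias to the whole class).
    """

    cut_quarter: str = "2016Q2"
    multiplier: float = 3.0
    drugs: tuple | None = None

    def __post_init__(self) -> None:
        if self.multiplier < 0:
            raise ValueError("surge multiplier must be nonnegative")


@dataclass(frozen=True)
class GeneratorConfig:
    n_reports: int
    drugs: dict  # drug name -> PS marginal probability (sums to 1)
    pts: dict  # PT name -> background inclusion probability
    planted_effects: dict = field(default_factory=dict)  # (drug, pt) -> rho
    quarter_range: tuple = ("2004Q1", "2023Q3")
    warning_surge: WarningSurge | None = None
    icd_pts: frozenset = frozenset()
    demographics: Demographics = field(default_factory=Demographics)
    dose_missingness: float = 0.758
    concomitant_rate: float = 0.30
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_reports <= 0:
            raise ValueError("n_reports must be positive")
        total = sum(self.drugs.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"drug marginals sum to {total}, not 1")
        for name, p in self.pts.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"background probability for PT {name!r} outside [0,1]")
        if FALLBACK_PT in self.pts:
            raise ValueError(f"PT name {FALLBACK_PT!r} is reserved for the fallback")
        for (d, pt), rho in self.planted_effects.items():
            if d not in self.drugs:
                raise ValueError(f"planted effect for unknown drug {d!r}")
            if pt not in self.pts:
                raise ValueError(f"planted effect for unknown PT {pt!r}")
            if rho < 0:
                raise ValueError(f"rho for ({d!r}, {pt!r}) must be >= 0")
        if not 0.0 <= self.dose_missingness <= 1.0:
            raise ValueError("dose_missingness must be in [0,1]")
        try:
            q = self.quarters()
        except Exception as exc:  # noqa: BLE001 - normalize parse errors
            raise ValueError(f"invalid quarter range {self.quarter_range}") from exc
        if len(q) == 0:
            raise ValueError(f"empty quarter range {self.quarter_range}")

    def quarters(self) -> pd.PeriodIndex:
        return pd.period_range(self.quarter_range[0], self.quarter_range[1], freq="Q")


@dataclass(frozen=True)
class AEReport:
    """One spontaneous report (at most one PS drug entry)."""

    report_id: str
    drug_entries: tuple  # of (drug name, role in {PS, SS, C, I})
    reaction_pts: tuple
    age_years: float | None
    sex: str  # F, M, missing
    country: str
    quarter: str
    indication: str
    outcome: str
    daily_dose_mg: float | None

    def __post_init__(self) -> None:
        if sum(1 for _, role in self.drug_entries if role == "PS") > 1:
            raise ValueError(f"report {self.report_id}: more than one PS drug")
        if not self.reaction_pts:
            raise ValueError(f"report {self.report_id}: no reaction PTs")


def _sample_categorical(rng, dist: dict, n: int) -> np.ndarray:
    labels = np.array(list(dist.keys()), dtype=object)
    probs = np.array(list(dist.values()), dtype=float)
    return labels[rng.choice(len(labels), size=n, p=probs / probs.sum())]


def _inclusion_prob_matrix(config: GeneratorConfig, ps_idx, post_cut):
    """Per-report x per-PT inclusion probabilities, clipped at 1."""
    drug_names = list(config.drugs)
    pt_names = list(config.pts)
    n = len(ps_idx)
    prob = np.tile(np.array([config.pts[p] for p in pt_names]), (n, 1))
    for (d, pt), rho in config.planted_effects.items():
        prob[ps_idx == drug_names.index(d), pt_names.index(pt)] *= rho
    if config.warning_surge is not None:
        s = config.warning_surge
        icd_cols = [j for j, p in enumerate(pt_names) if p in config.icd_pts]
        if icd_cols:
            rows = post_cut.copy()
            if s.drugs is not None:
                surged = np.isin(
                    ps_idx, [drug_names.index(d) for d in s.drugs if d in drug_names]
                )
                rows &= surged
            prob[np.ix_(rows.nonzero()[0], icd_cols)] *= s.multiplier
    over = prob > 1.0
    if over.any():
        for j in sorted(set(over.nonzero()[1])):
            d_over = sorted({drug_names[i] for i in ps_idx[over[:, j]]})
            logger.warning(
                "inclusion probability capped at 1 for PT %r (drugs %s)",
                pt_names[j],
                d_over,
            )
        prob = np.clip(prob, 0.0, 1.0)
    return prob, pt_names


def generate_frame(config: GeneratorConfig) -> pd.DataFrame:
    """Generate the dataset in the flat one-row-per-report x drug x PT layout.

    Deterministic: the same config (including seed) yields an identical
    frame.  This is the vectorized workhorse; :func:`generate` wraps it
    into :class:`AEReport` objects.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_reports
    drug_names = np.array(list(config.drugs), dtype=object)
    drug_probs = np.array(list(config.drugs.values()), dtype=float)

    ps_idx = rng.choice(len(drug_names), size=n, p=drug_probs / drug_probs.sum())
    quarters = config.quarters()
    q_idx = rng.integers(0, len(quarters), size=n)
    q_labels = np.array([str(q) for q in quarters], dtype=object)
    if config.warning_surge is not None:
        cut = pd.Period(config.warning_surge.cut_quarter, freq="Q")
        post_cut = np.array([q > cut for q in quarters])[q_idx]
    else:
        post_cut = np.zeros(n, dtype=bool)

    prob, pt_names = _inclusion_prob_matrix(config, ps_idx, post_cut)
    incl = rng.random((n, len(pt_names))) < prob

    # concomitant decoys: a second drug with role C, never equal to the PS drug
    has_conc = rng.random(n) < config.concomitant_rate
    conc_idx = rng.choice(len(drug_names), size=n, p=drug_probs / drug_probs.sum())
    has_conc &= conc_idx != ps_idx

    demo = config.demographics
    sex = _sample_categorical(rng, demo.sex, n)
    band = _sample_categorical(rng, demo.age_band, n)
    age = np.full(n, np.nan)
    for b, (lo, hi) in _AGE_BAND_RANGES.items():
        m = band == b
        age[m] = np.round(rng.uniform(lo, hi, size=int(m.sum())), 1)
    country = _sample_categorical(rng, demo.country, n)
    indication = _sample_categorical(rng, demo.indication, n)
    outcome = _sample_categorical(rng, demo.outcome, n)
    dose = np.round(rng.lognormal(math.log(10.0), 0.8, size=n), 2)
    dose[rng.random(n) < config.dose_missingness] = np.nan

    report_ids = np.array([f"R{i:08d}" for i in range(n)], dtype=object)

    rep_i, pt_j = incl.nonzero()
    pt_arr = np.array(pt_names, dtype=object)[pt_j]
    no_pt = (~incl.any(axis=1)).nonzero()[0]
    rep_i = np.concatenate([rep_i, no_pt])
    pt_arr = np.concatenate([pt_arr, np.full(len(no_pt), FALLBACK_PT, dtype=object)])
    order = np.argsort(rep_i, kind="stable")
    pts_per_report = pd.DataFrame(
        {"ridx": rep_i[order], "pt": pt_arr[order]}
    )

    ps_rows = pd.DataFrame(
        {"ridx": np.arange(n), "drug": drug_names[ps_idx], "role": "PS"}
    )
    c_rows = pd.DataFrame(
        {
            "ridx": has_conc.nonzero()[0],
            "drug": drug_names[conc_idx[has_conc]],
            "role": "C",
        }
    )
    drug_rows = pd.concat([ps_rows, c_rows], ignore_index=True)

    flat = drug_rows.merge(pts_per_report, on="ridx", how="left")
    ridx = flat["ridx"].to_numpy()
    flat = flat.assign(
        report_id=report_ids[ridx],
        age=age[ridx],
        sex=sex[ridx],
        country=country[ridx],
        quarter=q_labels[q_idx[ridx]],
        indication=indication[ridx],
        outcome=outcome[ridx],
        daily_dose_mg=dose[ridx],
    )
    flat = flat.sort_values(["ridx", "role", "drug", "pt"], kind="stable")
    return flat[FLAT_COLUMNS].reset_index(drop=True)


def generate(config: GeneratorConfig) -> list:
    """Generate the dataset as a list of :class:`AEReport` objects."""
    return frame_to_reports(generate_frame(config))


def reports_to_frame(reports) -> pd.DataFrame:
    """Flatten AEReport objects to the one-row-per-report x drug x PT layout."""
    rows = []
    for r in reports:
        for drug, role in r.drug_entries:
            for pt in r.reaction_pts:
                rows.append(
                    (
                        r.report_id,
                        drug,
                        role,
                        pt,
                        np.nan if r.age_years is None else r.age_years,
                        r.sex,
                        r.country,
                        r.quarter,
                        r.indication,
                        r.outcome,
                        np.nan if r.daily_dose_mg is None else r.daily_dose_mg,
                    )
                )
    return pd.DataFrame(rows, columns=FLAT_COLUMNS)


def frame_to_reports(frame: pd.DataFrame) -> list:
    """Reassemble AEReport objects from the flat layout."""
    out = []
    for rid, grp in frame.groupby("report_id", sort=True):
        entries = tuple(
            sorted({(d, role) for d, role in zip(grp["drug"], grp["role"])})
        )
        pts = tuple(sorted(set(grp["pt"])))
        first = grp.iloc[0]
        age = None if pd.isna(first["age"]) else float(first["age"])
        dose = None if pd.isna(first["daily_dose_mg"]) else float(first["daily_dose_mg"])
        out.append(
            AEReport(
                report_id=rid,
                drug_entries=entries,
                reaction_pts=pts,
                age_years=age,
                sex=str(first["sex"]),
                country=str(first["country"]),
                quarter=str(first["quarter"]),
                indication=str(first["indication"]),
                outcome=str(first["outcome"]),
                daily_dose_mg=dose,
            )
        )
    return out


def _pt_prob_given_drug(config: GeneratorConfig, drug: str, pt: str) -> float:
    """P(PT included | PS = drug), averaged over the quarter distribution."""
    base = config.pts[pt] * config.planted_effects.get((drug, pt), 1.0)
    s = config.warning_surge
    if (
        s is not None
        and pt in config.icd_pts
        and (s.drugs is None or drug in s.drugs)
    ):
        quarters = config.quarters()
        cut = pd.Period(s.cut_quarter, freq="Q")
        frac_post = float(np.mean([q > cut for q in quarters]))
        return frac_post * min(1.0, base * s.multiplier) + (1 - frac_post) * min(
            1.0, base
        )
    return min(1.0, base)


def expected_ror(config: GeneratorConfig, drug: str, pt: str) -> float:
    """Population reporting odds ratio implied by the generative process.

    Exact enumeration over the PS-drug x quarter mixture:
    ``odds(pt | PS=drug) / odds(pt | PS!=drug)``.  With ``rho = 1``
    everywhere (and no surge) this is 1 for every pair.
    """
    if drug not in config.drugs:
        raise KeyError(f"unknown drug {drug!r}")
    if pt not in config.pts:
        raise KeyError(f"unknown PT {pt!r}")
    p_t = _pt_prob_given_drug(config, drug, pt)
    w_rest = 1.0 - config.drugs[drug]
    if w_rest <= 0:
        raise ValueError("expected_ror undefined with a single drug at probability 1")
    p_o = sum(
        config.drugs[d] * _pt_prob_given_drug(config, d, pt)
        for d in config.drugs
        if d != drug
    ) / w_rest
    if p_t == 0.0:
        return 0.0
    if p_o == 0.0:
        return math.inf
    return (p_t / (1 - p_t)) / (p_o / (1 - p_o))


def rho_for_target_ror(
    config: GeneratorConfig, drug: str, pt: str, target_ror: float
) -> float:
    """Multiplier rho that plants an exact population ROR for one pair.

    Solves the oracle equation assuming no surge interaction on the target
    pair; other pairs' planted effects are honored.
    """
    if target_ror < 0:
        raise ValueError("target ROR must be nonnegative")
    w_rest = 1.0 - config.drugs[drug]
    p_o = sum(
        config.drugs[d] * _pt_prob_given_drug(config, d, pt)
        for d in config.drugs
        if d != drug
    ) / w_rest
    odds_t = target_ror * p_o / (1 - p_o)
    p_t = odds_t / (1 + odds_t)
    if p_t >= 1.0:
        raise ValueError("target ROR unattainable: required probability >= 1")
    return p_t / config.pts[pt]


def write_dataset(config: GeneratorConfig, out_csv, sidecar_json=None) -> Path:
    """Write the flat CSV plus a JSON sidecar echoing the config (with seed)."""
    frame = generate_frame(config)
    out_csv = Path(out_csv)
    frame.to_csv(out_csv, index=False)
    sidecar = Path(sidecar_json) if sidecar_json else out_csv.with_suffix(".config.json")
    cfg = asdict(config)
    cfg["planted_effects"] = [
        {"drug": d, "pt": p, "rho": r} for (d, p), r in config.planted_effects.items()
    ]
    cfg["icd_pts"] = sorted(config.icd_pts)
    cfg["quarter_range"] = list(config.quarter_range)
    if config.warning_surge is not None and cfg["warning_surge"]["drugs"] is not None:
        cfg["warning_surge"]["drugs"] = list(cfg["warning_surge"]["drugs"])
    sidecar.write_text(json.dumps(cfg, indent=2, sort_keys=True))
    return out_csv


#: studied antipsychotics with their PS marginal share of the report stream
STUDY_DRUG_MARGINALS = {
    "aripiprazole": 0.025,
    "asenapine": 0.002,
    "brexpiprazole": 0.003,
    "cariprazine": 0.003,
    "clozapine": 0.010,
    "iloperidone": 0.0005,
    "lurasidone": 0.005,
    "olanzapine": 0.015,
    "paliperidone": 0.008,
    "quetiapine": 0.020,
    "risperidone": 0.020,
    "ziprasidone": 0.005,
}

#: background reporting probability per SD PT (rare events) and common
#: non-SD decoy PTs that pad every report stream
STUDY_PT_MARGINALS = {
    "erectile dysfunction": 0.004,
    "libido decreased": 0.003,
    "sexual dysfunction": 0.002,
    "loss of libido": 0.001,
    "ejaculation failure": 0.0008,
    "ejaculation disorder": 0.0008,
    "libido increased": 0.0008,
    "anorgasmia": 0.0006,
    "hypersexuality": 0.0005,
    "priapism": 0.0004,
    "retrograde ejaculation": 0.0003,
    "compulsive sexual behavior": 0.0003,
    "psychosexual disorder": 0.0003,
    "excessive masturbation": 0.0002,
    "nausea": 0.05,
    "headache": 0.04,
    "dizziness": 0.03,
    "insomnia": 0.03,
    "weight increased": 0.02,
}

#: planted reporting-rate multipliers emulating the qualitative signal
#: structure of the studied class (strong hypersexuality/ICD reporting for
#: the D2 partial agonist, ejaculatory signals for the strong alpha1
#: antagonists, and so on)
STUDY_PLANTED_EFFECTS = {
    ("aripiprazole", "compulsive sexual behavior"): 40.0,
    ("aripiprazole", "hypersexuality"): 30.0,
    ("aripiprazole", "excessive masturbation"): 25.0,
    ("aripiprazole", "libido increased"): 10.0,
    ("aripiprazole", "psychosexual disorder"): 20.0,
    ("iloperidone", "retrograde ejaculation"): 60.0,
    ("iloperidone", "ejaculation failure"): 25.0,
    ("iloperidone", "priapism"): 20.0,
    ("paliperidone", "retrograde ejaculation"): 8.0,
    ("paliperidone", "ejaculation failure"): 8.0,
    ("paliperidone", "libido decreased"): 5.0,
    ("paliperidone", "loss of libido"): 5.0,
    ("paliperidone", "erectile dysfunction"): 4.0,
    ("risperidone", "ejaculation disorder"): 6.0,
    ("risperidone", "erectile dysfunction"): 4.0,
    ("risperidone", "libido decreased"): 3.0,
    ("olanzapine", "libido decreased"): 3.0,
    ("olanzapine", "erectile dysfunction"): 3.0,
    ("ziprasidone", "erectile dysfunction"): 6.0,
    ("ziprasidone", "priapism"): 6.0,
    ("quetiapine", "libido decreased"): 2.5,
    ("quetiapine", "erectile dysfunction"): 2.0,
    ("quetiapine", "anorgasmia"): 3.0,
    ("clozapine", "retrograde ejaculation"): 3.0,
    ("clozapine", "libido decreased"): 2.0,
    ("lurasidone", "libido decreased"): 2.5,
    ("brexpiprazole", "hypersexuality"): 8.0,
    ("brexpiprazole", "compulsive sexual behavior"): 8.0,
    ("cariprazine", "hypersexuality"): 6.0,
    ("cariprazine", "libido increased"): 5.0,
    ("asenapine", "libido decreased"): 3.0,
}


def default_study_config(
    n_reports: int = 150_000, seed: int = 0, surge: bool = True
) -> GeneratorConfig:
    """The study conditions used by the analysis scripts and the demo run.

    A 2004Q1-2023Q3 stream where the studied antipsychotics are a small
    minority of primary suspects against a dominant background, SD PTs
    are rare, planted multipliers reproduce the class's qualitative
    signal structure, and (optionally) ICD PT reporting triples after the
    2016Q2 warning.
    """
    from .termsets import default_termset

    drugs = dict(STUDY_DRUG_MARGINALS)
    drugs["other"] = 1.0 - sum(drugs.values())
    ts = default_termset()
    return GeneratorConfig(
        n_reports=n_reports,
        drugs=drugs,
        pts=dict(STUDY_PT_MARGINALS),
        planted_effects=dict(STUDY_PLANTED_EFFECTS),
        warning_surge=WarningSurge(cut_quarter="2016Q2", multiplier=3.0)
        if surge
        else None,
        icd_pts=ts.icd_related,
        seed=seed,
    )


def read_dataset(path) -> pd.DataFrame:
    """Read a flat report CSV (same schema as :func:`generate_frame`)."""
    df = pd.read_csv(path, dtype={"report_id": str, "quarter": str})
    missing = set(FLAT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"report file missing columns: {sorted(missing)}")
    return df[FLAT_COLUMNS]
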