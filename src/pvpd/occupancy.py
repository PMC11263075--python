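"""Receptor occupancy from binding constants and therapeutic exposure.

Occupancy follows the standard single-site saturation law

    occupancy (%) = 100 * C_U / (Ki + C_U)

with the unbound plasma concentration obtained from the unbound fraction
F_U, the total therapeutic concentration C_T (upper bound of the
recommended therapeutic range, in ng/mL) and the molecular weight MW
(g/mol):

    C_U [nM] = 1000 * F_U * C_T / MW

(ng/mL divided by g/mol is umol/L * 1e-3; the factor 1000 lands in nmol/L).

Two predictor variants serve the regression sensitivity analyses:
activity-signed occupancy (sign reversed for antagonists and inverse
agonists, missing when the activity is unknown) and pKi, the negative
base-10 logarithm of Ki on the molar scale (pKi = 9 - log10(Ki in nM)).
"""

from __future__ import annotations

import math
from importlib import resources

import numpy as np
import pandas as pd

RECEPTORS = (
    "5-HT1A",
    "5-HT2A",
    "5-HT2C",
    "5-HT7",
    "alpha1",
    "alpha2",
    "muscarinic",
    "D2",
    "D3",
    "H1",
)

ACTIVITIES = (
    "full_agonist",
    "partial_agonist",
    "antagonist",
    "inverse_agonist",
    "unspecified",
)

#: activities whose occupancy sign is reversed in the signed predictor
_NEGATIVE_ACTIVITIES = {"antagonist", "inverse_agonist"}

PHARMACOLOGY_COLUMNS = [
    "drug",
    "receptor",
    "ki_nM",
    "activity",
    "f_u",
    "c_t_ng_per_ml",
    "mw_g_per_mol",
    "source",
]


def _require_positive(value: float, name: str) -> float:
    value = float(value)
    if not math.isfinite(value) or value <= 0:
        raise ValueError(f"{name} must be positive, got {value}")
    return value


def unbound_concentration(f_u: float, c_t_ng_per_ml: float, mw_g_per_mol: float) -> float:
    """Unbound plasma concentration in nM: ``1000 * F_U * C_T / MW``."""
    f_u = float(f_u)
    if not 0 < f_u <= 1:
        raise ValueError(f"f_u must be in (0, 1], got {f_u}")
    c_t = _require_positive(c_t_ng_per_ml, "c_t_ng_per_ml")
    mw = _require_positive(mw_g_per_mol, "mw_g_per_mol")
    return 1000.0 * f_u * c_t / mw


def occupancy_pct(c_u_nM: float, ki_nM: float) -> float:
    """Fractional receptor occupancy as a percentage: ``100*C_U/(Ki+C_U)``."""
    c_u = _require_positive(c_u_nM, "c_u_nM")
    ki = _require_positive(ki_nM, "ki_nM")
    return 100.0 * c_u / (ki + c_u)


def signed_occupancy(occ_pct: float, activity: str) -> float:
    """Activity-signed occupancy; NaN when the activity is unspecified.

    An agonist and an antagonist with identical affinity act in opposite
    directions, so antagonists and inverse agonists carry a negative sign;
    drugs with unknown activity are excluded (NaN) from the signed models.
    """
    if not 0 <= occ_pct <= 100:
        raise ValueError(f"occ_pct must be in [0, 100], got {occ_pct}")
    if activity not in ACTIVITIES:
        raise ValueError(f"unknown activity {activity!r}")
    if activity == "unspecified":
        return math.nan
    return -occ_pct if activity in _NEGATIVE_ACTIVITIES else occ_pct


def pki(ki_nM: float) -> float:
    """pKi on the molar scale: ``-log10(Ki * 1e-9) = 9 - log10(Ki in nM)``."""
    ki = _require_positive(ki_nM, "ki_nM")
    return 9.0 - math.log10(ki)


def load_pharmacology(path=None) -> pd.DataFrame:
    """Read and validate a pharmacology CSV.

    With no path, loads the synthetic demonstration table shipped with the
    package (order-of-magnitude-plausible values for the studied
    antipsychotics; not literature-asserted).  Multiple Ki rows for one
    drug x receptor are collapsed by geometric mean, since binding
    constants span orders of magnitude.
    """
    if path is None:
        with resources.as_file(
            resources.files("pvpd.data").joinpath("synthetic_pharmacology.csv")
        ) as p:
            df = pd.read_csv(p)
    else:
        df = pd.read_csv(path)
    missing = set(PHARMACOLOGY_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"pharmacology file missing columns: {sorted(missing)}")
    bad_rec = set(df["receptor"]) - set(RECEPTORS)
    if bad_rec:
        raise ValueError(f"unknown receptors: {sorted(bad_rec)}")
    bad_act = set(df["activity"]) - set(ACTIVITIES)
    if bad_act:
        raise ValueError(f"unknown activities: {sorted(bad_act)}")
    for col in ("ki_nM", "f_u", "c_t_ng_per_ml", "mw_g_per_mol"):
        if (df[col] <= 0).any():
            raise ValueError(f"nonpositive values in column {col}")
    if (df["f_u"] > 1).any():
        raise ValueError("f_u values above 1")

    out = (
        df.groupby(["drug", "receptor"], sort=True)
        .agg(
            ki_nM=("ki_nM", lambda s: float(np.exp(np.log(s).mean()))),
            activity=("activity", "first"),
            f_u=("f_u", "first"),
            c_t_ng_per_ml=("c_t_ng_per_ml", "first"),
            mw_g_per_mol=("mw_g_per_mol", "first"),
            source=(
                "source",
                lambda s: s.iloc[0]
                if len(s) == 1
                else "geomean:" + "|".join(map(str, s)),
            ),
        )
        .reset_index()
    )
    return out[PHARMACOLOGY_COLUMNS]


def occupancy_table(pharm: pd.DataFrame) -> pd.DataFrame:
    """Per drug x receptor occupancy and regression predictors.

    Columns: ``drug, receptor, c_u_nM, occupancy_pct, signed_occupancy,
    pki`` (the ``occupancy.csv`` layout).
    """
    rows = []
    for _, r in pharm.iterrows():
        c_u = unbound_concentration(r["f_u"], r["c_t_ng_per_ml"], r["mw_g_per_mol"])
        occ = occupancy_pct(c_u, r["ki_nM"])
        rows.append(
            {
                "drug": r["drug"],
                "receptor": r["receptor"],
                "c_u_nM": c_u,
                "occupancy_pct": occ,
                "signed_occupancy": signed_occupancy(occ, r["activity"]),
                "pki": pki(r["ki_nM"]),
            }
        )
    return pd.DataFrame(
        rows, columns=["drug", "receptor", "c_u_nM", "occupancy_pct", "signed_occupancy", "pki"]
    )
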