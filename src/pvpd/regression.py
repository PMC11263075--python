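"""Per-receptor univariate regression of signal strength on occupancy.

For each receptor, the per-drug median ROR (dependent variable) is
regressed on a per-drug pharmacodynamic predictor (independent variable)
by ordinary least squares.  Four predictor modes mirror the main analysis
and its sensitivity variants:

``main``
    raw occupancy percentage;
``activity_signed``
    occupancy with the sign reversed for antagonists/inverse agonists,
    drugs of unknown activity dropped;
``pki``
    pKi replaces occupancy, sidestepping the multi-source inputs
    (F_U, C_T, MW) that occupancy needs;
``excl_icd_activity_signed``
    median RORs recomputed after removing impulse-control-disorder PTs,
    then the activity-signed fit.

A receptor enters a fit only with at least three drug data points;
drugs lacking either the predictor or a median ROR are dropped pairwise
per receptor.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .disproportionality import median_ror_table, signal_scan  # noqa: F401 (re-export context)

logger = logging.getLogger(__name__)

MODES = ("main", "activity_signed", "pki", "excl_icd_activity_signed")

_PREDICTOR_OF = {
    "main": "occupancy_pct",
    "activity_signed": "signed_occupancy",
    "pki": "pki",
    "excl_icd_activity_signed": "signed_occupancy",
}

MIN_POINTS = 3

REGRESSION_COLUMNS = [
    "receptor",
    "mode",
    "beta",
    "intercept",
    "p_value",
    "r2",
    "n_points",
]


@dataclass(frozen=True)
class RegressionFit:
    receptor: str
    predictor_kind: str
    beta: float
    intercept: float
    p_value: float
    r2: float
    n_points: int

    def __post_init__(self) -> None:
        if self.n_points < MIN_POINTS:
            raise ValueError(f"fit with n_points={self.n_points} < {MIN_POINTS}")


def fit_univariate(x, y, receptor: str = "", predictor_kind: str = "main") -> RegressionFit:
    """Ordinary least squares of y on x with the slope t-test (n-2 df).

    ``r2`` is the squared Pearson correlation (equivalently 1 - SSE/SST).
    A constant predictor is degenerate and rejected.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if len(x) < MIN_POINTS:
        raise ValueError(f"need at least {MIN_POINTS} points, got {len(x)}")
    if np.isnan(x).any() or np.isnan(y).any():
        raise ValueError("x and y must not contain NaN")
    if np.ptp(x) == 0:
        raise ValueError("degenerate predictor: x is constant")
    res = stats.linregress(x, y)
    r2 = float(res.rvalue**2)
    # a perfectly constant response has slope 0 and, by convention, r2 = 0
    if np.ptp(y) == 0:
        r2 = 0.0
    return RegressionFit(
        receptor=receptor,
        predictor_kind=predictor_kind,
        beta=float(res.slope),
        intercept=float(res.intercept),
        p_value=float(res.pvalue) if not math.isnan(res.pvalue) else 1.0,
        r2=r2,
        n_points=len(x),
    )


def eligible_receptors(occ_table: pd.DataFrame, predictor: str = "occupancy_pct"):
    """Receptors with at least three non-missing drug values for a predictor."""
    counts = occ_table.dropna(subset=[predictor]).groupby("receptor")["drug"].nunique()
    return set(counts[counts >= MIN_POINTS].index)


def regression_suite(
    signals: pd.DataFrame,
    occ_table: pd.DataFrame,
    mode: str = "main",
    termset=None,
    drugs=None,
    exclude_drugs=("iloperidone",),
    median_over: str = "included",
) -> pd.DataFrame:
    """Run the per-receptor fits for one predictor mode.

    Returns the ``regression.csv`` layout (one row per receptor).
    ``signals`` is the PT-level scan output; for the ICD-excluding mode a
    termset is required so ICD PT rows can be removed before medians are
    recomputed.  Receptors reduced below three points by missing
    predictors or missing medians are dropped with a logged notice.
    """
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}; expected one of {MODES}")
    predictor = _PREDICTOR_OF[mode]
    sig = signals[signals["level"] == "pt"]
    if mode == "excl_icd_activity_signed":
        if termset is None:
            raise ValueError("excl_icd_activity_signed mode requires a termset")
        sig = sig[~sig["event"].isin(termset.icd_related)]
    if drugs is None:
        drugs = sorted(sig["drug"].unique())
    drugs = [d for d in drugs if d not in set(exclude_drugs)]
    medians = median_ror_table(sig, drugs, over=median_over)

    occ = occ_table[~occ_table["drug"].isin(set(exclude_drugs))]
    rows = []
    for receptor, grp in occ.groupby("receptor"):
        pts = grp.dropna(subset=[predictor]).merge(
            medians.rename("median_ror"), left_on="drug", right_index=True
        )
        pts = pts.dropna(subset=["median_ror"])
        if len(pts) < MIN_POINTS:
            logger.info(
                "receptor %s dropped in mode %s: only %d usable points",
                receptor,
                mode,
                len(pts),
            )
            continue
        fit = fit_univariate(
            pts[predictor], pts["median_ror"], receptor=receptor, predictor_kind=mode
        )
        rows.append(
            {
                "receptor": receptor,
                "mode": mode,
                "beta": fit.beta,
                "intercept": fit.intercept,
                "p_value": fit.p_value,
                "r2": fit.r2,
                "n_points": fit.n_points,
            }
        )
    return pd.DataFrame(rows, columns=REGRESSION_COLUMNS)


def regression_all_modes(
    signals: pd.DataFrame,
    occ_table: pd.DataFrame,
    termset=None,
    **kwargs,
) -> pd.DataFrame:
    """All four predictor modes stacked into one table."""
    return pd.concat(
        [
            regression_suite(signals, occ_table, mode=m, termset=termset, **kwargs)
            for m in MODES
        ],
        ignore_index=True,
    )
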