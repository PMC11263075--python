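"""Case/non-case disproportionality estimation (ROR and IC).

A case is a report whose primary-suspect (PS) drug is the target drug and
whose reactions include at least one event PT; non-cases are all other
reports in the supplied dataset.  Each report contributes exactly once to
the 2x2 table; suspect roles other than PS (SS/C/I) never count as
exposure.

Estimators
----------
ROR
    (a*d)/(b*c) with a Woolf (log-normal) 95% confidence interval,
    ``exp(ln ROR +/- 1.96*sqrt(1/a + 1/b + 1/c + 1/d))``.  A zero cell
    leaves the estimate undefined (NaN) rather than silently corrected.
IC
    Observed-to-expected shrinkage information component,
    ``IC = log2((a + 0.5) / (E + 0.5))`` with ``E = (a+b)(a+c)/n``, and
    the credibility lower bound
    ``IC_025 = IC - 3.3*(a+0.5)^(-1/2) - 2.0*(a+0.5)^(-3/2)``.

A drug-PT pair enters downstream analyses only when its case count
exceeds 3 (``a >= 4``); a pair is a signal when ROR_025 > 1 (ROR) or
IC_025 > 0 (IC).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .termsets import TermSet, SUBGROUPS, normalize_pt

logger = logging.getLogger(__name__)

#: minimum case count for a pair to be included ("greater than 3")
MIN_CASES = 4

_Z975 = 1.959963984540054  # two-sided 95% normal quantile

SIGNAL_COLUMNS = [
    "drug",
    "event",
    "level",
    "a",
    "b",
    "c",
    "d",
    "ror",
    "ror_lo",
    "ror_hi",
    "ic",
    "ic_lo",
    "significant_ror",
    "significant_ic",
    "included",
]


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 counts for one drug-event pair (report-level)."""

    a: int  # PS=drug, event
    b: int  # PS=drug, no event
    c: int  # PS!=drug, event
    d: int  # PS!=drug, no event

    def __post_init__(self) -> None:
        for name in "abcd":
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"cell {name} must be a nonnegative integer, got {v}")

    @property
    def n_total(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def expected(self) -> float:
        """Expected case count under independence, E = (a+b)(a+c)/n."""
        if self.n_total == 0:
            return 0.0
        return (self.a + self.b) * (self.a + self.c) / self.n_total


@dataclass(frozen=True)
class SignalEstimate:
    """ROR/IC estimate with significance and inclusion flags for one pair."""

    drug: str
    event: str
    level: str  # "pt" or "subgroup"
    table: ContingencyTable
    ror: float
    ror_lo: float
    ror_hi: float
    ic: float
    ic_lo: float

    @property
    def n_cases(self) -> int:
        return self.table.a

    @property
    def significant_ror(self) -> bool:
        return bool(self.ror_lo > 1.0)

    @property
    def significant_ic(self) -> bool:
        return bool(self.ic_lo > 0.0)

    @property
    def included(self) -> bool:
        return include_pt(self.table)


def _dedup(frame: pd.DataFrame) -> pd.DataFrame:
    """Collapse duplicate (report_id, drug, role, pt) rows; keep last."""
    dup = frame.duplicated(["report_id", "drug", "role", "pt"], keep="last")
    if dup.any():
        logger.info("collapsing %d duplicate report rows (last wins)", int(dup.sum()))
        frame = frame[~dup]
    return frame


def report_index(frame: pd.DataFrame) -> pd.DataFrame:
    """Report-level view: one row per (report_id, pt) plus the PS drug.

    Precomputing this makes repeated 2x2 construction over many drugs and
    event sets cheap.  Reports without a PS row keep ``ps_drug = NaN`` and
    can only ever be non-cases for every drug.
    """
    frame = _dedup(frame)
    norm_pt = frame["pt"].map(normalize_pt)
    ps = (
        frame.loc[frame["role"] == "PS", ["report_id", "drug"]]
        .drop_duplicates("report_id", keep="last")
        .rename(columns={"drug": "ps_drug"})
    )
    pts = (
        frame.assign(pt=norm_pt)[["report_id", "pt"]]
        .drop_duplicates()
        .merge(ps, on="report_id", how="left")
    )
    return pts


def _as_report_index(reports) -> pd.DataFrame:
    from .synthetic_faers import reports_to_frame  # local: avoid cycle at import

    if isinstance(reports, pd.DataFrame):
        if set(reports.columns) == {"report_id", "pt", "ps_drug"}:
            return reports
        return report_index(reports)
    return report_index(reports_to_frame(reports))


def build_table(reports, drug: str, event_pts) -> ContingencyTable:
    """Build the 2x2 table for one drug against one event PT set.

    ``reports`` may be a list of AEReport objects, a flat report frame, or
    a precomputed :func:`report_index` frame.
    """
    idx = _as_report_index(reports)
    if idx.empty:
        logger.warning("build_table called on an empty report set")
        return ContingencyTable(0, 0, 0, 0)
    event_pts = {normalize_pt(p) for p in event_pts}
    ev_ids = idx.loc[idx["pt"].isin(event_pts), "report_id"].unique()
    per_report = idx.drop_duplicates("report_id")[["report_id", "ps_drug"]]
    exposed = per_report["ps_drug"] == drug
    event = per_report["report_id"].isin(ev_ids)
    a = int((exposed & event).sum())
    b = int((exposed & ~event).sum())
    c = int((~exposed & event).sum())
    d = int((~exposed & ~event).sum())
    return ContingencyTable(a, b, c, d)


def ror_estimate(t: ContingencyTable) -> tuple[float, float, float]:
    """Point estimate and Woolf 95% CI for the reporting odds ratio.

    Any zero cell yields ``(nan, nan, nan)``: the estimate is undefined,
    not corrected.
    """
    if min(t.a, t.b, t.c, t.d) == 0:
        return (math.nan, math.nan, math.nan)
    ror = (t.a * t.d) / (t.b * t.c)
    se = math.sqrt(1 / t.a + 1 / t.b + 1 / t.c + 1 / t.d)
    return (ror, ror * math.exp(-_Z975 * se), ror * math.exp(_Z975 * se))


def ic_estimate(t: ContingencyTable) -> tuple[float, float]:
    """Shrinkage information component and its 2.5% credibility bound."""
    if t.n_total <= 0:
        raise ValueError("IC undefined for an empty table")
    o = t.a + 0.5
    ic = math.log2(o / (t.expected + 0.5))
    ic_lo = ic - 3.3 * o ** -0.5 - 2.0 * o ** -1.5
    return (ic, ic_lo)


def include_pt(t: ContingencyTable) -> bool:
    """Inclusion filter: case count must exceed 3."""
    return t.a >= MIN_CASES


def estimate_signal(
    t: ContingencyTable, drug: str, event: str, level: str = "pt"
) -> SignalEstimate:
    ror, lo, hi = ror_estimate(t)
    ic, ic_lo = ic_estimate(t) if t.n_total > 0 else (math.nan, math.nan)
    return SignalEstimate(drug, event, level, t, ror, lo, hi, ic, ic_lo)


def _scan_counts(idx: pd.DataFrame, drugs, pt_sets: dict) -> list:
    """Shared counting core: (drug, label, a, b, c, d) for each pt set."""
    per_report_ps = (
        idx.drop_duplicates("report_id").set_index("report_id")["ps_drug"]
    )
    n_total = len(per_report_ps)
    ps_totals = per_report_ps.value_counts()
    out = []
    for label, pts in pt_sets.items():
        ev_reports = idx.loc[idx["pt"].isin(pts), "report_id"].unique()
        ev_ps = per_report_ps.loc[ev_reports]
        a_by_drug = ev_ps.value_counts()
        n_event = len(ev_reports)
        for drug in drugs:
            a = int(a_by_drug.get(drug, 0))
            n_ps = int(ps_totals.get(drug, 0))
            b = n_ps - a
            c = n_event - a
            d = n_total - a - b - c
            out.append((drug, label, a, b, c, d))
    return out


def signal_scan(reports, drugs, termset: TermSet) -> pd.DataFrame:
    """Full disproportionality scan: drug x PT and drug x subgroup estimates.

    Returns one row per drug x SD PT (``level='pt'``) and per drug x
    symptom subgroup (``level='subgroup'``, a report counting once per
    subgroup when any member PT is present), with ROR/IC statistics and
    flags, in the ``signals.csv`` layout.
    """
    idx = _as_report_index(reports)
    sd_pts = termset.sd_event_pts()
    if not sd_pts:
        raise ValueError("termset has no SD event PTs; refusing to scan")
    pt_sets = {pt: {pt} for pt in sorted(sd_pts)}
    counts = _scan_counts(idx, drugs, pt_sets)
    rows = [(d, ev, "pt", a, b, c, dd) for d, ev, a, b, c, dd in counts]
    sub_sets = {
        sg: termset.subgroup_pts(sg) for sg in SUBGROUPS if termset.subgroup_pts(sg)
    }
    counts = _scan_counts(idx, drugs, sub_sets)
    rows += [(d, ev, "subgroup", a, b, c, dd) for d, ev, a, b, c, dd in counts]

    records = []
    for drug, event, level, a, b, c, d in rows:
        t = ContingencyTable(a, b, c, d)
        est = estimate_signal(t, drug, event, level)
        records.append(
            {
                "drug": drug,
                "event": event,
                "level": level,
                "a": a,
                "b": b,
                "c": c,
                "d": d,
                "ror": est.ror,
                "ror_lo": est.ror_lo,
                "ror_hi": est.ror_hi,
                "ic": est.ic,
                "ic_lo": est.ic_lo,
                "significant_ror": est.significant_ror,
                "significant_ic": est.significant_ic,
                "included": est.included,
            }
        )
    return pd.DataFrame(records, columns=SIGNAL_COLUMNS)


def median_ror(
    signals: pd.DataFrame, drug: str, over: str = "included"
) -> float:
    """Per-drug median ROR over PT-level estimates.

    ``over='included'`` takes all PT estimates passing the case-count
    filter; ``over='significant'`` restricts further to ROR signals.
    Returns NaN (with a logged notice) when no estimate qualifies, which
    drops the drug from the regression stage.
    """
    if over not in ("included", "significant"):
        raise ValueError(f"unknown median_over mode {over!r}")
    rows = signals[
        (signals["drug"] == drug)
        & (signals["level"] == "pt")
        & signals["included"]
        & signals["ror"].notna()
    ]
    if over == "significant":
        rows = rows[rows["significant_ror"]]
    if rows.empty:
        logger.info("drug %r has no qualifying PT estimates; excluded", drug)
        return math.nan
    return float(np.median(rows["ror"]))


def median_ror_table(
    signals: pd.DataFrame, drugs, over: str = "included"
) -> pd.Series:
    """Median ROR per drug (NaN where a drug has no qualifying estimate)."""
    return pd.Series(
        {d: median_ror(signals, d, over=over) for d in drugs}, name="median_ror"
    )
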