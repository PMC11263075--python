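"""Sensitivity analyses for the disproportionality arm.

Two report-level checks probe the robustness of the drug-level
sexual-dysfunction signal:

* a time-window split around the May-2016 regulatory warning on
  impulse-control disorders (notoriety bias): reports are re-analysed
  separately before and after the warning, with the straddling gap
  excluded from both windows;
* a rare-PT exclusion: PTs mentioned fewer than ``min_total`` times in
  the whole dataset (any drug, any role) are removed from the event set
  to guard against high signals built on a handful of reports.

Window boundaries are quarter-resolved.  The defaults round the study's
month boundaries inward to whole quarters: pre-warning 2004Q1-2015Q1,
post-warning 2016Q3-2023Q3; the 2015Q2-2016Q2 gap belongs to neither.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .disproportionality import build_table, estimate_signal, report_index
from .termsets import TermSet, normalize_pt

logger = logging.getLogger(__name__)

DEFAULT_WINDOWS = (
    ("pre_warning", "2004Q1", "2015Q1"),
    ("post_warning", "2016Q3", "2023Q3"),
)

SENSITIVITY_COLUMNS = ["drug", "analysis", "n", "ror", "ror_lo", "ror_hi"]


@dataclass(frozen=True)
class SensitivitySpec:
    windows: tuple = DEFAULT_WINDOWS
    min_pt_total_reports: int = 500
    icd_exclusion: bool = True

    def __post_init__(self) -> None:
        if self.min_pt_total_reports < 0:
            raise ValueError("min_pt_total_reports must be >= 0")
        spans = sorted(
            (pd.Period(s, freq="Q"), pd.Period(e, freq="Q")) for _, s, e in self.windows
        )
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            if s2 <= e1:
                raise ValueError("sensitivity windows overlap")


def _window_mask(quarters: pd.Series, start: str, end: str) -> pd.Series:
    q = pd.PeriodIndex(quarters, freq="Q")
    return pd.Series(
        (q >= pd.Period(start, freq="Q")) & (q <= pd.Period(end, freq="Q")),
        index=quarters.index,
    )


def window_scan(
    reports: pd.DataFrame, drugs, termset: TermSet, windows=DEFAULT_WINDOWS
) -> pd.DataFrame:
    """Drug-level pooled-SD disproportionality per time window.

    Each window is analysed in isolation (its own comparator background);
    the event is "any SD PT".  Returns the ``sensitivity_ror.csv`` layout
    with one row per drug per window.
    """
    sd_pts = termset.sd_event_pts()
    rows = []
    for label, start, end in windows:
        sub = reports[_window_mask(reports["quarter"], start, end)]
        if sub.empty:
            logger.info("window %s (%s..%s) contains no reports", label, start, end)
            continue
        idx = report_index(sub)
        for drug in drugs:
            t = build_table(idx, drug, sd_pts)
            est = estimate_signal(t, drug, "sd_pooled", level="subgroup")
            rows.append(
                {
                    "drug": drug,
                    "analysis": label,
                    "n": t.a,
                    "ror": est.ror,
                    "ror_lo": est.ror_lo,
                    "ror_hi": est.ror_hi,
                }
            )
    return pd.DataFrame(rows, columns=SENSITIVITY_COLUMNS)


def exclude_rare_pts(
    reports: pd.DataFrame, termset: TermSet, min_total: int = 500
) -> frozenset:
    """SD PTs surviving the dataset-wide rarity filter.

    A PT is kept iff the number of distinct reports mentioning it across
    the whole dataset (any drug, any role) is at least ``min_total``
    ("fewer than" is strict).  ``min_total=0`` is the identity filter.
    """
    sd_pts = termset.sd_event_pts()
    counts = (
        reports.assign(pt=reports["pt"].map(normalize_pt))
        .drop_duplicates(["report_id", "pt"])
        .groupby("pt")["report_id"]
        .size()
    )
    return frozenset(pt for pt in sd_pts if int(counts.get(pt, 0)) >= min_total)


def rare_pt_scan(
    reports: pd.DataFrame, drugs, termset: TermSet, min_total: int = 500
) -> pd.DataFrame:
    """Drug-level pooled-SD estimates after the rare-PT exclusion."""
    kept = exclude_rare_pts(reports, termset, min_total)
    idx = report_index(reports)
    rows = []
    for drug in drugs:
        t = build_table(idx, drug, kept)
        est = estimate_signal(t, drug, "sd_pooled", level="subgroup")
        rows.append(
            {
                "drug": drug,
                "analysis": "excl_rare_pt",
                "n": t.a,
                "ror": est.ror,
                "ror_lo": est.ror_lo,
                "ror_hi": est.ror_hi,
            }
        )
    return pd.DataFrame(rows, columns=SENSITIVITY_COLUMNS)


def sensitivity_suite(
    reports: pd.DataFrame, drugs, termset: TermSet, spec: SensitivitySpec | None = None
) -> pd.DataFrame:
    """Window split plus rare-PT exclusion, stacked in one table."""
    spec = spec or SensitivitySpec()
    parts = [window_scan(reports, drugs, termset, spec.windows)]
    parts.append(rare_pt_scan(reports, drugs, termset, spec.min_pt_total_reports))
    return pd.concat(parts, ignore_index=True)
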