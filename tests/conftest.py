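import pandas as pd
import pytest

from pvpd.synthetic_faers import AEReport, reports_to_frame
from pvpd.termsets import TermSet, default_termset


@pytest.fixture(scope="session")
def termset() -> TermSet:
    return default_termset()


def make_report(rid, ps_drug, pts, conc=None, quarter="2010Q1", **kw):
    """Minimal AEReport with one PS drug and optional concomitant decoys."""
    entries = [(ps_drug, "PS")] + [(d, "C") for d in (conc or [])]
    defaults = dict(
        age_years=30.0,
        sex="M",
        country="US",
        indication="missing",
        outcome="other",
        daily_dose_mg=None,
    )
    defaults.update(kw)
    return AEReport(
        report_id=rid,
        drug_entries=tuple(entries),
        reaction_pts=tuple(pts),
        quarter=quarter,
        **defaults,
    )


@pytest.fixture
def six_reports():
    """Hand-enumerable 2x2 example for drugA vs event {ptX}.

    Two PS-drugA reports with the event, one report carrying drugA only
    as concomitant (never exposure), one PS-drugA report without the
    event, two PS-other reports with the event:
    a=2, b=1, c=3, d=0.
    """
    return [
        make_report("r1", "drugA", ["ptX"]),
        make_report("r2", "drugA", ["ptX", "ptY"]),
        make_report("r3", "other", ["ptX"], conc=["drugA"]),
        make_report("r4", "drugA", ["ptY"]),
        make_report("r5", "other", ["ptX"]),
        make_report("r6", "other", ["ptX"]),
    ]


@pytest.fixture
def six_reports_frame(six_reports) -> pd.DataFrame:
    return reports_to_frame(six_reports)
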