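"""2x2 construction, ROR/IC estimation, filters, and the brute-force oracle."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from pvpd.disproportionality import (
    ContingencyTable,
    build_table,
    ic_estimate,
    include_pt,
    median_ror,
    median_ror_table,
    ror_estimate,
    signal_scan,
)
from pvpd.synthetic_faers import generate_frame, GeneratorConfig, reports_to_frame
from pvpd.termsets import TermSet
from tests.conftest import make_report

Z = 1.959963984540054


# ---------------------------------------------------------------- oracles


def brute_force_table(reports, drug, event_pts):
    """Recount the 2x2 from scratch by looping over report objects."""
    a = b = c = d = 0
    for r in reports:
        exposed = any(dr == drug and role == "PS" for dr, role in r.drug_entries)
        event = any(pt in event_pts for pt in r.reaction_pts)
        if exposed and event:
            a += 1
        elif exposed:
            b += 1
        elif event:
            c += 1
        else:
            d += 1
    return a, b, c, d


def brute_force_or_ci(a, b, c, d):
    from fractions import Fraction

    orr = float(Fraction(a * d, b * c))  # correctly rounded exact rational
    half = Z * math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    log_or = math.log(a / b) - math.log(c / d)
    return orr, math.exp(log_or - half), math.exp(log_or + half)


def independent_ic(a, b, c, d):
    """IC via an independently written expression (natural logs)."""
    n = a + b + c + d
    e = (a + b) * (a + c) / n
    ic = (math.log(a + 0.5) - math.log(e + 0.5)) / math.log(2)
    lo = ic - 3.3 / math.sqrt(a + 0.5) - 2.0 / (a + 0.5) ** 1.5
    return ic, lo


# ---------------------------------------------------------------- build_table


class TestBuildTable:
    def test_hand_enumerated_six_reports(self, six_reports):
        t = build_table(six_reports, "drugA", {"ptX"})
        assert (t.a, t.b, t.c, t.d) == (2, 1, 3, 0)

    def test_accepts_flat_frame(self, six_reports, six_reports_frame):
        t = build_table(six_reports_frame, "drugA", {"ptX"})
        assert (t.a, t.b, t.c, t.d) == (2, 1, 3, 0)

    def test_concomitant_role_is_not_exposure(self):
        reports = [make_report("r1", "other", ["ptX"], conc=["drugA"])]
        t = build_table(reports, "drugA", {"ptX"})
        assert (t.a, t.b) == (0, 0) and t.c == 1

    def test_unmentioned_drug(self, six_reports):
        t = build_table(six_reports, "ghost", {"ptX"})
        assert (t.a, t.b) == (0, 0)
        assert t.c + t.d == 6

    def test_saturating_event_set(self, six_reports):
        t = build_table(six_reports, "drugA", {"ptX", "ptY"})
        assert t.b == 0 and t.d == 0

    def test_empty_reports_warns_and_zeroes(self, caplog):
        t = build_table([], "drugA", {"ptX"})
        assert (t.a, t.b, t.c, t.d) == (0, 0, 0, 0)

    def test_duplicate_rows_counted_once(self, six_reports_frame):
        doubled = pd.concat([six_reports_frame, six_reports_frame])
        t = build_table(doubled, "drugA", {"ptX"})
        assert (t.a, t.b, t.c, t.d) == (2, 1, 3, 0)

    def test_pt_matching_case_insensitive(self, six_reports):
        t = build_table(six_reports, "drugA", {"PtX "})
        assert t.a == 2

    @settings(derandomize=True, max_examples=200, deadline=None)
    @given(st.data())
    def test_oracle_equivalence_random_small_sets(self, data):
        """build_table + ror_estimate == brute-force recount + direct OR."""
        n = data.draw(st.integers(5, 40))
        drugs = ["drugA", "drugB", "other"]
        pts = ["ptX", "ptY"]
        reports = []
        for i in range(n):
            ps = data.draw(st.sampled_from(drugs))
            rpts = data.draw(st.lists(st.sampled_from(pts), min_size=1, max_size=2,
                                      unique=True))
            conc = data.draw(st.lists(st.sampled_from(drugs), max_size=1))
            reports.append(make_report(f"r{i}", ps, rpts, conc=[d for d in conc if d != ps]))
        a, b, c, d = brute_force_table(reports, "drugA", {"ptX"})
        t = build_table(reports, "drugA", {"ptX"})
        assert (t.a, t.b, t.c, t.d) == (a, b, c, d)
        ror, lo, hi = ror_estimate(t)
        if min(a, b, c, d) == 0:
            assert math.isnan(ror)
        else:
            exp_or, exp_lo, exp_hi = brute_force_or_ci(a, b, c, d)
            assert ror == exp_or
            assert lo == pytest.approx(exp_lo, rel=1e-12)
            assert hi == pytest.approx(exp_hi, rel=1e-12)


# ---------------------------------------------------------------- ROR


class TestRor:
    def test_hand_arithmetic(self):
        ror, lo, hi = ror_estimate(ContingencyTable(10, 90, 100, 9900))
        assert ror == pytest.approx(11.0)
        exp_or, exp_lo, exp_hi = brute_force_or_ci(10, 90, 100, 9900)
        assert (lo, hi) == (pytest.approx(exp_lo), pytest.approx(exp_hi))

    def test_statsmodels_cross_check(self):
        import statsmodels.api as sm

        tab = sm.stats.Table2x2([[10, 90], [100, 9900]])
        ror, lo, hi = ror_estimate(ContingencyTable(10, 90, 100, 9900))
        assert ror == pytest.approx(tab.oddsratio, rel=1e-12)
        sm_lo, sm_hi = tab.oddsratio_confint(0.05)
        assert lo == pytest.approx(sm_lo, rel=1e-9)
        assert hi == pytest.approx(sm_hi, rel=1e-9)

    def test_balanced_table_symmetric_about_one(self):
        ror, lo, hi = ror_estimate(ContingencyTable(50, 50, 50, 50))
        assert ror == pytest.approx(1.0)
        assert lo * hi == pytest.approx(1.0)

    def test_doubling_preserves_point_narrows_ci(self):
        r1, lo1, hi1 = ror_estimate(ContingencyTable(10, 90, 100, 9900))
        r2, lo2, hi2 = ror_estimate(ContingencyTable(20, 180, 200, 19800))
        assert r2 == pytest.approx(r1)
        assert hi2 / lo2 < hi1 / lo1

    @pytest.mark.parametrize("cells", [(0, 5, 5, 5), (5, 0, 5, 5), (5, 5, 0, 5), (5, 5, 5, 0)])
    def test_zero_cell_undefined(self, cells):
        ror, lo, hi = ror_estimate(ContingencyTable(*cells))
        assert math.isnan(ror) and math.isnan(lo) and math.isnan(hi)

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(
        a=st.integers(1, 500), b=st.integers(1, 500),
        c=st.integers(1, 500), d=st.integers(1, 500),
    )
    def test_monotone_in_a(self, a, b, c, d):
        r1, *_ = ror_estimate(ContingencyTable(a, b, c, d))
        r2, *_ = ror_estimate(ContingencyTable(a + 1, b, c, d))
        assert r2 > r1


# ---------------------------------------------------------------- IC


class TestIc:
    def test_zero_when_observed_equals_expected(self):
        # rows (100, 900), cols (100, 900), n=1000 -> E = 10 = a
        t = ContingencyTable(10, 90, 90, 810)
        assert t.expected == pytest.approx(10.0)
        ic, lo = ic_estimate(t)
        assert ic == pytest.approx(0.0)
        assert lo < ic

    def test_zero_observed_shrinks_negative(self):
        t = ContingencyTable(0, 100, 100, 800)
        ic, lo = ic_estimate(t)
        assert ic < 0 and lo < ic

    def test_independent_formula_cross_check(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            a, b, c, d = rng.integers(0, 400, size=4)
            if a + b + c + d == 0:
                continue
            t = ContingencyTable(int(a), int(b), int(c), int(d))
            ic, lo = ic_estimate(t)
            exp_ic, exp_lo = independent_ic(a, b, c, d)
            assert ic == pytest.approx(exp_ic, rel=1e-12, abs=1e-12)
            assert lo == pytest.approx(exp_lo, rel=1e-12, abs=1e-12)
            assert lo < ic

    def test_monotone_in_a(self):
        ic1, _ = ic_estimate(ContingencyTable(5, 95, 100, 9800))
        ic2, _ = ic_estimate(ContingencyTable(6, 94, 100, 9800))
        assert ic2 > ic1

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            ic_estimate(ContingencyTable(0, 0, 0, 0))


# ---------------------------------------------------------------- filters, medians


class TestInclusion:
    @pytest.mark.parametrize("a,expected", [(0, False), (3, False), (4, True), (10, True)])
    def test_threshold(self, a, expected):
        assert include_pt(ContingencyTable(a, 10, 10, 10)) is expected


class TestMedianRor:
    def make_signals(self, rors, included=None, significant=None):
        k = len(rors)
        return pd.DataFrame(
            {
                "drug": ["drugA"] * k,
                "event": [f"pt{i}" for i in range(k)],
                "level": ["pt"] * k,
                "ror": rors,
                "included": included or [True] * k,
                "significant_ror": significant or [True] * k,
            }
        )

    def test_even_count_midpoint(self):
        assert median_ror(self.make_signals([2.0, 8.0]), "drugA") == 5.0

    def test_odd_count(self):
        assert median_ror(self.make_signals([1.0, 10.0, 100.0]), "drugA") == 10.0

    def test_single_included(self):
        sig = self.make_signals([2.0, 8.0], included=[True, False])
        assert median_ror(sig, "drugA") == 2.0

    def test_significant_only_mode(self):
        sig = self.make_signals([2.0, 8.0], significant=[False, True])
        assert median_ror(sig, "drugA", over="significant") == 8.0

    def test_no_qualifying_gives_nan(self):
        sig = self.make_signals([2.0], included=[False])
        assert math.isnan(median_ror(sig, "drugA"))

    def test_invalid_mode(self):
        with pytest.raises(ValueError):
            median_ror(self.make_signals([2.0]), "drugA", over="all")


# ---------------------------------------------------------------- signal_scan


def _mini_termset():
    hlgt = "sexual function and fertility disorders"
    return TermSet(
        pt_names=frozenset({"ptx", "pty", "ptz"}),
        hlgt_of={"ptx": hlgt, "pty": hlgt, "ptz": hlgt},
        subgroup_of={"ptx": "erectile_dysfunction", "pty": "hyposexuality",
                     "ptz": "hyposexuality"},
        icd_related=frozenset(),
    )


class TestSignalScan:
    def test_singleton_subgroup_equals_pt_level(self):
        cfg = GeneratorConfig(
            n_reports=4000,
            drugs={"drugA": 0.2, "other": 0.8},
            pts={"ptx": 0.05, "pty": 0.05, "ptz": 0.02},
            planted_effects={("drugA", "ptx"): 3.0},
            seed=9,
        )
        sig = signal_scan(generate_frame(cfg), ["drugA"], _mini_termset())
        pt_row = sig[(sig.level == "pt") & (sig.event == "ptx")].iloc[0]
        sg_row = sig[(sig.level == "subgroup") & (sig.event == "erectile_dysfunction")].iloc[0]
        assert (pt_row.a, pt_row.b, pt_row.c, pt_row.d) == (sg_row.a, sg_row.b, sg_row.c, sg_row.d)
        assert pt_row.ror == sg_row.ror

    def test_planted_pair_significant_both_ways(self):
        cfg = GeneratorConfig(
            n_reports=20_000,
            drugs={"drugA": 0.1, "other": 0.9},
            pts={"ptx": 0.01, "pty": 0.05},
            planted_effects={("drugA", "ptx"): 10.0},
            seed=21,
        )
        sig = signal_scan(generate_frame(cfg), ["drugA"], _mini_termset())
        row = sig[(sig.level == "pt") & (sig.event == "ptx")].iloc[0]
        assert row.included and row.significant_ror and row.significant_ic

    def test_empty_termset_refused(self, six_reports_frame):
        with pytest.raises(ValueError, match="no SD"):
            signal_scan(six_reports_frame, ["drugA"], TermSet())

    def test_multi_subgroup_report_counts_once_per_subgroup(self):
        # one report with two PTs of the same subgroup -> a=1 there
        reports = [
            make_report("r1", "drugA", ["ptY", "ptZ"]),
            make_report("r2", "other", ["ptX"]),
            make_report("r3", "other", ["ptX"]),
        ]
        ts = _mini_termset()
        sig = signal_scan(reports_to_frame(reports), ["drugA"], ts)
        row = sig[(sig.level == "subgroup") & (sig.event == "hyposexuality")].iloc[0]
        assert row.a == 1

    def test_median_table_matches_median_ror(self):
        cfg = GeneratorConfig(
            n_reports=20_000,
            drugs={"drugA": 0.1, "other": 0.9},
            pts={"ptx": 0.02, "pty": 0.02},
            planted_effects={("drugA", "ptx"): 4.0},
            seed=3,
        )
        sig = signal_scan(generate_frame(cfg), ["drugA"], _mini_termset())
        tbl = median_ror_table(sig, ["drugA"])
        assert tbl["drugA"] == median_ror(sig, "drugA")
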