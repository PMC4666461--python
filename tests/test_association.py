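"""Endpoint labels, Fisher scan, odds ratios and region aggregation."""

import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import cnvsig
from cnvsig.association import ContingencyTable


def enumerate_fisher_p(a, b, c, d):
    """Independent oracle: two-sided exact p by full hypergeometric enumeration.

    Sums P(table) over all tables with the observed margins whose point
    probability does not exceed the observed table's (with a small relative
    tolerance for float ties, as the implementation uses).
    """
    row1, col1, n = a + b, a + c, a + b + c + d
    def prob(x):
        return (math.comb(col1, x) * math.comb(n - col1, row1 - x)
                / math.comb(n, row1))
    p_obs = prob(a)
    total = 0.0
    for x in range(max(0, row1 - (n - col1)), min(row1, col1) + 1):
        px = prob(x)
        if px <= p_obs * (1 + 1e-7):
            total += px
    return min(1.0, total)


def make_records(rows):
    frame = pd.DataFrame(rows)
    frame["patient_id"] = [f"P{i}" for i in range(len(rows))]
    return frame.set_index("patient_id", drop=False)


def record(followup, event=False, death=False, never_free=False, rec=np.nan):
    return dict(followup_months=followup, disease_event_flag=event,
                death_from_disease_flag=death, never_disease_free_flag=never_free,
                recurrence_months=rec, igcccg_risk="good", batch="train")


class TestEndpointLabels:
    def test_disease_death_at_36_months_poor_5ydss(self):
        records = make_records([record(36, event=True, death=True, rec=20)])
        labels = cnvsig.derive_endpoint_labels(records, "5yDSS")
        assert labels.iloc[0] == "poor"

    def test_never_disease_free_alive_72_months(self):
        records = make_records([record(72, event=True, never_free=True)])
        assert cnvsig.derive_endpoint_labels(records, "2yDFS").iloc[0] == "poor"
        assert cnvsig.derive_endpoint_labels(records, "5yDSS").iloc[0] == "good"

    def test_censored_at_40_months_ineligible_5ydss(self):
        records = make_records([record(40)])
        assert cnvsig.derive_endpoint_labels(records, "5yDSS").iloc[0] == "ineligible"
        assert cnvsig.derive_endpoint_labels(records, "2yDFS").iloc[0] == "good"

    def test_late_recurrence_good_2ydfs(self):
        records = make_records([record(80, event=True, rec=30)])
        assert cnvsig.derive_endpoint_labels(records, "2yDFS").iloc[0] == "good"

    def test_contradictory_flags_raise(self):
        records = make_records([record(30, event=False, death=True)])
        with pytest.raises(ValueError):
            cnvsig.derive_endpoint_labels(records, "5yDSS")

    def test_unknown_endpoint_rejected(self):
        with pytest.raises(ValueError):
            cnvsig.derive_endpoint_labels(make_records([record(10)]), "3yOS")


class TestFisher:
    def test_proportional_rows_p_one(self):
        assert cnvsig.fisher_exact(ContingencyTable(5, 5, 20, 20)) == pytest.approx(1.0)

    def test_worked_value_34_over_70(self):
        p = cnvsig.fisher_exact(ContingencyTable(3, 1, 1, 3))
        assert p == pytest.approx(float(Fraction(34, 70)), abs=1e-12)

    def test_zero_margin_warns_p_one(self):
        with pytest.warns(UserWarning):
            assert cnvsig.fisher_exact(ContingencyTable(0, 0, 3, 4)) == 1.0

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a, b, c, d = rng.integers(1, 11, size=4)
        p = cnvsig.fisher_exact(ContingencyTable(int(a), int(b), int(c), int(d)))
        assert p == pytest.approx(enumerate_fisher_p(int(a), int(b), int(c), int(d)),
                                  abs=1e-9)

    def test_all_altered_poor_one_sided_tail(self):
        # b = 0: the observed table is the most extreme in its own direction,
        # so the two-sided sum includes at least the one-sided tail
        t = ContingencyTable(7, 0, 10, 20)
        p = cnvsig.fisher_exact(t)
        tail = stats.hypergeom.pmf(7, 37, 17, 7)
        assert p >= tail - 1e-12
        assert p == pytest.approx(enumerate_fisher_p(7, 0, 10, 20), abs=1e-9)


class TestOddsRatio:
    def test_symmetric_table_or_one(self):
        or_, lo, hi = cnvsig.odds_ratio(ContingencyTable(1, 1, 1, 1))
        assert or_ == 1.0 and lo < 1.0 < hi

    def test_sample_or_arithmetic(self):
        or_, _, _ = cnvsig.odds_ratio(ContingencyTable(20, 8, 6, 19))
        assert round(or_, 2) == 7.92

    def test_zero_b_infinite_without_ci(self):
        or_, lo, hi = cnvsig.odds_ratio(ContingencyTable(7, 0, 10, 20))
        assert or_ == math.inf and math.isnan(lo) and math.isnan(hi)

    def test_woolf_interval_hand_computed(self):
        t = ContingencyTable(10, 5, 4, 12)
        or_, lo, hi = cnvsig.odds_ratio(t)
        se = math.sqrt(1 / 10 + 1 / 5 + 1 / 4 + 1 / 12)
        z = stats.norm.ppf(0.975)
        assert lo == pytest.approx(or_ * math.exp(-z * se))
        assert hi == pytest.approx(or_ * math.exp(z * se))

    def test_exact_conditional_option(self):
        t = ContingencyTable(10, 5, 4, 12)
        or_w, lo_w, hi_w = cnvsig.odds_ratio(t, method="woolf")
        or_e, lo_e, hi_e = cnvsig.odds_ratio(t, method="exact")
        assert or_w == or_e
        assert lo_e < or_e < hi_e


class TestCloneAssociation:
    def _setup(self):
        clone_map = cnvsig.build_clone_map([4], 1.0)
        patients = [f"P{i}" for i in range(12)]
        calls = pd.DataFrame("normal", index=clone_map.clone_ids, columns=patients)
        calls.loc["BAC-1-0001", patients[:5]] = "gain"
        calls.loc["BAC-1-0002", patients[0]] = "missing"
        labels = pd.Series(["poor"] * 4 + ["good"] * 7 + ["ineligible"],
                           index=patients)
        return clone_map, calls, labels

    def test_table_built_over_eligible_nonmissing(self):
        clone_map, calls, labels = self._setup()
        assoc = cnvsig.clone_association(calls, labels, "BAC-1-0001", "gain")
        t = assoc.table
        assert (t.a, t.b, t.c, t.d) == (4, 1, 0, 6)
        assert t.n == 11  # the ineligible patient is excluded

    def test_missing_calls_shrink_margins(self):
        clone_map, calls, labels = self._setup()
        calls.loc["BAC-1-0001", "P1"] = "missing"
        assoc = cnvsig.clone_association(calls, labels, "BAC-1-0001", "gain")
        assert assoc.table.n == 10

    def test_no_altered_patients_skipped(self):
        clone_map, calls, labels = self._setup()
        assert cnvsig.clone_association(calls, labels, "BAC-1-0003", "loss") is None

    def test_all_altered_poor_infinite_or(self):
        clone_map = cnvsig.build_clone_map([2], 1.0)
        patients = [f"P{i}" for i in range(20)]
        calls = pd.DataFrame("normal", index=clone_map.clone_ids, columns=patients)
        calls.loc["BAC-1-0001", patients[:7]] = "loss"
        labels = pd.Series(["poor"] * 7 + ["good"] * 13, index=patients)
        assoc = cnvsig.clone_association(calls, labels, "BAC-1-0001", "loss")
        assert assoc.odds_ratio == math.inf
        assert math.isnan(assoc.ci_low)


class TestNullCalibration:
    def test_clone_scan_rejection_rate_at_most_alpha(self):
        """Null cohorts: per-clone Fisher rejections occur at most at rate
        alpha (the exact test is conservative for discrete tables)."""
        clone_map = cnvsig.build_clone_map([10], 1.0)
        alpha, rejections, tests = 0.05, 0, 0
        rng = np.random.default_rng(99)
        patients = [f"P{i}" for i in range(53)]
        for _ in range(200):
            states = rng.choice(["gain", "normal", "loss"], p=[0.2, 0.6, 0.2],
                                size=(10, 53))
            calls = pd.DataFrame(states, index=clone_map.clone_ids,
                                 columns=patients)
            labels = pd.Series(np.where(rng.random(53) < 0.4, "poor", "good"),
                               index=patients)
            scan = cnvsig.associate_all(calls, labels, clone_map)
            rejections += int((scan["p_value"] < alpha).sum())
            tests += len(scan)
        rate = rejections / tests
        se = math.sqrt(alpha * (1 - alpha) / tests)
        assert rate <= alpha + 3 * se
        assert rate > 0.001  # sanity: the scan does reject sometimes


def scan_frame(rows):
    """Helper: build an association frame with given (chrom, pos, type, p)."""
    return pd.DataFrame([{
        "clone_id": f"cl{i}", "chromosome": ch, "position_mb": pos,
        "alteration_type": alt, "a": 5, "b": 1, "c": 5, "d": 10,
        "n_altered": 6, "p_value": p, "odds_ratio": 10.0,
        "ci_low": 1.5, "ci_high": 60.0,
    } for i, (ch, pos, alt, p) in enumerate(rows)])


class TestBuildRegions:
    def _map(self):
        return cnvsig.build_clone_map([250], 1.0)

    def test_gap_within_cutoff_merges(self):
        for gap, n_expected in ((10.4, 1), (11.4, 1), (12.0, 2)):
            scan = scan_frame([(1, 10.0, "loss", 0.01),
                               (1, 10.0 + gap, "loss", 0.01)])
            regions = cnvsig.build_regions(scan, self._map())
            assert len(regions) == n_expected, gap

    def test_types_never_merge(self):
        scan = scan_frame([(1, 10.0, "gain", 0.01), (1, 11.0, "loss", 0.01)])
        regions = cnvsig.build_regions(scan, self._map())
        assert len(regions) == 2

    def test_order_invariance(self):
        rows = [(1, 30.0, "loss", 0.02), (1, 10.0, "loss", 0.01),
                (1, 35.0, "loss", 0.03), (2, 5.0, "gain", 0.04)]
        r1 = cnvsig.build_regions(scan_frame(rows), self._map())
        r2 = cnvsig.build_regions(scan_frame(rows[::-1]), self._map())
        assert [r.label for r in r1] == [r.label for r in r2]

    def test_monotone_in_gap_cutoff(self):
        rows = [(1, 10.0, "loss", 0.01), (1, 18.0, "loss", 0.01),
                (1, 40.0, "loss", 0.01)]
        counts = [len(cnvsig.build_regions(scan_frame(rows), self._map(),
                                           max_gap_mb=g))
                  for g in (5.0, 11.5, 25.0)]
        assert counts == sorted(counts, reverse=True)

    def test_representative_clone_min_p(self):
        scan = scan_frame([(1, 10.0, "loss", 0.04), (1, 12.0, "loss", 0.001)])
        region = cnvsig.build_regions(scan, self._map())[0]
        assert region.representative_clone == "cl1"
        assert region.p_value == 0.001

    def test_min_clones_and_single_clone_flag(self):
        scan = scan_frame([(1, 10.0, "loss", 0.01), (1, 50.0, "loss", 0.01),
                           (1, 52.0, "loss", 0.01)])
        regions = cnvsig.build_regions(scan, self._map(), min_clones=1)
        assert [r.single_clone for r in regions] == [True, False]
        assert len(cnvsig.build_regions(scan, self._map(), min_clones=2)) == 1

    def test_same_type_regions_never_overlap(self):
        rng = np.random.default_rng(2)
        rows = [(1, float(p), "gain", 0.01)
                for p in np.sort(rng.choice(200, 30, replace=False))]
        regions = cnvsig.build_regions(scan_frame(rows), self._map())
        for r1, r2 in zip(regions, regions[1:]):
            assert r1.end_mb < r2.start_mb


class TestGapStatsAndTable:
    def test_worked_gap_stats(self):
        clone_map = cnvsig.build_clone_map([60], 1.0)
        # positions 10, 10.5, 11.4, 13.6 -> gaps 0.5, 0.9, 2.2
        frame = pd.DataFrame({
            "clone_id": ["a", "b", "c", "d"],
            "chromosome": 1, "position_mb": [10.0, 10.5, 11.4, 13.6]})
        cm = cnvsig.CloneMap(frame)
        region = cnvsig.GenomicRegion(1, 10.0, 13.6, "loss",
                                      ["a", "b", "c", "d"], 5, 0.01, 5.0,
                                      1.2, 20.0, "a")
        med, mean = cnvsig.region_gap_stats([region], cm)
        assert med == pytest.approx(0.9)
        assert mean == pytest.approx(1.2)

    def test_single_gap(self):
        frame = pd.DataFrame({"clone_id": ["a", "b"], "chromosome": 1,
                              "position_mb": [3.0, 4.0]})
        cm = cnvsig.CloneMap(frame)
        region = cnvsig.GenomicRegion(1, 3.0, 4.0, "loss", ["a", "b"],
                                      5, 0.01, 5.0, 1.2, 20.0, "a")
        assert cnvsig.region_gap_stats([region], cm) == (1.0, 1.0)

    def test_no_multiclone_regions_error(self):
        frame = pd.DataFrame({"clone_id": ["a"], "chromosome": 1,
                              "position_mb": [3.0]})
        cm = cnvsig.CloneMap(frame)
        region = cnvsig.GenomicRegion(1, 3.0, 3.0, "loss", ["a"], 5, 0.01,
                                      5.0, 1.2, 20.0, "a", single_clone=True)
        with pytest.raises(ValueError):
            cnvsig.region_gap_stats([region], cm)

    def test_region_table_formats_inf(self):
        inf_region = cnvsig.GenomicRegion(9, 72.7, 120.8, "gain", ["x"], 7,
                                          0.017, math.inf, math.nan, math.nan,
                                          "x", single_clone=True)
        protective = cnvsig.GenomicRegion(12, 82.3, 83.6, "gain", ["y"], 14,
                                          0.041, 0.18, 0.04, 0.80, "y")
        table = cnvsig.region_table([inf_region, protective])
        assert table.loc[0, "OR"] == "INF"
        assert table.loc[0, "95% C.I."] == "N/A"
        assert table.loc[1, "OR"] == "0.18"

    def test_empty_region_table_header_only(self):
        table = cnvsig.region_table([])
        assert len(table) == 0
        assert "P Value" in table.columns
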