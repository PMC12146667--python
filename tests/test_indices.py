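"""Residency/roaming index formulas, the monthly rule, and the size split."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from islandrange import indices as idx


def _receivers(intervals):
    rows = []
    for i, (a, b) in enumerate(intervals):
        rows.append(
            dict(site=f"R{i+1}", lon=0.0, lat=0.0, x=0.0, y=0.0, depth_m=20.0,
                 active_from=pd.Timestamp(a), active_to=pd.Timestamp(b))
        )
    return pd.DataFrame(rows)


class TestDetectionPeriod:
    def test_single_day(self):
        ts = pd.Series(pd.to_datetime(["2021-03-01T10:00:00"]))
        assert idx.detection_period(
            ts, pd.Timestamp("2021-02-27"), tz_hours=0.0
        ) == 1

    def test_fifteen_days(self):
        ts = pd.Series(pd.to_datetime(["2021-03-05T10:00:00", "2021-03-15T10:00:00"]))
        assert idx.detection_period(
            ts, pd.Timestamp("2021-02-27"), tz_hours=0.0
        ) == 15

    def test_conventions_differ(self):
        ts = pd.Series(pd.to_datetime(["2021-03-15T10:00:00"]))
        release = pd.Timestamp("2021-03-01T00:00:00")
        post = idx.detection_period(ts, release, convention="post_release", tz_hours=0.0)
        tagging = idx.detection_period(ts, release, convention="tagging", tz_hours=0.0)
        assert (post, tagging) == (13, 15)

    def test_empty_is_an_error_not_zero(self):
        with pytest.raises(ValueError, match="undefined"):
            idx.detection_period(pd.Series([], dtype="datetime64[ns]"),
                                 pd.Timestamp("2021-01-01"))


class TestResidency:
    def test_worked_values(self):
        # 45 distinct days over a 100-day period
        days = pd.to_datetime([f"2021-01-01T06:00:00"]) .repeat(1)
        ts = pd.Series(pd.date_range("2021-01-01T06:00", periods=45, freq="D"))
        assert idx.residency_index(ts, 100, tz_hours=0.0) == pytest.approx(0.45)

    def test_detected_every_day_is_one(self):
        ts = pd.Series(pd.date_range("2021-01-01T06:00", periods=30, freq="D"))
        assert idx.residency_index(ts, 30, tz_hours=0.0) == 1.0

    def test_alternate_days(self):
        # detections every other day over a 30-day period: 15/30
        ts = pd.Series(pd.date_range("2021-01-01T06:00", periods=15, freq="2D"))
        assert idx.residency_index(ts, 30, tz_hours=0.0) == pytest.approx(0.5)


class TestRoaming:
    def test_worked_values(self):
        rec = _receivers([("2021-01-01", "2021-12-31")] * 18)
        det = pd.DataFrame(
            {"tag_id": "T", "receiver_id": [f"R{i+1}" for i in range(12)],
             "timestamp": pd.Timestamp("2021-06-01")}
        )
        roi, n_det, n_avail = idx.roaming_index(
            det, rec, pd.Timestamp("2021-05-01"), pd.Timestamp("2021-07-01")
        )
        assert roi == pytest.approx(12 / 18)
        det1 = det.iloc[:1]
        roi1, _, _ = idx.roaming_index(
            det1, rec, pd.Timestamp("2021-05-01"), pd.Timestamp("2021-07-01")
        )
        assert roi1 == pytest.approx(1 / 18)

    def test_availability_denominator_excludes_late_deployments(self):
        """3 of 21 receivers deployed after the animal's last detection do not
        count as available (brute-force interval-overlap oracle)."""
        intervals = [("2021-01-01", "2021-12-31")] * 18 + [
            ("2021-09-01", "2021-12-31")
        ] * 3
        rec = _receivers(intervals)
        start, end = pd.Timestamp("2021-02-01"), pd.Timestamp("2021-06-30")
        oracle = sum(
            1 for a, b in intervals
            if not (pd.Timestamp(b) < start or pd.Timestamp(a) > end)
        )
        det = pd.DataFrame(
            {"tag_id": "T", "receiver_id": ["R1", "R5"],
             "timestamp": pd.Timestamp("2021-03-01")}
        )
        roi, n_det, n_avail = idx.roaming_index(det, rec, start, end)
        assert n_avail == oracle == 18
        assert roi == pytest.approx(2 / 18)

    def test_no_available_sites_is_an_error(self):
        rec = _receivers([("2022-01-01", "2022-12-31")])
        det = pd.DataFrame(
            {"tag_id": "T", "receiver_id": ["R1"], "timestamp": pd.Timestamp("2021-03-01")}
        )
        with pytest.raises(ValueError, match="available"):
            idx.roaming_index(det, rec, pd.Timestamp("2021-01-01"), pd.Timestamp("2021-06-01"))

    def test_roi_monotone_in_availability(self):
        """Widening deployment windows can only leave RoI equal or smaller
        denominators... i.e. RoI is monotone non-increasing as more sites
        become available, and detected sites never exceed available ones."""
        rng = np.random.default_rng(0)
        det = pd.DataFrame(
            {"tag_id": "T", "receiver_id": ["R1", "R2", "R3"],
             "timestamp": pd.Timestamp("2021-03-01")}
        )
        start, end = pd.Timestamp("2021-02-01"), pd.Timestamp("2021-04-01")
        prev = None
        for n_active in range(3, 12):
            rec = _receivers([("2021-01-01", "2021-12-31")] * n_active)
            roi, n_det, n_avail = idx.roaming_index(det, rec, start, end)
            assert n_det <= n_avail
            if prev is not None:
                assert roi <= prev + 1e-12
            prev = roi


class TestMonthlyIndices:
    @staticmethod
    def _frame(det_days, release="2021-01-16T00:00:00"):
        det = pd.DataFrame(
            {
                "tag_id": "T1",
                "receiver_id": "R1",
                "timestamp": pd.to_datetime([f"{d}T10:00:00" for d in det_days]),
            }
        )
        tags = pd.DataFrame(
            {"tag_id": ["T1"], "species": ["dusky"], "release_time": [pd.Timestamp(release)]}
        )
        rec = _receivers([("2021-01-01", "2021-12-31")] * 3)
        return det, rec, tags

    def test_boundary_month_rule(self):
        """Period 2021-01-20 .. 2021-03-10: January covers 12 days and March
        10 days, so only February is retained."""
        det, rec, tags = self._frame(
            ["2021-01-20", "2021-02-05", "2021-03-10"], release="2021-01-18T00:00:00"
        )
        out = idx.monthly_indices(det, rec, tags, tz_hours=0.0)
        assert list(out["month"]) == [2]

    def test_full_month_daily_detection(self):
        days = [f"2021-04-{d:02d}" for d in range(1, 31)]
        det, rec, tags = self._frame(days + ["2021-05-20"], release="2021-03-29T00:00:00")
        out = idx.monthly_indices(det, rec, tags, tz_hours=0.0)
        april = out.loc[out["month"] == 4].iloc[0]
        assert april["resi"] == 1.0

    def test_partial_detection_hand_count(self):
        """20 detected days in a fully covered 31-day month -> 20/31."""
        days = [f"2021-05-{d:02d}" for d in range(1, 21)]
        det, rec, tags = self._frame(
            ["2021-04-10"] + days + ["2021-06-20"], release="2021-04-08T00:00:00"
        )
        out = idx.monthly_indices(det, rec, tags, tz_hours=0.0)
        may = out.loc[out["month"] == 5].iloc[0]
        assert may["resi"] == pytest.approx(20 / 31)
        assert may["period_days"] == 31

    def test_monthly_mean_identity(self):
        """Month-length-weighted mean of monthly ResI equals overall ResI when
        the period spans whole months exactly."""
        rng = np.random.default_rng(5)
        days = []
        for m, ndays in [(1, 31), (2, 28), (3, 31)]:
            chosen = rng.choice(np.arange(1, ndays + 1),
                                size=rng.integers(5, ndays), replace=False)
            days += [f"2021-{m:02d}-{d:02d}" for d in sorted(chosen)]
        # force endpoints so the period is exactly Jan 1 .. Mar 31
        days = sorted(set(days + ["2021-01-01", "2021-03-31"]))
        det, rec, tags = self._frame(days, release="2020-12-30T00:00:00")
        monthly = idx.monthly_indices(det, rec, tags, tz_hours=0.0)
        overall = idx.overall_indices(det, rec, tags, tz_hours=0.0)
        weighted = (monthly["resi"] * monthly["period_days"]).sum() / monthly[
            "period_days"
        ].sum()
        assert weighted == pytest.approx(overall["resi"].iloc[0], abs=1e-12)


class TestSizeSplit:
    def test_worked_gap(self):
        cutoff, labels = idx.size_split([1.0, 1.1, 1.2, 1.8, 1.9, 2.0])
        assert cutoff == pytest.approx(1.5)
        assert list(labels) == ["small", "small", "small", "large", "large", "large"]

    def test_evenly_spaced_tie_goes_to_median(self):
        """With equal gaps the cutoff falls at the gap whose midpoint is
        closest to the median."""
        tls = [1.0, 1.2, 1.4, 1.6, 1.8, 2.0]
        cutoff, _ = idx.size_split(tls)
        assert cutoff == pytest.approx(1.5)

    def test_identical_lengths_error(self):
        with pytest.raises(ValueError, match="gap"):
            idx.size_split([1.5, 1.5, 1.5, 1.5])

    def test_too_few_error(self):
        with pytest.raises(ValueError, match="4"):
            idx.size_split([1.0, 2.0, 3.0])

    @given(
        tls=st.lists(st.floats(0.5, 4.5), min_size=6, max_size=30),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_labels_respect_cutoff(self, tls):
        """Whenever a split exists, every animal below the cutoff is small and
        every animal at or above it is large."""
        try:
            cutoff, labels = idx.size_split(tls)
        except ValueError:
            return
        tls = np.asarray(tls)
        assert ((tls >= cutoff) == (labels == "large")).all()


def test_resi_recovers_programmed_presence():
    """An archetype present with daily probability p yields mean ResI within
    0.05 of p (20 animals followed for a year, seed-fixed)."""
    from conftest import scaled_scenario
    from islandrange.simulate import simulate_dataset, as_telemetry_data
    from islandrange import io

    sc = scaled_scenario(study_end="2022-03-01")
    p = 0.6
    arch = sc.archetypes[1]  # pier resident: flat presence
    arch.monthly_presence = [p] * 12
    arch.n_animals = 20
    arch.never_detected_prob = 0.0
    arch.shed_tag_prob = 0.0
    sc.archetypes = [arch]
    ds = simulate_dataset(sc, seed=21)
    data = as_telemetry_data(ds)
    det, _ = io.qc_pipeline(data)
    overall = idx.overall_indices(det, data.receivers, data.tags)
    assert abs(overall["resi"].mean() - p) < 0.05
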