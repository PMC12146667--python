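"""Jitter, centre-of-activity binning, kernel UDs and overlap."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from shapely import affinity
from shapely.geometry import Point

from islandrange import activity
from islandrange.activity import GridSpec, KernelUD, ud_overlap
from islandrange.geo import LandMask, LocalProjection


def _receivers(sites):
    return pd.DataFrame(
        [dict(site=s, x=x, y=y, depth_m=20.0,
              active_from=pd.Timestamp("2021-01-01"),
              active_to=pd.Timestamp("2021-12-31"))
         for s, (x, y) in sites.items()]
    )


def _detections(rows):
    return pd.DataFrame(rows, columns=["tag_id", "receiver_id", "timestamp"]).assign(
        timestamp=lambda d: pd.to_datetime(d["timestamp"])
    )


class TestJitter:
    def test_zero_rmax_identity(self):
        rec = _receivers({"R1": (100.0, -50.0)})
        det = _detections([("T", "R1", "2021-06-01T00:10:00")] * 5)
        out = activity.jitter_detections(det, rec, rmax=0.0, rng=1)
        assert (out["x"] == 100.0).all() and (out["y"] == -50.0).all()

    def test_distances_bounded_and_uniform(self):
        """All jitter radii lie in [0, 25] m and their empirical distribution
        is Uniform(0, 25) by a KS test at alpha = 0.01 (10^4 draws)."""
        rec = _receivers({"R1": (0.0, 0.0)})
        det = _detections([("T", "R1", "2021-06-01T00:10:00")] * 10_000)
        out = activity.jitter_detections(det, rec, rmax=25.0, rng=42)
        r = np.hypot(out["x"], out["y"])
        assert (r >= 0).all() and (r <= 25.0).all()
        p = stats.kstest(r, stats.uniform(0, 25).cdf).pvalue
        assert p > 0.01


class TestComputeCoas:
    def test_weighted_mean_of_receivers(self):
        """3 detections at (0,0) and 1 at (400,0) in one bin, zero jitter:
        COA = (100, 0)."""
        rec = _receivers({"R1": (0.0, 0.0), "R2": (400.0, 0.0)})
        det = _detections(
            [("T", "R1", f"2021-06-01T00:{m:02d}:00") for m in (5, 15, 25)]
            + [("T", "R2", "2021-06-01T00:35:00")]
        )
        pos = activity.jitter_detections(det, rec, rmax=0.0, rng=0)
        coas = activity.compute_coas(pos, tz_hours=0.0)
        assert len(coas) == 1
        assert coas["x"].iloc[0] == pytest.approx(100.0)
        assert coas["y"].iloc[0] == pytest.approx(0.0)
        assert coas["n_detections"].iloc[0] == 4

    def test_single_receiver_within_jitter_radius(self):
        rec = _receivers({"R1": (500.0, 500.0)})
        det = _detections([("T", "R1", f"2021-06-01T02:{m:02d}:00") for m in range(10)])
        pos = activity.jitter_detections(det, rec, rmax=25.0, rng=3)
        coas = activity.compute_coas(pos, tz_hours=0.0)
        assert np.hypot(coas["x"].iloc[0] - 500.0, coas["y"].iloc[0] - 500.0) <= 25.0

    def test_two_active_bins_two_records(self):
        rec = _receivers({"R1": (0.0, 0.0)})
        det = _detections(
            [("T", "R1", "2021-06-01T01:00:00"), ("T", "R1", "2021-06-01T09:30:00")]
        )
        pos = activity.jitter_detections(det, rec, rmax=0.0, rng=0)
        coas = activity.compute_coas(pos, tz_hours=0.0)
        assert len(coas) == 2
        assert list(coas["bin_start"]) == [
            pd.Timestamp("2021-06-01T00:00:00"), pd.Timestamp("2021-06-01T08:00:00")
        ]

    def test_redundant_site_exclusion(self):
        rec = _receivers({"Main": (0.0, 0.0), "Twin": (200.0, 0.0)})
        det = _detections(
            [("T", "Main", "2021-06-01T01:00:00"), ("T", "Twin", "2021-06-01T01:30:00")]
        )
        pos = activity.jitter_detections(det, rec, rmax=0.0, rng=0)
        coas = activity.compute_coas(pos, tz_hours=0.0, exclude_sites=["Twin"])
        assert coas["x"].iloc[0] == pytest.approx(0.0)


class TestKernelUD:
    def test_single_coa_closed_form(self):
        """Single-point KDE areas match the bivariate-normal highest-density
        closed forms within one grid-cell area."""
        ud = KernelUD(h=300.0, cell=50.0).fit(np.array([[0.0, 0.0]]))
        cell_area = 50.0 * 50.0 / 1e6
        a95_expected = np.pi * (-2 * np.log(0.05)) * 300.0**2 / 1e6
        a50_expected = np.pi * (-2 * np.log(0.5)) * 300.0**2 / 1e6
        assert abs(ud.area(95) - a95_expected) <= cell_area
        assert abs(ud.area(50) - a50_expected) <= cell_area
        assert ud.area(50) <= ud.area(95)

    def test_two_distant_clusters_double_area(self):
        rng = np.random.default_rng(0)
        c1 = rng.normal(0.0, 150.0, (300, 2))
        c2 = rng.normal(0.0, 150.0, (300, 2)) + [5000.0, 0.0]
        single = KernelUD(h=300.0, cell=50.0).fit(c1).area(95)
        double = KernelUD(h=300.0, cell=50.0).fit(np.vstack([c1, c2])).area(95)
        assert double == pytest.approx(2 * single, rel=0.05)

    def test_mass_normalised_after_masking(self):
        proj = LocalProjection(167.95, -29.04)
        island = affinity.scale(Point(0, 0).buffer(1.0, quad_segs=64), 2000.0, 1200.0)
        land = LandMask(geographic=island, projection=proj, projected=island)
        coas = np.array([[2500.0, 0.0], [2600.0, 100.0], [-2500.0, 0.0]])
        ud = KernelUD(h=300.0, cell=50.0, land=land).fit(coas)
        assert ud.density_[~ud.water_mask_].sum() == 0.0
        assert ud.density_.sum() * 50.0**2 == pytest.approx(1.0, abs=1e-9)

    def test_resampling_stability(self):
        """Doubling the COA sample from the same distribution moves the 95%
        area by less than 5%."""
        rng = np.random.default_rng(7)
        base = rng.normal(0.0, 400.0, (2000, 2))
        more = rng.normal(0.0, 400.0, (4000, 2))
        a1 = KernelUD(h=300.0, cell=50.0).fit(base).area(95)
        a2 = KernelUD(h=300.0, cell=50.0).fit(more).area(95)
        assert abs(a2 - a1) / a1 < 0.05

    def test_empty_error(self):
        with pytest.raises(ValueError):
            KernelUD().fit(np.empty((0, 2)))


class TestOverlap:
    @staticmethod
    def _manual_ud(grid, hot_cells):
        """A fitted-looking KernelUD whose mass is uniform on given cells."""
        ud = KernelUD(h=300.0, cell=grid.cell, grid=grid)
        dens = np.zeros((grid.ny, grid.nx))
        for iy, ix in hot_cells:
            dens[iy, ix] = 1.0
        dens /= dens.sum() * grid.cell**2
        ud.grid_ = grid
        ud.density_ = dens
        ud.water_mask_ = np.ones_like(dens, dtype=bool)
        ud.n_coas_ = len(hot_cells)
        return ud

    def test_identity_and_disjoint(self):
        grid = GridSpec(0.0, 0.0, 50.0, 40, 40)
        a = self._manual_ud(grid, [(5, 5), (5, 6), (6, 5)])
        b = self._manual_ud(grid, [(20, 20), (20, 21)])
        assert ud_overlap(a, a, 95) == pytest.approx(1.0)
        assert ud_overlap(a, b, 95) == 0.0
        assert ud_overlap(a, b, 95) == ud_overlap(b, a, 95)

    def test_nested_areas_one_and_three(self):
        """A (1 km^2) nested inside B (3 km^2): overlap = 1 / mean(1,3) = 0.5."""
        grid = GridSpec(0.0, 0.0, 50.0, 80, 80)
        a_cells = [(iy, ix) for iy in range(20) for ix in range(20)]   # 1 km^2
        b_cells = [(iy, ix) for iy in range(30) for ix in range(40)]   # 3 km^2
        a = self._manual_ud(grid, a_cells)
        b = self._manual_ud(grid, b_cells)
        assert ud_overlap(a, b, 95) == pytest.approx(0.5)

    def test_overlap_never_exceeds_one(self):
        rng = np.random.default_rng(2)
        grid = GridSpec(-4000.0, -4000.0, 50.0, 160, 160)
        a = KernelUD(h=300.0, cell=50.0, grid=grid).fit(rng.normal(0, 500, (200, 2)))
        b = KernelUD(h=300.0, cell=50.0, grid=grid).fit(rng.normal(200, 500, (200, 2)))
        for lv in (50, 95):
            v = ud_overlap(a, b, lv)
            assert 0.0 <= v <= 1.0

    def test_mismatched_grids_error(self):
        a = KernelUD(h=300.0, cell=50.0).fit(np.array([[0.0, 0.0]]))
        b = KernelUD(h=300.0, cell=50.0).fit(np.array([[5000.0, 5000.0]]))
        with pytest.raises(ValueError, match="grid"):
            ud_overlap(a, b, 95)


def test_jitter_seed_sensitivity(small_dataset):
    """Two jitter seeds change the pooled 95% UD area by < 2%."""
    from islandrange import io
    from islandrange.simulate import as_telemetry_data

    data = as_telemetry_data(small_dataset)
    det, _ = io.qc_pipeline(data)
    det = det.loc[det["tag_id"].isin(det["tag_id"].unique()[:6])]
    areas = []
    for seed in (1, 2):
        pos = activity.jitter_detections(det, data.receivers, rng=seed)
        coas = activity.compute_coas(pos, exclude_sites=["Chute", "Jonny"])
        coas = activity.snap_to_shore(coas, data.land)
        xy = coas[["x", "y"]].to_numpy()
        grid = GridSpec.around(xy, 50.0, 4 * 300.0)
        areas.append(KernelUD(h=300.0, cell=50.0, grid=grid, land=data.land).fit(xy).area(95))
    assert abs(areas[1] - areas[0]) / areas[0] < 0.02


def test_snapped_coas_on_water(small_dataset):
    """After shore snapping no COA lies strictly inside land."""
    from islandrange import io
    from islandrange.simulate import as_telemetry_data

    data = as_telemetry_data(small_dataset)
    det, _ = io.qc_pipeline(data)
    det = det.loc[det["tag_id"].isin(det["tag_id"].unique()[:4])]
    pos = activity.jitter_detections(det, data.receivers, rng=1)
    coas = activity.snap_to_shore(activity.compute_coas(pos), data.land)
    assert not data.land.contains_xy(coas["x"].to_numpy(), coas["y"].to_numpy()).any()
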