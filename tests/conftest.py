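"""Shared fixtures: a hand-computable two-animal fixture and a scaled
synthetic scenario reused across test modules."""

import json

import numpy as np
import pandas as pd
import pytest

from islandrange.geo import LandMask, LocalProjection
from islandrange.simulate import default_scenario, simulate_dataset


def diamond_island_geojson(path, lon0=167.95, lat0=-29.04, size_deg=0.02):
    """A small diamond-shaped island polygon centred at (lon0, lat0)."""
    ring = [
        [lon0 + size_deg, lat0],
        [lon0, lat0 + size_deg],
        [lon0 - size_deg, lat0],
        [lon0, lat0 - size_deg],
        [lon0 + size_deg, lat0],
    ]
    gj = {"type": "Polygon", "coordinates": [ring]}
    with open(path, "w") as fh:
        json.dump(gj, fh)
    return path


@pytest.fixture
def hand_fixture(tmp_path):
    """Two animals with hand-computable indices (timezone UTC for easy dates).

    T1: start 2021-03-03, detections on 6 days to Mar 20 (period 18),
        sites {R1, R2} of {R1, R2} available (R3 deployed later) —
        ResI 6/18, RoI 1.0; March is a boundary month covering 18 days.
    T2: start 2021-03-02, detected daily in March (30 d), alternate days
        Apr 1-19 (10 d), plus May 1 and May 5 — period 65, ResI 42/65;
        May covers only 5 days and is dropped from the monthly records.
    """
    land = diamond_island_geojson(tmp_path / "land.geojson")
    proj = LocalProjection(167.95, -29.04)

    def lonlat(x, y):
        lon, lat = proj.inverse(np.array([x]), np.array([y]))
        return float(lon[0]), float(lat[0])

    sites = {"R1": (4000.0, 0.0), "R2": (0.0, 4000.0), "R3": (-4000.0, 0.0)}
    rec_rows = []
    for site, (x, y) in sites.items():
        lon, lat = lonlat(x, y)
        active = ("2021-07-01", "2021-12-31") if site == "R3" else ("2021-01-01", "2021-12-31")
        rec_rows.append(
            dict(station_name=site, longitude=lon, latitude=lat, depth_m=20.0,
                 deployment_date=active[0], recovery_date=active[1])
        )
    pd.DataFrame(rec_rows).to_csv(tmp_path / "receivers.csv", index=False)

    tags = pd.DataFrame(
        [
            dict(transmitter_id="T1", species="dusky", sex="F", total_length_m=2.1,
                 release_site="R1", release_datetime="2021-03-01T00:00:00Z"),
            dict(transmitter_id="T2", species="galapagos", sex="M", total_length_m=1.6,
                 release_site="R1", release_datetime="2021-02-28T00:00:00Z"),
        ]
    )
    tags.to_csv(tmp_path / "tags.csv", index=False)

    det = []
    for d in [3, 4, 5, 10, 15]:
        det.append(("T1", "R1", f"2021-03-{d:02d}T12:00:00Z"))
    det.append(("T1", "R2", "2021-03-20T12:00:00Z"))
    for d in range(2, 32):
        det.append(("T2", "R1", f"2021-03-{d:02d}T06:00:00Z"))
    det.append(("T2", "R2", "2021-03-15T07:00:00Z"))
    for d in range(1, 20, 2):
        det.append(("T2", "R1", f"2021-04-{d:02d}T06:00:00Z"))
    det.append(("T2", "R1", "2021-05-01T06:00:00Z"))
    det.append(("T2", "R1", "2021-05-05T06:00:00Z"))
    pd.DataFrame(det, columns=["transmitter_id", "station_name", "detection_datetime"]).to_csv(
        tmp_path / "detections.csv", index=False
    )
    return {
        "detections": tmp_path / "detections.csv",
        "receivers": tmp_path / "receivers.csv",
        "tags": tmp_path / "tags.csv",
        "land": land,
        "tz_hours": 0.0,
    }


def scaled_scenario(factor: int = 6, study_end: str = "2022-10-01"):
    """Default scenario with n_animals reduced by ``factor`` and a shorter
    window, so tests stay fast; everything else is the stated world."""
    sc = default_scenario()
    for a in sc.archetypes:
        a.n_animals = max(4, a.n_animals // factor)
        if a.name == "offshore_seasonal":
            a.release_window = ("2021-03-01", "2021-05-01")
    sc.study_end = study_end
    return sc


@pytest.fixture(scope="session")
def small_dataset():
    """One scaled synthetic dataset shared by the read-only tests."""
    return simulate_dataset(scaled_scenario(), seed=11)
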