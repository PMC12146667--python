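"""Synthetic island telemetry scenarios with known ground truth.

Generates complete, internally consistent datasets for the whole
pipeline: an elliptical island polygon, a receiver array hugging the
coast (plus an offshore cluster and late-deployed sites), tagged animals
drawn from species archetypes (a seasonal migrant generalist, two
resident pier-attached species, an offshore site-attached seasonal
species), daily presence/anchor movement, distance-dependent detection
of random-interval transmissions, and QC artefacts (shed transmitters,
never-detected individuals).

Every random quantity flows from one seeded generator, and the scenario
serialises to YAML, so a dataset is reproducible from (scenario, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml
from shapely.geometry import Point
from shapely import affinity

from .geo import LandMask, LocalProjection
from .io import TelemetryData, FilterReport

MONTHS = np.arange(1, 13)
STEP_H = 2.0
STEPS_PER_DAY = int(24 / STEP_H)


@dataclass
class ArchetypeSpec:
    """Species archetype: seasonal presence, site affinity, movement noise.

    ``monthly_presence`` gives the probability that an animal is present in
    the array on a given day of each month (January first).  When present,
    the animal sits at a daily anchor site drawn from ``site_weights`` (its
    own release site boosted by ``release_site_boost``), re-drawn each day
    with probability ``daily_transition``, and its 2-h positions scatter
    isotropically around the anchor with s.d. ``scatter_sd`` metres.
    """

    name: str
    species: str
    n_animals: int
    monthly_presence: list
    site_weights: dict
    scatter_sd: float = 150.0
    daily_transition: float = 0.3
    release_site_boost: float = 1.0
    shed_tag_prob: float = 0.0
    never_detected_prob: float = 0.0
    tx_interval: tuple = (80.0, 140.0)
    release_sites: list = field(default_factory=list)
    release_window: tuple = ("2021-02-01", "2022-02-01")
    tl_mean: float = 2.0
    tl_sd: float = 0.3
    tl_min: float = 1.0
    tl_max: float = 4.5
    prop_female: float = 0.7


@dataclass
class Scenario:
    """A complete synthetic world: island, array, archetypes, study window."""

    center_lon: float = 167.9547
    center_lat: float = -29.0408
    island_a: float = 4000.0  # ellipse semi-axes, metres
    island_b: float = 2500.0
    study_start: str = "2021-02-01"
    study_end: str = "2024-04-01"
    tz_hours: float = 11.0
    d50: float = 250.0  # 50%-efficiency detection distance
    range_s: float = 50.0  # logistic range-model scale
    receivers: list = field(default_factory=list)  # dicts: site,x,y,depth_m,from,to
    archetypes: list = field(default_factory=list)
    seed: int | None = None

    def projection(self) -> LocalProjection:
        return LocalProjection(self.center_lon, self.center_lat)

    def island_polygon(self):
        return affinity.scale(
            Point(0.0, 0.0).buffer(1.0, quad_segs=64), self.island_a, self.island_b
        )

    def land_mask(self) -> LandMask:
        proj = self.projection()
        poly = self.island_polygon()

        def inv(x, y):
            return proj.inverse(np.asarray(x), np.asarray(y))

        from shapely.ops import transform as shapely_transform

        geographic = shapely_transform(inv, poly)
        return LandMask(geographic=geographic, projection=proj, projected=poly)

    def receiver_frame(self) -> pd.DataFrame:
        proj = self.projection()
        df = pd.DataFrame(self.receivers)
        df["active_from"] = pd.to_datetime(df["active_from"])
        df["active_to"] = pd.to_datetime(df["active_to"])
        df["lon"], df["lat"] = proj.inverse(df["x"].to_numpy(), df["y"].to_numpy())
        return df[["site", "lon", "lat", "x", "y", "depth_m", "active_from", "active_to"]]


def _coastal_site(scenario_a, scenario_b, theta, offshore=350.0):
    """Point ``offshore`` metres beyond the ellipse along the outward normal."""
    x, y = scenario_a * np.cos(theta), scenario_b * np.sin(theta)
    nx, ny = np.cos(theta) / scenario_a, np.sin(theta) / scenario_b
    norm = np.hypot(nx, ny)
    return x + offshore * nx / norm, y + offshore * ny / norm


def default_scenario() -> Scenario:
    """The standard synthetic island: 21 receivers, 4 archetypes, 3+ years.

    Topology mirrors a small remote island: two pier sites on the north and
    south coasts, a west-coast hotspot with two redundant neighbours, an
    offshore deep cluster ~6 km south, and three late-deployed sites.
    Archetype rates (presence seasonality, never-detected and shed-tag
    probabilities, transmitter intervals, lengths) follow the field setting
    the generator emulates.
    """
    sc = Scenario()
    a, b = sc.island_a, sc.island_b
    early = ("2021-02-01", "2024-04-30")
    late = ("2023-02-01", "2024-04-30")

    coastal = {
        # name: (angle on ellipse, depth)
        "Cascade": (0.35 * np.pi, 4.0),     # north-east pier
        "Simons": (0.18 * np.pi, 20.0),
        "Steels": (0.55 * np.pi, 22.0),
        "Cemetery": (0.75 * np.pi, 18.0),
        "Headstone": (1.00 * np.pi, 25.0),  # west hotspot
        "Anson": (0.88 * np.pi, 20.0),
        "Bumboras": (1.20 * np.pi, 20.0),
        "PointRoss": (1.32 * np.pi, 22.0),
        "Kingston": (1.50 * np.pi, 3.0),    # south pier
        "Surf": (1.58 * np.pi, 10.0),
        "Duncombe": (1.70 * np.pi, 20.0),
        "CaptainCook": (1.85 * np.pi, 22.0),
        "BirdRock": (0.05 * np.pi, 24.0),
    }
    receivers = []
    for site, (theta, depth) in coastal.items():
        x, y = _coastal_site(a, b, theta, 350.0)
        receivers.append(
            dict(site=site, x=float(x), y=float(y), depth_m=depth,
                 active_from=early[0], active_to=early[1])
        )
    # redundant neighbours a few hundred metres from the hotspot
    hx, hy = _coastal_site(a, b, np.pi, 350.0)
    receivers.append(dict(site="Chute", x=float(hx + 120.0), y=float(hy + 260.0),
                          depth_m=24.0, active_from=early[0], active_to=early[1]))
    receivers.append(dict(site="Jonny", x=float(hx + 150.0), y=float(hy - 280.0),
                          depth_m=23.0, active_from=early[0], active_to=early[1]))
    # nearshore islet site and the offshore deep cluster
    receivers.append(dict(site="Nepean", x=500.0, y=-float(b) - 1200.0, depth_m=15.0,
                          active_from=early[0], active_to=early[1]))
    receivers.append(dict(site="Cabbage", x=-1500.0, y=float(b) + 900.0, depth_m=18.0,
                          active_from=early[0], active_to=early[1]))
    receivers.append(dict(site="PhillipMain", x=800.0, y=-float(b) - 5500.0, depth_m=50.0,
                          active_from=early[0], active_to=early[1]))
    # late deployments: two south of the offshore islet, one east
    receivers.append(dict(site="Phillip1", x=300.0, y=-float(b) - 6100.0, depth_m=48.0,
                          active_from=late[0], active_to=late[1]))
    receivers.append(dict(site="Phillip2", x=1400.0, y=-float(b) - 6200.0, depth_m=52.0,
                          active_from=late[0], active_to=late[1]))
    receivers.append(dict(site="Fishbowl", x=float(a) + 1300.0, y=-800.0, depth_m=30.0,
                          active_from=late[0], active_to=late[1]))
    sc.receivers = receivers

    coastal_names = [r["site"] for r in receivers
                     if r["site"] not in {"PhillipMain", "Phillip1", "Phillip2"}]
    generalist_weights = {s: 1.0 for s in coastal_names}
    generalist_weights["Headstone"] = 3.0
    generalist_weights["Chute"] = 0.5
    generalist_weights["Jonny"] = 0.5

    pier_weights = {
        "Cascade": 2.0, "Simons": 1.5, "Kingston": 2.0, "Surf": 1.2,
        "Nepean": 1.0, "Cemetery": 0.3, "BirdRock": 0.3, "Steels": 0.2,
        "Headstone": 0.2, "Duncombe": 0.2,
    }

    sc.archetypes = [
        ArchetypeSpec(
            name="migrant_generalist",
            species="tiger",
            n_animals=47,
            monthly_presence=[0.85, 0.85, 0.70, 0.60, 0.30, 0.02,
                              0.02, 0.02, 0.02, 0.02, 0.60, 0.85],
            site_weights=generalist_weights,
            scatter_sd=800.0,
            daily_transition=0.5,
            release_site_boost=1.0,
            shed_tag_prob=0.0,
            never_detected_prob=0.043,
            tx_interval=(80.0, 140.0),
            release_sites=["Headstone"],
            release_window=("2021-02-01", "2021-06-01"),
            tl_mean=3.83, tl_sd=0.4, tl_min=2.3, tl_max=4.4,
            prop_female=0.85,
        ),
        ArchetypeSpec(
            name="pier_resident_dusky",
            species="dusky",
            n_animals=34,
            monthly_presence=[0.55] * 12,
            site_weights=pier_weights,
            scatter_sd=500.0,
            daily_transition=0.25,
            release_site_boost=6.0,
            shed_tag_prob=0.03,
            never_detected_prob=0.21,
            tx_interval=(80.0, 140.0),
            release_sites=["Cascade", "Cascade", "Kingston"],
            release_window=("2021-02-01", "2022-02-01"),
            tl_mean=2.28, tl_sd=0.28, tl_min=1.6, tl_max=2.8,
            prop_female=0.65,
        ),
        ArchetypeSpec(
            name="pier_resident_galapagos",
            species="galapagos",
            n_animals=32,
            monthly_presence=[0.50] * 12,
            site_weights=pier_weights,
            scatter_sd=500.0,
            daily_transition=0.25,
            release_site_boost=6.0,
            shed_tag_prob=0.0,
            never_detected_prob=0.28,
            tx_interval=(80.0, 140.0),
            release_sites=["Cascade", "Kingston"],
            release_window=("2021-02-01", "2022-02-01"),
            tl_mean=1.64, tl_sd=0.2, tl_min=1.3, tl_max=2.0,
            prop_female=0.7,
        ),
        ArchetypeSpec(
            name="offshore_seasonal",
            species="sandbar",
            n_animals=20,
            monthly_presence=[0.70, 0.70, 0.60, 0.50, 0.40, 0.10,
                              0.10, 0.10, 0.10, 0.10, 0.50, 0.70],
            site_weights={"PhillipMain": 3.0, "Phillip1": 1.0, "Phillip2": 1.0},
            scatter_sd=400.0,
            daily_transition=0.2,
            release_site_boost=1.0,
            shed_tag_prob=0.05,
            never_detected_prob=0.5,
            tx_interval=(90.0, 150.0),
            release_sites=["PhillipMain"],
            release_window=("2023-02-01", "2023-04-01"),
            tl_mean=1.38, tl_sd=0.08, tl_min=1.2, tl_max=1.5,
            prop_female=0.65,
        ),
    ]
    return sc


def scenario_to_yaml(scenario: Scenario, path) -> None:
    d = asdict(scenario)
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=False)


def scenario_from_yaml(path) -> Scenario:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    d["archetypes"] = [ArchetypeSpec(**a) for a in d.get("archetypes", [])]
    return Scenario(**d)


# ---------------------------------------------------------------------------
# simulation


def _make_tags(scenario: Scenario, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    i = 0
    for arch in scenario.archetypes:
        w0, w1 = pd.Timestamp(arch.release_window[0]), pd.Timestamp(arch.release_window[1])
        span_days = max(int((w1 - w0).days), 1)
        for _ in range(arch.n_animals):
            i += 1
            tl = float(np.clip(rng.normal(arch.tl_mean, arch.tl_sd), arch.tl_min, arch.tl_max))
            release_site = arch.release_sites[rng.integers(len(arch.release_sites))]
            # release mid-morning local time
            release = (
                w0
                + pd.Timedelta(days=int(rng.integers(span_days)))
                + pd.Timedelta(hours=9 - scenario.tz_hours + float(rng.uniform(0, 6)))
            )
            rows.append(
                dict(
                    tag_id=f"A69-{i:04d}",
                    species=arch.species,
                    archetype=arch.name,
                    sex="F" if rng.random() < arch.prop_female else "M",
                    total_length_m=round(tl, 2),
                    release_site=release_site,
                    release_time=release,
                )
            )
    return pd.DataFrame(rows)


def simulate_tracks(
    scenario: Scenario, rng: np.random.Generator | int | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate daily presence, anchors and 2-h positions for every animal.

    Returns (tags, truth, positions): tag metadata, the ground-truth daily
    presence/anchor calendar, and true positions at 2-h steps (local-midnight
    anchored, timestamps UTC) for present days.
    """
    rng = np.random.default_rng(rng if rng is not None else scenario.seed)
    tags = _make_tags(scenario, rng)
    rec = pd.DataFrame(scenario.receivers)
    site_xy = {r["site"]: (r["x"], r["y"]) for _, r in rec.iterrows()}
    arch_by_name = {a.name: a for a in scenario.archetypes}

    end_date = pd.Timestamp(scenario.study_end)
    tz = pd.Timedelta(hours=scenario.tz_hours)

    truth_rows = []
    pos_frames = []
    for _, tag in tags.iterrows():
        arch = arch_by_name[tag["archetype"]]
        sites = list(arch.site_weights)
        w = np.array([arch.site_weights[s] for s in sites], dtype=float)
        if arch.release_site_boost != 1.0 and tag["release_site"] in sites:
            w = w.copy()
            w[sites.index(tag["release_site"])] *= arch.release_site_boost
        w = w / w.sum()

        first_day = (tag["release_time"] + tz).normalize()
        days = pd.date_range(first_day, (end_date + tz).normalize(), freq="D")
        n = len(days)
        if n == 0:  # released after the study window closed
            continue
        presence_p = np.array(arch.monthly_presence, dtype=float)[days.month - 1]
        present = rng.random(n) < presence_p
        # daily anchor: candidate redrawn on switch days, held otherwise
        switch = rng.random(n) < arch.daily_transition
        switch[0] = True
        cand = rng.choice(len(sites), size=n, p=w)
        last = np.maximum.accumulate(np.where(switch, np.arange(n), -1))
        anchor_idx = cand[last]

        truth_rows.append(
            pd.DataFrame(
                {
                    "tag_id": tag["tag_id"],
                    "date": days,
                    "present": present,
                    "anchor_site": np.array(sites)[anchor_idx],
                }
            )
        )
        if not present.any():
            continue
        pres_days = np.nonzero(present)[0]
        day_starts = (days[pres_days] - tz).to_numpy()  # UTC instant of local midnight
        step_starts = (
            day_starts[:, None] + np.timedelta64(2 * 3600, "s") * np.arange(STEPS_PER_DAY)
        ).ravel()
        a_idx = np.repeat(anchor_idx[pres_days], STEPS_PER_DAY)
        ax = np.array([site_xy[s][0] for s in sites])[a_idx]
        ay = np.array([site_xy[s][1] for s in sites])[a_idx]
        npts = len(step_starts)
        pos_frames.append(
            pd.DataFrame(
                {
                    "tag_id": tag["tag_id"],
                    "step_start": step_starts,
                    "x": ax + rng.normal(0.0, arch.scatter_sd, npts),
                    "y": ay + rng.normal(0.0, arch.scatter_sd, npts),
                }
            )
        )
    truth = (
        pd.concat(truth_rows, ignore_index=True)
        if truth_rows
        else pd.DataFrame(columns=["tag_id", "date", "present", "anchor_site"])
    )
    positions = (
        pd.concat(pos_frames, ignore_index=True)
        if pos_frames
        else pd.DataFrame(columns=["tag_id", "step_start", "x", "y"])
    )
    return tags, truth, positions


def detection_probability(distance, d50: float = 250.0, s: float = 50.0):
    """Logistic detection-range model p(d) = 1 / (1 + exp((d - d50) / s))."""
    return 1.0 / (1.0 + np.exp((np.asarray(distance, dtype=float) - d50) / s))


def simulate_detections(
    positions: pd.DataFrame,
    receivers: pd.DataFrame,
    tags: pd.DataFrame,
    d50: float = 250.0,
    range_scale: float = 50.0,
    rng: np.random.Generator | int | None = None,
    p_floor: float = 1e-5,
    tx_intervals: dict | None = None,
) -> pd.DataFrame:
    """Turn true positions into probabilistic receiver detections.

    Within each 2-h step the transmitter emits with inter-transmission gaps
    ~ Uniform(lo, hi); every transmission is detected independently by every
    active receiver with probability p(distance).  Simultaneous detections on
    several receivers are allowed.
    """
    rng = np.random.default_rng(rng)
    rx = receivers["x"].to_numpy()
    ry = receivers["y"].to_numpy()
    rsite = receivers["site"].to_numpy()
    r_from = receivers["active_from"].to_numpy()
    r_to = receivers["active_to"].to_numpy()
    r_to_excl = r_to + np.timedelta64(1, "D")  # recovery date inclusive
    if tx_intervals is None:
        if "_tx_interval" in tags.columns:
            tx_intervals = dict(zip(tags["tag_id"], tags["_tx_interval"]))
        else:
            tx_intervals = {}
    out = []
    for tag_id, g in positions.groupby("tag_id", sort=True):
        lo, hi = tx_intervals.get(tag_id, (80.0, 140.0))
        M = int(STEP_H * 3600 / lo) + 2
        t0 = g["step_start"].to_numpy()
        d = np.hypot(
            g["x"].to_numpy()[:, None] - rx[None, :],
            g["y"].to_numpy()[:, None] - ry[None, :],
        )
        p = detection_probability(d, d50, range_scale)
        avail = (t0[:, None] >= r_from[None, :]) & (t0[:, None] < r_to_excl[None, :])
        p = np.where(avail, p, 0.0)
        p[p < p_floor] = 0.0
        hot = p.any(axis=1)
        if not hot.any():
            continue
        hs = np.nonzero(hot)[0]
        gaps = rng.uniform(lo, hi, size=(len(hs), M))
        tx_off = np.cumsum(gaps, axis=1)
        tx_valid = tx_off < STEP_H * 3600
        si, ri = np.nonzero(p[hs])
        u = rng.random((len(si), M))
        det = (u < p[hs][si, ri, None]) & tx_valid[si]
        pi, mi = np.nonzero(det)
        ts = t0[hs[si[pi]]] + (tx_off[si[pi], mi] * 1e6).astype("timedelta64[us]")
        out.append(
            pd.DataFrame(
                {"tag_id": tag_id, "receiver_id": rsite[ri[pi]], "timestamp": ts}
            )
        )
    if not out:
        return pd.DataFrame(columns=["tag_id", "receiver_id", "timestamp"])
    det = pd.concat(out, ignore_index=True)
    det["timestamp"] = det["timestamp"].astype("datetime64[s]").astype("datetime64[ns]")
    det = det.sort_values(["tag_id", "timestamp"], kind="mergesort").reset_index(drop=True)
    return det


def inject_artifacts(
    detections: pd.DataFrame,
    tags: pd.DataFrame,
    scenario: Scenario,
    rng: np.random.Generator | int | None = None,
    shed_ping_s: float = 600.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply never-detected and shed-tag artefacts to simulated detections.

    Never-detected animals lose every detection.  A shed tag keeps its
    genuine detections up to a random shed date, after which the record is a
    continuous single-receiver ping train (cadence ``shed_ping_s``) until the
    study end — the stationary signature the QC filter must catch.
    """
    rng = np.random.default_rng(rng)
    arch_by_name = {a.name: a for a in scenario.archetypes}
    end = pd.Timestamp(scenario.study_end)
    flags = []
    drop_ids = []
    extra = []
    det = detections
    for _, tag in tags.iterrows():
        arch = arch_by_name[tag["archetype"]]
        status = "normal"
        if rng.random() < arch.never_detected_prob:
            status = "never_detected"
            drop_ids.append(tag["tag_id"])
        elif rng.random() < arch.shed_tag_prob:
            g = det.loc[det["tag_id"] == tag["tag_id"]]
            if len(g):
                tmin, tmax = g["timestamp"].min(), g["timestamp"].max()
                if (end - tmin) > pd.Timedelta(days=90):
                    status = "shed_tag"
                    span = (end - pd.Timedelta(days=60)) - tmin
                    shed_at = tmin + span * rng.random()
                    before = g.loc[g["timestamp"] <= shed_at]
                    site = (
                        before["receiver_id"].iloc[-1]
                        if len(before)
                        else g["receiver_id"].iloc[0]
                    )
                    pings = pd.date_range(shed_at, end, freq=f"{int(shed_ping_s)}s")
                    det = det.loc[
                        ~((det["tag_id"] == tag["tag_id"]) & (det["timestamp"] > shed_at))
                    ]
                    extra.append(
                        pd.DataFrame(
                            {"tag_id": tag["tag_id"], "receiver_id": site, "timestamp": pings}
                        )
                    )
        flags.append({"tag_id": tag["tag_id"], "artifact": status})
    det = det.loc[~det["tag_id"].isin(drop_ids)]
    if extra:
        det = pd.concat([det] + extra, ignore_index=True)
    det = det.sort_values(["tag_id", "timestamp"], kind="mergesort").reset_index(drop=True)
    return det, pd.DataFrame(flags)


def simulate_dataset(
    scenario: Scenario | None = None,
    seed: int | None = None,
    out_dir=None,
):
    """End-to-end dataset generation; optionally writes the four input files.

    Returns a dict with detections, receivers, tags, truth, artifacts and the
    land mask.  With ``out_dir`` set, writes ``detections.csv``,
    ``receivers.csv``, ``tags.csv`` and ``land.geojson`` in the IMOS-style
    dialect that :func:`islandrange.io.read_inputs` expects.
    """
    scenario = scenario or default_scenario()
    rng = np.random.default_rng(seed if seed is not None else scenario.seed)
    tags, truth, positions = simulate_tracks(scenario, rng)
    # carry per-archetype transmitter intervals into the tag frame
    arch_by_name = {a.name: a for a in scenario.archetypes}
    tags["_tx_interval"] = [
        tuple(arch_by_name[a].tx_interval) for a in tags["archetype"]
    ]
    receivers = scenario.receiver_frame()
    det = simulate_detections(
        positions, receivers, tags, d50=scenario.d50, range_scale=scenario.range_s, rng=rng
    )
    det, artifacts = inject_artifacts(det, tags, scenario, rng=rng)
    land = scenario.land_mask()
    result = {
        "detections": det,
        "receivers": receivers,
        "tags": tags.drop(columns=["_tx_interval"]),
        "truth": truth,
        "artifacts": artifacts,
        "land": land,
        "scenario": scenario,
    }
    if out_dir is not None:
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        det_out = pd.DataFrame(
            {
                "transmitter_id": det["tag_id"],
                "station_name": det["receiver_id"],
                "detection_datetime": det["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%SZ"),
            }
        )
        det_out.to_csv(out / "detections.csv", index=False)
        pd.DataFrame(
            {
                "station_name": receivers["site"],
                "longitude": receivers["lon"],
                "latitude": receivers["lat"],
                "depth_m": receivers["depth_m"],
                "deployment_date": receivers["active_from"].dt.strftime("%Y-%m-%d"),
                "recovery_date": receivers["active_to"].dt.strftime("%Y-%m-%d"),
            }
        ).to_csv(out / "receivers.csv", index=False)
        pd.DataFrame(
            {
                "transmitter_id": result["tags"]["tag_id"],
                "species": result["tags"]["species"],
                "sex": result["tags"]["sex"],
                "total_length_m": result["tags"]["total_length_m"],
                "release_site": result["tags"]["release_site"],
                "release_datetime": result["tags"]["release_time"].dt.strftime(
                    "%Y-%m-%dT%H:%M:%SZ"
                ),
            }
        ).to_csv(out / "tags.csv", index=False)
        land.to_geojson(out / "land.geojson")
        scenario_to_yaml(scenario, out / "scenario.yaml")
    return result


def as_telemetry_data(dataset: dict) -> TelemetryData:
    """Wrap an in-memory simulated dataset as validated TelemetryData."""
    det = dataset["detections"].sort_values(
        ["tag_id", "timestamp"], kind="mergesort"
    ).reset_index(drop=True)
    return TelemetryData(
        detections=det,
        receivers=dataset["receivers"],
        tags=dataset["tags"],
        land=dataset["land"],
        projection=dataset["land"].projection,
        report=FilterReport(),
    )
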