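"""Reading, validation and quality control of passive acoustic telemetry tables.

Input dialect follows the IMOS/AODN animal-tracking exports:

* detections CSV: ``transmitter_id, station_name, detection_datetime`` (ISO-8601 UTC)
* receivers CSV:  ``station_name, longitude, latitude, depth_m, deployment_date,
  recovery_date``
* tags CSV:       ``transmitter_id, species, sex, total_length_m, release_site,
  release_datetime``
* land:           GeoJSON Polygon/MultiPolygon in WGS84

Three sequential quality-control filters produce analysis-ready detection
sets: (1) a post-release trim discarding the first 48 h after tagging,
(2) removal of animals whose record ends in a long continuous run at a
single receiver (shed transmitter or dead animal), and (3) removal of
animals detected over a period of two weeks or less.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geo import LandMask, LocalProjection

DETECTION_COLS = ["transmitter_id", "station_name", "detection_datetime"]
RECEIVER_COLS = [
    "station_name",
    "longitude",
    "latitude",
    "depth_m",
    "deployment_date",
    "recovery_date",
]
TAG_COLS = [
    "transmitter_id",
    "species",
    "sex",
    "total_length_m",
    "release_site",
    "release_datetime",
]

#: Norfolk-style default: local days are UTC+11 (configurable everywhere).
DEFAULT_TZ_HOURS = 11.0


def local_date(ts: pd.Series | pd.Timestamp, tz_hours: float = DEFAULT_TZ_HOURS):
    """Calendar date in the local (fixed-offset) timezone of UTC timestamps."""
    shifted = ts + pd.Timedelta(hours=tz_hours)
    if isinstance(shifted, pd.Timestamp):
        return shifted.normalize()
    return shifted.dt.normalize()


def _parse_datetime(series: pd.Series, what: str) -> pd.Series:
    parsed = pd.to_datetime(series, errors="coerce", utc=True, format="mixed")
    if parsed.isna().any():
        bad = np.nonzero(parsed.isna().to_numpy())[0]
        rows = ", ".join(str(i + 2) for i in bad[:10])  # +2: header + 1-based
        raise ValueError(
            f"unparseable {what} timestamp at file row(s) {rows}"
            + (" ..." if len(bad) > 10 else "")
        )
    return parsed.dt.tz_localize(None)


def _require_columns(df: pd.DataFrame, cols, what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{what} table is missing column(s): {', '.join(missing)}")


def read_detections(path) -> pd.DataFrame:
    raw = pd.read_csv(path)
    _require_columns(raw, DETECTION_COLS, "detections")
    return pd.DataFrame(
        {
            "tag_id": raw["transmitter_id"].astype(str),
            "receiver_id": raw["station_name"].astype(str),
            "timestamp": _parse_datetime(raw["detection_datetime"], "detection"),
        }
    )


def read_receivers(path, projection: LocalProjection | None = None) -> pd.DataFrame:
    raw = pd.read_csv(path)
    _require_columns(raw, RECEIVER_COLS, "receivers")
    rec = pd.DataFrame(
        {
            "site": raw["station_name"].astype(str),
            "lon": raw["longitude"].astype(float),
            "lat": raw["latitude"].astype(float),
            "depth_m": raw["depth_m"].astype(float),
            "active_from": _parse_datetime(raw["deployment_date"], "deployment"),
            "active_to": _parse_datetime(raw["recovery_date"], "recovery"),
        }
    )
    if (rec["active_from"] >= rec["active_to"]).any():
        bad = rec.loc[rec["active_from"] >= rec["active_to"], "site"].tolist()
        raise ValueError(f"receiver deployment ends before it starts: {bad}")
    if projection is not None:
        rec["x"], rec["y"] = projection.forward(rec["lon"], rec["lat"])
    return rec


def read_tags(path) -> pd.DataFrame:
    raw = pd.read_csv(path)
    _require_columns(raw, TAG_COLS, "tags")
    tags = pd.DataFrame(
        {
            "tag_id": raw["transmitter_id"].astype(str),
            "species": raw["species"].astype(str),
            "sex": raw["sex"].astype(str),
            "total_length_m": raw["total_length_m"].astype(float),
            "release_site": raw["release_site"].astype(str),
            "release_time": _parse_datetime(raw["release_datetime"], "release"),
        }
    )
    if "maturity" in raw.columns:
        tags["maturity"] = raw["maturity"].astype(str)
    if (tags["total_length_m"] <= 0).any():
        raise ValueError("total_length_m must be positive")
    if tags["tag_id"].duplicated().any():
        dup = tags.loc[tags["tag_id"].duplicated(), "tag_id"].tolist()
        raise ValueError(f"duplicate tag_id in tag metadata: {dup}")
    return tags


@dataclass
class FilterReport:
    """Per-animal accounting of the sequential quality-control filters."""

    per_animal: pd.DataFrame = None  # tag_id, n_raw, n_after_trim, period_days, flag
    filter_counts: dict = field(default_factory=dict)
    period_convention: str = "post_release"
    n_dropped_outside_deployment: int = 0

    def summary(self) -> pd.DataFrame:
        return (
            self.per_animal.groupby("flag", dropna=False)
            .size()
            .rename("n_animals")
            .reset_index()
        )


@dataclass
class TelemetryData:
    """Validated inputs in a shared projected frame plus the QC report."""

    detections: pd.DataFrame
    receivers: pd.DataFrame
    tags: pd.DataFrame
    land: LandMask
    projection: LocalProjection
    report: FilterReport | None = None


def drop_outside_deployment(detections: pd.DataFrame, receivers: pd.DataFrame):
    """Remove detections logged outside their receiver's active interval.

    Recovery dates given at midnight are treated as inclusive of that whole
    local day (field metadata usually records dates, not instants).
    """
    rec = receivers.set_index("site")
    unknown = sorted(set(detections["receiver_id"]) - set(rec.index))
    if unknown:
        raise ValueError(f"detections reference unknown receiver(s): {unknown}")
    start = rec.loc[detections["receiver_id"], "active_from"].to_numpy()
    end = rec.loc[detections["receiver_id"], "active_to"].to_numpy()
    end_is_date = end == end.astype("datetime64[D]").astype(end.dtype)
    end = np.where(end_is_date, end + np.timedelta64(1, "D"), end)
    t = detections["timestamp"].to_numpy()
    ok = (t >= start) & (t < end)
    return detections.loc[ok].reset_index(drop=True), int((~ok).sum())


def read_inputs(
    detections_csv,
    receivers_csv,
    tags_csv,
    land_geojson,
    tz_hours: float = DEFAULT_TZ_HOURS,
) -> TelemetryData:
    """Load and cross-validate the four standard inputs.

    Establishes the local azimuthal-equidistant frame centred on the land
    polygon centroid, projects receiver positions into it, drops detections
    outside their receiver's deployment interval, and sorts detections by
    (tag_id, timestamp).
    """
    land = LandMask.from_geojson(land_geojson)
    receivers = read_receivers(receivers_csv, projection=land.projection)
    tags = read_tags(tags_csv)
    detections = read_detections(detections_csv)

    unknown_tags = sorted(set(detections["tag_id"]) - set(tags["tag_id"]))
    if unknown_tags:
        raise ValueError(f"detections reference unknown tag(s): {unknown_tags}")

    detections, n_dropped = drop_outside_deployment(detections, receivers)
    detections = detections.sort_values(["tag_id", "timestamp"], kind="mergesort")
    detections = detections.reset_index(drop=True)
    report = FilterReport(n_dropped_outside_deployment=n_dropped)
    return TelemetryData(
        detections=detections,
        receivers=receivers,
        tags=tags,
        land=land,
        projection=land.projection,
        report=report,
    )


def trim_post_release(
    detections: pd.DataFrame, tags: pd.DataFrame, window_h: float = 48.0
) -> pd.DataFrame:
    """Drop every detection within ``window_h`` hours of the animal's release.

    The removal window is closed: a detection at exactly release + 48 h is
    discarded.
    """
    release = tags.set_index("tag_id")["release_time"]
    missing = sorted(set(detections["tag_id"]) - set(release.index))
    if missing:
        raise ValueError(f"no release_time for tag(s): {missing}")
    cutoff = release.loc[detections["tag_id"]].to_numpy() + pd.Timedelta(
        hours=window_h
    ).to_numpy()
    keep = detections["timestamp"].to_numpy() > cutoff
    return detections.loc[keep].reset_index(drop=True)


def flag_shed_or_dead(
    detections: pd.DataFrame,
    min_days: float = 7.0,
    max_gap_h: float = 24.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Remove animals whose record ends as a stationary single-receiver run.

    An animal is flagged iff its terminal run of detections occurs at exactly
    one receiver, spans at least ``min_days``, and contains no silence longer
    than ``max_gap_h``.  The whole animal is removed, not just the run: such a
    signature means the transmitter was shed or the animal died, so nothing
    after tagging can be attributed to live behaviour with confidence.

    Returns the filtered detections and a flags table
    (tag_id, terminal_site, run_days, flagged).
    """
    rows = []
    flagged_ids = []
    for tag_id, g in detections.groupby("tag_id", sort=True):
        t = g["timestamp"].to_numpy()
        r = g["receiver_id"].to_numpy()
        # terminal single-receiver suffix, truncated at the last long silence:
        # genuine earlier visits to the same site must not mask the signature
        last_site = r[-1]
        idx = len(r) - 1
        while idx > 0 and r[idx - 1] == last_site:
            idx -= 1
        run_t = t[idx:]
        if len(run_t) > 1:
            gaps = np.diff(run_t) > np.timedelta64(int(max_gap_h * 3600), "s")
            breaks = np.nonzero(gaps)[0]
            if len(breaks):
                run_t = run_t[breaks[-1] + 1 :]
        span_days = (run_t[-1] - run_t[0]) / np.timedelta64(1, "h") / 24.0
        flagged = bool(span_days >= min_days)
        rows.append(
            {
                "tag_id": tag_id,
                "terminal_site": last_site,
                "run_days": float(span_days),
                "flagged": flagged,
            }
        )
        if flagged:
            flagged_ids.append(tag_id)
    flags = pd.DataFrame(rows, columns=["tag_id", "terminal_site", "run_days", "flagged"])
    out = detections.loc[~detections["tag_id"].isin(flagged_ids)].reset_index(drop=True)
    return out, flags


def apply_min_detection_period(
    detections: pd.DataFrame,
    tags: pd.DataFrame,
    min_days: float = 14.0,
    convention: str = "post_release",
    tz_hours: float = DEFAULT_TZ_HOURS,
    window_h: float = 48.0,
    prior_flags: pd.DataFrame | None = None,
    n_raw: pd.Series | None = None,
) -> tuple[pd.DataFrame, FilterReport]:
    """Remove animals with a detection period of ``min_days`` days or less.

    The detection period runs from the period start (release date under the
    ``"tagging"`` convention; the end of the post-release trim window under the
    default ``"post_release"`` convention) to the date of last detection,
    counting both endpoint dates.  Retention requires strictly more than
    ``min_days`` days.  The report assigns each excluded animal exactly one
    primary flag: shed_or_dead (from ``prior_flags``), short_period, or
    never_detected.
    """
    from .indices import detection_period

    shed_ids = set()
    if prior_flags is not None and len(prior_flags):
        shed_ids = set(prior_flags.loc[prior_flags["flagged"], "tag_id"])

    per_animal = []
    keep_ids = []
    grouped = dict(tuple(detections.groupby("tag_id")))
    for _, tag in tags.iterrows():
        tid = tag["tag_id"]
        g = grouped.get(tid)
        raw_n = int(n_raw.get(tid, 0)) if n_raw is not None else (
            len(g) if g is not None else 0
        )
        if tid in shed_ids:
            flag, period = "shed_or_dead", np.nan
        elif g is None or len(g) == 0:
            flag = "never_detected" if raw_n == 0 else "short_period"
            period = np.nan
        else:
            period = detection_period(
                g["timestamp"],
                release_time=tag["release_time"],
                convention=convention,
                tz_hours=tz_hours,
                window_h=window_h,
            )
            if period > min_days:
                flag = "retained"
                keep_ids.append(tid)
            else:
                flag = "short_period"
        per_animal.append(
            {
                "tag_id": tid,
                "species": tag["species"],
                "n_raw": raw_n,
                "n_after_trim": len(g) if g is not None else 0,
                "detection_period_days": period,
                "flag": flag,
            }
        )
    per_animal = pd.DataFrame(per_animal)
    counts = per_animal.groupby("flag").size().to_dict()
    report = FilterReport(
        per_animal=per_animal,
        filter_counts=counts,
        period_convention=convention,
    )
    out = detections.loc[detections["tag_id"].isin(keep_ids)].reset_index(drop=True)
    return out, report


def qc_pipeline(
    data: TelemetryData,
    window_h: float = 48.0,
    shed_min_days: float = 7.0,
    shed_max_gap_h: float = 24.0,
    min_period_days: float = 14.0,
    convention: str = "post_release",
    tz_hours: float = DEFAULT_TZ_HOURS,
) -> tuple[pd.DataFrame, FilterReport]:
    """Run trim -> shed/dead -> minimum-period on validated inputs."""
    n_raw = data.detections.groupby("tag_id").size()
    trimmed = trim_post_release(data.detections, data.tags, window_h=window_h)
    kept, flags = flag_shed_or_dead(
        trimmed, min_days=shed_min_days, max_gap_h=shed_max_gap_h
    )
    final, report = apply_min_detection_period(
        kept,
        data.tags,
        min_days=min_period_days,
        convention=convention,
        tz_hours=tz_hours,
        window_h=window_h,
        prior_flags=flags,
        n_raw=n_raw,
    )
    report.n_dropped_outside_deployment = (
        data.report.n_dropped_outside_deployment if data.report else 0
    )
    report.filter_counts["n_detections_raw"] = int(len(data.detections))
    report.filter_counts["n_detections_after_trim"] = int(len(trimmed))
    report.filter_counts["n_detections_final"] = int(len(final))
    return final, report
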