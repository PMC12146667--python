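"""Residency and roaming indices from filtered acoustic detections.

The residency index (ResI) of an animal is the number of local calendar
days with at least one detection anywhere in the array divided by the
number of days in its detection period.  The roaming index (RoI) is the
number of unique receiver sites with detections divided by the number of
sites whose deployment overlapped the animal's detection period.  Both
are computed over the whole track and per calendar month; boundary
months are kept only when more than 14 days of them fall inside the
detection period, below which the indices are too noisy to compare.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io import DEFAULT_TZ_HOURS, local_date

DAY = pd.Timedelta(days=1)


def _period_start(
    release_time: pd.Timestamp,
    convention: str,
    tz_hours: float,
    window_h: float,
) -> pd.Timestamp:
    """Local date on which the detection period starts."""
    if convention == "post_release":
        anchor = release_time + pd.Timedelta(hours=window_h)
    elif convention == "tagging":
        anchor = release_time
    else:
        raise ValueError(f"unknown detection-period convention: {convention!r}")
    return local_date(pd.Timestamp(anchor), tz_hours)


def detection_period(
    timestamps: pd.Series,
    release_time: pd.Timestamp,
    convention: str = "post_release",
    tz_hours: float = DEFAULT_TZ_HOURS,
    window_h: float = 48.0,
) -> int:
    """Detection period in whole days, counting both endpoint dates.

    A single-day record has a period of 1.  Raises on an empty record —
    an undefined period must not be confused with zero days.
    """
    timestamps = pd.Series(timestamps)
    if len(timestamps) == 0:
        raise ValueError("detection period is undefined for an empty record")
    start = _period_start(release_time, convention, tz_hours, window_h)
    last = local_date(timestamps, tz_hours).max()
    if last < start:
        raise ValueError("last detection precedes the period start")
    return int((last - start) / DAY) + 1


def residency_index(
    timestamps: pd.Series,
    period_days: int,
    tz_hours: float = DEFAULT_TZ_HOURS,
) -> float:
    """Distinct local detection dates divided by the detection period."""
    if period_days < 1:
        raise ValueError("period_days must be >= 1")
    days = local_date(pd.Series(timestamps), tz_hours).nunique()
    return days / period_days


def available_sites(
    receivers: pd.DataFrame,
    period_start: pd.Timestamp,
    period_end: pd.Timestamp,
) -> list[str]:
    """Sites whose deployment interval overlaps [period_start, period_end].

    Any overlap counts.  Interval endpoints are dates; a deployment ending on
    the period's first day is still available.
    """
    start = receivers["active_from"]
    end = receivers["active_to"]
    ok = (start <= period_end) & (end >= period_start)
    return receivers.loc[ok, "site"].tolist()


def roaming_index(
    detections: pd.DataFrame,
    receivers: pd.DataFrame,
    period_start: pd.Timestamp,
    period_end: pd.Timestamp,
) -> tuple[float, int, int]:
    """Unique detected sites over concurrently available sites.

    Returns (roi, n_detected, n_available).
    """
    avail = available_sites(receivers, period_start, period_end)
    if not avail:
        raise ValueError(
            "no receiver was available during the detection period; "
            "array metadata and detections disagree"
        )
    detected = detections["receiver_id"].nunique()
    return detected / len(avail), int(detected), len(avail)


def overall_indices(
    detections: pd.DataFrame,
    receivers: pd.DataFrame,
    tags: pd.DataFrame,
    convention: str = "post_release",
    tz_hours: float = DEFAULT_TZ_HOURS,
    window_h: float = 48.0,
) -> pd.DataFrame:
    """One whole-track index record per detected animal."""
    rows = []
    release = tags.set_index("tag_id")
    for tag_id, g in detections.groupby("tag_id"):
        rt = release.loc[tag_id, "release_time"]
        start = _period_start(rt, convention, tz_hours, window_h)
        period = detection_period(
            g["timestamp"], rt, convention=convention, tz_hours=tz_hours, window_h=window_h
        )
        end = start + (period - 1) * DAY
        dates = local_date(g["timestamp"], tz_hours)
        roi, n_det, n_avail = roaming_index(g, receivers, start, end)
        rows.append(
            {
                "tag_id": tag_id,
                "species": release.loc[tag_id, "species"],
                "scope": "overall",
                "year": np.nan,
                "month": np.nan,
                "days_detected": int(dates.nunique()),
                "period_days": period,
                "resi": dates.nunique() / period,
                "sites_detected": n_det,
                "sites_available": n_avail,
                "roi": roi,
            }
        )
    return pd.DataFrame(rows)


def monthly_indices(
    detections: pd.DataFrame,
    receivers: pd.DataFrame,
    tags: pd.DataFrame,
    min_boundary_days: int = 14,
    convention: str = "post_release",
    tz_hours: float = DEFAULT_TZ_HOURS,
    window_h: float = 48.0,
) -> pd.DataFrame:
    """Per-animal monthly index records.

    A month at the start or end of a detection period is retained only when
    strictly more than ``min_boundary_days`` of it fall inside the period.
    The monthly ResI denominator is the number of days of the month inside
    the period; RoI availability is assessed against that same window.
    """
    rows = []
    release = tags.set_index("tag_id")
    for tag_id, g in detections.groupby("tag_id"):
        rt = release.loc[tag_id, "release_time"]
        start = _period_start(rt, convention, tz_hours, window_h)
        period = detection_period(
            g["timestamp"], rt, convention=convention, tz_hours=tz_hours, window_h=window_h
        )
        end = start + (period - 1) * DAY
        dates = local_date(g["timestamp"], tz_hours)
        for month_start in pd.date_range(
            start.replace(day=1), end.replace(day=1), freq="MS"
        ):
            month_end = month_start + pd.offsets.MonthEnd(0)
            win_start = max(start, month_start)
            win_end = min(end, month_end)
            days_in_period = int((win_end - win_start) / DAY) + 1
            is_boundary = (month_start < start) or (month_end > end)
            if is_boundary and days_in_period <= min_boundary_days:
                continue
            in_month = dates[(dates >= win_start) & (dates <= win_end)]
            roi, n_det, n_avail = roaming_index(
                g.loc[in_month.index], receivers, win_start, win_end
            )
            rows.append(
                {
                    "tag_id": tag_id,
                    "species": release.loc[tag_id, "species"],
                    "scope": "month",
                    "year": month_start.year,
                    "month": month_start.month,
                    "days_detected": int(in_month.nunique()),
                    "period_days": days_in_period,
                    "resi": in_month.nunique() / days_in_period,
                    "sites_detected": n_det,
                    "sites_available": n_avail,
                    "roi": roi,
                }
            )
    return pd.DataFrame(rows)


def size_split(
    total_lengths,
    gap_rule: str = "midpoint",
) -> tuple[float, np.ndarray]:
    """Mechanistic small/large split at the largest interquartile length gap.

    Candidate gaps are those between consecutive sorted total lengths whose
    both endpoints lie within [Q25, Q75] (linear-interpolation quantiles).
    The cutoff is the midpoint of the largest such gap (``gap_rule`` may also
    be ``"lower"`` or ``"upper"``); ties go to the gap whose midpoint is
    closest to the median.  Animals with TL >= cutoff are labelled large.

    Returns (cutoff, labels) with labels in {"small", "large"}.
    """
    tl = np.sort(np.asarray(total_lengths, dtype=float))
    if len(tl) < 4:
        raise ValueError("size split requires at least 4 individuals")
    q25, q50, q75 = np.quantile(tl, [0.25, 0.5, 0.75])
    lo, hi = tl[:-1], tl[1:]
    eligible = (lo >= q25) & (hi <= q75)
    if not eligible.any() or np.all(tl == tl[0]):
        raise ValueError("no length gap inside the interquartile range")
    gaps = hi - lo
    if np.max(gaps[eligible]) <= 0:
        raise ValueError("no length gap inside the interquartile range")
    best = np.max(gaps[eligible])
    cand = np.nonzero(eligible & (gaps == best))[0]
    mids = (lo[cand] + hi[cand]) / 2.0
    pick = cand[np.argmin(np.abs(mids - q50))]
    if gap_rule == "midpoint":
        cutoff = (lo[pick] + hi[pick]) / 2.0
    elif gap_rule == "lower":
        # just above the gap's lower edge, so the edge animal stays small
        cutoff = float(np.nextafter(lo[pick], np.inf))
    elif gap_rule == "upper":
        cutoff = hi[pick]  # smallest length in the large group
    else:
        raise ValueError(f"unknown gap_rule: {gap_rule!r}")
    original = np.asarray(total_lengths, dtype=float)
    labels = np.where(original >= cutoff, "large", "small")
    return float(cutoff), labels


def size_split_table(
    tags: pd.DataFrame, species: list[str] | None = None, gap_rule: str = "midpoint"
) -> pd.DataFrame:
    """Apply :func:`size_split` per species; returns tag_id -> size_class."""
    out = []
    for sp, g in tags.groupby("species"):
        if species is not None and sp not in species:
            continue
        try:
            cutoff, labels = size_split(g["total_length_m"], gap_rule=gap_rule)
        except ValueError:
            continue
        out.append(
            pd.DataFrame(
                {"tag_id": g["tag_id"], "species": sp, "cutoff_m": cutoff, "size_class": labels}
            )
        )
    if not out:
        return pd.DataFrame(columns=["tag_id", "species", "cutoff_m", "size_class"])
    return pd.concat(out, ignore_index=True)
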