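"""End-to-end orchestration: QC -> indices -> activity space -> seasonal -> sites.

A :class:`RunConfig` captures every analysis choice (paths, timezone,
filter thresholds, kernel bandwidth, excluded sites, PERMANOVA terms,
seeds); ``run_all`` executes the stages, writes one tidy CSV per stage
plus a markdown report, and embeds the serialised config so a run is
reproducible from its output directory alone.
"""

from __future__ import annotations

import logging
import shutil
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import activity, community, indices as idx, io, seasonal

log = logging.getLogger("islandrange")

#: sites ignored when building COAs (redundant neighbours of a longer-running
#: station) and sites excluded from the site-use analysis (not deployed for
#: the whole study) — configuration, not code.
DEFAULT_REDUNDANT_SITES = ["Chute", "Jonny"]
DEFAULT_USE_MATRIX_EXCLUSIONS = [
    "Cabbage", "Fishbowl", "Phillip1", "Phillip2", "Chute", "Jonny",
]


@dataclass
class RunConfig:
    detections: str = "detections.csv"
    receivers: str = "receivers.csv"
    tags: str = "tags.csv"
    land: str = "land.geojson"
    out_dir: str = "islandrange_out"
    tz_hours: float = 11.0
    trim_window_h: float = 48.0
    shed_min_days: float = 7.0
    shed_max_gap_h: float = 24.0
    min_period_days: float = 14.0
    period_convention: str = "post_release"
    coa_bin_h: float = 2.0
    jitter_rmax: float = 25.0
    kde_h: float = 300.0
    kde_cell: float = 50.0
    ud_levels: tuple = (50.0, 95.0)
    redundant_sites: list = field(default_factory=lambda: list(DEFAULT_REDUNDANT_SITES))
    use_matrix_exclusions: list = field(
        default_factory=lambda: list(DEFAULT_USE_MATRIX_EXCLUSIONS)
    )
    permanova_unit: str = "individual_month"
    permanova_terms: list = field(
        default_factory=lambda: ["species", "month", "release_site", "sex", "size_class"]
    )
    n_permutations: int = 999
    size_cutoff_species: list = field(default_factory=lambda: ["dusky", "galapagos"])
    fixed_size_cutoffs: dict = field(default_factory=lambda: {"tiger": 3.0})
    jitter_seed: int = 1
    permutation_seed: int = 1
    write_grids: bool = False

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


def _se(x) -> float:
    x = np.asarray(x, dtype=float)
    return float(np.std(x, ddof=1) / np.sqrt(len(x))) if len(x) > 1 else float("nan")


def _mean_se(x) -> str:
    x = np.asarray(x, dtype=float)
    return f"{np.mean(x):.2f} ± {_se(x):.2f}"


def tagging_summary(tags: pd.DataFrame, report: io.FilterReport) -> pd.DataFrame:
    """Per-species tagging table: counts, analyzed subset, length summaries.

    Length statistics are computed over analyzed individuals only (those
    retained by the QC filters), matching the convention of reporting the
    animals that enter the analysis.
    """
    per = report.per_animal
    rows = []
    for sp, g in tags.groupby("species"):
        kept = per.loc[(per["species"] == sp) & (per["flag"] == "retained"), "tag_id"]
        ga = g.loc[g["tag_id"].isin(kept)]
        use = ga if len(ga) else g
        rows.append(
            {
                "species": sp,
                "n_tagged": len(g),
                "n_analyzed": len(ga),
                "n_never_detected": int(
                    (per.loc[per["species"] == sp, "flag"] == "never_detected").sum()
                ),
                "n_short_period": int(
                    (per.loc[per["species"] == sp, "flag"] == "short_period").sum()
                ),
                "n_shed_or_dead": int(
                    (per.loc[per["species"] == sp, "flag"] == "shed_or_dead").sum()
                ),
                "tl_min": use["total_length_m"].min(),
                "tl_max": use["total_length_m"].max(),
                "tl_mean_se": _mean_se(use["total_length_m"]),
            }
        )
    return pd.DataFrame(rows)


def detection_summary(overall: pd.DataFrame) -> pd.DataFrame:
    """Per-species detection table: days detected, period, ResI, RoI."""
    rows = []
    for sp, g in overall.groupby("species"):
        rows.append(
            {
                "species": sp,
                "n": len(g),
                "days_detected_min": int(g["days_detected"].min()),
                "days_detected_max": int(g["days_detected"].max()),
                "days_detected_mean_se": _mean_se(g["days_detected"]),
                "period_min": int(g["period_days"].min()),
                "period_max": int(g["period_days"].max()),
                "period_mean_se": _mean_se(g["period_days"]),
                "resi_min": round(g["resi"].min(), 2),
                "resi_max": round(g["resi"].max(), 2),
                "resi_mean_se": _mean_se(g["resi"]),
                "roi_min": round(g["roi"].min(), 2),
                "roi_max": round(g["roi"].max(), 2),
                "roi_mean_se": _mean_se(g["roi"]),
            }
        )
    return pd.DataFrame(rows)


def _activity_groups(coas: pd.DataFrame, tags: pd.DataFrame, split_species) -> pd.Series:
    """Group label per COA: species, or species@release-site for pier species."""
    meta = tags.set_index("tag_id")
    sp = meta.loc[coas["tag_id"], "species"].to_numpy()
    site = meta.loc[coas["tag_id"], "release_site"].to_numpy()
    return pd.Series(
        np.where(np.isin(sp, list(split_species)), sp + "@" + site, sp),
        index=coas.index,
    )


def run_all(config: RunConfig) -> Path:
    """Execute every stage; returns the output directory.

    Raises on the first stage failure after removing a freshly created
    output directory (pre-existing directories are left in place).
    """
    out = Path(config.out_dir)
    created = not out.exists()
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        config.to_yaml(out / "config.yaml")
        t0 = time.time()

        log.info("stage 1/5: reading inputs and applying QC filters")
        data = io.read_inputs(
            config.detections, config.receivers, config.tags, config.land,
            tz_hours=config.tz_hours,
        )
        det, report = io.qc_pipeline(
            data,
            window_h=config.trim_window_h,
            shed_min_days=config.shed_min_days,
            shed_max_gap_h=config.shed_max_gap_h,
            min_period_days=config.min_period_days,
            convention=config.period_convention,
            tz_hours=config.tz_hours,
        )
        report.per_animal.to_csv(out / "qc_report.csv", index=False)

        log.info("stage 2/5: residency and roaming indices")
        overall = idx.overall_indices(
            det, data.receivers, data.tags,
            convention=config.period_convention, tz_hours=config.tz_hours,
            window_h=config.trim_window_h,
        )
        monthly = idx.monthly_indices(
            det, data.receivers, data.tags,
            convention=config.period_convention, tz_hours=config.tz_hours,
            window_h=config.trim_window_h,
        )
        all_indices = pd.concat([overall, monthly], ignore_index=True)
        all_indices.to_csv(out / "indices.csv", index=False)

        log.info("stage 3/5: centres of activity and utilisation distributions")
        positioned = activity.jitter_detections(
            det, data.receivers, rmax=config.jitter_rmax, rng=config.jitter_seed
        )
        coas = activity.compute_coas(
            positioned, bin_h=config.coa_bin_h, tz_hours=config.tz_hours,
            exclude_sites=config.redundant_sites,
        )
        coas = activity.snap_to_shore(coas, data.land)
        coas.to_csv(out / "coas.csv", index=False)
        groups = _activity_groups(coas, data.tags, config.size_cutoff_species)
        fits, ud_summary = activity.group_uds(
            coas, groups, land=data.land, h=config.kde_h, cell=config.kde_cell,
            levels=tuple(config.ud_levels),
        )
        ud_summary.to_csv(out / "ud_summary.csv", index=False)
        for lv in config.ud_levels:
            activity.overlap_matrix(fits, lv).to_csv(out / f"overlap{int(lv)}.csv")
        if config.write_grids:
            for gname, fit in fits.items():
                safe = str(gname).replace("@", "_at_")
                activity.write_ascii_grid(fit, out / f"ud_{safe}.asc")

        log.info("stage 4/5: seasonal smoothing of monthly indices")
        seasonal_fits = []
        seasonal_tests = []
        for response in ("resi", "roi"):
            model = seasonal.fit_seasonal(all_indices, response=response)
            for sp in model.species_:
                curve = model.predict_curve(sp)
                curve.insert(0, "response", response)
                seasonal_fits.append(curve)
            tests = model.smooth_significance()
            tests.insert(0, "response", response)
            seasonal_tests.append(tests)
        pd.concat(seasonal_fits, ignore_index=True).to_csv(
            out / "seasonal_fit.csv", index=False
        )
        seasonal_tests = pd.concat(seasonal_tests, ignore_index=True)
        seasonal_tests.to_csv(out / "seasonal_tests.csv", index=False)

        log.info("stage 5/5: site-use composition and PERMANOVA")
        use = community.build_use_matrix(
            det, site_exclusions=config.use_matrix_exclusions,
            unit=config.permanova_unit, tz_hours=config.tz_hours,
        )
        sizes = idx.size_split_table(
            data.tags.loc[data.tags["species"].isin(config.size_cutoff_species)]
        )
        fixed = [
            {"tag_id": t, "species": sp, "cutoff_m": c,
             "size_class": "large" if tl >= c else "small"}
            for sp, c in config.fixed_size_cutoffs.items()
            for t, tl in data.tags.loc[
                data.tags["species"] == sp, ["tag_id", "total_length_m"]
            ].itertuples(index=False)
        ]
        if fixed:
            sizes = pd.concat([sizes, pd.DataFrame(fixed)], ignore_index=True)
        use_meta = community.attach_metadata(use, data.tags, sizes)
        use_meta.to_csv(out / "use_matrix.csv", index=False)

        site_cols = [c for c in use.columns if c not in ("tag_id", "year", "month")]
        tables = []
        for label, species_sel, terms in _permanova_plans(config, use_meta):
            sel = use_meta["species"].isin(species_sel)
            sub = use_meta.loc[sel].reset_index(drop=True)
            X = sub[site_cols].to_numpy()
            keep_cols = X.sum(axis=0) > 0
            D = community.bray_curtis(X[:, keep_cols])
            tab = community.permanova(
                D, sub, terms,
                n_permutations=config.n_permutations, seed=config.permutation_seed,
            )
            tab.insert(0, "analysis", label)
            tables.append(tab)
        permanova_tab = pd.concat(tables, ignore_index=True)
        permanova_tab.to_csv(out / "permanova.csv", index=False)

        log.info("writing report")
        _write_report(
            out, config, data, report, overall, ud_summary, fits,
            seasonal_tests, permanova_tab,
        )
        log.info("run complete in %.1f s", time.time() - t0)
        return out
    except Exception:
        log.exception("run failed; removing partial outputs")
        if created:
            shutil.rmtree(out, ignore_errors=True)
        raise
    finally:
        log.removeHandler(handler)
        handler.close()


def _permanova_plans(config: RunConfig, use_meta: pd.DataFrame):
    """Split site-preference tests by species group, as single-tagging-site
    or single-site species cannot carry every factor."""
    plans = []
    resident = [s for s in config.size_cutoff_species if s in set(use_meta["species"])]
    if len(resident) >= 1:
        terms = [t for t in config.permanova_terms]
        ok = [
            t for t in terms
            if use_meta.loc[use_meta["species"].isin(resident), t.split(":")[0]].nunique() > 1
            or ":" in t
        ]
        if len(resident) < 2 and "species" in ok:
            ok.remove("species")
        plans.append(("residents", resident, ok))
    others = sorted(
        set(use_meta["species"]) - set(resident) - {"sandbar"}
    )
    for sp in others:
        sub = use_meta.loc[use_meta["species"] == sp]
        terms = [
            t for t in ("month", "sex", "size_class")
            if t in use_meta.columns and sub[t].nunique() > 1
        ]
        if terms:
            plans.append((sp, [sp], terms))
    return plans


def _md_table(df: pd.DataFrame) -> str:
    header = "| " + " | ".join(str(c) for c in df.columns) + " |"
    sep = "|" + "|".join(["---"] * len(df.columns)) + "|"
    body = [
        "| " + " | ".join(str(v) for v in row) + " |"
        for row in df.itertuples(index=False)
    ]
    return "\n".join([header, sep] + body)


def _write_report(
    out, config, data, report, overall, ud_summary, fits, seasonal_tests, permanova_tab
):
    parts = ["# Island residency and space-use report", ""]
    parts += ["## Tagging summary", "", _md_table(tagging_summary(data.tags, report)), ""]
    parts += ["## Detection summary", "", _md_table(detection_summary(overall)), ""]
    parts += ["## Utilisation distribution areas (km²)", "", _md_table(ud_summary.round(3)), ""]
    for lv in config.ud_levels:
        m = activity.overlap_matrix(fits, lv).round(3)
        parts += [f"## UD overlap at {int(lv)}%", "", _md_table(m.reset_index()), ""]
    parts += ["## Seasonal smooth tests", "", _md_table(seasonal_tests.round(4)), ""]
    parts += ["## Site-preference PERMANOVA", "", _md_table(permanova_tab.round(4)), ""]
    (Path(out) / "report.md").write_text("\n".join(parts))
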