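# islandrange

Comparative space-use analysis for passive acoustic telemetry around
islands and seamounts.  Movement ecologists tagging co-occurring shark
(or other large fish) species at a remote island face the same analysis
chain every time: clean the detection record, quantify how resident and
how mobile each animal is, estimate where each species concentrates its
activity, test whether site preferences differ by species, season, size,
sex or release site — and do all of it reproducibly.  `islandrange`
implements that chain as a tested library with a thin CLI, plus a
synthetic-island generator so every stage can be validated against known
ground truth.

## What it computes

**Quality control.**  Post-release trimming (first 48 h discarded), a
shed-tag/dead-animal filter (records ending in a continuous multi-day
single-receiver run), and exclusion of animals detected over ≤ 14 days.

**Residency and roaming.**  For each animal with detection period *T*
(first eligible date to last detection, inclusive):

- residency index `ResI = (days with ≥ 1 detection) / |T|`
- roaming index `RoI = (sites with detections) / (sites available during T)`

computed whole-track and per calendar month (boundary months kept only
when covering > 14 days).

**Activity space.**  2-h centre-of-activity (COA) positions — the mean
of detection positions jittered uniformly 0–25 m from their receiver —
snapped to shore when on land, then a fixed-bandwidth Gaussian kernel
utilisation distribution (h = 300 m, 50-m grid, land masked and the
surface renormalised over water).  50%/95% UD areas and the pairwise
overlap `area(A∩B) / mean(area A, area B)`.

**Seasonality.**  A GAMM-style model per index:
`y = β_sp + s_sp(month) + b_animal + b_year + ε`, with `s_sp` a cyclic
penalized cubic spline (period 12, k = 12) and REML-estimated smoothing
parameters and variance components; per-species Wald/F tests of the
smooth, with a within-animal permutation alternative.

**Site preference.**  Individual(-month) × site proportions of hourly
detection presence, Bray–Curtis distances, and a from-scratch sequential
PERMANOVA (pseudo-F, R², permutation p with 999 permutations),
cross-checked against scikit-bio and vegan.

**Synthetic island.**  A scenario generator (ellipse island, 21-receiver
array with late deployments, four species archetypes, logistic detection
range 50% at 250 m, shed-tag and never-detected artefacts) whose ground
truth exercises the full pipeline end to end.

## Worked example

Simulate a scaled synthetic island (one sixth of the animals, 20
months), run QC, and summarise the indices:

```python
from islandrange.simulate import default_scenario, simulate_dataset, as_telemetry_data
from islandrange import io, indices as idx

sc = default_scenario()
for a in sc.archetypes:
    a.n_animals = max(4, a.n_animals // 6)
    if a.name == "offshore_seasonal":
        a.release_window = ("2021-03-01", "2021-05-01")
sc.study_end = "2022-10-01"

ds = simulate_dataset(sc, seed=11)
data = as_telemetry_data(ds)
det, report = io.qc_pipeline(data)
print(f"{len(ds['detections'])} detections from {ds['tags'].shape[0]} tagged animals")
print(report.summary().to_string(index=False))
overall = idx.overall_indices(det, data.receivers, data.tags)
print(overall.groupby("species")[["resi", "roi"]].mean().round(2).to_string())
```

prints

```
334285 detections from 21 tagged animals
          flag  n_animals
never_detected          5
      retained         16
           resi   roi
species
dusky      0.52  0.58
galapagos  0.48  0.61
tiger      0.32  0.94
```

The pier-resident archetypes (dusky, galapagos) are detected roughly
every other day (ResI ≈ 0.5) at a moderate share of sites; the seasonal
migrant archetype (tiger) is absent for months at a time (lower ResI)
but, when present, roams across nearly the whole array (RoI 0.94).  Five
animals were tagged but never detected and are reported, not silently
dropped.

The same analysis from the shell:

```bash
islandrange simulate --seed 7 --out data/
islandrange run --config run.yaml      # all stages + report.md
```

`islandrange run` writes per-stage CSVs (`qc_report.csv`, `indices.csv`,
`coas.csv`, `ud_summary.csv`, `overlap50.csv`, `seasonal_fit.csv`,
`seasonal_tests.csv`, `use_matrix.csv`, `permanova.csv`), a markdown
report with tagging/detection summaries, UD areas, overlap matrices,
seasonal tests and PERMANOVA tables, and a copy of the config for
reproducibility.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

regenerates the default synthetic scenario from the given seed and runs
the complete pipeline on it — QC, whole-track and monthly indices, the
cyclic seasonal smoother for both indices, jittered COAs, land-masked
kernel UDs with overlap matrices, and the site-preference PERMANOVA —
writing its JSON summary to `--out`.

## Layout

- `src/islandrange/geo.py` — ellipsoidal azimuthal-equidistant frame, land masks, shore snapping
- `src/islandrange/io.py` — IMOS-dialect readers, validation, QC filters
- `src/islandrange/indices.py` — detection period, ResI/RoI, monthly rule, size split
- `src/islandrange/activity.py` — jitter, COAs, `KernelUD`, overlap
- `src/islandrange/seasonal.py` — `CyclicSeasonalModel` (cyclic spline + random intercepts, REML)
- `src/islandrange/community.py` — use matrices, Bray–Curtis, `Permanova`
- `src/islandrange/simulate.py` — synthetic island scenarios
- `src/islandrange/pipeline.py`, `cli.py` — orchestration and CLI
- `docs/methods.md` — models, assumptions, numerical choices, limitations
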