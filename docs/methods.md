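# Methods

`islandrange` analyses passive acoustic telemetry from a receiver array
around a small island: which species are present when, how far they range
across the array, which areas and sites they prefer, and how much space
use overlaps between species.  This note records the models, the choices
behind them, and what the synthetic-data tests do and do not establish.

## Coordinate frame

All metric computation happens in a local azimuthal-equidistant frame
centred on the centroid of the land polygon.  The projection is built
directly on WGS84 geodesics (Vincenty inverse/direct): a point maps to
(s·sin α, s·cos α) where s and α are geodesic distance and azimuth from
the centre.  Distances from the centre are exact; pairwise distances at
island scale (< 30 km) are accurate to well under 0.1%, comfortably below
the positional noise of the data.  A spherical projection was rejected:
at |lat| ≈ 29° the ellipsoid's meridional/normal curvature anisotropy is
±0.26%, violating the 0.2% isometry budget we impose on the frame.

Calendar "days" are counted in a configurable fixed-offset local timezone
(default UTC+11, appropriate for the south-west Pacific).  All timestamps
are stored UTC; only day/month binning uses the offset.

## Detection quality control

Three sequential filters, each configurable:

1. **Post-release trim** (`window_h`, default 48 h): every detection at or
   before release + 48 h is dropped (closed window), removing behaviour
   confounded by capture and tagging.
2. **Shed-tag / dead-animal filter** (`min_days` = 7, `max_gap_h` = 24):
   an animal is removed entirely when its record *ends* in a continuous
   single-receiver run — the terminal run at the last receiver, truncated
   at the last silence longer than `max_gap_h`, spanning at least
   `min_days`.  The truncation matters: a live animal that genuinely
   visited the same site earlier (with multi-day absences in between)
   must not mask a true stationary-transmitter signature.  The whole
   animal is removed, not just the run, because once the transmitter is
   known to have been shed (or the animal dead) no earlier boundary can
   be trusted from the detection record alone.
3. **Minimum detection period**: animals detected over a period of 14
   days or less are excluded (retention requires strictly > 14 days);
   such animals most likely left the study area and do not represent
   local habitat use.

Two conventions exist in the field for when the detection period starts:
at the tagging date, or at the end of the post-release window.  Both are
implemented (`convention="tagging" | "post_release"`); the default is
`post_release` and every report records which was used.  The period ends
on the date of last detection and counts both endpoint dates (a
single-day record has period 1).

Every excluded animal carries exactly one primary flag —
`shed_or_dead`, `short_period`, or `never_detected` — in the filter
report.

## Residency and roaming indices

* **ResI** = (number of local days with ≥ 1 detection anywhere) /
  (detection-period days) ∈ [0, 1].
* **RoI** = (unique receiver sites with detections) / (sites whose
  deployment overlapped the detection period) ∈ [0, 1].  *Any* temporal
  overlap makes a site available; the data cannot resolve partial-month
  availability more finely without modelling detectability itself.

Monthly indices use the same formulas per calendar month, with the ResI
denominator equal to the number of days of that month inside the period,
and RoI availability judged against that same sub-window.  Boundary
months are kept only when more than 14 days of them fall inside the
period — below that the indices are dominated by sampling noise.

**Size split.**  Where maturity cannot be assigned, species are split
into small/large at the midpoint of the largest gap between consecutive
sorted total lengths whose endpoints both lie within [Q25, Q75]
(linear-interpolation quantiles).  Ties go to the gap whose midpoint is
closest to the median.  The cutoff convention (`gap_rule`:
midpoint/lower/upper) only moves the reported number, never the labels,
because no animal lies inside the chosen gap.

## Activity space

Raw detections are converted to 2-h **centres of activity** (COAs): each
detection is placed at its receiver plus a uniform jitter (distance ~
U(0, 25) m, angle ~ U(0, 2π)); the COA is the mean jittered position per
(animal, 2-h bin), which equals the detection-count-weighted mean of
receiver positions up to jitter noise.  Bins anchor at local midnight.
Stations deployed within a few hundred metres of a longer-running
neighbour are excluded first (a configuration list), so a tight receiver
cluster is represented once.  COAs falling on land are snapped to the
nearest shoreline point.

The utilisation distribution is a fixed-bandwidth bivariate Gaussian KDE
(`h` = 300 m on both axes, no cross term) evaluated on a regular grid
(cell 50 m, padding 4 h beyond the COA bounding box) by binning COAs and
convolving with a Gaussian (`scipy.ndimage.gaussian_filter`, truncated at
8 σ).  Binning displaces a COA by at most half a cell (25 m ≪ h) and is
what keeps multi-million-detection datasets tractable.  Land cells are
zeroed and the surface renormalised over water (clipping without
renormalisation is available via `renormalize=False`).  The level-p UD is
the smallest set of cells whose cumulative mass reaches p, with cells
ranked by density and ties broken deterministically by cell index; its
area is the cell count × cell².  On a single COA this reproduces the
bivariate-normal highest-density closed forms (π·5.991·h² at 95%,
π·1.386·h² at 50%) within one cell area.

**Overlap** between two groups at level p is area(A∩B) / mean(area(A),
area(B)): 1 for identical UDs, 0 for disjoint ones, and never above 1.
Groups share one grid frame so intersections are cellwise.

## Seasonal smoother

Monthly indices are modelled as

y = β_species + s_species(month) + b_animal + b_year + ε

with s a cyclic penalized cubic B-spline (12 basis functions, period 12;
coefficients folded modulo 12 so value and all derivatives are continuous
across the December–January wrap) and a cyclic second-difference penalty.
Each smooth is re-expressed in mixed-model form through the penalty
eigenbasis, giving one variance ratio per species smooth plus variance
components for animal and year; all ratios are estimated by REML on the
Gaussian working model (profiled residual variance, Nelder–Mead on the
log ratios, Woodbury identities on the random-effects cross-products so
each objective evaluation is O(q³) for q ≈ 10²).  Indices live on [0, 1];
the identity link keeps effects on the index scale (a logit transform is
available but makes amplitudes harder to read and was not needed for
calibration).

**Significance** of each species' smooth is a Wald/F test of the
*unpenalized* spline basis: with the animal/year variance ratios held at
their REML estimates, the GLS residual sums of squares with and without
that species' basis give F = (ΔRSS/d) / (RSS_full/(n−p)).  A test built
on the penalized (shrunk) coefficients with an edf-rank pseudoinverse was
rejected during development: rank truncation by posterior variance drops
exactly the low-frequency directions that carry seasonal signal.  The
unpenalized GLS form is empirically calibrated — type-I error 0.056 at
α = 0.05 over 500 simulated null datasets — and its power against a
0.3-amplitude seasonal signal is effectively 1.  A permutation variant
(months shuffled within animal, smoothing parameters fixed, ≥ 999
permutations, p floored at 1/(n+1)) is available when the Gaussian
working model is in doubt.

## Site-use composition and PERMANOVA

Analysis units are individuals or individual-months (default; month is a
tested factor).  Each unit's row is the proportion of its *hourly
detection presences* per included site: two detections at one site in
the same hour count once.  Sites not deployed for the whole study are
excluded by configuration.  Rows sum to 1.

Dissimilarity is Bray–Curtis, d(u,v) = Σ|uᵢ−vᵢ|/Σ(uᵢ+vᵢ).  The
PERMANOVA Gower-centres −½d² and reads sequential (Type-I) sums of
squares off nested orthonormal projections of the factor design; term
order is configurable (species, month, release site, sex, size by
default).  pseudo-F = (SS_term/df)/(SS_res/df_res); p-values come from
free permutation of unit labels, p = (1 + #{F* ≥ F}) / (1 + n_perm),
default 999 permutations.  With repeated rows per animal free
permutation overstates exchangeability; a strata option (permute within
individual) is provided and the default is a documented caveat.  On
univariate Euclidean distances the pseudo-F reproduces the classical
one-way ANOVA F exactly, and the implementation is cross-checked against
scikit-bio and vegan::adonis2 in the test suite.

## Synthetic island generator

The generator states a world whose downstream truths are known:

* an elliptical island (8 × 5 km) with a 21-receiver array: pier sites on
  the north-east and south coasts, a west-coast hotspot flanked by two
  redundant stations ~300 m away, an offshore deep cluster ~6 km south,
  and three stations deployed two years late;
* four archetypes with the tagged-animal numbers of the emulated field
  setting (47 seasonal migrants, 34 + 32 pier residents, 20 offshore
  seasonal animals): a **seasonal migrant generalist** (present ~85% of
  summer days, ~2% June–October, hotspot weighted 3×, highly mobile), two
  **resident pier-attached species** (flat ~0.5 daily presence, own
  release site weighted 6×), and an **offshore site-attached seasonal
  species** (uses only the offshore cluster, transmitter interval
  90–150 s instead of 80–140 s);
* movement: presence is drawn per *day* from the month's probability
  (the daily-residency recovery property fixes this choice; per-step
  draws would inflate day-level presence to 1−(1−p)¹²); a daily anchor
  site persists with probability 1−`daily_transition`; 2-h positions are
  anchor + isotropic Gaussian scatter.  Scatter s.d. (400–800 m) is set
  larger than the detection range so that a present animal is within
  range for only part of a day — with scatter below the detection range
  every present animal would be logged essentially continuously, which
  neither matches real arrays nor stays computationally reasonable;
* detection: within each 2-h step the transmitter emits with gaps ~
  U(lo, hi); each transmission is detected independently by each active
  receiver with p(d) = 1/(1+exp((d−250)/50)) — 50% at 250 m, ~0.99 at
  the receiver, <10⁻⁴ beyond ~700 m.  The logistic scale (50 m) is a
  choice; only the 50%-at-250 m point is anchored to field range tests;
* artefacts: never-detected animals (per-archetype probabilities 0.04 to
  0.5) lose all detections; shed tags switch, at a random date, to a
  continuous single-receiver ping train until study end.  The train is
  emitted at a 10-min cadence rather than the true transmitter cadence —
  far below the 24-h QC gap threshold, so the flag's behaviour is
  unchanged while the synthetic tables stay tractable.

What a green synthetic test establishes: the formulas, filters, smoother
and tests recover programmed truths (seasonal absences, hotspot
preference, release-site fidelity, shed-tag signatures) through the full
detection physics.  What it does not: real tag-collision interference,
range variation with sea state, clock drift, or behaviour more complex
than anchor-plus-scatter movement.  Quantities that depend on the real
study's data (species mean indices, UD areas in km²) are therefore not
asserted against the synthetic world.

## Numerical notes and limitations

* KDE contour areas are grid-quantised (one 50-m cell ≈ 0.0025 km²);
  bandwidth is taken as given, not estimated.
* REML uses a derivative-free optimizer with variance ratios clamped to
  e^±25; the reported trace is the best-so-far objective and is
  non-increasing by construction.
* The smoother assumes Gaussian errors on [0,1] indices; near the
  boundaries (ResI ≈ 0 or 1) intervals can spill outside [0,1].
* PERMANOVA assumes exchangeable units under the null; with
  individual-month units the default free permutation is liberal for
  strongly autocorrelated individuals (use `strata`).
* The size-split requires ≥ 4 animals and a positive interquartile gap;
  degenerate inputs raise rather than guess.
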