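# Methods notes

This note documents the models and procedures implemented in `aukforage`,
the defaults and why they were chosen, what the synthetic-data generators do
and do not emulate, and the numerical conventions that matter when comparing
output against other software.

## Geometry

All coordinates travel as WGS84 lon/lat. Metric work happens in a local
spherical azimuthal-equidistant frame centred on the colony (default
70.733°N, 21.583°W), in km, with R = 6371 km. Distances from the projection
centre are exact great-circle distances; at the ≤ 200 km scale of a little
auk foraging range the distortion of other distances is well below 0.5%,
smaller than GPS fix error at a 15-min interval. Polygon work (ice
distance, kernel overlap, regional means) is done on vertex-projected
geometries, so curved edges are approximated by chords; synthetic polygons
are densified enough that this is negligible. Segment speeds and path
lengths use the haversine great-circle distance directly (no projection).

## Track classification and trips

- The speed assigned to a fix is the great-circle distance from the
  previous fix divided by the elapsed time — at a 15-min interval this is
  the only "instant" speed available.
- Behaviour: speed < 10 km/h ⇒ `forage_rest`, else `travel`. The
  comparison is strict, so exactly 10.0 km/h is travel. Foraging and
  resting are merged deliberately: they cannot be separated at this
  sampling rate and co-occur spatially.
- The first fix of each bird has undefined speed and is excluded from
  behavioural tallies; segments spanning a gap longer than 3× the bird's
  median fix interval are flagged and excluded from labelling (GPS
  dropouts should not manufacture slow "foraging" segments).
- A trip is a maximal run of fixes more than `radius_km` (default 1.0 km;
  the choice is not critical because commuting legs cross any plausible
  radius within one fix) from the colony; it is complete when bracketed by
  inside-radius fixes. Duration runs from the first to the last outside
  fix; path length sums segment distances within the outside run.
  Incomplete trips keep their maximum distance but contribute no duration
  or path length to summaries.
- Year comparisons use the two-sided Wilcoxon rank-sum test. The reported
  W is the Mann–Whitney U of the first sample (what R's `wilcox.test`
  prints); p is exact when the combined n ≤ 20 and there are no ties,
  otherwise a normal approximation with continuity correction.

## Utilization distributions and overlap

- UD: bivariate Gaussian product kernel on a regular grid (default
  200 × 200 cells, extent = point bounding box padded by 3 bandwidths),
  renormalised to unit mass on the grid.
- Bandwidth: the "ad-hoc"/reference rule h = σ·n^(−1/6) with
  σ = sqrt((var_x + var_y)/2), the convention of classical home-range
  tools. A fixed bandwidth can be passed instead.
- Volume contour: grid cells sorted by density, accumulated until the
  target mass (default 0.75) is reached, then polygonised (row runs of
  cells merged into rectangles before the union). The contained mass
  therefore overshoots the level by at most one cell's mass. For an
  isotropic normal UD with variance σ², the 75% contour area is
  π σ²·(−2 ln 0.25) ≈ 2.77 π σ²; the KDE of N(0, σ²I) samples smooths to
  variance σ² + h², which the tests account for.
- Overlap is reported against all three denominators (area of A, of B, and
  of the union), because "percentage of overlap" between a kernel and a
  habitat band is inherently ambiguous; pick the denominator that answers
  your question. The shelf-break band (between the 500 m and 1500 m
  isobaths) can be built from two isobath polylines by closing them along
  their endpoints.

## Dives

- Calibration: Star-Oddi DST micro-TD depths are corrected with the
  pressure-chamber affine law depth = 1.0473·raw + 0.4498 m; G5 and LUL
  tags are identity. Unknown tag models pass through with a warning (or
  raise in strict mode).
- Detection: a dive is a maximal run of samples ≥ `min_depth` (default
  2 m) whose run length × sampling interval is ≥ `min_duration` (default
  8 s). Durations are counted as samples × interval, which makes detection
  invariant to the 1/2/4-s sampling rates for dives at least three samples
  long. The thresholds sit far below the species' typical dives
  (~17–21 m, ~55–60 s), so the reported means are insensitive to them;
  they are configurable. No surface-offset drift correction is applied by
  default.

## Diet

- Composition tables: per-sample relative abundance = count / sample
  total; group statistics are the mean and SD of per-sample RAs, and
  occurrence frequency is the percentage of samples containing the taxon.
  Zero-total samples are excluded with a warning.
- LFSI: point estimate GP_i − E_i on proportions. The parametric
  bootstrap draws GP* and E* independently from plain normals with the
  observed means and SDs — deliberately not truncated to [0, 1], which
  keeps the bootstrap SD at the closed form sqrt(sd_GP² + sd_E²) (0.178
  for the headline taxon, printed 0.18). Percentile confidence intervals;
  a seed (or generator) is required so results are reproducible. Over a
  shared taxon universe the point estimates sum to zero by construction.
- Net-haul densities assume 100% filtration of a vertical WP2 haul:
  density = count / (π (d/2)² · depth), defaults d = 0.57 m, depth = 50 m.
- Between-year tests on published-style summaries use the pooled-variance
  Student's t (df = n₁ + n₂ − 2, which reproduces the printed df = 38 at
  n = 20/20); Welch users can compute from raw data via scipy directly.
  Tests run on raw per-sample RAs, untransformed.
- Calanus species from prosome length: two stage-specific cut-points per
  stage order finmarchicus < glacialis < hyperboreus; a length exactly on
  a cut goes to the larger species. The shipped default cut-points are
  assumed placeholders; `suggest_cutpoints` fits cut-points at the deepest
  KDE minima of a pooled length distribution, which is the recommended
  route for real data.
- Clustering: Bray–Curtis dissimilarities on counts (or relative
  abundances behind a flag) with Ward agglomeration. The default is the
  minimum-variance recursion on squared dissimilarities (ward.D2
  convention); the historical recursion on raw dissimilarities (ward.D) is
  selectable and can group differently — treat group memberships as
  variant-dependent.
- Habitat comparisons: tie-corrected Kruskal–Wallis (H = 0, p = 1 by
  convention when every observation is identical), pairwise two-sided
  Wilcoxon, and a compact letter display from the maximal cliques of the
  not-significantly-different graph at the stated α.

## Growth and condition

- Growth: random-intercept LMMs (grouping: chick) on the linear window
  age 4–14 d, fitted by ML — not REML — because candidates differ in fixed
  effects. Candidates: all combinations of age and year plus their
  interaction. k counts fixed effects + the random-intercept variance +
  the residual variance, and AIC = 2k − 2 logL with that k (software
  differs here; comparisons across packages should check the convention).
  Selection: among converged fits within 2 AIC of the best, the fewest
  parameters wins; ties break to lower AIC. Fits that do not converge or
  return a non-finite likelihood are excluded.
- Condition: the index is the residual of a pooled OLS of mass on wing and
  head-bill length. The headline between-year test is the one-way F on
  those residuals (df matches the published convention: n − 2 for two
  years); the covariate-adjusted ANCOVA F is also reported since the two
  can disagree when size distributions shift between years.

## Sea ice

Regional mean SIC is the unweighted mean over grid cells inside the region
polygon and days inside the window (default: a 150 × 200 km rectangle
centred on the colony, 15 July – 15 August, spanning chick rearing).
Missing cells are ignored and counted. Equal weighting is appropriate for a
~12.5 km near-equal-area product; cosine-latitude weighting is available
behind a flag. The trend is OLS of yearly mean SIC on year with
t = slope/SE on n − 2 df; a constant series raises rather than reporting an
undefined t.

## Synthetic data: what it emulates, and what it does not

One deterministic RNG substream per generator (keyed, not positional), so
adding a generator never changes another's output; identical configs give
byte-identical files. Ground truth is always written alongside the data,
never inside it.

- Tracks: one trip per bird — straight eastward commute at 45 km/h
  (typical auk flight speed) to an apex ~ N(100, 26²) km (bracketing the
  observed yearly means 88.7 and 108.2 with the observed SD ≈ 26), a
  20–28 h low-speed forage/rest cluster (positions jittered 0.6 km around
  the apex, implying speeds of a few km/h), and a straight return. The
  within-trip time budget is a free parameter, not an estimate — no field
  time budget exists to anchor it. Real tracks have tortuous commutes,
  wind drift and multi-patch foraging; none of that is emulated, so
  passing tests validate the estimators' arithmetic, not their behaviour
  on messy trajectories.
- Dives: square-wave profiles; Poisson(270/day) dives, depth ~ N(19, 4²) m
  and duration ~ N(57, 6²) s (between the two observed yearly means), with
  sub-decimetre surface noise. No descent/ascent ramps, wiggles or drift,
  so detector recovery near 100% is expected by construction.
- Zooplankton: Dirichlet-multinomial counts (concentration 50, moderate
  overdispersion) around the observed community composition of each
  bathymetric stratum; pouch loads from clipped-normal RA vectors around
  the observed per-year means/SDs. Clipping at zero biases extremely
  skewed taxa slightly; the dominant taxa are unaffected.
- Growth: mass = 21 + 6·age + chick intercept (SD 6 g) + noise (SD 5 g),
  ages 4–14 every second day, optional injected year effect. Morphometrics:
  mass linear in wing and head-bill with N(0, 8²) g residuals.
- Sea ice: i.i.d. clipped-normal fields per day on a 12.5-km grid — no
  spatial or temporal autocorrelation, so it exercises the averaging and
  trend machinery only.

## Problem sizes

Defaults in the tests and acceptance script were chosen as the smallest
sizes at which the estimators' sampling error is comfortably inside the
asserted tolerances: 6–50 birds per scenario, one 24-h TDR record, 10–20
haul samples per stratum, 30–50 chicks, 1000-replicate type-I-error
simulations, and 10⁵-point Monte-Carlo area oracles.

## Known limitations

- The kernel estimator is a plain product-kernel KDE: no Brownian-bridge
  or autocorrelation-aware variants, and positions are treated as
  independent, which overstates effective sample size on real tracks.
- Trip-boundary and dive-definition thresholds are assumptions (documented
  above), not field-calibrated values.
- Compact letter displays are exact only for the handful of strata used
  here (clique enumeration is exponential and capped at 12 groups).
- The ward.D/ward.D2 choice, the bootstrap CI type (percentile), and the
  overlap denominator all change numbers; each is flagged at the API
  surface rather than silently fixed.
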