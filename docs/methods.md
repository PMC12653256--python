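# Methods

## Trajectory model

Migrating planthoppers are modelled as passive tracers at a single
representative flight level (1000 m nominal; the level is metadata —
no vertical motion or terrain following). Backward integration uses
the Petterssen predictor–corrector (an iterated implicit midpoint
rule): from position **x** at time *t*, the predictor is
**x**₁ = **x** + **v**(**x**, t)·Δt and the corrector iterates
**x**₁ ← **x** + ½[**v**(**x**, t) + **v**(**x**₁, t+Δt)]·Δt until the
update falls below 10⁻¹² deg (at most 4 iterations). Velocities are
converted to degree rates with a spherical-Earth metric,
dlat/dt = v/111 320 m deg⁻¹ and dlon/dt = u/(111 320·cos φ); under a
uniform wind the scheme is exact to machine precision, and in sheared
synthetic fields forward re-integration from a backward endpoint
returns to the landing point within 2 km at the default 6-minute step.

Behavioural constraints:

* **Takeoff** at the most recent 19:00 (local clock, UTC+8 throughout;
  the pipeline does no timezone arithmetic) strictly before the
  landing time, so flight duration is 1–24 h by construction.
* **Temperature floor** 16.5 °C, enforced at the landing point and at
  every integration step. A violation truncates the trajectory
  (`truncated_temp`) and it contributes no endpoint: a backward
  simulation cannot distinguish landing from never-flying, so the path
  segment beyond the first violation is treated as invalid rather than
  as a landing trigger.
* **Landing hours**: trap catches are scored per night, so the default
  enumerates hourly landings 20:00–06:00 of the capture night (11
  backward trajectories per event, durations 1–11 h). The full
  physiological window 20:00→19:00 next day (durations up to 24 h) is
  available via `FlightConfig.full_window()`. Which landing hours the
  original field analysis launched is not recorded anywhere we know
  of; the nocturnal default is our assumption and is config-visible.
* Trajectories leaving the meteorological grid are flagged
  (`exited_domain`), excluded from endpoint sets, and counted in the
  run report.

Wind/temperature fields live on a regular (time, lat, lon) grid at one
level; sampling is bilinear in space and linear in time, so node
values are reproduced exactly and interpolants stay within the bounds
of the surrounding knots. Readers accept CF-style NetCDF (classic
format via the scipy engine) and a hand-writable long-format CSV
dialect (`time, lat, lon, u, v, T`). Descending axes are normalised to
ascending on load. Longitudes are degrees east in [−180, 180); no
antimeridian wraparound (the study domain is far from it).

## Valid-source screening

Endpoints pass three criteria, evaluated in order with the first
failure reported: (1) not north of the 25° N cutoff — rice north of it
is still at sowing/seedling stage in May and cannot supply emigrants;
the cutoff is a strict "north of", so latitude exactly 25.0 is
retained; (2) inside a rice polygon (GeoJSON with `rice`/`macroptery`
properties, or a 0/1 raster converted to cell boxes); (3) the polygon
hosts macropterous adults. Point-in-polygon tests are planar in
geographic coordinates; across a <15° domain the error is negligible
at the 0.5° analysis resolution. The audit counts every endpoint
exactly once (partition property), and enlarging the mask can only
grow the valid set (monotonicity) — both are property-tested.

## Density mapping

Valid endpoints are counted on a half-open 0.5° fishnet
(`[edge, edge+size)`, so edge points belong to the higher cell) and
normalised to probabilities per endpoint set (per destination group).
Interpolation to a surface uses Sibson natural-neighbour weights
computed by explicit Voronoi area-stealing on the non-empty cell
centroids (shapely's Voronoi diagram, clipped to a padded envelope;
for queries inside the convex hull the inserted cell is bounded, so
the envelope cannot affect the weights). Queries outside the hull are
returned as NaN, never extrapolated. A barycentric linear fallback is
provided for robustness comparisons. Whether the original maps
interpolated cell centroids or raw points, and how they normalised, is
unrecorded; centroid probabilities per group are our choice. The
interface requires ≥3 non-collinear data cells and raises a
degenerate-geometry error otherwise (the 2-point case is rejected
rather than silently reduced to 1-D interpolation).

## Probit dose–mortality analysis

Replicates are pooled per concentration, control mortality above 10 %
discards the assay, and Abbott's correction is applied whenever the
control shows non-zero mortality at or below 10 %. The probit line
Φ⁻¹(p) = α + β·log₁₀ c (base-10 logarithm, the classic Finney
convention) is fitted by Fisher scoring with step-halving; convergence
requires the score norm below 10⁻⁸ within 100 iterations. All-dead or
all-alive corrected responses raise a separation error.

Two numerical points deserve emphasis:

* **Control-rate uncertainty.** The plug-in Abbott correction shifts
  every corrected response by the same estimated control rate; the
  binomial Fisher information is blind to that error source, and with
  a 5 % control rate estimated from 80 insects the induced variance in
  log LC50 is comparable to the binomial variance itself. We propagate
  Var(ĉ) = ĉ(1−ĉ)/n₀ into the parameter covariance by the delta
  method. Without this, measured CI coverage drops and same-truth
  populations are declared different ~4× too often.
* **Heterogeneity.** Pearson χ² over dose groups (df = k−2) measures
  lack of fit. The covariance is inflated by h = χ²/df only when χ²
  is significant at α = 0.05 (Finney's convention). Inflating whenever
  χ²/df > 1 systematically overcovers on-model data (97.0 % measured
  vs 96.0 % for the gated rule at the reference design, 4000
  replicates), which would distort the CI-overlap test the attribution
  rests on.

The 95 % CI for LC50 comes from Fieller's theorem: the roots of
(α + βm)² = z²(v₁₁ + 2m·v₁₂ + m²v₂₂) in m = log₁₀ LC50,
back-transformed; when g = z²v₂₂/β² ≥ 1 the interval is unbounded and
an error is raised. The delta method is available for comparison and
agrees to 3 significant figures when the slope is precise. LC50 is
equivariant under concentration rescaling, and simulated-data coverage
at the reference design is 96 % (within the nominal 95 ± 2 band).

## Grouping and attribution

Significance between two populations is declared by non-overlapping
95 % CIs (α = 0.05, no multiplicity correction — deliberately matching
the field convention this analysis follows). The compact letter
display uses insertion–absorption: starting from one letter containing
everything, each significantly different pair splits the letters that
contain both, and absorbed (subset) letters are dropped; populations
are processed in ascending LC50 so letter naming is deterministic, and
the letters provably reproduce the pairwise matrix in both directions
(property-tested on random interval sets).

Destination groups are the CLD classes, required to (i) be
single-letter per site and (ii) agree across the two insecticides.
Group ranges are pooled as the interval envelope (min lower, max
upper). The matching rule defaults to **both_all**: source S is
attributed to group G iff for *both* insecticides S's CI overlaps the
CI of *every* member of G. The disjunctive reading ("pymetrozine or
nitenpyram") is selectable (`either_all`), as is envelope matching
(`both_pooled`), but only the conjunctive rule jointly reproduces the
published match lists, which is why it is the default.

Letters are always recomputed from the intervals. Where printed
letters contradict strict overlap the pair is emitted in a discrepancy
report: on the packaged tables this flags Xingbin–Youxian and
Xingbin–Babu for nitenpyram (overlap but no shared printed letter) and
six pymetrozine pairs among {Fangchenggang, Hepu, Bobai} ×
{Zhaoping, Babu} (shared printed letter "c" but disjoint CIs). None of
these affects attribution, which only tests source-vs-destination
pairs. The published table notes also say "same row" where the
comparison plainly runs down the column; we treat that as a typo.

## Synthetic data and what it does (not) show

The generators emulate the four input kinds: analytic wind scenarios
(uniform, solid-body rotation, Gaussian southwesterly jet — no
reanalysis realism, no turbulence ensembles), Poisson trap series with
immigration pulses, toy rice masks, and binomial bioassays at the
standard design (5 log-spaced concentrations spanning LC10–LC90,
80 insects per concentration, matching the field protocol's 4 × 20
replicates so recovery tests are faithful to its power). A generated
assay whose control mortality exceeds 10 % is discarded and redrawn,
as the lab protocol repeats discarded tests. All generators take an
explicit seed; there is no global random state.

The planted-source scenario drives a uniform 10 m/s southwesterly over
two destination traps, with a rice belt to the southwest, a true
source sharing the destinations' susceptibility truth (pymetrozine
LC50 30 mg/L, slope 3.2; nitenpyram 1.0 mg/L, slope 3.4; 5 % control
mortality — values chosen once as field-realistic) and a decoy source
at 3× both LC50s. The pipeline attributes the destination group to the
true source and rejects the decoy across seeds 0–9. Passing this shows
internal consistency of trajectory + filter + fit + overlap matching
under idealised advection and on-model mortality; it does not validate
against real atmospheric transport, real spatial heterogeneity in
susceptibility, or assay overdispersion beyond binomial.

## Problem sizes and numerical defaults

Simulation-based checks use 500 replicates for median-recovery
targets, 1000 for coverage, and 10 seeds for end-to-end recovery —
sizes at which Monte-Carlo error is comfortably below the decision
tolerances while keeping a full run in seconds to minutes. Defaults:
6-min integration step, 0.5° fishnet, 25.0° N cutoff, 10 % control
rule, 95 % intervals, probit (not logit) link. Known limitations: no
vertical structure or ARL/GDAS decoding (pre-extracted grids only), no
resistance-ratio computation (no reference susceptible strain), CI
overlap is conservative relative to a formal ratio test, and printed
CIs from the original software may differ in the third significant
figure from our Fieller intervals, which is why the packaged tables —
not refits — anchor the published-data attribution.
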