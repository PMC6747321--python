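# Methods

## Problem

A person's inhaled pollutant mass over a day depends on where they were, what
the air there contained, and how hard they were breathing. `pape` estimates
it by partitioning the day into periods, attaching a time-integrated
concentration SZ(p) (μg/m³·min) to each period, and multiplying by the
activity's minute ventilation VE (m³/min). Indoor periods use measured indoor
air; everything else uses an interpolated outdoor surface. "Indoor" means
beacon-covered microenvironments only (here: the monitored workplace); time
spent in shops, vehicles or other unmonitored interiors falls back to the
outdoor surface, which understates the difference between those spaces and
street air.

## Outdoor surfaces

Each hour's station readings of one pollutant are interpolated onto a regular
grid (default 100 × 100 nodes over the station bounding box padded by 5 %).
Four techniques are available:

- **IDW** — weights ∝ d⁻ⁱᵈᵖ, normalised; a convex combination of the data,
  hence bounded and translation-equivariant, but not exact away from the
  power→∞ limit.
- **Simple kriging** — known constant mean (the hour's sample mean unless
  overridden); weights solve C λ = c₀ in covariance form
  C(d) = (c0 + c) − γ(d).
- **Ordinary kriging** — unknown constant mean, Σλ = 1 enforced by a
  Lagrange multiplier.
- **Collocated co-kriging** — ordinary kriging of the primary variable plus
  β · (secondary value at the target − secondary mean). The secondary
  pollutant is only measured at stations, so its target value is itself
  ordinary-kriged with the same variogram before centring. β = 0 or a
  constant secondary field reduce exactly to ordinary kriging.

Variogram families: circular, spherical, exponential, gaussian, all with
γ(0) = 0, nugget c0, partial sill c and range α. Circular and spherical
plateau at c0 + c beyond the range.

**Model selection.** Stations are split into k = 5 near-equal folds by a
seeded permutation (default seed 20170324). Every technique/parameter
combination from the default grids (idp ∈ {0.1, 0.3, 0.5, 0.8, 2, 5}; sill ∈
{1, 10, 100, 250, 500, 600, 700, 800, 900}; range ∈ {0.1, 0.5, 1, 10, 20, 50,
80}; nugget ∈ {1e-5, 1e-4, 1e-3, 0.01, 0.1, 1, 10, 50, 100, 200}; β ∈ {0.05,
0.12, 0.2, 0.5, 0.9, 1, 1.5, 3}; variogram ∈ {gaussian, circular,
exponential}) is scored by RMSE pooled over held-out stations; the least-RMSE
spec wins, with exact ties broken IDW < simple < ordinary < co-kriging, then
ascending parameter order, so selection is fully deterministic. The β grid
doubles as the simple-kriging known-mean candidates; for co-kriging only
β ∈ [0, 1] candidates are admissible. The search is vectorised so that one
covariance factorisation per (variogram, fold) serves the simple-kriging,
ordinary-kriging and co-kriging candidates and all β values at once; a full
default-grid search on 24 stations takes about two seconds.

**Numerical choices.** Distances are planar Euclidean on raw lon/lat degrees
— the study area spans under 0.3° and the range grid is degree-scaled —
switchable to haversine km. 1e-10 is added to the kriging matrix diagonal
before solving (the nugget grid reaches 1e-5 and gaussian systems are
ill-conditioned); a target within 1e-9° of a station returns that station's
value with zero variance, which also guards exactness against
regularisation-induced drift. Duplicate station coordinates are averaged with
a warning. Map lookup is bilinear between the four surrounding nodes;
out-of-bounds queries clamp to the nearest edge with a warning.

## Indoor periods

Beacon pings are sorted and split into maximal runs whose inter-ping gaps
never exceed the threshold (default 10 min; a gap of exactly the threshold
does **not** split — the rule is "more than"). Each ping is matched to the
nearest-in-time monitor reading, ties toward the earlier reading; duplicate
matches collapse to one sample per distinct monitor timestamp. SZ is the
trapezoidal integral of the matched samples in minutes — exact for
piecewise-linear signals, additive under splits at any instant (sub-window
SZ linearly interpolates the signal at the cut points), and monotone in the
signal. A single-sample period integrates to 0. The printed form of the SZ
summation is ambiguous about the placement of the ½; the trapezoidal reading
is the only one with correct μg/m³·min units, and is what this package
implements.

## Timeline integration

The activity trace is validated (overlaps rejected, zero-duration rows
dropped), sorted, and gap-filled so it tiles the day midnight-to-midnight:
untracked time becomes "rest" at the preceding segment's coordinates (the
following segment's for a leading gap). Indoor periods then replace outdoor
time: a period straddling trace segments is split at segment boundaries so
each piece inherits one activity, and its SZ is recomputed over the
sub-window, preserving the total. Outdoor SZ sums hourly map lookups at the
segment's representative coordinate weighted by minutes of overlap with each
hour. Every record satisfies exposure = SZ × VE identically, and the records
partition the day with no gaps or overlaps. Indoor records may take
explicitly supplied workplace coordinates when those are known to higher
precision than the tracked segment's point.

VE defaults: 0.00893 m³/min at rest and in transport (deliberately shared —
both are near-sedentary), 0.01326 m³/min walking. Running and cycling have no
default and must be supplied; the case-study day never exercises them.

## Route ranking

A route is an ordered list of timestamped waypoints. Per leg, the
concentration is the mean of the map values at the two endpoints (the
sampling rule is a package choice; a dense space–time resampling of a smooth
gradient field agrees within 2 %) and contributes concentration × leg
minutes. Exposure is SZ × VE of the travel activity, so the ranking of
same-activity routes is invariant to the VE value. The ranking reports each
option's percentage saving against a designated baseline route.

## Synthetic scenarios

`synthdata` emulates the study conditions: ~24 stations (default) sampling
an hourly Gaussian random field in a Madrid-like bounding box (mean 10 μg/m³,
partial sill 4, gaussian variogram with 0.08° correlation length, AR(1)
hour-to-hour correlation ρ = 0.8 — PM2.5-like levels with smooth
traffic-driven variation), realised exactly by covariance-matrix Cholesky
factorisation at the sampled sites; a minute-scale indoor stream (baseline
12 μg/m³, diurnal sinusoid of amplitude 5, optional Gaussian noise, 300 s
cadence) with a closed-form integral for oracle checks; beacon pings at 60 s
cadence with 10 % i.i.d. dropout of interior pings (window edges always
kept) and validated >10-min silences between occupancy windows; and a trace
templated on the packaged case-study day. The latent field is jointly
simulated at any requested extra points so truth is known exactly at trace
locations.

What passing the synthetic end-to-end check shows: under dense stations
(n = 100), exact interpolation, noise-free indoor signal and zero dropout,
the pipeline's daily total is within 1 % of the analytic exposure (observed
≈ 0.2 %). What it does not show: performance under real-world station
sparsity, non-Gaussian pollution spikes, beacon radio dropouts correlated
with location, device calibration error, or activity-labelling error — the
generator's fields are smoother and its noise better behaved than real
feeds.

## Problem sizes

The test suite uses grids of 8–40 nodes per axis and reduced CV grids except
where the full default grid is the point of the check (smooth-field model
selection); the acceptance script runs the full default grid on 25 stations
and a 150 × 150 recovery scenario with 100 stations. The whole suite runs in
well under a minute on one core.

## Known limitations

- Co-kriging is the collocated simplification with a scalar β, not a full
  linear model of coregionalisation; cross-variograms are not fitted.
- The outdoor SZ of a segment uses one representative coordinate, not a path
  integral (transport segments in the trace carry a single point).
- Hourly surfaces are piecewise-constant in time; sub-hour outdoor dynamics
  are not modelled.
- Timestamps are timezone-naive local times; the pipeline never crosses a
  DST boundary in the packaged scenarios.
- The empirical variogram is provided for inspection; parameter choice is by
  cross-validated grid search, not curve fitting.
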