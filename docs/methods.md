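# Methods

This note documents the models and procedures implemented in `drivehunt`,
the choices made where the design was genuinely open, and what the
synthetic study conditions do and do not establish.

## Data model and conventions

Coordinates are Euclidean metres in a declared projected CRS; geographic
(lon/lat) input is rejected rather than auto-projected, because every
metric in the pipeline is a Euclidean distance. Timestamps are stored and
compared in UTC; civil clock times (the 08:00 dawn, the 08:00–18:00 day
period, hunt-log start/end columns) are evaluated in a configurable study
time zone (default Europe/Paris). Fixes flagged `fix_ok = False` are kept
for duty-cycle reporting but excluded from all metrics.

## Movement metrics

Steps join consecutive valid fixes. A step longer than
`gap_tolerance_factor` (default 2.0) times the nominal fix interval is
flagged as spanning a missed fix; such composite steps contribute to
cumulative distance (with their count reported) but define no turning
angle and no speed, since a 4-minute composite step biases both the angle
distribution and the speed toward zero. Speeds use the actual per-step
duration, not the nominal interval, so irregular sampling is handled
correctly. Sinuosity is the mean cosine of the defined turning angles,
wrapped to (−π, π].

The immediate distance DistI sums 2-minute steps over the hunt window.
The delayed distance DistD sums hourly steps from the hunt to the first
subsequent 08:00; the window origin defaults to hunt start with a
`delayed_from = "hunt_end"` switch, because the two descriptions of this
window in the source literature differ and both are defensible. Hourly
positions are the valid fixes nearest each grid hour (within half an
hour), so DistD is well defined on the 2-minute duty cycle too.

Net-displacement profiles tile the five days around the hunt into
day (08:00–18:00) and night (18:00–08:00) periods — fixed clock times, not
solar ephemeris — and aggregate per-event median distances from the
encounter point across events, per response group, with quartiles.

## Hunting events and classification

An event is one individual whose valid fix nearest hunt start (within half
the 2-minute interval) lies inside the hunted polygon; animals entering
mid-drive are not events, which matches anchoring the encounter point at
the hunt-start position. A fix exactly on the boundary counts as inside (a
deer standing on the shooting line has not crossed it); an optional signed
buffer lets users erode or dilate the polygon by the GPS error scale.
Classification is a pure function of geometry: *fleeing* iff any valid fix
in the hunt window is strictly outside, even if the animal re-enters.
Events with fewer than two valid fixes, or fewer than half the expected
fixes, in the window are left unclassified rather than guessed.

## Familiarity index

The annual UD is a fixed isotropic Gaussian kernel density of 12-hourly
subsampled relocations on a regular grid (default 10–20 m cells, padded
three bandwidths beyond the data). The default bandwidth is the ad hoc
reference rule h = σ n^{−1/6} with σ² the mean marginal variance — the
default of the kernel home-range tools commonly used for this analysis — 
with a fixed numeric bandwidth as the alternative. Isopleth levels are
found by sorting cell densities and accumulating mass, i.e. each L% region
is the minimal-area superlevel set holding L/100 of the probability;
regions are polygonized by marching squares on the zero-padded grid, with
even-odd ring assembly, and bands are set differences of successive
levels. Overlaps with hunted areas use exact polygon arithmetic (the
raster route agrees within grid tolerance).

The band weights are 1.0, 0.9, …, 0.2 for the nine full-width bands and
0.15 for the half-width terminal band iso(90–95). The intermediate values
are the linear descent consistent with the anchor weights (1.0, 0.9 and
0.15); this is a documented choice, as only the first two and the last
coefficient are fixed by the index definition.

## Return times

The post-hunt clock starts at the first valid fix outside the polygon at
or after hunt start (for stayers, their first exit after the hunters
leave) and stops at the first return, defined as `min_dwell_fixes`
(default 1) consecutive inside fixes. The control duration is measured
backwards from hunt start: the entry fix of the presence spell containing
the start, minus the preceding exit fix. Both are right-censored at 144 h;
a single horizon keeps the two conditions comparable even though the
source design phrases them slightly differently (6 days vs one week), and
it is switchable per condition. Exactly-72-h durations code as long
returns (the dichotomy's boundary is open in its verbal definition and
measure-zero in practice); records censored before 72 h leave the
indicator undefined. Kaplan–Meier estimation uses lifelines, with its
default 95% band; the bimodality of return times is reported descriptively
(histogram plus a valley/peak ratio, censored durations stacked at the
horizon), not re-fitted as a mixture.

## Response models

The log-distance model is a linear mixed model with the five covariates on
their natural scales and a per-individual random intercept, fitted by
REML via statsmodels MixedLM. Internally the covariates are standardized
for conditioning and the estimates and covariance transformed back, so
reported coefficients are on natural scales. Intervals are Wald at 95%
and 75%. With a single individual the model degrades to OLS with
sigma_u pinned at 0 and a recorded warning. The fitting contract is
estimate-plus-intervals; a Bayesian backend with weakly informative
priors would satisfy the same contract, and the backend used is recorded
in the result.

The short-return model is a Bernoulli GLMM with logit link, random
intercept only: the additive Gaussian residual sometimes written alongside
such models is not identifiable in a standard binary GLMM and is not
implemented. The marginal likelihood integrates the random intercept by
Gauss–Hermite quadrature (30 nodes) per individual, maximized by L-BFGS-B
over (β, log σ_u); standard errors come from the numerical Hessian. A
constant response raises a separation error; exploding estimates set a
separation flag with the interval blow-up visible in the output. In a
test, the fit is cross-checked against ordinary logistic regression in
the σ_u = 0 regime.

The flee/stay contrast of cumulative distances is a pooled-variance
two-sample t test (df = n₁ + n₂ − 2), oriented staying − fleeing.

## Synthetic study conditions

The generator's defaults are the study conditions: 14 individuals, home
ranges ~561 ha (SD 282) calibrated so an Ornstein–Uhlenbeck
(centre-attracted) walk's 95% kernel range matches the drawn size via
A₉₅ = 2π(σ² + h²)(−ln 0.05); 23 hunt days spread over mid-November to
late February with 4–6 hour-long drives per day; convex hunted areas drawn
from a truncated normal (mean 101 ha, SD 30, range 47–201); covariates
uniform on their observed ranges (a modelling convenience — only medians
and ranges are reported for them); flee probability 0.68; fix success
0.82/0.86 per duty cycle; and per-axis GPS noise set so the median radial
error (Rayleigh) is 5.8 m.

Fleeing kinematics are a fast near-straight run (speed ≈ N(16, 3.5) km/h
per 2-min step) until ~400 m past the shooting line, then a slow tortuous
wander; staying deer linger at ≈0.45 km/h with occasional ~8.5 km/h
flushes and reversing headings (turning angles clustered near π), confined
40 m inside the boundary so location error cannot fake a crossing. These
scales reproduce the reported group medians of maximum speed, sinuosity
and DistI. Both branches retreat ~2.2 km from the encounter by dawn.

Return behaviour is generated at the level of area-presence spells, not
left emergent from the walk, so the survival-stage targets are controlled
exactly; the walk is conditioned to honour the spell schedule (a scripted
window around each event, Ornstein–Uhlenbeck wandering elsewhere; the
hand-off between regimes can produce a one-hour transition step of a few
hundred metres, comparable to normal hourly movement). Spells are a
mixture: a non-return mass (0.38 post-hunt, 0.12 control) censored beyond
the 144-h horizon, plus a lognormal returner mode with log-sd 0.25 whose
median is set so the *marginal* spell distribution has the configured
median (34 h / 17 h) — the quantity a Kaplan–Meier median reads off under
horizon censoring. The log-sd is a choice: return times are strongly
bimodal, with returners clustered at the day scale well under 72 h, and a
tight mode keeps the sample KM median a stable estimator. Event times are
snapped to the hourly fix grid, so measured durations track generated
spells to fix resolution (occasionally worse when a return excursion's
fixes are lost to dropout).

In the full-population generator each drive exposes at most one collared
individual (probability 0.3 per drive, ≈34 events per season); exposures
of the same individual are separated by ≥400 h so event windows never
overlap. Unexposed drives are placed away from monitored home ranges, but
chance presences can still produce detected events without ground-truth
labels; recovery tests therefore join on event id. Model-recovery studies
use direct simulators that draw from the two response models themselves,
with documented (arbitrary but plausible) generating coefficients.

What passing tests show — and do not. The synthetic herd has stationary
circular-ish home ranges, independent fix dropout, isotropic noise,
behaviour independent of covariates, and scripted rather than emergent
returns. Passing the recovery suite therefore validates the *pipeline*
(geometry, censoring logic, estimators, interval calibration) under known
truth; it does not validate the behavioural conclusions for real deer,
whose movement violates most of these simplifications.

## Numerical choices and problem sizes

Grid cell 10–20 m for UDs (20 m in benchmark scripts), 30 Gauss–Hermite
nodes, KDE chunked at 2048 points, polygon predicates via prepared
geometries. Benchmark problem sizes: 1000-point UDs, 500-event classifier
studies, 200-record survival estimates, 100-replicate coverage runs at 200
events / 20 individuals — sizes at which the Monte-Carlo error of each
check is comfortably inside its stated tolerance.

## Known limitations

No solar ephemeris (fixed 08:00/18:00 boundaries); no smoothing or
state-space filtering of fixes; no bandwidth selection study (reference
rule only); isopleth mass accuracy is grid-limited; the logistic GLMM
reports Wald intervals, which can undercover for very small samples or
near-separated data; hunted-area polygons are convex in the generator;
no habituation across repeated hunts.
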