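# Methods

This note documents the models and procedures `foragerep` implements,
the defaults it ships, the design choices that were genuinely open, and
what the synthetic-data tests do and do not demonstrate.

## Sensor processing

**Zero-offset correction.** Pressure sensors drift, so raw surface
readings wander from 0 m. The surface baseline is estimated as a
centred rolling 5th percentile of the raw depths and subtracted;
corrected depths are clipped at ≥ 0. The window default is 30 min:
long enough to contain many surface intervals (surface time is roughly
half the dive cycle), short enough that a drift of a few metres over a
few hours changes by ≪ 0.5 m within a window. A longer window (hours)
systematically lags a fast drift ramp by the window half-width times the
drift rate, which is why the default is deliberately short; both window
and quantile are config fields (`zoc_window_s`, `zoc_quantile`).

**Dive detection.** A dive is a maximal run of samples at ≥ 5 m
(`dive_threshold_m`), the conventional threshold that excludes
travelling and surface activity. Duration is the span of the run plus
one sample interval. The detector is verified against a brute-force
linear scan on random traces.

**Dive phases.** The bottom phase is every sample at ≥ 80% of the
dive's maximum depth; bottom time is its span. Descent rate is maximum
depth divided by the time from the first submerged sample to the first
bottom-phase sample. Vertical distance per dive is 2 × max depth (down
and back up), which is insensitive to the sampling interval; summed
|Δdepth| would grow with wiggles at 1 s sampling and shrink at 5 s.
These are deterministic, testable stand-ins for toolchain-internal
rules that are rarely printed; the 80% cut-off is the field's usual
bottom-phase definition.

**Modal dive depth** is the centre of the most populated 1 m bin of
per-dive maximum depths; ties break toward the deeper bin (a benthic
forager's deeper mode is the ecologically meaningful one). Daylight
assignment uses the dive's *start* time against a fixed local clock
window (07:00–18:00 by default) — clock-based, not solar-elevation
based, with the UTC offset a config field.

## Track processing

Fixes implying > 6 m s⁻¹ from the previously retained fix are removed
by a forward single pass (McConnell-style); the first fix is always
kept. The filtered track is linearly interpolated at 10 s in a local
azimuthal-equidistant plane centred on the colony (distances from the
centre exact, directions preserved; no projection library is required —
the forward/inverse formulas are closed-form spherical). Ranges and
bearings reported per trip are great-circle quantities.

A trip is a period outside the colony's 1 km buffer of ≥ 6 h
containing ≥ 1 dive. Fixes inside any haul-out buffer, or during dry
periods ≥ 10 min (no depth activity while stationary), are excluded and
their time is subtracted from the trip duration; a mid-trip haul-out
therefore shortens, but does not split, a trip. Dives are joined to the
nearest-in-time interpolated fix. Total distance travelled is the
horizontal path length plus the summed dive vertical distances.

## Benthic classification

Each dive's index is max depth × (bottom time / duration). For a
benthic-dominated diver over a shelf this is bimodal: benthic dives pile
up near the seafloor depth × ~0.5 bottom fraction, pelagic dives sit
far lower. A Gaussian KDE (Silverman bandwidth) is fitted per
individual — the split is relative to each animal's own diving — the
two highest interior maxima are taken as modes and the density minimum
between them (nadir) is the decision boundary; ties label benthic.
Labels are exactly invariant to positive affine rescaling of the index
(Silverman's bandwidth scales with the data); invariance under arbitrary
nonlinear monotone transforms is *not* guaranteed for any KDE-based
split and is not claimed. If the density has no interior minimum the
split is undefined; the fallback labels the whole mode benthic when the
mean bottom fraction is ≥ 0.4, else pelagic, and flags the fit.

## Site fidelity

Dive time is accumulated per 1 × 1 km cell (grid anchored at the
colony so all trips share cell boundaries), smoothed with a bivariate
Gaussian kernel and renormalized after truncation to the smallest cell
set holding 95% of the mass. The reference bandwidth is generalized to
dive-time weights: h = σ̂ · n_eff^(−1/6) with σ̂² the mean of the
weighted x/y variances and n_eff = (Σw)²/Σw². Truncation happens
*before* overlap computation, and both UDs are renormalized — the
overlap of the 95% home ranges, switchable via `isopleth`. Overlap is
Bhattacharyya affinity BA = Σ√(p·q) over the union of cells; FSFI is
the mean BA over all unordered trip pairs of an individual.

## Success and efficiency indices

A logistic model maps descent rate and duration of each *benthic* dive
to a prey-capture probability (pelagic dives are excluded by
construction — the validation behind such models is benthic-only). The
shipped coefficients (−1.0, 1.2 per m s⁻¹, 0.004 per s) are synthetic
placeholders flagged `"synthetic placeholder — not video-validated"`;
studies applying the package to real data must substitute calibrated
coefficients via the config. Per trip, FTSI = Σp / Σ(benthic dive
hours) (expressed per hour so values land at O(10)), FTEI = Σp /
(benthic vertical distance / time at sea). Both are reported per trip
and aggregated per individual as means across trips (the natural
individual-level summary when responses are regressed on
individual-level predictors).

## Repeatability

The random-intercept model y = Xβ + α_ind + ε is fitted by REML with a
dedicated profiled solver (1-D optimization over σ²_α/σ²_ε using the
Sherman–Morrison structure of the per-group covariance; each evaluation
is O(n)). The solver is cross-checked in the test suite against the
closed-form balanced ANOVA estimator, statsmodels MixedLM and lme4.
R = σ²_α/(σ²_α+σ²_ε); boundary estimates floor at σ²_α = 0 (R = 0).
Total distance, trip duration and dive rate are cube-root transformed
toward Gaussian residuals before fitting.

**Fixed-effect selection.** Candidate morphometrics first pass a
pairwise collinearity screen (|Pearson r| > 0.7 drops one member; mass
and standard length are dropped preferentially as the usual redundant
size proxies). All subsets are then fitted by maximum likelihood and
ranked by AICc = −2logL + 2k + 2k(k+1)/(n−k−1) with k counting fixed
effects plus both variance components. Among models within ΔAICc < 4 of
the best, the most parsimonious is selected (ties → lower AICc) — the
Δ<4 band read as a nesting rule. Under a null response this selects the
intercept-only model in the large majority of replicates, which a plain
arg-min over AICc does not. The winner is refitted with REML for
reported estimates; with fixed effects present the repeatability is an
adjusted repeatability.

**Permutation test.** Individual labels are permuted across rows
(N = 1000 by default) and p = (1 + #{stat_perm ≥ stat_obs})/(N + 1).
The permuted statistic is the between/within mean-square ratio of the
fixed-effect residuals — a strictly monotone transform of the
*unconstrained* repeatability estimate. The boundary-floored REML R has
a point mass at 0 under the null (about half of null fits), which would
make tie-laden p-values non-uniform; the mean-square ratio is
continuous, so null p-values are uniform (verified by KS test in the
suite) and each permutation costs O(n) instead of a refit.

**Bootstrap CI.** Parametric: responses are simulated from the fitted
β, σ²_α, σ²_ε, refitted, and the 2.5/97.5 percentiles of R reported
(N = 1000 default). Coverage at 50 individuals × 8 trips is within
[0.90, 0.99] across true R ∈ {0.2, 0.5, 0.8} in the calibration tests.

**Proportions.** Benthic and daylight diving proportions are modelled on
the logit scale with the per-trip dive count as binomial denominator.
The implementation uses the empirical logit y = log((k+½)/(n−k+½)) in
the same mixed model, subtracts the estimated binomial sampling variance
(mean of 1/(n·p̃·q̃)) from the residual to isolate the observation-level
random effect (overdispersion) variance, and reports the link-scale
repeatability R = σ²_α/(σ²_α + σ²_OLRE + π²/3), π²/3 being the logistic
distribution-specific variance. This is exact in the large-denominator
limit; per-trip dive counts here are in the hundreds, where the
binomial correction is < 1% of the denominator. Recovery of a true
link-scale R = 0.5 is within ±0.08 in the calibration tests. No
bootstrap CI is produced for proportion behaviours.

**Bands.** R ≤ 0.25 low, ≤ 0.5 considerable, ≤ 0.75 moderate,
otherwise high; boundary values fall to the lower band. R′ = 1 − R is
reported alongside and sums with R to 1 exactly by construction.
Bearing never enters the linear repeatability models; it is summarized
only by its circular dispersion.

## Consistency models

Per individual (≥ 3 trips): CV = sd/mean per behaviour (undefined and
flagged when the mean is 0), circular SD of trip bearings
√(−2 ln R̄)·180/π with R̄ the mean resultant length, FSFI, and
mean/CV of FTSI and FTEI. Four OLS models (responses: mean FTSI, mean
FTEI, CV FTSI, CV FTEI) are selected over subsets of {six behaviour
CVs, bearing circular SD, FSFI} with the same AICc-within-Δ4 parsimony
rule; the CVs of total and horizontal distance are excluded a priori
(collinear with the trip-duration CV). Reports carry the formula, AICc
winner's AIC/logLik, a likelihood-ratio test against the intercept-only
model (ML, χ² with df = number of predictors), r², and per-covariate
estimate/SE/t/95% CI.

## Synthetic population generator

The generator emulates a colony of ~34 lactating females over a
shallow shelf: each individual draws latent means for bearing to its
foraging grounds (population mean 203.5°), log trip duration (median
~4 days) and logit benthic propensity (population dive-level mean
0.75); each trip draws around those means, so between- and
within-individual variances — and hence the realized repeatability of
every behaviour — are configuration knobs with known truth. The logit
latent mean is calibrated numerically (Gauss–Hermite quadrature) so the
*dive-level* benthic fraction matches the configured propensity despite
the Jensen bias of the logit-normal.

Trips are an outbound correlated random walk at 1 m s⁻¹ toward a patch
placed at the trip's bearing and ~80 km (speed is capped well under the
6 m s⁻¹ filter so clean tracks pass untouched), an area-restricted
loop at the patch at 0.4 m s⁻¹, and a return leg timed to match the
drawn duration. The seafloor is a smooth deterministic field in
61–69 m, so modal dive depth inherits between-individual variance from
patch location. Dives are trapezoids: benthic dives to the local
seafloor with ~50% bottom fraction, pelagic dives to 30–70% of the
seafloor with ~15% — the two components that make the classification
index bimodal by construction. Surface gaps are log-normal (median
90 s) with occasional extended surface bouts; a linear pressure drift
(1.5 m over the deployment) and 0.12 m Gaussian sensor noise exercise
the zero-offset correction. Colony attendance between trips appears as
stationary fixes with no depth record (the sensor logs wet only);
optional mid-trip haul-out visits pin the track to a configured site and
blank the depth record there. Morphometrics are multivariate normal
around the field means (mass 70.4 kg, standard length 151.4 cm, flipper
42.5 cm, axis 63.2 cm, girth 99.2 cm) with strong mass–girth and
mass–length correlations so the collinearity screen has something to
do. All randomness flows from a single seed; fixed seed → bit-identical
output.

What the generator does *not* emulate: GPS location error (tracks are
clean, so the speed filter only ever removes test-injected errors),
tides and currents, prey-field dynamics, solar daylight geometry,
sex/age structure (a homogeneous adult-female population is assumed),
or behavioural dependence between consecutive trips. Tests passing on
this generator demonstrate the pipeline's correctness and the
estimators' calibration under the stated model — not that real
deployments satisfy that model.

## Problem sizes

The shipped test-and-verification runs use reduced scales chosen to
exercise every code path with comfortable statistical margins: pipeline
tests run 12 individuals × 3–5 trips of ~1–2 days; classifier
calibration uses 8 individuals (~4,000 dives); Gaussian repeatability
calibration uses 50 individuals × 8 trips × 100 replicates with
300-draw bootstraps; null calibration uses 200 replicates × 199
permutations. The full study scale (34 individuals, 3–12 trips of 2–11
days) is the generator default and runs end-to-end in a few minutes.

## Known limitations

- The capture-probability coefficients are placeholders; FTSI/FTEI from
  the defaults are internally consistent but not biologically
  calibrated.
- The empirical-logit proportion estimator assumes per-trip dive counts
  large enough that the binomial correction is small (tens of dives or
  more); with very few dives per trip a full GLMM would be preferable.
- The wet/dry proxy infers haul-outs from absence of depth activity
  plus stationarity; loggers that record dry zeros rather than gaps
  would need the `wet_depth_m` threshold adjusted.
- Grid-based FSFI is exactly translation-invariant only for shifts by
  whole cells; sub-cell shifts change the discretization slightly (the
  1 km cell is small relative to the ~10 km kernel bandwidths, so the
  effect is at the third decimal).
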