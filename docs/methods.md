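# Methods

## The additive decomposition model

Each upper-mixed-layer monthly series x_t (t = 0, 1, … in months from the
first sample; abundance, size and biomass variables log10-transformed
upstream) is modelled as

    x_t = x̄ + b·t + Σᵢ Aᵢ·cos(2πt/Tᵢ − θᵢ) + η_t,
    η_t = φ·η_{t−lag} + ε_t,   ε_t ~ white noise,

and fitted stage-wise in the order the terms are listed: climatological
mean, linear trend, periodic components, autocorrelation. The order
matters — trend leakage corrupts the low-frequency periodogram ordinates,
so the trend is removed before the harmonic search, and the AR term is
estimated last on what the deterministic terms leave behind.

**Phase convention.** A·cos(2πt/T − θ) with θ ∈ [0, 2π), so a component
peaks T_max = θT/2π months after the series start. This is the only
convention under which a ledger row's (θ, T, T_max) triple is internally
consistent, and it is asserted across five independent rows in the test
suite.

**Trend.** OLS of x on t over observed months, retained when the slope
differs from zero at p < α (default 0.05). Slopes are kept per month
internally and reported per year (×12) as well, the unit in which decadal
ledgers of this kind print them; the intercept refers to t = 0 (first
month of the record).

**Periodicity detection.** The periodogram is evaluated at the Fourier
frequencies j/n, j = 1 … ⌊(n−1)/2⌋ — by FFT when the series is complete,
by the Lomb–Scargle generalization at the same frequencies when months
are missing (no imputation, ever). Fisher's G = max I_j / Σ I_j is tested
against its exact null distribution
P(G > g) = Σ_j (−1)^{j−1} C(m,j)(1−jg)^{m−1}. While significant, the
winning period is fitted by least squares through the cos/sin linear
parameterization (A = √(c₁²+c₂²), θ = atan2(c₂, c₁) mod 2π), subtracted,
and the search repeats (at most `max_harmonics` = 4 components,
returned in decreasing amplitude).

Two refinements depart from the textbook recipe, both chosen here:

1. *Red-noise guard.* The G-test's null assumes white noise; monthly
   environmental residuals are typically red (lag-1 AR), which inflates
   low-frequency ordinates and manufactures spurious long-period
   "cycles" (measured: 32% of synthetic temperature decades acquired a
   phantom second harmonic). Detection therefore runs on a lag-1
   prewhitened copy of the residual whenever its lag-1 autocorrelation
   leaves the ±1.96/√n band; fitting always happens on the unwhitened
   residual so amplitudes and phases keep their units. Exactly white
   residuals are tested as-is, preserving the exact calibration
   (measured type-I rate 0.047 at α = 0.05 over 1000 series).
2. *Gated period refinement.* The winning Fourier period may be refined
   by local least squares over a ±0.5-month window, but the off-grid
   value replaces the grid value only when an F-test (α = 0.01) says the
   fit improves significantly. A 120-month record has 1/12 cycles/month
   exactly on its Fourier grid, so near-annual cycles report T = 12;
   free refinement would only inject frequency noise into the phase.

After the stage-wise search, the intercept, slope and all cos/sin
coefficients are re-fitted jointly in one OLS at the identified periods:
t and the cosine basis are not exactly orthogonal on a finite span, and
this polish removes the leakage (it also makes noiseless, fully-modelled
series decompose to machine-precision-zero residuals).

**Autocorrelation.** The AR term uses the smallest lag whose partial
autocorrelation (Durbin–Levinson on a pairwise-complete ACF, which
remains defined across gaps) leaves the ±1.96/√n band; φ is then the
no-intercept OLS coefficient of η_t on η_{t−lag}. The default scan depth
is lag 1: residual persistence beyond one month is rare once seasonality
is removed, decadal ledgers of this kind report a single lag-1
coefficient, and scanning 12 lags at an unadjusted band would carry a
~46% family-wise false-positive rate. The depth is configurable.

**Variance ledger.** Every retained component is expressed as a share of
the variance of the original series: Var(b·t)/Var(x) for the trend,
(A²/2)/Var(x) per harmonic, and for the AR term the drop in residual
variance it achieves, again over Var(x). The reported total is the exact
sum of the parts. These conventions are not arbitrary: they are the only
set under which a published ledger of this design is internally
consistent (trend slopes per year, AR share of original variance,
component shares summing to the printed total).

## Pre-whitened correlation

Cross-variable correlation uses the residuals ε_t — what remains after
mean, trend, harmonics and the AR prediction are removed — paired
strictly by month, pairwise-complete, with per-cell n reported. Pearson r
with a two-tailed t-test on n−2 degrees of freedom; stars at
0.001/0.01/0.05; no multiple-testing correction by default (a
Benjamini–Hochberg option exists in the API but is off, matching the
reporting convention of the monitoring literature this ledger layout
comes from). The point of the machinery is demonstrated directly in the
tests: two series sharing only an annual cycle have raw |r| > 0.5 yet
non-significant pre-whitened correlation in ≈94% of simulated decades.

## Cytometric standing stocks

Gating is an automatic surrogate for manual cytogram gates: 2-means
clustering on standardized (log₁₀ green fluorescence, log₁₀ RALS), the
higher-green cluster labelled HNA, after excluding events whose red
(photosynthetic) fluorescence exceeds a configurable threshold so that
picocyanobacteria cannot contaminate the HNA cluster. Degenerate
single-cluster cytograms are flagged rather than split. Abundance is
events over analysed volume (daily-calibrated flow rate × acquisition
time). Group mean cell volume comes from the group's *mean RALS* through
a user-supplied power-law calibration (stored log-log, strictly
increasing, with extrapolation warnings) and the sphere formula; the
calibration shipped as default (d = 0.047·RALS^0.5 µm) places typical
LNA/HNA clusters at 0.050/0.056 µm³ and is a stand-in — instrument
calibrations are empirical and must be supplied per dataset. Carbon
follows pg C cell⁻¹ = 0.12·V^0.72, biomass concentration is
abundance × per-cell carbon × 10⁻³ (pg ml⁻¹ → µg l⁻¹). The total group
reports LNA+HNA abundance exactly, the abundance-weighted mean size, and
the summed biomass. For microscopy-derived length/width tables the
capped-cylinder volume (π/4)·w²·(l − w/3) is provided; it reduces to the
sphere at l = w.

## Hydrography

Mixed-layer depth is the shallowest depth z at which the density
increase over the 5 m above first reaches 0.05 kg m⁻³
(ρ(z) − ρ(z−5) ≥ 0.05, ρ interpolated linearly between bottle depths); a
cast with no crossing is mixed to its deepest sample by convention. The
stratification index is (T_surface − T_75m)/75 with the surface taken as
the shallowest sample (required ≤ 5 m — casts rarely sample 0 m).
Upper-mixed-layer averages are unweighted means over sampled depths
within the layer: bottle spacing is 10–25 m, too coarse for trapezoidal
weighting to be meaningful.

## Temperature–size experiments

Monthly incubations at three temperatures (in situ −3, in situ,
in situ +3 °C), triplicate bottles, cell size read twice daily. Each
bottle is summarized before regression; the default summary averages the
time points up to the within-bottle abundance maximum (the
exponential-growth phase), with 'mean' and 'final' as alternatives,
because which time point enters the regression is genuinely open and the
growth-phase mean is the most defensible single choice. The monthly
response is the model I (OLS) slope of bottle size on temperature,
µm³ °C⁻¹; temperature is set by the experimenter and treated as
error-free. Seasonal-window statistics average a series over a calendar
window (April–July default) within April–March analysis years and
regress annual means on year. `projected_size_change` aggregates
per-group relative changes 100·Σ w_g·slope_g·ΔT/baseline_g under equal
or composition weights — both are reported because the aggregation
behind a single community-level figure is underdetermined.

## The synthetic scenario (what it emulates, what it does not)

The default decadal scenario generates ten variables whose means, yearly
trend slopes, 12-month harmonic (T, A, θ) triples and lag-1 φ follow a
published variance-decomposition ledger for a ten-year coastal record;
the innovation SDs are back-computed from that ledger's %-variance
column (e.g. temperature: A = 3.89 °C with noise set so the cycle
carries ~80% of variance and σ_ε = 1.28 with φ = 0.34 so the AR term
adds ~2%). Abundance/size/biomass series are generated directly on the
log10 scale. Cytograms are log-normal clouds at a 46/54 LNA/HNA mix;
casts carry a density step at a seasonally varying depth (15 m summer,
58 m winter) and a linear thermal gradient to 75 m; incubations plant
thermal size responses of −0.00041/−0.00091 µm³ °C⁻¹ (LNA/HNA).

What passing tests on this scenario show: the estimators recover known
parameters at realistic signal-to-noise, the ledger identities hold, the
detection tests are calibrated. What they do not show: robustness to
non-sinusoidal seasonality, regime shifts, heteroskedastic or
non-Gaussian noise, instrument drift in the cytometer, or gating
ambiguity when the LNA/HNA clouds genuinely merge — real records contain
all of these. Series variables are generated independently, so the
cross-variable structure of real data (biomass literally being
abundance × size) is emulated only where a test plants it explicitly via
correlated innovations.

## Numerical choices and degenerate inputs

* Ties for the maximal periodogram ordinate resolve to the lower
  frequency (deterministic).
* A residual whose variance falls below 10⁻¹⁴ of the original variance
  stops the harmonic search (prevents the G-test from "detecting"
  floating-point dust on noiseless input).
* Zero-variance series: no trend, no harmonics, no AR — the mean is the
  fit; the Fisher G-test on a zero-variance input raises.
* Correlation with a zero-variance side returns an undefined-r record
  (flagged) rather than raising.
* Missing months are NaN throughout: least-squares fits use observed
  pairs, the periodogram switches to Lomb–Scargle, the ACF is
  pairwise-complete. Nothing is interpolated.
* With an AR term, ε_t is undefined for the first `lag` months (NaN);
  correlations pair on months where both residuals exist.
* Reproducibility: every generator takes an explicit seed; the pipeline
  re-run with the same seed is byte-identical, and k-means gating uses a
  fixed random state.

## Problem sizes used in the checks

Simulation-based tests use 120-month series (the native design),
100–1000 replicates for calibration rates, 200 seeds for parameter
recovery, 50–400 seeds for coverage-style checks, and n ≤ 48 for the
brute-force grid-search equivalence oracle; the acceptance script runs
10 replicate decades per decomposition quantity and 50 replicate
incubations per slope. These sizes keep every estimate's Monte-Carlo
error well inside the asserted bands.

## Known limitations

* The Fisher G-test red-noise guard whitens at lag 1 only; strongly red
  residuals at longer lags could still inflate detection.
* The %-variance ledger is descriptive, not an ANOVA: components are not
  orthogonal on a finite span, so shares can sum above the harmonic's
  asymptotic share by small amounts.
* `fit_ar` estimates a single coefficient at one lag; it is not a
  general ARMA fit.
* The RALS→diameter default calibration is synthetic plumbing; real use
  requires the instrument's own bead-referenced calibration.
* Cross-group slope regressions on estimated slopes are attenuated by
  estimation error in the regressor (errors-in-variables); the package
  reports the OLS value as is.
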