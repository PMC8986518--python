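# Methods

This note records the statistical conventions, parameter choices and
known limitations of `ecotimescale`, in the order data flows through the
package.

## Spectra and cospectra

The raw periodogram of a length-n series is computed at the positive
Fourier frequencies f_k = k/n, k = 1..⌊n/2⌋, as power_k = (2/n)|X_k|²
with the Nyquist ordinate (even n) not doubled, so that Σ power equals
the centered sum of squares Σ(x − x̄)². The series is demeaned before
the FFT; no taper and no detrending are applied (both are deliberate:
downstream everything is sum-normalized, which removes scale, and the
census workflow is defined on untrended data). The cross-periodogram is
(2/n)·X_k·conj(Y_k); its real part (cospectrum) sums to the centered
cross product, its imaginary part is the quadrature spectrum.

Smoothing is two passes of a clipped moving average ("Daniell" smoother)
with spans 5 then 7: each ordinate is replaced by the mean of the
span-wide window intersected with the index range and renormalized.
This rule preserves constants and leaves interior points equal to the
convolution of the two boxcars (a trapezoidal kernel); it does *not*
preserve the total mass exactly at the boundaries — no clipped,
row-renormalized smoother can do both, and constant-preservation is the
property the null-band logic relies on.

Order of operations: smooth the raw estimate first, then normalize —
spectra by their own sum (Σ = 1), cospectra by rescaling so the sum
equals the Pearson correlation of the raw series (exact for unsmoothed
cospectra by Parseval; for smoothed ones the factor absorbs the
smoother's slight boundary mass distortion). The timescale partition of
the correlation is taken on the *unsmoothed* normalized cospectrum,
where band sums are exact; a frequency lying exactly on a band edge
(1/f = 12 or 4 months) is assigned to the shorter-timescale band.

Spectral exponents are OLS slopes of log power against log frequency
over the full Fourier grid, natural logs (the slope is base-invariant).
Zero-power ordinates — which occur deterministically when a generating
spectrum vanishes at the Nyquist frequency — are excluded with a warning
provided at least 80% of the grid survives; otherwise the exponent is
undefined and an error is raised.

## Band-stop seasonal filtering

The seasonal filter removes all cyclic components with periods in a stop
band (default 9–15 months) by projecting out the least-squares subspace
spanned by sines/cosines on a frequency grid 4× finer than the Rayleigh
resolution inside the band, truncated to its numerically resolved
dimensions by an SVD cut at 3% of the leading singular value. The
projection is symmetric, hence exactly zero-phase, and has no boundary
transients; in-band sinusoids are rejected by better than 40 dB at any
series length (integer cycles or not), while 6-month and 36-month
components change by under 2% at the defaults. A forward–backward IIR
implementation was evaluated first and rejected: the boundary kink of
reflect-padded filtering leaks a strong seasonal cycle (amplitude ~10 °C)
into the ends of the output at any order and padding, which violates the
filter's accuracy contract on realistic monthly temperature data.

Harmonic regression (`harmonic_fit`) fits sine/cosine pairs at 12 and 6
months plus an intercept by OLS and reports the nested-model F test of
the semiannual pair.

## Permutation surrogates

The null of "no timescale dependence" is simulated by applying one
shared random permutation of time to every series (tandem shuffling),
which preserves each series' marginal distribution and every same-time
cross statistic exactly, including the Pearson correlation. For each of
2000 surrogates the full estimation pipeline (smooth, normalize) is
rerun; pointwise per-frequency percentiles (95th one-sided for spectra,
2.5th/97.5th for cospectra) form the significance bands. Percentiles
use the linear-interpolation order statistic. Bands are pointwise, not
simultaneous: under the null about 5% of frequencies exceed the band by
construction. A single `numpy` Generator seeded by the caller drives
all permutations, so bands are bit-reproducible. The reported
"crossing" timescale is the short-period boundary of the first
contiguous exceedance run from the low-frequency end.

## Colored-noise synthesis

Bivariate noise with a prescribed spectral matrix is generated in the
frequency domain: at each positive Fourier frequency the 2×2 matrix
S(f)·[[1, c], [c, 1]] (zero quadrature) is Cholesky-factored and applied
to independent standard complex Gaussians; the DC coefficient is zero
(mean-zero noise), the Nyquist coefficient is drawn real, and Hermitian
symmetry plus an inverse FFT gives real series. The scaling convention
makes the expected sample variance of each series equal the mean of S
over the frequency grid; for the linear family S(f) = 0.5 + b(f − ¼),
b ∈ [−2, 2], that mean is 0.5 for every slope, so total variance is
color-independent, and the per-frequency correlation — hence the series
correlation — is c (0.9 by default). Realizations are generated at
exactly the length consumed (n = 100 for the competition runs); at that
length the realized spectrum is granular (50 Fourier bins), which is
part of the study conditions rather than a defect. Note that only
b = +2 is an exact power law (S = 2f, log–log slope +1); the red end is
linear, not a power law, so its measured log–log exponent (~−2.3 at
n = 100) is steeper than −1.

## Competition simulator

The map is iterated from the deterministic coexistence equilibrium
N₁* = K(1−α)/(1−αβ), N₂* = K(1−β)/(1−αβ) (the initial condition is not
part of the original protocol; the equilibrium start removes transients
and is exposed as an argument). Parameters default to r = 0.3 (strongly
undercompensatory), K = 50, σ = 0.75, β = 0.25, T = 100 steps,
extinction threshold 5% of K applied after every step (zero is
absorbing, so "extinct at any time" and "extinct at T" coincide); runs
feeding spectral summaries disable the threshold so trajectories stay
positive. The exponent argument of the map is clamped at ±50 as an
overflow guard; it never triggers at these parameters. Each replicate
draws a fresh noise pair; no common random numbers across sweep cells.

Initial-condition sensitivity (α = 0.75, reddest noise, 2000
replicates): native extinction ≈ 0.98 from the equilibrium start versus
≈ 0.96 from N(0) = K — a ~2 pp effect, within the tolerance used for
the headline comparisons. The symmetric-competition corner is
insensitive (≈ 0.56 either way).

Sweeps cover 101 slopes from +2 to −2 by default with 2000 replicates
per (α, slope) cell; extinction probabilities carry binomial standard
errors. Mean spectral exponents along the sweep come from a second set
of threshold-free replicates, using unsmoothed spectra for both
populations and noise.

## Climate era analysis

Each station's 100-year annual series is split into four 25-year eras
(1915–1939 … 1990–2014). Per era the series is quadratically detrended
(OLS; residuals standardized by the residual sd with ddof = 3 — the
exponent is invariant to this constant) and the unsmoothed-periodogram
exponent computed. Stations missing any year of an era are dropped from
that era (no imputation).

Quadratic detrending of a *stationary* colored series removes genuine
low-frequency variance and therefore blue-shifts the measured exponent
(≈ +0.4 at 25-year windows). This bias is an inherent property of the
detrend-then-estimate pipeline, affects any analysis of this design, and
is accounted for explicitly in the synthetic generator (below).

Era shifts are tested with paired t-tests whose sample size is replaced
by an effective sample size in both the standard error and the degrees
of freedom, Bonferroni-corrected (×3). The effective sample size is the
variance-of-the-mean reading of the Clifford/Dutilleul correction:
n_eff = n / (mean row sum of the field's spatial correlation matrix).
The correlation structure is estimated from Moran-type class
correlations in 12 equal-count great-circle distance classes (up to half
the maximum pairwise distance) by a method-of-moments fit of a nugget +
exponential correlogram whose *expected* class correlations account for
the mean-centering constraint (the centered pair products sum to
−n·s²/2, which makes naive class-sum estimators catastrophically
unstable). A chi-square pre-test returns the full n when no spatial
autocorrelation is detectable, and for the era tests the class
correlograms of all four era fields are pooled (they share the station
geometry and the climate field's structure), roughly halving the noise
of the fitted structure. Accuracy: essentially unbiased in moderate
correlation regimes; in the hardest regime (true n_eff ≈ 14 from 200
stations) the single-field estimate is right-skewed with a median ~13%
above the truth — the estimator is validated against a direct
covariance-summation oracle at the 25% level there.

## Mean-field wavelet

The generalized Morse wavelet is defined in the frequency domain as
a·ω^β·exp(−ω^γ) for ω > 0 with γ = 3 and β = P²/γ = 20 (time-bandwidth
product P² = 60), normalized to unit peak; its peak angular frequency is
ω_p = (β/γ)^{1/γ}. The CWT is evaluated by frequency-domain
multiplication on a geometric scale grid of 10 voices per octave
spanning periods 2·dt to n·dt/2. The cone of influence uses the
one-sided e-folding time of the wavelet envelope, measured numerically
at a reference scale (the envelope shape is scale-invariant, so e-fold
time is linear in scale); cells closer to either edge than the e-fold
time at their scale are flagged as edge-affected. The mean field is the
arithmetic average of station power surfaces. Surrogates permute the
*raw* annual series of all stations in tandem and re-detrend before the
CWT (permute-then-detrend), with the pointwise 95th percentile over 2000
surrogates as the hot-spot threshold; calibration tests restrict to
cells outside the cone of influence, where the flagged fraction is ≈5%
under a white-noise network.

## Synthetic-data generators

The generators encode the statistical structure the analyses assume and
are the basis of the package's round-trip self-tests.

*Census pairs* (n = 140 months): latent log abundance = log(mean count,
default 15) + log-sd (0.45) × [√sync × shared forcing + √(1−sync) ×
white noise], exponentiated, rounded, floored at zero; species 2 also
receives a semiannual log-scale harmonic. The shared forcing is a
unit-variance power-law red series (spectrum ∝ f^−1.6) so the induced
synchrony sits at long timescales — a linear-family red spectrum was
tried first and rejected because it is broadband (density 0.63 at the
6-month frequency against a mean of 0.5) and leaked shared power into
the semiannual bin. The default synchrony target 0.58 reproduces a
realized count correlation of ≈0.55 on average (rounding and the
exponential transform attenuate slightly).

*Monthly temperatures*: mean (18 °C) + linear trend + annual (8 °C) and
semiannual (1 °C) cosines + red residuals (power-law slope −1,
sd 1 °C). Amplitudes are typical of a southern-California monthly
series.

*Station networks* (200 stations, 100 years, four eras): within each era
the standardized residual field is Gaussian, exponentially correlated in
space and power-law colored in time, built as (Cholesky of the spatial
covariance) × (temporal spectral synthesis). The spatial e-folding
range defaults to 500 km. Era slope targets default to (+0.5, +0.3,
+0.4, −0.2) — blue, blue, blue, red — and are prescribed for the
*detrended* residuals, i.e. for what the era analysis measures: the
synthesis slope is passed through a fixed-seed Monte-Carlo calibration
table that inverts the detrending blue-shift (built once per era
length; a flat target requires a synthesis slope of ≈ −0.54 at 25
years). Per-station quadratic trend coefficients and station means are
drawn with small spreads so detrending is exercised.

What the generators do **not** emulate: observation error and gaps in
census protocols, non-Gaussian temperature extremes, the irregular
spatial density of real station networks, instrument changes or
homogenization artifacts, and any mechanistic link between temperature
and the census counts. Passing round-trip tests therefore demonstrates
the correctness and calibration of the estimators under the stated
second-order structure, not the ecological conclusions themselves.

## Problem sizes in the test suite

The test suite runs everything at the protocol's native sizes where that
is cheap (2000 surrogates at n = 140; 2000 replicates per extinction
cell; 2000 surrogates × 50 stations for the wavelet calibration) and
scales down only replication counts that enter as Monte-Carlo averaging
(e.g. 21-slope grids instead of 101 for monotonicity checks, 20 network
seeds for the era-shift success rate), with tolerances chosen from the
binomial/Monte-Carlo error at those sizes.

## Known limitations

* Surrogate bands are pointwise; no family-wise error control is
  offered beyond the Bonferroni correction in the era tests.
* The effective-sample-size estimator assumes an isotropic,
  exponential-with-nugget correlogram; strongly anisotropic fields will
  be mis-fit (the df correction then errs in the direction of the
  fitted structure).
* The era-shift testing problem is intrinsically marginal at these
  effect sizes: with era exponent targets mirroring the observed means
  (differences of 0.2, 0.1 and 0.6) every comparison is a true shift,
  so a well-powered test occasionally flags the small early-era shifts
  and, at realistic spatial correlation (true n_eff ≈ 25–30), sometimes
  misses the large final one; no degrees-of-freedom correction can make
  "only the final shift flagged" a near-certain event.
* The Morse cone-of-influence convention (envelope e-folding) is stated,
  not claimed identical to any particular toolbox default.
* Counts are modeled as rounded lognormals; very low-abundance censuses
  (frequent zeros) would need an explicit count distribution.
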