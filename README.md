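# ecotimescale

Timescale analysis of ecological and climatic time series: which
timescales carry the variance of a population's fluctuations, which carry
the synchrony between two populations, and what happens to two competing
species when the *color* of environmental noise shifts from blue (fast)
to red (slow)?

The package grew out of a question in invasion ecology: a native and an
invasive tree squirrel sharing a habitat fluctuate in synchrony over long
timescales, apparently driven by shared environmental forcing, while
climate records suggest that interannual temperature fluctuations are
themselves shifting toward longer timescales. `ecotimescale` provides
the full toolchain for that style of analysis, usable on any uniformly
sampled series:

* **Spectra and cospectra** — FFT periodograms and cross-periodograms at
  the Fourier frequencies, two passes of a clipped Daniell smoother
  (spans 5 and 7), spectra normalized to sum to 1 and cospectra to the
  Pearson correlation *R*, so the cospectrum reads as a decomposition of
  the correlation across timescales, with exact band partitioning
  (e.g. *R* = *R*(>12 mo) + *R*(4–12 mo) + *R*(≤4 mo)).
* **Permutation surrogate bands** — the same random reordering of time
  applied to all series "in tandem" preserves every time-independent
  statistic while destroying autocorrelation; pointwise 95% percentile
  bands over 2000 such surrogates flag significant timescales.
* **Colored correlated noise** — Chambers-style frequency-domain
  synthesis from any target spectral matrix, including the linear
  blue→white→red family S(f) = 0.5 + b·(f − ¼) with a constant
  cross-correlation (cospectrum fraction 0.9).
* **Stochastic competition** — the discrete-time Lotka–Volterra map

      N₁(t+1) = N₁(t)·exp[ r₁(K₁ − N₁ − αN₂)/K₁ + σ₁ε₁(t) ]
      N₂(t+1) = N₂(t)·exp[ r₂(K₂ − N₂ − βN₁)/K₂ + σ₂ε₂(t) ]

  with an absorbing extinction threshold (5% of K), swept over noise
  color and competition intensity to estimate extinction probabilities
  and replicate-averaged population spectra.
* **Climate timescale shifts** — era-wise spectral exponents (OLS slope
  of log power vs log frequency) of quadratically detrended annual
  temperature series across a station network, compared between eras
  with paired t-tests whose degrees of freedom are deflated to a
  Clifford/Dutilleul-style effective sample size, Bonferroni-corrected.
* **Mean-field Morse wavelet** — generalized Morse CWT (γ=3,
  time-bandwidth 60) averaged over stations, with a cone of influence
  and tandem-permutation significance hot-spots.
* **Synthetic data** — seeded generators for census-like bivariate
  counts, monthly temperatures, and spatially correlated station
  networks with prescribed era-varying spectral exponents, so the whole
  pipeline is testable without any downloads.

## Worked example

```python
import numpy as np
from ecotimescale.models import SpectralModel
from ecotimescale.synthetic import CensusSynthSpec, synth_census

native, invader = synth_census(CensusSynthSpec(seed=42))
res = SpectralModel([native, invader], names=["native", "invader"]).fit(
    surrogates=2000, seed=0)
print(res.summary())
```

```
Timescale decomposition (native, invader; n=140, dt=1, spans=(5, 7))
--------------------------------------------------------------------
spectral exponent [native]: -0.614
spectral exponent [invader]: -0.741
95% band crossing [native]: 23.3 sampling units
95% band crossing [invader]: 20.0 sampling units
Pearson correlation: +0.411
  correlation at timescale >12: +0.348
  correlation at timescale 4-12: +0.050
  correlation at timescale <=4: +0.013
```

Both simulated census series are red (negative spectral exponents), their
smoothed normalized spectra cross the permutation null band only at
timescales near two years, and of the total correlation R = 0.41 about
85% sits at timescales beyond a year — the generator's long-timescale
shared forcing, recovered by the analysis.

The competition experiment at the sweep corners:

```python
from ecotimescale.competition import CompetitionParams, extinction_sweep
df = extinction_sweep(CompetitionParams(), alpha_values=(0.25, 0.75),
                      slopes=np.array([2.0, -2.0]), n_reps=2000,
                      master_seed=1, compute_exponents=False)
print(df.round(3).to_string(index=False))
```

```
 alpha  slope  p_ext_native  p_ext_invader  se_native  se_invader
  0.25    2.0         0.000          0.000      0.000       0.000
  0.25   -2.0         0.576          0.560      0.011       0.011
  0.75    2.0         0.022          0.000      0.003       0.000
  0.75   -2.0         0.978          0.464      0.003       0.011
```

Under blue noise extinction is rare; the reddest noise drives both
species to ~55–58% extinction risk under symmetric competition, and the
native species to near-certain extinction when the invader competes
strongly (α = 0.75).

A command-line interface mirrors the library:

```bash
ecotimescale synth census --seed 3 --out census.csv
ecotimescale cospectrum --input census.csv --surrogates 2000 --seed 1
ecotimescale sweep --alphas .25,.50,.75 --reps 2000 --seed 1 --out sweep.csv
```

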