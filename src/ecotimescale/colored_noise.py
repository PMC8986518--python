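"""Spectrally colored correlated noise from a target spectral matrix.

Implements Chambers-style frequency-domain synthesis: at each positive
Fourier frequency the 2x2 target spectral matrix (spectra on the diagonal,
cospectrum off-diagonal, zero quadrature) is Cholesky-factored and applied
to independent standard complex Gaussian vectors; Hermitian symmetry and
an inverse FFT give real-valued series whose expected periodogram matches
the target.

The built-in spectrum family is the linear blue->white->red ramp
S(f) = 0.5 + b*(f - 0.25) on f in [0, 0.5]: slope b = +2 is "blue" noise
(power rising from 0 at f=0 to 1 at f=0.5), b = 0 is white noise at
constant power 0.5, and b = -2 is "red" noise.  All slopes share the same
mean power 0.5, hence the same total variance 0.5; the cospectrum is a
constant fraction c (default 0.9) of the spectrum, giving a
frequency-independent cross-correlation of c.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_spectra import SpectrumEstimate, fourier_frequencies, normalize_spectrum
from .core_spectra import spectral_exponent as _spectral_exponent
from .core_spectra import SpectralExponent

__all__ = ["NoiseSpectrumSpec", "NoiseRealization", "linear_spectrum",
           "generate", "generate_batch", "realized_exponent", "slope_grid"]


@dataclass
class NoiseSpectrumSpec:
    """Linear bivariate spectral matrix: S(f) = mean_power + slope*(f - 0.25).

    ``cospectrum_fraction`` scales the off-diagonal cospectrum as c*S(f)
    (zero quadrature), so the implied per-frequency correlation is c at
    every frequency.  Nonnegativity of S on [0, 0.5] requires
    ``|slope| <= 4*mean_power``.
    """

    slope: float
    mean_power: float = 0.5
    cospectrum_fraction: float = 0.9

    def __post_init__(self) -> None:
        if abs(self.slope) > 4 * self.mean_power + 1e-12:
            raise ValueError("slope magnitude too large: spectrum would be "
                             "negative inside [0, 0.5]")
        if abs(self.cospectrum_fraction) > 1:
            raise ValueError("|cospectrum_fraction| must be <= 1 for a positive "
                             "semidefinite spectral matrix")

    def density(self, f: np.ndarray | float) -> np.ndarray:
        """Target spectral density at frequency f (cycles per step)."""
        return self.mean_power + self.slope * (np.asarray(f, dtype=float) - 0.25)


@dataclass
class NoiseRealization:
    """A bivariate noise draw; rows of ``eps`` are the two series."""

    eps: np.ndarray                     # (2, n)
    spec: NoiseSpectrumSpec
    seed: int | None = None

    @property
    def eps1(self) -> np.ndarray:
        return self.eps[0]

    @property
    def eps2(self) -> np.ndarray:
        return self.eps[1]

    @property
    def n(self) -> int:
        return self.eps.shape[-1]


def linear_spectrum(slope: float, mean_power: float = 0.5,
                    cospectrum_fraction: float = 0.9) -> NoiseSpectrumSpec:
    """The linear spectrum family: slope +2 = blue, 0 = white, -2 = red."""
    return NoiseSpectrumSpec(slope=slope, mean_power=mean_power,
                             cospectrum_fraction=cospectrum_fraction)


def slope_grid(n_slopes: int = 101) -> np.ndarray:
    """Evenly spaced spectral slopes from +2 (blue) down to -2 (red)."""
    return np.linspace(2.0, -2.0, n_slopes)


def generate_batch(spec: NoiseSpectrumSpec, n: int, n_reps: int,
                   rng: np.random.Generator) -> np.ndarray:
    """Draw ``n_reps`` independent bivariate realizations, shape (n_reps, 2, n).

    Scaling convention: the expected sample variance of each series equals
    the mean of S over the positive Fourier frequencies (~= mean_power),
    so the total variance is slope-independent.  The DC coefficient is
    zero (mean-zero noise) and the Nyquist coefficient is drawn real.
    """
    if n < 4:
        raise ValueError("n must be at least 4")
    m = n // 2
    freqs = fourier_frequencies(n)
    S = np.clip(spec.density(freqs), 0.0, None)
    c = spec.cospectrum_fraction
    # Cholesky factor of the per-frequency correlation matrix [[1,c],[c,1]]
    l21, l22 = c, np.sqrt(1.0 - c * c)

    has_nyquist = (n % 2 == 0)
    m_c = m - 1 if has_nyquist else m       # number of fully complex bins

    z = rng.standard_normal((n_reps, 2, m_c, 2)) * np.sqrt(0.5)
    Z = z[..., 0] + 1j * z[..., 1]          # E|Z|^2 = 1
    X = np.empty((n_reps, 2, m + 1), dtype=complex)
    X[:, :, 0] = 0.0
    amp = np.sqrt(n * S[:m_c])
    X[:, 0, 1:m_c + 1] = amp * Z[:, 0]
    X[:, 1, 1:m_c + 1] = amp * (l21 * Z[:, 0] + l22 * Z[:, 1])
    if has_nyquist:
        g = rng.standard_normal((n_reps, 2))
        amp_nyq = np.sqrt(2.0 * n * S[m - 1])
        X[:, 0, m] = amp_nyq * g[:, 0]
        X[:, 1, m] = amp_nyq * (l21 * g[:, 0] + l22 * g[:, 1])
    out = np.fft.irfft(X, n=n, axis=-1)
    return out


def generate(spec: NoiseSpectrumSpec, n: int,
             seed: int | None = None,
             rng: np.random.Generator | None = None) -> NoiseRealization:
    """One bivariate realization of length ``n`` (deterministic given seed)."""
    if rng is None:
        rng = np.random.default_rng(seed)
    eps = generate_batch(spec, n, 1, rng)[0]
    return NoiseRealization(eps=eps, spec=spec, seed=seed)


def realized_exponent(real: NoiseRealization) -> list[SpectralExponent]:
    """Spectral exponent of each series' unsmoothed normalized spectrum."""
    from .core_spectra import TimeSeries, periodogram

    out = []
    for row in real.eps:
        s = normalize_spectrum(periodogram(TimeSeries(row)))
        out.append(_spectral_exponent(s))
    return out
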