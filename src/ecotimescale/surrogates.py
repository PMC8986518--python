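"""Permutation surrogate nulls for spectra and cospectra.

The null hypothesis is that the series have no timescale dependence: a
random reordering of time destroys all autocorrelation while leaving every
time-independent statistic (mean, variance, marginal distribution, and --
because the same permutation is applied to every series "in tandem" -- the
cross-correlation) exactly unchanged.  Pointwise percentile bands of the
smoothed normalized surrogate spectra and cospectra then flag frequencies
where the observed estimates are unusually large or small.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_spectra import (
    TimeSeries,
    daniell_smooth,
    fourier_frequencies,
    smoothing_matrix,
)

__all__ = ["SurrogateBands", "tandem_shuffle", "surrogate_bands",
           "threshold_crossing_period"]


@dataclass
class SurrogateBands:
    """Pointwise percentile bands under the tandem-permutation null."""

    freqs: np.ndarray
    upper95_spectrum: np.ndarray          # (n_series, n_freqs)
    lower2p5_cospectrum: np.ndarray | None
    upper97p5_cospectrum: np.ndarray | None
    n_surrogates: int
    seed: int | None
    dt: float = 1.0


def tandem_shuffle(series_set: list[np.ndarray] | np.ndarray,
                   rng: np.random.Generator) -> list[np.ndarray]:
    """Apply one shared random permutation of time to every series.

    Pairing across series is preserved, so the multiset of values of each
    series and every same-time cross statistic (e.g. the Pearson
    correlation) are exactly invariant.
    """
    arrs = [np.asarray(s, dtype=float) for s in series_set]
    n = arrs[0].size
    if any(a.size != n for a in arrs):
        raise ValueError("all series must have equal length")
    perm = rng.permutation(n)
    return [a[perm] for a in arrs]


def _raw_power_rows(M: np.ndarray) -> np.ndarray:
    """One-sided periodogram ordinates of each row of a demeaned matrix."""
    n = M.shape[-1]
    F = np.fft.rfft(M, axis=-1)
    P = (2.0 / n) * np.abs(F[..., 1:]) ** 2
    if n % 2 == 0:
        P[..., -1] /= 2.0
    return P


def surrogate_bands(series_set: list[TimeSeries] | list[np.ndarray],
                    spans: tuple[int, ...] = (5, 7),
                    n_surrogates: int = 2000,
                    seed: int | None = None,
                    rng: np.random.Generator | None = None) -> SurrogateBands:
    """Percentile bands of smoothed normalized surrogate spectra/cospectra.

    For each of ``n_surrogates`` tandem permutations the same estimation
    pipeline applied to the observed data is rerun: raw periodogram,
    Daniell smoothing with ``spans``, normalization of spectra to unit sum
    and of the cospectrum to the (permutation-invariant) Pearson
    correlation.  Per-frequency one-sided 95th percentiles are returned
    for the spectra and two-sided 2.5/97.5 percentiles for the cospectrum
    of the first pair of series.

    Deterministic given ``seed``; percentiles use the linear-interpolation
    order statistic.
    """
    if n_surrogates < 100:
        raise ValueError("need at least 100 surrogates for stable percentiles")
    if rng is None:
        rng = np.random.default_rng(seed)
    vals = [s.values if isinstance(s, TimeSeries) else np.asarray(s, float)
            for s in series_set]
    dt = series_set[0].dt if isinstance(series_set[0], TimeSeries) else 1.0
    n = vals[0].size
    if any(v.size != n for v in vals):
        raise ValueError("all series must have equal length")
    k = len(vals)
    V = np.stack(vals)                      # (k, n)
    Vc = V - V.mean(axis=1, keepdims=True)

    m = n // 2
    freqs = fourier_frequencies(n)
    Sm = smoothing_matrix(m, spans).T       # right-multiply to smooth rows

    do_cospec = k >= 2
    if do_cospec:
        r_obs = float(np.corrcoef(V[0], V[1])[0, 1])

    # all permutations up front: (n_surrogates, n) index matrix
    perms = np.argsort(rng.random((n_surrogates, n)), axis=1)

    spec_draws = np.empty((k, n_surrogates, m))
    cospec_draws = np.empty((n_surrogates, m)) if do_cospec else None
    chunk = 256                             # bound peak memory for the FFTs
    for lo in range(0, n_surrogates, chunk):
        idx = perms[lo:lo + chunk]          # (c, n)
        shuffled = Vc[:, idx]               # (k, c, n) shared permutation
        F = np.fft.rfft(shuffled, axis=-1)[..., 1:]
        P = (2.0 / n) * np.abs(F) ** 2
        if n % 2 == 0:
            P[..., -1] /= 2.0
        P = P @ Sm
        P /= P.sum(axis=-1, keepdims=True)
        spec_draws[:, lo:lo + idx.shape[0]] = P
        if do_cospec:
            C = ((2.0 / n) * (F[0] * np.conj(F[1]))).real
            if n % 2 == 0:
                C[..., -1] /= 2.0
            C = C @ Sm
            C *= (r_obs / C.sum(axis=-1))[:, None]
            cospec_draws[lo:lo + idx.shape[0]] = C

    upper95 = np.percentile(spec_draws, 95.0, axis=1)
    if do_cospec:
        lower = np.percentile(cospec_draws, 2.5, axis=0)
        upper = np.percentile(cospec_draws, 97.5, axis=0)
    else:
        lower = upper = None
    return SurrogateBands(freqs=freqs, upper95_spectrum=upper95,
                          lower2p5_cospectrum=lower, upper97p5_cospectrum=upper,
                          n_surrogates=n_surrogates, seed=seed, dt=dt)


def threshold_crossing_period(freqs: np.ndarray, power: np.ndarray,
                              band: np.ndarray, dt: float = 1.0) -> float | None:
    """Timescale at which an estimate crosses above a significance band.

    Returns the period (in units of ``dt``) of the short-timescale
    boundary of the longest-period contiguous run of frequencies where
    ``power`` exceeds ``band``, or None if it never does.
    """
    exceed = power > band
    if not exceed.any():
        return None
    # first contiguous run starting from the lowest frequency that exceeds
    start = int(np.argmax(exceed))
    end = start
    while end + 1 < exceed.size and exceed[end + 1]:
        end += 1
    return float(dt / freqs[end])
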