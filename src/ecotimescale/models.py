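"""Model/Results interfaces over the spectral and climate pipelines.

Two fitted-analysis surfaces in the statsmodels idiom: construct a model
from data, call :meth:`fit`, and read estimates, uncertainties and a
``summary()`` table off the results object.

* :class:`SpectralModel` -- smoothed normalized spectra (and, for
  bivariate input, the cospectrum, its timescale partition of the
  Pearson correlation, and tandem-permutation significance bands).
* :class:`ClimateShiftModel` -- era-wise spectral exponents for a
  station network with spatially corrected paired tests between eras.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import core_spectra as cs
from . import surrogates as sg
from .climate import DEFAULT_ERAS, CorrectedPairedTest, era_exponents, era_shift_tests

__all__ = ["SpectralModel", "SpectralResults",
           "ClimateShiftModel", "ClimateShiftResults"]


class SpectralModel:
    """Timescale decomposition of one or two uniformly sampled series.

    Parameters
    ----------
    data : array-like, TimeSeries, or sequence of up to two of them
        One series gives spectra only; two give the cospectrum and the
        correlation partition as well.
    dt : float
        Sampling interval (months for the census/temperature use case).
    spans : tuple of int
        Daniell smoothing spans (two clipped moving-average passes).
    names : sequence of str, optional
        Labels used in the summary.
    """

    def __init__(self, data, dt: float = 1.0, spans: tuple[int, ...] = (5, 7),
                 names=None):
        if isinstance(data, (cs.TimeSeries, np.ndarray)) or (
                np.ndim(data) == 1 and not isinstance(data[0], (list, tuple,
                                                                np.ndarray,
                                                                cs.TimeSeries))):
            data = [data]
        self.series = [d if isinstance(d, cs.TimeSeries)
                       else cs.TimeSeries(np.asarray(d, float), dt=dt)
                       for d in data]
        if not 1 <= len(self.series) <= 2:
            raise ValueError("SpectralModel takes one or two series")
        self.dt = self.series[0].dt
        self.spans = tuple(spans)
        self.names = list(names) if names else \
            [f"series{i + 1}" for i in range(len(self.series))]

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, columns=None, dt: float = 1.0,
                       **kw) -> "SpectralModel":
        cols = list(columns) if columns else [c for c in df.columns
                                              if c.lower() not in ("date", "t",
                                                                   "time", "year")]
        return cls([df[c].to_numpy(float) for c in cols[:2]], dt=dt,
                   names=cols[:2], **kw)

    def fit(self, surrogates: int = 2000, seed: int | None = None,
            timescale_edges: tuple[float, ...] = (12.0, 4.0)) -> "SpectralResults":
        """Estimate smoothed normalized spectra (+ cospectrum, bands, partition).

        ``surrogates=0`` skips the permutation bands.
        """
        spectra = []
        for ts in self.series:
            raw = cs.periodogram(ts)
            spectra.append(cs.normalize_spectrum(
                cs.smooth_spectrum(raw, self.spans)))
        cospectrum = partition = r = None
        if len(self.series) == 2:
            r = float(np.corrcoef(self.series[0].values,
                                  self.series[1].values)[0, 1])
            raw_cross = cs.cross_periodogram(*self.series)
            cospectrum = cs.normalize_cospectrum(
                cs.smooth_cross_spectrum(raw_cross, self.spans), r)
            partition = cs.partition_correlation(
                cs.normalize_cospectrum(raw_cross, r), timescale_edges)
        bands = None
        if surrogates:
            bands = sg.surrogate_bands(self.series, spans=self.spans,
                                       n_surrogates=surrogates, seed=seed)
        return SpectralResults(model=self, spectra=spectra,
                               cospectrum=cospectrum, partition=partition,
                               pearson_r=r, bands=bands)


@dataclass
class SpectralResults:
    """Fitted spectral decomposition; see :class:`SpectralModel`."""

    model: SpectralModel
    spectra: list
    cospectrum: object | None
    partition: object | None
    pearson_r: float | None
    bands: object | None

    @property
    def freqs(self) -> np.ndarray:
        return self.spectra[0].freqs

    @property
    def periods(self) -> np.ndarray:
        return self.spectra[0].periods

    def spectral_exponents(self) -> list[float]:
        """Exponents of the *unsmoothed* normalized spectra."""
        return [cs.spectral_exponent(
            cs.normalize_spectrum(cs.periodogram(ts))).slope
            for ts in self.model.series]

    def significant_timescale(self, which: int = 0) -> float | None:
        """Longest-timescale band crossing of series ``which``, if any."""
        if self.bands is None:
            return None
        return sg.threshold_crossing_period(
            self.freqs, self.spectra[which].power,
            self.bands.upper95_spectrum[which], dt=self.model.dt)

    def to_frame(self) -> pd.DataFrame:
        """Tidy per-frequency table of everything estimated."""
        d = {"frequency": self.freqs, "period": self.periods}
        for name, s in zip(self.model.names, self.spectra):
            d[f"power_{name}"] = s.power
        if self.cospectrum is not None:
            d["cospectrum"] = self.cospectrum.cospectrum
            d["quadrature"] = self.cospectrum.quadrature
        if self.bands is not None:
            for i, name in enumerate(self.model.names):
                d[f"upper95_{name}"] = self.bands.upper95_spectrum[i]
            if self.bands.lower2p5_cospectrum is not None:
                d["cospec_lower2p5"] = self.bands.lower2p5_cospectrum
                d["cospec_upper97p5"] = self.bands.upper97p5_cospectrum
        return pd.DataFrame(d)

    def summary(self) -> str:
        lines = ["Timescale decomposition"
                 f" ({', '.join(self.model.names)}; n={self.model.series[0].n},"
                 f" dt={self.model.dt:g}, spans={self.model.spans})"]
        lines.append("-" * len(lines[0]))
        for name, expo in zip(self.model.names, self.spectral_exponents()):
            lines.append(f"spectral exponent [{name}]: {expo:+.3f}")
        for i, name in enumerate(self.model.names):
            ts_cross = self.significant_timescale(i)
            if ts_cross is not None:
                lines.append(f"95% band crossing [{name}]: "
                             f"{ts_cross:.1f} sampling units")
        if self.pearson_r is not None:
            lines.append(f"Pearson correlation: {self.pearson_r:+.3f}")
        if self.partition is not None:
            for lab, v in zip(self.partition.band_labels,
                              self.partition.band_correlations):
                lines.append(f"  correlation at timescale {lab}: {v:+.3f}")
        return "\n".join(lines)


class ClimateShiftModel:
    """Era-wise spectral-exponent shifts for a station network.

    ``stations`` is a list of :class:`~ecotimescale.climate.StationSeries`
    or a tidy DataFrame (station_id, lat, lon, year, mean_temp); ``eras``
    are inclusive (start, end) year spans.
    """

    def __init__(self, stations, eras: tuple[tuple[int, int], ...] = DEFAULT_ERAS):
        self.stations = stations
        self.eras = tuple(eras)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kw) -> "ClimateShiftModel":
        need = {"station_id", "lat", "lon", "year", "mean_temp"}
        if not need <= set(df.columns):
            raise ValueError(f"missing columns: {sorted(need - set(df.columns))}")
        return cls(df, **kw)

    def fit(self) -> "ClimateShiftResults":
        table = era_exponents(self.stations, self.eras)
        tests = era_shift_tests(table)
        return ClimateShiftResults(model=self, exponent_table=table, tests=tests)


@dataclass
class ClimateShiftResults:
    """Era exponent table plus spatially corrected paired tests."""

    model: ClimateShiftModel
    exponent_table: pd.DataFrame
    tests: list[CorrectedPairedTest] = field(default_factory=list)

    @property
    def era_labels(self) -> list[str]:
        return [c for c in self.exponent_table.columns if c not in ("lat", "lon")]

    def era_means(self) -> pd.Series:
        return self.exponent_table[self.era_labels].mean()

    def era_histograms(self, bins: int = 20) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        out = {}
        for lab in self.era_labels:
            vals = self.exponent_table[lab].dropna().to_numpy()
            out[lab] = np.histogram(vals, bins=bins)
        return out

    def summary(self) -> str:
        lines = [f"Era spectral exponents ({len(self.exponent_table)} stations)"]
        lines.append("-" * len(lines[0]))
        for lab, m in self.era_means().items():
            lines.append(f"  {lab}: mean exponent {m:+.3f}")
        lines.append("Paired era comparisons (spatially corrected, Bonferroni):")
        for t in self.tests:
            lines.append(f"  {t.era_pair[0]} vs {t.era_pair[1]}: "
                         f"diff={t.mean_difference:+.3f}, n_eff={t.n_eff:.1f}, "
                         f"t={t.t_statistic:+.2f}, p_adj={t.p_adjusted:.4g}")
        return "\n".join(lines)
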