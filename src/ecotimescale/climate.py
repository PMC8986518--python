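"""Era-wise spectral exponents for station networks and spatially corrected tests.

A century of annual-mean temperatures per station is split into 25-year
eras; each era's series is quadratically detrended, its unsmoothed
periodogram gives a spectral exponent (log-power vs log-frequency slope),
and era-to-era shifts in the station-mean exponent are tested with paired
t-tests whose sample size is deflated to a Clifford/Dutilleul-style
*effective* sample size, because nearby stations are not independent.
Bonferroni correction accounts for the three adjacent-era comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core_spectra import TimeSeries, normalize_spectrum, periodogram, spectral_exponent

__all__ = [
    "StationSeries",
    "CorrectedPairedTest",
    "DEFAULT_ERAS",
    "quadratic_detrend",
    "era_exponents",
    "effective_sample_size",
    "corrected_paired_ttest",
    "era_shift_tests",
]

DEFAULT_ERAS: tuple[tuple[int, int], ...] = (
    (1915, 1939), (1940, 1964), (1965, 1989), (1990, 2014))

_EARTH_RADIUS_KM = 6371.0


@dataclass
class StationSeries:
    """Georeferenced annual series for one station."""

    station_id: str
    lat: float
    lon: float
    years: np.ndarray
    mean_temp: np.ndarray

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=int)
        self.mean_temp = np.asarray(self.mean_temp, dtype=float)
        if self.years.size != self.mean_temp.size:
            raise ValueError("years and mean_temp must align")
        if self.years.size and np.any(np.diff(self.years) != 1):
            raise ValueError("years must be contiguous")


@dataclass
class CorrectedPairedTest:
    """Paired t-test with spatially corrected degrees of freedom."""

    era_pair: tuple[str, str]
    mean_difference: float
    n_stations: int
    n_eff: float
    t_statistic: float
    df: float
    p_raw: float
    p_adjusted: float


def quadratic_detrend(values: np.ndarray) -> np.ndarray:
    """Residuals of an OLS quadratic fit, standardized to unit residual sd.

    The residual standard deviation uses ddof = 3 (intercept, linear and
    quadratic coefficients estimated).  Raises on (near-)exact quadratic
    input, whose residual variance is zero.
    """
    y = np.asarray(values, dtype=float)
    n = y.size
    if n < 5:
        raise ValueError("need at least 5 points to detrend quadratically")
    t = np.arange(n, dtype=float)
    X = np.column_stack([np.ones(n), t, t * t])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    rss = float(resid @ resid)
    scale = np.sqrt(rss / (n - 3))
    if not np.isfinite(scale) or scale < 1e-10 * max(1.0, np.abs(y).max()):
        raise ValueError("zero residual variance after quadratic detrend")
    return resid / scale


def quadratic_residual_projector(n: int) -> np.ndarray:
    """Annihilator matrix of the quadratic-trend design (I minus hat matrix)."""
    t = np.arange(n, dtype=float)
    X = np.column_stack([np.ones(n), t, t * t])
    Q, _ = np.linalg.qr(X)
    return np.eye(n) - Q @ Q.T


def detrend_standardize_rows(raw: np.ndarray, M: np.ndarray) -> np.ndarray:
    """Vectorized :func:`quadratic_detrend` of every row of ``raw``."""
    n = raw.shape[-1]
    R = raw @ M.T
    scale = np.sqrt((R * R).sum(axis=-1, keepdims=True) / (n - 3))
    if np.any(scale <= 0):
        raise ValueError("zero residual variance after quadratic detrend")
    return R / scale


def _station_frame(stations) -> pd.DataFrame:
    if isinstance(stations, pd.DataFrame):
        return stations
    rows = []
    for s in stations:
        rows.append(pd.DataFrame({"station_id": s.station_id, "lat": s.lat,
                                  "lon": s.lon, "year": s.years,
                                  "mean_temp": s.mean_temp}))
    return pd.concat(rows, ignore_index=True)


def era_exponents(stations,
                  era_bounds: tuple[tuple[int, int], ...] = DEFAULT_ERAS,
                  ) -> pd.DataFrame:
    """Per-station, per-era spectral exponents of detrended annual series.

    ``stations`` is either a list of :class:`StationSeries` or a tidy
    DataFrame with columns station_id, lat, lon, year, mean_temp.  For
    each era the station's series is quadratically detrended and the
    exponent of the unsmoothed normalized periodogram is computed.
    Stations missing any year of an era get NaN for that era.

    Returns a DataFrame indexed by station_id with lat, lon and one
    column per era (labelled "1915-1939", ...).
    """
    df = _station_frame(stations)
    labels = [f"{a}-{b}" for a, b in era_bounds]
    out = []
    for sid, g in df.groupby("station_id", sort=True):
        g = g.sort_values("year")
        rec = {"station_id": sid, "lat": g["lat"].iloc[0], "lon": g["lon"].iloc[0]}
        for (a, b), lab in zip(era_bounds, labels):
            sel = g[(g["year"] >= a) & (g["year"] <= b)]
            if len(sel) != b - a + 1:
                rec[lab] = np.nan
                continue
            resid = quadratic_detrend(sel["mean_temp"].to_numpy())
            spec = normalize_spectrum(periodogram(TimeSeries(resid, dt=1.0)))
            rec[lab] = spectral_exponent(spec).slope
        out.append(rec)
    return pd.DataFrame(out).set_index("station_id")


def great_circle_distances(lat: np.ndarray, lon: np.ndarray) -> np.ndarray:
    """Pairwise haversine distances in kilometres."""
    phi = np.radians(np.asarray(lat, dtype=float))
    lam = np.radians(np.asarray(lon, dtype=float))
    dphi = phi[:, None] - phi[None, :]
    dlam = lam[:, None] - lam[None, :]
    a = np.sin(dphi / 2) ** 2 + np.cos(phi)[:, None] * np.cos(phi)[None, :] \
        * np.sin(dlam / 2) ** 2
    return 2 * _EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0, 1)))


def effective_sample_size(diffs: np.ndarray, lat: np.ndarray, lon: np.ndarray,
                          n_classes: int = 12,
                          gate_level: float = 0.05,
                          aux_fields: np.ndarray | None = None) -> float:
    """Effective sample size of spatially autocorrelated paired differences.

    The variance-of-the-mean reading of the Clifford/Dutilleul correction
    applied to one spatial field (the paired differences): if the field
    has spatial correlation matrix C, the variance of its mean is
    inflated by the mean row sum of C and

        n_eff = n / (mean row sum of C),

    clamped to [2, n].  C is estimated from Moran-type spatial
    autocorrelations in ``n_classes`` equal-count great-circle distance
    classes (up to half the maximum pairwise distance) by fitting a
    nugget + exponential correlogram ``C = a*exp(-D/r) + (1-a)*I`` whose
    *expected* class correlations account for the mean-centering bias of
    the Moran estimates (naively summing class correlations is badly
    unstable, because the centered pair products are constrained to sum
    to -n*s2/2).

    A pre-test guards the independent case: the weighted sum of squared
    class correlations is compared against its chi-square null at
    ``gate_level``; when no spatial autocorrelation is detectable the
    full sample size is returned.

    ``aux_fields`` (shape n_fields x n) optionally supplies additional
    fields sharing the same spatial structure (e.g. the individual era
    exponent fields of a paired comparison); their class correlograms
    are pooled, roughly halving the noise of the fitted structure.
    """
    d = np.asarray(diffs, dtype=float)
    n = d.size
    if n < 10:
        raise ValueError("need at least 10 stations")
    fields = np.atleast_2d(np.asarray(aux_fields, dtype=float)) \
        if aux_fields is not None else d[None, :]
    if fields.shape[1] != n:
        raise ValueError("aux_fields must align with diffs")
    D = great_circle_distances(lat, lon)
    iu = np.triu_indices(n, k=1)
    pair_d = D[iu]
    if pair_d.max() <= 0:
        raise ValueError("degenerate geometry: all stations co-located")
    half_max = pair_d.max() / 2.0
    in_range = pair_d <= half_max
    if in_range.sum() < n_classes:
        n_classes = max(1, int(in_range.sum()))

    dr = pair_d[in_range]
    qs = np.quantile(dr, np.linspace(0, 1, n_classes + 1))
    qs[-1] = np.nextafter(qs[-1], np.inf)
    cls = np.clip(np.searchsorted(qs, dr, side="right") - 1, 0, n_classes - 1)
    wk = np.bincount(cls, minlength=n_classes).astype(float)
    ok = wk > 0

    rhos = []
    for f in fields:
        z = f - f.mean()
        s2 = float(z @ z) / n
        if s2 == 0:
            continue
        cross = (z[iu[0]] * z[iu[1]])[in_range]
        r = np.zeros(n_classes)
        for k in np.nonzero(ok)[0]:
            r[k] = cross[cls == k].mean() / s2
        rhos.append(r)
    if not rhos:
        return 2.0
    rhos = np.array(rhos)
    rho = rhos.mean(axis=0)

    # gate: detectable spatial autocorrelation at all?  under independence
    # each class correlation is ~N(-1/n, 1/|P_k|), so the weighted sum of
    # squares over classes and fields is approximately chi-square with one
    # dof per class per field
    T = float(sum((wk[ok] * (r[ok] + 1.0 / n) ** 2).sum() for r in rhos))
    if T <= stats.chi2.ppf(1.0 - gate_level, int(ok.sum()) * len(rhos)):
        return float(n)

    # method-of-moments fit of (a, r) matching expected centered class
    # correlations; grid over r, linear scan over the nugget fraction
    # ranges are only estimable up to the lags the correlogram covers
    r_grid = np.exp(np.linspace(np.log(half_max / 50.0), np.log(half_max), 24))
    a_grid = np.linspace(0.0, 1.0, 101)
    mk_I = -1.0 / n
    t_I = 1.0 - 1.0 / n
    best = (np.inf, 0.0, 1.0)
    for r in r_grid:
        E = np.exp(-D / r)
        rm = E.mean(axis=1)
        Ec = E - rm[:, None] - rm[None, :] + E.mean()   # B E B (centering)
        ec = Ec[iu][in_range]
        mk_E = np.zeros(n_classes)
        for k in np.nonzero(ok)[0]:
            mk_E[k] = ec[cls == k].mean()
        t_E = np.trace(Ec) / n                           # E[s2]/sigma2 for E part
        cbar = E.mean()                                  # 1'E1 / n^2
        for a in a_grid:
            pred = (a * mk_E + (1 - a) * mk_I) / (a * t_E + (1 - a) * t_I)
            sse = float((wk[ok] * (rho[ok] - pred[ok]) ** 2).sum())
            if sse < best[0]:
                best = (sse, a, cbar)
    _, a, cbar = best
    inflation = a * cbar * n + (1 - a)                   # mean row sum of C
    return float(np.clip(n / inflation, 2.0, n))


def corrected_paired_ttest(exp_a: np.ndarray, exp_b: np.ndarray,
                           lat: np.ndarray, lon: np.ndarray,
                           n_comparisons: int = 3,
                           era_pair: tuple[str, str] = ("A", "B"),
                           aux_fields: np.ndarray | None = None,
                           ) -> CorrectedPairedTest:
    """Paired t-test of two era exponent fields with spatial correction.

    The t statistic uses the effective sample size in place of n in both
    the standard error and the degrees of freedom; the p-value is
    Bonferroni-multiplied by ``n_comparisons``.  By default the two era
    fields themselves are pooled when the spatial correlogram is
    estimated (they share the station geometry and climate-field
    structure); pass ``aux_fields`` to pool over more fields.
    """
    a = np.asarray(exp_a, dtype=float)
    b = np.asarray(exp_b, dtype=float)
    lat = np.asarray(lat, dtype=float)
    lon = np.asarray(lon, dtype=float)
    ok = np.isfinite(a) & np.isfinite(b)
    if aux_fields is not None:
        aux = np.atleast_2d(np.asarray(aux_fields, dtype=float))
        ok &= np.isfinite(aux).all(axis=0)
        aux = aux[:, ok]
    else:
        aux = None
    a, b, lat, lon = a[ok], b[ok], lat[ok], lon[ok]
    if aux is None:
        aux = np.stack([a, b])
    d = a - b
    n = d.size
    sd = d.std(ddof=1)
    if sd == 0:
        return CorrectedPairedTest(era_pair=era_pair, mean_difference=0.0,
                                   n_stations=n, n_eff=float(n), t_statistic=0.0,
                                   df=float(n - 1), p_raw=1.0, p_adjusted=1.0)
    n_eff = effective_sample_size(d, lat, lon, aux_fields=aux)
    t_stat = d.mean() / (sd / np.sqrt(n_eff))
    df = n_eff - 1.0
    p_raw = 2.0 * float(stats.t.sf(abs(t_stat), df))
    return CorrectedPairedTest(era_pair=era_pair,
                               mean_difference=float(d.mean()),
                               n_stations=n, n_eff=n_eff,
                               t_statistic=float(t_stat), df=df,
                               p_raw=p_raw,
                               p_adjusted=min(1.0, n_comparisons * p_raw))


def era_shift_tests(exponent_table: pd.DataFrame,
                    era_labels: list[str] | None = None,
                    ) -> list[CorrectedPairedTest]:
    """Corrected paired tests between consecutive eras of an exponent table."""
    if era_labels is None:
        era_labels = [c for c in exponent_table.columns if c not in ("lat", "lon")]
    lat = exponent_table["lat"].to_numpy()
    lon = exponent_table["lon"].to_numpy()
    tests = []
    n_comp = len(era_labels) - 1
    all_fields = exponent_table[era_labels].to_numpy().T   # pooled correlogram
    for ea, eb in zip(era_labels[:-1], era_labels[1:]):
        tests.append(corrected_paired_ttest(
            exponent_table[ea].to_numpy(), exponent_table[eb].to_numpy(),
            lat, lon, n_comparisons=n_comp, era_pair=(ea, eb),
            aux_fields=all_fields))
    return tests
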