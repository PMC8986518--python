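"""CSV readers/writers for the formats the command-line tools speak."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .climate import StationSeries
from .core_spectra import TimeSeries


def read_series_csv(path, dt: float = 1.0) -> list[TimeSeries]:
    """Read `date,value` or `date,value1,value2` (monthly cadence) CSV.

    Missing values are an error, not imputed; the offending row is named.
    """
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected a date column plus 1-2 value columns")
    value_cols = df.columns[1:3]
    for col in value_cols:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.index[vals.isna()]
        if len(bad):
            raise ValueError(f"{path}: non-numeric or missing value in column "
                             f"'{col}', row {int(bad[0]) + 2}")
    start = str(df.iloc[0, 0])
    return [TimeSeries(df[c].to_numpy(float), dt=dt, start_label=start)
            for c in value_cols]


def write_series_csv(path, series: list[TimeSeries], names=None) -> None:
    names = names or [f"value{i + 1}" for i in range(len(series))]
    d = {"t": np.arange(series[0].n)}
    for nm, s in zip(names, series):
        d[nm] = s.values
    pd.DataFrame(d).to_csv(path, index=False)


def read_station_csv(path) -> pd.DataFrame:
    """Read the tidy station rectangle `station_id,lat,lon,year,mean_temp`."""
    df = pd.read_csv(path)
    need = ["station_id", "lat", "lon", "year", "mean_temp"]
    missing = [c for c in need if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    vals = pd.to_numeric(df["mean_temp"], errors="coerce")
    bad = vals.index[vals.isna()]
    if len(bad):
        raise ValueError(f"{path}: missing mean_temp at row {int(bad[0]) + 2}")
    return df


def stations_to_frame(stations: list[StationSeries]) -> pd.DataFrame:
    rows = [pd.DataFrame({"station_id": s.station_id, "lat": s.lat, "lon": s.lon,
                          "year": s.years, "mean_temp": s.mean_temp})
            for s in stations]
    return pd.concat(rows, ignore_index=True)
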