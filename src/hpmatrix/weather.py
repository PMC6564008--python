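"""Daily mean-temperature series: GHCN-Daily CSV reader and a synthetic
upper-Midwest growing-season climatology.

The simulation needs one mean temperature per projection day.  Field runs
read a GHCN-Daily-style CSV (``DATE`` plus ``TAVG`` or ``TMAX``/``TMIN``,
degC or tenths of degC); self-contained runs use
:func:`synthetic_climatology`, a sinusoidal annual cycle with Gaussian daily
noise parameterized to resemble southwestern Minnesota (the region whose
station record drove the original field-season scenario).
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "TemperatureSeries",
    "WeatherError",
    "read_ghcn_daily",
    "synthetic_climatology",
]


class WeatherError(ValueError):
    """Raised for unusable temperature input (missing range, long gaps...)."""


@dataclass(frozen=True)
class TemperatureSeries:
    """Contiguous daily mean temperatures (degC) from ``start_date``."""

    start_date: dt.date
    values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.values.ndim != 1 or self.values.size == 0:
            raise WeatherError("temperature series must be a non-empty 1-d array")
        if not np.isfinite(self.values).all():
            raise WeatherError("temperature series contains non-finite values")

    def __len__(self) -> int:
        return self.values.size

    @property
    def dates(self) -> pd.DatetimeIndex:
        return pd.date_range(self.start_date, periods=len(self), freq="D")

    def with_offset(self, offset: float) -> "TemperatureSeries":
        """Uniformly shift every day by ``offset`` degC (sensitivity sweeps)."""
        return TemperatureSeries(self.start_date, self.values + offset)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"date": self.dates, "tmean_c": self.values})


def read_ghcn_daily(
    path,
    start_date: dt.date,
    horizon_days: int,
    units: str = "auto",
    max_gap_days: int = 3,
) -> TemperatureSeries:
    """Read daily mean temperatures from a GHCN-Daily-style CSV.

    Daily mean = ``TAVG`` if present, else ``(TMAX + TMIN)/2``.  With
    ``units="auto"`` tenths-of-degC encoding (the raw GHCN integer
    convention) is detected by magnitude and rescaled.  Gaps up to
    ``max_gap_days`` are linearly interpolated; longer gaps or a window not
    covered by the file raise :class:`WeatherError`.
    """
    df = pd.read_csv(path)
    df.columns = [c.strip().upper() for c in df.columns]
    if "DATE" not in df.columns:
        raise WeatherError(f"{path}: no DATE column")
    try:
        dates = pd.to_datetime(df["DATE"])
    except (ValueError, TypeError) as exc:
        raise WeatherError(f"{path}: unparseable DATE values: {exc}") from exc
    if "TAVG" in df.columns:
        tmean = pd.to_numeric(df["TAVG"], errors="coerce")
    elif "TMAX" in df.columns and "TMIN" in df.columns:
        tmean = (
            pd.to_numeric(df["TMAX"], errors="coerce")
            + pd.to_numeric(df["TMIN"], errors="coerce")
        ) / 2.0
    else:
        raise WeatherError(f"{path}: need TAVG or TMAX+TMIN columns")
    series = pd.Series(tmean.values, index=dates).sort_index()
    series = series[~series.index.duplicated(keep="first")]
    if units == "tenths" or (
        units == "auto" and series.abs().max() > 60.0
    ):  # plausible air temps never exceed 60 degC
        series = series / 10.0
    window = pd.date_range(start_date, periods=horizon_days, freq="D")
    if window[0] < series.index.min() or window[-1] > series.index.max():
        raise WeatherError(
            f"{path}: requested window {window[0].date()}..{window[-1].date()} "
            f"not covered by file range {series.index.min().date()}.."
            f"{series.index.max().date()}"
        )
    full = series.reindex(pd.date_range(series.index.min(), series.index.max(), freq="D"))
    gap_sizes = full.isna().astype(int).groupby(full.notna().cumsum()).sum()
    if (gap_sizes > max_gap_days).any():
        raise WeatherError(
            f"{path}: gap longer than {max_gap_days} days in temperature record"
        )
    full = full.interpolate(method="linear", limit_area="inside")
    values = full.reindex(window).to_numpy()
    if np.isnan(values).any():
        raise WeatherError(f"{path}: missing values remain in requested window")
    return TemperatureSeries(start_date, values)


def synthetic_climatology(
    start_date: dt.date,
    horizon_days: int,
    mean_peak: float = 23.5,
    amplitude: float = 16.0,
    peak_doy: int = 205,
    noise_sd: float = 3.0,
    offset: float = 0.0,
    seed: int | None = None,
) -> TemperatureSeries:
    """Generate a synthetic daily mean-temperature series.

    The seasonal cycle is sinusoidal with its maximum ``mean_peak`` (degC)
    on day-of-year ``peak_doy`` and a trough of ``mean_peak - 2*amplitude``
    half a year away:

        T(doy) = mean_peak - amplitude*(1 - cos(2*pi*(doy - peak_doy)/365))
                 + offset + Normal(0, noise_sd)

    Defaults emulate a southwestern-Minnesota summer (July mean about
    23.5 degC, late-July peak, January mean about -8.5 degC, day-to-day
    weather noise of 3 degC).  ``offset`` shifts every day uniformly and
    implements the +/- 3 degC temperature sweep.  The noise stream is
    drawn from a generator seeded with ``seed``, so a fixed seed
    reproduces the series exactly.
    """
    if horizon_days < 1:
        raise WeatherError("horizon_days must be >= 1")
    dates = pd.date_range(start_date, periods=horizon_days, freq="D")
    doy = dates.dayofyear.to_numpy()
    seasonal = mean_peak - amplitude * (1.0 - np.cos(2.0 * np.pi * (doy - peak_doy) / 365.0))
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, noise_sd, size=horizon_days) if noise_sd > 0 else 0.0
    return TemperatureSeries(start_date, seasonal + offset + noise)
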