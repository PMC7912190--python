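"""Thermal heat-stress indices for cowshed microclimate readings.

Computes dew-point temperature (Tdp), the temperature-humidity index (THI,
Yousef form), the heat load index (HLI) and accumulated heat load units
(AHLU) from microclimate readings (dry-bulb temperature AT, relative
humidity RH, air speed AS and black-globe temperature GT), plus the ordinal
heat-stress bands used to interpret each index.

All numeric functions are vectorised over numpy arrays; scalars work too.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DewPointTerms",
    "HLI_LOWER_THRESHOLD",
    "HLI_UPPER_THRESHOLD",
    "dew_point",
    "thi_yousef",
    "hli",
    "ahlu_increment",
    "ahlu_series",
    "categorize",
    "CATEGORY_BANDS",
    "compute_indices",
    "clock_to_hours",
]

#: HLI band within which cattle neither gain nor discharge heat load.
HLI_LOWER_THRESHOLD = 77.0
HLI_UPPER_THRESHOLD = 86.0

#: Default low-branch HLI humidity coefficient.  0.28 is the coefficient of
#: the source HLI formulation; see ``hli`` for the rationale.
DEFAULT_LOW_RH_COEFF = 0.28


class DewPointTerms(NamedTuple):
    """Intermediate ``b`` and dew-point temperature (°C) of the Magnus inversion."""

    b: np.ndarray | float
    Tdp: np.ndarray | float


def dew_point(AT, RH) -> DewPointTerms:
    """Dew-point temperature from dry-bulb temperature and relative humidity.

    Uses the Magnus-form inversion

        b   = [ln(RH/100) + 17.27·AT/(237.3 + AT)] / 17.27
        Tdp = 237.3·b / (1 − b)

    Parameters
    ----------
    AT : array_like
        Dry-bulb temperature, °C.
    RH : array_like
        Relative humidity, %, in (0, 100].  RH = 0 is a domain error
        (logarithm of zero).

    Returns
    -------
    DewPointTerms
        ``b`` (dimensionless, < 1) and ``Tdp`` (°C, ≤ AT).  At saturation
        (RH = 100) ``Tdp == AT`` exactly.
    """
    AT = np.asarray(AT, dtype=float)
    RH = np.asarray(RH, dtype=float)
    if np.any(RH <= 0):
        raise ValueError("invalid-humidity: RH must be > 0 (log of zero at RH=0)")
    if np.any(RH > 100):
        raise ValueError("invalid-humidity: RH must be <= 100")
    b = (np.log(RH / 100.0) + (17.27 * AT) / (237.3 + AT)) / 17.27
    Tdp = (237.3 * b) / (1.0 - b)
    if Tdp.ndim == 0:
        return DewPointTerms(float(b), float(Tdp))
    return DewPointTerms(b, Tdp)


def thi_yousef(AT, Tdp):
    """Temperature-humidity index (Yousef): THI = AT + 0.36·Tdp + 41.2."""
    AT = np.asarray(AT, dtype=float)
    Tdp = np.asarray(Tdp, dtype=float)
    out = AT + 0.36 * Tdp + 41.2
    return float(out) if out.ndim == 0 else out


def hli(GT, RH, AS, low_rh_coeff: float = DEFAULT_LOW_RH_COEFF):
    """Heat load index from globe temperature, humidity and air speed.

    Piecewise in globe temperature, with the branch switch at GT = 25 °C
    (boundary on the high branch):

        GT ≥ 25:  HLI = 8.62 + 0.38·RH + 1.55·GT − 0.5·AS + e^(2.4 − AS)
        GT < 25:  HLI = 10.66 + c·RH + 1.3·GT − AS

    ``low_rh_coeff`` (``c``) defaults to 0.28, the coefficient of the source
    HLI formulation.  Some secondary descriptions print 2.8, which is
    physically implausible (a humidity of 80% alone would contribute 224
    index units); pass ``low_rh_coeff=2.8`` to reproduce that variant.
    """
    GT = np.asarray(GT, dtype=float)
    RH = np.asarray(RH, dtype=float)
    AS = np.asarray(AS, dtype=float)
    if np.any(AS < 0):
        raise ValueError("air speed must be non-negative")
    high = 8.62 + 0.38 * RH + 1.55 * GT - 0.5 * AS + np.exp(2.4 - AS)
    low = 10.66 + low_rh_coeff * RH + 1.3 * GT - AS
    out = np.where(GT >= 25.0, high, low)
    return float(out) if out.ndim == 0 else out


def ahlu_increment(hli_values,
                   lower: float = HLI_LOWER_THRESHOLD,
                   upper: float = HLI_UPPER_THRESHOLD):
    """Hourly heat-load balance implied by an HLI value.

    Negative (discharge) below the lower threshold, zero inside the
    thermoneutral band [lower, upper], positive (accumulation) above it:

        HLI < lower          →  HLI − lower
        lower ≤ HLI ≤ upper  →  0
        HLI > upper          →  HLI − upper
    """
    h = np.asarray(hli_values, dtype=float)
    out = np.where(h < lower, h - lower, np.where(h > upper, h - upper, 0.0))
    return float(out) if out.ndim == 0 else out


def ahlu_series(hli_values: Sequence[float],
                clock_hours: Sequence[float],
                lower: float = HLI_LOWER_THRESHOLD,
                upper: float = HLI_UPPER_THRESHOLD) -> np.ndarray:
    """Accumulated heat load units along one farm-day of HLI measurements.

    The series starts fresh at the first time point: the first AHLU equals
    the increment at that time point (no interval weighting, no overnight
    carry-over), and each subsequent value is

        AHLU_t = AHLU_{t-1} + increment_t × (t − t_{previous})   [hours]

    clamped at zero after every update (a cow cannot hold a negative heat
    load).  ``clock_hours`` must be strictly increasing.

    Returns the AHLU at each time point as a float array.
    """
    h = np.asarray(hli_values, dtype=float)
    t = np.asarray(clock_hours, dtype=float)
    if h.size == 0:
        raise ValueError("need at least one time point")
    if h.shape != t.shape:
        raise ValueError("hli_values and clock_hours must have equal length")
    if np.any(np.diff(t) <= 0):
        raise ValueError("clock times must be strictly increasing")
    inc = ahlu_increment(h, lower, upper)
    inc = np.atleast_1d(inc)
    out = np.empty_like(inc)
    out[0] = max(inc[0], 0.0)
    for i in range(1, inc.size):
        out[i] = max(out[i - 1] + inc[i] * (t[i] - t[i - 1]), 0.0)
    return out


# Ordinal heat-stress bands, half-open [lower, upper).  Each entry maps an
# index name to (thresholds, labels) with len(labels) == len(thresholds)+1.
CATEGORY_BANDS: dict[str, tuple[tuple[float, ...], tuple[str, ...]]] = {
    "AT": ((20.0, 27.0),
           ("normal", "heat stress threshold", "mid-severe heat stress")),
    "THI": ((68.0, 72.0, 80.0),
            ("normal", "heat stress threshold",
             "mild-moderate heat stress", "moderate-severe heat stress")),
    "HLI": ((70.0, 77.0, 86.0),
            ("cool", "moderate", "hot", "very hot")),
    "AHLU": ((10.0, 25.0, 50.0),
             ("low heat load", "moderate heat load",
              "high heat load", "very high heat load")),
}


def categorize(index_name: str, value):
    """Ordinal heat-stress band for an index value.

    Bands are half-open ``[lower, upper)`` and jointly cover the whole real
    line, so every value falls in exactly one band.  ``index_name`` must be
    one of AT, THI, HLI, AHLU.
    """
    try:
        thresholds, labels = CATEGORY_BANDS[index_name]
    except KeyError:
        raise KeyError(f"unknown index name: {index_name!r}; "
                       f"expected one of {sorted(CATEGORY_BANDS)}") from None
    v = np.asarray(value, dtype=float)
    idx = np.searchsorted(np.asarray(thresholds), v, side="right")
    out = np.asarray(labels, dtype=object)[idx]
    return str(out) if v.ndim == 0 else out


def clock_to_hours(clock_time) -> np.ndarray | float:
    """Convert 'HH:MM' strings (or numbers already in hours) to fractional hours."""
    def one(v):
        if isinstance(v, str):
            hh, mm = v.split(":")
            return int(hh) + int(mm) / 60.0
        return float(v)

    if np.isscalar(clock_time) or isinstance(clock_time, str):
        return one(clock_time)
    return np.array([one(v) for v in clock_time])


@dataclass
class ThermalIndexSeries:
    """Per-time-point indices and bands for one farm-day."""

    farm_id: object
    clock_hours: np.ndarray
    table: pd.DataFrame  # columns Tdp, THI, HLI, AHLU_increment, AHLU + categories


def compute_indices(readings: pd.DataFrame,
                    hli_low_rh_coeff: float = DEFAULT_LOW_RH_COEFF,
                    lower: float = HLI_LOWER_THRESHOLD,
                    upper: float = HLI_UPPER_THRESHOLD) -> pd.DataFrame:
    """Append index and band columns to a long-format readings table.

    ``readings`` needs columns ``farm_id, clock_time, AT, RH, AS, GT``
    (clock_time as 'HH:MM' or numeric hours).  The AHLU recursion is run
    separately per farm in clock-time order.  Returns a copy with added
    columns ``Tdp, THI, HLI, AHLU_increment, AHLU, at_category,
    thi_category, hli_category, ahlu_category``.
    """
    required = {"farm_id", "clock_time", "AT", "RH", "AS", "GT"}
    missing = required - set(readings.columns)
    if missing:
        raise ValueError(f"missing input columns: {sorted(missing)}")
    df = readings.copy()
    hours = clock_to_hours(df["clock_time"].to_numpy())
    df["_hours"] = hours
    _, tdp = dew_point(df["AT"].to_numpy(), df["RH"].to_numpy())
    df["Tdp"] = tdp
    df["THI"] = thi_yousef(df["AT"].to_numpy(), tdp)
    df["HLI"] = hli(df["GT"].to_numpy(), df["RH"].to_numpy(),
                    df["AS"].to_numpy(), low_rh_coeff=hli_low_rh_coeff)
    df["AHLU_increment"] = ahlu_increment(df["HLI"].to_numpy(), lower, upper)
    ahlu = np.empty(len(df))
    for _, idx in df.groupby("farm_id", sort=False).groups.items():
        sub = df.loc[idx].sort_values("_hours")
        vals = ahlu_series(sub["HLI"].to_numpy(), sub["_hours"].to_numpy(),
                           lower, upper)
        ahlu[df.index.get_indexer(sub.index)] = vals
    df["AHLU"] = ahlu
    df["at_category"] = categorize("AT", df["AT"].to_numpy())
    df["thi_category"] = categorize("THI", df["THI"].to_numpy())
    df["hli_category"] = categorize("HLI", df["HLI"].to_numpy())
    df["ahlu_category"] = categorize("AHLU", df["AHLU"].to_numpy())
    return df.drop(columns="_hours")
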