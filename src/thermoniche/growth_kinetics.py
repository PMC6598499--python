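"""Growth-rate estimation from fluorescence time series.

Raw minimum-fluorescence (F0) readings are used as a biomass proxy; the
exponential growth rate in divisions per day is the ordinary least squares
slope of log2(F0) against time.  Replicate rates are averaged per
strain x temperature, and viability fractions are computed from
viable/dead cell counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConsistencyError, DataError, EstimationError

__all__ = [
    "FluorescenceSeries",
    "GrowthRateEstimate",
    "ReplicateSummary",
    "ViabilityCount",
    "ViabilitySummary",
    "estimate_growth_rate",
    "average_replicates",
    "viability_fraction",
    "read_f0_csv",
    "growth_rate_table",
]

#: Default regression window: all points within the first 5 days.
DEFAULT_WINDOW = (0.0, 5.0)


@dataclass(frozen=True)
class FluorescenceSeries:
    """One replicate's F0 measurements over time at one temperature.

    Parameters
    ----------
    strain_id : str
        Strain label.
    temperature : float
        Incubation temperature in degrees Celsius.
    replicate : int
        Replicate index.
    times : tuple of float
        Measurement times in days, strictly increasing.
    f0 : tuple of float
        Minimum fluorescence yield per time point (arbitrary units).
    """

    strain_id: str
    temperature: float
    replicate: int
    times: tuple
    f0: tuple

    def __post_init__(self):
        times = tuple(float(t) for t in self.times)
        f0 = tuple(float(v) for v in self.f0)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "f0", f0)
        if len(times) != len(f0):
            raise DataError(
                f"{self.strain_id}@{self.temperature}C rep {self.replicate}: "
                f"{len(times)} times but {len(f0)} F0 values"
            )
        if len(times) < 2:
            raise DataError("a fluorescence series needs at least 2 observations")
        if any(b <= a for a, b in zip(times, times[1:])):
            raise DataError("times must be strictly increasing")
        if not all(math.isfinite(v) for v in f0):
            raise DataError("F0 values must be finite")
        if any(v < 0 for v in f0):
            raise DataError("F0 values must be nonnegative")


@dataclass(frozen=True)
class GrowthRateEstimate:
    """OLS slope of log2(F0) vs time: growth rate in divisions per day."""

    rate: float
    r_squared: float
    n_points: int
    window: tuple
    strain_id: str = ""
    temperature: float = float("nan")
    replicate: int = -1

    def __post_init__(self):
        if self.n_points < 2:
            raise DataError("growth-rate estimate needs n_points >= 2")
        if not (0.0 <= self.r_squared <= 1.0 + 1e-12):
            raise DataError(f"r_squared out of [0,1]: {self.r_squared}")


@dataclass(frozen=True)
class ReplicateSummary:
    """Replicate-averaged growth rate for one strain x temperature."""

    strain_id: str
    temperature: float
    mean_rate: float
    se_rate: float
    n_replicates: int

    def __post_init__(self):
        if self.se_rate < 0:
            raise DataError("se_rate must be >= 0")


@dataclass(frozen=True)
class ViabilityCount:
    """Viable/total cell counts for one replicate (SYTOX-type assay)."""

    strain_id: str
    temperature: float
    replicate: int
    viable: int
    total: int

    def __post_init__(self):
        if self.total <= 0:
            raise DataError("total count must be > 0")
        if not (0 <= self.viable <= self.total):
            raise DataError("viable count must be in [0, total]")


@dataclass(frozen=True)
class ViabilitySummary:
    mean_fraction: float
    fractions: tuple
    verdict: str  # "viable cells detected" or "no viable cells"


def _resolve_window(series: FluorescenceSeries, window) -> np.ndarray:
    """Return boolean mask of points inside the requested window."""
    times = np.asarray(series.times)
    if window is None or window == "default":
        # first 5 days relative to the first observation (shift-invariant)
        span = DEFAULT_WINDOW[1] - DEFAULT_WINDOW[0]
        return times <= times[0] + span
    if window == "all":
        return np.ones_like(times, dtype=bool)
    lo, hi = window
    return (times >= lo) & (times <= hi)


def _ols_rate(times: np.ndarray, f0: np.ndarray) -> tuple:
    log2f = np.log2(f0)
    if np.ptp(log2f) == 0.0:
        # exactly constant series: slope 0, R^2 defined as 1 (perfect flat fit)
        return 0.0, 1.0
    res = stats.linregress(times, log2f)
    return float(res.slope), float(res.rvalue**2)


def estimate_growth_rate(
    series: FluorescenceSeries,
    window="default",
    drop_nonpositive: bool = False,
) -> GrowthRateEstimate:
    """Estimate the growth rate (divisions/day) from a fluorescence series.

    The rate is the OLS slope of log2(F0) against time in days, restricted
    to the requested window.

    Parameters
    ----------
    series : FluorescenceSeries
    window : "default", "auto", "all", or (start_day, end_day)
        "default" keeps the points within 5 days of the first observation.
        "auto" scans contiguous windows of >= 4 points and keeps the one
        with the highest R^2.
    drop_nonpositive : bool
        If True, silently drop F0 <= 0 points instead of raising.

    Raises
    ------
    DataError
        If any F0 inside the window is nonpositive (unless dropped).
    EstimationError
        If fewer than 2 usable points remain.
    """
    times = np.asarray(series.times, dtype=float)
    f0 = np.asarray(series.f0, dtype=float)

    if window == "auto":
        return _auto_window_estimate(series, drop_nonpositive)

    mask = _resolve_window(series, window)
    t, v = times[mask], f0[mask]
    bad = np.nonzero(v <= 0)[0]
    if bad.size:
        if drop_nonpositive:
            keep = v > 0
            t, v = t[keep], v[keep]
        else:
            i = int(bad[0])
            raise DataError(
                f"nonpositive F0 ({v[i]}) at day {t[i]} for "
                f"{series.strain_id}@{series.temperature}C rep {series.replicate}"
            )
    if t.size < 2:
        raise EstimationError(
            f"fewer than 2 usable points in window for "
            f"{series.strain_id}@{series.temperature}C rep {series.replicate}"
        )
    rate, r2 = _ols_rate(t, v)
    return GrowthRateEstimate(
        rate=rate,
        r_squared=min(r2, 1.0),
        n_points=int(t.size),
        window=(float(t[0]), float(t[-1])),
        strain_id=series.strain_id,
        temperature=series.temperature,
        replicate=series.replicate,
    )


def _auto_window_estimate(series, drop_nonpositive):
    """Contiguous window of >= 4 points maximizing R^2."""
    times = np.asarray(series.times, dtype=float)
    f0 = np.asarray(series.f0, dtype=float)
    if drop_nonpositive:
        keep = f0 > 0
        times, f0 = times[keep], f0[keep]
    elif np.any(f0 <= 0):
        i = int(np.nonzero(f0 <= 0)[0][0])
        raise DataError(
            f"nonpositive F0 ({f0[i]}) at day {times[i]} for "
            f"{series.strain_id}@{series.temperature}C rep {series.replicate}"
        )
    n = times.size
    min_pts = min(4, n)
    if n < 2:
        raise EstimationError("fewer than 2 usable points")
    best = None
    for i in range(n):
        for j in range(i + min_pts, n + 1):
            rate, r2 = _ols_rate(times[i:j], f0[i:j])
            if best is None or r2 > best[1]:
                best = (rate, r2, i, j)
    rate, r2, i, j = best
    return GrowthRateEstimate(
        rate=rate,
        r_squared=min(r2, 1.0),
        n_points=j - i,
        window=(float(times[i]), float(times[j - 1])),
        strain_id=series.strain_id,
        temperature=series.temperature,
        replicate=series.replicate,
    )


def average_replicates(estimates: Sequence[GrowthRateEstimate]) -> ReplicateSummary:
    """Average replicate growth rates for one strain x temperature.

    mean = arithmetic mean of rates; SE = sample (n-1) standard deviation
    divided by sqrt(n).
    """
    estimates = list(estimates)
    if not estimates:
        raise DataError("cannot average an empty list of estimates")
    strains = {e.strain_id for e in estimates}
    temps = {e.temperature for e in estimates}
    if len(strains) > 1 or len(temps) > 1:
        raise ConsistencyError(
            f"mixed labels in replicate set: strains={sorted(strains)}, "
            f"temperatures={sorted(temps)}"
        )
    rates = np.array([e.rate for e in estimates], dtype=float)
    n = rates.size
    mean = float(rates.mean())
    se = float(rates.std(ddof=1) / math.sqrt(n)) if n > 1 else 0.0
    return ReplicateSummary(
        strain_id=estimates[0].strain_id,
        temperature=estimates[0].temperature,
        mean_rate=mean,
        se_rate=se,
        n_replicates=n,
    )


def viability_fraction(counts: Sequence[ViabilityCount]) -> ViabilitySummary:
    """Per-replicate viable fractions, their mean, and an alive/dead verdict."""
    counts = list(counts)
    if not counts:
        raise DataError("cannot summarize an empty list of viability counts")
    fractions = tuple(c.viable / c.total for c in counts)
    mean = float(np.mean(fractions))
    verdict = "viable cells detected" if any(f > 0 for f in fractions) else "no viable cells"
    return ViabilitySummary(mean_fraction=mean, fractions=fractions, verdict=verdict)


# ---------------------------------------------------------------------------
# CSV plumbing

F0_COLUMNS = ["strain_id", "temperature_c", "replicate", "time_days", "f0"]


def read_f0_csv(path) -> list:
    """Read a long-format F0 table into FluorescenceSeries objects.

    Expected columns: strain_id, temperature_c, replicate, time_days, f0.
    """
    df = pd.read_csv(path)
    missing = [c for c in F0_COLUMNS if c not in df.columns]
    if missing:
        raise DataError(f"F0 CSV missing columns: {missing}")
    out = []
    for (sid, temp, rep), grp in df.groupby(
        ["strain_id", "temperature_c", "replicate"], sort=True
    ):
        grp = grp.sort_values("time_days")
        out.append(
            FluorescenceSeries(
                strain_id=str(sid),
                temperature=float(temp),
                replicate=int(rep),
                times=tuple(grp["time_days"]),
                f0=tuple(grp["f0"]),
            )
        )
    return out


def growth_rate_table(
    series_list: Iterable[FluorescenceSeries],
    window="default",
    drop_nonpositive: bool = False,
) -> pd.DataFrame:
    """Estimate all rates and average replicates.

    Returns a DataFrame with columns strain_id, temperature_c, mean_rate,
    se_rate, n_replicates (the thermal_response input schema).
    """
    groups: dict = {}
    for s in series_list:
        est = estimate_growth_rate(s, window=window, drop_nonpositive=drop_nonpositive)
        groups.setdefault((s.strain_id, s.temperature), []).append(est)
    rows = []
    for (sid, temp) in sorted(groups):
        summ = average_replicates(groups[(sid, temp)])
        rows.append(
            dict(
                strain_id=sid,
                temperature_c=temp,
                mean_rate=summ.mean_rate,
                se_rate=summ.se_rate,
                n_replicates=summ.n_replicates,
            )
        )
    return pd.DataFrame(rows, columns=["strain_id", "temperature_c", "mean_rate", "se_rate", "n_replicates"])
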