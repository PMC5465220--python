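"""Plate-reader growth-rate screening.

Implements the log-phase screen used for 96-well OD600 time series:
detection of the logarithmic-phase window by explicit OD rules, an
exponential (log-linear) fit with validity gates, normalization of the
treated growth rate to the untreated control, and replicate aggregation.

The log phase of a well is the maximal contiguous run of readings with

    OD > od_floor  (default 0.055)   and   OD < max(OD of that well) / 2,

truncated where the cumulative number of consecutive-pair OD decreases
inside the run first exceeds ``max_decreases`` (default 5).  The growth
rate is the slope of an ordinary least-squares fit of ln(OD) against time
over that window; a fit is valid only if R² > 0.9 and RMSE < 0.2 (both on
the ln(OD) scale) and the window holds at least three readings.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GrowthCurve",
    "GrowthFit",
    "NormalizedGrowth",
    "GrowthRateModel",
    "read_plate_timeseries",
    "detect_log_phase",
    "fit_growth_rate",
    "normalize_growth",
    "aggregate_replicates",
]

logger = logging.getLogger(__name__)

OD_FLOOR = 0.055
MAX_DECREASES = 5
R2_GATE = 0.9
RMSE_GATE = 0.2
MIN_WINDOW = 3


@dataclass(frozen=True)
class GrowthCurve:
    """One well's OD600 readings on a common time grid.

    ``times`` are minutes since inoculation, strictly increasing; ``od``
    are blank-corrected OD600 readings (must be finite and positive).
    """

    well_id: str
    strain: str
    condition: str
    times: np.ndarray
    od: np.ndarray

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        od = np.asarray(self.od, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "od", od)
        if times.ndim != 1 or od.shape != times.shape:
            raise ValueError("times and od must be 1-D arrays of equal length")
        if len(times) < 4:
            raise ValueError(f"well {self.well_id}: need >= 4 readings, got {len(times)}")
        if not np.all(np.diff(times) > 0):
            raise ValueError(f"well {self.well_id}: times must be strictly increasing")
        if not (np.all(np.isfinite(od)) and np.all(od > 0)):
            raise ValueError(f"well {self.well_id}: OD readings must be finite and > 0")

    def __len__(self) -> int:
        return len(self.times)


@dataclass(frozen=True)
class GrowthFit:
    """Result of an exponential fit over a detected log-phase window.

    ``slope`` is the specific growth rate mu in h^-1 from ln(OD) vs time,
    ``doubling_time`` is 60*ln(2)/mu in minutes, and ``valid`` applies the
    R² > 0.9 / RMSE < 0.2 / window-length >= 3 gates.
    """

    well_id: str
    window_start: int
    window_end: int
    slope: float
    doubling_time: float
    r2: float
    rmse: float
    valid: bool
    reason: str = ""

    @property
    def window(self) -> tuple[int, int]:
        return (self.window_start, self.window_end)


@dataclass(frozen=True)
class NormalizedGrowth:
    """Replicate summary of treated/untreated growth-rate ratios."""

    strain: str
    condition: str
    normalized_rate: float
    sd: float
    n: int
    low_n: bool = False  # True when n < 3 (reported screens require n >= 3)


def read_plate_timeseries(
    path, layout: Mapping[str, tuple[str, str]]
) -> list[GrowthCurve]:
    """Read a long-format plate CSV (columns well, time_min, od).

    ``layout`` maps well ids to (strain, condition).  Wells present in the
    file but absent from the layout are logged and skipped.  Rows are sorted
    by time within each well; duplicate timestamps or non-numeric OD raise.
    """
    df = pd.read_csv(path)
    required = {"well", "time_min", "od"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"plate file missing column(s): {sorted(missing)}")
    df["time_min"] = pd.to_numeric(df["time_min"], errors="raise")
    df["od"] = pd.to_numeric(df["od"], errors="raise")

    curves: list[GrowthCurve] = []
    for well, grp in df.groupby("well", sort=True):
        if well not in layout:
            logger.warning("well %s not in layout; skipping", well)
            continue
        grp = grp.sort_values("time_min")
        times = grp["time_min"].to_numpy(dtype=float)
        if np.any(np.diff(times) == 0):
            raise ValueError(f"well {well}: duplicate timestamps")
        strain, condition = layout[well]
        curves.append(
            GrowthCurve(
                well_id=str(well),
                strain=strain,
                condition=condition,
                times=times,
                od=grp["od"].to_numpy(dtype=float),
            )
        )
    return curves


def detect_log_phase(
    curve: GrowthCurve,
    od_floor: float = OD_FLOOR,
    max_decreases: int = MAX_DECREASES,
) -> tuple[int, int] | None:
    """Locate the logarithmic-phase window of a growth curve.

    Returns half-open indices ``(start, end)`` of the maximal contiguous run
    of readings with ``od > od_floor`` and ``od < max(od)/2``, truncated at
    the reading where the cumulative count of consecutive-pair decreases
    (counted from the run's start) first exceeds ``max_decreases``.  Returns
    None when no reading qualifies.
    """
    od = curve.od
    half_max = od.max() / 2.0
    ok = (od > od_floor) & (od < half_max)
    if not ok.any():
        return None

    # enumerate contiguous runs of qualifying readings, keep the longest
    best: tuple[int, int] | None = None
    i = 0
    n = len(od)
    while i < n:
        if not ok[i]:
            i += 1
            continue
        j = i
        while j < n and ok[j]:
            j += 1
        start, end = i, j
        # truncate at the reading where the decrease count first exceeds the cap
        decreases = 0
        for k in range(start + 1, end):
            if od[k] < od[k - 1]:
                decreases += 1
                if decreases > max_decreases:
                    end = k
                    break
        if best is None or (end - start) > (best[1] - best[0]):
            best = (start, end)
        i = j
    return best


def _ols_line(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float, float]:
    """OLS of y on x; returns slope, intercept, r2, rmse (population RMSE)."""
    xm, ym = x.mean(), y.mean()
    sxx = np.sum((x - xm) ** 2)
    if sxx == 0:
        raise ValueError("degenerate window: constant time axis")
    slope = np.sum((x - xm) * (y - ym)) / sxx
    intercept = ym - slope * xm
    resid = y - (slope * x + intercept)
    sst = np.sum((y - ym) ** 2)
    r2 = 1.0 if sst == 0 else 1.0 - np.sum(resid**2) / sst
    rmse = float(np.sqrt(np.mean(resid**2)))
    return float(slope), float(intercept), float(r2), rmse


def fit_growth_rate(
    curve: GrowthCurve,
    window: tuple[int, int] | None,
    r2_gate: float = R2_GATE,
    rmse_gate: float = RMSE_GATE,
) -> GrowthFit:
    """Fit ln(OD) vs time over a log-phase window by OLS.

    The slope is converted to a per-hour growth rate mu; doubling time is
    60*ln(2)/mu minutes.  The fit is valid only when R² > ``r2_gate``,
    RMSE < ``rmse_gate`` (ln scale), the window holds >= 3 readings and the
    slope is positive.
    """

    def invalid(reason: str, start: int = 0, end: int = 0) -> GrowthFit:
        return GrowthFit(curve.well_id, start, end, math.nan, math.nan,
                         math.nan, math.nan, False, reason)

    if window is None:
        return invalid("no log phase detected")
    start, end = window
    if end - start < MIN_WINDOW:
        return invalid("window too short", start, end)
    od = curve.od[start:end]
    if np.any(od <= 0):
        return invalid("non-positive OD inside window", start, end)

    t_hours = curve.times[start:end] / 60.0
    slope, _, r2, rmse = _ols_line(t_hours, np.log(od))
    if slope <= 0:
        return GrowthFit(curve.well_id, start, end, slope, math.nan, r2, rmse,
                         False, "non-positive growth rate")
    doubling = 60.0 * math.log(2) / slope
    valid = (r2 > r2_gate) and (rmse < rmse_gate)
    reason = "" if valid else f"fit gates failed (r2={r2:.3f}, rmse={rmse:.3f})"
    return GrowthFit(curve.well_id, start, end, slope, doubling, r2, rmse,
                     valid, reason)


class GrowthRateModel:
    """Log-phase growth model for one well, statsmodels-style.

    Combines log-phase detection and the exponential fit; ``fit()`` returns
    the :class:`GrowthFit` result.

    Parameters
    ----------
    curve : GrowthCurve
    od_floor, max_decreases : log-phase detection thresholds
    r2_gate, rmse_gate : fit validity gates (ln-OD scale)
    """

    def __init__(
        self,
        curve: GrowthCurve,
        od_floor: float = OD_FLOOR,
        max_decreases: int = MAX_DECREASES,
        r2_gate: float = R2_GATE,
        rmse_gate: float = RMSE_GATE,
    ) -> None:
        self.curve = curve
        self.od_floor = od_floor
        self.max_decreases = max_decreases
        self.r2_gate = r2_gate
        self.rmse_gate = rmse_gate

    def detect_window(self) -> tuple[int, int] | None:
        return detect_log_phase(self.curve, self.od_floor, self.max_decreases)

    def fit(self) -> GrowthFit:
        return fit_growth_rate(
            self.curve, self.detect_window(), self.r2_gate, self.rmse_gate
        )


def normalize_growth(treated: GrowthFit, untreated: GrowthFit) -> float:
    """Treated / untreated growth-rate ratio (1.0 = no effect, <1 slower).

    Equals doubling_untreated / doubling_treated.  Raises if either fit is
    invalid, propagating its reason.
    """
    for side, fit in (("treated", treated), ("untreated", untreated)):
        if not fit.valid:
            raise ValueError(f"{side} fit invalid: {fit.reason or 'unknown reason'}")
    return treated.slope / untreated.slope


def aggregate_replicates(values: Sequence[float]) -> NormalizedGrowth | pd.Series:
    """Mean, sample SD and n of replicate normalized rates.

    SD is 0 when n == 1; summaries with n < 3 are flagged ``low_n`` since
    reported screens require at least three replicates.
    """
    vals = np.asarray(list(values), dtype=float)
    if vals.size == 0:
        raise ValueError("no replicate values to aggregate")
    sd = float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0
    return NormalizedGrowth(
        strain="", condition="",
        normalized_rate=float(vals.mean()), sd=sd, n=int(vals.size),
        low_n=vals.size < 3,
    )


def fits_to_frame(fits: Sequence[GrowthFit], curves: Sequence[GrowthCurve]) -> pd.DataFrame:
    """Tabulate per-well fits (well, strain, condition, mu, doubling time, gates)."""
    meta = {c.well_id: c for c in curves}
    rows = []
    for f in fits:
        c = meta[f.well_id]
        rows.append(
            dict(well=f.well_id, strain=c.strain, condition=c.condition,
                 mu_per_hour=f.slope, doubling_time_min=f.doubling_time,
                 r2=f.r2, rmse=f.rmse, valid=f.valid, reason=f.reason)
        )
    return pd.DataFrame(rows)
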