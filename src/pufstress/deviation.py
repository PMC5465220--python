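"""Deviation-based differential-expression callers.

Two callers reproduce the study's bespoke statistics:

* **Mean deviation** (wild-type CaCl2 response): a gene is called when its
  log2 ratio deviates from the across-gene mean by strictly more than
  ``sd_multiplier`` (default 2) sample standard deviations.

* **Trend deviation** (knockout vs parent, and synergy): an OLS trend line
  is fitted to the scatter of query log2 ratios (y) against reference
  ratios (x); a gene is called when its vertical residual from the line
  exceeds strictly +/- ``sd_multiplier`` sample SDs of the residuals.
  Under a Gaussian null this flags ~2.3-2.5% of genes per tail — about a
  hundred genes in a ~5,000-gene background — without an arbitrary
  fold-change cutoff.

The **synergy** model sets the expected double-deletion change to the sum
of the two single-deletion log2 changes (the product of fold changes in
linear space) and applies the trend-deviation rule to observed vs
expected.  Replicate batches are always analyzed separately; a consensus
is taken over the per-replicate call sets afterwards.

All three models follow the Model -> fit() -> Results pattern: construct
from data, call :meth:`fit`, inspect the Results object (estimates, calls
DataFrame, ``summary()``).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .expression import RatioProfile

__all__ = [
    "TrendFit",
    "MeanDeviationModel",
    "TrendDeviationModel",
    "SynergyModel",
    "DeviationResults",
    "fit_trend",
    "mean_deviation_calls",
    "trend_deviation_calls",
    "synergy_calls",
    "replicate_consensus",
]

STATUS_INDUCED = "induced"
STATUS_REPRESSED = "repressed"
STATUS_NONE = "none"


@dataclass(frozen=True)
class TrendFit:
    """OLS trend line y = slope*x + intercept with the residual spread."""

    slope: float
    intercept: float
    residual_sd: float  # sample SD (ddof=1) of vertical residuals
    n_genes: int

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.slope * np.asarray(x, dtype=float) + self.intercept


def fit_trend(x: Sequence[float], y: Sequence[float]) -> TrendFit:
    """Ordinary least squares of y on x with the sample SD of residuals.

    Requires >= 3 genes and non-constant x.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 genes to fit a trend")
    xm = x.mean()
    sxx = float(np.sum((x - xm) ** 2))
    if sxx == 0.0:
        raise ValueError("constant x: trend undefined")
    slope = float(np.sum((x - xm) * (y - y.mean())) / sxx)
    intercept = float(y.mean() - slope * xm)
    resid = y - (slope * x + intercept)
    residual_sd = float(np.std(resid, ddof=1))
    # points exactly on a line leave only float rounding noise: treat as 0
    if residual_sd <= 1e-10 * max(float(np.std(y)), 1e-300):
        residual_sd = 0.0
    return TrendFit(slope=slope, intercept=intercept,
                    residual_sd=residual_sd, n_genes=x.size)


def _status(residual: np.ndarray, cutoff: float) -> np.ndarray:
    """Strict +/-cutoff exceedance; cutoff 0 (SD == 0) flags nothing."""
    status = np.full(residual.shape, STATUS_NONE, dtype=object)
    if cutoff > 0:
        status[residual > cutoff] = STATUS_INDUCED
        status[residual < -cutoff] = STATUS_REPRESSED
    return status


class DeviationResults:
    """Results of a deviation caller.

    Attributes
    ----------
    calls : DataFrame with columns gene_id, x, y, residual, status
        (the mean-deviation caller has no x column).
    trend : TrendFit or None
    residual_sd : float — spread used for the cutoff.
    sd_multiplier : float
    """

    def __init__(
        self,
        calls: pd.DataFrame,
        residual_sd: float,
        sd_multiplier: float,
        trend: TrendFit | None = None,
        kind: str = "trend-deviation",
    ) -> None:
        self.calls = calls
        self.residual_sd = residual_sd
        self.sd_multiplier = sd_multiplier
        self.trend = trend
        self.kind = kind

    @property
    def cutoff(self) -> float:
        return self.sd_multiplier * self.residual_sd

    def flagged(self, status: str | None = None) -> set[str]:
        """Gene ids called induced, repressed, or (default) either."""
        if status is None:
            mask = self.calls["status"] != STATUS_NONE
        else:
            mask = self.calls["status"] == status
        return set(self.calls.loc[mask, "gene_id"])

    def tail_fraction(self, status: str) -> float:
        return float((self.calls["status"] == status).mean())

    def summary(self) -> str:
        n = len(self.calls)
        ni = int((self.calls["status"] == STATUS_INDUCED).sum())
        nr = int((self.calls["status"] == STATUS_REPRESSED).sum())
        lines = [
            f"{self.kind} caller ({n} genes)",
            "-" * 46,
        ]
        if self.trend is not None:
            lines.append(
                f"trend line: y = {self.trend.slope:.4f} x + {self.trend.intercept:+.4f}"
            )
        lines += [
            f"residual SD:          {self.residual_sd:.4f}",
            f"cutoff (+/- {self.sd_multiplier:g} SD):   {self.cutoff:.4f}",
            f"induced   (> +cutoff): {ni}  ({100 * ni / n:.2f}%)",
            f"repressed (< -cutoff): {nr}  ({100 * nr / n:.2f}%)",
        ]
        return "\n".join(lines)

    def plot(self, ax=None):
        """Scatter of y vs x with the trend line and +/-cutoff band;
        flagged genes colored red (induced) / blue (repressed)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        df = self.calls
        x = df["x"] if "x" in df else np.arange(len(df))
        colors = df["status"].map(
            {STATUS_INDUCED: "red", STATUS_REPRESSED: "blue", STATUS_NONE: "0.6"}
        )
        ax.scatter(x, df["y"], s=6, c=colors, linewidths=0)
        if self.trend is not None:
            xs = np.linspace(float(np.min(x)), float(np.max(x)), 50)
            ys = self.trend.predict(xs)
            ax.plot(xs, ys, "k-", lw=1)
            ax.plot(xs, ys + self.cutoff, "k--", lw=0.8)
            ax.plot(xs, ys - self.cutoff, "k--", lw=0.8)
        ax.set_xlabel("reference log2 ratio")
        ax.set_ylabel("query log2 ratio")
        return ax


def _as_series(values, name: str) -> pd.Series:
    if isinstance(values, RatioProfile):
        return values.log2_ratio
    if isinstance(values, pd.Series):
        return values
    arr = np.asarray(values, dtype=float)
    return pd.Series(arr, index=[f"g{i}" for i in range(arr.size)], name=name)


class MeanDeviationModel:
    """Flag genes deviating from the mean log2 ratio by > k sample SDs.

    Used for the wild-type CaCl2 response, where there is no reference
    strain to regress against.
    """

    def __init__(self, profile, sd_multiplier: float = 2.0) -> None:
        self.values = _as_series(profile, "log2_ratio")
        if self.values.size < 3:
            raise ValueError("need at least 3 genes")
        self.sd_multiplier = float(sd_multiplier)

    def fit(self) -> DeviationResults:
        v = self.values.to_numpy(dtype=float)
        mean = v.mean()
        sd = float(np.std(v, ddof=1))
        deviation = v - mean
        calls = pd.DataFrame(
            dict(gene_id=self.values.index, y=v, residual=deviation,
                 status=_status(deviation, self.sd_multiplier * sd))
        )
        return DeviationResults(calls, residual_sd=sd,
                                sd_multiplier=self.sd_multiplier,
                                kind="mean-deviation")


class TrendDeviationModel:
    """Flag genes by their vertical residual from the best-fit trend line.

    ``x`` is the reference axis (e.g. parent strain log2 T45/T0 ratios),
    ``y`` the query axis (e.g. deletion strain).  Inputs must come from a
    single replicate batch — never pool batches before fitting.

    Parameters
    ----------
    x, y : RatioProfile, Series or array of per-gene log2 ratios.
    sd_multiplier : cutoff in residual SDs (default 2).
    """

    def __init__(self, x, y, sd_multiplier: float = 2.0) -> None:
        xs = _as_series(x, "x")
        ys = _as_series(y, "y")
        if not xs.index.equals(ys.index):
            raise ValueError("gene lists of x and y differ")
        self.x = xs
        self.y = ys
        self.sd_multiplier = float(sd_multiplier)

    def fit(self) -> DeviationResults:
        trend = fit_trend(self.x.to_numpy(float), self.y.to_numpy(float))
        resid = self.y.to_numpy(float) - trend.predict(self.x.to_numpy(float))
        calls = pd.DataFrame(
            dict(gene_id=self.x.index, x=self.x.to_numpy(float),
                 y=self.y.to_numpy(float), residual=resid,
                 status=_status(resid, self.sd_multiplier * trend.residual_sd))
        )
        return DeviationResults(calls, residual_sd=trend.residual_sd,
                                sd_multiplier=self.sd_multiplier, trend=trend,
                                kind="trend-deviation")


class SynergyModel(TrendDeviationModel):
    """Double-deletion synergy under the multiplicative (product) model.

    The expected double-deletion log2 change of each gene is the sum of the
    two single-deletion log2 changes versus their own parents (the product
    of the fold changes in linear space).  Observed double-deletion changes
    are regressed on the expectation and genes deviating by more than
    ``sd_multiplier`` residual SDs are flagged as synergistic.
    """

    def __init__(self, double, single1, single2, sd_multiplier: float = 2.0) -> None:
        obs = _as_series(double, "observed")
        s1 = _as_series(single1, "single1")
        s2 = _as_series(single2, "single2")
        if isinstance(double, RatioProfile):
            for p in (single1, single2):
                if isinstance(p, RatioProfile) and p.contrast != double.contrast:
                    raise ValueError("profiles come from different contrasts")
        if not (s1.index.equals(obs.index) and s2.index.equals(obs.index)):
            raise ValueError("gene lists differ between profiles")
        expected = s1 + s2
        super().__init__(expected.rename("expected"), obs, sd_multiplier)

    def fit(self) -> DeviationResults:
        res = super().fit()
        res.kind = "synergy"
        res.calls = res.calls.rename(columns={"x": "expected", "y": "observed"})
        return res


# ---------------------------------------------------------------------------
# functional wrappers

def mean_deviation_calls(profile, sd_multiplier: float = 2.0) -> DeviationResults:
    """Mean +/- k*SD caller on one ratio profile (see MeanDeviationModel)."""
    return MeanDeviationModel(profile, sd_multiplier).fit()


def trend_deviation_calls(x, y, sd_multiplier: float = 2.0) -> tuple[TrendFit, DeviationResults]:
    """Trend-line residual caller for a deletion (y) vs its parent (x)."""
    res = TrendDeviationModel(x, y, sd_multiplier).fit()
    return res.trend, res


def synergy_calls(double, single1, single2, sd_multiplier: float = 2.0) -> tuple[TrendFit, DeviationResults]:
    """Observed vs product-of-singles synergy caller (see SynergyModel)."""
    res = SynergyModel(double, single1, single2, sd_multiplier).fit()
    return res.trend, res


def replicate_consensus(call_sets: Iterable[set], min_support: int = 2) -> set:
    """Items appearing in at least ``min_support`` of the per-replicate sets.

    The study reports only calls (or GO terms) supported by two or more
    independent biological repeats.
    """
    call_sets = [set(s) for s in call_sets]
    if not call_sets:
        raise ValueError("need at least one call set")
    counts: dict = {}
    for s in call_sets:
        for item in s:
            counts[item] = counts.get(item, 0) + 1
    return {item for item, c in counts.items() if c >= min_support}
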