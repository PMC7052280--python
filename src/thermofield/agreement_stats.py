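"""Agreement analyses between blending modes and across flights.

Bland-Altman analysis quantifies systematic differences between the two
orthomosaic blending modes: per-plot differences (``average`` minus
``disabled``) are plotted against per-plot means, summarized by the bias
(mean difference), normal-theory limits of agreement (bias +/- 1.96 sd) and
the OLS slope of difference on mean.  Cross-flight repeatability of the
spatially corrected genotype values is summarized by pairwise Pearson
correlation matrices, optionally restricted to a "stay-green" genotype
subset (no visual senescence up to a cutoff date).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import FitError, InputError


@dataclass
class BlandAltman:
    """Paired agreement summary between two measurement modes."""

    mean: np.ndarray  # per-plot mean of the two modes
    diff: np.ndarray  # per-plot difference, average - disabled
    bias: float
    loa_low: float  # bias - 1.96 sd
    loa_high: float  # bias + 1.96 sd
    slope: float  # OLS slope of diff on mean
    intercept: float

    @property
    def n(self) -> int:
        return len(self.diff)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"mean": self.mean, "diff": self.diff})


def bland_altman(x_avg, x_dis) -> BlandAltman:
    """Bland-Altman agreement of paired plot values from the two blending
    modes; the difference is defined as ``average - disabled``."""
    x_avg = np.asarray(x_avg, dtype=float)
    x_dis = np.asarray(x_dis, dtype=float)
    if x_avg.shape != x_dis.shape:
        raise InputError("paired vectors must have equal length")
    ok = np.isfinite(x_avg) & np.isfinite(x_dis)
    x_avg, x_dis = x_avg[ok], x_dis[ok]
    if len(x_avg) < 3:
        raise InputError("need at least 3 pairs")
    mean = (x_avg + x_dis) / 2.0
    diff = x_avg - x_dis
    bias = float(diff.mean())
    sd = float(diff.std(ddof=1))
    if np.ptp(mean) > 0:
        res = stats.linregress(mean, diff)
        slope, intercept = float(res.slope), float(res.intercept)
    else:
        slope, intercept = 0.0, bias
    return BlandAltman(
        mean=mean, diff=diff, bias=bias,
        loa_low=bias - 1.96 * sd, loa_high=bias + 1.96 * sd,
        slope=slope, intercept=intercept,
    )


def mode_regression(x_avg, x_dis):
    """OLS of the ``average``-mode values on the ``disabled``-mode values.

    Returns ``(intercept, slope, r_squared)``; near-identity (slope ~ 1,
    R^2 ~ 1) indicates the modes rank plots the same way.
    """
    x_avg = np.asarray(x_avg, dtype=float)
    x_dis = np.asarray(x_dis, dtype=float)
    if x_avg.shape != x_dis.shape:
        raise InputError("paired vectors must have equal length")
    ok = np.isfinite(x_avg) & np.isfinite(x_dis)
    x_avg, x_dis = x_avg[ok], x_dis[ok]
    if len(x_avg) < 3:
        raise InputError("need at least 3 pairs")
    if np.ptp(x_dis) == 0:
        raise FitError("zero variance in the predictor mode")
    res = stats.linregress(x_dis, x_avg)
    return float(res.intercept), float(res.slope), float(res.rvalue**2)


def correlation_matrix(values: pd.DataFrame, min_shared: int = 3) -> pd.DataFrame:
    """Pairwise Pearson correlations of genotype values between flights.

    ``values`` has one row per genotype and one column per flight.  Each pair
    uses the genotypes observed in both flights; cells with fewer than
    ``min_shared`` shared genotypes are left missing.  Diagonal = 1.
    """
    if values.shape[1] < 2:
        raise InputError("need >= 2 flights")
    flights = list(values.columns)
    out = pd.DataFrame(np.eye(len(flights)), index=flights, columns=flights)
    for i, a in enumerate(flights):
        for j in range(i + 1, len(flights)):
            b = flights[j]
            pair = values[[a, b]].dropna()
            if len(pair) < min_shared:
                out.loc[a, b] = out.loc[b, a] = np.nan
                continue
            r = float(np.corrcoef(pair[a], pair[b])[0, 1])
            out.loc[a, b] = out.loc[b, a] = r
    return out


def stay_green_subset(senescence: pd.DataFrame, cutoff_date) -> list[str]:
    """Genotypes with senescence score 0 on every date up to the cutoff.

    ``senescence`` is a genotype x date table of integer scores (0 = fully
    green ... 10 = fully senescent); columns must be sortable dates.
    """
    dates = list(senescence.columns)
    if not (min(dates) <= cutoff_date <= max(dates)):
        raise InputError(f"cutoff {cutoff_date!r} outside the scored date span")
    upto = [d for d in dates if d <= cutoff_date]
    green = senescence[upto].le(0).all(axis=1)
    subset = sorted(senescence.index[green])
    if not subset:
        warnings.warn("no stay-green genotypes up to the cutoff date")
    return subset
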