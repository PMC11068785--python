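"""Validation computations: fit metrics, water-balance ET, and trend analysis.

Fit metrics follow the standard hydrological definitions (Pearson R, RMSE,
Nash-Sutcliffe efficiency, OLS slope/intercept of simulation on observation).
Basin evapotranspiration can be inferred independently from the water balance
as precipitation minus runoff minus storage change.  Annual trends pair an
ordinary-least-squares slope (Sen's slope optional) with a two-sided
Mann-Kendall significance test with tie correction.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "FitMetrics",
    "fit_metrics",
    "water_balance_et",
    "mann_kendall",
    "linear_trend_mk",
    "ratio_to_reference",
]


@dataclass(frozen=True)
class FitMetrics:
    r: float
    rmse: float
    nse: float | None
    slope: float
    intercept: float
    n: int


def _pairwise_complete(sim, obs):
    sim = np.asarray(sim, dtype=float)
    obs = np.asarray(obs, dtype=float)
    if sim.shape != obs.shape:
        raise ValueError("sim and obs must have the same shape")
    ok = np.isfinite(sim) & np.isfinite(obs)
    return sim[ok], obs[ok]


def fit_metrics(sim, obs) -> FitMetrics:
    """Pearson R, RMSE, NSE and the OLS fit of sim on obs.

    Missing values are removed pairwise; the retained count is reported.
    NSE is undefined (None) for constant observations rather than forced to
    a number.
    """
    sim, obs = _pairwise_complete(sim, obs)
    n = sim.size
    if n < 3:
        raise ValueError("need at least 3 paired values")
    rmse = float(np.sqrt(np.mean((sim - obs) ** 2)))
    sq_dev = float(np.sum((obs - obs.mean()) ** 2))
    if sq_dev == 0.0:
        nse = None
        r = math.nan
        slope, intercept = math.nan, math.nan
    else:
        nse = 1.0 - float(np.sum((sim - obs) ** 2)) / sq_dev
        if np.ptp(sim) == 0.0:
            r = math.nan
            slope, intercept = 0.0, float(sim[0])
        else:
            r = float(stats.pearsonr(sim, obs).statistic)
            res = stats.linregress(obs, sim)
            slope, intercept = float(res.slope), float(res.intercept)
    return FitMetrics(r=r, rmse=rmse, nse=nse, slope=slope, intercept=intercept, n=n)


def water_balance_et(precip: float, runoff: float, d_storage: float) -> float:
    """Basin ET from the water balance: ET_wb = P - Q - dS (same units, same period)."""
    return precip - runoff - d_storage


def mann_kendall(series) -> tuple[int, float]:
    """Two-sided Mann-Kendall trend test.

    Returns (S, p).  S is the pairwise concordance statistic
    sum_{i<j} sign(x_j - x_i); the p-value uses the normal approximation with
    tie-corrected variance and a continuity correction, which is standard for
    n > 10 and conservative below.
    """
    x = np.asarray(series, dtype=float)
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 values")
    s = 0
    for i in range(n - 1):
        s += int(np.sum(np.sign(x[i + 1:] - x[i])))
    # tie-corrected variance
    _, counts = np.unique(x, return_counts=True)
    var_s = (n * (n - 1) * (2 * n + 5)
             - np.sum(counts * (counts - 1) * (2 * counts + 5))) / 18.0
    if var_s <= 0.0:
        return s, 1.0
    if s > 0:
        z = (s - 1) / math.sqrt(var_s)
    elif s < 0:
        z = (s + 1) / math.sqrt(var_s)
    else:
        z = 0.0
    p = 2.0 * stats.norm.sf(abs(z))
    return s, float(p)


def sens_slope(series) -> float:
    """Median of pairwise slopes, a robust alternative trend estimator."""
    x = np.asarray(series, dtype=float)
    n = x.size
    slopes = [(x[j] - x[i]) / (j - i) for i in range(n - 1) for j in range(i + 1, n)]
    return float(np.median(slopes))


def linear_trend_mk(annual_series, estimator: str = "ols") -> tuple[float, float]:
    """Annual trend (units yr-1) with Mann-Kendall significance.

    The slope is ordinary least squares by default (``estimator='sen'`` for
    Sen's slope); the p-value always comes from the Mann-Kendall test.
    """
    x = np.asarray(annual_series, dtype=float)
    if x.size < 8:
        raise ValueError("need at least 8 years for a trend")
    t = np.arange(x.size, dtype=float)
    if estimator == "ols":
        slope = float(stats.linregress(t, x).slope) if np.ptp(x) > 0 else 0.0
    elif estimator == "sen":
        slope = sens_slope(x)
    else:
        raise ValueError("estimator must be 'ols' or 'sen'")
    _, p = mann_kendall(x)
    return slope, p


def ratio_to_reference(sim_annual_mean: float, ref_annual_mean: float) -> float:
    """Simple quotient of simulated to reference annual means."""
    if ref_annual_mean <= 0.0:
        raise ValueError("reference must be positive")
    return sim_annual_mean / ref_annual_mean
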