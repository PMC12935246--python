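"""Theil-Sen slope estimation and Mann-Kendall trend testing.

The Sen slope is the median of all pairwise slopes (x_j − x_i)/(t_j − t_i),
i < j — robust to outliers. The Mann-Kendall statistic
S = sum_{i<j} sign(x_j − x_i) is tested against its tie-corrected variance
var(S) = [n(n−1)(2n+5) − sum_t t(t−1)(2t+5)] / 18 with a continuity
correction, giving a standard-normal deviate and a two-sided p-value. Both
are applied either to a single regional series or per-pixel over a cube.

Per-pixel application classifies each pixel at significance level alpha into
significant/non-significant increase/decrease.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .grids import GridCube, GridError

SIG_INCREASE, NONSIG_INCREASE = 3, 2
NONSIG_DECREASE, SIG_DECREASE = 1, 0
TREND_CLASS_NAMES = {3: "sig_increase", 2: "nonsig_increase",
                     1: "nonsig_decrease", 0: "sig_decrease"}


def sen_slope(series: np.ndarray, times: np.ndarray | None = None) -> float:
    """Median of all pairwise slopes; NaN if fewer than 3 valid points."""
    x = np.asarray(series, dtype=np.float64)
    t = np.arange(len(x), dtype=np.float64) if times is None else \
        np.asarray(times, dtype=np.float64)
    ok = np.isfinite(x) & np.isfinite(t)
    x, t = x[ok], t[ok]
    n = len(x)
    if n < 3:
        return np.nan
    i, j = np.triu_indices(n, k=1)
    return float(np.median((x[j] - x[i]) / (t[j] - t[i])))


def mann_kendall(series: np.ndarray) -> tuple[float, float, float, float]:
    """Mann-Kendall test: returns (S, var_S, z, p).

    Tie-corrected variance; continuity correction z = (S −/+ 1)/sqrt(var_S)
    with z = 0 when S = 0. An all-tied series gives z = 0, p = 1.
    """
    x = np.asarray(series, dtype=np.float64)
    x = x[np.isfinite(x)]
    n = len(x)
    if n < 2:
        return np.nan, np.nan, np.nan, np.nan
    i, j = np.triu_indices(n, k=1)
    s = float(np.sum(np.sign(x[j] - x[i])))
    _, counts = np.unique(x, return_counts=True)
    ties = counts[counts > 1]
    var_s = (n * (n - 1) * (2 * n + 5)
             - np.sum(ties * (ties - 1) * (2 * ties + 5))) / 18.0
    if var_s <= 0:
        return s, 0.0, 0.0, 1.0
    if s > 0:
        z = (s - 1.0) / np.sqrt(var_s)
    elif s < 0:
        z = (s + 1.0) / np.sqrt(var_s)
    else:
        z = 0.0
    p = 2.0 * stats.norm.sf(abs(z))
    return s, float(var_s), float(z), float(p)


@dataclass
class TrendField:
    """Per-pixel trend results for an annualised cube."""

    slope: np.ndarray     # units of the variable per year
    z: np.ndarray
    p: np.ndarray
    sig_class: np.ndarray  # codes in TREND_CLASS_NAMES, -1 invalid
    alpha: float

    def class_fractions(self) -> dict[str, float]:
        valid = self.sig_class >= 0
        total = valid.sum()
        return {name: (float(np.sum(self.sig_class == code) / total)
                       if total else np.nan)
                for code, name in TREND_CLASS_NAMES.items()}


def _pairwise_stats(data: np.ndarray, times: np.ndarray):
    """Vectorised Sen slope + M-K S over a (n_time, n_pixel) block."""
    n = data.shape[0]
    i, j = np.triu_indices(n, k=1)
    diff = data[j] - data[i]
    slopes = diff / (times[j] - times[i])[:, None]
    slope = np.median(slopes, axis=0)
    s = np.sum(np.sign(diff), axis=0)
    return slope, s


def trend_map(cube_values: np.ndarray, times: np.ndarray,
              alpha: float = 0.05) -> TrendField:
    """Per-pixel Theil-Sen slope and Mann-Kendall significance.

    ``cube_values`` is (n_time, rows, cols) (NaN = invalid; a pixel with any
    NaN or fewer than 3 steps is masked); ``times`` are e.g. years.
    """
    vals = np.asarray(cube_values, dtype=np.float64)
    if vals.ndim == 2:
        vals = vals[:, :, None]
    n, rows, cols = vals.shape
    times = np.asarray(times, dtype=np.float64)
    if times.shape != (n,):
        raise GridError("times must match the cube's first dimension")
    flat = vals.reshape(n, -1)
    ok = np.all(np.isfinite(flat), axis=0) & (n >= 3)

    slope = np.full(flat.shape[1], np.nan)
    z = np.full(flat.shape[1], np.nan)
    p = np.full(flat.shape[1], np.nan)
    if ok.any():
        sl, s = _pairwise_stats(flat[:, ok], times)
        slope[ok] = sl
        # tie-corrected variance per pixel
        var_s = np.empty(sl.shape)
        sub = flat[:, ok]
        base = n * (n - 1) * (2 * n + 5)
        for k in range(sub.shape[1]):
            _, counts = np.unique(sub[:, k], return_counts=True)
            ties = counts[counts > 1]
            var_s[k] = (base - np.sum(ties * (ties - 1) * (2 * ties + 5))) / 18.0
        zz = np.zeros_like(sl)
        pos, neg = (s > 0) & (var_s > 0), (s < 0) & (var_s > 0)
        zz[pos] = (s[pos] - 1.0) / np.sqrt(var_s[pos])
        zz[neg] = (s[neg] + 1.0) / np.sqrt(var_s[neg])
        z[ok] = zz
        pp = 2.0 * stats.norm.sf(np.abs(zz))
        pp[var_s <= 0] = 1.0
        p[ok] = pp

    sig = np.full(flat.shape[1], -1, dtype=np.int16)
    valid = np.isfinite(slope)
    inc = valid & (slope >= 0)
    dec = valid & (slope < 0)
    sig[inc & (p < alpha)] = SIG_INCREASE
    sig[inc & ~(p < alpha)] = NONSIG_INCREASE
    sig[dec & ~(p < alpha)] = NONSIG_DECREASE
    sig[dec & (p < alpha)] = SIG_DECREASE
    shape = (rows, cols)
    return TrendField(slope=slope.reshape(shape), z=z.reshape(shape),
                      p=p.reshape(shape), sig_class=sig.reshape(shape),
                      alpha=alpha)


def annual_trend_map(cube: GridCube, how: str = "sum",
                     alpha: float = 0.05) -> TrendField:
    """Trend field of per-pixel calendar-year aggregates of a monthly cube."""
    years, annual = cube.annual_aggregate(how=how)
    return trend_map(annual, np.asarray(years, dtype=float), alpha=alpha)


def regional_series_trend(series: np.ndarray,
                          times: np.ndarray | None = None) -> dict[str, float]:
    """Sen slope + M-K summary for one regional-mean series."""
    s, var_s, z, p = mann_kendall(series)
    return {"slope": sen_slope(series, times), "S": s, "var_S": var_s,
            "z": z, "p": p}
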