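"""CASA light-use-efficiency net primary productivity model.

Monthly NPP(x,t) = APAR(x,t) x eps(x,t), where APAR = 0.5 * SOL * FPAR
(half of total solar radiation is photosynthetically active) and the actual
light-use efficiency eps = T1 * T2 * W * eps_max is the class maximum
efficiency downscaled by two temperature stress scalars and a moisture
stress scalar:

* FPAR is estimated from NDVI twice — a linear ramp between the class NDVI
  bounds and a simple-ratio (SR = (1+NDVI)/(1−NDVI)) ramp — and the two
  estimates are mixed with weight ``fpar_mix_alpha``.
* T1 = 0.8 + 0.02*Topt − 0.0005*Topt^2 penalises pixels whose optimal
  growth temperature is extreme; Topt is the mean temperature of the
  calendar month with maximal multi-year mean NDVI (earliest month on ties).
* T2 is a double-logistic penalty for months departing from Topt.
* W rises from 0.5 (fully water-stressed) to 1. The default mode derives an
  estimated evapotranspiration from precipitation and a net-radiation proxy
  (regional evapotranspiration coupling); a soil-moisture mode normalises SM
  by its per-pixel 95th percentile instead.

Default eps_max (gC/MJ): farmland 0.542, grassland 0.542, woodland 0.692 —
configurable, as these are calibration constants, not universal values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .grids import (GridCube, GridError, LandCoverMap,
                    FARMLAND, WOODLAND, GRASSLAND, VEGETATED_CLASSES)

DEFAULT_EPS_MAX = {FARMLAND: 0.542, WOODLAND: 0.692, GRASSLAND: 0.542}

#: net-radiation proxy Rn ~ a*PET + b*P (regional evapotranspiration lineage)
RN_PROXY_A = 0.369
RN_PROXY_B = 0.598


@dataclass
class CasaParams:
    """Tunable CASA parameterisation."""

    eps_max: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_EPS_MAX))
    ndvi_bounds: dict[int, tuple[float, float]] | None = None
    fpar_bounds: tuple[float, float] = (0.001, 0.95)
    fpar_mix_alpha: float = 0.5
    water_stress_mode: str = "et_ratio"  # or "soil_moisture"

    def __post_init__(self) -> None:
        for code, v in self.eps_max.items():
            if not v > 0:
                raise GridError(f"eps_max for class {code} must be positive")
        lo, hi = self.fpar_bounds
        if not (0 <= lo < hi <= 1):
            raise GridError("fpar_bounds must satisfy 0 <= min < max <= 1")
        if not (0 <= self.fpar_mix_alpha <= 1):
            raise GridError("fpar_mix_alpha must be in [0, 1]")
        if self.ndvi_bounds is not None:
            for code, (nlo, nhi) in self.ndvi_bounds.items():
                if not nlo < nhi:
                    raise GridError(f"NDVI bounds for class {code} inverted")
        if self.water_stress_mode not in ("et_ratio", "soil_moisture"):
            raise GridError(f"unknown water stress mode {self.water_stress_mode!r}")


def percentile_ndvi_bounds(ndvi: GridCube, landcover: LandCoverMap,
                           lo_pct: float = 5.0,
                           hi_pct: float = 95.0) -> dict[int, tuple[float, float]]:
    """Per-class (NDVI_min, NDVI_max) as record percentiles, robust to outliers."""
    ndvi.meta.check_match(landcover.meta, "ndvi vs landcover")
    vals = ndvi.masked()
    bounds = {}
    for code in VEGETATED_CLASSES:
        mask = landcover.class_mask(code)
        if not mask.any():
            continue
        sample = vals[:, mask]
        sample = sample[np.isfinite(sample)]
        if sample.size == 0:
            continue
        nlo, nhi = np.percentile(sample, [lo_pct, hi_pct])
        if nhi <= nlo:  # degenerate class record; fall back to full range
            nlo, nhi = float(sample.min()), float(sample.min()) + 1e-3
        bounds[code] = (float(nlo), float(nhi))
    return bounds


def _ramp(x, x_lo, x_hi, y_lo, y_hi):
    with np.errstate(invalid="ignore", divide="ignore"):
        y = (x - x_lo) / (x_hi - x_lo) * (y_hi - y_lo) + y_lo
    return np.clip(y, y_lo, y_hi)


def fpar(ndvi: GridCube, landcover: LandCoverMap,
         params: CasaParams) -> GridCube:
    """Fraction of absorbed PAR from NDVI (mixed ramp / simple-ratio estimate)."""
    ndvi.meta.check_match(landcover.meta, "ndvi vs landcover")
    if params.ndvi_bounds is None:
        bounds = percentile_ndvi_bounds(ndvi, landcover)
    else:
        bounds = params.ndvi_bounds
    f_lo, f_hi = params.fpar_bounds
    alpha = params.fpar_mix_alpha
    vals = np.clip(ndvi.masked(), -1.0, 0.99)  # SR undefined at NDVI=1
    out = np.zeros_like(vals)
    veg_any = np.zeros(ndvi.meta.shape, dtype=bool)
    for code in VEGETATED_CLASSES:
        mask = landcover.class_mask(code)
        if not mask.any() or code not in bounds:
            continue
        n_lo, n_hi = bounds[code]
        n_hi = min(n_hi, 0.99)
        sr = (1.0 + vals) / (1.0 - vals)
        sr_lo = (1.0 + n_lo) / (1.0 - n_lo)
        sr_hi = (1.0 + n_hi) / (1.0 - n_hi)
        f_ndvi = _ramp(vals, n_lo, n_hi, f_lo, f_hi)
        f_sr = _ramp(sr, sr_lo, sr_hi, f_lo, f_hi)
        mixed = alpha * f_ndvi + (1.0 - alpha) * f_sr
        out[:, mask] = mixed[:, mask]
        veg_any |= mask
    valid = ndvi.valid_mask & veg_any[None, :, :]
    out = np.where(np.isfinite(out), out, 0.0)
    return ndvi.copy_with(values=out, units="1", valid_mask=valid)


def optimal_temperature(ndvi: GridCube, temp: GridCube) -> np.ndarray:
    """Per-pixel optimal temperature Topt.

    Topt is the multi-year mean temperature of the calendar month whose
    multi-year mean NDVI is maximal at that pixel; the earliest month wins
    ties. Pixels with no valid NDVI anywhere are NaN.
    """
    ndvi.align_check(temp)
    nvals, tvals = ndvi.masked(), temp.masked()
    shape = ndvi.meta.shape
    ndvi_clim = np.full((12, *shape), -np.inf)
    temp_clim = np.full((12, *shape), np.nan)
    for m in range(1, 13):
        idx = ndvi.calendar_month_indices(m)
        if idx.size:
            with np.errstate(invalid="ignore"):
                nc = np.nanmean(nvals[idx], axis=0)
            ndvi_clim[m - 1] = np.where(np.isfinite(nc), nc, -np.inf)
            temp_clim[m - 1] = np.nanmean(tvals[idx], axis=0)
    best = np.argmax(ndvi_clim, axis=0)  # argmax returns first max: earliest month
    topt = np.take_along_axis(temp_clim, best[None], axis=0)[0]
    all_invalid = np.all(~np.isfinite(ndvi_clim) | (ndvi_clim == -np.inf), axis=0)
    topt[all_invalid] = np.nan
    return topt


def temperature_stress(temp: GridCube,
                       topt: np.ndarray) -> tuple[GridCube, GridCube]:
    """Temperature stress scalars T1 (climatological) and T2 (monthly).

    T1 = 0.8 + 0.02*Topt − 0.0005*Topt^2, broadcast over time.
    T2 = 1.1814 / (1+exp(0.2*(Topt−10−T))) / (1+exp(0.3*(−Topt−10+T))).
    Both clamped at 0 below.
    """
    topt = np.asarray(topt, dtype=np.float64)
    if topt.shape != temp.meta.shape:
        raise GridError("topt shape must match the grid")
    t = temp.masked()
    t1_2d = 0.8 + 0.02 * topt - 0.0005 * topt**2
    t1 = np.broadcast_to(t1_2d[None], t.shape).copy()
    with np.errstate(over="ignore", invalid="ignore"):
        t2 = 1.1814 / (1.0 + np.exp(0.2 * (topt[None] - 10.0 - t))) \
            / (1.0 + np.exp(0.3 * (-topt[None] - 10.0 + t)))
    valid = temp.valid_mask & np.isfinite(topt)[None]
    t1 = np.where(valid, np.maximum(t1, 0.0), 0.0)
    t2 = np.where(valid & np.isfinite(t2), np.maximum(t2, 0.0), 0.0)
    return (temp.copy_with(values=t1, units="1", valid_mask=valid),
            temp.copy_with(values=t2, units="1", valid_mask=valid.copy()))


def estimated_evapotranspiration(precip: np.ndarray,
                                 rn: np.ndarray) -> np.ndarray:
    """Regional evapotranspiration coupling of precipitation and net radiation.

    EET = P*Rn*(P^2 + Rn^2 + P*Rn) / ((P + Rn)*(P^2 + Rn^2)); zero when
    either input is zero.
    """
    p = np.maximum(np.asarray(precip, dtype=np.float64), 0.0)
    r = np.maximum(np.asarray(rn, dtype=np.float64), 0.0)
    num = p * r * (p**2 + r**2 + p * r)
    den = (p + r) * (p**2 + r**2)
    with np.errstate(invalid="ignore", divide="ignore"):
        eet = num / den
    return np.where(den > 0, eet, 0.0)


def water_stress(precip: GridCube, pet: GridCube,
                 sm: GridCube | None = None,
                 mode: str = "et_ratio") -> GridCube:
    """Moisture stress scalar W in [0.5, 1].

    ``et_ratio`` (default): W = 0.5 + 0.5*EET/PET with EET from the
    precipitation / net-radiation coupling and Rn approximated as
    a*PET + b*P (a=0.369, b=0.598). Months with PET = 0 floor at W = 0.5.
    ``soil_moisture``: W = 0.5 + 0.5*SM/SM_p95 (per-pixel 95th percentile),
    clipped.
    """
    if mode == "et_ratio":
        precip.align_check(pet)
        p, e = precip.masked(), pet.masked()
        rn = RN_PROXY_A * e + RN_PROXY_B * p
        eet = estimated_evapotranspiration(p, rn)
        with np.errstate(invalid="ignore", divide="ignore"):
            ratio = np.where(e > 0, eet / e, 0.0)
        w = 0.5 + 0.5 * np.clip(ratio, 0.0, 1.0)
        valid = precip.valid_mask & pet.valid_mask
    elif mode == "soil_moisture":
        if sm is None:
            raise GridError("soil_moisture mode requires an SM cube")
        s = sm.masked()
        p95 = np.nanpercentile(s, 95, axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            ratio = s / p95[None]
        w = 0.5 + 0.5 * np.clip(ratio, 0.0, 1.0)
        valid = sm.valid_mask & (p95 > 0)[None]
        precip = sm
    else:
        raise GridError(f"unknown water stress mode {mode!r}")
    w = np.where(np.isfinite(w), w, 0.5)
    return precip.copy_with(values=w, units="1", valid_mask=valid)


def apar(sol: GridCube, fpar_cube: GridCube) -> GridCube:
    """Absorbed PAR = 0.5 * SOL * FPAR (MJ m-2 month-1)."""
    sol.align_check(fpar_cube)
    if np.any(sol.values[sol.valid_mask] < 0):
        raise GridError("solar radiation must be non-negative")
    vals = 0.5 * sol.values * fpar_cube.values
    valid = sol.valid_mask & fpar_cube.valid_mask
    return sol.copy_with(values=np.where(valid, vals, 0.0),
                         units="MJ/m2/month", valid_mask=valid)


def npp_monthly(apar_cube: GridCube, t1: GridCube, t2: GridCube, w: GridCube,
                landcover: LandCoverMap, params: CasaParams) -> GridCube:
    """Monthly NPP = APAR * T1 * T2 * W * eps_max(class); gC m-2 month-1.

    Non-vegetated classes are masked. A vegetated class present on the grid
    without an eps_max entry is a hard error.
    """
    apar_cube.align_check(t1, t2, w)
    apar_cube.meta.check_match(landcover.meta, "apar vs landcover")
    eps = np.full(landcover.meta.shape, np.nan)
    for code in VEGETATED_CLASSES:
        mask = landcover.class_mask(code)
        if not mask.any():
            continue
        if code not in params.eps_max:
            raise GridError(f"eps_max missing for vegetated class {code}")
        eps[mask] = params.eps_max[code]
    vals = apar_cube.values * t1.values * t2.values * w.values * eps[None]
    valid = (apar_cube.valid_mask & t1.valid_mask & t2.valid_mask
             & w.valid_mask & np.isfinite(eps)[None])
    vals = np.where(valid, np.maximum(vals, 0.0), 0.0)
    return apar_cube.copy_with(values=vals, units="gC/m2/month",
                               valid_mask=valid)


def npp_annual(npp: GridCube, year: int) -> np.ndarray:
    """Per-pixel annual NPP sum (gC m-2 a-1); NaN if any month is masked."""
    idx = [i for i, (y, _) in enumerate(npp.times) if y == year]
    if len(idx) != 12:
        raise GridError(f"year {year} incomplete: {len(idx)} months present")
    vals = npp.masked()[idx]
    return vals.sum(axis=0)  # any NaN month propagates


def run_casa(ndvi: GridCube, temp: GridCube, sol: GridCube, precip: GridCube,
             pet: GridCube, landcover: LandCoverMap, params: CasaParams,
             sm: GridCube | None = None) -> GridCube:
    """Full monthly CASA chain from raw inputs to the NPP cube."""
    f = fpar(ndvi, landcover, params)
    topt = optimal_temperature(ndvi, temp)
    t1, t2 = temperature_stress(temp, topt)
    w = water_stress(precip, pet, sm=sm, mode=params.water_stress_mode)
    a = apar(sol, f)
    return npp_monthly(a, t1, t2, w, landcover, params)


def benchmark_regression(npp: GridCube, reference: GridCube,
                         landcover: LandCoverMap) -> dict[str, float]:
    """Agreement of class-mean annual NPP with a reference NPP cube.

    Regresses the class-by-year mean annual sums of the modelled cube against
    the reference and reports slope, intercept, R^2 and p. On self-consistent
    data (reference equal to the model) R^2 = 1.
    """
    npp.align_check(reference)
    npp.meta.check_match(landcover.meta)
    xs, ys = [], []
    years = [y for y in npp.years()
             if sum(1 for yy, _ in npp.times if yy == y) == 12]
    for code in VEGETATED_CLASSES:
        mask = landcover.class_mask(code)
        if not mask.any():
            continue
        for y in years:
            a = npp_annual(npp, y)[mask]
            b = npp_annual(reference, y)[mask]
            ok = np.isfinite(a) & np.isfinite(b)
            if ok.sum() == 0:
                continue
            xs.append(np.mean(b[ok]))
            ys.append(np.mean(a[ok]))
    if len(xs) < 3:
        raise GridError("not enough class-year points for the benchmark")
    res = stats.linregress(xs, ys)
    return {"slope": float(res.slope), "intercept": float(res.intercept),
            "r2": float(res.rvalue**2), "p": float(res.pvalue),
            "n": len(xs)}
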