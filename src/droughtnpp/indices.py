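"""Multi-scale drought indices: SPEI, SSMI, severity grades, frequency, aridity.

SPEI at accumulation scale *k* standardises the k-month running sum of the
climatic water balance D = P − PET. Within each calendar-month stratum the
accumulated series is fitted with a three-parameter log-logistic distribution
via L-moments (unbiased probability-weighted moments) and the fitted
cumulative probability is mapped to a standard normal deviate through the
classical rational approximation of the inverse normal. PET comes from the
Thornthwaite temperature/latitude method.

SSMI at scale *k* is the per-calendar-month z-score of the k-month running
mean of soil moisture: (SM − stratum mean) / stratum SD, with population SD
so the standardisation is exact over the record.

Severity grades follow the SPEI and SSMI classification tables used in
Chinese drought monitoring practice: under SPEI, "no drought" extends down to
−0.5; under SSMI any negative value already counts as mild drought.
"""

from __future__ import annotations

import calendar
import logging
from dataclasses import dataclass

import numpy as np
from scipy.special import gamma as gamma_fn

from .grids import GridCube, GridError

logger = logging.getLogger(__name__)

SEVERITY_NONE, SEVERITY_MILD, SEVERITY_MODERATE = 0, 1, 2
SEVERITY_SEVERE, SEVERITY_EXTREME = 3, 4
SEVERITY_NAMES = {0: "none", 1: "mild", 2: "moderate", 3: "severe", 4: "extreme"}

# inverse-normal rational approximation coefficients
_C0, _C1, _C2 = 2.515517, 0.802853, 0.010328
_D1, _D2, _D3 = 1.432788, 0.189269, 0.001308

_PROB_FLOOR = 1e-6


@dataclass
class DroughtIndexCube:
    """Standard-normal-scale drought index with its accumulation scale."""

    cube: GridCube
    scale_k: int
    index_kind: str  # "spei" | "ssmi"

    def __post_init__(self) -> None:
        if self.scale_k < 1:
            raise GridError("scale_k must be >= 1")
        if self.index_kind not in ("spei", "ssmi"):
            raise GridError(f"unknown index kind {self.index_kind!r}")


@dataclass
class SeverityCube:
    """Categorical drought-severity cube, codes 0 none .. 4 extreme."""

    cube: GridCube  # integer codes stored as float with mask
    scheme: str

    def counts(self) -> dict[int, int]:
        vals = self.cube.values[self.cube.valid_mask].astype(int)
        return {s: int(np.sum(vals == s)) for s in SEVERITY_NAMES}


# ---------------------------------------------------------------------------
# Thornthwaite PET


def _day_length_hours(latitude_deg: np.ndarray, month: int) -> np.ndarray:
    """Mean day length (hours) at mid-month for the given latitudes."""
    mid = sum(calendar.mdays[1:month]) + calendar.mdays[month] / 2.0
    decl = 0.4093 * np.sin(2.0 * np.pi * mid / 365.0 - 1.405)
    lat = np.radians(latitude_deg)
    cos_omega = np.clip(-np.tan(lat) * np.tan(decl), -1.0, 1.0)
    omega = np.arccos(cos_omega)
    return 24.0 * omega / np.pi


def pet_thornthwaite(temp: GridCube,
                     latitude_per_row: np.ndarray | None = None) -> GridCube:
    """Monthly Thornthwaite potential evapotranspiration (mm/month).

    The annual heat index I is built from the multi-year mean temperature of
    each calendar month (months with a positive mean only); PET is zero for
    months at or below 0 °C. Latitude enters through the day-length
    correction and defaults to the grid's row-center y coordinates
    (interpreted as degrees).
    """
    if latitude_per_row is None:
        latitude_per_row = temp.meta.row_center_latitudes()
    latitude_per_row = np.asarray(latitude_per_row, dtype=np.float64)
    if latitude_per_row.shape != (temp.meta.n_rows,):
        raise GridError("latitude_per_row must have one entry per grid row")
    if np.any(np.abs(latitude_per_row) > 66.5):
        raise GridError("Thornthwaite day-length formula requires |lat| <= 66.5")

    tvals = temp.masked()
    # per-pixel climatology of each calendar month
    clim = np.full((12, *temp.meta.shape), np.nan)
    for m in range(1, 13):
        idx = temp.calendar_month_indices(m)
        if idx.size:
            clim[m - 1] = np.nanmean(tvals[idx], axis=0)
    heat = np.nansum(np.where(clim > 0, clim, 0.0) ** 1.514 / 5.0**1.514, axis=0)
    a = (6.75e-7 * heat**3 - 7.71e-5 * heat**2 + 1.792e-2 * heat + 0.49239)

    pet = np.zeros_like(tvals)
    with np.errstate(invalid="ignore", divide="ignore"):
        for i, (_, month) in enumerate(temp.times):
            L = _day_length_hours(latitude_per_row, month)[:, None]
            N = calendar.mdays[month]
            t = tvals[i]
            warm = (t > 0) & (heat > 0)
            raw = np.zeros_like(t)
            raw[warm] = 16.0 * (10.0 * t[warm] / heat[warm]) ** a[warm]
            pet[i] = raw * (L / 12.0) * (N / 30.0)
    pet = np.where(np.isfinite(pet), pet, 0.0)
    mask = temp.valid_mask.copy()
    pet[~mask] = 0.0
    return temp.copy_with(values=np.maximum(pet, 0.0), units="mm/month",
                          valid_mask=mask)


# ---------------------------------------------------------------------------
# accumulation helpers


def _rolling_accumulate(cube: GridCube, k: int, how: str) -> tuple[np.ndarray, np.ndarray]:
    """k-step running sum/mean along time; first k−1 steps invalid.

    A window is valid only if every member month is valid.
    """
    vals = cube.masked()
    n = cube.n_times
    if k > n:
        raise GridError(f"accumulation scale {k} exceeds record length {n}")
    acc = np.full_like(vals, np.nan)
    for i in range(k - 1, n):
        win = vals[i - k + 1 : i + 1]
        acc[i] = win.sum(axis=0) if how == "sum" else win.mean(axis=0)
    valid = np.isfinite(acc)
    return acc, valid


# ---------------------------------------------------------------------------
# SPEI


def _unbiased_pwm(sorted_x: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Unbiased probability-weighted moments w0, w1, w2 (decreasing weights).

    ``sorted_x`` has shape (n, ...) sorted ascending along axis 0. These are
    the PWMs E[X(1-F)^s] the log-logistic L-moment fit is written in terms
    of: w_s = (1/n) sum_i x_(i) * C(n-i, s)/C(n-1, s).
    """
    n = sorted_x.shape[0]
    i = np.arange(1, n + 1, dtype=np.float64).reshape((n,) + (1,) * (sorted_x.ndim - 1))
    w0 = sorted_x.mean(axis=0)
    w1 = np.sum(sorted_x * (n - i), axis=0) / (n * (n - 1))
    w2 = np.sum(sorted_x * (n - i) * (n - i - 1), axis=0) / (n * (n - 1) * (n - 2))
    return w0, w1, w2


def _loglogistic_params(w0, w1, w2):
    """Three-parameter log-logistic fit from decreasing-weight PWMs.

    Parameterised as the generalized-logistic family (Hosking), which is the
    log-logistic with shape kappa = -1/beta and extends smoothly to
    negatively L-skewed samples. Returns (xi location, alpha scale, kappa
    shape); fits with |L-skewness| >= 0.95 or degenerate L-scale are NaN.
    """
    lam1 = w0
    lam2 = w0 - 2.0 * w1
    lam3 = w0 - 6.0 * w1 + 6.0 * w2
    with np.errstate(invalid="ignore", divide="ignore"):
        tau3 = lam3 / lam2
        kappa = -tau3
        # kappa*pi/sin(kappa*pi) == Gamma(1+kappa)*Gamma(1-kappa)
        g = gamma_fn(1.0 + kappa) * gamma_fn(1.0 - kappa)
        alpha = np.where(np.abs(kappa) < 1e-8, lam2, lam2 / g)
        xi = np.where(np.abs(kappa) < 1e-8, lam1,
                      lam1 - alpha * (1.0 - g) / kappa)
    ok = (np.isfinite(alpha) & np.isfinite(xi) & np.isfinite(kappa)
          & (lam2 > 0) & (np.abs(kappa) < 0.95))
    return (np.where(ok, xi, np.nan), np.where(ok, alpha, np.nan),
            np.where(ok, kappa, np.nan))


def _glo_cdf(x, xi, alpha, kappa):
    """Generalized-logistic CDF, clipped to the open unit interval.

    Out-of-support values saturate at the probability floor/ceiling (the
    fitted distribution assigns them probability 0 or 1).
    """
    with np.errstate(invalid="ignore", divide="ignore", over="ignore"):
        t = (x - xi) / alpha
        small = np.abs(kappa) < 1e-8
        arg = 1.0 - kappa * t
        y = np.where(small, t,
                     -np.log(np.maximum(arg, 1e-300)) / np.where(small, 1.0,
                                                                 kappa))
        cdf = 1.0 / (1.0 + np.exp(-y))
    # saturate beyond the support edge xi + alpha/kappa
    upper_out = (kappa > 1e-8) & (arg <= 0)
    lower_out = (kappa < -1e-8) & (arg <= 0)
    cdf = np.where(upper_out, 1.0 - _PROB_FLOOR, cdf)
    cdf = np.where(lower_out, _PROB_FLOOR, cdf)
    return np.clip(cdf, _PROB_FLOOR, 1.0 - _PROB_FLOOR)


def inverse_normal_rational(p: np.ndarray) -> np.ndarray:
    """Standard-normal deviate for cumulative probability p.

    Classical rational approximation (|error| < 4.5e-4), applied symmetrically
    around the median.
    """
    p = np.clip(np.asarray(p, dtype=np.float64), _PROB_FLOOR, 1.0 - _PROB_FLOOR)
    lower = p <= 0.5
    pp = np.where(lower, p, 1.0 - p)
    w = np.sqrt(-2.0 * np.log(pp))
    z = w - (_C0 + _C1 * w + _C2 * w**2) / (1.0 + _D1 * w + _D2 * w**2 + _D3 * w**3)
    return np.where(lower, -z, z)


def spei(precip: GridCube, pet: GridCube, scale_k: int) -> DroughtIndexCube:
    """SPEI at accumulation scale k from monthly P and PET cubes.

    Fit reference period is the full record. Per pixel and calendar-month
    stratum the k-month accumulated water balance is fitted with a
    log-logistic distribution (L-moments); pixels whose stratum series is
    degenerate or not fully valid are masked (counted in the log).
    """
    precip.align_check(pet)
    d = precip.masked() - pet.masked()
    dcube = precip.copy_with(values=np.where(np.isfinite(d), d, 0.0),
                             units="mm", valid_mask=np.isfinite(d))
    acc, acc_valid = _rolling_accumulate(dcube, scale_k, "sum")

    out = np.full_like(acc, np.nan)
    n_masked = 0
    for month in range(1, 13):
        idx = precip.calendar_month_indices(month)
        idx = idx[idx >= scale_k - 1]
        if idx.size < 4:
            continue
        stratum = acc[idx]  # (n_years, rows, cols)
        full = np.all(np.isfinite(stratum), axis=0)
        spread = np.nanstd(stratum, axis=0) > 0
        fit_ok = full & spread
        n_masked += int(np.sum(full & ~spread))
        x = np.sort(np.where(fit_ok, stratum, 0.0), axis=0)
        w0, w1, w2 = _unbiased_pwm(x)
        xi, alpha, kappa = _loglogistic_params(w0, w1, w2)
        fit_ok = fit_ok & np.isfinite(alpha)
        cdf = _glo_cdf(stratum, xi, alpha, kappa)
        z = inverse_normal_rational(cdf)
        z[:, ~fit_ok] = np.nan
        out[idx] = z
    if n_masked:
        logger.warning("spei: %d pixel-strata masked (degenerate series)", n_masked)
    valid = np.isfinite(out)
    cube = precip.copy_with(values=np.where(valid, out, 0.0), units="1",
                            valid_mask=valid)
    return DroughtIndexCube(cube=cube, scale_k=scale_k, index_kind="spei")


# ---------------------------------------------------------------------------
# SSMI


def ssmi(sm: GridCube, scale_k: int = 1,
         stratify: str = "calendar_month") -> DroughtIndexCube:
    """Standardised soil-moisture index: z-score of the k-month running mean.

    ``stratify`` selects the standardisation population: "calendar_month"
    (default — each calendar month against its own multi-year statistics) or
    "whole_series". Population SD is used, so stratum mean/SD of the output
    are exactly 0/1 over the record.
    """
    if len(sm.years()) < 2:
        raise GridError("ssmi requires at least 2 years of data")
    acc, _ = _rolling_accumulate(sm, scale_k, "mean")
    out = np.full_like(acc, np.nan)
    n_masked = 0

    def _zscore(block: np.ndarray) -> np.ndarray:
        mu = np.nanmean(block, axis=0)
        sd = np.nanstd(block, axis=0)  # population SD
        with np.errstate(invalid="ignore", divide="ignore"):
            z = (block - mu) / sd
        # relative tolerance: a stratum whose spread is rounding noise is
        # degenerate, not standardisable
        degenerate = ~(sd > 1e-10 * np.maximum(1.0, np.abs(mu)))
        z[:, degenerate] = np.nan
        return z

    if stratify == "calendar_month":
        for month in range(1, 13):
            idx = sm.calendar_month_indices(month)
            idx = idx[idx >= scale_k - 1]
            if idx.size < 2:
                continue
            z = _zscore(acc[idx])
            n_masked += int(np.sum(np.isfinite(acc[idx]) & ~np.isfinite(z)))
            out[idx] = z
    elif stratify == "whole_series":
        out = _zscore(acc)
    else:
        raise ValueError(f"unknown stratification {stratify!r}")
    if n_masked:
        logger.warning("ssmi: %d values masked (zero stratum SD)", n_masked)
    valid = np.isfinite(out)
    cube = sm.copy_with(values=np.where(valid, out, 0.0), units="1",
                        valid_mask=valid)
    return DroughtIndexCube(cube=cube, scale_k=scale_k, index_kind="ssmi")


# ---------------------------------------------------------------------------
# severity classification

#: (severity code, lower-exclusive, upper-inclusive) — boundaries closed on
#: the dry side, exactly as the grading tables print them.
SPEI_SCHEME = [
    (SEVERITY_EXTREME, -np.inf, -2.0),
    (SEVERITY_SEVERE, -2.0, -1.5),
    (SEVERITY_MODERATE, -1.5, -1.0),
    (SEVERITY_MILD, -1.0, -0.5),
    (SEVERITY_NONE, -0.5, np.inf),
]
SSMI_SCHEME = [
    (SEVERITY_EXTREME, -np.inf, -2.0),
    (SEVERITY_SEVERE, -2.0, -1.5),
    (SEVERITY_MODERATE, -1.5, -1.0),
    (SEVERITY_MILD, -1.0, 0.0),
    (SEVERITY_NONE, 0.0, np.inf),
]
SCHEMES = {"spei_table1": SPEI_SCHEME, "ssmi_table2": SSMI_SCHEME}
_DEFAULT_SCHEME_FOR_KIND = {"spei": "spei_table1", "ssmi": "ssmi_table2"}


def classify_severity_values(values: np.ndarray, scheme: str) -> np.ndarray:
    """Map index values to severity codes 0..4 under the named scheme."""
    rules = SCHEMES[scheme]
    out = np.full(np.shape(values), -1, dtype=np.int16)
    v = np.asarray(values, dtype=np.float64)
    for code, lo, hi in rules:
        sel = (v > lo) & (v <= hi) if np.isfinite(hi) else (v > lo)
        out[sel] = code
    return out


def classify(index: DroughtIndexCube, scheme: str | None = None) -> SeverityCube:
    """Severity grades for an index cube; the scheme must match its kind."""
    if scheme is None:
        scheme = _DEFAULT_SCHEME_FOR_KIND[index.index_kind]
    expected = _DEFAULT_SCHEME_FOR_KIND[index.index_kind]
    if scheme != expected:
        raise GridError(
            f"scheme {scheme!r} does not match index kind {index.index_kind!r}")
    codes = classify_severity_values(index.cube.values, scheme).astype(np.float64)
    cube = index.cube.copy_with(values=codes, units="severity")
    return SeverityCube(cube=cube, scheme=scheme)


# ---------------------------------------------------------------------------
# drought frequency


def drought_frequency(index: DroughtIndexCube, threshold: float = -1.0,
                      month_subset: list[int] | None = None) -> np.ndarray:
    """Drought frequency (percent of months at or below the threshold).

    ``month_subset`` restricts counting to given calendar months (e.g. [3,4,5]
    for spring). Returns a 2-D percent map; pixels with no valid months are
    NaN.
    """
    cube = index.cube
    if month_subset is not None and len(month_subset) == 0:
        raise GridError("month_subset is empty")
    steps = [i for i, (_, m) in enumerate(cube.times)
             if month_subset is None or m in month_subset]
    if not steps:
        raise GridError("no time steps selected")
    vals = cube.masked()[steps]
    hits = np.nansum(vals <= threshold, axis=0).astype(np.float64)
    total = np.sum(np.isfinite(vals), axis=0).astype(np.float64)
    with np.errstate(invalid="ignore", divide="ignore"):
        dfi = 100.0 * hits / total
    dfi[total == 0] = np.nan
    return dfi


def drought_area_series(severity: SeverityCube) -> "np.ndarray":
    """Per-month fraction of valid pixels at each severity (cols: none..extreme).

    Fractions (including the none class) sum to 1 every month.
    """
    vals = severity.cube.values
    mask = severity.cube.valid_mask
    n_t = severity.cube.n_times
    out = np.zeros((n_t, 5))
    for i in range(n_t):
        valid = mask[i]
        total = valid.sum()
        if total == 0:
            out[i] = np.nan
            continue
        for s in range(5):
            out[i, s] = np.sum(vals[i][valid] == s) / total
    return out


# ---------------------------------------------------------------------------
# aridity


AI_CLASSES = ["humid", "semi_humid", "semi_arid", "arid"]


def classify_aridity(ai: np.ndarray) -> tuple[np.ndarray, dict[str, float]]:
    """Aridity classes: humid (<1), semi-humid [1,1.5), semi-arid [1.5,4), arid (>=4).

    Returns (integer map 0..3 with -1 for invalid, area fraction per class).
    """
    ai = np.asarray(ai, dtype=np.float64)
    valid = np.isfinite(ai)
    if np.any(ai[valid] < 0):
        raise GridError("aridity index must be non-negative")
    codes = np.full(ai.shape, -1, dtype=np.int16)
    codes[valid & (ai < 1.0)] = 0
    codes[valid & (ai >= 1.0) & (ai < 1.5)] = 1
    codes[valid & (ai >= 1.5) & (ai < 4.0)] = 2
    codes[valid & (ai >= 4.0)] = 3
    n_valid = valid.sum()
    fracs = {name: float(np.sum(codes == i) / n_valid) if n_valid else np.nan
             for i, name in enumerate(AI_CLASSES)}
    return codes, fracs
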