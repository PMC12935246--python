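"""Pixel-wise Pearson and partial correlation of NPP with climate drivers.

Per-pixel product-moment correlations over years, with two-sided t-tests
(t = r*sqrt((n−2)/(1−r^2)), df = n−2). Partial correlations condition on
1–3 controls through the inverse of the joint correlation matrix
(r_ij|rest = −Ω_ij / sqrt(Ω_ii Ω_jj)) with df = n − 2 − #controls. Area
summaries report the mean coefficient, the positive fraction and the
significant fraction over valid pixels.

Drought-index correlations align aggregation windows with index scale: the
3-month index at a season's final month represents that season, the 12-month
index at December represents the year, and 1-month indices pair with monthly
NPP directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .grids import GridCube, GridError
from .indices import DroughtIndexCube

#: season -> (member months, final month carrying the 3-month index)
SEASONS = {"spring": ((3, 4, 5), 5), "summer": ((6, 7, 8), 8),
           "autumn": ((9, 10, 11), 11), "winter": ((12, 1, 2), 2)}


@dataclass
class CorrelationField:
    """Per-pixel correlation result."""

    r: np.ndarray
    p: np.ndarray
    n_eff: np.ndarray
    kind: str = "pearson"
    controls: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.kind == "pearson" and self.controls:
            raise GridError("pearson field cannot have controls")
        if self.kind == "partial" and not self.controls:
            raise GridError("partial field must name its controls")


def _t_pvalue(r: np.ndarray, df: np.ndarray | int) -> np.ndarray:
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt(df / np.maximum(1.0 - r**2, 1e-300))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p[np.isclose(np.abs(r), 1.0)] = 0.0
    return p


def pearson_map(a: np.ndarray, b: np.ndarray) -> CorrelationField:
    """Per-pixel Pearson r over the first axis of two (n, rows, cols) stacks.

    Pixels with any missing value or zero variance in either series are
    masked (NaN).
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise GridError("stacks must have identical shapes")
    n = a.shape[0]
    if n < 3:
        raise GridError("need at least 3 samples per pixel")
    ok = np.all(np.isfinite(a), axis=0) & np.all(np.isfinite(b), axis=0)
    am = a - a.mean(axis=0)
    bm = b - b.mean(axis=0)
    sa = np.sqrt((am**2).sum(axis=0))
    sb = np.sqrt((bm**2).sum(axis=0))
    ok &= (sa > 0) & (sb > 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (am * bm).sum(axis=0) / (sa * sb)
    r = np.where(ok, np.clip(r, -1.0, 1.0), np.nan)
    p = np.full(r.shape, np.nan)
    p[ok] = _t_pvalue(r[ok], n - 2)
    n_eff = np.where(ok, n, 0)
    return CorrelationField(r=r, p=p, n_eff=n_eff, kind="pearson")


def partial_map(target: np.ndarray, driver: np.ndarray,
                controls: list[np.ndarray],
                control_names: list[str] | None = None) -> CorrelationField:
    """Per-pixel partial correlation of target and driver given controls.

    Controls whose series is constant at a pixel are dropped there (a fully
    degenerate control set reduces to plain Pearson); a singular joint
    correlation matrix masks the pixel.
    """
    if not (1 <= len(controls) <= 3):
        raise GridError("1-3 controls required")
    stacks = [np.asarray(s, dtype=np.float64) for s in
              (target, driver, *controls)]
    shape = stacks[0].shape
    for s in stacks:
        if s.shape != shape:
            raise GridError("all stacks must share a shape")
    n = shape[0]
    names = control_names or [f"control{i+1}" for i in range(len(controls))]
    flat = [s.reshape(n, -1) for s in stacks]
    npix = flat[0].shape[1]
    r = np.full(npix, np.nan)
    p = np.full(npix, np.nan)
    n_eff = np.zeros(npix, dtype=int)
    for k in range(npix):
        cols = [f[:, k] for f in flat]
        if not all(np.all(np.isfinite(c)) for c in cols[:2]):
            continue
        if cols[0].std() == 0 or cols[1].std() == 0:
            continue
        live = [c for c in cols[2:]
                if np.all(np.isfinite(c)) and c.std() > 0]
        mat = np.column_stack([cols[0], cols[1], *live])
        corr = np.corrcoef(mat, rowvar=False)
        if mat.shape[1] == 2:
            rr = corr[0, 1]
        else:
            try:
                omega = np.linalg.inv(corr)
            except np.linalg.LinAlgError:
                continue
            denom = np.sqrt(omega[0, 0] * omega[1, 1])
            if not np.isfinite(denom) or denom == 0:
                continue
            rr = -omega[0, 1] / denom
        df = n - 2 - len(live)
        if df < 1:
            continue
        r[k] = np.clip(rr, -1.0, 1.0)
        p[k] = _t_pvalue(np.array([r[k]]), df)[0]
        n_eff[k] = n
    out_shape = shape[1:] if len(shape) > 1 else ()
    return CorrelationField(r=r.reshape(out_shape), p=p.reshape(out_shape),
                            n_eff=n_eff.reshape(out_shape), kind="partial",
                            controls=names)


def area_summary(fld: CorrelationField, alpha: float = 0.05) -> dict[str, float]:
    """Mean r, fraction positive and fraction significant over valid pixels."""
    valid = np.isfinite(fld.r)
    if not valid.any():
        raise GridError("correlation field has no valid pixels")
    r, p = fld.r[valid], fld.p[valid]
    return {"mean_r": float(np.mean(r)),
            "frac_positive": float(np.mean(r > 0)),
            "frac_significant": float(np.mean(p < alpha)),
            "n_pixels": int(valid.sum())}


# ---------------------------------------------------------------------------
# annualisation helpers


def annualize(cube: GridCube, how: str = "sum") -> tuple[list[int], np.ndarray]:
    return cube.annual_aggregate(how=how)


def npp_driver_correlation(npp: GridCube, driver: GridCube,
                           driver_how: str = "sum",
                           controls: list[tuple[GridCube, str, str]] | None = None
                           ) -> CorrelationField:
    """Annual NPP vs an annualised driver, optionally partial.

    ``controls`` entries are (cube, aggregate-how, name). NPP is annualised
    by summation; drivers by the stated aggregate (sum for precipitation and
    radiation, mean for temperature).
    """
    years_a, npp_ann = npp.annual_aggregate("sum")
    years_b, drv_ann = driver.annual_aggregate(driver_how)
    if years_a != years_b:
        raise GridError("NPP and driver cover different years")
    if not controls:
        return pearson_map(npp_ann, drv_ann)
    ctrl_stacks, names = [], []
    for cube, how, name in controls:
        years_c, ann = cube.annual_aggregate(how)
        if years_c != years_a:
            raise GridError(f"control {name} covers different years")
        ctrl_stacks.append(ann)
        names.append(name)
    return partial_map(npp_ann, drv_ann, ctrl_stacks, control_names=names)


def lagged_index_correlation(npp: GridCube, index: DroughtIndexCube,
                             selection: dict) -> CorrelationField:
    """Correlate NPP aggregates with matching-scale drought-index values.

    ``selection`` is one of::

        {"season": "summer"}   3-month index at the season's final month vs
                               the seasonal NPP sum (requires scale_k == 3)
        {"annual": True}       12-month index at December vs the annual NPP
                               sum (requires scale_k == 12)
        {"months": [6, 7]}     1-month index vs monthly NPP pooled over the
                               listed calendar months (requires scale_k == 1)
    """
    cube = index.cube
    npp.align_check(cube)
    vals_n, vals_i = npp.masked(), cube.masked()
    if "season" in selection:
        if index.scale_k != 3:
            raise GridError("seasonal selection requires a 3-month index")
        season = selection["season"]
        if season not in SEASONS:
            raise GridError(f"unknown season {season!r}")
        members, final = SEASONS[season]
        pairs_n, pairs_i = [], []
        for y in npp.years():
            try:
                if season == "winter":
                    steps = [npp.time_index(y - 1, 12), npp.time_index(y, 1),
                             npp.time_index(y, 2)]
                else:
                    steps = [npp.time_index(y, m) for m in members]
                i_final = npp.time_index(y, final)
            except GridError:
                continue
            pairs_n.append(vals_n[steps].sum(axis=0))
            pairs_i.append(vals_i[i_final])
        if len(pairs_n) < 3:
            raise GridError("fewer than 3 complete seasons in the record")
        return pearson_map(np.stack(pairs_n), np.stack(pairs_i))
    if selection.get("annual"):
        if index.scale_k != 12:
            raise GridError("annual selection requires a 12-month index")
        years, npp_ann = npp.annual_aggregate("sum")
        idx_dec = np.stack([vals_i[npp.time_index(y, 12)] for y in years])
        return pearson_map(npp_ann, idx_dec)
    if "months" in selection:
        months = list(selection["months"])
        if not months:
            raise GridError("month subset is empty")
        if index.scale_k != 1:
            raise GridError("monthly selection requires a 1-month index")
        steps = [i for i, (_, m) in enumerate(npp.times) if m in months]
        if len(steps) < 3:
            raise GridError("month subset selects fewer than 3 steps")
        return pearson_map(vals_n[steps], vals_i[steps])
    raise GridError(f"unrecognised selection {selection!r}")
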