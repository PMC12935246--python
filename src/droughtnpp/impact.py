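"""Drought impact on NPP (ΔNPP tables) and categorical skill validation.

ΔNPP is the percent change of NPP in drought months relative to a
non-drought baseline: for every vegetation class and calendar month the
baseline is the mean NPP over all pixel-months of that class where the
severity grade is "none", across years. Drought pixel-months are then
expressed as 100·(NPP − baseline)/baseline and aggregated by
(class, severity[, month]). Rows with no contributing samples are absent,
never reported as zero.

Skill validation compares a monthly regional drought flag series against a
dated event catalog using month-level contingency counting: hits are flagged
months inside catalog events, misses are unflagged event months, false
alarms are flagged months outside all events, giving POD = H/(H+M),
FAR = F/(H+F), CSI = H/(H+M+F).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grids import (GridCube, GridError, LandCoverMap, VEGETATED_CLASSES,
                    CLASS_NAMES, month_range)
from .indices import DroughtIndexCube, SeverityCube, SEVERITY_NAMES

logger = logging.getLogger(__name__)

EARLY_SEASON_MONTHS = (3, 4, 5)   # early growing season
PEAK_SEASON_MONTHS = (6, 7, 8)    # peak growing season


def non_drought_baseline(npp: GridCube, severity: SeverityCube,
                         landcover: LandCoverMap) -> pd.DataFrame:
    """Baseline mean NPP per (vegetation class, calendar month).

    Pools all pixels of a class and all years where the severity grade is
    "none" in that calendar month. (class, month) cells with zero
    non-drought samples are absent (logged), and downstream ΔNPP rows that
    would need them are skipped.
    """
    npp.align_check(severity.cube)
    npp.meta.check_match(landcover.meta, "npp vs landcover")
    vals = npp.masked()
    sev = severity.cube.values
    sev_ok = severity.cube.valid_mask
    rows = []
    for code in VEGETATED_CLASSES:
        cmask = landcover.class_mask(code)
        if not cmask.any():
            continue
        for month in range(1, 13):
            idx = npp.calendar_month_indices(month)
            if idx.size == 0:
                continue
            block = vals[idx][:, cmask]
            none = (sev[idx][:, cmask] == 0) & sev_ok[idx][:, cmask]
            sample = block[none & np.isfinite(block)]
            if sample.size == 0:
                logger.warning("no non-drought baseline for class %s month %d",
                               CLASS_NAMES[code], month)
                continue
            rows.append({"class_code": code, "class": CLASS_NAMES[code],
                         "month": month, "baseline": float(sample.mean()),
                         "n": int(sample.size)})
    return pd.DataFrame(rows, columns=["class_code", "class", "month",
                                       "baseline", "n"])


def delta_npp(npp: GridCube, severity: SeverityCube, landcover: LandCoverMap,
              baseline: pd.DataFrame | None = None,
              by_month: bool = True) -> pd.DataFrame:
    """ΔNPP table: mean percent NPP anomaly by class x severity (x month).

    Each drought pixel-month (severity >= mild) contributes
    100·(NPP − baseline(class, month)) / baseline(class, month). Zero
    baselines are excluded (counted in the log). Returned columns:
    class_code, class, severity_code, severity[, month], delta_npp_pct, n.
    """
    if baseline is None:
        baseline = non_drought_baseline(npp, severity, landcover)
    if baseline.empty:
        raise GridError("no baseline rows available")
    base_lut = {(int(r.class_code), int(r.month)): r.baseline
                for r in baseline.itertuples()}
    n_zero = sum(1 for b in base_lut.values() if b == 0)
    if n_zero:
        logger.warning("delta_npp: %d zero baselines excluded", n_zero)
    vals = npp.masked()
    sev = severity.cube.values
    sev_ok = severity.cube.valid_mask
    rows = []
    for code in VEGETATED_CLASSES:
        cmask = landcover.class_mask(code)
        if not cmask.any():
            continue
        for month in range(1, 13):
            b = base_lut.get((code, month))
            if b is None or b == 0:
                continue
            idx = npp.calendar_month_indices(month)
            block = vals[idx][:, cmask]
            sblock = sev[idx][:, cmask]
            okblock = sev_ok[idx][:, cmask] & np.isfinite(block)
            for s in (1, 2, 3, 4):
                sample = block[(sblock == s) & okblock]
                if sample.size == 0:
                    continue
                d = 100.0 * (sample - b) / b
                rows.append({"class_code": code, "class": CLASS_NAMES[code],
                             "severity_code": s, "severity": SEVERITY_NAMES[s],
                             "month": month,
                             "delta_npp_pct": float(d.mean()),
                             "n": int(sample.size)})
    df = pd.DataFrame(rows, columns=["class_code", "class", "severity_code",
                                     "severity", "month", "delta_npp_pct", "n"])
    if df.empty or by_month:
        return df
    return aggregate_delta_table(df, by_month=False)


def aggregate_delta_table(df: pd.DataFrame, by_month: bool = False) -> pd.DataFrame:
    """Collapse a monthly ΔNPP table over months (n-weighted mean)."""
    if by_month or df.empty:
        return df
    grouped = []
    for (code, s), sub in df.groupby(["class_code", "severity_code"]):
        w = sub["n"].to_numpy(dtype=float)
        grouped.append({"class_code": code, "class": CLASS_NAMES[code],
                        "severity_code": s, "severity": SEVERITY_NAMES[s],
                        "delta_npp_pct": float(np.average(
                            sub["delta_npp_pct"], weights=w)),
                        "n": int(w.sum())})
    return pd.DataFrame(grouped, columns=["class_code", "class",
                                          "severity_code", "severity",
                                          "delta_npp_pct", "n"])


def seasonal_anomaly_profile(delta_table: pd.DataFrame) -> pd.DataFrame:
    """Early (Mar-May) vs peak (Jun-Aug) growing-season ΔNPP comparison.

    Needs a monthly-resolved ΔNPP table. Returns one row per class x
    severity with the n-weighted mean ΔNPP in each window and which window
    is more negative; the comparison is absent (NaN) when a window has no
    rows.
    """
    if "month" not in delta_table.columns or delta_table.empty:
        raise GridError("a monthly-resolved delta table is required")
    rows = []
    for (code, s), sub in delta_table.groupby(["class_code", "severity_code"]):
        def _mean(months):
            w = sub[sub["month"].isin(months)]
            if w.empty:
                return np.nan, 0
            return (float(np.average(w["delta_npp_pct"], weights=w["n"])),
                    int(w["n"].sum()))
        early, n_early = _mean(EARLY_SEASON_MONTHS)
        peak, n_peak = _mean(PEAK_SEASON_MONTHS)
        if np.isfinite(early) and np.isfinite(peak):
            deeper = "peak" if peak < early else "early"
        else:
            deeper = ""
        rows.append({"class_code": code, "class": CLASS_NAMES[code],
                     "severity_code": s, "severity": SEVERITY_NAMES[s],
                     "early_mean_delta_pct": early, "n_early": n_early,
                     "peak_mean_delta_pct": peak, "n_peak": n_peak,
                     "more_negative_window": deeper})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# event-catalog skill validation


def regional_drought_flags(index: DroughtIndexCube,
                           rule: str = "mean_index",
                           tau: float = -0.5,
                           phi: float = 0.3,
                           severity_threshold: float = -0.5) -> pd.Series:
    """Monthly regional drought flag series.

    ``rule``:
      * ``mean_index``   — flag months whose regional mean index <= tau;
      * ``area_fraction`` — flag months where the fraction of valid pixels at
        or below ``severity_threshold`` (>= mild) reaches phi.

    Indexed by (year, month); months with no valid pixels are False.
    """
    cube = index.cube
    vals = cube.masked()
    flags = []
    for i in range(cube.n_times):
        v = vals[i][np.isfinite(vals[i])]
        if v.size == 0:
            flags.append(False)
        elif rule == "mean_index":
            flags.append(bool(v.mean() <= tau))
        elif rule == "area_fraction":
            flags.append(bool(np.mean(v <= severity_threshold) >= phi))
        else:
            raise GridError(f"unknown flag rule {rule!r}")
    idx = pd.MultiIndex.from_tuples(cube.times, names=["year", "month"])
    return pd.Series(flags, index=idx, name="drought_flag")


def catalog_months(catalog: pd.DataFrame) -> set[tuple[int, int]]:
    """All (year, month) pairs covered by any catalog event."""
    months: set[tuple[int, int]] = set()
    for row in catalog.itertuples():
        months |= set(month_range((int(row.start_year), int(row.start_month)),
                                  (int(row.end_year), int(row.end_month))))
    return months


@dataclass
class SkillScores:
    """Contingency counts and categorical scores (absent scores are None)."""

    hits: int
    misses: int
    false_alarms: int

    @property
    def pod(self) -> float | None:
        d = self.hits + self.misses
        return self.hits / d if d else None

    @property
    def far(self) -> float | None:
        d = self.hits + self.false_alarms
        return self.false_alarms / d if d else None

    @property
    def csi(self) -> float | None:
        d = self.hits + self.misses + self.false_alarms
        return self.hits / d if d else None

    def as_dict(self) -> dict:
        return {"hits": self.hits, "misses": self.misses,
                "false_alarms": self.false_alarms,
                "pod": self.pod, "far": self.far, "csi": self.csi}


def skill_scores(flags: pd.Series, catalog: pd.DataFrame) -> SkillScores:
    """Month-level contingency of a flag series against an event catalog.

    Catalog months must lie within the flag range; months outside any event
    that are flagged count as false alarms.
    """
    flag_months = set(flags.index)
    event = catalog_months(catalog)
    if not event <= flag_months:
        out = sorted(event - flag_months)[:3]
        raise GridError(f"catalog months outside flag range, e.g. {out}")
    flagged = {t for t, f in flags.items() if f}
    hits = len(flagged & event)
    misses = len(event - flagged)
    false_alarms = len(flagged - event)
    return SkillScores(hits=hits, misses=misses, false_alarms=false_alarms)
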