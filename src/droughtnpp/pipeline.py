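"""End-to-end orchestration: configuration, staged runs, manifest, summary.

A run takes monthly climate/NDVI/soil-moisture cubes (generated synthetically
or read from disk) through the full analysis chain —

    drought indices (PET -> SPEI-1/3/12, SSMI) -> CASA NPP -> trend fields ->
    driver correlations -> ΔNPP impact tables -> event-catalog skill scores

— writing every product (NetCDF cubes, TIFF fields, CSV tables, JSON
scalars) under an output directory together with a JSON manifest of paths
and SHA-256 checksums. Identical configuration and seed give identical
checksums.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from . import association, casa, impact, indices, synthetic, trends
from .grids import (GridCube, GridError, read_cube, read_landcover,
                    read_event_catalog, write_cube, write_field,
                    write_landcover, write_event_catalog, CLASS_NAMES,
                    VEGETATED_CLASSES)

logger = logging.getLogger(__name__)

_SYNTH_KEYS = {f.name for f in synthetic.SynthConfig.__dataclass_fields__.values()}


@dataclass
class RunConfig:
    """Validated pipeline configuration."""

    outdir: str = "droughtnpp_run"
    seed: int = 0
    synthetic: bool = True
    synth: dict = field(default_factory=dict)   # SynthConfig overrides
    inputs: dict = field(default_factory=dict)  # paths when synthetic=False
    casa: dict = field(default_factory=dict)    # CasaParams overrides
    spei_scales: tuple[int, ...] = (1, 3, 12)
    dfi_threshold: float = -1.0
    trend_alpha: float = 0.05
    corr_alpha: float = 0.05
    skill_rule: str = "mean_index"
    skill_tau: float = -0.5
    skill_phi: float = 0.3
    skill_scale: int = 3
    impact_index_scale: int = 1
    reference_npp: str | None = None
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        unknown = set(self.synth) - _SYNTH_KEYS
        if unknown:
            raise GridError(f"unknown synth config keys: {sorted(unknown)}")
        allowed_casa = {f for f in casa.CasaParams.__dataclass_fields__}
        unknown = set(self.casa) - allowed_casa
        if unknown:
            raise GridError(f"unknown casa config keys: {sorted(unknown)}")
        if any(k < 1 for k in self.spei_scales):
            raise GridError("spei_scales must be positive")
        if self.skill_rule not in ("mean_index", "area_fraction"):
            raise GridError(f"unknown skill rule {self.skill_rule!r}")
        if self.impact_index_scale not in self.spei_scales:
            raise GridError("impact_index_scale must be one of spei_scales")

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise GridError(f"unknown config keys: {sorted(unknown)}")
        if "spei_scales" in data:
            data["spei_scales"] = tuple(data["spei_scales"])
        return cls(**data)

    def synth_config(self) -> synthetic.SynthConfig:
        kwargs = dict(self.synth)
        kwargs.setdefault("seed", self.seed)
        if "drought_events" in kwargs:
            kwargs["drought_events"] = tuple(
                synthetic.DroughtEvent(tuple(e["start"]), tuple(e["end"]),
                                       e["deficit_fraction"],
                                       tuple(e["region"]) if e.get("region")
                                       else None)
                for e in kwargs["drought_events"])
        if "ndvi_coupling" in kwargs:
            kwargs["ndvi_coupling"] = {int(k): float(v) for k, v in
                                       kwargs["ndvi_coupling"].items()}
        return synthetic.SynthConfig(**kwargs)

    def casa_params(self) -> casa.CasaParams:
        return casa.CasaParams(**self.casa)


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


class _Products:
    """Collects artifact paths for the manifest."""

    def __init__(self, outdir: str):
        self.outdir = outdir
        os.makedirs(outdir, exist_ok=True)
        self.paths: dict[str, str] = {}

    def path(self, name: str, filename: str) -> str:
        p = os.path.join(self.outdir, filename)
        self.paths[name] = p
        return p

    def write_json(self, name: str, filename: str, obj) -> str:
        p = self.path(name, filename)
        with open(p, "w") as fh:
            json.dump(obj, fh, indent=2, sort_keys=True, default=float)
        return p

    def write_csv(self, name: str, filename: str, df: pd.DataFrame) -> str:
        p = self.path(name, filename)
        df.to_csv(p, index=False, float_format="%.10g")
        return p

    def manifest(self) -> dict:
        return {name: {"path": os.path.relpath(p, self.outdir),
                       "sha256": _sha256(p)}
                for name, p in sorted(self.paths.items())}


def _regional_mean_series(cube: GridCube) -> np.ndarray:
    return np.nanmean(cube.masked().reshape(cube.n_times, -1), axis=1)


def _stage_inputs(config: RunConfig, prod: _Products) -> dict:
    if config.synthetic:
        scenario = synthetic.generate(config.synth_config())
        catalog = synthetic.make_event_catalog(scenario["truth"])
        scenario["truth"].to_json(prod.path("synth_truth", "synth_truth.json"))
        write_event_catalog(catalog, prod.path("event_catalog", "events.csv"))
        for name in ("precip", "temp", "sol", "sm", "ndvi"):
            write_cube(scenario[name], prod.path(f"input_{name}", f"{name}.nc"))
        write_landcover(scenario["landcover"],
                        prod.path("landcover", "landcover.tif"))
        scenario["catalog"] = catalog
        return scenario
    required = {"precip", "temp", "sol", "ndvi", "landcover"}
    missing = required - set(config.inputs)
    if missing:
        raise GridError(f"inputs missing: {sorted(missing)}")
    data = {name: read_cube(config.inputs[name])
            for name in ("precip", "temp", "sol", "ndvi")
            if name in config.inputs}
    if "sm" in config.inputs:
        data["sm"] = read_cube(config.inputs["sm"])
    data["landcover"] = read_landcover(config.inputs["landcover"])
    data["catalog"] = (read_event_catalog(config.inputs["catalog"])
                       if "catalog" in config.inputs else None)
    data["pet"] = indices.pet_thornthwaite(data["temp"])
    return data


def _stage_indices(config: RunConfig, data: dict, prod: _Products) -> dict:
    pet = data["pet"]
    write_cube(pet, prod.path("pet", "pet.nc"))
    out = {}
    for k in config.spei_scales:
        idx = indices.spei(data["precip"], pet, k)
        out[f"spei_{k}"] = idx
        write_cube(idx.cube, prod.path(f"spei_{k}", f"spei_{k}.nc"),
                   extra_attrs={"scale_k": k, "index_kind": "spei"})
        sev = indices.classify(idx)
        out[f"severity_spei_{k}"] = sev
        area = indices.drought_area_series(sev)
        df = pd.DataFrame(area, columns=[f"frac_{indices.SEVERITY_NAMES[s]}"
                                         for s in range(5)])
        df.insert(0, "year", [y for y, _ in idx.cube.times])
        df.insert(1, "month", [m for _, m in idx.cube.times])
        prod.write_csv(f"drought_area_spei_{k}", f"drought_area_spei_{k}.csv", df)
    if "sm" in data:
        for k in (1, 12):
            idx = indices.ssmi(data["sm"], k)
            out[f"ssmi_{k}"] = idx
            write_cube(idx.cube, prod.path(f"ssmi_{k}", f"ssmi_{k}.nc"),
                       extra_attrs={"scale_k": k, "index_kind": "ssmi"})
        out["severity_ssmi_1"] = indices.classify(out["ssmi_1"])
    # drought frequency maps
    meta = data["precip"].meta
    dfi1 = indices.drought_frequency(out[f"spei_{config.spei_scales[0]}"],
                                     config.dfi_threshold)
    write_field(dfi1, meta, prod.path("dfi_monthly", "dfi_monthly.tif"),
                units="%")
    if "spei_12" in out:
        dfi12 = indices.drought_frequency(out["spei_12"], config.dfi_threshold)
        write_field(dfi12, meta, prod.path("dfi_annual", "dfi_annual.tif"),
                    units="%")
    for season, months in (("spring", (3, 4, 5)), ("summer", (6, 7, 8)),
                           ("autumn", (9, 10, 11)), ("winter", (12, 1, 2))):
        dfi = indices.drought_frequency(out[f"spei_{config.spei_scales[0]}"],
                                        config.dfi_threshold,
                                        month_subset=list(months))
        write_field(dfi, meta, prod.path(f"dfi_{season}", f"dfi_{season}.tif"),
                    units="%")
    return out


def _stage_npp(config: RunConfig, data: dict, prod: _Products) -> dict:
    params = config.casa_params()
    npp = casa.run_casa(data["ndvi"], data["temp"], data["sol"],
                        data["precip"], data["pet"], data["landcover"],
                        params, sm=data.get("sm"))
    write_cube(npp, prod.path("npp_monthly", "npp_monthly.nc"))
    years = [y for y in npp.years()
             if sum(1 for yy, _ in npp.times if yy == y) == 12]
    annual = np.stack([casa.npp_annual(npp, y) for y in years])
    any_valid = np.any(np.isfinite(annual), axis=0)
    mean_annual = np.full(annual.shape[1:], np.nan)
    mean_annual[any_valid] = np.nanmean(annual[:, any_valid], axis=0)
    write_field(mean_annual, npp.meta,
                prod.path("npp_mean_annual", "npp_mean_annual.tif"),
                units="gC/m2/a")
    reference = npp
    if config.reference_npp:
        reference = read_cube(config.reference_npp)
    bench = casa.benchmark_regression(npp, reference, data["landcover"])
    prod.write_json("npp_benchmark", "npp_benchmark.json", bench)
    return {"npp": npp, "annual_years": years, "annual": annual}


def _write_trend_field(tf: trends.TrendField, meta, prod: _Products,
                       name: str) -> None:
    for band, arr in (("slope", tf.slope), ("z", tf.z), ("p", tf.p),
                      ("class", tf.sig_class.astype(float))):
        write_field(arr, meta, prod.path(f"trend_{name}_{band}",
                                         f"trend_{name}_{band}.tif"))


def _stage_trends(config: RunConfig, data: dict, idx: dict, nppres: dict,
                  prod: _Products) -> dict:
    alpha = config.trend_alpha
    meta = data["precip"].meta
    out = {}
    # per-pixel annual trends
    for name, cube, how in (("npp", nppres["npp"], "sum"),
                            ("precip", data["precip"], "sum"),
                            ("temp", data["temp"], "mean")):
        tf = trends.annual_trend_map(cube, how=how, alpha=alpha)
        out[name] = tf
        _write_trend_field(tf, meta, prod, name)
    fr = {name: out[name].class_fractions() for name in out}
    prod.write_json("trend_class_fractions", "trend_class_fractions.json", fr)
    # regional annual series + Sen/M-K summaries
    years = nppres["annual_years"]
    series = {
        "temp_mean_degC": [float(np.nanmean(v)) for v in
                           data["temp"].annual_aggregate("mean")[1]],
        "precip_total_mm": [float(np.nanmean(v)) for v in
                            data["precip"].annual_aggregate("sum")[1]],
        "npp_total_gc_m2": [float(np.nanmean(a)) for a in nppres["annual"]],
    }
    for key in ("spei_12", "ssmi_12"):
        if key in idx:
            cube = idx[key].cube
            dec = [cube.masked()[cube.time_index(y, 12)] for y in years]
            series[key] = [float(np.nanmean(d)) for d in dec]
    df = pd.DataFrame({"year": years, **series})
    prod.write_csv("regional_annual_series", "regional_annual_series.csv", df)
    summaries = {name: trends.regional_series_trend(np.asarray(v),
                                                    np.asarray(years, float))
                 for name, v in series.items()}
    prod.write_json("regional_trends", "regional_trends.json", summaries)
    out["regional"] = summaries
    return out


def _stage_correlations(config: RunConfig, data: dict, idx: dict,
                        nppres: dict, prod: _Products) -> dict:
    npp = nppres["npp"]
    alpha = config.corr_alpha
    meta = npp.meta
    drivers = [("precip", data["precip"], "sum"),
               ("temp", data["temp"], "mean"),
               ("sol", data["sol"], "sum")]
    summaries = []
    fields = {}
    for name, cube, how in drivers:
        fld = association.npp_driver_correlation(npp, cube, driver_how=how)
        fields[f"pearson_{name}"] = fld
        others = [(c, h, n) for n, c, h in drivers if n != name]
        pfld = association.npp_driver_correlation(
            npp, cube, driver_how=how,
            controls=[(c, h, n) for c, h, n in others])
        fields[f"partial_{name}"] = pfld
        for kind, f in (("pearson", fld), ("partial", pfld)):
            write_field(f.r, meta, prod.path(f"corr_{kind}_{name}_r",
                                             f"corr_{kind}_{name}_r.tif"))
            write_field(f.p, meta, prod.path(f"corr_{kind}_{name}_p",
                                             f"corr_{kind}_{name}_p.tif"))
            s = association.area_summary(f, alpha=alpha)
            summaries.append({"driver": name, "kind": kind, **s})
    # drought-index correlations
    lag_rows = []
    if "spei_3" in idx:
        for season in association.SEASONS:
            fld = association.lagged_index_correlation(npp, idx["spei_3"],
                                                       {"season": season})
            s = association.area_summary(fld, alpha=alpha)
            lag_rows.append({"index": "spei_3", "window": season, **s})
            write_field(fld.r, meta,
                        prod.path(f"corr_spei3_{season}_r",
                                  f"corr_spei3_{season}_r.tif"))
    for key, sel, label in (("spei_12", {"annual": True}, "annual"),
                            ("ssmi_12", {"annual": True}, "annual"),
                            ("spei_1", {"months": list(range(1, 13))}, "monthly"),
                            ("ssmi_1", {"months": list(range(1, 13))}, "monthly")):
        if key in idx:
            fld = association.lagged_index_correlation(npp, idx[key], sel)
            s = association.area_summary(fld, alpha=alpha)
            lag_rows.append({"index": key, "window": label, **s})
            write_field(fld.r, meta, prod.path(f"corr_{key}_{label}_r",
                                               f"corr_{key}_{label}_r.tif"))
    prod.write_csv("corr_driver_summary", "corr_driver_summary.csv",
                   pd.DataFrame(summaries))
    prod.write_csv("corr_index_summary", "corr_index_summary.csv",
                   pd.DataFrame(lag_rows))
    # SPEI-SSMI coupling map (same-scale monthly indices)
    coupling = None
    if "spei_1" in idx and "ssmi_1" in idx:
        a, b = idx["spei_1"].cube.masked(), idx["ssmi_1"].cube.masked()
        keep = np.all(np.isfinite(a) & np.isfinite(b), axis=0)
        fld = association.pearson_map(np.where(np.isfinite(a), a, 0.0),
                                      np.where(np.isfinite(b), b, 0.0))
        fld.r[~keep] = np.nan
        fld.p[~keep] = np.nan
        coupling = association.area_summary(fld, alpha=alpha)
        write_field(fld.r, meta, prod.path("corr_spei_ssmi_r",
                                           "corr_spei_ssmi_r.tif"))
        prod.write_json("spei_ssmi_coupling", "spei_ssmi_coupling.json",
                        coupling)
    return {"fields": fields, "driver_summaries": summaries,
            "index_summaries": lag_rows, "spei_ssmi": coupling}


def _stage_impact(config: RunConfig, data: dict, idx: dict, nppres: dict,
                  prod: _Products) -> dict:
    sev = idx[f"severity_spei_{config.impact_index_scale}"]
    npp = nppres["npp"]
    lc = data["landcover"]
    baseline = impact.non_drought_baseline(npp, sev, lc)
    prod.write_csv("npp_baseline", "npp_baseline.csv", baseline)
    monthly = impact.delta_npp(npp, sev, lc, baseline, by_month=True)
    prod.write_csv("delta_npp_monthly", "delta_npp_monthly.csv", monthly)
    table = impact.aggregate_delta_table(monthly)
    prod.write_csv("delta_npp", "delta_npp.csv", table)
    if not monthly.empty:
        profile = impact.seasonal_anomaly_profile(monthly)
        prod.write_csv("seasonal_anomaly_profile",
                       "seasonal_anomaly_profile.csv", profile)
    return {"delta": table, "monthly": monthly, "baseline": baseline}


def _stage_validate(config: RunConfig, data: dict, idx: dict,
                    prod: _Products) -> dict | None:
    catalog = data.get("catalog")
    if catalog is None or catalog.empty:
        return None
    key = f"spei_{config.skill_scale}"
    if key not in idx:
        key = f"spei_{config.spei_scales[0]}"
    flags = impact.regional_drought_flags(idx[key], rule=config.skill_rule,
                                          tau=config.skill_tau,
                                          phi=config.skill_phi)
    scores = impact.skill_scores(flags, catalog)
    out = scores.as_dict()
    out["rule"] = config.skill_rule
    out["index"] = key
    prod.write_json("skill_scores", "skill_scores.json", out)
    return out


def run(config: RunConfig) -> dict:
    """Execute the full pipeline; returns the manifest dict (also on disk)."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), 20))
    prod = _Products(config.outdir)
    stage = "inputs"
    try:
        data = _stage_inputs(config, prod)
        stage = "indices"
        idx = _stage_indices(config, data, prod)
        stage = "npp"
        nppres = _stage_npp(config, data, prod)
        stage = "trends"
        _stage_trends(config, data, idx, nppres, prod)
        stage = "correlations"
        _stage_correlations(config, data, idx, nppres, prod)
        stage = "impact"
        _stage_impact(config, data, idx, nppres, prod)
        stage = "validate"
        _stage_validate(config, data, idx, prod)
    except Exception as exc:
        raise GridError(f"pipeline stage {stage!r} failed: {exc}") from exc
    manifest = {"config": {**asdict(config),
                           "spei_scales": list(config.spei_scales)},
                "artifacts": prod.manifest()}
    with open(os.path.join(config.outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def summarize(manifest_path: str) -> str:
    """Human-readable report of a run's headline numbers.

    Missing artifacts are listed as absent; nothing crashes.
    """
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    outdir = os.path.dirname(os.path.abspath(manifest_path))
    lines = ["drought-NPP pipeline summary", "=" * 30]
    absent = []

    def _load(name):
        art = manifest["artifacts"].get(name)
        if art is None:
            absent.append(name)
            return None
        p = os.path.join(outdir, art["path"])
        if not os.path.exists(p):
            absent.append(name)
            return None
        return p

    p = _load("regional_annual_series")
    if p:
        df = pd.read_csv(p)
        lines.append(f"mean annual NPP: {df['npp_total_gc_m2'].mean():.2f} gC/m2/a")
        lines.append(f"mean annual T: {df['temp_mean_degC'].mean():.2f} degC; "
                     f"mean annual P: {df['precip_total_mm'].mean():.2f} mm")
    p = _load("regional_trends")
    if p:
        with open(p) as fh:
            tr = json.load(fh)
        for k, v in tr.items():
            lines.append(f"Sen slope {k}: {v['slope']:.4g}/a (p={v['p']:.3g})")
    p = _load("trend_class_fractions")
    if p:
        with open(p) as fh:
            fr = json.load(fh)
        npp_fr = fr.get("npp", {})
        if npp_fr:
            lines.append("NPP trend area fractions: " + ", ".join(
                f"{k}={100 * v:.1f}%" for k, v in npp_fr.items()))
    p = _load("corr_driver_summary")
    if p:
        df = pd.read_csv(p)
        for row in df.itertuples():
            lines.append(
                f"NPP~{row.driver} ({row.kind}): mean r={row.mean_r:.3f}, "
                f"positive {100 * row.frac_positive:.1f}%, "
                f"significant {100 * row.frac_significant:.1f}%")
    p = _load("skill_scores")
    if p:
        with open(p) as fh:
            sc = json.load(fh)
        lines.append(f"skill: POD={sc['pod']:.4f} FAR={sc['far']:.4f} "
                     f"CSI={sc['csi']:.4f} (H={sc['hits']} M={sc['misses']} "
                     f"F={sc['false_alarms']})")
    p = _load("delta_npp")
    if p:
        df = pd.read_csv(p)
        for _, row in df.iterrows():
            lines.append(f"dNPP {row['class']}/{row['severity']}: "
                         f"{row['delta_npp_pct']:+.1f}% (n={row['n']})")
    if absent:
        lines.append("absent artifacts: " + ", ".join(absent))
    return "\n".join(lines)
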