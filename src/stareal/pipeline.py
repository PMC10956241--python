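"""End-to-end orchestration: configuration, logging, file I/O and reports.

A single :class:`RunConfig` drives the full analysis: load (or synthesize)
child records and a zone map, aggregate to a zone panel, build contiguity
weights, fit variograms per wave, krige the mortality surface, classify
hotspots, and compare the space-time dynamic models. Every table a stage
produces is persisted as CSV in the output directory, and a provenance
block (config hash, seed, package versions) accompanies the report.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .geostat import empirical_semivariogram, fit_all_families, ordinary_kriging, select_variogram
from .hotspot import hotspot_panel
from .stdm import PRESETS, ModelSpec, compare_models
from .synthetic import (
    ChildRecords,
    ZoneMap,
    ZonePanel,
    aggregate_to_zones,
    default_zone_map,
    simulate_child_records,
)
from .weights import contiguity_from_edges, contiguity_from_map, edges_from_csv, row_standardize

log = logging.getLogger("stareal")

FLOAT_FMT = "%.12g"  # fixed formatting so reruns are byte-identical


class StageError(RuntimeError):
    """A pipeline stage failed; partial artifacts are kept on disk."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {cause}")


@dataclass
class RunConfig:
    """Inputs and knobs for one pipeline run.

    With no input paths the pipeline synthesizes the default study-scale
    scenario (65 zones, 4 waves) from ``seed``.
    """

    outdir: str = "stareal_run"
    seed: int = 0
    panel_csv: str | None = None
    records_csv: str | None = None
    map_geojson: str | None = None
    edges_csv: str | None = None
    contiguity: str = "queen"
    variogram_families: tuple[str, ...] = ("exponential", "spherical", "circular", "gaussian")
    n_bins: int = 12
    model_specs: tuple[str, ...] = PRESETS
    weighted_covariates: bool = True

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        for name in ("panel_csv", "records_csv", "map_geojson", "edges_csv"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"config {name} points at missing file {p}")
        if self.contiguity not in {"queen", "rook"}:
            raise ValueError("contiguity must be 'queen' or 'rook'")

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class RunReport:
    prevalence: pd.DataFrame | None
    variogram: pd.DataFrame
    kriging: pd.DataFrame
    hotspots: pd.DataFrame
    comparison: pd.DataFrame
    fit_report: pd.DataFrame
    provenance: dict

    def tables(self) -> dict[str, pd.DataFrame]:
        out = {
            "variogram_table": self.variogram,
            "kriging_surface": self.kriging,
            "hotspot_table": self.hotspots,
            "model_comparison": self.comparison,
            "fit_report": self.fit_report,
        }
        if self.prevalence is not None:
            out["prevalence_table"] = self.prevalence
        return out


def prevalence_table(data) -> pd.DataFrame:
    """Weighted death proportion per wave, also formatted as percent.

    For child records this is ``sum(w * died) / sum(w)`` per wave; for a
    zone panel (proportions only, no weights) it is the unweighted mean of
    zone proportions per wave.
    """
    if isinstance(data, ChildRecords):
        df = data.frame
        rows = []
        for wave, grp in df.groupby("wave"):
            wsum = grp["weight"].sum()
            if wsum <= 0:
                raise ValueError(f"zero total weight in wave {wave}")
            p = float((grp["weight"] * grp["died"]).sum() / wsum)
            rows.append({"wave": wave, "n_children": len(grp), "prevalence": p})
    elif isinstance(data, ZonePanel):
        rows = [
            {
                "wave": w,
                "n_children": np.nan,
                "prevalence": float(data.y[data.mask[:, t], t].mean()),
            }
            for t, w in enumerate(data.wave_labels)
        ]
    else:
        raise TypeError("expected ChildRecords or ZonePanel")
    out = pd.DataFrame(rows).sort_values("wave").reset_index(drop=True)
    out["prevalence_pct"] = 100.0 * out["prevalence"]
    return out


def _load_inputs(cfg: RunConfig):
    records = panel = None
    if cfg.records_csv:
        records = ChildRecords.from_csv(cfg.records_csv)
    if cfg.panel_csv:
        try:
            panel = ZonePanel.from_csv(cfg.panel_csv)
        except ValueError as exc:
            raise ValueError(f"{cfg.panel_csv}: {exc}") from exc
    if cfg.map_geojson:
        zone_map = ZoneMap.from_geojson(cfg.map_geojson)
    else:
        zone_map = default_zone_map(seed=cfg.seed)
    if records is None and panel is None:
        log.info("no input data configured; synthesizing default scenario")
        records = simulate_child_records(
            zone_map,
            seed=cfg.seed,
            W=row_standardize(contiguity_from_map(zone_map, cfg.contiguity)),
        )
    return records, panel, zone_map


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute aggregation -> weights -> variogram/kriging -> hotspots ->
    model comparison, persisting every table under ``config.outdir``."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}

    def stage(name):
        class _Ctx:
            def __enter__(self):
                log.info("stage %s: start", name)
                self.t0 = time.perf_counter()

            def __exit__(self, exc_type, exc, tb):
                timings[name] = round(time.perf_counter() - self.t0, 4)
                if exc is not None:
                    log.error("stage %s: failed (%s)", name, exc)
                    raise StageError(name, exc) from exc
                log.info("stage %s: done in %.2fs", name, timings[name])

        return _Ctx()

    with stage("load"):
        records, panel, zone_map = _load_inputs(config)
        zone_map.to_geojson(outdir / "zones.geojson")

    prevalence = None
    with stage("aggregate"):
        if records is not None:
            records.to_csv(outdir / "child_records.csv")
            prevalence = prevalence_table(records)
            prevalence.to_csv(outdir / "prevalence_table.csv", index=False, float_format=FLOAT_FMT)
            if panel is None:
                panel = aggregate_to_zones(
                    records, zone_map, weighted_covariates=config.weighted_covariates
                )
        panel.to_csv(outdir / "zone_panel.csv")

    with stage("weights"):
        if config.edges_csv:
            Wb = contiguity_from_edges(edges_from_csv(config.edges_csv), panel.zone_ids)
        else:
            Wb = contiguity_from_map(zone_map, config.contiguity)
        W = row_standardize(Wb)
        Wb.to_edges().to_csv(outdir / "adjacency_edges.csv", index=False)

    centroids = zone_map.centroids()
    with stage("variogram"):
        vg_rows, best_fits = [], {}
        for t, wave in enumerate(panel.wave_labels):
            obs = panel.mask[:, t]
            emp = empirical_semivariogram(centroids[obs], panel.y[obs, t], n_bins=config.n_bins)
            fits = fit_all_families(
                emp, centroids[obs], panel.y[obs, t], families=config.variogram_families
            )
            best_fits[wave] = (select_variogram(fits), obs)
            for f in fits:
                vg_rows.append(
                    {
                        "wave": wave,
                        "model": f.family,
                        "nugget": f.nugget,
                        "sill": f.sill,
                        "range": f.range_,
                        "mse": f.mse,
                        "rmsse": f.rmsse,
                        "selected": f is best_fits[wave][0],
                    }
                )
        variogram = pd.DataFrame(vg_rows)
        variogram.to_csv(outdir / "variogram_table.csv", index=False, float_format=FLOAT_FMT)

    with stage("krige"):
        kr_rows = []
        for t, wave in enumerate(panel.wave_labels):
            fit, obs = best_fits[wave]
            res = ordinary_kriging(fit, centroids[obs], panel.y[obs, t], centroids)
            for i, z in enumerate(panel.zone_ids):
                kr_rows.append(
                    {
                        "zone_id": z,
                        "wave": wave,
                        "x": centroids[i, 0],
                        "y": centroids[i, 1],
                        "prediction": res.prediction[i],
                        "variance": res.variance[i],
                    }
                )
        kriging = pd.DataFrame(kr_rows)
        kriging.to_csv(outdir / "kriging_surface.csv", index=False, float_format=FLOAT_FMT)

    with stage("hotspot"):
        hotspots = hotspot_panel(panel, W)
        hotspots.to_csv(outdir / "hotspot_table.csv", index=False, float_format=FLOAT_FMT)

    with stage("models"):
        specs = [ModelSpec.preset(s) for s in config.model_specs]
        comp = compare_models(panel, W, specs, compute_se=False)
        comparison = comp.frame
        comparison.to_csv(outdir / "model_comparison.csv", index=False, float_format=FLOAT_FMT)
        from .stdm import fit_stdm  # refit selected with SEs

        best = fit_stdm(panel, W, ModelSpec.preset(comp.selected), drop_first=True)
        fit_report = best.table
        fit_report.to_csv(outdir / "fit_report.csv", index=False, float_format=FLOAT_FMT)
        with open(outdir / "fit_report.json", "w") as fh:
            json.dump(best.to_dict(), fh, indent=2, default=float)

    import scipy

    provenance = {
        "config": asdict(config),
        "config_hash": config.hash(),
        "seed": config.seed,
        "versions": {
            "stareal": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "scipy": scipy.__version__,
        },
        "timings_s": timings,
    }
    with open(outdir / "provenance.json", "w") as fh:
        json.dump(provenance, fh, indent=2)
    return RunReport(prevalence, variogram, kriging, hotspots, comparison, fit_report, provenance)
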