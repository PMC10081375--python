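"""End-to-end pipeline driver: simulate -> features -> train -> predict ->
aggregate -> covariates -> associate -> report.

Every stage writes plain-text artifacts into the output directory and records
their SHA-256 hashes in ``manifest.json`` together with the configuration and
package version; a rerun skips stages whose recorded outputs are present and
unmodified, so any stage is resumable from disk.  ``verify`` re-hashes all
recorded files.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import sys
import time

import numpy as np
import pandas as pd

from . import __version__
from . import association as assoc
from . import covariates as cov
from . import io as pio
from . import synthetic as syn
from .features import build_feature_table
from .geometry import read_geojson_polygons, write_geojson_polygons
from .gridagg import GridSpec, aggregate_to_areas, exposure_table, predict_surface
from .grids import write_esri_ascii
from .network import CVReport, PruneSchedule, PrunedFNN, TrainConfig, cross_validate, prune, train

__all__ = ["STAGES", "run_pipeline", "verify"]

STAGES = ("simulate", "features", "train", "cv", "predict", "aggregate",
          "covariates", "associate", "report")

log = logging.getLogger("peilink.pipeline")


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(1 << 20), b""):
            h.update(block)
    return h.hexdigest()


class _Manifest:
    def __init__(self, outdir: str):
        self.path = os.path.join(outdir, "manifest.json")
        self.doc = {"version": __version__, "stages": {}, "files": {}}
        if os.path.exists(self.path):
            with open(self.path) as fh:
                self.doc = json.load(fh)

    def stage_done(self, stage: str, outdir: str) -> bool:
        rec = self.doc["stages"].get(stage)
        if not rec:
            return False
        for rel in rec["outputs"]:
            p = os.path.join(outdir, rel)
            if not os.path.exists(p) or self.doc["files"].get(rel) != _sha256(p):
                return False
        return True

    def record(self, stage: str, outdir: str, outputs: list[str], seconds: float) -> None:
        for rel in outputs:
            self.doc["files"][rel] = _sha256(os.path.join(outdir, rel))
        self.doc["stages"][stage] = {"outputs": outputs, "seconds": round(seconds, 3)}
        with open(self.path, "w") as fh:
            json.dump(self.doc, fh, indent=1, sort_keys=True)


def _setup_logging(outdir: str) -> None:
    if log.handlers:
        return
    log.setLevel(logging.INFO)
    fmt = logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s")
    for h in (logging.StreamHandler(sys.stderr),
              logging.FileHandler(os.path.join(outdir, "run.log"))):
        h.setFormatter(fmt)
        log.addHandler(h)


class _Context:
    """Lazily loads stage inputs from the artifact directory."""

    def __init__(self, cfg: pio.PipelineConfig, outdir: str):
        self.cfg = cfg
        self.outdir = outdir
        self._cache: dict[str, object] = {}

    def path(self, *parts) -> str:
        return os.path.join(self.outdir, *parts)

    def region(self) -> syn.StudyRegion:
        if "region" not in self._cache:
            rc = self.cfg.region
            self._cache["region"] = syn.generate_region(
                seed=self.cfg.seed, n_areas=rc.n_areas, n_tracts=rc.n_tracts,
                extent_km=rc.extent_km, grid_res_m=rc.grid_res_m, years=rc.years)
        return self._cache["region"]

    def inventory(self):
        if "inventory" not in self._cache:
            self._cache["inventory"] = pio.read_inventory_csv(
                self.path("facilities.csv"), self.cfg.chemicals, self.cfg.region.years)
        return self._cache["inventory"]

    def climate(self):
        if "climate" not in self._cache:
            self._cache["climate"] = pio.read_climate_dir(self.path("climate"),
                                                          self.cfg.region.years)
        return self._cache["climate"]

    def terrain(self):
        if "terrain" not in self._cache:
            self._cache["terrain"] = pio.read_terrain(self.path("terrain.asc"))
        return self._cache["terrain"]

    def monitors(self) -> pd.DataFrame:
        return pio.read_table(self.path("monitors.csv"), pio.MONITOR_COLUMNS)

    def features(self) -> pd.DataFrame:
        if "features" not in self._cache:
            self._cache["features"] = pio.read_table(
                self.path("features.csv"),
                ("receptor_id", "x", "y", "source_id", "chemical", "year",
                 "T", "H", "EM", "D", "ED", "W"))
        return self._cache["features"]

    def areas(self):
        ids, polys, props = read_geojson_polygons(self.path("small_areas.geojson"))
        return ids, polys

    def train_config(self, seed_offset: int = 0) -> TrainConfig:
        f = self.cfg.fnn
        return TrainConfig(hidden=f.hidden, lr=f.lr, epochs=f.epochs,
                           seed=self.cfg.seed + seed_offset,
                           val_fraction=f.val_fraction, patience=f.patience,
                           log_target=f.log_target)


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _stage_simulate(ctx: _Context) -> list[str]:
    cfg = ctx.cfg
    region = ctx.region()
    write_geojson_polygons(ctx.path("small_areas.geojson"), region.area_ids, region.areas,
                           [{"weight": float(w)} for w in region.area_weights])
    write_geojson_polygons(ctx.path("tracts.geojson"), region.tract_ids, region.tracts,
                           [{"weight": float(w)} for w in region.tract_weights])
    inventory = syn.generate_emissions(
        region, n_facilities=cfg.emissions.n_facilities, chemicals=cfg.chemicals,
        seed=cfg.seed + 1, zero_fraction=cfg.emissions.zero_fraction,
        log_mean_kg=cfg.emissions.log_mean_kg, log_sd_kg=cfg.emissions.log_sd_kg)
    pio.write_inventory_csv(ctx.path("facilities.csv"), inventory)
    climate = syn.generate_climate(region, seed=cfg.seed + 2)
    pio.write_climate_dir(ctx.path("climate"), climate)
    terrain = syn.generate_terrain(region, seed=cfg.seed + 3)
    write_esri_ascii(ctx.path("terrain.asc"), terrain.raster)

    params = syn.DispersionParams(decay_km=cfg.oracle.decay_km,
                                  alignment_gain=cfg.oracle.alignment_gain)
    oracle = syn.make_oracle(inventory, climate, terrain, params)
    monitors = syn.sample_monitors(region, oracle, n_sites=cfg.monitors.n_sites,
                                   chemicals=cfg.chemicals, noise_cv=cfg.monitors.noise_cv,
                                   seed=cfg.seed + 4)
    pio.write_table(ctx.path("monitors.csv"), monitors)

    truth_exp = syn.true_area_exposures(region, oracle, cfg.chemicals,
                                        region.years, cell_m=cfg.cell_m)
    tracts = syn.generate_tracts(region, seed=cfg.seed + 5)
    pio.write_table(ctx.path("tracts.csv"), tracts)
    outcomes, truth = syn.generate_outcomes(
        region, truth_exp, effects_per_iqr=cfg.outcomes.effects_per_iqr,
        noise_sd=cfg.outcomes.noise_sd, baseline_rate=cfg.outcomes.baseline_rate,
        seed=cfg.seed + 6, tract_table=tracts)
    pio.write_table(ctx.path("outcomes.csv"), outcomes)
    truth.to_json(ctx.path("truth.json"))
    ctx._cache.update(inventory=inventory, climate=climate, terrain=terrain)
    outs = ["small_areas.geojson", "tracts.geojson", "facilities.csv", "terrain.asc",
            "monitors.csv", "tracts.csv", "outcomes.csv", "truth.json"]
    outs += sorted(os.path.join("climate", f) for f in os.listdir(ctx.path("climate")))
    return outs


def _stage_features(ctx: _Context) -> list[str]:
    monitors = ctx.monitors()
    sites = monitors[["site_id", "x", "y"]].drop_duplicates("site_id")
    receptors = sites.rename(columns={"site_id": "receptor_id"})
    tables = []
    for chem in ctx.cfg.chemicals:
        for year in ctx.cfg.region.years:
            tables.append(build_feature_table(ctx.inventory(), ctx.climate(),
                                              ctx.terrain(), receptors, chem, int(year)))
    pio.write_table(ctx.path("features.csv"), pd.concat(tables, ignore_index=True))
    return ["features.csv"]


def _models_dir(ctx) -> str:
    d = ctx.path("models")
    os.makedirs(d, exist_ok=True)
    return d


def _stage_train(ctx: _Context) -> list[str]:
    feats = ctx.features()
    monitors = ctx.monitors()
    outs = []
    _models_dir(ctx)
    for i, chem in enumerate(ctx.cfg.chemicals):
        ft = feats[feats["chemical"] == chem]
        rec = monitors[monitors["chemical"] == chem]
        tc = ctx.train_config(seed_offset=10 + i)
        net = train(ft, rec, tc)
        if ctx.cfg.fnn.run_prune:
            net = prune(net, ft, rec,
                        PruneSchedule(fractions=ctx.cfg.fnn.prune_fractions,
                                      retrain_epochs=ctx.cfg.fnn.prune_retrain_epochs,
                                      tolerance=ctx.cfg.fnn.prune_tolerance), tc)
        rel = os.path.join("models", f"model_{chem}.json")
        net.save(ctx.path(rel))
        outs.append(rel)
    return outs


def _stage_cv(ctx: _Context) -> list[str]:
    if not ctx.cfg.fnn.run_cv:
        pd.DataFrame(columns=["chemical", "fold", "n_sites", "n_records",
                              "pearson", "spearman"]).to_csv(ctx.path("cv_report.csv"),
                                                             index=False)
        return ["cv_report.csv"]
    feats = ctx.features()
    monitors = ctx.monitors()
    frames = []
    for i, chem in enumerate(ctx.cfg.chemicals):
        rep = cross_validate(feats[feats["chemical"] == chem],
                             monitors[monitors["chemical"] == chem],
                             k=ctx.cfg.fnn.cv_folds, seed=ctx.cfg.seed + 20 + i,
                             config=ctx.train_config(seed_offset=20 + i))
        frames.append(rep.folds.assign(chemical=chem))
    pd.concat(frames, ignore_index=True).to_csv(ctx.path("cv_report.csv"), index=False)
    return ["cv_report.csv"]


def _stage_predict(ctx: _Context) -> list[str]:
    grid = GridSpec.for_region(ctx.region(), ctx.cfg.cell_m)
    outs = []
    os.makedirs(ctx.path("surfaces"), exist_ok=True)
    for chem in ctx.cfg.chemicals:
        net = PrunedFNN.load(ctx.path("models", f"model_{chem}.json"))
        for year in ctx.cfg.region.years:
            sfc = predict_surface(net, grid, ctx.inventory(), ctx.climate(),
                                  ctx.terrain(), chem, int(year))
            rel = os.path.join("surfaces", f"pei_{chem}_{year}.asc")
            write_esri_ascii(ctx.path(rel), sfc)
            outs.append(rel)
    return outs


def _stage_aggregate(ctx: _Context) -> list[str]:
    from .grids import read_esri_ascii

    ids, polys = ctx.areas()
    grid = GridSpec.for_region(ctx.region(), ctx.cfg.cell_m)
    assign = grid.assign_centroids(ids, polys)
    rows = []
    for chem in ctx.cfg.chemicals:
        for year in ctx.cfg.region.years:
            sfc = read_esri_ascii(ctx.path("surfaces", f"pei_{chem}_{year}.asc"))
            vals = aggregate_to_areas(sfc.data, assign, ids, grid=grid, areas=polys)
            rows.append(pd.DataFrame({"area_id": ids, "chemical": chem,
                                      "year": int(year), "pei": vals}))
    annual = pd.concat(rows, ignore_index=True)
    pio.write_table(ctx.path("exposures.csv"), exposure_table(annual))
    return ["exposures.csv"]


def _stage_covariates(ctx: _Context) -> list[str]:
    tracts = pio.read_table(ctx.path("tracts.csv"), ("tract_id",) + cov.TRACT_COUNT_COLUMNS)
    _, tract_polys, _ = read_geojson_polygons(ctx.path("tracts.geojson"))
    ids, polys = ctx.areas()
    table = cov.areal_interpolate(tracts, tract_polys, ids, polys)
    pio.write_table(ctx.path("covariates.csv"), table)
    return ["covariates.csv"]


def _stage_associate(ctx: _Context) -> list[str]:
    exp = pio.read_table(ctx.path("exposures.csv"), pio.EXPOSURE_COLUMNS)
    mean_exp = (exp[exp["year"] == "mean"]
                if exp["year"].dtype == object else exp[exp["year"].astype(str) == "mean"])
    wide = mean_exp.pivot(index="area_id", columns="chemical", values="pei")
    outcomes = pio.read_table(ctx.path("outcomes.csv"), pio.OUTCOME_COLUMNS)
    covs = pio.read_table(ctx.path("covariates.csv"), ("area_id",) + cov.ADJUSTMENT_COLUMNS)
    outcomes = outcomes.set_index("area_id").reindex(wide.index)
    covs = covs.set_index("area_id").reindex(wide.index).reset_index()
    results = assoc.run_associations(wide, outcomes.reset_index(), covs,
                                     fdr=ctx.cfg.association.fdr)
    assoc.report(results, csv_path=ctx.path("associations.csv"))

    y = outcomes["lbw_rate"].to_numpy(dtype=float)
    sig = [r.chemical for r in results if r.significant_after_bh]
    pairs = assoc.pearson_screen(wide, ctx.cfg.association.corr_threshold)
    rows = []
    for primary in sig:
        for a, b, r in pairs:
            if primary not in (a, b):
                continue
            other = b if a == primary else a
            tp = assoc.fit_two_pollutant(wide[primary], wide[other], y, covs,
                                         primary_name=primary, co_name=other)
            rows.append(tp.__dict__)
    pd.DataFrame(rows, columns=["chemical", "co_pollutant", "effect", "ci_low",
                                "ci_high", "p_value", "pearson_r"]).to_csv(
        ctx.path("two_pollutant.csv"), index=False)
    return ["associations.csv", "two_pollutant.csv"]


def _stage_report(ctx: _Context) -> list[str]:
    df = pio.read_table(ctx.path("associations.csv"),
                        ("chemical", "effect_pct_per_iqr", "ci_low", "ci_high", "p"))
    doc = {"associations": df.to_dict(orient="records"),
           "n_significant": int(df["significant"].astype(bool).sum())
           if "significant" in df else None}
    with open(ctx.path("report.json"), "w") as fh:
        json.dump(doc, fh, indent=1)
    return ["report.json"]


_STAGE_FNS = {
    "simulate": _stage_simulate,
    "features": _stage_features,
    "train": _stage_train,
    "cv": _stage_cv,
    "predict": _stage_predict,
    "aggregate": _stage_aggregate,
    "covariates": _stage_covariates,
    "associate": _stage_associate,
    "report": _stage_report,
}


def run_pipeline(config: pio.PipelineConfig, outdir: str,
                 upto: str = "report", resume: bool = True) -> str:
    """Run stages in order through ``upto``; completed stages are skipped.

    Returns the artifact directory.  The saved ``config.yaml`` and
    ``manifest.json`` make a finished run self-describing.
    """
    if upto not in STAGES:
        raise ValueError(f"unknown stage {upto!r}; choose from {STAGES}")
    os.makedirs(outdir, exist_ok=True)
    _setup_logging(outdir)
    config.to_yaml(os.path.join(outdir, "config.yaml"))
    manifest = _Manifest(outdir)
    ctx = _Context(config, outdir)
    for stage in STAGES[:STAGES.index(upto) + 1]:
        if resume and manifest.stage_done(stage, outdir):
            log.info("stage %-10s skipped (outputs up to date)", stage)
            continue
        t0 = time.perf_counter()
        outputs = _STAGE_FNS[stage](ctx)
        dt = time.perf_counter() - t0
        manifest.record(stage, outdir, outputs, dt)
        log.info("stage %-10s done in %6.1fs (%d file(s))", stage, dt, len(outputs))
    return outdir


def verify(outdir: str) -> list[str]:
    """Re-hash every file the manifest records; return mismatched paths."""
    manifest = _Manifest(outdir)
    bad = []
    for rel, digest in manifest.doc["files"].items():
        p = os.path.join(outdir, rel)
        if not os.path.exists(p) or _sha256(p) != digest:
            bad.append(rel)
    return bad
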