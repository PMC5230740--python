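"""End-to-end pipeline: synthesize -> history analyses -> grid -> models.

``run_pipeline`` executes every stage on a synthetic world (or ingested
data), writes a versioned results directory and returns a manifest listing
seeds, file paths, row counts and wall-clock per stage.  Outputs are
deterministic under a fixed config and seed; only the manifest records
timing and is therefore excluded from byte-identity.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as aio
from .config import WorldConfig
from .grid import (MODEL_PREDICTORS, collinearity_screen, filter_cells,
                   transform_table)
from .history import (censor_records, colonial_test,
                      country_colonisation_pressure, gdp_regression,
                      null_country_count, null_country_overlap,
                      null_family_counts, realm_chisq, split_quartiles)
from .sar import correlogram, lm_specification_tests, morans_i
from .selection import (SarEngine, compare_without_cp, forward_stepwise,
                        realm_holdout_cv, removal_impacts,
                        single_predictor_scan)
from .synthetic import synthesize
from .weights import build_weights

logger = logging.getLogger(__name__)

LAYOUT_VERSION = 1


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    layout_version: int = LAYOUT_VERSION
    stages: list = field(default_factory=list)

    def add(self, stage: str, outputs: dict, seconds: float):
        self.stages.append({"stage": stage, "outputs": outputs,
                            "wall_clock_s": round(seconds, 3)})
        logger.info("stage=%s done in %.2fs", stage, seconds)

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2, sort_keys=True,
                          default=str)


def _hash_config(config: WorldConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_pipeline(config, outdir, iterations: int = 1000) -> RunManifest:
    """Run every stage and write the results directory.

    ``config`` is a WorldConfig or a path to a TOML/YAML file.  The
    randomization-null iteration count is reduced relative to a full run via
    ``iterations`` to keep demo runs fast.
    """
    if not isinstance(config, WorldConfig):
        config = WorldConfig.from_file(config)
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config_hash=_hash_config(config), seed=config.seed)

    # -- stage 1: synthesize -------------------------------------------------
    t0 = time.perf_counter()
    world = synthesize(config)
    aio.write_records_csv(world.records, outdir / "records.csv")
    aio.write_ranges_geojson(world.ranges, outdir / "ranges.geojson",
                             grid=world.grid)
    manifest.add("synthesize", {
        "records.csv": len(world.records),
        "ranges.geojson": len(world.ranges)}, time.perf_counter() - t0)

    # -- stage 2: introduction-history analyses ------------------------------
    t0 = time.perf_counter()
    records = censor_records(world.records)
    split = split_quartiles(records)
    qrows = []
    for k, (q, span) in enumerate(zip(split.quartiles, split.spans), start=1):
        _, totals = country_colonisation_pressure(q)
        qrows.append({"quartile": k, "n_records": len(q),
                      "span_start": span[0], "span_end": span[1], **totals})
    pd.DataFrame(qrows).to_csv(outdir / "quartiles.csv", index=False)

    q1, q4 = split.quartiles[0], split.quartiles[3]
    nulls = {
        "q1_countries": null_country_count(
            records, q1, iterations=iterations, seed=config.seed).to_dict(),
        "q4_countries": null_country_count(
            records, q4, iterations=iterations, seed=config.seed + 1
        ).to_dict(),
        "q1_q4_overlap": null_country_overlap(
            records, q1, q4, iterations=iterations,
            seed=config.seed + 2).to_dict(),
    }
    (outdir / "nulls.json").write_text(json.dumps(nulls, indent=2,
                                                  sort_keys=True))

    avifauna = world.species_pool.rename(
        columns={"species_id": "species", "family_id": "family"})
    fam = null_family_counts(
        sorted({r.species_id for r in q1}), avifauna[["species", "family"]],
        iterations=iterations, seed=config.seed + 3)
    fam.table.to_csv(outdir / "family_test.csv", index=False)

    counts_q1 = {}
    for r in q1:
        counts_q1[r.country_id] = counts_q1.get(r.country_id, 0) + 1
    counts_q4 = {}
    for r in q4:
        counts_q4[r.country_id] = counts_q4.get(r.country_id, 0) + 1
    flags = world.colony_flags()
    g1900, g2000 = world.gdp_maps()
    w1, p1 = colonial_test(counts_q1, flags)
    w4, p4 = colonial_test(counts_q4, flags)
    gdp_hist = gdp_regression(counts_q1, g1900)
    gdp_mod = gdp_regression(counts_q4, g2000)

    realms = sorted({r for r in world.country_realm.values()})
    sp_realm = dict(zip(world.species_pool["species_id"],
                        world.species_pool["native_realm"]))
    hist_counts = [sum(1 for s in {r.species_id for r in q1}
                       if sp_realm[s] == rl) for rl in realms]
    mod_counts = [sum(1 for s in {r.species_id for r in q4}
                      if sp_realm[s] == rl) for rl in realms]
    chi2, chi2_p = realm_chisq(hist_counts, mod_counts, seed=config.seed + 4)

    history_report = {
        "colonial": {"q1": {"W": w1, "p": p1}, "q4": {"W": w4, "p": p4}},
        "gdp": {"q1": gdp_hist.__dict__, "q4": gdp_mod.__dict__},
        "realm_shift": {"chi2": chi2, "p_sim": chi2_p,
                        "realms": realms, "historic": hist_counts,
                        "modern": mod_counts},
    }
    (outdir / "history.json").write_text(
        json.dumps(history_report, indent=2, sort_keys=True, default=float))
    manifest.add("history", {"quartiles.csv": 4, "nulls.json": len(nulls),
                             "family_test.csv": len(fam.table),
                             "history.json": 3}, time.perf_counter() - t0)

    # -- stage 3: grid table -------------------------------------------------
    t0 = time.perf_counter()
    table = transform_table(world.grid_table)
    table, removals = filter_cells(table)
    aio.write_grid_csv(table, outdir / "grid_table.csv")
    corr, excluded, retained, high = collinearity_screen(
        table, [p for p in MODEL_PREDICTORS if p in table.columns]
        + [c for c in ("sqrt_temp_range", "log_elev_median")
           if c in table.columns])
    corr.to_csv(outdir / "collinearity.csv", float_format="%.6g")
    (outdir / "grid_ledger.json").write_text(json.dumps(
        {"removed": removals, "n_cells": len(table),
         "predictors_retained": retained, "predictors_excluded": excluded,
         "high_correlation_pairs": high}, indent=2, sort_keys=True))
    manifest.add("grid", {"grid_table.csv": len(table)},
                 time.perf_counter() - t0)

    # -- stage 4: spatial models ---------------------------------------------
    t0 = time.perf_counter()
    weights = build_weights(table, threshold_km=1.5 * config.cell_km)
    weights.to_csv(outdir / "weights.csv")
    predictors = [p for p in retained if p in table.columns]
    moran = {p: morans_i(table[p].to_numpy(dtype=float), weights,
                         permutations=199, seed=config.seed + 5).I
             for p in ["log1p_ASR"] + predictors}
    engine = SarEngine(table, weights, response="log1p_ASR", model="err")
    X, _ = engine.design(tuple(predictors))
    lm = lm_specification_tests(table["log1p_ASR"].to_numpy(dtype=float), X,
                                weights)
    manifest.add("spatial", {"weights.csv": int(weights.binary.nnz)},
                 time.perf_counter() - t0)

    # -- stage 5: model selection --------------------------------------------
    t0 = time.perf_counter()
    scan = single_predictor_scan(engine, predictors)
    scan.to_csv(outdir / "scan.csv", index=False)
    mam, trace = forward_stepwise(engine, predictors)
    impacts = removal_impacts(trace.terms, engine)
    impacts.to_csv(outdir / "removal_impacts.csv", index=False)
    nocp_res, nocp_trace, delta, newly, _ = compare_without_cp(
        engine, predictors)
    # realm size floor scaled to the world: 100 cells at study scale, less
    # for demo grids so at least two realms are always retained
    min_n = max(5, min(100, len(table) // 10))
    cv = realm_holdout_cv(table, predictors, min_n=min_n,
                          threshold_km=1.5 * config.cell_km)
    cv.folds.assign(terms=cv.folds["terms"].map(json.dumps)).to_csv(
        outdir / "cv_folds.csv", index=False)
    xcols = ["bin_lo_km", "bin_hi_km"]
    bins = np.arange(0, 6.5) * config.cell_km * 1.5
    cg_raw = correlogram(table["log1p_ASR"].to_numpy(dtype=float),
                         table[["x_km", "y_km"]].to_numpy(), bins)
    cg_res = correlogram(mam.resid, table[["x_km", "y_km"]].to_numpy(), bins)

    report = {
        "moran": moran,
        "lm_tests": lm.__dict__,
        "mam": mam.to_dict(),
        "mam_terms": trace.terms,
        "no_cp": {"aic_gap": delta, "terms": nocp_trace.terms,
                  "newly_admitted": newly},
        "cv_mean_rmse": cv.mean_rmse,
        "correlogram_first_bin": {"raw": float(cg_raw["moran_i"].iloc[0]),
                                  "mam_resid": float(cg_res["moran_i"].iloc[0])},
    }
    (outdir / "model_report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True, default=float))
    manifest.add("selection", {"model_report.json": 1,
                               "cv_folds.csv": len(cv.folds)},
                 time.perf_counter() - t0)

    (outdir / "manifest.json").write_text(manifest.to_json())
    return manifest
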