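"""End-to-end orchestration: simulate -> prep -> calibrate -> project -> risk.

Each stage derives its own RNG sub-seed from the pipeline seed, writes
its artifacts under the output directory and logs record counts, so the
whole run is reproducible bit-for-bit from (config, seed) and the audit
trail (raw -> deduplicated -> thinned -> train/test) is emitted for any
dataset. Stage subcommands in the CLI rerun the deterministic chain up
to the requested stage, so any stage can be regenerated from the
configuration alone.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .calibration import ENMCalibration
from .config import PipelineConfig
from .fileio import (write_occurrences, write_polygons, write_raster, write_stack)
from .grid import BinaryMap, EnvStack, GridSpec
from .maxent import bootstrap_final
from .occurrences import OccurrenceSet
from .postprocess import binarize, change_map, crop_to_calibration
from .preprocess import (deduplicate, environmental_coverage, filter_correlated,
                         jackknife_rank, split_train_test, thin_spatial)
from .rng import derive_seed
from .synthetic import (GaussianResponse, ScenarioShift, VirtualSpecies,
                        apply_scenario, make_congener, make_env_stack,
                        make_threat_layers, sample_occurrences, true_suitability)
from .threats import (RiskCategories, classify_risk, consistency_layer,
                      contact_zone, hfp_overlap, loss_map, maintained_map,
                      pa_overlap, pa_risk_summary, risk_index, zero_risk)

__all__ = ["run_pipeline", "STAGES"]

STAGES = ("simulate", "prep", "calibrate", "project", "risk")

log = logging.getLogger("enmrisk")


def _subset_stack(stack: EnvStack, names: list[str]) -> EnvStack:
    idx = [stack.names.index(n) for n in names]
    return EnvStack(stack.grid, list(names), stack.data[idx].copy(),
                    stack.mask.copy())


def _ensemble_mean(models, stack: EnvStack) -> np.ndarray:
    return np.mean([m.predict_stack(stack, output="logistic") for m in models],
                   axis=0)


def _suit_at(surface: np.ndarray, grid: GridSpec, occ: OccurrenceSet) -> np.ndarray:
    row, col = grid.cell_of(occ.coords[:, 0], occ.coords[:, 1])
    ok = row >= 0
    vals = surface[row[ok], col[ok]]
    return vals[np.isfinite(vals)]


def run_pipeline(config: PipelineConfig, outdir=None, through: str = "risk") -> dict:
    """Run the pipeline through the named stage; returns a results dict.

    Artifacts (rasters, CSV tables, model files, manifest) are written
    under ``outdir`` (default: ``config.outdir``).
    """
    if through not in STAGES:
        raise ValueError(f"unknown stage {through!r}; expected one of {STAGES}")
    last = STAGES.index(through)
    outdir = Path(outdir if outdir is not None else config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = config.seed
    state: dict = {"config": config, "outdir": outdir, "log": {}}

    _stage_simulate(config, seed, outdir, state)
    if last >= 1:
        _stage_prep(config, seed, outdir, state)
    if last >= 2:
        _stage_calibrate(config, seed, outdir, state)
    if last >= 3:
        _stage_project(config, seed, outdir, state)
    if last >= 4:
        _stage_risk(config, seed, outdir, state)

    manifest = {
        "package_version": __version__,
        "config_hash": config.content_hash(),
        "seed": seed,
        "stages_run": list(STAGES[: last + 1]),
        "log": state["log"],
        "versions": _versions(),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                     default=str))
    config.to_yaml(outdir / "config.yaml")
    state["manifest"] = manifest
    return state


def _versions() -> dict:
    import pandas
    import scipy
    import shapely
    import sklearn

    return {
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pandas.__version__,
        "scikit-learn": sklearn.__version__,
        "shapely": shapely.__version__,
    }


# ---------------------------------------------------------------------------

def _stage_simulate(config, seed, outdir, state) -> None:
    grid = GridSpec(config.n_rows, config.n_cols, config.origin_x,
                    config.origin_y, config.cell_size, config.crs_tag)
    stack = make_env_stack(grid, config.n_vars, config.corr_length,
                           seed=derive_seed(seed, "env"),
                           gradient_weight=config.gradient_weight)
    # the focal species responds to the first two predictors; the rest are noise
    curves = {"var1": GaussianResponse(0.5, 1.0)}
    if config.n_vars >= 2:
        curves["var2"] = GaussianResponse(-0.3, 1.2)
    species = VirtualSpecies(curves, name="focal")
    congener = make_congener(species, config.congener_breadth_scale,
                             config.congener_optimum_shift, name="congener")

    futures = {}
    for sc in config.scenarios:
        shift = ScenarioShift(
            additive={"var1": sc.additive},
            multiplicative={"var1": sc.multiplicative},
            gradient={"var1": sc.gradient},
            noise_sd=sc.noise_sd,
            name=sc.name,
        )
        futures[sc.name] = apply_scenario(
            stack, shift, seed=derive_seed(seed, f"scenario:{sc.name}"))

    occ = sample_occurrences(species, stack, config.n_presence,
                             seed=derive_seed(seed, "occurrences"))
    occ_congener = sample_occurrences(congener, stack,
                                      config.n_presence_congener,
                                      seed=derive_seed(seed, "occ-congener"))
    hfp, pas = make_threat_layers(grid, config.n_protected_areas,
                                  tuple(config.pa_size_range),
                                  seed=derive_seed(seed, "threats"))

    inputs = outdir / "inputs"
    inputs.mkdir(exist_ok=True)
    write_stack(stack, inputs / "current")
    for name, fut in futures.items():
        write_stack(fut, inputs / name)
    write_occurrences(occ, inputs / "occurrences.csv")
    write_occurrences(occ_congener, inputs / "occurrences_congener.csv")
    write_raster(inputs / "hfp.asc", hfp, grid)
    write_polygons(pas, inputs / "protected_areas.geojson")
    write_raster(inputs / "true_suitability.asc",
                 true_suitability(species, stack), grid)

    state.update(grid=grid, stack=stack, futures=futures, species=species,
                 congener=congener, occ_raw=occ, occ_congener_raw=occ_congener,
                 hfp=hfp, pas=pas)
    state["log"]["simulate"] = {
        "n_occurrences": len(occ), "n_occurrences_congener": len(occ_congener),
        "n_protected_areas": len(pas), "scenarios": list(futures),
    }
    log.info("simulate: %s", state["log"]["simulate"])


def _stage_prep(config, seed, outdir, state) -> None:
    stack = state["stack"]
    audit = {}
    occ = state["occ_raw"]
    audit["raw"] = len(occ)
    occ = deduplicate(occ)
    audit["deduplicated"] = len(occ)
    occ = thin_spatial(occ, config.thin_distance, seed=derive_seed(seed, "thin"))
    audit["thinned"] = len(occ)
    occ = split_train_test(occ, config.split_fraction,
                           seed=derive_seed(seed, "split"))
    audit["train"] = len(occ.train)
    audit["test"] = len(occ.test)
    coverage = environmental_coverage(occ, stack)

    gains = jackknife_rank(occ.train, stack, seed=derive_seed(seed, "jackknife"))
    selection = filter_correlated(stack, config.correlation_threshold,
                                  ranking=gains)
    selection.jackknife_gain = gains
    reduced = _subset_stack(stack, selection.kept)
    reduced_futures = {name: _subset_stack(fut, selection.kept)
                       for name, fut in state["futures"].items()}

    occ_c = thin_spatial(deduplicate(state["occ_congener_raw"]),
                         config.thin_distance,
                         seed=derive_seed(seed, "thin-congener"))

    prep = outdir / "prep"
    prep.mkdir(exist_ok=True)
    write_occurrences(occ, prep / "occurrences_clean.csv")
    write_occurrences(occ_c, prep / "occurrences_congener_clean.csv")
    selection.audit_table().to_csv(prep / "predictor_selection.csv", index=False)
    coverage.to_csv(prep / "train_coverage.csv")

    state.update(occ=occ, occ_congener=occ_c, selection=selection,
                 stack_reduced=reduced, futures_reduced=reduced_futures,
                 coverage=coverage)
    audit["kept_variables"] = selection.kept
    state["log"]["prep"] = audit
    log.info("prep: %s", audit)


def _stage_calibrate(config, seed, outdir, state) -> None:
    cal = ENMCalibration(
        rms=tuple(config.rms), feature_classes=config.feature_classes,
        E=config.eval_error, proc_iterations=config.proc_iterations,
        proc_sample_fraction=config.proc_sample_fraction,
        or_cut=config.omission_cut, daicc_cut=config.daicc_cut,
        seed=derive_seed(seed, "calibration"),
    )
    cal.fit(state["stack_reduced"], state["occ"])
    if cal.best_config_ is None:
        raise RuntimeError("calibrate stage failed: no candidate model was "
                           "selected; see calibration_results.csv")
    caldir = outdir / "calibration"
    caldir.mkdir(exist_ok=True)
    cal.results_.to_csv(caldir / "calibration_results.csv", index=False)
    state.update(calibration=cal, best_config=cal.best_config_)
    state["log"]["calibrate"] = {
        "n_candidates": len(cal.candidates_),
        "selection": cal.selection_report_,
        "best": cal.best_config_.label(),
    }
    log.info("calibrate: %s", state["log"]["calibrate"])


def _stage_project(config, seed, outdir, state) -> None:
    best = state["best_config"]
    stack = state["stack_reduced"]
    occ = state["occ"]

    boot = bootstrap_final(stack, occ, feature_classes=best.classes, rm=best.rm,
                           B=config.n_bootstrap,
                           seed=derive_seed(seed, "bootstrap"))
    current_suit = boot.mean
    train_suits = _suit_at(current_suit, stack.grid, occ)
    current_map = binarize(current_suit, stack.grid, train_suits,
                           E=config.binarize_error, mask=stack.mask,
                           provenance={"model": best.label(), "scenario": "current"})

    boot_c = bootstrap_final(stack, state["occ_congener"],
                             feature_classes="lq", rm=1.0, B=config.n_bootstrap,
                             seed=derive_seed(seed, "bootstrap-congener"))
    congener_suit = boot_c.mean
    congener_train = _suit_at(congener_suit, stack.grid, state["occ_congener"])
    congener_map = binarize(congener_suit, stack.grid, congener_train,
                            E=config.binarize_error, mask=stack.mask,
                            provenance={"model": "congener-lq-rm1",
                                        "scenario": "current"})

    future_maps, congener_future_maps, change_rows = {}, {}, []
    projdir = outdir / "projection"
    projdir.mkdir(exist_ok=True)
    for name, fut in state["futures_reduced"].items():
        suit = _ensemble_mean(boot.models, fut)
        fmap = crop_to_calibration(
            binarize(suit, fut.grid, train_suits, E=config.binarize_error,
                     mask=fut.mask,
                     provenance={"model": best.label(), "scenario": name}),
            stack.mask)
        future_maps[name] = fmap
        suit_c = _ensemble_mean(boot_c.models, fut)
        congener_future_maps[name] = crop_to_calibration(
            binarize(suit_c, fut.grid, congener_train, E=config.binarize_error,
                     mask=fut.mask,
                     provenance={"model": "congener", "scenario": name}),
            stack.mask)
        ch = change_map(current_map, fmap)
        change_rows.append({
            "scenario": name, "gained_pct": ch.gained_pct,
            "lost_pct": ch.lost_pct, "maintained_pct": ch.maintained_pct,
            "overlap_index": ch.overlap, "union_cells": ch.union_cells,
        })
        write_raster(projdir / f"suitability_{name}.asc", suit, fut.grid,
                     fut.mask)
        write_raster(projdir / f"egd_{name}.asc",
                     fmap.values.astype(float), fut.grid, fmap.mask)

    write_raster(projdir / "suitability_current.asc", current_suit, stack.grid,
                 stack.mask)
    write_raster(projdir / "egd_current.asc",
                 current_map.values.astype(float), stack.grid, current_map.mask)
    boot.models[0].to_json(projdir / "final_model_replicate1.json")
    changes = pd.DataFrame(change_rows)
    changes.to_csv(projdir / "range_change.csv", index=False)

    state.update(bootstrap=boot, current_suit=current_suit,
                 current_map=current_map, future_maps=future_maps,
                 congener_map=congener_map,
                 congener_future_maps=congener_future_maps, changes=changes)
    state["log"]["project"] = {
        "threshold": current_map.provenance["threshold"],
        "current_cells": current_map.n_present,
        "future_cells": {k: v.n_present for k, v in future_maps.items()},
    }
    log.info("project: %s", state["log"]["project"])


def _stage_risk(config, seed, outdir, state) -> None:
    current = state["current_map"]
    futures: dict[str, BinaryMap] = state["future_maps"]
    hfp, pas = state["hfp"], state["pas"]
    riskdir = outdir / "risk"
    riskdir.mkdir(exist_ok=True)

    threat_rows = []
    for name, m in {"current": current, **futures}.items():
        prop_hfp, area_hfp = hfp_overlap(m, hfp, cut=config.hfp_cut,
                                         cell_area=config.cell_size**2)
        threat_rows.append({
            "scenario": name,
            "hfp_overlap_pct": 100 * prop_hfp,
            "hfp_area": area_hfp,
            "pa_overlap_pct": 100 * pa_overlap(m, pas),
        })
    threat_df = pd.DataFrame(threat_rows)

    contact_rows, contact_maps, maintained_maps, loss_maps = [], [], [], []
    czone_current, prop_current = contact_zone(current, state["congener_map"])
    contact_rows.append({"scenario": "current",
                         "contact_pct": 100 * prop_current})
    for name, fmap in futures.items():
        cz, prop = contact_zone(fmap, state["congener_future_maps"][name])
        contact_rows.append({"scenario": name, "contact_pct": 100 * prop})
        contact_maps.append(cz)
        maintained_maps.append(maintained_map(current, fmap))
        loss_maps.append(loss_map(current, fmap))
    contact_df = pd.DataFrame(contact_rows)

    loss_counts = consistency_layer(loss_maps)
    contact_counts = consistency_layer(contact_maps)
    zr = zero_risk(maintained_maps, contact_maps)
    rmap = risk_index(loss_counts, contact_counts, current.grid,
                      n_scenarios=len(futures), w_loss=config.w_loss,
                      w_contact=config.w_contact, scale=config.risk_scale,
                      zero_risk_mask=zr.presence, valid_mask=current.mask)
    cats = RiskCategories(tuple(config.risk_low), tuple(config.risk_moderate),
                          config.risk_high_min)
    codes, proportions = classify_risk(rmap, cats)
    overall_pa, pa_table = pa_risk_summary(rmap, pas, cats,
                                           cell_area=config.cell_size**2)

    write_raster(riskdir / "risk_index.asc", rmap.risk.astype(float),
                 current.grid, rmap.valid_mask)
    write_raster(riskdir / "risk_category.asc", codes.astype(float),
                 current.grid, rmap.valid_mask)
    write_raster(riskdir / "zero_risk.asc", zr.values.astype(float),
                 current.grid)
    threat_df.to_csv(riskdir / "threat_overlaps.csv", index=False)
    contact_df.to_csv(riskdir / "contact_zones.csv", index=False)
    pa_table.to_csv(riskdir / "pa_risk_table.csv", index=False)
    at_risk = rmap.valid_mask & (rmap.risk > 0)
    risk_summary = {
        "n_scenarios": len(futures),
        "risk_min_positive": float(rmap.risk[at_risk].min()) if at_risk.any()
        else float("nan"),
        "risk_max": float(rmap.risk[at_risk].max()) if at_risk.any()
        else float("nan"),
        "zero_risk_cells": int(zr.n_present),
        "at_risk_cells": int(at_risk.sum()),
        "category_proportions": proportions,
        "pa_summary": overall_pa,
    }
    (riskdir / "risk_summary.json").write_text(
        json.dumps(risk_summary, indent=1, default=float))

    state.update(risk_map=rmap, risk_codes=codes, zero_risk_map=zr,
                 threat_table=threat_df, contact_table=contact_df,
                 pa_table=pa_table, risk_summary=risk_summary)
    state["log"]["risk"] = {k: v for k, v in risk_summary.items()
                            if k not in ("category_proportions", "pa_summary")}
    log.info("risk: %s", state["log"]["risk"])
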