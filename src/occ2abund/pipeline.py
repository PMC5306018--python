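"""End-to-end orchestration of the two-stage abundance pipeline.

Stages communicate only through files under a working directory, so each
stage is independently runnable and testable:

    workdir/
      config.yaml            frozen run configuration
      sim/                   synthetic landscape, surveys, abundance samples
      prep/                  presence–absence table, pruned covariate stack
      stage1/                per-species occupancy maps + model score table
      stage2/                harmonized records, CV reports, abundance maps
      manifest.json          provenance: seeds, counts at every filter

All randomness derives from the configured seed; rerunning a stage with the
same config reproduces its outputs bit for bit.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import abundance as ab
from . import harmonize as hz
from . import occurrence as occ
from . import sdm
from .config import PipelineConfig
from .covariates import PruneReport, extract_site_covariates, prune_correlated
from .grids import CovariateStack, read_map, read_stack, write_map, write_stack
from .synthetic import (TETRAD, gen_covariate_stack, gen_virtual_species,
                        sample_abundance, sample_occurrences)


def _species_seed(config: PipelineConfig, sp_index: int, repeat: int) -> int:
    return (config.seed * 100003 + sp_index * 1009 + repeat * 7 + 11) % (2 ** 31)


def _update_manifest(workdir: Path, key: str, payload: dict) -> None:
    path = workdir / "manifest.json"
    manifest = json.loads(path.read_text()) if path.exists() else {}
    manifest[key] = payload
    path.write_text(json.dumps(manifest, indent=1, sort_keys=True))


def simulate(config: PipelineConfig, workdir) -> None:
    """Generate the landscape, truth surfaces, surveys and abundance samples."""
    workdir = Path(workdir)
    sim = workdir / "sim"
    sim.mkdir(parents=True, exist_ok=True)
    config.to_yaml(workdir / "config.yaml")

    stack = gen_covariate_stack(config.landscape)
    truth = gen_virtual_species(stack, config.landscape)
    write_stack(sim / "stack.tif", stack)

    grid = config.landscape.grid
    truth_stack = CovariateStack(grid)
    for i, sp in enumerate(truth.species):
        truth_stack.add_layer(f"occupancy_{sp}", truth.occupancy_surface[i])
        truth_stack.add_layer(f"realized_{sp}",
                              truth.realized_occurrence[i].astype(float))
        truth_stack.add_layer(f"abundance_{sp}", truth.abundance_surface[i])
    for name, layer in truth.cover_surfaces.items():
        truth_stack.add_layer(name, layer)
    truth_stack.add_layer("woodland_fraction", truth.woodland_fraction)
    truth_stack.add_layer("linear_fraction", truth.linear_fraction)
    write_stack(sim / "truth.tif", truth_stack)
    np.savetxt(sim / "interaction_matrix.csv", truth.interaction_matrix,
               delimiter=",")

    records, log = sample_occurrences(truth, config.effort, seed=config.seed)
    records.to_csv(sim / "records.csv", index=False)
    log.to_csv(sim / "survey_log.csv", index=False)

    patch, plot = sample_abundance(truth, config.n_patch_source,
                                   config.n_plot_source, config.noise_sd,
                                   seed=config.seed)
    patch.to_csv(sim / "patch_records.csv", index=False)
    plot.to_csv(sim / "plot_records.csv", index=False)
    _update_manifest(workdir, "simulate", {
        "seed": config.seed, "n_records": len(records), "n_surveys": len(log),
        "n_patch_records": len(patch), "n_plot_records": len(plot)})


def prep_occurrence(config: PipelineConfig, workdir) -> pd.DataFrame:
    """Raw records + survey log -> presence–absence table (CSV)."""
    workdir = Path(workdir)
    prep = workdir / "prep"
    prep.mkdir(parents=True, exist_ok=True)
    records = pd.read_csv(workdir / "sim" / "records.csv")
    log = pd.read_csv(workdir / "sim" / "survey_log.csv")

    simplified = occ.simplify_records(records, window=config.year_window)
    well = occ.identify_well_surveyed(log, min_surveys=config.min_surveys,
                                      min_species=config.min_species,
                                      window=config.year_window)
    all_tetrads = sorted(set(simplified["tetrad_id"]) | well)
    tx, ty = occ.parse_tetrad_id(all_tetrads)
    grid = config.landscape.grid
    size = grid.cell_size * TETRAD
    coords = pd.DataFrame({"tetrad_id": all_tetrads,
                           "easting": (tx + 0.5) * size + grid.x0,
                           "northing": (ty + 0.5) * size + grid.y0})
    table = occ.build_presence_absence(simplified, well, config.species, coords)
    table.to_csv(prep / "pa_table.csv", index=False)
    _update_manifest(workdir, "prep_occurrence", {
        "records_in": len(records), "tetrad_level": len(simplified),
        "well_surveyed": len(well), "pa_rows": len(table)})
    return table


def prep_covariates(config: PipelineConfig, workdir) -> CovariateStack:
    """Prune the covariate stack by the correlation rule; write report."""
    workdir = Path(workdir)
    prep = workdir / "prep"
    prep.mkdir(parents=True, exist_ok=True)
    stack = read_stack(workdir / "sim" / "stack.tif")
    report = PruneReport()
    pruned = prune_correlated(stack, threshold=config.correlation_threshold,
                              report=report)
    write_stack(prep / "pruned_stack.tif", pruned)
    report.to_frame().to_csv(prep / "prune_report.csv", index=False)
    _update_manifest(workdir, "prep_covariates", {
        "layers_in": len(stack.names), "layers_out": len(pruned.names),
        "removed": [r["removed"] for r in report.rows]})
    return pruned


def run_stage1(config: PipelineConfig, workdir) -> dict[str, np.ndarray]:
    """Fit, score, select, screen and ensemble SDMs for every species.

    Selection scores come from the 70/30 runs; the surviving members are then
    refitted on 100% of the rows before the final map prediction. Species
    with fewer than one presence or one absence (or too few rows to split)
    are skipped with a logged reason. Returns {species: occupancy map}.
    """
    workdir = Path(workdir)
    out = workdir / "stage1"
    out.mkdir(parents=True, exist_ok=True)
    table = pd.read_csv(workdir / "prep" / "pa_table.csv")
    stack = read_stack(workdir / "prep" / "pruned_stack.tif")
    categorical = stack.categorical_names()
    cell_features = stack.as_table()

    score_rows = []
    skipped = {}
    maps = {}
    n_fitted = 0
    for sp_i, sp in enumerate(config.species):
        rows = table[table[sp].notna()].reset_index(drop=True)
        y = rows[sp].to_numpy(dtype=int)
        if len(rows) < 10 or np.unique(y).size < 2:
            skipped[sp] = (f"{len(rows)} usable rows, "
                           f"{int(y.sum())} presences — cannot fit")
            continue
        feats = extract_site_covariates(stack, rows["easting"].to_numpy(),
                                        rows["northing"].to_numpy())
        feats = feats[stack.names]
        fitted: list[sdm.FittedSDM] = []
        for repeat in range(config.repeats):
            seed = _species_seed(config, sp_i, repeat)
            train, test = split_data_for(y, config.split_fraction, seed)
            if train is None:
                continue
            for alg in config.algorithms:
                model = sdm.fit_algorithm(
                    alg, feats.iloc[train], y[train], categorical=categorical,
                    hyperparameters=config.hyperparameters.get(alg),
                    repeat=repeat, seed=seed)
                model.train_idx, model.test_idx = train, test
                sdm.score_model(model, feats.iloc[test], y[test])
                fitted.append(model)
                n_fitted += 1
        selected = sdm.select_models(fitted, gap=config.selection_gap,
                                     fallback_k=config.fallback_k)
        final = sdm.reject_inconsistent(
            selected, cell_features[stack.names],
            deviation_threshold=config.deviation_threshold)
        # refit survivors on 100% of the data; keep their 70/30 scores
        refitted = []
        for m in final:
            r = sdm.fit_algorithm(m.algorithm, feats, y, categorical=categorical,
                                  hyperparameters=config.hyperparameters.get(
                                      m.algorithm),
                                  repeat=m.repeat, seed=m.seed)
            r.score = m.score
            refitted.append(r)
        ensemble = sdm.build_ensemble(refitted)
        occupancy = sdm.predict_occupancy(ensemble, stack)
        maps[sp] = occupancy
        write_map(out / f"occupancy_{sp}.tif", stack.grid, occupancy)
        for m in fitted:
            score_rows.append({
                "species": sp, "algorithm": m.algorithm, "repeat": m.repeat,
                "seed": m.seed, "roc": m.score.roc_auc, "tss": m.score.tss,
                "tss_threshold": m.score.tss_threshold,
                "selected": m.selected, "rejected": m.rejected})
    scores = pd.DataFrame(score_rows)
    scores.to_csv(out / "scores.csv", index=False)
    _update_manifest(workdir, "stage1", {
        "n_fitted_models": n_fitted, "n_species_mapped": len(maps),
        "skipped": skipped, "repeats": config.repeats,
        "algorithms": list(config.algorithms)})
    return maps


def split_data_for(y: np.ndarray, fraction: float, seed: int,
                   max_tries: int = 20):
    """70/30 split retried until both classes appear in the training part."""
    for t in range(max_tries):
        train, test = sdm.split_data(len(y), fraction, seed + 10007 * t)
        if np.unique(y[train]).size == 2 and np.unique(y[test]).size == 2:
            return train, test
    return None, None


def harmonize_abundance(config: PipelineConfig, workdir) -> pd.DataFrame:
    """Convert both raw abundance dialects to ha/km² using the woodland and
    linear-feature layers; write the harmonized record table."""
    workdir = Path(workdir)
    out = workdir / "stage2"
    out.mkdir(parents=True, exist_ok=True)
    patch = pd.read_csv(workdir / "sim" / "patch_records.csv")
    plot = pd.read_csv(workdir / "sim" / "plot_records.csv")
    truth = read_stack(workdir / "sim" / "truth.tif")
    merged = hz.merge_sources(patch, plot, truth.layers["woodland_fraction"],
                              truth.layers["linear_fraction"])
    merged.to_csv(out / "harmonized.csv", index=False)
    _update_manifest(workdir, "harmonize", {
        "n_patch_in": len(patch), "n_plot_in": len(plot),
        "n_harmonized": len(merged)})
    return merged


def run_stage2(config: PipelineConfig, workdir) -> dict[str, np.ndarray]:
    """Per-species abundance forests: fold-rule gate -> fit -> CV -> map."""
    workdir = Path(workdir)
    out = workdir / "stage2"
    out.mkdir(parents=True, exist_ok=True)
    merged = pd.read_csv(out / "harmonized.csv")
    truth = read_stack(workdir / "sim" / "truth.tif")
    cover = {c: truth.layers[c] for c in ab.COVER_NAMES}

    occupancy = {}
    for sp in config.species:
        path = workdir / "stage1" / f"occupancy_{sp}.tif"
        if not path.exists():
            raise FileNotFoundError(f"missing stage-1 occupancy map for {sp}: {path}")
        _, occupancy[sp] = read_map(path)

    cv_rows, refusal_rows = [], []
    maps = {}
    for sp_i, sp in enumerate(config.species):
        recs = merged[merged["species"] == sp]
        seed = _species_seed(config, sp_i, 0) + 1
        features_all = ab.assemble_features(occupancy, cover, sp)
        by_cell = features_all.set_index("cell_id")
        usable = recs[recs["cell_id"].isin(by_cell.index)]
        feats = by_cell.loc[usable["cell_id"].to_numpy()].reset_index()
        y = usable["cover"].to_numpy(dtype=float)
        n_nonzero = int(np.count_nonzero(y))
        k = ab.choose_fold_count(n_nonzero, per_fold=config.per_fold,
                                 max_k=config.max_k,
                                 min_nonzero=config.min_nonzero)
        if isinstance(k, ab.FoldRefusal):
            refusal_rows.append({"species": sp, "n_nonzero": k.n_nonzero,
                                 "reason": k.reason})
            continue
        report = ab.cross_validate(feats, y, k, focal=sp,
                                   hyperparameters=config.rf_params, seed=seed)
        model = ab.fit_abundance_rf(feats, y, sp,
                                    hyperparameters=config.rf_params, seed=seed)
        importance = ab.variable_importance(model, feats, y, seed=seed)
        importance.to_csv(out / f"importance_{sp}.csv", index=False)
        amap = ab.predict_abundance_map(model, occupancy, cover,
                                        zero_cutoff=config.zero_cutoff)
        maps[sp] = amap
        write_map(out / f"abundance_{sp}.tif", truth.grid, amap)
        obs_pred = pd.DataFrame({"cell_id": feats["cell_id"], "observed": y,
                                 "predicted": model.predict(feats)})
        obs_pred.to_csv(out / f"obs_vs_pred_{sp}.csv", index=False)
        cv_rows.append({"species": sp, "k": report.k, "n_rows": len(y),
                        "n_nonzero": n_nonzero,
                        "rmse": report.pooled_rmse, "mae": report.pooled_mae,
                        "r_squared": report.r_squared,
                        "r_squared_caveat": report.r_squared_caveat,
                        "seed": seed})
    pd.DataFrame(cv_rows).to_csv(out / "cv_reports.csv", index=False)
    pd.DataFrame(refusal_rows, columns=["species", "n_nonzero", "reason"]) \
        .to_csv(out / "refusals.csv", index=False)
    (out / "cv_reports.json").write_text(json.dumps(cv_rows, indent=1))
    _update_manifest(workdir, "stage2", {
        "n_modeled": len(cv_rows), "n_refused": len(refusal_rows),
        "refused": [r["species"] for r in refusal_rows]})
    return maps


def run_all(config: PipelineConfig, workdir) -> None:
    """Figure-style orchestration: simulate -> prep -> stage 1 -> harmonize
    -> stage 2, all under one seed set."""
    simulate(config, workdir)
    prep_occurrence(config, workdir)
    prep_covariates(config, workdir)
    run_stage1(config, workdir)
    harmonize_abundance(config, workdir)
    run_stage2(config, workdir)
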