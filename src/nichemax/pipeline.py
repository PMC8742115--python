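"""End-to-end pipeline: data → selection → fit → diagnostics → projection.

The pipeline mirrors the two-stage modelling workflow: occurrences are
deduplicated to the analysis grid; a first-stage RM subset of the
environmental layers is chosen from a background correlation sample; a
full maximum-entropy model is fitted and its variable diagnostics drive a
backward elimination to the smallest submodel keeping ≥ 99.5% of the full
training AUC; the reduced model is refitted and projected onto every
scenario stack; and each projection is summarized as a threshold-free
contraction/expansion table, an area-weighted delta histogram and a
variable-shift summary.  A JSON manifest records inputs, settings and
seeds so any run can be reproduced exactly.

Also hosts the synthetic recovery benchmark used by the test-suite and the
acceptance script: the same pipeline run against a landscape with a known
niche truth, scored by how well it recovers that truth.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from . import __version__
from .grid_io import (EnvStack, cell_areas, dedup_to_grid, read_env_stack,
                      write_ascii_grid, OccurrenceSet)
from .maxent_core import SuitabilityMap, fit_maxent, predict, sample_background
from .scenario_change import (change_accounting, change_histogram,
                              classify_suitability, net_change,
                              suitability_delta, variable_shift_summary)
from .synthetic_data import (DEFAULT_SCENARIO_SHIFTS, apply_scenario_shift,
                             calibrate_intercept, default_truth,
                             sample_presences, simulate_env, true_suitability)
from .variable_importance import rank_and_reduce, variable_metrics
from .variable_selection import background_correlation, select_subset

logger = logging.getLogger(__name__)

PAST_SCENARIO_HINTS = ("lgm", "mh", "past")

DEFAULT_CONFIG = {
    "seed": 0,
    "output_dir": "run",
    "synthetic": {
        "n_rows": 64,
        "n_cols": 64,
        "n_presences": 500,
        "scenarios": list(DEFAULT_SCENARIO_SHIFTS),
    },
    "model": {
        "n_background": 2000,
        "reg_multiplier": 1.0,
        "max_iter": 2500,
        "tol": 1e-5,
        "feature_classes": ["linear", "quadratic", "hinge"],
        "n_hinge_knots": 8,
    },
    "selection": {
        "k": None,          # first-stage RM subset size; None keeps all variables
        "n_corr_sample": 100_000,
        "auc_floor": 0.995,
    },
}


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def _scenario_direction(name: str) -> str:
    low = name.lower()
    return "past-to-current" if any(h in low for h in PAST_SCENARIO_HINTS) \
        else "current-to-future"


def _load_inputs(config: dict):
    """Return (current stack, {scenario: stack}, occurrences) per config."""
    if "synthetic" in config and config["synthetic"]:
        syn = config["synthetic"]
        seed = int(config["seed"])
        current = simulate_env(n_rows=syn["n_rows"], n_cols=syn["n_cols"], seed=seed)
        truth = calibrate_intercept(current, default_truth(seed))
        tmap = true_suitability(current, truth)
        occ = sample_presences(tmap, syn["n_presences"], seed=seed + 1)
        scenarios = {
            name: apply_scenario_shift(current, DEFAULT_SCENARIO_SHIFTS[name], name)
            for name in syn["scenarios"]
        }
        return current, scenarios, occ, truth
    paths = config["paths"]
    current = read_env_stack(sorted(Path(paths["current"]).glob("*.asc")), "current",
                             crs_tag=paths.get("crs_tag", "synthetic-planar"))
    scenarios = {}
    for name, directory in paths.get("scenarios", {}).items():
        files = sorted(Path(directory).glob("*.asc"))
        if not files:
            raise FileNotFoundError(f"no rasters found for scenario {name!r} in {directory}")
        scenarios[name] = read_env_stack(files, name,
                                         crs_tag=paths.get("crs_tag", "synthetic-planar"))
    occ = OccurrenceSet.from_csv(paths["occurrences"])
    return current, scenarios, occ, None


def run_pipeline(config: dict | None = None) -> Path:
    """Run the full analysis; returns the output run directory.

    ``config`` overrides :data:`DEFAULT_CONFIG` (nested merge).  Outputs:
    model JSON, per-scenario suitability grids (.asc), change tables,
    histograms and shift summaries (CSV), the variable-metrics table, and
    ``manifest.json`` with every input, setting and seed.
    """
    config = _merge(DEFAULT_CONFIG, config or {})
    out_dir = Path(config["output_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = int(config["seed"])
    mcfg, scfg = config["model"], config["selection"]

    stage = "load-inputs"
    try:
        current, scenarios, occ, truth = _load_inputs(config)
        if not scenarios:
            raise ValueError("no scenario stacks configured")

        stage = "dedup"
        occ = dedup_to_grid(occ, current.grid, current.nodata_mask)
        pres_cells = occ.cells()

        stage = "variable-selection"
        corr = background_correlation(current, scfg["n_corr_sample"], seed=seed + 10)
        k = scfg.get("k")
        if k and k < corr.p:
            subset = select_subset(corr, k)
            variables = subset.subset
            subset.to_frame().to_csv(out_dir / "rm_subset.csv", index=False)
        else:
            variables = corr.variables
            subset = None

        stage = "background-sample"
        bg_cells = sample_background(current, mcfg["n_background"], seed=seed + 20)
        presence = current.values_at(pres_cells, variables)
        background = current.values_at(bg_cells, variables)

        fit_kwargs = dict(
            feature_classes=tuple(mcfg["feature_classes"]),
            n_hinge_knots=mcfg["n_hinge_knots"],
            reg_multiplier=mcfg["reg_multiplier"],
            max_iter=mcfg["max_iter"],
            tol=mcfg["tol"],
        )
        stage = "full-fit"
        full_model = fit_maxent(presence, background, seed=seed, **fit_kwargs)

        stage = "variable-metrics"
        metrics = variable_metrics(full_model, presence, background,
                                   seed=seed + 30, **fit_kwargs)
        stage = "rank-and-reduce"
        selected, audit = rank_and_reduce(metrics, presence, background,
                                          auc_floor=scfg["auc_floor"],
                                          full_model=full_model, **fit_kwargs)
        metrics_out = metrics.copy()
        metrics_out["kept"] = [v in selected for v in metrics_out.index]
        metrics_out.to_csv(out_dir / "variable_metrics.csv", index_label="variable")
        (out_dir / "reduction_audit.json").write_text(json.dumps(audit, indent=2))

        stage = "final-fit"
        model = fit_maxent(presence[selected], background[selected], seed=seed, **fit_kwargs)
        model.to_json(out_dir / "model.json")

        stage = "projection"
        current_map = predict(model, current, "cloglog")
        write_ascii_grid(out_dir / "suitability_current.asc", current_map.grid,
                         current_map.values)
        areas = cell_areas(current.grid)
        class_map = classify_suitability(current_map)
        change_rows, net_rows = [], []
        for name in sorted(scenarios):
            stack = scenarios[name]
            smap = predict(model, stack, "cloglog")
            write_ascii_grid(out_dir / f"suitability_{name}.asc", smap.grid, smap.values)
            direction = _scenario_direction(name)
            if direction == "past-to-current":
                delta = suitability_delta(smap, current_map, direction)
            else:
                delta = suitability_delta(current_map, smap, direction)
            table = change_accounting(current_map, delta, areas, scenario=name)
            change_rows.append(table.to_frame())
            net_rows.append({"scenario": name, "direction": direction,
                             "total_C_1e3km2": table.total_contraction,
                             "total_E_1e3km2": table.total_expansion,
                             "net_1e3km2": net_change(table)})
            hist = change_histogram(delta, class_map, areas)
            hist.to_csv(out_dir / f"histogram_{name}.csv")
            shift = variable_shift_summary(current, stack, occ)
            shift.to_csv(out_dir / f"variable_shift_{name}.csv", index=False)
        pd.concat(change_rows, ignore_index=True).to_csv(
            out_dir / "change_tables.csv", index=False)
        pd.DataFrame(net_rows).to_csv(out_dir / "net_change.csv", index=False)

        stage = "manifest"
        manifest = {
            "version": __version__,
            "config": config,
            "seed": seed,
            "derived_seeds": {"correlation": seed + 10, "background": seed + 20,
                              "permutation": seed + 30},
            "n_occurrences_dedup": int(len(occ)),
            "variables_stage1": variables,
            "rm_value": None if subset is None else subset.rm_value,
            "variables_final": selected,
            "training": model.training,
            "scenarios": sorted(scenarios),
            "truth": None if truth is None else asdict(truth),
        }
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
    logger.info("pipeline complete: %s", out_dir)
    return out_dir


# ---------------------------------------------------------------------------
# Recovery benchmark


def run_recovery_benchmark(seed: int = 0, n_rows: int = 64, n_cols: int = 64,
                           n_presences: int = 500, n_background: int = 2000,
                           auc_floor: float = 0.995, fit_tol: float = 1e-5) -> dict:
    """Fit the model against a known synthetic truth and score the recovery.

    Returns a dict with the fitted model, the Spearman rank correlation of
    predicted vs true suitability over all cells, the variable-metrics
    table, the reduced variable set, and bookkeeping for the noise/decoy
    variables.
    """
    stack = simulate_env(n_rows=n_rows, n_cols=n_cols, seed=seed)
    truth = calibrate_intercept(stack, default_truth(seed))
    tmap = true_suitability(stack, truth)
    occ = sample_presences(tmap, n_presences, seed=seed + 1)
    occ = dedup_to_grid(occ, stack.grid, stack.nodata_mask)
    bg_cells = sample_background(stack, n_background, seed=seed + 2)
    presence = stack.values_at(occ.cells())
    background = stack.values_at(bg_cells)
    fit_kwargs = dict(reg_multiplier=1.0, max_iter=2500, tol=fit_tol)
    model = fit_maxent(presence, background, seed=seed, **fit_kwargs)
    pred = predict(model, stack, "cloglog")
    finite = np.isfinite(pred.values) & np.isfinite(tmap.values)
    rho = float(spearmanr(pred.values[finite], tmap.values[finite]).statistic)
    metrics = variable_metrics(model, presence, background, seed=seed + 3, **fit_kwargs)
    selected, audit = rank_and_reduce(metrics, presence, background,
                                      auc_floor=auc_floor, full_model=model, **fit_kwargs)
    noise_vars = [v for v in model.variables if v.startswith("NOISE")]
    return {
        "model": model,
        "stack": stack,
        "truth": truth,
        "truth_map": tmap,
        "presence": presence,
        "background": background,
        "occurrences": occ,
        "prediction": pred,
        "spearman": rho,
        "metrics": metrics,
        "selected": selected,
        "audit": audit,
        "informative_vars": truth.informative_vars,
        "noise_vars": noise_vars,
    }
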