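"""Variable diagnostics and second-stage backward selection.

Four complementary importance measures are computed for each environmental
variable of a fitted model:

* **percent contribution** — the optimizer's accepted gain increments,
  credited to the updated feature's source variable(s) and normalized to
  percentages.  Explicitly path-dependent: it describes the fitting
  trajectory, not the model alone.
* **permutation importance** — the drop in training AUC after permuting one
  variable's values jointly across presence and background rows through the
  *fixed* model, floored at zero and normalized to percentages.
* **jackknife gains** — refits without each variable ("without") and with
  each variable alone ("with only"), both reported as ratios to the
  full-model training gain.

The aggregate rank (mean of the four per-metric ranks) drives a backward
elimination that drops the worst-ranked variable while the refit keeps at
least ``auc_floor`` of the full model's training AUC; the ranking is frozen
from the full model and not recomputed between drops.
"""

from __future__ import annotations

import logging
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .maxent_core import MaxEntModel, auc, feature_matrix, fit_maxent

logger = logging.getLogger(__name__)


def percent_contribution(model: MaxEntModel) -> pd.Series:
    """Percent contribution per variable from the fit trace.

    Each positive gain increment is credited to the updated feature's
    source variable(s), split equally for two-variable product features,
    then normalized to sum to 100.
    """
    if not model.trace:
        raise ValueError("model has no fit trace; cannot compute percent contribution")
    credit = {v: 0.0 for v in model.variables}
    for j, dgain in model.trace:
        if dgain <= 0:
            continue
        srcs = model.features[j].source_vars
        for v in srcs:
            credit[v] += dgain / len(srcs)
    total = sum(credit.values())
    if total <= 0:
        raise ValueError("no positive gain increments in trace")
    return pd.Series({v: 100.0 * c / total for v, c in credit.items()}, name="percent_contribution")


def permutation_importance(model: MaxEntModel, presence: pd.DataFrame,
                           background: pd.DataFrame, seed: int | None = None,
                           reps: int = 1) -> pd.Series:
    """Permutation importance per variable, as percentages of the total drop.

    One shared permutation reshuffles a variable's column across the
    concatenated presence+background rows; the fixed model is re-evaluated
    and the training-AUC drop recorded (negative drops floored at zero).
    ``reps`` permutations are averaged.  A variable not used by any model
    feature scores exactly zero.
    """
    rng = np.random.default_rng(seed)
    m = len(presence)
    data = pd.concat([presence[model.variables], background[model.variables]],
                     ignore_index=True)
    base_scores = model.linear_predictor(data)
    base_auc = auc(base_scores[:m], base_scores[m:])
    used = {v for j, s in enumerate(model.features) if model.lambdas[j] != 0.0
            for v in s.source_vars}
    drops = {}
    for var in model.variables:
        if var not in used:
            drops[var] = 0.0
            continue
        acc = 0.0
        for _ in range(reps):
            perm = rng.permutation(len(data))
            shuffled = data.copy()
            shuffled[var] = data[var].to_numpy()[perm]
            scores = model.linear_predictor(shuffled)
            acc += max(0.0, base_auc - auc(scores[:m], scores[m:]))
        drops[var] = acc / reps
    total = sum(drops.values())
    if total <= 0:
        warnings.warn("no permutation produced an AUC drop; importances undefined, returning 0s")
        return pd.Series({v: 0.0 for v in drops}, name="permutation_importance")
    return pd.Series({v: 100.0 * d / total for v, d in drops.items()},
                     name="permutation_importance")


def jackknife(presence: pd.DataFrame, background: pd.DataFrame,
              full_model: MaxEntModel | None = None,
              **fit_kwargs) -> pd.DataFrame:
    """Leave-one-out and only-one jackknife training-gain ratios.

    Runs 2p refits (p = number of variables): each variable removed
    ("without") and each variable alone ("with only"); gains are reported
    as ratios to the full-model gain.
    """
    variables = list(presence.columns)
    if len(variables) < 2:
        raise ValueError("jackknife needs at least two variables")
    if full_model is None:
        full_model = fit_maxent(presence, background, **fit_kwargs)
    full_gain = full_model.training["gain"]
    if full_gain <= 0:
        raise ValueError("full-model gain is not positive; jackknife ratios undefined")
    rows = {}
    for var in variables:
        rest = [v for v in variables if v != var]
        m_without = fit_maxent(presence[rest], background[rest], **fit_kwargs)
        m_only = fit_maxent(presence[[var]], background[[var]], **fit_kwargs)
        rows[var] = {
            "jk_without": m_without.training["gain"] / full_gain,
            "jk_only": max(m_only.training["gain"], 0.0) / full_gain,
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def variable_metrics(model: MaxEntModel, presence: pd.DataFrame,
                     background: pd.DataFrame, seed: int | None = None,
                     perm_reps: int = 1, **fit_kwargs) -> pd.DataFrame:
    """Combined metrics table with per-metric and aggregate ranks.

    Rank direction: higher percent contribution, permutation importance and
    with-only gain mean more important (rank 1); for the "without" gain a
    LOWER ratio means the model misses the variable more, so rank 1 goes to
    the lowest ratio.  Ties share the mean rank.
    """
    pc = percent_contribution(model)
    pi = permutation_importance(model, presence, background, seed=seed, reps=perm_reps)
    jk = jackknife(presence, background, full_model=model, **fit_kwargs)
    df = pd.DataFrame({
        "percent_contribution": pc,
        "permutation_importance": pi,
        "jk_without": jk["jk_without"],
        "jk_only": jk["jk_only"],
    }).loc[model.variables]
    df["rank_contribution"] = rankdata(-df["percent_contribution"])
    df["rank_permutation"] = rankdata(-df["permutation_importance"])
    df["rank_jk_without"] = rankdata(df["jk_without"])
    df["rank_jk_only"] = rankdata(-df["jk_only"])
    df["aggregate_rank"] = df[[
        "rank_contribution", "rank_permutation", "rank_jk_without", "rank_jk_only",
    ]].mean(axis=1)
    return df


def rank_and_reduce(metrics: pd.DataFrame, presence: pd.DataFrame,
                    background: pd.DataFrame, auc_floor: float = 0.995,
                    full_model: MaxEntModel | None = None,
                    **fit_kwargs):
    """Backward elimination to the smallest submodel keeping the AUC floor.

    Variables are dropped one at a time in order of worst aggregate rank
    (frozen from the full model; ties broken by lower permutation
    importance, then by reverse variable name).  A drop is kept while the
    refit's training AUC stays at or above ``auc_floor ×`` the full model's
    training AUC.  Returns ``(selected_variables, audit_log)`` where the
    audit log records every attempted drop.  If even the full set cannot
    meet the floor (floor > 1), the full set is returned with a warning.
    """
    variables = list(metrics.index)
    if full_model is None:
        full_model = fit_maxent(presence[variables], background[variables], **fit_kwargs)
    full_auc = full_model.training["train_auc"]
    target = auc_floor * full_auc
    audit: list[dict] = []
    if full_auc < target:
        warnings.warn("AUC floor unreachable even with the full variable set")
        return variables, [{"step": 0, "kept": list(variables), "auc": full_auc,
                            "status": "floor unreachable; full set returned"}]
    # frozen drop order: worst aggregate rank first
    order = sorted(
        variables,
        key=lambda v: (-metrics.loc[v, "aggregate_rank"],
                       metrics.loc[v, "permutation_importance"],
                       tuple(-ord(c) for c in v)),
    )
    selected = list(variables)
    for step, var in enumerate(order, start=1):
        if len(selected) == 1:
            break
        candidate = [v for v in selected if v != var]
        refit = fit_maxent(presence[candidate], background[candidate], **fit_kwargs)
        cand_auc = refit.training["train_auc"]
        ok = cand_auc >= target
        audit.append({"step": step, "dropped": var, "kept": list(candidate),
                      "auc": cand_auc, "auc_ratio": cand_auc / full_auc,
                      "status": "dropped" if ok else "kept (floor violated)"})
        if ok:
            selected = candidate
        else:
            break
    logger.info("rank_and_reduce: %d -> %d variables at floor %.4f",
                len(variables), len(selected), auc_floor)
    return selected, audit


def response_curve(model: MaxEntModel, variable: str, n_points: int = 100):
    """Marginal response: cloglog suitability along one variable's range.

    The variable sweeps its training range while every other variable is
    held at its background mean.  Returns ``(x, suitability)`` arrays.
    """
    used = {v for s in model.features for v in s.source_vars}
    if variable not in model.variables or variable not in used:
        raise ValueError(f"variable {variable!r} is not used by the model")
    spec = next(s for s in model.features if variable in s.source_vars)
    which = spec.source_vars.index(variable)
    lo, hi = spec.vmin[which], spec.vmax[which]
    x = np.linspace(lo, hi, n_points)
    values = pd.DataFrame({
        v: np.full(n_points, model.background_means[v]) for v in model.variables
    })
    values[variable] = x
    return x, model.predict_cloglog(values)
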