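"""Presence-only maximum-entropy suitability model.

The model estimates a probability distribution q over landscape cells that
maximizes entropy subject to the fitted feature expectations staying close
to their presence-sample means.  Equivalently, it maximizes the
L1-regularized training gain

    G(λ) = mean_presence(λ·f) − log Σ_landscape exp(λ·f) + log N − Σ_j β_j |λ_j|

which is concave in the feature weights λ.  Feature classes are the usual
transformations of the raw environmental variables (linear, quadratic,
pairwise product, hinge, threshold), each min–max scaled to [0, 1] on the
training data and clamped to the training range on projection.  The
per-feature penalty is β_j = reg_multiplier · c_class · s_j / √m with s_j
the presence-sample standard deviation of feature j and m the presence
count.

Fitting uses cyclic coordinate-wise proximal (soft-threshold) ascent with a
Newton-style step and backtracking, so the gain is non-decreasing across
iterations and the L1 penalty is handled exactly.  The accepted per-feature
gain increments are recorded as a trace for percent-contribution
accounting.

Outputs: the raw distribution q(x) = exp(λ·f(x) − log Z), and the cloglog
suitability 1 − exp(−e^H · q(x)) with H the entropy of the fitted raw
distribution, which maps scores to [0, 1] monotonically.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import rankdata

from .grid_io import EnvStack, GridSpec

logger = logging.getLogger(__name__)

DEFAULT_FEATURE_CLASSES = ("linear", "quadratic", "hinge")
ALL_FEATURE_CLASSES = ("linear", "quadratic", "product", "hinge", "threshold")

#: Per-class base regularization constants (global multiplier applied on top).
CLASS_REG_BASE = {"linear": 1.0, "quadratic": 1.0, "product": 1.0,
                  "hinge": 0.5, "threshold": 1.0}


# ---------------------------------------------------------------------------
# Features


@dataclass(frozen=True)
class FeatureSpec:
    """One derived feature: class, source variable(s), knot, scaling range.

    ``vmin``/``vmax`` are the training min/max of each source variable;
    values are clamped to that range before the transform, so projections
    onto novel climates never extrapolate a feature beyond [0, 1].
    """

    feature_class: str
    source_vars: tuple[str, ...]
    vmin: tuple[float, ...]
    vmax: tuple[float, ...]
    knot: float | None = None
    orientation: str | None = None  # hinge: forward | reverse

    @property
    def name(self) -> str:
        base = "*".join(self.source_vars)
        if self.feature_class == "hinge":
            return f"hinge_{self.orientation}({base}@{self.knot:.6g})"
        if self.feature_class == "threshold":
            return f"thresh({base}>{self.knot:.6g})"
        return f"{self.feature_class}({base})"

    def _scaled(self, values: pd.DataFrame, which: int = 0) -> np.ndarray:
        var = self.source_vars[which]
        lo, hi = self.vmin[which], self.vmax[which]
        v = np.clip(values[var].to_numpy(dtype=float), lo, hi)
        span = hi - lo
        return (v - lo) / span if span > 0 else np.zeros(len(v))

    def evaluate(self, values: pd.DataFrame) -> np.ndarray:
        cls = self.feature_class
        if cls == "linear":
            return self._scaled(values)
        if cls == "quadratic":
            return self._scaled(values) ** 2
        if cls == "product":
            return self._scaled(values, 0) * self._scaled(values, 1)
        var = self.source_vars[0]
        lo, hi = self.vmin[0], self.vmax[0]
        v = np.clip(values[var].to_numpy(dtype=float), lo, hi)
        if cls == "hinge":
            if self.orientation == "forward":
                span = hi - self.knot
                return np.maximum(0.0, v - self.knot) / span if span > 0 else np.zeros(len(v))
            span = self.knot - lo
            return np.maximum(0.0, self.knot - v) / span if span > 0 else np.zeros(len(v))
        if cls == "threshold":
            return (v > self.knot).astype(float)
        raise ValueError(f"unknown feature class {cls!r}")


def build_features(values: pd.DataFrame,
                   classes: Sequence[str] = DEFAULT_FEATURE_CLASSES,
                   n_hinge_knots: int = 8,
                   knot_values: pd.DataFrame | None = None):
    """Expand raw variables into a feature basis.

    Returns ``(specs, matrix)``: the feature specifications (carrying the
    min–max normalization constants needed to re-evaluate them later with
    clamping) and the feature matrix over ``values``.  Hinge and threshold
    knots are placed at equal quantiles of ``knot_values`` (default: the
    same table), one forward and one reverse hinge per knot.  Zero-variance
    variables keep their (constant-zero) linear feature but skip nonlinear
    classes, with a warning.
    """
    classes = list(classes)
    if not classes:
        raise ValueError("at least one feature class must be enabled")
    unknown = set(classes) - set(ALL_FEATURE_CLASSES)
    if unknown:
        raise ValueError(f"unknown feature classes: {sorted(unknown)}")
    if knot_values is None:
        knot_values = values
    variables = list(values.columns)
    specs: list[FeatureSpec] = []
    vstats = {}
    for var in variables:
        v = values[var].to_numpy(dtype=float)
        if not np.all(np.isfinite(v)):
            raise ValueError(f"non-finite values in variable {var!r}")
        vstats[var] = (float(v.min()), float(v.max()))
        if v.min() == v.max() and set(classes) - {"linear"}:
            warnings.warn(f"variable {var!r} has zero variance; nonlinear features skipped")

    def mk(cls, vars_, **kw):
        return FeatureSpec(cls, tuple(vars_),
                           tuple(vstats[v][0] for v in vars_),
                           tuple(vstats[v][1] for v in vars_), **kw)

    for var in variables:
        lo, hi = vstats[var]
        constant = lo == hi
        if "linear" in classes:
            specs.append(mk("linear", [var]))
        if constant:
            continue
        if "quadratic" in classes:
            specs.append(mk("quadratic", [var]))
        if "hinge" in classes or "threshold" in classes:
            qs = np.linspace(0, 1, n_hinge_knots + 2)[1:-1]
            knots = np.unique(np.quantile(knot_values[var].to_numpy(dtype=float), qs))
            for knot in knots:
                if not lo < knot < hi:
                    continue
                if "hinge" in classes:
                    specs.append(mk("hinge", [var], knot=float(knot), orientation="forward"))
                    specs.append(mk("hinge", [var], knot=float(knot), orientation="reverse"))
                if "threshold" in classes:
                    specs.append(mk("threshold", [var], knot=float(knot)))
    if "product" in classes:
        for i, va in enumerate(variables):
            for vb in variables[i + 1:]:
                if vstats[va][0] == vstats[va][1] or vstats[vb][0] == vstats[vb][1]:
                    continue
                specs.append(mk("product", [va, vb]))
    matrix = feature_matrix(specs, values)
    return specs, matrix


def feature_matrix(specs: Sequence[FeatureSpec], values: pd.DataFrame) -> np.ndarray:
    missing = {v for s in specs for v in s.source_vars} - set(values.columns)
    if missing:
        raise KeyError(f"missing layer(s) for model features: {sorted(missing)}")
    if not specs:
        return np.zeros((len(values), 0))
    return np.column_stack([s.evaluate(values) for s in specs])


# ---------------------------------------------------------------------------
# Model


@dataclass
class MaxEntModel:
    """Fitted maximum-entropy model with everything needed to project it."""

    features: list[FeatureSpec]
    lambdas: np.ndarray
    betas: np.ndarray
    reg_multiplier: float
    logZ: float
    entropy: float
    variables: list[str]
    background_means: dict[str, float]
    training: dict
    trace: list[tuple[int, float]] = field(default_factory=list)

    def linear_predictor(self, values: pd.DataFrame) -> np.ndarray:
        return feature_matrix(self.features, values) @ self.lambdas

    def predict_raw(self, values: pd.DataFrame) -> np.ndarray:
        return np.exp(self.linear_predictor(values) - self.logZ)

    def predict_cloglog(self, values: pd.DataFrame) -> np.ndarray:
        return 1.0 - np.exp(-np.exp(self.entropy) * self.predict_raw(values))

    def predict_values(self, values: pd.DataFrame, transform: str = "cloglog") -> np.ndarray:
        if transform == "raw":
            return self.predict_raw(values)
        if transform == "cloglog":
            return self.predict_cloglog(values)
        raise ValueError(f"unknown transform {transform!r}")

    # -- serialization ------------------------------------------------------

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "features": [asdict(s) for s in self.features],
            "lambdas": self.lambdas.tolist(),
            "betas": self.betas.tolist(),
            "reg_multiplier": self.reg_multiplier,
            "logZ": self.logZ,
            "entropy": self.entropy,
            "variables": self.variables,
            "background_means": self.background_means,
            "training": self.training,
            "trace": [[int(j), float(g)] for j, g in self.trace],
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "MaxEntModel":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        payload = json.loads(text)
        feats = [
            FeatureSpec(s["feature_class"], tuple(s["source_vars"]),
                        tuple(s["vmin"]), tuple(s["vmax"]), s["knot"], s["orientation"])
            for s in payload["features"]
        ]
        return cls(
            features=feats,
            lambdas=np.asarray(payload["lambdas"], dtype=float),
            betas=np.asarray(payload["betas"], dtype=float),
            reg_multiplier=payload["reg_multiplier"],
            logZ=payload["logZ"],
            entropy=payload["entropy"],
            variables=payload["variables"],
            background_means=payload["background_means"],
            training=payload["training"],
            trace=[(int(j), float(g)) for j, g in payload["trace"]],
        )


@dataclass
class SuitabilityMap:
    """Per-cell suitability on a grid; NaN marks nodata."""

    grid: GridSpec
    values: np.ndarray
    transform: str = "cloglog"
    scenario: str = "current"
    model_id: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValueError("suitability values shape does not match grid")


# ---------------------------------------------------------------------------
# Sampling and evaluation


def sample_background(stack: EnvStack, n: int, seed: int | None = None) -> np.ndarray:
    """Uniform sample of unmasked cells without replacement, (k, 2) indices.

    If ``n`` exceeds the number of available cells, all cells are returned
    with a warning.  The sample is returned in row-major grid order, so it
    is reproducible and order-stable under a fixed seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    cells = stack.unmasked_cells()
    if len(cells) == 0:
        raise ValueError("stack is fully masked; cannot sample background")
    if n >= len(cells):
        if n > len(cells):
            warnings.warn(f"requested {n} background cells, only {len(cells)} available; using all")
        return cells
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(cells), size=n, replace=False)
    return cells[np.sort(idx)]


def auc(presence_scores, background_scores) -> float:
    """Rank-based AUC (Mann–Whitney U / (m·n)) with midrank tie handling.

    The probability that a random presence scores above a random background
    cell, ties counting one half.
    """
    p = np.asarray(presence_scores, dtype=float)
    b = np.asarray(background_scores, dtype=float)
    if len(p) == 0 or len(b) == 0:
        raise ValueError("both score sets must be non-empty")
    combined = np.concatenate([p, b])
    if np.all(combined == combined[0]):
        warnings.warn("all scores identical; AUC degenerate at 0.5")
        return 0.5
    ranks = rankdata(combined)
    u = ranks[: len(p)].sum() - len(p) * (len(p) + 1) / 2.0
    return float(u / (len(p) * len(b)))


# ---------------------------------------------------------------------------
# Fitting


def _gain(eta, pres_idx, lambdas, betas):
    n = len(eta)
    return float(eta[pres_idx].mean() - logsumexp(eta) + np.log(n)
                 - np.abs(lambdas) @ betas)


def fit_maxent(presence: pd.DataFrame, background: pd.DataFrame, *,
               feature_classes: Sequence[str] = DEFAULT_FEATURE_CLASSES,
               n_hinge_knots: int = 8,
               reg_multiplier: float = 1.0,
               max_iter: int = 2500,
               tol: float = 1e-5,
               seed: int | None = None,
               beta_override: float | np.ndarray | None = None,
               drop_duplicate_presences: bool = True) -> MaxEntModel:
    """Fit the maximum-entropy model (see module docstring).

    ``presence`` and ``background`` are tables of raw environmental values
    (one row per cell, one column per variable).  The normalization sample
    ("landscape") is the concatenation of the two.  Exact duplicate
    presence rows are dropped defensively (grid deduplication upstream
    should already have removed them; disable via
    ``drop_duplicate_presences`` for data where distinct cells can share
    identical values).  ``max_iter`` counts full coordinate cycles;
    convergence is declared when the relative gain change over a cycle
    falls below ``tol``.  ``beta_override`` replaces the computed
    per-feature penalties (0 gives the unregularized fit; used by oracles
    and tests).
    """
    if len(presence) == 0:
        raise ValueError("no presence records")
    if set(presence.columns) != set(background.columns):
        raise ValueError("presence and background tables must share columns")
    if drop_duplicate_presences:
        presence = presence.drop_duplicates().reset_index(drop=True)
    else:
        presence = presence.reset_index(drop=True)
    background = background.reset_index(drop=True)
    landscape = pd.concat([presence, background[presence.columns]], ignore_index=True)

    specs, F = build_features(landscape, feature_classes, n_hinge_knots,
                              knot_values=background)
    if not np.all(np.isfinite(F)):
        bad = [specs[j].name for j in np.nonzero(~np.isfinite(F).all(axis=0))[0]]
        raise ValueError(f"non-finite feature values: {bad}")
    n, d = F.shape
    m = len(presence)
    pres_idx = np.arange(m)
    pres_mean = F[pres_idx].mean(axis=0)

    if beta_override is not None:
        betas = np.broadcast_to(np.asarray(beta_override, dtype=float), (d,)).copy()
    else:
        s = F[pres_idx].std(axis=0)
        base = np.array([CLASS_REG_BASE[spec.feature_class] for spec in specs])
        betas = reg_multiplier * base * s / np.sqrt(m)

    lambdas = np.zeros(d)
    eta = np.zeros(n)
    gain = 0.0
    trace: list[tuple[int, float]] = []
    n_cycles = 0
    for cycle in range(max_iter):
        gain_start = gain
        for j in range(d):
            fj = F[:, j]
            w = np.exp(eta - eta.max())
            w /= w.sum()
            ef = float(w @ fj)
            grad = pres_mean[j] - ef
            lam = lambdas[j]
            bj = betas[j]
            if lam == 0.0 and abs(grad) <= bj:
                continue
            var = float(w @ (fj * fj)) - ef * ef
            h = max(var, 1e-12)
            z = lam + grad / h
            lam_new = np.sign(z) * max(abs(z) - bj / h, 0.0)
            delta = lam_new - lam
            if delta == 0.0:
                continue
            # backtrack to keep the concave gain non-decreasing
            for _ in range(50):
                trial_lam = lambdas.copy()
                trial_lam[j] = lam + delta
                trial_eta = eta + delta * fj
                trial_gain = _gain(trial_eta, pres_idx, trial_lam, betas)
                if trial_gain >= gain - 1e-12:
                    break
                delta *= 0.5
            else:
                continue
            if trial_gain > gain:
                trace.append((j, trial_gain - gain))
            lambdas[j] = lam + delta
            eta = trial_eta
            gain = trial_gain
        n_cycles = cycle + 1
        if abs(gain - gain_start) < tol * max(abs(gain), 1e-9):
            break

    logZ = float(logsumexp(eta))
    q = np.exp(eta - logZ)
    entropy = float(logZ - q @ eta)
    train_auc = auc(feature_matrix(specs, presence) @ lambdas,
                    feature_matrix(specs, background) @ lambdas)
    model = MaxEntModel(
        features=specs,
        lambdas=lambdas,
        betas=betas,
        reg_multiplier=reg_multiplier,
        logZ=logZ,
        entropy=entropy,
        variables=list(landscape.columns),
        background_means={c: float(background[c].mean()) for c in background.columns},
        training={
            "gain": gain,
            "train_auc": train_auc,
            "n_presence": int(m),
            "n_background": int(len(background)),
            "n_landscape": int(n),
            "max_iter": int(max_iter),
            "n_cycles": n_cycles,
            "tol": tol,
            "seed": seed,
        },
        trace=trace,
    )
    logger.info("fit_maxent: %d features, gain %.4f, training AUC %.4f (%d cycles)",
                d, gain, train_auc, n_cycles)
    return model


def predict(model: MaxEntModel, stack: EnvStack, transform: str = "cloglog") -> SuitabilityMap:
    """Project a fitted model onto a scenario stack.

    Features are clamped to their training ranges before evaluation, so
    climates outside the training envelope saturate rather than
    extrapolate.  Nodata cells propagate as NaN.
    """
    missing = set(model.variables) - set(stack.layer_names)
    if missing:
        raise KeyError(f"stack {stack.scenario!r} is missing layer(s): {sorted(missing)}")
    cells = stack.unmasked_cells()
    values = stack.values_at(cells, model.variables)
    out = np.full(stack.grid.shape, np.nan)
    out[cells[:, 0], cells[:, 1]] = model.predict_values(values, transform)
    return SuitabilityMap(stack.grid, out, transform, stack.scenario)
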