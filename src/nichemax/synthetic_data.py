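"""Synthetic landscapes with a known niche truth.

Every stage of the pipeline is exercised against data generated here:
spatially smooth, cross-correlated environmental fields on a regular grid;
per-scenario additive/multiplicative climate shifts (warming of the
temperature variables, drying of the precipitation variables, mirroring
the direction of change in the scenarios the pipeline targets); and
presence samples drawn from a known unimodal niche response,

    s(x) = logistic( a0 − Σ_j ((v_j(x) − opt_j) / tol_j)² )

over the informative variables only.  The intercept a0 is calibrated so
the landscape-mean suitability matches a target prevalence.  All
randomness is driven by recorded seeds, so generated stacks are
bitwise-reproducible.

The defaults define the package's recovery benchmark: a 64×64 planar grid
(1 km cells), six variables — three informative (BIO1, BIO9, BIO16), one
decoy correlated with an informative one (BIO18, r = 0.8 with BIO16) and
two pure-noise variables — 500 presences and 2,000 background cells.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
import json
from pathlib import Path

import numpy as np
from scipy import ndimage
from scipy.special import expit

import pandas as pd

from .grid_io import EnvStack, GridSpec, OccurrenceSet
from .maxent_core import SuitabilityMap

logger = logging.getLogger(__name__)

#: Affine mapping of standardized fields to plausible climate ranges
#: (mean, sd) per default variable; temperatures in °C, precipitation in mm.
DEFAULT_VALUE_RANGES = {
    "BIO1": (12.0, 5.0),
    "BIO9": (18.0, 6.0),
    "BIO16": (350.0, 120.0),
    "BIO18": (120.0, 60.0),
    "NOISE1": (0.0, 1.0),
    "NOISE2": (0.0, 1.0),
}

DEFAULT_VARIABLES = list(DEFAULT_VALUE_RANGES)


def default_correlation() -> np.ndarray:
    """Target cross-correlation of the default six fields.

    Mild BIO1–BIO9 correlation (collinear temperature summaries), a strong
    BIO16–BIO18 correlation making BIO18 a decoy for the informative
    BIO16, and independent noise variables.
    """
    p = len(DEFAULT_VARIABLES)
    C = np.eye(p)
    i = {v: k for k, v in enumerate(DEFAULT_VARIABLES)}
    C[i["BIO1"], i["BIO9"]] = C[i["BIO9"], i["BIO1"]] = 0.6
    C[i["BIO16"], i["BIO18"]] = C[i["BIO18"], i["BIO16"]] = 0.8
    return C


@dataclass
class SyntheticTruth:
    """Known niche response: per-variable (optimum, tolerance) on the logit scale."""

    response: dict[str, tuple[float, float]]
    intercept: float = 2.0
    prevalence: float = 0.15
    seeds: dict[str, int] = field(default_factory=lambda: {"field": 0, "presence": 1,
                                                           "background": 2})

    @property
    def informative_vars(self) -> list[str]:
        return list(self.response)

    def __post_init__(self) -> None:
        for var, (_, tol) in self.response.items():
            if tol == 0:
                raise ValueError(f"zero tolerance for variable {var!r}")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))


def default_truth(seed: int = 0) -> SyntheticTruth:
    """Default unimodal niche over the three informative variables.

    Optima sit inside but off-center of the generated value ranges so the
    response is unimodal over the landscape, with tolerances wide enough
    that a few hundred presences recover the niche shape.
    """
    return SyntheticTruth(
        response={"BIO1": (15.0, 4.0), "BIO9": (22.0, 6.0), "BIO16": (420.0, 150.0)},
        prevalence=0.15,
        seeds={"field": seed, "presence": seed + 1, "background": seed + 2},
    )


def simulate_env(n_rows: int = 64, n_cols: int = 64,
                 variables=None, correlation: np.ndarray | None = None,
                 smoothness: float = 4.0, seed: int | None = 0,
                 value_ranges: dict | None = None,
                 scenario: str = "synthetic-current") -> EnvStack:
    """Simulate spatially smooth, cross-correlated environmental fields.

    Per variable: white noise → Gaussian-kernel smoothing (``smoothness``
    in cells; 0 skips smoothing) → cross-variable mixing by the Cholesky
    factor of the target correlation → per-field standardization → affine
    mapping to the variable's climate range.  The grid is planar with 1 km
    cells so all downstream areas are exact.
    """
    if variables is None:
        variables = DEFAULT_VARIABLES
    variables = list(variables)
    p = len(variables)
    if p < 2:
        raise ValueError("need at least two variables")
    if correlation is None:
        correlation = default_correlation() if variables == DEFAULT_VARIABLES else np.eye(p)
    correlation = np.asarray(correlation, dtype=float)
    if correlation.shape != (p, p):
        raise ValueError("correlation shape does not match variable count")
    try:
        L = np.linalg.cholesky(correlation)
    except np.linalg.LinAlgError as exc:
        raise ValueError("target correlation matrix is not positive definite") from exc
    if value_ranges is None:
        value_ranges = DEFAULT_VALUE_RANGES
    rng = np.random.default_rng(seed)
    n = n_rows * n_cols
    fields = rng.standard_normal((p, n_rows, n_cols))
    if smoothness > 0:
        for k in range(p):
            fields[k] = ndimage.gaussian_filter(fields[k], smoothness, mode="reflect")
    flat = fields.reshape(p, n)
    flat = (flat - flat.mean(axis=1, keepdims=True)) / flat.std(axis=1, keepdims=True)
    mixed = L @ flat
    mixed = (mixed - mixed.mean(axis=1, keepdims=True)) / mixed.std(axis=1, keepdims=True)
    grid = GridSpec(n_rows=n_rows, n_cols=n_cols, origin_x=0.0, origin_y=n_rows * 1000.0,
                    cell_size_x=1000.0, cell_size_y=1000.0, crs_tag="synthetic-planar")
    layers = {}
    for k, var in enumerate(variables):
        mean, sd = value_ranges.get(var, (0.0, 1.0))
        layers[var] = mean + sd * mixed[k].reshape(n_rows, n_cols)
    return EnvStack(grid, layers, scenario)


#: Per-scenario shifts (offset, scale) per layer, emulating the direction of
#: change in the climate scenarios: past scenarios colder and wetter, future
#: scenarios warmer and drier, more severe along the pathway/time axis.
DEFAULT_SCENARIO_SHIFTS = {
    "synthetic-lgm": {"BIO1": (-5.0, 1.0), "BIO9": (-6.0, 1.0),
                      "BIO16": (0.0, 1.15), "BIO18": (0.0, 1.10)},
    "synthetic-mh": {"BIO1": (-1.5, 1.0), "BIO9": (-2.0, 1.0),
                     "BIO16": (0.0, 1.05), "BIO18": (0.0, 1.03)},
    "synthetic-rcp45-2050": {"BIO1": (1.8, 1.0), "BIO9": (2.0, 1.0),
                             "BIO16": (0.0, 0.95), "BIO18": (0.0, 0.93)},
    "synthetic-rcp45-2070": {"BIO1": (2.3, 1.0), "BIO9": (2.6, 1.0),
                             "BIO16": (0.0, 0.92), "BIO18": (0.0, 0.90)},
    "synthetic-rcp85-2050": {"BIO1": (2.8, 1.0), "BIO9": (3.2, 1.0),
                             "BIO16": (0.0, 0.90), "BIO18": (0.0, 0.87)},
    "synthetic-rcp85-2070": {"BIO1": (4.3, 1.0), "BIO9": (4.8, 1.0),
                             "BIO16": (0.0, 0.85), "BIO18": (0.0, 0.80)},
}


def apply_scenario_shift(stack: EnvStack, shifts: dict, label: str) -> EnvStack:
    """Apply per-layer affine shifts ``layer ← layer·scale + offset``.

    Layers without an entry in ``shifts`` are unchanged; an entry for an
    unknown layer is an error.
    """
    unknown = set(shifts) - set(stack.layer_names)
    if unknown:
        raise KeyError(f"shift defined for unknown layer(s): {sorted(unknown)}")
    layers = {}
    for name, vals in stack.layers.items():
        if name in shifts:
            offset, scale = shifts[name]
            layers[name] = vals * scale + offset
        else:
            layers[name] = vals.copy()
    return EnvStack(stack.grid, layers, label, stack.nodata_mask.copy())


def true_suitability(stack: EnvStack, truth: SyntheticTruth) -> SuitabilityMap:
    """Evaluate the known niche response over a stack."""
    missing = set(truth.informative_vars) - set(stack.layer_names)
    if missing:
        raise KeyError(f"informative variable(s) missing from stack: {sorted(missing)}")
    g = np.full(stack.grid.shape, truth.intercept, dtype=float)
    for var, (opt, tol) in truth.response.items():
        g -= ((stack.layers[var] - opt) / tol) ** 2
    s = expit(g)
    s[stack.nodata_mask] = np.nan
    return SuitabilityMap(stack.grid, s, transform="truth", scenario=stack.scenario)


def calibrate_intercept(stack: EnvStack, truth: SyntheticTruth,
                        rel_tol: float = 0.02, max_iter: int = 100) -> SyntheticTruth:
    """Bisect the intercept so landscape-mean suitability ≈ prevalence."""
    target = truth.prevalence

    def mean_s(a0):
        t = SyntheticTruth(truth.response, a0, target, truth.seeds)
        return float(np.nanmean(true_suitability(stack, t).values))

    lo, hi = -30.0, 30.0
    for _ in range(max_iter):
        mid = (lo + hi) / 2
        m = mean_s(mid)
        if abs(m - target) <= rel_tol * target:
            break
        if m < target:
            lo = mid
        else:
            hi = mid
    return SyntheticTruth(truth.response, mid, target, truth.seeds)


def sample_presences(truth_map: SuitabilityMap, n_target: int,
                     seed: int | None = None) -> OccurrenceSet:
    """Draw presence cells ∝ true suitability, without replacement.

    Cell centers are reported as planar "lon/lat" coordinates on the
    synthetic grid; the sample is one-per-cell by construction, so it is
    already grid-deduplicated.
    """
    vals = truth_map.values
    finite = np.isfinite(vals)
    rows, cols = np.nonzero(finite)
    weights = vals[rows, cols].astype(float)
    if n_target > len(rows):
        raise ValueError(f"n_target={n_target} exceeds {len(rows)} usable cells")
    total = weights.sum()
    if total <= 0:
        raise ValueError("true suitability is zero everywhere; cannot sample presences")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(rows), size=n_target, replace=False, p=weights / total)
    idx = np.sort(idx)
    x, y = truth_map.grid.cell_center(rows[idx], cols[idx])
    df = pd.DataFrame({"longitude": x, "latitude": y, "source": "synthetic"})
    return OccurrenceSet(df, rows[idx], cols[idx], crs_tag=truth_map.grid.crs_tag)
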