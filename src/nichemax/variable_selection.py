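"""First-stage variable selection by the RM matrix-correlation criterion.

Climate layers are strongly collinear, so before any suitability modelling
the candidate set is reduced to the k-variable subset whose span best
reproduces the full correlation structure.  The criterion is the matrix
correlation RM between the standardized data matrix and its orthogonal
projection onto the span of the subset's columns; it depends on the data
only through the correlation matrix:

    RM(K) = sqrt( tr( R[:,K] · R[K,K]^{-1} · R[K,:] ) / p )

RM is 1 for the full set, monotone non-decreasing as the subset grows, and
invariant to variable reordering and sign flips.
"""

from __future__ import annotations

import itertools
import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grid_io import EnvStack

logger = logging.getLogger(__name__)

#: Refuse exhaustive enumeration above this many subsets; fall back to greedy.
MAX_EXHAUSTIVE_SUBSETS = 1_000_000

#: Ridge added to near-singular subset blocks before inversion.
RIDGE = 1e-10


@dataclass
class CorrelationMatrix:
    """Pairwise Pearson correlations with an ordered variable list."""

    variables: list[str]
    R: np.ndarray

    def __post_init__(self) -> None:
        self.R = np.asarray(self.R, dtype=float)
        p = len(self.variables)
        if self.R.shape != (p, p):
            raise ValueError("correlation matrix shape does not match variable list")
        if not np.allclose(self.R, self.R.T, atol=1e-8):
            raise ValueError("correlation matrix is not symmetric")
        if not np.allclose(np.diag(self.R), 1.0, atol=1e-8):
            raise ValueError("correlation matrix diagonal is not 1")
        eigmin = float(np.linalg.eigvalsh(self.R).min())
        if eigmin < -1e-8:
            raise ValueError(f"correlation matrix is not PSD (min eigenvalue {eigmin:.3g})")

    @property
    def p(self) -> int:
        return len(self.variables)

    def indices(self, subset) -> list[int]:
        lookup = {v: i for i, v in enumerate(self.variables)}
        try:
            return [lookup[v] for v in subset]
        except KeyError as exc:
            raise KeyError(f"unknown variable {exc.args[0]!r}") from exc


@dataclass
class SubsetResult:
    subset: list[str]
    rm_value: float
    search_mode: str
    n_background_sampled: int = 0
    seed: int | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "variable": self.subset,
                "rm_value": self.rm_value,
                "search_mode": self.search_mode,
                "n_background_sampled": self.n_background_sampled,
                "seed": self.seed,
            }
        )


def background_correlation(stack: EnvStack, n_sample: int = 100_000,
                           seed: int | None = None) -> CorrelationMatrix:
    """Pearson correlations over a random background sample of unmasked cells.

    Constant layers carry no correlation information and are excluded with a
    warning.  If ``n_sample`` exceeds the number of usable cells, all cells
    are used (with a warning) — the estimate is then exact for the grid.
    """
    cells = stack.unmasked_cells()
    n_avail = len(cells)
    if n_avail == 0:
        raise ValueError("stack is fully masked")
    rng = np.random.default_rng(seed)
    if n_sample >= n_avail:
        if n_sample > n_avail:
            warnings.warn(
                f"requested {n_sample} background cells but only {n_avail} available; using all"
            )
        sample = cells
    else:
        idx = rng.choice(n_avail, size=n_sample, replace=False)
        sample = cells[np.sort(idx)]
    df = stack.values_at(sample)
    keep = []
    for name in df.columns:
        if np.std(df[name].to_numpy()) == 0.0:
            warnings.warn(f"layer {name!r} is constant over the background sample; excluded")
        else:
            keep.append(name)
    if len(keep) < 2:
        raise ValueError("fewer than two non-constant layers; cannot form a correlation matrix")
    R = np.corrcoef(df[keep].to_numpy(), rowvar=False)
    # guard tiny asymmetries from floating point
    R = (R + R.T) / 2.0
    np.fill_diagonal(R, 1.0)
    return CorrelationMatrix(keep, R)


def rm_coefficient(corr: CorrelationMatrix, subset) -> float:
    """RM criterion of a variable subset (see module docstring)."""
    subset = list(subset)
    if not subset:
        raise ValueError("empty subset")
    K = corr.indices(subset)
    R = corr.R
    RKK = R[np.ix_(K, K)]
    RpK = R[:, K]
    try:
        sol = np.linalg.solve(RKK, RpK.T)
    except np.linalg.LinAlgError:
        warnings.warn("singular subset correlation block; ridge-regularizing")
        sol = np.linalg.solve(RKK + RIDGE * np.eye(len(K)), RpK.T)
    val = float(np.trace(RpK @ sol)) / corr.p
    return math.sqrt(min(max(val, 0.0), 1.0))


def select_subset(corr: CorrelationMatrix, k: int, mode: str = "exhaustive",
                  n_background_sampled: int = 0, seed: int | None = None) -> SubsetResult:
    """Best k-variable subset under RM.

    ``exhaustive`` enumerates all C(p, k) subsets (refused above
    ``MAX_EXHAUSTIVE_SUBSETS``, where it falls back to greedy with a
    warning); ``greedy`` grows the subset by the best marginal RM gain.
    Ties are broken by variable-name order, so results are deterministic.
    """
    p = corr.p
    if not 1 <= k < p:
        raise ValueError(f"k must be in [1, p); got k={k}, p={p}")
    order = sorted(range(p), key=lambda i: corr.variables[i])
    if mode == "exhaustive" and math.comb(p, k) > MAX_EXHAUSTIVE_SUBSETS:
        warnings.warn(
            f"C({p},{k}) = {math.comb(p, k)} subsets exceeds the enumeration guard; "
            "falling back to greedy search"
        )
        mode = "greedy"

    if mode == "exhaustive":
        best, best_rm = None, -1.0
        # iterate in name order so the first maximum is the name-order tie-break
        for combo in itertools.combinations(order, k):
            names = [corr.variables[i] for i in combo]
            rm = rm_coefficient(corr, names)
            if rm > best_rm + 1e-15:
                best, best_rm = names, rm
        result = SubsetResult(sorted(best), best_rm, "exhaustive", n_background_sampled, seed)
    elif mode == "greedy":
        chosen: list[str] = []
        remaining = [corr.variables[i] for i in order]
        rm = 0.0
        while len(chosen) < k:
            best_var, best_rm = None, -1.0
            for v in remaining:
                trial = rm_coefficient(corr, chosen + [v])
                if trial > best_rm + 1e-15:
                    best_var, best_rm = v, trial
            chosen.append(best_var)
            remaining.remove(best_var)
            rm = best_rm
        result = SubsetResult(sorted(chosen), rm, "greedy", n_background_sampled, seed)
    else:
        raise ValueError(f"unknown search mode {mode!r}")
    logger.info("select_subset: k=%d mode=%s RM=%.6f subset=%s",
                k, result.search_mode, result.rm_value, result.subset)
    return result
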