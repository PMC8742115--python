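"""Threshold-free contraction/expansion accounting between scenarios.

Instead of binarizing suitability at an arbitrary threshold, range change
is measured directly on the signed per-cell suitability difference:

* past pairs:   delta = suitability_current − suitability_past
* future pairs: delta = suitability_future  − suitability_current

so positive deltas always mean expansion and negative deltas contraction.
Cell areas with negative/positive delta are accumulated per class of
*current* suitability (class edges 0.03, 0.1, 0.2, 0.4, 0.6, 1.0; cells
below 0.03 are excluded as far outside the species' range), reported in
10³ km².  Net change is total expansion minus total contraction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .grid_io import GridSpec, GridMismatchError
from .maxent_core import SuitabilityMap

logger = logging.getLogger(__name__)

#: Class breaks for suitability maps (left-closed, right-open, last closed).
SUITABILITY_BREAKS = (0.0, 0.2, 0.4, 0.6, 0.8, 1.0)
SUITABILITY_LABELS = ("non-suitable", "low", "general", "medium", "high")

#: Class breaks for the change accounting on current suitability.
CHANGE_BREAKS = (0.03, 0.1, 0.2, 0.4, 0.6, 1.0)


@dataclass
class DeltaMap:
    """Signed suitability difference with its direction convention."""

    grid: GridSpec
    delta: np.ndarray
    direction: str  # past-to-current | current-to-future
    scenario_pair: tuple[str, str]  # (reference, comparison)

    def __post_init__(self) -> None:
        self.delta = np.asarray(self.delta, dtype=float)
        if self.delta.shape != self.grid.shape:
            raise ValueError("delta shape does not match grid")
        if self.direction not in ("past-to-current", "current-to-future"):
            raise ValueError(f"unknown direction {self.direction!r}")


@dataclass
class ChangeTable:
    """Per-current-suitability-class contraction/expansion areas, 10³ km²."""

    scenario: str
    class_breaks: tuple[float, ...]
    contraction: np.ndarray  # per class
    expansion: np.ndarray
    direction: str = "current-to-future"

    @property
    def total_contraction(self) -> float:
        return float(self.contraction.sum())

    @property
    def total_expansion(self) -> float:
        return float(self.expansion.sum())

    @property
    def class_labels(self) -> list[str]:
        b = self.class_breaks
        labels = [f"{lo:g}-{hi:g}" for lo, hi in zip(b[:-1], b[1:])]
        labels[-1] = f">{b[-2]:g}"
        return labels

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "scenario": self.scenario,
            "class": self.class_labels,
            "contraction_1e3km2": self.contraction,
            "expansion_1e3km2": self.expansion,
        })


def classify_suitability(smap: SuitabilityMap,
                         breaks=SUITABILITY_BREAKS,
                         labels=SUITABILITY_LABELS) -> np.ndarray:
    """Class index per cell (−1 for nodata); boundary values go up a class.

    Intervals are left-closed right-open with the last interval closed, so
    a value exactly at 0.2 belongs to "low" and 1.0 to "high".
    """
    breaks = tuple(breaks)
    if any(b2 <= b1 for b1, b2 in zip(breaks, breaks[1:])):
        raise ValueError("class breaks must be strictly increasing")
    if labels is not None and len(labels) != len(breaks) - 1:
        raise ValueError("need one label per class")
    vals = smap.values
    cls = np.digitize(vals, breaks[1:-1], right=False)
    cls = np.where(np.isnan(vals), -1, cls).astype(int)
    # top break closed
    cls = np.where(vals > breaks[-1], -1, cls)
    return cls


def suitability_delta(reference: SuitabilityMap, comparison: SuitabilityMap,
                      direction: str) -> DeltaMap:
    """``comparison − reference`` with the direction convention recorded.

    For past scenarios pass (past, current, "past-to-current"); for future
    scenarios pass (current, future, "current-to-future").  Either way
    positive delta means expansion.
    """
    if not reference.grid.same_geometry(comparison.grid):
        raise GridMismatchError("suitability maps are on different grids")
    if reference.transform != comparison.transform:
        raise ValueError("suitability maps use different transforms")
    delta = comparison.values - reference.values
    return DeltaMap(reference.grid, delta, direction,
                    (reference.scenario, comparison.scenario))


def change_accounting(current: SuitabilityMap, delta: DeltaMap,
                      areas_km2: np.ndarray, breaks=CHANGE_BREAKS,
                      min_delta: float = 0.0, scenario: str | None = None) -> ChangeTable:
    """Accumulate contraction/expansion areas per current-suitability class.

    Cells with current suitability below ``breaks[0]`` (default 0.03) are
    excluded.  Cells with delta < −min_delta contribute their area to C,
    delta > +min_delta to E, and exactly-unchanged cells to neither.
    Areas are reported in 10³ km².
    """
    if not current.grid.same_geometry(delta.grid):
        raise GridMismatchError("current map and delta map are on different grids")
    areas_km2 = np.asarray(areas_km2, dtype=float)
    if areas_km2.shape != current.grid.shape:
        raise ValueError("area layer shape does not match grid")
    breaks = tuple(breaks)
    n_class = len(breaks) - 1
    cur = current.values
    valid = np.isfinite(cur) & np.isfinite(delta.delta) & (cur >= breaks[0])
    cls = np.digitize(cur, breaks[1:-1], right=False)
    contraction = np.zeros(n_class)
    expansion = np.zeros(n_class)
    for c in range(n_class):
        in_class = valid & (cls == c) & (cur <= breaks[-1])
        d = delta.delta
        contraction[c] = areas_km2[in_class & (d < -min_delta)].sum() / 1e3
        expansion[c] = areas_km2[in_class & (d > min_delta)].sum() / 1e3
    label = scenario if scenario is not None else (
        delta.scenario_pair[0] if delta.direction == "past-to-current"
        else delta.scenario_pair[1])
    return ChangeTable(label, breaks, contraction, expansion, delta.direction)


def net_change(table: ChangeTable) -> float:
    """Net area change in 10³ km² (positive = net expansion)."""
    return table.total_expansion - table.total_contraction


def format_million_km2(value_1e3km2: float) -> str:
    return f"{value_1e3km2 / 1e3:.2f} million km²"


def change_histogram(delta: DeltaMap, class_map: np.ndarray,
                     areas_km2: np.ndarray, n_bins: int = 40) -> pd.DataFrame:
    """Area-weighted histogram of deltas, stacked by current class.

    Bin edges are symmetric over [−1, 1].  Rows are delta bins, columns are
    class indices present in ``class_map``; entries are summed areas (km²).
    The per-class column totals equal the class areas of the current map,
    so they are identical across scenarios sharing the current map.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    class_map = np.asarray(class_map)
    areas_km2 = np.asarray(areas_km2, dtype=float)
    edges = np.linspace(-1.0, 1.0, n_bins + 1)
    classes = sorted(c for c in np.unique(class_map) if c >= 0)
    out = {}
    d = delta.delta
    for c in classes:
        sel = (class_map == c) & np.isfinite(d)
        hist, _ = np.histogram(np.clip(d[sel], -1, 1), bins=edges, weights=areas_km2[sel])
        out[c] = hist
    idx = pd.IntervalIndex.from_breaks(edges, closed="left")
    return pd.DataFrame(out, index=idx)


def variable_shift_summary(current_stack, scenario_stack,
                           occurrences=None,
                           quantiles=(0.05, 0.25, 0.5, 0.75, 0.95)) -> pd.DataFrame:
    """Quantiles of per-cell variable differences (scenario − current).

    Computed for the whole study area and, if an occurrence set with cell
    assignments is given, separately for the occurrence cells.  Summarizes
    how each variable is projected to shift, and whether occupied sites
    shift like the landscape at large.
    """
    shared = [v for v in current_stack.layer_names if v in scenario_stack.layer_names]
    if not shared:
        raise ValueError("stacks share no layers")
    if not current_stack.grid.same_geometry(scenario_stack.grid):
        raise GridMismatchError("stacks are on different grids")
    mask = current_stack.nodata_mask | scenario_stack.nodata_mask
    rows = []
    for var in shared:
        diff = scenario_stack.layers[var] - current_stack.layers[var]
        vals = diff[~mask]
        rec = {"variable": var, "region": "study-area"}
        rec.update({f"q{int(q * 100):02d}": float(np.quantile(vals, q)) for q in quantiles})
        rows.append(rec)
        if occurrences is not None:
            cells = occurrences.cells()
            ov = diff[cells[:, 0], cells[:, 1]]
            ov = ov[np.isfinite(ov)]
            rec = {"variable": var, "region": "occurrences"}
            rec.update({f"q{int(q * 100):02d}": float(np.quantile(ov, q)) for q in quantiles})
            rows.append(rec)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Packaged reference accounting table


def load_reference_change_table(path: str | Path | None = None) -> pd.DataFrame:
    """Load the packaged published contraction/expansion area table.

    Per-class C/E areas (10³ km²) for six scenarios relative to the current
    climate, plus the totals as printed in the source study.  The LGM
    expansion entries do not sum to their printed total (the published row
    is internally inconsistent); both are stored and the row is flagged via
    ``inconsistent_total`` rather than second-guessing the typo.
    """
    if path is None:
        ref = resources.files("nichemax").joinpath("data/reference_change_areas.csv")
        with resources.as_file(ref) as p:
            return pd.read_csv(p)
    return pd.read_csv(path)


def reference_change_tables(df: pd.DataFrame | None = None) -> dict[str, dict]:
    """Reference table as ChangeTable objects plus printed totals.

    Returns a dict keyed by scenario with ``table`` (a ChangeTable built
    from the per-class entries), ``printed_total_C``/``printed_total_E``
    and ``net`` (printed E − printed C, the study's own net arithmetic).
    """
    if df is None:
        df = load_reference_change_table()
    out = {}
    for scenario, grp in df.groupby("scenario", sort=False):
        cls = grp[grp["kind"] == "class"].sort_values("class_low")
        tot = grp[grp["kind"] == "printed_total"].iloc[0]
        breaks = tuple(cls["class_low"].tolist() + [cls["class_high"].iloc[-1]])
        table = ChangeTable(
            scenario=scenario,
            class_breaks=breaks,
            contraction=cls["contraction_1e3km2"].to_numpy(dtype=float),
            expansion=cls["expansion_1e3km2"].to_numpy(dtype=float),
            direction=str(tot["direction"]),
        )
        out[scenario] = {
            "table": table,
            "printed_total_C": float(tot["contraction_1e3km2"]),
            "printed_total_E": float(tot["expansion_1e3km2"]),
            "net": float(tot["expansion_1e3km2"]) - float(tot["contraction_1e3km2"]),
            "inconsistent_total": bool(tot["inconsistent_total"]),
        }
    return out
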