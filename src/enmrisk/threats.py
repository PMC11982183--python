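"""Anthropogenic-pressure overlays and weighted extinction-risk maps.

Threat overlays measure how much of a species' estimated geographic
distribution (EGD) lies under high human footprint (strictly above a
cutoff, 10 by default), inside protected areas (cell centers covered by
the dissolved polygon layer), or in contact with a hybridizing congener
(intersection of both species' binary ranges).

Risk maps synthesize scenario consistency: per future period, one
integer layer counts in how many scenarios a cell loses currently
suitable range, another in how many scenarios it falls in the congener
contact zone. Both counts are rescaled (x10) and combined by a weighted
sum (0.7 range loss / 0.3 contact), giving per-cell risk values
7a + 3b for counts a, b in 0..S; with S = 4 scenarios the attainable
positive values run from 3 (contact in a single scenario) to 40 (loss
and contact in all four). Zero-risk cells are those maintained in every
scenario with contact in none. Risk values are banded into low (3-14),
moderate (15-28) and high (29+) categories.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from shapely.geometry.base import BaseGeometry

from .grid import BinaryMap, ConfigurationError, GridSpec

__all__ = [
    "hfp_overlap",
    "rasterize_polygons",
    "pa_overlap",
    "contact_zone",
    "consistency_layer",
    "loss_map",
    "maintained_map",
    "RiskMap",
    "risk_index",
    "zero_risk",
    "RiskCategories",
    "classify_risk",
    "pa_risk_summary",
    "filter_protected_areas",
]


def hfp_overlap(
    egd: BinaryMap, hfp: np.ndarray, cut: float = 10.0, cell_area: float = 1.0
) -> tuple[float, float]:
    """(proportion, area) of the range under high human footprint (> cut)."""
    hfp = np.asarray(hfp, dtype=float)
    if hfp.shape != egd.grid.shape:
        raise ValueError("human-footprint raster is not on the map's grid")
    if not np.isfinite(cut):
        raise ConfigurationError("cut must be finite")
    pres = egd.presence
    n = int(pres.sum())
    if n == 0:
        warnings.warn("empty range: high-footprint proportion undefined")
        return float("nan"), 0.0
    high = int((pres & (hfp > cut)).sum())
    return high / n, high * cell_area


def _validate_polygons(polygons) -> list[BaseGeometry]:
    polys = list(polygons)
    for i, p in enumerate(polys):
        if not isinstance(p, BaseGeometry):
            raise TypeError(f"polygon {i} is not a shapely geometry")
        if not p.is_valid:
            raise ValueError(f"invalid geometry at index {i}")
    return polys


def rasterize_polygons(polygons, grid: GridSpec) -> np.ndarray:
    """Boolean raster: cell True iff its center is covered by the
    dissolved union of the polygons (overlaps counted once)."""
    polys = _validate_polygons(polygons)
    if not polys:
        return np.zeros(grid.shape, dtype=bool)
    dissolved = shapely.union_all(polys)
    x, y = grid.cell_centers()
    return shapely.intersects_xy(dissolved, x.ravel(), y.ravel()).reshape(grid.shape)


def pa_overlap(egd: BinaryMap, polygons) -> float:
    """Proportion of the range's presence cells inside protected areas."""
    pres = egd.presence
    n = int(pres.sum())
    if n == 0:
        warnings.warn("empty range: protected-area proportion undefined")
        return float("nan")
    covered = rasterize_polygons(polygons, egd.grid)
    return int((pres & covered).sum()) / n


def contact_zone(egd_a: BinaryMap, egd_b: BinaryMap) -> tuple[BinaryMap, float]:
    """Intersection of two ranges and the proportion of ``egd_a`` in contact."""
    if egd_a.grid != egd_b.grid:
        raise ValueError("ranges are on different grids")
    inter = egd_a.presence & egd_b.presence
    bm = BinaryMap(egd_a.grid, inter.astype(np.uint8), egd_a.mask & egd_b.mask,
                   {"kind": "contact-zone"})
    n_a = int(egd_a.presence.sum())
    if n_a == 0:
        warnings.warn("empty focal range: contact proportion undefined")
        return bm, float("nan")
    return bm, int(inter.sum()) / n_a


def consistency_layer(maps: list[BinaryMap]) -> np.ndarray:
    """Per-cell count of maps (scenarios) with presence."""
    if not maps:
        raise ValueError("at least one map is required")
    grid = maps[0].grid
    for m in maps[1:]:
        if m.grid != grid:
            raise ValueError("maps are on different grids")
    return np.sum([m.presence for m in maps], axis=0).astype(int)


def loss_map(current: BinaryMap, future: BinaryMap) -> BinaryMap:
    """Cells losing range in a scenario: current-present and future-absent."""
    if current.grid != future.grid:
        raise ValueError("maps are on different grids")
    lost = current.presence & ~future.presence
    return BinaryMap(current.grid, lost.astype(np.uint8),
                     current.mask & future.mask, {"kind": "loss"})


def maintained_map(current: BinaryMap, future: BinaryMap) -> BinaryMap:
    """Cells suitable both now and in a scenario."""
    if current.grid != future.grid:
        raise ValueError("maps are on different grids")
    kept = current.presence & future.presence
    return BinaryMap(current.grid, kept.astype(np.uint8),
                     current.mask & future.mask, {"kind": "maintained"})


@dataclass
class RiskMap:
    """Weighted scenario-consistency risk surface.

    risk = w_loss * scale * loss_count + w_contact * scale * contact_count

    with integer counts in [0, n_scenarios]. ``zero_risk`` marks cells
    maintained in every scenario with no congener contact in any; those
    cells necessarily have both counts 0 and risk 0.
    """

    grid: GridSpec
    loss_count: np.ndarray
    contact_count: np.ndarray
    risk: np.ndarray
    n_scenarios: int
    w_loss: float = 0.7
    w_contact: float = 0.3
    scale: float = 10.0
    zero_risk_mask: np.ndarray | None = None
    valid_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.valid_mask is None:
            self.valid_mask = np.ones(self.grid.shape, dtype=bool)
        if self.zero_risk_mask is not None:
            viol = self.zero_risk_mask & (self.risk != 0)
            if viol.any():
                raise ValueError(
                    f"{int(viol.sum())} zero-risk cell(s) have nonzero risk"
                )

    def attainable_values(self) -> np.ndarray:
        """Sorted set of values the weighted sum can produce."""
        a, b = np.meshgrid(np.arange(self.n_scenarios + 1),
                           np.arange(self.n_scenarios + 1))
        vals = self.w_loss * self.scale * a + self.w_contact * self.scale * b
        vals = np.where(np.abs(vals - np.rint(vals)) < 1e-9, np.rint(vals), vals)
        return np.unique(vals.ravel())

    @property
    def domain(self) -> np.ndarray:
        """Cells belonging to the risk surface: at-risk or zero-risk."""
        at_risk = self.valid_mask & (self.risk > 0)
        if self.zero_risk_mask is None:
            return at_risk
        return at_risk | (self.zero_risk_mask & self.valid_mask)


def risk_index(
    loss_count: np.ndarray,
    contact_count: np.ndarray,
    grid: GridSpec,
    n_scenarios: int,
    w_loss: float = 0.7,
    w_contact: float = 0.3,
    scale: float = 10.0,
    zero_risk_mask: np.ndarray | None = None,
    valid_mask: np.ndarray | None = None,
) -> RiskMap:
    """Weighted sum of rescaled scenario-consistency counts."""
    a = np.asarray(loss_count)
    b = np.asarray(contact_count)
    if (a < 0).any() or (b < 0).any():
        raise ValueError("consistency counts must be nonnegative")
    if (a > n_scenarios).any() or (b > n_scenarios).any():
        raise ValueError(f"counts exceed the number of scenarios ({n_scenarios})")
    risk = w_loss * scale * a + w_contact * scale * b
    near = np.abs(risk - np.rint(risk)) < 1e-9
    risk = np.where(near, np.rint(risk), risk)
    return RiskMap(grid, a, b, risk, n_scenarios, w_loss, w_contact, scale,
                   zero_risk_mask,
                   np.ones(grid.shape, bool) if valid_mask is None else valid_mask)


def zero_risk(maintained_maps: list[BinaryMap],
              contact_maps: list[BinaryMap]) -> BinaryMap:
    """Cells maintained in ALL scenarios and in contact in NONE."""
    if len(maintained_maps) != len(contact_maps):
        raise ValueError("scenario sets differ between maintained and contact maps")
    if not maintained_maps:
        raise ValueError("at least one scenario is required")
    grid = maintained_maps[0].grid
    for m in maintained_maps + contact_maps:
        if m.grid != grid:
            raise ValueError("maps are on different grids")
    kept_all = np.logical_and.reduce([m.presence for m in maintained_maps])
    contact_any = np.logical_or.reduce([m.presence for m in contact_maps])
    flag = kept_all & ~contact_any
    return BinaryMap(grid, flag.astype(np.uint8),
                     np.ones(grid.shape, bool), {"kind": "zero-risk"})


@dataclass(frozen=True)
class RiskCategories:
    """Risk bands: low [3, 14], moderate [15, 28], high [29, max]."""

    low: tuple[float, float] = (3.0, 14.0)
    moderate: tuple[float, float] = (15.0, 28.0)
    high_min: float = 29.0

    def __post_init__(self) -> None:
        if not self.low[0] <= self.low[1] < self.moderate[0] <= self.moderate[1] \
                < self.high_min:
            raise ConfigurationError("risk category bounds must be ordered")

    def of(self, value: float) -> str:
        if value <= 0:
            return "none"
        if value >= self.high_min:
            return "high"
        if value >= self.moderate[0]:
            return "moderate"
        return "low"


CATEGORY_CODES = {"none": 0, "low": 1, "moderate": 2, "high": 3}


def classify_risk(rmap: RiskMap, cats: RiskCategories = RiskCategories()):
    """Categorical raster plus category proportions over at-risk cells.

    Cells with risk 0 (including zero-risk) are coded "none" and reported
    separately from the at-risk proportions.
    """
    risk = rmap.risk
    attainable = rmap.attainable_values()
    present = np.unique(risk[rmap.valid_mask])
    stray = [v for v in present if not np.any(np.isclose(v, attainable))]
    if stray:
        warnings.warn(f"risk values {stray} are outside the attainable set; "
                      "check weights/scale configuration")
    codes = np.zeros(rmap.grid.shape, dtype=np.uint8)
    at_risk = rmap.valid_mask & (risk > 0)
    codes[at_risk & (risk < cats.moderate[0])] = CATEGORY_CODES["low"]
    codes[at_risk & (risk >= cats.moderate[0]) & (risk < cats.high_min)] = \
        CATEGORY_CODES["moderate"]
    codes[at_risk & (risk >= cats.high_min)] = CATEGORY_CODES["high"]
    n_at_risk = int(at_risk.sum())
    if n_at_risk:
        proportions = {
            name: float((codes == code).sum()) / n_at_risk
            for name, code in CATEGORY_CODES.items() if name != "none"
        }
    else:
        proportions = {name: float("nan") for name in ("low", "moderate", "high")}
    return codes, proportions


def pa_risk_summary(
    rmap: RiskMap,
    polygons,
    cats: RiskCategories = RiskCategories(),
    cell_area: float = 1.0,
) -> tuple[dict, pd.DataFrame]:
    """Risk composition inside protected areas.

    Returns an overall summary over all PA-covered cells of the risk
    surface (share at zero risk, and of at-risk cells the share per
    category) and a per-PA table with columns ``area`` (polygon area),
    ``overlap_pct`` (share of the PA's cells on the risk surface),
    ``zero_pct`` and ``moderate_high_pct``.
    """
    polys = _validate_polygons(polygons)
    codes, _ = classify_risk(rmap, cats)
    domain = rmap.domain
    at_risk = rmap.valid_mask & (rmap.risk > 0)
    zero = domain & ~at_risk

    covered_all = rasterize_polygons(polys, rmap.grid)
    in_domain = covered_all & domain
    n_dom = int(in_domain.sum())
    overall = {"pa_cells_on_risk_surface": n_dom}
    if n_dom:
        overall["zero_risk_pct"] = 100.0 * int((in_domain & zero).sum()) / n_dom
        n_risk = int((in_domain & at_risk).sum())
        for name, code in CATEGORY_CODES.items():
            if name == "none":
                continue
            overall[f"{name}_pct_of_at_risk"] = (
                100.0 * int((in_domain & (codes == code)).sum()) / n_risk
                if n_risk else float("nan")
            )
    else:
        overall["zero_risk_pct"] = float("nan")

    x, y = rmap.grid.cell_centers()
    rows = []
    for i, poly in enumerate(polys):
        cells = shapely.intersects_xy(poly, x.ravel(), y.ravel()).reshape(
            rmap.grid.shape)
        n_cells = int(cells.sum())
        on_surface = cells & domain
        n_on = int(on_surface.sum())
        mod_high = cells & (codes >= CATEGORY_CODES["moderate"])
        rows.append({
            "pa_index": i,
            "area": poly.area,
            "cells": n_cells,
            "overlap_pct": 100.0 * n_on / n_cells if n_cells else 0.0,
            "zero_pct": 100.0 * int((on_surface & zero).sum()) / n_on
            if n_on else float("nan"),
            "moderate_high_pct": 100.0 * int(mod_high.sum()) / n_on
            if n_on else float("nan"),
        })
    return overall, pd.DataFrame(rows)


def filter_protected_areas(
    pa_table: pd.DataFrame,
    min_area: float = 100.0,
    min_overlap_pct: float = 40.0,
) -> pd.DataFrame:
    """PAs larger than ``min_area`` with at least ``min_overlap_pct`` of
    their surface on the risk map (the reporting filter for key PAs)."""
    sel = (pa_table["area"] > min_area) & (pa_table["overlap_pct"] >= min_overlap_pct)
    return pa_table.loc[sel].reset_index(drop=True)
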