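"""From continuous suitability to binary ranges and change accounting.

Binarization uses the modified lower presence threshold: with error
proportion E and n training presences, the threshold is the
(floor(E*n)+1)-th smallest training-presence suitability, so at most
floor(E*n) training presences are omitted (none when E = 0). Range
change between a current and a future binary map is a per-cell four-way
classification; gained/lost/maintained percentages are reported over the
union of the two ranges, and the overlap index O (cells in the
intersection over cells in the union) equals the maintained proportion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .grid import BinaryMap, ConfigurationError, GridSpec
from .occurrences import OccurrenceSet

__all__ = [
    "lower_presence_threshold",
    "binarize",
    "crop_to_calibration",
    "ChangeMap",
    "change_map",
    "overlap_index",
    "area",
    "validate_independent",
    "CHANGE_CODES",
]

# per-cell change categories
CHANGE_CODES = {"stable_absent": 0, "gained": 1, "lost": 2, "maintained": 3}


def lower_presence_threshold(training_suitabilities, E: float = 0.2,
                             conservative: bool = False) -> float:
    """Threshold excluding up to a proportion E of the lowest training
    presences: the (floor(E*n)+1)-th smallest suitability.

    With ``conservative=True`` the floor(E*n)-th smallest is used
    instead — the largest threshold whose expected omission of new
    presences, floor(E*n)/(n+1), stays at or below E. This variant is
    used when candidate models are scored against an omission-rate cut
    of E, where the default rule would push a perfectly calibrated
    model's expected test omission just past the cut.
    """
    vals = np.sort(np.asarray(training_suitabilities, dtype=float).ravel())
    vals = vals[np.isfinite(vals)]
    n = vals.size
    if n == 0:
        raise ValueError("empty training suitability set")
    if not 0 <= E < 0.5:
        raise ConfigurationError("E must be in [0, 0.5)")
    idx = int(np.floor(E * n))
    if conservative:
        idx = max(idx - 1, 0)
    return float(vals[idx])


def binarize(
    suitability: np.ndarray,
    grid: GridSpec,
    training_suitabilities,
    E: float = 0.2,
    mask: np.ndarray | None = None,
    provenance: dict | None = None,
) -> BinaryMap:
    """Presence-absence map: cell present iff suitability >= the modified
    lower presence threshold at error E."""
    thr = lower_presence_threshold(training_suitabilities, E)
    suit = np.asarray(suitability, dtype=float)
    if mask is None:
        mask = np.isfinite(suit)
    values = (np.nan_to_num(suit, nan=-np.inf) >= thr).astype(np.uint8)
    prov = {"threshold": thr, "E": E}
    if provenance:
        prov.update(provenance)
    return BinaryMap(grid, values, mask, prov)


def crop_to_calibration(bmap: BinaryMap, calibration_mask: np.ndarray) -> BinaryMap:
    """Set cells outside the calibration mask to absent/nodata."""
    calibration_mask = np.asarray(calibration_mask, dtype=bool)
    if calibration_mask.shape != bmap.grid.shape:
        raise ValueError("calibration mask is not on the map's grid")
    values = np.where(calibration_mask, bmap.values, 0).astype(np.uint8)
    mask = bmap.mask & calibration_mask
    prov = dict(bmap.provenance)
    prov["cropped"] = True
    return BinaryMap(bmap.grid, values, mask, prov)


@dataclass
class ChangeMap:
    """Current-vs-future comparison of two binary ranges.

    ``categories`` codes cells per :data:`CHANGE_CODES`; the summary
    percentages are proportions of the union of both ranges and sum to
    100; ``overlap`` is intersection over union.
    """

    grid: GridSpec
    categories: np.ndarray
    gained_pct: float
    lost_pct: float
    maintained_pct: float
    overlap: float
    union_cells: int

    @property
    def defined(self) -> bool:
        return self.union_cells > 0


def change_map(current: BinaryMap, future: BinaryMap) -> ChangeMap:
    """Per-cell gain/loss/maintenance classification and union-based summary."""
    if current.grid != future.grid:
        raise ValueError("current and future maps are on different grids")
    p, f = current.presence, future.presence
    cats = np.zeros(current.grid.shape, dtype=np.uint8)
    cats[f & ~p] = CHANGE_CODES["gained"]
    cats[p & ~f] = CHANGE_CODES["lost"]
    cats[p & f] = CHANGE_CODES["maintained"]
    union = int((p | f).sum())
    inter = int((p & f).sum())
    if union == 0:
        warnings.warn("both ranges are empty; change proportions undefined")
        return ChangeMap(current.grid, cats, np.nan, np.nan, np.nan, np.nan, 0)
    gained = int((f & ~p).sum())
    lost = int((p & ~f).sum())
    return ChangeMap(
        grid=current.grid,
        categories=cats,
        gained_pct=100.0 * gained / union,
        lost_pct=100.0 * lost / union,
        maintained_pct=100.0 * inter / union,
        overlap=inter / union,
        union_cells=union,
    )


def overlap_index(p: BinaryMap, f: BinaryMap) -> float:
    """Intersection-over-union of two binary ranges (the O index)."""
    if p.grid != f.grid:
        raise ValueError("maps are on different grids")
    a, b = p.presence, f.presence
    union = int((a | b).sum())
    if union == 0:
        raise ValueError("empty union: overlap index undefined")
    return int((a & b).sum()) / union


def area(bmap: BinaryMap, cell_area: float = 1.0,
         row_weights: np.ndarray | None = None) -> float:
    """Presence area: cell count x cell area, optionally row-weighted
    (e.g. cosine-latitude weights for geographic grids)."""
    if not cell_area > 0:
        raise ConfigurationError("cell_area must be > 0")
    pres = bmap.presence
    if row_weights is None:
        return float(pres.sum() * cell_area)
    w = np.asarray(row_weights, dtype=float)
    if w.shape != (bmap.grid.n_rows,):
        raise ValueError("row_weights must have one entry per grid row")
    return float((pres.sum(axis=1) * w).sum() * cell_area)


@dataclass
class ValidationResult:
    """Independent-record validation against a predicted range."""

    n_inside: int
    n_outside: int
    nearest_known_dist: np.ndarray
    novel_flags: np.ndarray


def validate_independent(
    bmap: BinaryMap,
    new_occ: OccurrenceSet,
    known_occ: OccurrenceSet,
    novelty_band: tuple[float, float] | None = None,
) -> ValidationResult:
    """Count independent records inside the predicted range and flag
    novel ones.

    Points on nodata cells are counted outside (with a warning). Each new
    point's distance to the nearest known record is reported; a point is
    flagged novel when that distance falls inside ``novelty_band``
    (min, max, map units).
    """
    n = len(new_occ)
    if n == 0:
        return ValidationResult(0, 0, np.empty(0), np.zeros(0, dtype=bool))
    row, col = bmap.grid.cell_of(new_occ.coords[:, 0], new_occ.coords[:, 1])
    inside = np.zeros(n, dtype=bool)
    on_grid = row >= 0
    if not on_grid.all():
        warnings.warn(f"{int((~on_grid).sum())} new record(s) outside the grid extent")
    r, c = row[on_grid], col[on_grid]
    nodata = ~bmap.mask[r, c]
    if nodata.any():
        warnings.warn(f"{int(nodata.sum())} new record(s) on nodata cells; "
                      "counted outside")
    inside[np.flatnonzero(on_grid)] = bmap.presence[r, c]

    if len(known_occ) > 0:
        tree = cKDTree(known_occ.coords)
        dist, _ = tree.query(new_occ.coords)
    else:
        dist = np.full(n, np.inf)
    if novelty_band is not None:
        lo, hi = novelty_band
        novel = (dist >= lo) & (dist <= hi)
    else:
        novel = np.zeros(n, dtype=bool)
    return ValidationResult(
        n_inside=int(inside.sum()),
        n_outside=int(n - inside.sum()),
        nearest_known_dist=dist,
        novel_flags=novel,
    )
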