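"""Synthetic landscapes with analytically known ground truth.

Every input the risk-assessment pipeline needs can be simulated here:
spatially autocorrelated standardized predictors, scenario-shifted future
predictor stacks, virtual species with parametric response curves (and a
broader-niched congener), presence samples drawn from true suitability,
a patchy human-footprint surface and polygonal protected areas.

The generators trade realism for recoverable truth: predictors are
standardized Gaussian random fields rather than bioclim look-alikes, and
species' suitability is an exact function of the predictors, so every
downstream stage can be validated against the known answer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter
from shapely.geometry import Polygon, box

from .grid import ConfigurationError, EnvStack, GridSpec, BinaryMap
from .occurrences import OccurrenceSet

__all__ = [
    "GaussianResponse",
    "LogisticResponse",
    "VirtualSpecies",
    "ScenarioShift",
    "make_env_stack",
    "apply_scenario",
    "true_suitability",
    "true_range",
    "sample_occurrences",
    "make_threat_layers",
    "make_congener",
]


# ---------------------------------------------------------------------------
# response curves and virtual species
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GaussianResponse:
    """Bell-shaped response: suitability ``exp(-(x - optimum)^2 / (2 breadth^2))``."""

    optimum: float
    breadth: float

    def __post_init__(self) -> None:
        if not self.breadth > 0:
            raise ConfigurationError("breadth must be > 0")

    def __call__(self, x: np.ndarray) -> np.ndarray:
        z = (np.asarray(x, dtype=float) - self.optimum) / self.breadth
        return np.exp(-0.5 * z * z)


@dataclass(frozen=True)
class LogisticResponse:
    """Sigmoid response rising (direction=+1) or falling (direction=-1) at ``midpoint``."""

    midpoint: float
    slope: float
    direction: int = 1

    def __post_init__(self) -> None:
        if not self.slope > 0:
            raise ConfigurationError("slope must be > 0")
        if self.direction not in (1, -1):
            raise ConfigurationError("direction must be +1 or -1")

    def __call__(self, x: np.ndarray) -> np.ndarray:
        z = self.direction * (np.asarray(x, dtype=float) - self.midpoint) * self.slope
        return 1.0 / (1.0 + np.exp(-z))


@dataclass(frozen=True)
class VirtualSpecies:
    """A species defined by per-variable response curves.

    ``curves`` maps predictor names to callables returning per-variable
    suitability in [0, 1]; per-cell suitability combines them with a
    product or geometric mean, and the "true" range is the set of cells
    at or above ``prevalence_threshold``.
    """

    curves: dict
    combination_rule: str = "product"
    prevalence_threshold: float = 0.5
    name: str = "virtual"

    def __post_init__(self) -> None:
        if not self.curves:
            raise ConfigurationError("at least one response curve is required")
        if self.combination_rule not in ("product", "geometric_mean"):
            raise ConfigurationError(
                f"unknown combination rule {self.combination_rule!r}"
            )
        if not 0 <= self.prevalence_threshold <= 1:
            raise ConfigurationError("prevalence_threshold must be in [0, 1]")


def make_congener(
    vs: VirtualSpecies,
    breadth_scale: float = 2.0,
    optimum_shift: float = 1.0,
    name: str = "congener",
) -> VirtualSpecies:
    """A broader-niched relative with shifted optima.

    Gaussian curve breadths are multiplied by ``breadth_scale`` and optima
    shifted by ``optimum_shift`` (logistic midpoints shifted likewise, with
    slopes divided by ``breadth_scale``), so a partial contact zone with
    the focal species exists by construction.
    """
    shifted = {}
    for var, curve in vs.curves.items():
        if isinstance(curve, GaussianResponse):
            shifted[var] = GaussianResponse(
                curve.optimum + optimum_shift, curve.breadth * breadth_scale
            )
        elif isinstance(curve, LogisticResponse):
            shifted[var] = LogisticResponse(
                curve.midpoint + optimum_shift,
                curve.slope / breadth_scale,
                curve.direction,
            )
        else:
            shifted[var] = curve
    return VirtualSpecies(
        shifted, vs.combination_rule, vs.prevalence_threshold, name=name
    )


# ---------------------------------------------------------------------------
# predictor stacks
# ---------------------------------------------------------------------------

def make_env_stack(
    spec: GridSpec,
    n_vars: int,
    corr_length: float = 5.0,
    seed: int = 0,
    gradient_weight: float = 0.5,
    names: list[str] | None = None,
) -> EnvStack:
    """Spatially autocorrelated standardized predictor surfaces.

    Each variable is Gaussian-smoothed white noise (kernel sd
    ``corr_length`` cells) plus a deterministic planar gradient in a
    seeded random direction with relative weight ``gradient_weight``,
    standardized to mean 0, sd 1 over valid cells. Bit-reproducible for a
    fixed seed.
    """
    if n_vars < 1:
        raise ConfigurationError("n_vars must be >= 1")
    if corr_length < 1:
        raise ConfigurationError("corr_length must be >= 1 cell")
    rng = np.random.default_rng(seed)
    if names is None:
        names = [f"var{i + 1}" for i in range(n_vars)]
    rr, cc = np.meshgrid(
        np.linspace(-0.5, 0.5, spec.n_rows), np.linspace(-0.5, 0.5, spec.n_cols),
        indexing="ij",
    )
    layers = np.empty((n_vars, spec.n_rows, spec.n_cols))
    for i in range(n_vars):
        noise = gaussian_filter(rng.standard_normal(spec.shape), sigma=corr_length,
                                mode="reflect")
        sd = noise.std()
        if sd > 0:
            noise = noise / sd
        theta = rng.uniform(0, 2 * math.pi)
        ramp = math.cos(theta) * cc + math.sin(theta) * (-rr)  # -rr: +y is northward
        ramp_sd = ramp.std()
        field_ = noise + gradient_weight * (ramp / ramp_sd if ramp_sd > 0 else ramp)
        layers[i] = field_
    stack = EnvStack(spec, names, layers)
    _standardize(stack)
    return stack


def _standardize(stack: EnvStack) -> None:
    """In-place per-variable standardization over valid cells."""
    m = stack.mask
    for i in range(stack.n_vars):
        vals = stack.data[i][m]
        mu, sd = vals.mean(), vals.std()
        if sd == 0:
            raise ConfigurationError(f"layer {stack.names[i]!r} is constant")
        stack.data[i][m] = (vals - mu) / sd
        # re-center exactly so |mean| is at rounding level
        stack.data[i][m] -= stack.data[i][m].mean()


# ---------------------------------------------------------------------------
# scenarios
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScenarioShift:
    """Per-variable transformation defining a future scenario.

    future = multiplicative * current + additive + gradient * y_norm + noise

    where ``y_norm`` runs from -0.5 (southern edge) to +0.5 (northern
    edge), so a positive ``gradient`` makes values climb poleward, and
    ``noise`` is seeded Gaussian noise with sd ``noise_sd`` (skipped
    entirely when the sd is 0, making the zero shift an exact identity).
    """

    additive: dict = field(default_factory=dict)
    multiplicative: dict = field(default_factory=dict)
    gradient: dict = field(default_factory=dict)
    noise_sd: float = 0.0
    name: str = "scenario"

    @classmethod
    def zero(cls, name: str = "identity") -> "ScenarioShift":
        return cls(name=name)

    @classmethod
    def uniform(cls, names, additive=0.0, multiplicative=1.0, gradient=0.0,
                noise_sd=0.0, name="scenario") -> "ScenarioShift":
        return cls(
            additive={n: additive for n in names},
            multiplicative={n: multiplicative for n in names},
            gradient={n: gradient for n in names},
            noise_sd=noise_sd,
            name=name,
        )


def apply_scenario(stack: EnvStack, shift: ScenarioShift, seed: int = 0) -> EnvStack:
    """Trend-shifted future stack on the same grid; zero shift is identity."""
    for d in (shift.additive, shift.multiplicative, shift.gradient):
        unknown = set(d) - set(stack.names)
        if unknown:
            raise ConfigurationError(
                f"shift refers to unknown variables {sorted(unknown)}"
            )
    rng = np.random.default_rng(seed)
    y_norm = np.linspace(0.5, -0.5, stack.grid.n_rows)[:, None]  # top row is north
    out = stack.data.copy()
    for i, name in enumerate(stack.names):
        mult = shift.multiplicative.get(name, 1.0)
        add = shift.additive.get(name, 0.0)
        grad = shift.gradient.get(name, 0.0)
        if mult != 1.0:
            out[i] = out[i] * mult
        if add != 0.0:
            out[i] = out[i] + add
        if grad != 0.0:
            out[i] = out[i] + grad * y_norm
        if shift.noise_sd > 0:
            out[i] = out[i] + rng.normal(0.0, shift.noise_sd, stack.grid.shape)
    return stack.with_data(out)


# ---------------------------------------------------------------------------
# truth surfaces and sampling
# ---------------------------------------------------------------------------

def true_suitability(vs: VirtualSpecies, stack: EnvStack) -> np.ndarray:
    """Exact suitability surface in [0, 1]; NaN outside the valid mask."""
    missing = set(vs.curves) - set(stack.names)
    if missing:
        raise ConfigurationError(f"no curve-matching layers for {sorted(missing)}")
    parts = [np.clip(curve(stack.layer(var)), 0.0, 1.0)
             for var, curve in vs.curves.items()]
    prod = np.prod(parts, axis=0)
    if vs.combination_rule == "geometric_mean":
        suit = prod ** (1.0 / len(parts))
    else:
        suit = prod
    return np.where(stack.mask, suit, np.nan)


def true_range(vs: VirtualSpecies, stack: EnvStack) -> BinaryMap:
    """Cells at or above the species' prevalence threshold."""
    suit = true_suitability(vs, stack)
    values = (np.nan_to_num(suit, nan=-1.0) >= vs.prevalence_threshold).astype(np.uint8)
    bm = BinaryMap(stack.grid, values, stack.mask.copy(),
                   {"species": vs.name, "threshold": vs.prevalence_threshold,
                    "kind": "true-range"})
    if bm.n_present == 0:
        raise ConfigurationError(
            f"true range of {vs.name!r} is empty at threshold "
            f"{vs.prevalence_threshold}"
        )
    return bm


def sample_occurrences(
    vs: VirtualSpecies,
    stack: EnvStack,
    n: int,
    bias: np.ndarray | None = None,
    seed: int = 0,
    jitter: bool = True,
    source: str = "simulated",
) -> OccurrenceSet:
    """Presence points drawn with probability proportional to suitability x bias.

    Cells are drawn with replacement; coordinates are cell centers with
    uniform sub-cell jitter (so duplicates in cell space remain distinct
    points). Raises a degenerate-input error when all weights are zero.
    """
    if n < 1:
        raise ConfigurationError("n must be >= 1")
    suit = true_suitability(vs, stack)
    w = np.nan_to_num(suit, nan=0.0).astype(float)
    if bias is not None:
        bias = np.asarray(bias, dtype=float)
        if bias.shape != stack.grid.shape:
            raise ConfigurationError("bias raster shape does not match grid")
        if (bias < 0).any():
            raise ConfigurationError("bias must be nonnegative")
        w = w * bias
    w[~stack.mask] = 0.0
    total = w.sum()
    if not total > 0:
        raise ValueError("degenerate input: all sampling weights are zero")
    rng = np.random.default_rng(seed)
    flat = rng.choice(stack.grid.n_cells, size=n, replace=True, p=w.ravel() / total)
    row, col = np.unravel_index(flat, stack.grid.shape)
    g = stack.grid
    x = g.origin_x + (col + 0.5) * g.cell_size
    y = g.origin_y + (g.n_rows - row - 0.5) * g.cell_size
    if jitter:
        x = x + rng.uniform(-0.499, 0.499, n) * g.cell_size
        y = y + rng.uniform(-0.499, 0.499, n) * g.cell_size
    return OccurrenceSet.from_arrays(x, y, species=vs.name, source=source)


# ---------------------------------------------------------------------------
# threat layers
# ---------------------------------------------------------------------------

def make_threat_layers(
    spec: GridSpec,
    n_pa: int = 8,
    pa_size_range: tuple[float, float] = (3.0, 8.0),
    hfp_params: dict | None = None,
    seed: int = 0,
) -> tuple[np.ndarray, list[Polygon]]:
    """A patchy human-footprint surface and protected-area polygons.

    The human-footprint raster has values in [0, 50]: a low smoothed
    background plus ``n_hotspots`` Gaussian-shaped high-pressure clusters
    (urban-like patches). Protected areas are ``n_pa`` axis-aligned
    rectangles with side lengths drawn uniformly from ``pa_size_range``
    (in cells), clipped to the grid extent; they may overlap.
    """
    if n_pa < 0:
        raise ConfigurationError("n_pa must be >= 0")
    params = {"n_hotspots": 5, "hotspot_sd_cells": 4.0, "background_max": 8.0,
              "hotspot_peak": 45.0, "smooth_cells": 3.0}
    if hfp_params:
        params.update(hfp_params)
    rng = np.random.default_rng(seed)

    base = gaussian_filter(rng.random(spec.shape), sigma=params["smooth_cells"],
                           mode="reflect")
    base = base - base.min()
    if base.max() > 0:
        base = base / base.max()
    hfp = base * params["background_max"]

    rows, cols = np.meshgrid(np.arange(spec.n_rows), np.arange(spec.n_cols),
                             indexing="ij")
    for _ in range(int(params["n_hotspots"])):
        r0 = rng.uniform(0, spec.n_rows)
        c0 = rng.uniform(0, spec.n_cols)
        amp = rng.uniform(0.6, 1.0) * params["hotspot_peak"]
        sd = params["hotspot_sd_cells"]
        hfp = hfp + amp * np.exp(-((rows - r0) ** 2 + (cols - c0) ** 2) / (2 * sd**2))
    hfp = np.clip(hfp, 0.0, 50.0)

    xmin, ymin, xmax, ymax = spec.extent
    extent_box = box(xmin, ymin, xmax, ymax)
    polygons: list[Polygon] = []
    for _ in range(int(n_pa)):
        w = rng.uniform(*pa_size_range) * spec.cell_size
        h = rng.uniform(*pa_size_range) * spec.cell_size
        cx = rng.uniform(xmin, xmax)
        cy = rng.uniform(ymin, ymax)
        poly = box(cx - w / 2, cy - h / 2, cx + w / 2, cy + h / 2).intersection(
            extent_box
        )
        if not poly.is_empty and poly.area > 0:
            polygons.append(poly)
    return hfp, polygons
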