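"""Occurrence cleaning and predictor selection.

Mirrors the standard presence-data protocol: exact-duplicate removal, a
minimum-distance spatial filter against autocorrelation (10 km in the
default configuration), an even train/test split with an environmental
coverage check, a pairwise Pearson correlation filter (|r| >= 0.8 by
default) that keeps the higher-ranked variable of each offending pair,
and a jackknife ranking of variables by single-variable model gain.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .grid import ConfigurationError, EnvStack
from .occurrences import OccurrenceSet

__all__ = [
    "PredictorSelection",
    "deduplicate",
    "thin_spatial",
    "split_train_test",
    "environmental_coverage",
    "filter_correlated",
    "jackknife_rank",
]


def _pairwise_distances(coords: np.ndarray, metric: str) -> np.ndarray:
    if metric == "euclidean":
        return squareform(pdist(coords)) if len(coords) > 1 else np.zeros((len(coords),) * 2)
    if metric == "haversine":
        # coords as (lon, lat) degrees -> great-circle km
        lon = np.radians(coords[:, 0])[:, None]
        lat = np.radians(coords[:, 1])[:, None]
        dlat = lat - lat.T
        dlon = lon - lon.T
        a = np.sin(dlat / 2) ** 2 + np.cos(lat) * np.cos(lat.T) * np.sin(dlon / 2) ** 2
        return 2 * 6371.0 * np.arcsin(np.sqrt(np.clip(a, 0, 1)))
    raise ConfigurationError(f"unknown distance metric {metric!r}")


def deduplicate(occ: OccurrenceSet) -> OccurrenceSet:
    """Drop exact duplicate (species, x, y) records, keeping the first."""
    df = occ.records.drop_duplicates(subset=["species", "x", "y"], keep="first")
    return OccurrenceSet(df.reset_index(drop=True))


def thin_spatial(
    occ: OccurrenceSet,
    min_dist: float,
    seed: int = 0,
    metric: str = "euclidean",
) -> OccurrenceSet:
    """Greedy spatial thinning to a minimum pairwise distance.

    Records are visited in a seed-shuffled order; each is kept iff it lies
    at least ``min_dist`` from every record already kept. The result
    satisfies the distance constraint, is inclusion-maximal (no discarded
    record could be added back), and thinning it again is a no-op.
    """
    if min_dist < 0:
        raise ConfigurationError("min_dist must be >= 0")
    n = len(occ)
    if n == 0 or min_dist == 0:
        return occ.copy()
    coords = occ.coords
    if not np.isfinite(coords).all():
        raise ConfigurationError("occurrence coordinates must be finite")
    dist = _pairwise_distances(coords, metric)
    order = np.random.default_rng(seed).permutation(n)
    kept: list[int] = []
    for i in order:
        if all(dist[i, j] >= min_dist for j in kept):
            kept.append(i)
    kept.sort()
    return occ.subset(np.isin(np.arange(n), kept))


def split_train_test(
    occ: OccurrenceSet,
    fraction: float = 0.5,
    seed: int = 0,
) -> OccurrenceSet:
    """Random train/test partition with |train| = round(fraction * n)."""
    if not 0 < fraction < 1:
        raise ConfigurationError("fraction must be in (0, 1)")
    n = len(occ)
    if n < 4:
        raise ValueError(f"insufficient data: need >= 4 records, got {n}")
    n_train = int(round(fraction * n))
    n_train = min(max(n_train, 1), n - 1)
    perm = np.random.default_rng(seed).permutation(n)
    labels = np.empty(n, dtype=object)
    labels[perm[:n_train]] = "train"
    labels[perm[n_train:]] = "test"
    out = occ.copy()
    out.records["partition"] = labels
    return out


def environmental_coverage(occ: OccurrenceSet, stack: EnvStack) -> pd.Series:
    """Per variable, the fraction of the full data's min-max range spanned
    by the training subset (1.0 when the full range is degenerate)."""
    env_all = stack.extract(occ.coords[:, 0], occ.coords[:, 1])
    train = occ.train
    env_train = stack.extract(train.coords[:, 0], train.coords[:, 1])
    cov = {}
    for i, name in enumerate(stack.names):
        a = env_all[:, i][np.isfinite(env_all[:, i])]
        t = env_train[:, i][np.isfinite(env_train[:, i])]
        full = a.max() - a.min() if a.size else 0.0
        cov[name] = 1.0 if full == 0 else float((t.max() - t.min()) / full) if t.size else 0.0
    return pd.Series(cov, name="coverage")


@dataclass
class PredictorSelection:
    """Outcome of the pairwise-correlation filter.

    ``dropped`` rows record (variable, correlated partner, |r| that
    triggered removal); constant variables appear with partner None.
    """

    kept: list[str]
    dropped: pd.DataFrame
    jackknife_gain: pd.Series | None = None

    def audit_table(self) -> pd.DataFrame:
        rows = [{"variable": v, "status": "kept", "partner": "", "abs_r": np.nan}
                for v in self.kept]
        for _, r in self.dropped.iterrows():
            rows.append({"variable": r["variable"], "status": "dropped",
                         "partner": r["partner"], "abs_r": r["abs_r"]})
        return pd.DataFrame(rows)


def filter_correlated(
    stack: EnvStack,
    threshold: float = 0.8,
    ranking: dict | pd.Series | None = None,
    sample: np.ndarray | None = None,
) -> PredictorSelection:
    """Iteratively drop the lower-ranked member of each highly correlated pair.

    Pearson correlations are computed over ``sample`` (rows = cells,
    columns = variables; defaults to all valid cells of the calibration
    stack). While any surviving pair has |r| >= ``threshold``, the pair
    with the largest |r| is resolved by dropping its lower-ranked
    variable. Constant variables have undefined correlations: they are
    dropped up front with a warning.
    """
    if not 0 < threshold <= 1:
        raise ConfigurationError("threshold must be in (0, 1]")
    names = list(stack.names)
    if ranking is None:
        ranking = {n: -i for i, n in enumerate(names)}  # earlier = higher rank
    ranking = pd.Series(ranking)
    missing = set(names) - set(ranking.index)
    if missing:
        raise ConfigurationError(f"ranking missing for {sorted(missing)}")
    X = stack.table() if sample is None else np.asarray(sample, dtype=float)
    if X.shape[1] != len(names):
        raise ConfigurationError("sample has wrong number of columns")

    dropped_rows = []
    alive = []
    for j, name in enumerate(names):
        if np.std(X[:, j]) == 0:
            warnings.warn(f"variable {name!r} is constant; dropping it")
            dropped_rows.append({"variable": name, "partner": None, "abs_r": np.nan})
        else:
            alive.append(j)

    while len(alive) > 1:
        corr = np.corrcoef(X[:, alive], rowvar=False)
        np.fill_diagonal(corr, 0.0)
        absr = np.abs(corr)
        i, j = np.unravel_index(np.argmax(absr), absr.shape)
        if absr[i, j] < threshold:
            break
        a, b = names[alive[i]], names[alive[j]]
        # drop the lower-ranked; tie broken toward keeping the earlier name
        if (ranking[a], -names.index(a)) >= (ranking[b], -names.index(b)):
            keep_name, drop_name, drop_pos = a, b, j
        else:
            keep_name, drop_name, drop_pos = b, a, i
        dropped_rows.append(
            {"variable": drop_name, "partner": keep_name, "abs_r": float(absr[i, j])}
        )
        del alive[drop_pos]

    kept = [names[k] for k in alive]
    dropped = pd.DataFrame(dropped_rows, columns=["variable", "partner", "abs_r"])
    return PredictorSelection(kept=kept, dropped=dropped)


def jackknife_rank(
    occ: OccurrenceSet,
    stack: EnvStack,
    rm: float = 1.0,
    feature_classes: str = "lq",
    background: np.ndarray | None = None,
    max_background: int = 10000,
    seed: int = 0,
) -> pd.Series:
    """Per-variable importance as single-variable regularized training gain.

    For each predictor a one-variable model is fitted with the given
    settings; its regularized training gain (mean presence log-density
    minus the log of the uniform background density, minus the L1 penalty)
    is returned. A variable whose fit fails gets NaN with a warning.
    """
    from .maxent import MaxentModel, background_table

    if stack.n_vars < 2:
        raise ConfigurationError("jackknife ranking needs >= 2 variables")
    pres = stack.extract(occ.coords[:, 0], occ.coords[:, 1])
    pres = pres[np.isfinite(pres).all(axis=1)]
    if background is None:
        background = background_table(stack, max_background=max_background, seed=seed)
    gains = {}
    for i, name in enumerate(stack.names):
        try:
            model = MaxentModel(feature_classes=feature_classes, rm=rm)
            model.fit_presence_background(pres[:, [i]], background[:, [i]],
                                          names=[name])
            gains[name] = model.training_gain_
        except Exception as exc:  # noqa: BLE001 - record and continue
            warnings.warn(f"single-variable fit failed for {name!r}: {exc}")
            gains[name] = np.nan
    return pd.Series(gains, name="jackknife_gain")
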