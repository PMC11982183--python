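"""Candidate-model calibration and selection.

A candidate grid crosses regularization multipliers with every non-empty
subset of the feature classes (4 RMs x 5 classes = 124 candidates under
the defaults). Each candidate is fitted on the training presences and
scored by

* statistical significance from a bootstrap partial-ROC test on the
  withheld presences (AUC ratio above the null line at sensitivities
  >= 1 - E),
* the omission rate of the withheld presences under the modified lower
  presence threshold at error E, and
* small-sample AICc from the normalized raw densities at the presences.

Selection proceeds significance -> omission <= cut -> delta AICc <= cut,
with delta AICc recomputed among the survivors of the first two stages.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .features import FEATURE_CLASSES
from .grid import ConfigurationError, EnvStack
from .maxent import MaxentModel, background_table
from .occurrences import OccurrenceSet
from .postprocess import lower_presence_threshold

__all__ = [
    "CandidateConfig",
    "enumerate_candidates",
    "omission_rate",
    "PartialROCResult",
    "partial_roc",
    "partial_roc_raster",
    "aicc_score",
    "aicc",
    "select_best",
    "ENMCalibration",
]


@dataclass(frozen=True)
class CandidateConfig:
    rm: float
    classes: str

    def label(self) -> str:
        return f"rm{self.rm:g}_{self.classes}"


def enumerate_candidates(rms=(0.1, 0.5, 1.0, 2.0), classes: str = "lqpth"):
    """All non-empty subsets of ``classes`` crossed with all ``rms``.

    Stable order: subsets by (size, class order), multipliers innermost.
    """
    if not rms:
        raise ConfigurationError("at least one regularization multiplier required")
    cls = [c for c in FEATURE_CLASSES if c in set(classes)]
    if not cls or set(classes) - set(FEATURE_CLASSES):
        raise ConfigurationError(f"classes must be a non-empty subset of "
                                 f"{FEATURE_CLASSES!r}, got {classes!r}")
    configs = []
    for size in range(1, len(cls) + 1):
        for subset in combinations(cls, size):
            for rm in rms:
                configs.append(CandidateConfig(rm=float(rm), classes="".join(subset)))
    return configs


def omission_rate(test_suitabilities, threshold: float) -> float:
    """Fraction of evaluation presences strictly below the threshold."""
    vals = np.asarray(test_suitabilities, dtype=float)
    if vals.size == 0:
        raise ValueError("empty test set")
    return float(np.mean(vals < threshold))


@dataclass
class PartialROCResult:
    mean_auc_ratio: float
    p_value: float
    ratios: np.ndarray


def partial_roc(
    landscape_suitabilities,
    test_suitabilities,
    E: float = 0.05,
    iterations: int = 100,
    sample_fraction: float = 0.5,
    seed: int = 0,
    n_thresholds: int = 100,
) -> PartialROCResult:
    """Bootstrap partial-ROC test of a suitability surface.

    The evaluation region is the threshold range over which the full
    test set keeps sensitivity >= 1 - E (up to its E-omission
    suitability value); it is fixed per dataset and sampled at
    ``n_thresholds`` evenly spaced thresholds. Per iteration,
    ``ceil(sample_fraction * n)`` test presences are resampled with
    replacement; their curve of sensitivity against the proportion of
    the landscape predicted present is integrated (trapezoid) over the
    region and divided by the area under the null diagonal on the same
    region. The p-value is the proportion of iterations with AUC ratio
    <= 1. Fixing the region from the full test set keeps the test
    calibrated under a null surface; re-selecting it from each
    resample's own curve would bias ratios upward.
    """
    if not 0 <= E <= 0.5:
        raise ConfigurationError("E must be in [0, 0.5]")
    if iterations < 1:
        raise ConfigurationError("iterations must be >= 1")
    land = np.asarray(landscape_suitabilities, dtype=float).ravel()
    land = land[np.isfinite(land)]
    test = np.asarray(test_suitabilities, dtype=float).ravel()
    test = test[np.isfinite(test)]
    if test.size < 5:
        raise ValueError("partial ROC needs at least 5 test presences")
    if land.size == 0 or land.min() == land.max():
        raise ValueError("constant suitability surface: AUC ratio undefined")

    # upper edge of the evaluation region: the largest threshold at which
    # the full test set still reaches sensitivity >= 1 - E, i.e. its
    # E-omission suitability value
    v_star = np.sort(test)[int(np.floor(E * test.size))]
    lo = land.min()
    thresholds = np.linspace(lo, v_star, n_thresholds)[::-1]
    land_sorted = np.sort(land)
    # proportion of landscape at or above each threshold (ascending in af)
    af = 1.0 - np.searchsorted(land_sorted, thresholds, side="left") / land.size
    auc_null = np.trapezoid(af, af)
    if not auc_null > 0:
        raise ValueError("degenerate evaluation region: null partial AUC is 0")

    rng = np.random.default_rng(seed)
    m = int(np.ceil(sample_fraction * test.size))
    resamples = test[rng.integers(0, test.size, size=(iterations, m))]
    # per-iteration sensitivity at each threshold of the fixed region
    sens = (resamples[:, :, None] >= thresholds[None, None, :]).mean(axis=1)
    ratios = np.trapezoid(sens, af, axis=1) / auc_null
    return PartialROCResult(
        mean_auc_ratio=float(ratios.mean()),
        p_value=float(np.mean(ratios <= 1.0)),
        ratios=ratios,
    )


def partial_roc_raster(suitability: np.ndarray, grid, occ: OccurrenceSet,
                       **kwargs) -> PartialROCResult:
    """Partial ROC of a suitability raster against test occurrence points."""
    row, col = grid.cell_of(occ.coords[:, 0], occ.coords[:, 1])
    inside = row >= 0
    test = suitability[row[inside], col[inside]]
    return partial_roc(suitability, test, **kwargs)


def aicc_score(n: int, k: int, loglik: float) -> float:
    """Small-sample AICc = 2k - 2 lnL + 2k(k+1)/(n-k-1); NaN when k >= n-1."""
    if k >= n - 1:
        return float("nan")
    return 2.0 * k - 2.0 * loglik + (2.0 * k * (k + 1)) / (n - k - 1)


def aicc(model: MaxentModel, stack: EnvStack, occ: OccurrenceSet) -> float:
    """AICc of a fitted model from raw densities renormalized over the
    landscape, evaluated at the presence points.

    Any presence with zero raw density gives -inf log-likelihood and an
    invalid (NaN) score, as does k >= n - 1.
    """
    raw_land = model.predict_stack(stack, output="raw")
    total = np.nansum(raw_land)
    pres = stack.extract(occ.coords[:, 0], occ.coords[:, 1])
    ok = np.isfinite(pres).all(axis=1)
    raw_i = model.predict_raw(pres[ok]) / total
    n = int(ok.sum())
    if n == 0 or np.any(raw_i <= 0):
        return float("nan")
    loglik = float(np.sum(np.log(raw_i)))
    return aicc_score(n, model.n_nonzero_, loglik)


def select_best(
    results: pd.DataFrame,
    or_cut: float = 0.05,
    daicc_cut: float = 2.0,
    strict: bool = False,
):
    """Significance -> omission -> delta-AICc selection cascade.

    ``results`` must have columns ``proc_p``, ``omission_rate`` and
    ``aicc``. Delta AICc is recomputed among the survivors of the first
    two stages. Returns ``(results_with_flags, selected_index, report)``
    where ``report`` lists how many candidates survived each stage. When
    a stage eliminates everyone, strict mode raises; otherwise the stage
    is skipped (recorded in the report) and the cascade continues.
    """
    if len(results) == 0:
        raise ValueError("no candidates to select from")
    df = results.copy()
    df["significant"] = df["proc_p"] <= 0.05
    df["low_omission"] = df["omission_rate"] <= or_cut
    report = {"candidates": len(df)}

    surviving = df.index
    for stage, flag in (("significant", "significant"), ("low_omission", "low_omission")):
        passed = df.loc[surviving].index[df.loc[surviving, flag]]
        report[stage] = len(passed)
        if len(passed) == 0:
            if strict:
                raise RuntimeError(f"selection failed: no candidate passed "
                                   f"the {stage!r} stage")
            report[f"{stage}_skipped"] = True
        else:
            surviving = passed

    aicc_vals = df.loc[surviving, "aicc"]
    valid = aicc_vals[np.isfinite(aicc_vals)]
    df["delta_aicc"] = np.nan
    if len(valid) == 0:
        if strict:
            raise RuntimeError("selection failed: no surviving candidate has "
                               "a valid AICc")
        report["aicc_skipped"] = True
        selected = list(surviving)
    else:
        df.loc[surviving, "delta_aicc"] = aicc_vals - valid.min()
        selected = list(df.loc[surviving].index[
            df.loc[surviving, "delta_aicc"] <= daicc_cut])
    df["selected"] = df.index.isin(selected)
    report["selected"] = len(selected)
    return df, selected, report


class ENMCalibration(BaseEstimator):
    """Grid-search style calibration over candidate model configurations.

    Follows the scikit-learn searcher idiom: construct with the grid and
    evaluation settings, call :meth:`fit` with a predictor stack and a
    partitioned occurrence set, then inspect ``results_`` (one row per
    candidate), ``selected_`` and ``best_config_``.

    Parameters mirror the study protocol defaults: RM grid
    (0.1, 0.5, 1, 2), all 31 non-empty subsets of "lqpth", evaluation
    error E = 5%, 100 partial-ROC bootstrap iterations on half the test
    data, omission cut 5% and delta-AICc cut 2.
    """

    def __init__(
        self,
        rms=(0.1, 0.5, 1.0, 2.0),
        feature_classes: str = "lqpth",
        E: float = 0.05,
        proc_iterations: int = 100,
        proc_sample_fraction: float = 0.5,
        or_cut: float = 0.05,
        daicc_cut: float = 2.0,
        strict: bool = False,
        n_hinge_knots: int = 10,
        n_threshold_knots: int = 10,
        seed: int = 0,
    ):
        self.rms = rms
        self.feature_classes = feature_classes
        self.E = E
        self.proc_iterations = proc_iterations
        self.proc_sample_fraction = proc_sample_fraction
        self.or_cut = or_cut
        self.daicc_cut = daicc_cut
        self.strict = strict
        self.n_hinge_knots = n_hinge_knots
        self.n_threshold_knots = n_threshold_knots
        self.seed = seed

    def fit(self, stack: EnvStack, occ: OccurrenceSet):
        """Evaluate every candidate on the train/test partition of ``occ``."""
        train, test = occ.train, occ.test
        if len(train) == 0 or len(test) == 0:
            raise ValueError("occurrence set must have non-empty train and test parts")
        pres_train = stack.extract(train.coords[:, 0], train.coords[:, 1])
        pres_train = pres_train[np.isfinite(pres_train).all(axis=1)]
        pres_test = stack.extract(test.coords[:, 0], test.coords[:, 1])
        pres_test = pres_test[np.isfinite(pres_test).all(axis=1)]
        background = background_table(stack, seed=self.seed)

        self.candidates_ = enumerate_candidates(self.rms, self.feature_classes)
        rows = []
        self.models_ = {}
        for idx, cand in enumerate(self.candidates_):
            row = {"rm": cand.rm, "classes": cand.classes, "label": cand.label(),
                   "proc_mean_auc_ratio": np.nan, "proc_p": np.nan,
                   "omission_rate": np.nan, "aicc": np.nan, "k": np.nan,
                   "error": ""}
            try:
                model = MaxentModel(
                    feature_classes=cand.classes, rm=cand.rm,
                    n_hinge_knots=self.n_hinge_knots,
                    n_threshold_knots=self.n_threshold_knots,
                )
                model.fit_presence_background(pres_train, background,
                                              names=stack.names)
                land = model.predict_stack(stack, output="logistic")
                suit_train = model.predict_logistic(pres_train)
                suit_test = model.predict_logistic(pres_test)
                proc = partial_roc(
                    land, suit_test, E=self.E,
                    iterations=self.proc_iterations,
                    sample_fraction=self.proc_sample_fraction,
                    seed=self.seed + idx,
                )
                thr = lower_presence_threshold(suit_train, self.E,
                                               conservative=True)
                row.update(
                    proc_mean_auc_ratio=proc.mean_auc_ratio,
                    proc_p=proc.p_value,
                    omission_rate=omission_rate(suit_test, thr),
                    aicc=aicc(model, stack, occ.train),
                    k=model.n_nonzero_,
                )
                self.models_[cand.label()] = model
            except (ValueError, RuntimeError, ConfigurationError) as exc:
                row["error"] = str(exc)
            rows.append(row)
        results = pd.DataFrame(rows)
        results, selected_idx, report = select_best(
            results, or_cut=self.or_cut, daicc_cut=self.daicc_cut,
            strict=self.strict,
        )
        self.results_ = results
        self.selection_report_ = report
        self.selected_ = [self.candidates_[i] for i in selected_idx]
        if self.selected_:
            # among selected, prefer the lowest AICc (then fewest parameters)
            sel = results.loc[selected_idx].sort_values(["aicc", "k"])
            best_i = sel.index[0]
            self.best_config_ = self.candidates_[best_i]
            self.best_model_ = self.models_.get(self.best_config_.label())
        else:
            self.best_config_ = None
            self.best_model_ = None
        return self
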