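"""Feature construction for presence-background maximum-entropy models.

Predictors are expanded into the five classic feature classes — linear
(l), quadratic (q), product (p), threshold (t) and hinge (h) — and every
feature column is min-max rescaled to [0, 1] using constants derived from
the background sample, so penalties are comparable across classes.
Threshold and hinge knots are placed evenly over the background range of
each variable. On transfer, input values can be clamped to the background
range seen at fit time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grid import ConfigurationError

__all__ = ["FeatureSpec", "FeatureExpander", "FEATURE_CLASSES"]

FEATURE_CLASSES = "lqpth"


@dataclass(frozen=True)
class FeatureSpec:
    """Which feature classes to build, and how many knots for t/h.

    ``classes`` is a non-empty string over {l, q, p, t, h} (order
    irrelevant, duplicates ignored).
    """

    classes: str = "lqpth"
    n_hinge_knots: int = 10
    n_threshold_knots: int = 10

    def __post_init__(self) -> None:
        cls = set(self.classes)
        if not cls:
            raise ConfigurationError("feature classes must be non-empty")
        unknown = cls - set(FEATURE_CLASSES)
        if unknown:
            raise ConfigurationError(f"unknown feature classes {sorted(unknown)}")
        if "h" in cls and self.n_hinge_knots < 2:
            raise ConfigurationError("hinge features need >= 2 knots")
        if "t" in cls and self.n_threshold_knots < 2:
            raise ConfigurationError("threshold features need >= 2 knots")

    @property
    def class_set(self) -> frozenset:
        return frozenset(self.classes)

    def canonical(self) -> str:
        return "".join(c for c in FEATURE_CLASSES if c in self.class_set)


class FeatureExpander:
    """Deterministic expansion of raw predictor values into scaled features.

    Fit on the background sample; afterwards :meth:`transform` maps any
    (n, n_vars) array to an (n, n_features) array in [0, 1] (up to
    extrapolation when clamping is off).

    Attributes
    ----------
    feature_names_ : list of str
    feature_class_ : ndarray of single-character class codes per feature
    var_min_, var_max_ : per-variable clamp bounds (background range)
    """

    def __init__(self, spec: FeatureSpec):
        self.spec = spec

    def fit(self, background: np.ndarray, names: list[str] | None = None):
        X = np.asarray(background, dtype=float)
        if X.ndim != 2 or X.shape[0] < 2:
            raise ConfigurationError("background must be a 2-D array with >= 2 rows")
        if not np.isfinite(X).all():
            raise ValueError("non-finite values in background sample")
        n_vars = X.shape[1]
        self.var_names_ = list(names) if names is not None else [
            f"var{i + 1}" for i in range(n_vars)
        ]
        if len(self.var_names_) != n_vars:
            raise ConfigurationError("names length does not match columns")
        self.var_min_ = X.min(axis=0)
        self.var_max_ = X.max(axis=0)

        self.hinge_knots_ = {}
        self.threshold_knots_ = {}
        cls = self.spec.class_set
        for j, name in enumerate(self.var_names_):
            lo, hi = self.var_min_[j], self.var_max_[j]
            if "h" in cls:
                # forward hinges rise from knot to max; reverse fall from knot to min
                k = self.spec.n_hinge_knots
                self.hinge_knots_[name] = np.linspace(lo, hi, k + 1)
            if "t" in cls:
                k = self.spec.n_threshold_knots
                self.threshold_knots_[name] = np.linspace(lo, hi, k + 2)[1:-1]
        # scaling constants from the raw (unscaled) background features
        raw = self._raw_features(X)
        self.feature_names_, self.feature_class_ = self._feature_meta()
        self.feat_min_ = raw.min(axis=0)
        self.feat_max_ = raw.max(axis=0)
        self.n_features_ = raw.shape[1]
        return self

    # -- construction ------------------------------------------------------

    def _feature_meta(self):
        names, classes = [], []
        cls = self.spec.class_set
        vn = self.var_names_
        if "l" in cls:
            for v in vn:
                names.append(f"l({v})")
                classes.append("l")
        if "q" in cls:
            for v in vn:
                names.append(f"q({v})")
                classes.append("q")
        if "p" in cls:
            for a in range(len(vn)):
                for b in range(a + 1, len(vn)):
                    names.append(f"p({vn[a]}*{vn[b]})")
                    classes.append("p")
        if "t" in cls:
            for v in vn:
                for knot in self.threshold_knots_[v]:
                    names.append(f"t({v}:{knot:.6g})")
                    classes.append("t")
        if "h" in cls:
            for v in vn:
                knots = self.hinge_knots_[v]
                for knot in knots[:-1]:
                    names.append(f"h({v}:fwd:{knot:.6g})")
                    classes.append("h")
                for knot in knots[1:]:
                    names.append(f"h({v}:rev:{knot:.6g})")
                    classes.append("h")
        return names, np.array(classes)

    def _raw_features(self, X: np.ndarray) -> np.ndarray:
        cols = []
        cls = self.spec.class_set
        n_vars = X.shape[1]
        if "l" in cls:
            cols.append(X)
        if "q" in cls:
            cols.append(X**2)
        if "p" in cls:
            prods = [X[:, a] * X[:, b]
                     for a in range(n_vars) for b in range(a + 1, n_vars)]
            if prods:
                cols.append(np.column_stack(prods))
        if "t" in cls:
            tcols = []
            for j, name in enumerate(self.var_names_):
                for knot in self.threshold_knots_[name]:
                    tcols.append((X[:, j] > knot).astype(float))
            if tcols:
                cols.append(np.column_stack(tcols))
        if "h" in cls:
            hcols = []
            for j, name in enumerate(self.var_names_):
                knots = self.hinge_knots_[name]
                lo, hi = knots[0], knots[-1]
                for knot in knots[:-1]:
                    denom = hi - knot
                    hcols.append(
                        np.clip((X[:, j] - knot) / denom, 0.0, 1.0)
                        if denom > 0 else np.zeros(X.shape[0])
                    )
                for knot in knots[1:]:
                    denom = knot - lo
                    hcols.append(
                        np.clip((knot - X[:, j]) / denom, 0.0, 1.0)
                        if denom > 0 else np.zeros(X.shape[0])
                    )
            if hcols:
                cols.append(np.column_stack(hcols))
        if not cols:
            return np.empty((X.shape[0], 0))
        return np.concatenate(cols, axis=1)

    def transform(self, X: np.ndarray, clamp: bool = True) -> np.ndarray:
        """Expanded, [0, 1]-rescaled feature matrix for raw predictor values."""
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != len(self.var_names_):
            raise ConfigurationError(
                f"expected {len(self.var_names_)} columns, got {X.shape}"
            )
        if not np.isfinite(X).all():
            raise ValueError("non-finite values in input")
        if clamp:
            X = np.clip(X, self.var_min_, self.var_max_)
        raw = self._raw_features(X)
        span = self.feat_max_ - self.feat_min_
        safe = np.where(span > 0, span, 1.0)
        scaled = (raw - self.feat_min_) / safe
        scaled[:, span == 0] = 0.0
        return scaled

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "spec": {
                "classes": self.spec.canonical(),
                "n_hinge_knots": self.spec.n_hinge_knots,
                "n_threshold_knots": self.spec.n_threshold_knots,
            },
            "var_names": self.var_names_,
            "var_min": self.var_min_.tolist(),
            "var_max": self.var_max_.tolist(),
            "hinge_knots": {k: v.tolist() for k, v in self.hinge_knots_.items()},
            "threshold_knots": {k: v.tolist() for k, v in self.threshold_knots_.items()},
            "feat_min": self.feat_min_.tolist(),
            "feat_max": self.feat_max_.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureExpander":
        spec = FeatureSpec(**d["spec"])
        exp = cls(spec)
        exp.var_names_ = list(d["var_names"])
        exp.var_min_ = np.asarray(d["var_min"], dtype=float)
        exp.var_max_ = np.asarray(d["var_max"], dtype=float)
        exp.hinge_knots_ = {k: np.asarray(v, dtype=float)
                            for k, v in d["hinge_knots"].items()}
        exp.threshold_knots_ = {k: np.asarray(v, dtype=float)
                                for k, v in d["threshold_knots"].items()}
        exp.feature_names_, exp.feature_class_ = exp._feature_meta()
        exp.feat_min_ = np.asarray(d["feat_min"], dtype=float)
        exp.feat_max_ = np.asarray(d["feat_max"], dtype=float)
        exp.n_features_ = len(exp.feature_names_)
        return exp
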