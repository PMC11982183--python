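"""L1-penalized presence-background maximum-entropy model.

The model places a Gibbs density ``raw(x) = exp(lambda . f(x)) / Z`` over
the background cells of the calibration area, with features f built by
:class:`enmrisk.features.FeatureExpander`. The coefficient vector lambda
minimizes the convex objective

    -(1/m) sum_i lambda . f(x_i)  +  log Z(lambda)  +  sum_j beta_j |lambda_j|

over the m presence points, where ``beta_j = rm * c_class * sd_j / sqrt(m)``
is the per-feature L1 penalty: ``rm`` is the regularization multiplier,
``c_class`` a class-specific constant (l/q/p 1.0, hinge 0.5, threshold
2.0) and ``sd_j`` the feature's sample standard deviation over the
presences. This is the standard regularized Gibbs formulation; it shares
its optimum with the classic sequential-update algorithm but is solved
here with a bound-constrained quasi-Newton method on the positive/negative
split of lambda.

Raw output sums to one over the background; the logistic output is
``tau e^H raw / ((1 - tau) + tau e^H raw)`` with the background entropy H
and default prevalence tau = 0.5, so a cell of typical suitability maps
to about 0.5.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp
from sklearn.base import BaseEstimator

from .features import FeatureExpander, FeatureSpec
from .grid import ConfigurationError, EnvStack
from .occurrences import OccurrenceSet

__all__ = [
    "MaxentModel",
    "background_table",
    "bootstrap_final",
    "BootstrapResult",
    "CLASS_PENALTY",
]

# class-specific base penalty multipliers (documented constants)
CLASS_PENALTY = {"l": 1.0, "q": 1.0, "p": 1.0, "h": 0.5, "t": 2.0}


def background_table(
    stack: EnvStack,
    max_cells: int = 50000,
    max_background: int = 10000,
    seed: int = 0,
) -> np.ndarray:
    """Background sample: all valid cells when there are at most
    ``max_cells``, otherwise a seeded uniform sample of ``max_background``."""
    table = stack.table()
    if table.shape[0] <= max_cells:
        return table
    rng = np.random.default_rng(seed)
    idx = rng.choice(table.shape[0], size=max_background, replace=False)
    return table[idx]


class MaxentModel(BaseEstimator):
    """Presence-background maximum-entropy species distribution model.

    Parameters
    ----------
    feature_classes : str
        Non-empty subset of "lqpth".
    rm : float
        Regularization multiplier scaling all L1 penalties (> 0).
    n_hinge_knots, n_threshold_knots : int
        Knots per variable for hinge/threshold features.
    clamp : bool
        Clamp transfer inputs to the background range seen at fit time.
    tau : float
        Prevalence constant of the logistic output.
    tol : float
        Projected-gradient tolerance of the solver.
    coef_threshold : float
        Coefficients with |lambda| below this are set to exactly zero.

    Attributes (after fit)
    ----------------------
    coef_ : ndarray, penalized coefficients (one per feature)
    feature_names_ : list of str
    expander_ : fitted FeatureExpander (normalizing constants)
    log_z_ : float, log of the density normalizer over the background
    entropy_ : float, Shannon entropy H of the background raw distribution
    n_nonzero_ : int, number of nonzero coefficients (the AICc "k")
    training_gain_ : float, regularized training gain
    """

    def __init__(
        self,
        feature_classes: str = "lqpth",
        rm: float = 1.0,
        n_hinge_knots: int = 10,
        n_threshold_knots: int = 10,
        clamp: bool = True,
        tau: float = 0.5,
        tol: float = 1e-6,
        max_iter: int = 2000,
        coef_threshold: float = 1e-5,
    ):
        self.feature_classes = feature_classes
        self.rm = rm
        self.n_hinge_knots = n_hinge_knots
        self.n_threshold_knots = n_threshold_knots
        self.clamp = clamp
        self.tau = tau
        self.tol = tol
        self.max_iter = max_iter
        self.coef_threshold = coef_threshold

    # -- fitting -----------------------------------------------------------

    def fit(self, X, y):
        """Scikit-learn entry point: rows with y == 1 are presences, rows
        with y == 0 the background sample."""
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if set(np.unique(y)) - {0, 1}:
            raise ValueError("y must contain only 0 (background) and 1 (presence)")
        return self.fit_presence_background(X[y == 1], X[y == 0])

    def fit_presence_background(self, X_presence, X_background, names=None):
        """Fit from separate presence and background predictor tables."""
        if not self.rm > 0:
            raise ConfigurationError("rm must be > 0")
        Xp = np.asarray(X_presence, dtype=float)
        Xb = np.asarray(X_background, dtype=float)
        if Xp.ndim != 2 or Xp.shape[0] < 1:
            raise ValueError("at least one presence is required")
        if Xb.ndim != 2 or Xb.shape[0] < 2:
            raise ValueError("background must have at least 2 rows")
        if Xp.shape[1] != Xb.shape[1]:
            raise ValueError("presence and background have different variables")

        spec = FeatureSpec(self.feature_classes, self.n_hinge_knots,
                           self.n_threshold_knots)
        self.expander_ = FeatureExpander(spec).fit(Xb, names=names)
        Fp = self.expander_.transform(Xp, clamp=self.clamp)
        Fb = self.expander_.transform(Xb, clamp=False)
        m, n_feat = Fp.shape
        if n_feat == 0:
            raise ConfigurationError("feature expansion produced no features")

        sd = Fp.std(axis=0)
        class_mult = np.array([CLASS_PENALTY[c] for c in self.expander_.feature_class_])
        beta = self.rm * class_mult * np.where(sd > 0, sd, 1.0) / np.sqrt(m)
        self.penalties_ = beta

        fbar = Fp.mean(axis=0)

        def objective(u):
            lam = u[:n_feat] - u[n_feat:]
            eta_b = Fb @ lam
            lz = logsumexp(eta_b)
            p = np.exp(eta_b - lz)
            obj = -fbar @ lam + lz + beta @ (u[:n_feat] + u[n_feat:])
            g = -fbar + p @ Fb
            grad = np.concatenate([g + beta, -g + beta])
            return obj, grad

        u0 = np.zeros(2 * n_feat)
        res = minimize(
            objective, u0, jac=True, method="L-BFGS-B",
            bounds=[(0.0, None)] * (2 * n_feat),
            options={"maxiter": self.max_iter, "ftol": 1e-14, "gtol": self.tol},
        )
        if not np.isfinite(res.fun):
            raise RuntimeError(f"maxent fit failed: {res.message}")
        lam = res.x[:n_feat] - res.x[n_feat:]
        lam[np.abs(lam) < self.coef_threshold] = 0.0
        self.coef_ = lam
        self.feature_names_ = list(self.expander_.feature_names_)
        self.n_features_in_ = Xp.shape[1]
        self.n_nonzero_ = int(np.count_nonzero(lam))

        eta_b = Fb @ lam
        self.log_z_ = float(logsumexp(eta_b))
        p = np.exp(eta_b - self.log_z_)
        with np.errstate(divide="ignore", invalid="ignore"):
            self.entropy_ = float(-np.sum(np.where(p > 0, p * np.log(p), 0.0)))
        self.n_background_ = Xb.shape[0]
        self.n_presence_ = m
        mean_log_raw = float(fbar @ lam - self.log_z_)
        self.training_gain_ = (
            mean_log_raw + np.log(self.n_background_) - float(beta @ np.abs(lam))
        )
        self.converged_ = bool(res.success)
        return self

    # -- prediction --------------------------------------------------------

    def _check_fitted(self):
        if not hasattr(self, "coef_"):
            raise RuntimeError("model is not fitted")

    def linear_predictor(self, X) -> np.ndarray:
        self._check_fitted()
        F = self.expander_.transform(np.asarray(X, dtype=float), clamp=self.clamp)
        return F @ self.coef_

    def predict_raw(self, X) -> np.ndarray:
        """Gibbs density exp(lambda . f - log Z); sums to 1 over the
        fitting background."""
        return np.exp(self.linear_predictor(X) - self.log_z_)

    def predict_logistic(self, X) -> np.ndarray:
        eta = self.linear_predictor(X) - self.log_z_ + self.entropy_
        t = self.tau
        with np.errstate(over="ignore"):
            e = np.exp(eta)
        return t * e / ((1 - t) + t * e)

    def predict(self, X, output: str = "logistic") -> np.ndarray:
        if output == "logistic":
            return self.predict_logistic(X)
        if output == "raw":
            return self.predict_raw(X)
        raise ConfigurationError(f"unknown output type {output!r}")

    def predict_stack(self, stack: EnvStack, output: str = "logistic") -> np.ndarray:
        """Suitability raster over a predictor stack (NaN outside the mask)."""
        self._check_fitted()
        missing = set(self.expander_.var_names_) - set(stack.names)
        if missing:
            raise ValueError(f"stack is missing model variables {sorted(missing)}")
        idx = [stack.names.index(v) for v in self.expander_.var_names_]
        table = stack.data[idx][:, stack.mask].T
        vals = self.predict(table, output=output)
        out = np.full(stack.grid.shape, np.nan)
        out[stack.mask] = vals
        return out

    # -- serialization -----------------------------------------------------

    def to_json(self, path=None) -> str:
        """Plain-text lambdas file: features, coefficients, normalizers,
        entropy and normalizer so predictions are reproducible later."""
        self._check_fitted()
        d = {
            "params": self.get_params(),
            "expander": self.expander_.to_dict(),
            "coef": self.coef_.tolist(),
            "log_z": self.log_z_,
            "entropy": self.entropy_,
            "n_background": self.n_background_,
            "n_presence": self.n_presence_,
            "training_gain": self.training_gain_,
        }
        text = json.dumps(d, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "MaxentModel":
        if isinstance(source, str) and source.lstrip().startswith("{"):
            d = json.loads(source)
        else:
            with open(source) as fh:
                d = json.load(fh)
        model = cls(**d["params"])
        model.expander_ = FeatureExpander.from_dict(d["expander"])
        model.coef_ = np.asarray(d["coef"], dtype=float)
        model.feature_names_ = list(model.expander_.feature_names_)
        model.log_z_ = float(d["log_z"])
        model.entropy_ = float(d["entropy"])
        model.n_background_ = int(d["n_background"])
        model.n_presence_ = int(d["n_presence"])
        model.training_gain_ = float(d["training_gain"])
        model.n_nonzero_ = int(np.count_nonzero(model.coef_))
        model.n_features_in_ = len(model.expander_.var_names_)
        return model


@dataclass
class BootstrapResult:
    """Final-model ensemble: per-replicate logistic surfaces and their mean."""

    mean: np.ndarray
    replicates: np.ndarray  # (B, n_rows, n_cols)
    models: list


def bootstrap_final(
    stack: EnvStack,
    occ: OccurrenceSet,
    feature_classes: str = "lqpth",
    rm: float = 1.0,
    B: int = 5,
    seed: int = 0,
    background: np.ndarray | None = None,
    resample: bool = True,
    allow_partial: bool = False,
    **model_kwargs,
) -> BootstrapResult:
    """Final model over the complete occurrence set via B bootstrap trials.

    Each replicate refits the chosen configuration on a resample (with
    replacement) of the presences; the ensemble mean of the logistic
    surfaces is the final prediction. With ``resample=False`` every
    replicate uses the presences as-is (B=1 then equals a single fit).
    """
    if B < 1:
        raise ConfigurationError("B must be >= 1")
    pres = stack.extract(occ.coords[:, 0], occ.coords[:, 1])
    pres = pres[np.isfinite(pres).all(axis=1)]
    if len(pres) == 0:
        raise ValueError("no presences fall on valid cells")
    if background is None:
        background = background_table(stack, seed=seed)
    rng = np.random.default_rng(seed)
    surfaces, models, failures = [], [], []
    for b in range(B):
        rows = (rng.integers(0, len(pres), len(pres)) if resample
                else np.arange(len(pres)))
        model = MaxentModel(feature_classes=feature_classes, rm=rm, **model_kwargs)
        try:
            model.fit_presence_background(pres[rows], background, names=stack.names)
        except Exception as exc:  # noqa: BLE001
            failures.append((b, exc))
            continue
        surfaces.append(model.predict_stack(stack, output="logistic"))
        models.append(model)
    if failures and not allow_partial:
        raise RuntimeError(f"{len(failures)} bootstrap replicate(s) failed: "
                           f"{failures[0][1]}")
    if not surfaces:
        raise RuntimeError("all bootstrap replicates failed")
    reps = np.stack(surfaces)
    return BootstrapResult(mean=reps.mean(axis=0), replicates=reps, models=models)
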