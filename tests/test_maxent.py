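"""Maximum-entropy model: feature expansion, penalized fit (against
brute-force oracles), prediction contracts and the bootstrap ensemble."""

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.special import logsumexp

import enmrisk as er
from enmrisk.features import FeatureExpander, FeatureSpec
from enmrisk.maxent import CLASS_PENALTY


def penalized_objective(lam, Fp, Fb, beta):
    """The fit criterion, recomputed independently of the estimator."""
    lam = np.asarray(lam, dtype=float)
    return (-Fp.mean(axis=0) @ lam + logsumexp(Fb @ lam)
            + beta @ np.abs(lam))


class TestFeatures:
    def test_feature_counts(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((50, 3))
        f_l = FeatureExpander(FeatureSpec("l")).fit(X)
        assert f_l.n_features_ == 3
        f_lp = FeatureExpander(FeatureSpec("lp")).fit(X)
        assert f_lp.n_features_ == 3 + 3  # C(3,2) products
        f_t = FeatureExpander(FeatureSpec("t", n_threshold_knots=7)).fit(X)
        assert f_t.n_features_ == 3 * 7

    def test_forward_hinge_shape(self):
        X = np.linspace(0.0, 10.0, 101)[:, None]
        exp = FeatureExpander(FeatureSpec("h", n_hinge_knots=5)).fit(X)
        F = exp.transform(X)
        fwd_idx = [i for i, n in enumerate(exp.feature_names_) if ":fwd:" in n]
        knots = exp.hinge_knots_["var1"]
        for col, knot in zip(fwd_idx, knots[:-1]):
            vals = F[:, col]
            below = X[:, 0] <= knot
            assert np.all(vals[below] == 0.0)
            assert vals[-1] == pytest.approx(1.0)
            above = ~below
            slope = np.diff(vals[above]) / np.diff(X[above, 0])
            assert np.allclose(slope, slope[0])  # rises linearly to 1 at max

    def test_scaled_to_unit_interval_on_background(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((200, 2)) * 3
        exp = FeatureExpander(FeatureSpec("lqpth")).fit(X)
        F = exp.transform(X)
        assert F.min() >= 0.0 and F.max() <= 1.0

    def test_nonfinite_rejected(self):
        exp = FeatureExpander(FeatureSpec("l")).fit(np.zeros((5, 1)) + [[1.0]])
        with pytest.raises(ValueError):
            exp.transform(np.array([[np.nan]]))


class TestFit:
    def test_uniform_presences_give_flat_model(self):
        rng = np.random.default_rng(2)
        bg = rng.standard_normal((1000, 2))
        pres = bg[rng.integers(0, 1000, 1000)]  # presences ~ background
        m = er.MaxentModel(feature_classes="l", rm=1.0)
        m.fit_presence_background(pres, bg)
        assert np.all(np.abs(m.coef_) <= 1e-2)
        assert m.entropy_ == pytest.approx(np.log(1000), rel=0.01)

    def test_sign_recovery_against_grid_search_oracle(self):
        # presences concentrated where var1 > 1 sd must give a positive
        # linear coefficient; cross-checked against a 1-D grid search of
        # the same penalized likelihood
        rng = np.random.default_rng(3)
        bg = rng.standard_normal((500, 1))
        pres = bg[bg[:, 0] > 1.0]
        m = er.MaxentModel(feature_classes="l", rm=1.0)
        m.fit_presence_background(pres, bg)
        assert m.coef_[0] > 0

        Fp = m.expander_.transform(pres)
        Fb = m.expander_.transform(bg, clamp=False)
        grid = np.linspace(-20, 20, 4001)
        vals = [penalized_objective([g], Fp, Fb, m.penalties_) for g in grid]
        assert grid[int(np.argmin(vals))] > 0
        assert abs(grid[int(np.argmin(vals))] - m.coef_[0]) <= 0.02

    def test_oracle_equivalence_linear_two_vars(self):
        # on {l}-only specs the solver must match an independent
        # derivative-free minimizer of the same objective
        for seed in range(3):
            rng = np.random.default_rng(seed)
            bg = rng.standard_normal((200, 2))
            w = np.exp(0.8 * bg[:, 0] - 0.5 * bg[:, 1])
            pres = bg[rng.choice(200, 100, p=w / w.sum())]
            m = er.MaxentModel(feature_classes="l", rm=0.5)
            m.fit_presence_background(pres, bg)
            Fp = m.expander_.transform(pres)
            Fb = m.expander_.transform(bg, clamp=False)
            res = minimize(penalized_objective, np.zeros(2),
                           args=(Fp, Fb, m.penalties_),
                           method="Nelder-Mead",
                           options={"xatol": 1e-8, "fatol": 1e-12,
                                    "maxiter": 5000})
            assert np.all(np.abs(res.x - m.coef_) <= 1e-2)

    @pytest.mark.parametrize("seed", range(10))
    def test_stronger_regularization_never_adds_coefficients(self, seed):
        rng = np.random.default_rng(seed)
        bg = rng.standard_normal((300, 2))
        w = np.exp(0.6 * bg[:, 0])
        pres = bg[rng.choice(300, 60, p=w / w.sum())]
        counts = []
        for rm in (0.5, 1.0, 2.0):
            m = er.MaxentModel(feature_classes="lqp", rm=rm)
            m.fit_presence_background(pres, bg)
            counts.append(m.n_nonzero_)
        assert counts[0] >= counts[1] >= counts[2]

    def test_penalty_scaling_constants(self):
        rng = np.random.default_rng(4)
        bg = rng.standard_normal((100, 1))
        pres = bg[:20]
        m = er.MaxentModel(feature_classes="lt", rm=2.0)
        m.fit_presence_background(pres, bg)
        cls = m.expander_.feature_class_
        Fp = m.expander_.transform(pres)
        sd = Fp.std(axis=0)
        expect = 2.0 * np.array([CLASS_PENALTY[c] for c in cls]) \
            * np.where(sd > 0, sd, 1.0) / np.sqrt(20)
        np.testing.assert_allclose(m.penalties_, expect)

    def test_input_validation(self):
        m = er.MaxentModel()
        with pytest.raises(ValueError):
            m.fit(np.zeros((4, 2)), np.array([0, 1, 2, 1]))
        with pytest.raises(ValueError):
            m.fit_presence_background(np.zeros((0, 2)), np.zeros((10, 2)))


@pytest.fixture(scope="module")
def fitted(bench):
    stack, occ = bench["stack"], bench["occ"]
    pres = stack.extract(occ.coords[:, 0], occ.coords[:, 1])
    m = er.MaxentModel(feature_classes="lq", rm=1.0)
    m.fit_presence_background(pres, er.background_table(stack),
                              names=stack.names)
    return m


class TestPredict:
    def test_raw_sums_to_one_over_background(self, fitted, bench):
        raw = fitted.predict_raw(er.background_table(bench["stack"]))
        assert raw.sum() == pytest.approx(1.0, abs=1e-6)

    def test_logistic_bounded_and_rank_preserving(self, fitted, bench):
        tbl = er.background_table(bench["stack"])
        raw = fitted.predict_raw(tbl)
        logi = fitted.predict_logistic(tbl)
        assert np.all((logi > 0) & (logi < 1))
        order = np.argsort(raw)
        assert np.all(np.diff(logi[order]) >= 0)

    def test_uniform_model_logistic_half(self):
        rng = np.random.default_rng(5)
        bg = rng.standard_normal((400, 1))
        m = er.MaxentModel(feature_classes="l", rm=1e6)  # penalty kills coef
        m.fit_presence_background(bg[:50], bg)
        assert m.n_nonzero_ == 0
        logi = m.predict_logistic(bg)
        np.testing.assert_allclose(logi, 0.5, atol=1e-12)

    def test_missing_variable_rejected(self, fitted, bench):
        stack = bench["stack"]
        partial = er.EnvStack(stack.grid, ["var1"], stack.data[:1].copy())
        with pytest.raises(ValueError, match="missing"):
            fitted.predict_stack(partial)

    def test_serialization_round_trip(self, fitted, bench):
        text = fitted.to_json()
        clone = er.MaxentModel.from_json(text)
        tbl = er.background_table(bench["stack"])
        np.testing.assert_allclose(clone.predict_logistic(tbl),
                                   fitted.predict_logistic(tbl), atol=1e-12)


class TestBootstrap:
    def test_identity_resample_equals_single_fit(self, bench):
        stack, occ = bench["stack"], bench["occ"]
        boot = er.bootstrap_final(stack, occ, feature_classes="lq", rm=1.0,
                                  B=1, seed=1, resample=False)
        pres = stack.extract(occ.coords[:, 0], occ.coords[:, 1])
        pres = pres[np.isfinite(pres).all(axis=1)]
        m = er.MaxentModel(feature_classes="lq", rm=1.0)
        m.fit_presence_background(pres, er.background_table(stack),
                                  names=stack.names)
        np.testing.assert_allclose(boot.mean,
                                   m.predict_stack(stack), atol=1e-8)

    def test_default_five_replicates_mean_bounded(self, bench):
        boot = er.bootstrap_final(bench["stack"], bench["occ"],
                                  feature_classes="lq", rm=1.0, seed=2)
        assert boot.replicates.shape[0] == 5
        lo = boot.replicates.min(axis=0)
        hi = boot.replicates.max(axis=0)
        ok = np.isfinite(boot.mean)
        assert np.all(boot.mean[ok] >= lo[ok] - 1e-12)
        assert np.all(boot.mean[ok] <= hi[ok] + 1e-12)
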