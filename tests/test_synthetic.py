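"""Synthetic-landscape generators: standardization, determinism, spatial
structure, scenario shifts, truth surfaces, sampling and threat layers."""

import numpy as np
import pytest
from scipy.stats import binomtest, chisquare

import enmrisk as er
from enmrisk.grid import ConfigurationError


def morans_i_lag1(field):
    """Direct double-loop Moran's I with rook (lag-1) neighbours."""
    n_rows, n_cols = field.shape
    z = field - field.mean()
    num = den_w = 0.0
    for i in range(n_rows):
        for j in range(n_cols):
            for di, dj in ((0, 1), (0, -1), (1, 0), (-1, 0)):
                a, b = i + di, j + dj
                if 0 <= a < n_rows and 0 <= b < n_cols:
                    num += z[i, j] * z[a, b]
                    den_w += 1
    return (field.size / den_w) * num / (z**2).sum()


class TestEnvStack:
    def test_standardized_layers(self, grid20):
        st = er.make_env_stack(grid20, 3, corr_length=5, seed=1)
        assert st.data.shape == (3, 20, 20)
        for layer in st.data:
            assert abs(layer.mean()) < 1e-9
            assert layer.std() == pytest.approx(1.0, abs=1e-9)

    def test_deterministic(self, grid20):
        a = er.make_env_stack(grid20, 3, corr_length=5, seed=1)
        b = er.make_env_stack(grid20, 3, corr_length=5, seed=1)
        np.testing.assert_array_equal(a.data, b.data)

    def test_correlation_length_raises_morans_i(self, grid20):
        smooth = er.make_env_stack(grid20, 1, corr_length=8, seed=4)
        rough = er.make_env_stack(grid20, 1, corr_length=1, seed=4)
        assert morans_i_lag1(smooth.data[0]) > morans_i_lag1(rough.data[0])

    def test_invalid_spec_rejected(self, grid20):
        with pytest.raises(ConfigurationError):
            er.make_env_stack(grid20, 0, corr_length=5, seed=1)
        with pytest.raises(ConfigurationError):
            er.make_env_stack(grid20, 2, corr_length=0.5, seed=1)
        with pytest.raises(ConfigurationError):
            er.GridSpec(1, 5)


class TestScenario:
    def test_zero_shift_is_identity(self, stack20):
        out = er.apply_scenario(stack20, er.ScenarioShift.zero(), seed=3)
        np.testing.assert_array_equal(out.data, stack20.data)

    def test_additive_shift_moves_mean_exactly(self, stack20):
        shift = er.ScenarioShift(additive={"var1": 1.0})
        out = er.apply_scenario(stack20, shift, seed=3)
        assert out.layer("var1").mean() == pytest.approx(
            stack20.layer("var1").mean() + 1.0, abs=1e-12)
        np.testing.assert_array_equal(out.layer("var2"), stack20.layer("var2"))

    def test_unknown_variable_rejected(self, stack20):
        with pytest.raises(ConfigurationError):
            er.apply_scenario(stack20, er.ScenarioShift(additive={"nope": 1.0}))

    def test_warming_moves_range_poleward(self):
        # species tracks a pure north-south gradient; uniform warming must
        # displace its true range northward (recomputed from the curves)
        grid = er.GridSpec(40, 10)
        y = np.linspace(1.5, -1.5, 40)[:, None] * np.ones((1, 10))
        stack = er.EnvStack(grid, ["var1"], y[None, :, :])
        vs = er.VirtualSpecies({"var1": er.GaussianResponse(0.0, 0.5)})
        now = er.true_range(vs, stack)
        fut = er.true_range(vs, er.apply_scenario(
            stack, er.ScenarioShift(additive={"var1": -0.5})))
        rows_now = np.where(now.presence.any(axis=1))[0]
        rows_fut = np.where(fut.presence.any(axis=1))[0]
        assert rows_fut.mean() < rows_now.mean()  # row 0 is north


class TestTrueSuitability:
    def test_unit_at_optima_and_zero_in_limit(self, species):
        grid = er.GridSpec(2, 2)
        at_opt = er.EnvStack(grid, ["var1", "var2"],
                             np.stack([np.full((2, 2), 0.5),
                                       np.full((2, 2), -0.3)]))
        np.testing.assert_allclose(er.true_suitability(species, at_opt), 1.0)
        curve = er.GaussianResponse(0.0, 1.0)
        assert curve(np.array([1e6]))[0] == pytest.approx(0.0, abs=1e-12)

    def test_product_rule(self):
        # curves yielding 0.8 and 0.5 at the cell combine to 0.4
        grid = er.GridSpec(2, 2)
        x1 = np.full((2, 2), np.sqrt(-2 * np.log(0.8)))
        x2 = np.full((2, 2), np.sqrt(-2 * np.log(0.5)))
        stack = er.EnvStack(grid, ["var1", "var2"], np.stack([x1, x2]))
        vs = er.VirtualSpecies({"var1": er.GaussianResponse(0.0, 1.0),
                                "var2": er.GaussianResponse(0.0, 1.0)})
        np.testing.assert_allclose(er.true_suitability(vs, stack), 0.4, rtol=1e-12)

    def test_missing_curve_variable_rejected(self, stack20):
        vs = er.VirtualSpecies({"nope": er.GaussianResponse(0, 1)})
        with pytest.raises(ConfigurationError):
            er.true_suitability(vs, stack20)


class TestSampling:
    def test_uniform_suitability_uniform_cells(self):
        grid = er.GridSpec(10, 10)
        stack = er.EnvStack(grid, ["var1"], np.zeros((1, 10, 10)))
        vs = er.VirtualSpecies({"var1": er.GaussianResponse(0.0, 1.0)})
        occ = er.sample_occurrences(vs, stack, 5000, seed=5)
        row, col = grid.cell_of(occ.coords[:, 0], occ.coords[:, 1])
        counts = np.bincount(row * 10 + col, minlength=100)
        assert chisquare(counts).pvalue > 0.01

    def test_single_suitable_cell_forces_location(self):
        grid = er.GridSpec(5, 5)
        x = np.full((5, 5), 100.0)
        x[2, 3] = 0.0  # only this cell is at the optimum
        stack = er.EnvStack(grid, ["var1"], x[None])
        vs = er.VirtualSpecies({"var1": er.GaussianResponse(0.0, 0.01)})
        occ = er.sample_occurrences(vs, stack, 50, seed=6)
        row, col = grid.cell_of(occ.coords[:, 0], occ.coords[:, 1])
        assert (row == 2).all() and (col == 3).all()

    def test_bias_concentrates_sampling(self):
        grid = er.GridSpec(10, 10)
        stack = er.EnvStack(grid, ["var1"], np.zeros((1, 10, 10)))
        vs = er.VirtualSpecies({"var1": er.GaussianResponse(0.0, 1.0)})
        bias = np.full((10, 10), 0.1)
        bias[:5, :5] = 10.0  # NW quadrant 100x more likely
        occ = er.sample_occurrences(vs, stack, 400, bias=bias, seed=7)
        row, col = grid.cell_of(occ.coords[:, 0], occ.coords[:, 1])
        in_quad = int(((row < 5) & (col < 5)).sum())
        # quadrant weight = 250 / (250 + 7.5) ~ 0.97; binomial lower bound
        assert binomtest(in_quad, 400, 0.97, alternative="less").pvalue > 1e-4
        assert in_quad / 400 > 0.9

    def test_all_zero_weights_rejected(self):
        grid = er.GridSpec(5, 5)
        stack = er.EnvStack(grid, ["var1"], np.zeros((1, 5, 5)))
        vs = er.VirtualSpecies({"var1": er.GaussianResponse(0.0, 1.0)})
        with pytest.raises(ValueError, match="degenerate"):
            er.sample_occurrences(vs, stack, 10, bias=np.zeros((5, 5)), seed=1)

    def test_reproducible(self, stack20, species):
        a = er.sample_occurrences(species, stack20, 30, seed=9)
        b = er.sample_occurrences(species, stack20, 30, seed=9)
        np.testing.assert_array_equal(a.coords, b.coords)


class TestThreatLayers:
    def test_no_protected_areas(self, grid20):
        hfp, pas = er.make_threat_layers(grid20, n_pa=0, seed=1)
        assert pas == []
        bm = er.BinaryMap(grid20, np.ones(grid20.shape, np.uint8))
        assert er.pa_overlap(bm, pas) == 0.0

    def test_hfp_bounds_and_zero_overlap(self, grid20):
        hfp, _ = er.make_threat_layers(grid20, seed=2)
        assert hfp.min() >= 0 and hfp.max() <= 50
        bm = er.BinaryMap(grid20, np.ones(grid20.shape, np.uint8))
        prop, area_ = er.hfp_overlap(bm, np.zeros(grid20.shape), cut=10)
        assert prop == 0.0 and area_ == 0.0

    def test_rasterized_pa_area_matches_polygon_area(self, grid20):
        _, pas = er.make_threat_layers(grid20, n_pa=5, pa_size_range=(3, 6),
                                       seed=3)
        for poly in pas:
            cells = er.rasterize_polygons([poly], grid20).sum()
            # cell-center rasterization is within one boundary ring
            perimeter_cells = poly.length / grid20.cell_size + 4
            assert abs(cells - poly.area) <= perimeter_cells
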