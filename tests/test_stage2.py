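"""Second-stage regressors: B-spline designs, model kinds, grid search."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ganiv.stage2 import (
    DfnnConfig,
    MfdlConfig,
    bspline_design,
    fit_second_stage,
    predict,
)

FAST = DfnnConfig(lr_grid=(1e-2,), l2_grid=(1e-4,), max_epochs=600)


class TestBsplineDesign:
    @given(
        n_basis=st.integers(min_value=4, max_value=15),
        order=st.integers(min_value=1, max_value=3),
    )
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_partition_of_unity(self, n_basis, order):
        if n_basis < order + 1:
            n_basis = order + 1
        x = np.linspace(-2.0, 3.0, 40)
        B = bspline_design(x, n_basis, order)
        assert np.abs(B.sum(axis=1) - 1.0).max() < 1e-10

    def test_order_zero_is_indicator_basis(self):
        x = np.linspace(0, 1, 23)
        B = bspline_design(x, 6, 0)
        assert np.all((B > 0).sum(axis=1) == 1)
        assert np.allclose(B.max(axis=1), 1.0)

    def test_shape(self):
        assert bspline_design(np.linspace(0, 1, 7), 10, 3).shape == (7, 10)

    def test_too_few_basis_functions_rejected(self):
        with pytest.raises(ValueError):
            bspline_design([0.0, 1.0], 3, 3)

    def test_cubic_basis_reproduces_quadratic_exactly(self):
        # degree-3 splines span quadratics: the OLS fit on the basis
        # interpolates g^2 on the training domain
        x = np.linspace(-2, 2, 200)
        B = bspline_design(x, 10, 3)
        y = x**2
        coef, *_ = np.linalg.lstsq(B, y, rcond=None)
        assert np.abs(B @ coef - y).max() < 1e-8


class TestLinearKind:
    def test_noiseless_linear_fit_exact(self):
        rng = np.random.default_rng(0)
        g = rng.normal(size=100)
        y = 1.0 + 2.0 * g
        m = fit_second_stage(g, y, kind="linear")
        assert m.coef[0] == pytest.approx(1.0, abs=1e-8)
        assert m.coef[1][0] == pytest.approx(2.0, abs=1e-8)
        assert np.abs(predict(m, g) - y).max() < 1e-6

    def test_degenerate_target_rejected(self):
        with pytest.raises(ValueError):
            fit_second_stage(np.arange(10.0), np.ones(10), kind="linear")


class TestNetworkKinds:
    def test_dfnn_outperforms_linear_on_cosine_outcome(self):
        rng = np.random.default_rng(1)
        g = rng.normal(size=800)
        y = 2.0 * np.cos(g) + 0.1 * rng.standard_normal(800)
        tr, te = np.arange(640), np.arange(640, 800)
        dfnn = fit_second_stage(g[tr], y[tr], FAST, kind="dfnn")
        lin = fit_second_stage(g[tr], y[tr], kind="linear")
        mse_dfnn = np.mean((predict(dfnn, g[te]) - y[te]) ** 2)
        mse_lin = np.mean((predict(lin, g[te]) - y[te]) ** 2)
        assert mse_dfnn < mse_lin

    def test_dfnn_recovers_quadratic_on_noiseless_data(self):
        rng = np.random.default_rng(2)
        g = rng.normal(size=1000)
        y = 0.5 * g**2 + g
        tr, te = np.arange(800), np.arange(800, 1000)
        cfg = DfnnConfig(lr_grid=(1e-2, 1e-3), l2_grid=(1e-3, 1e-4),
                         max_epochs=2000)
        m = fit_second_stage(g[tr], y[tr], cfg, kind="dfnn")
        mse = np.mean((predict(m, g[te]) - y[te]) ** 2)
        assert mse < 1e-2 * y.var()

    def test_default_config_values(self):
        cfg = DfnnConfig()
        assert cfg.n_basis == 10
        assert cfg.spline_order == 3
        assert cfg.cv_folds == 3

    def test_mfdl_requires_two_blocks(self):
        with pytest.raises(ValueError):
            fit_second_stage(np.arange(30.0), np.random.default_rng(0).normal(size=30),
                             MfdlConfig(lr_grid=(1e-2,), l2_grid=(1e-4,)),
                             kind="mfdl")

    def test_mfdl_uses_second_modality(self):
        # outcome driven by the tag block; a model seeing both blocks must
        # fit far better than the exposure-only baseline variance
        rng = np.random.default_rng(3)
        g = rng.normal(size=500)
        tags = rng.choice([0.0, 1.0, 2.0], size=(500, 6))
        y = tags @ np.full(6, 0.8) + 0.1 * rng.standard_normal(500)
        cfg = MfdlConfig(lr_grid=(1e-2,), l2_grid=(1e-4,), max_epochs=800)
        m = fit_second_stage([g, tags], y, cfg, kind="mfdl")
        mse = np.mean((predict(m, [g, tags]) - y) ** 2)
        assert mse < 0.25 * y.var()

    def test_early_stopping_history_is_monotone_nonincreasing(self):
        rng = np.random.default_rng(4)
        g = rng.normal(size=400)
        y = np.sin(g) + 0.2 * rng.standard_normal(400)
        m = fit_second_stage(g, y, FAST, kind="shallow_nn")
        hist = np.asarray(m.history)
        assert np.all(np.diff(hist) <= 1e-12)
        assert hist[-1] <= hist[0]

    def test_grid_search_selection_reproducible(self):
        rng = np.random.default_rng(5)
        g = rng.normal(size=300)
        y = g**2 + 0.3 * rng.standard_normal(300)
        cfg = DfnnConfig(lr_grid=(1e-2, 1e-3), l2_grid=(1e-3, 1e-4),
                         max_epochs=300, seed=11)
        sel = [fit_second_stage(g, y, cfg, kind="dfnn").selected for _ in range(2)]
        assert sel[0] == sel[1]

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            fit_second_stage(np.arange(10.0), np.arange(10.0), kind="forest")


@pytest.fixture(scope="module")
def fitted():
    rng = np.random.default_rng(6)
    g = rng.normal(size=300)
    y = np.cos(g) + 0.1 * rng.standard_normal(300)
    return g, fit_second_stage(g, y, FAST, kind="dfnn")


class TestPredict:
    def test_deterministic(self, fitted):
        g, m = fitted
        assert np.array_equal(predict(m, g), predict(m, g))

    def test_permutation_equivariance(self, fitted):
        g, m = fitted
        perm = np.random.default_rng(7).permutation(len(g))
        assert np.allclose(predict(m, g)[perm], predict(m, g[perm]))

    def test_block_shape_mismatch_rejected(self, fitted):
        _, m = fitted
        with pytest.raises(Exception):
            predict(m, [np.zeros((5, 1)), np.zeros((4, 2))])
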