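"""Centering, derivative transforms and the OPLS orthogonal-variation filter."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import chemocal as cc
from chemocal.errors import (
    DegenerateDataError,
    ParameterError,
    ShapeMismatchError,
)
from chemocal.pls import fit_pls1


def _ortho_fixture(rng, n=12, p=40):
    """X = y·aᵀ + t_o·p_oᵀ with t_o ⟂ y and a ∦ p_o."""
    y = rng.normal(size=n)
    y -= y.mean()
    a = rng.normal(size=p)
    t_o = rng.normal(size=n)
    t_o -= (t_o @ y) / (y @ y) * y
    p_o = rng.normal(size=p)
    return np.outer(y, a) + np.outer(t_o, p_o), y, np.outer(y, a)


class TestCentering:
    def test_matches_elementwise_subtraction_oracle(self, rng):
        X = rng.normal(size=(6, 9))
        y = rng.normal(size=6)
        model = cc.fit_center(X, y)
        Xc, yc = cc.apply_center(model, X, y)
        np.testing.assert_allclose(Xc, X - X.mean(axis=0), atol=1e-14)
        np.testing.assert_allclose(yc, y - y.mean(), atol=1e-14)
        assert np.abs(Xc.mean(axis=0)).max() < 1e-12

    def test_identical_rows_center_to_zero(self):
        X = np.tile([1.0, 2.0, 3.0], (4, 1))
        Xc = cc.apply_center(cc.fit_center(X), X)
        assert np.abs(Xc).max() == 0.0

    def test_frozen_on_new_data_and_single_sample_ok(self, rng):
        X = rng.normal(size=(5, 7))
        model = cc.fit_center(X)
        new = rng.normal(size=(1, 7))
        np.testing.assert_allclose(
            cc.apply_center(model, new), new - model.column_means, atol=1e-14
        )

    def test_center_then_uncenter_is_identity(self, rng):
        X = rng.normal(size=(5, 7))
        y = rng.normal(size=5)
        model = cc.fit_center(X, y)
        Xc, yc = cc.apply_center(model, X, y)
        Xu, yu = cc.invert_center(model, Xc, yc)
        np.testing.assert_allclose(Xu, X, atol=1e-14)
        np.testing.assert_allclose(yu, y, atol=1e-14)

    def test_degenerate_and_mismatch_errors(self, rng):
        with pytest.raises(DegenerateDataError):
            cc.fit_center(rng.normal(size=(1, 4)))
        model = cc.fit_center(rng.normal(size=(3, 4)))
        with pytest.raises(ShapeMismatchError):
            cc.apply_center(model, rng.normal(size=(2, 5)))


class TestFirstDerivative:
    def test_constant_spectrum_gives_zero(self):
        sp = cc.SpectraMatrix(np.arange(200.0, 220.0), np.full((2, 20), 0.7), ["a", "b"])
        for method in ("finite_difference", "savitzky_golay"):
            d = cc.first_derivative(sp, method)
            assert np.abs(d.absorbance).max() < 1e-12

    def test_linear_ramp_finite_difference(self):
        grid = np.arange(200.0, 231.0)
        sp = cc.SpectraMatrix(grid, (2.0 * grid)[None, :], ["a"])
        d = cc.first_derivative(sp, "finite_difference")
        assert d.n_wavelengths == 30  # midpoint grid
        np.testing.assert_allclose(d.absorbance, 2.0, atol=1e-12)
        np.testing.assert_allclose(d.wavelengths_nm, 0.5 * (grid[:-1] + grid[1:]))

    def test_savitzky_golay_matches_analytic_cubic(self):
        grid = np.arange(0.0, 51.0)
        poly = 1e-4 * grid**3 - 2e-3 * grid**2 + 0.05 * grid + 1.0
        sp = cc.SpectraMatrix(grid, poly[None, :], ["a"])
        d = cc.first_derivative(sp, "savitzky_golay", window=7, polyorder=3)
        analytic = 3e-4 * grid**2 - 4e-3 * grid + 0.05
        np.testing.assert_allclose(
            d.absorbance[0, 3:-3], analytic[3:-3], atol=1e-8
        )

    def test_parameter_validation(self):
        sp = cc.SpectraMatrix(np.arange(200.0, 210.0), np.zeros((1, 10)), ["a"])
        with pytest.raises(ParameterError):
            cc.first_derivative(sp, "savitzky_golay", window=4)
        with pytest.raises(ParameterError):
            cc.first_derivative(sp, "savitzky_golay", window=5, polyorder=5)
        with pytest.raises(ParameterError):
            cc.first_derivative(sp, "savitzky_golay", window=11)
        with pytest.raises(ParameterError):
            cc.first_derivative(sp, "unknown")

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(
        a=st.floats(-5, 5, allow_nan=False),
        b=st.floats(-5, 5, allow_nan=False),
        seed=st.integers(0, 2**16),
    )
    def test_derivative_operators_are_linear(self, a, b, seed):
        r = np.random.default_rng(seed)
        grid = np.arange(200.0, 240.0)
        X = r.normal(size=(2, 40))
        Y = r.normal(size=(2, 40))
        for method in ("finite_difference", "savitzky_golay"):
            mix = cc.first_derivative(
                cc.SpectraMatrix(grid, a * X + b * Y, ["u", "v"]), method
            )
            dX = cc.first_derivative(cc.SpectraMatrix(grid, X, ["u", "v"]), method)
            dY = cc.first_derivative(cc.SpectraMatrix(grid, Y, ["u", "v"]), method)
            np.testing.assert_allclose(
                mix.absorbance, a * dX.absorbance + b * dY.absorbance, atol=1e-9
            )


class TestOPLS:
    def test_pure_predictive_structure_is_a_noop(self, rng):
        y = rng.normal(size=10)
        y -= y.mean()
        X = np.outer(y, rng.normal(size=25))  # nothing orthogonal to remove
        filt = cc.fit_opls(X, y, n_ortho=1)
        assert filt.n_ortho == 0
        np.testing.assert_allclose(cc.apply_opls(filt, X), X, atol=1e-12)

    def test_removes_constructed_orthogonal_component(self, rng):
        X, y, signal = _ortho_fixture(rng)
        filt = cc.fit_opls(X, y, n_ortho=1)
        Xf = cc.apply_opls(filt, X)
        rel = np.linalg.norm(Xf - signal) / np.linalg.norm(signal)
        assert rel < 1e-8

    def test_removed_scores_orthogonal_to_response(self, noisy_train, train_design):
        y = train_design.column("PR")
        center = cc.fit_center(noisy_train, y)
        Xc, yc = cc.apply_center(center, noisy_train, y)
        filt = cc.fit_opls(Xc.absorbance, yc, n_ortho=2)
        for a in range(filt.n_ortho):
            t_o = Xc.absorbance @ filt.weights[:, a]
            rel = abs(t_o @ yc) / (np.linalg.norm(t_o) * np.linalg.norm(yc))
            assert rel < 1e-8
            assert abs(np.linalg.norm(filt.weights[:, a]) - 1) < 1e-12

    def test_apply_reproduces_fit_time_residual_and_is_idempotent(self, rng):
        X, y, _ = _ortho_fixture(rng)
        filt = cc.fit_opls(X, y, n_ortho=1)
        Xf = cc.apply_opls(filt, X)
        np.testing.assert_allclose(Xf, filt.training_filtered, atol=1e-12)
        np.testing.assert_allclose(cc.apply_opls(filt, Xf), Xf, atol=1e-10)

    def test_empty_filter_is_identity(self, rng):
        X = rng.normal(size=(4, 6))
        filt = cc.OPLSFilter(np.empty((6, 0)), np.empty((6, 0)))
        np.testing.assert_allclose(cc.apply_opls(filt, X), X)

    def test_never_increases_frobenius_norm(self, rng):
        for trial in range(5):
            r = np.random.default_rng(trial)
            X = r.normal(size=(10, 20))
            y = r.normal(size=10)
            y -= y.mean()
            X -= X.mean(axis=0)
            filt = cc.fit_opls(X, y, n_ortho=2)
            Xf = cc.apply_opls(filt, X)
            assert np.linalg.norm(Xf) <= np.linalg.norm(X) + 1e-12

    def test_filtering_helps_single_lv_calibration(self, rng):
        X, y, _ = _ortho_fixture(rng)
        filt = cc.fit_opls(X, y, n_ortho=1)
        Xf = cc.apply_opls(filt, X)
        rmsec = []
        for data in (Xf, X):
            model = fit_pls1(data, y, 1)
            resid = y - model.scores @ model.y_loadings
            rmsec.append(np.sqrt(np.mean(resid**2)))
        assert rmsec[0] <= rmsec[1] + 1e-12

    def test_degenerate_response_rejected(self, rng):
        X = rng.normal(size=(5, 8))
        with pytest.raises(DegenerateDataError):
            cc.fit_opls(X, np.zeros(5), 1)
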