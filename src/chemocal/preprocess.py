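"""Preprocessing: mean centering, first-derivative spectra, and OPLS filtering.

All preprocessing parameters are estimated on training data only and applied
frozen to new data — centering never re-estimates means, and the OPLS filter
reuses the training weight/loading vectors — so no information leaks from a
test set into calibration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import savgol_filter

from .errors import (
    DegenerateDataError,
    ParameterError,
    ShapeMismatchError,
)
from .io import SpectraMatrix

logger = logging.getLogger(__name__)


def _as_matrix(X) -> np.ndarray:
    if isinstance(X, SpectraMatrix):
        return X.absorbance
    return np.atleast_2d(np.asarray(X, dtype=float))


def _like(X, values: np.ndarray):
    """Rebuild a SpectraMatrix around new values when the input was one."""
    if isinstance(X, SpectraMatrix):
        return SpectraMatrix(X.wavelengths_nm.copy(), values, list(X.sample_ids))
    return values


@dataclass
class CenteringModel:
    """Frozen per-wavelength training means, optionally with the response mean."""

    column_means: np.ndarray
    response_mean: float | None = None

    def __post_init__(self) -> None:
        self.column_means = np.asarray(self.column_means, dtype=float).ravel()


def fit_center(X, y=None) -> CenteringModel:
    """Estimate column means of ``X`` (and the mean of ``y`` when given)."""
    A = _as_matrix(X)
    if A.shape[0] < 2:
        raise DegenerateDataError(
            f"centering needs ≥2 samples, got {A.shape[0]}"
        )
    ymean = None if y is None else float(np.mean(np.asarray(y, dtype=float)))
    return CenteringModel(A.mean(axis=0), ymean)


def apply_center(model: CenteringModel, X, y=None):
    """Subtract the stored training means; never re-estimates on new data."""
    A = _as_matrix(X)
    if A.shape[1] != model.column_means.size:
        raise ShapeMismatchError(
            f"data has {A.shape[1]} wavelengths, centering model has "
            f"{model.column_means.size}"
        )
    Xc = _like(X, A - model.column_means)
    if y is None:
        return Xc
    if model.response_mean is None:
        raise DegenerateDataError("centering model was fit without a response")
    yc = np.asarray(y, dtype=float) - model.response_mean
    return Xc, yc


def invert_center(model: CenteringModel, X, y=None):
    """Add the stored means back (inverse of :func:`apply_center`)."""
    A = _as_matrix(X)
    if A.shape[1] != model.column_means.size:
        raise ShapeMismatchError("width mismatch against centering model")
    Xu = _like(X, A + model.column_means)
    if y is None:
        return Xu
    return Xu, np.asarray(y, dtype=float) + (model.response_mean or 0.0)


def first_derivative(
    X: SpectraMatrix,
    method: str = "finite_difference",
    window: int = 5,
    polyorder: int = 2,
) -> SpectraMatrix:
    """First-derivative spectra, dA/dλ (AU nm⁻¹).

    ``finite_difference`` returns forward differences on the midpoint grid
    (p points → p−1); ``savitzky_golay`` returns a same-length smoothed
    derivative (default window 5, polynomial order 2).
    """
    grid = X.wavelengths_nm
    if method == "finite_difference":
        if X.n_wavelengths < 2:
            raise ParameterError("finite differences need ≥2 wavelengths")
        step = X.step_nm
        dA = np.diff(X.absorbance, axis=1) / step
        mid = 0.5 * (grid[:-1] + grid[1:])
        return SpectraMatrix(mid, dA, list(X.sample_ids))
    if method == "savitzky_golay":
        if window % 2 == 0:
            raise ParameterError(f"window must be odd, got {window}")
        if polyorder >= window:
            raise ParameterError(
                f"polyorder ({polyorder}) must be < window ({window})"
            )
        if window >= X.n_wavelengths:
            raise ParameterError(
                f"window ({window}) must be < wavelength count ({X.n_wavelengths})"
            )
        dA = savgol_filter(
            X.absorbance, window, polyorder, deriv=1, delta=X.step_nm, axis=1
        )
        return SpectraMatrix(grid.copy(), dA, list(X.sample_ids))
    raise ParameterError(f"unknown derivative method {method!r}")


@dataclass
class OPLSFilter:
    """Orthogonal-variation filter: unit weight vectors and loadings removed from X.

    Each stored component was estimated so that its training score vector
    t_o = X·w_o is orthogonal to the response; subtracting t_o·p_oᵀ removes
    response-uncorrelated systematic variation from the spectra.
    """

    weights: np.ndarray    # p × k, unit-norm columns w_o
    loadings: np.ndarray   # p × k, columns p_o
    training_column_means: np.ndarray | None = None
    training_filtered: np.ndarray | None = field(default=None, repr=False)

    @property
    def n_ortho(self) -> int:
        return self.weights.shape[1]


def fit_opls(X, y, n_ortho: int = 1) -> OPLSFilter:
    """Fit an OPLS filter on centered training data.

    Per component: w ∝ Xᵀy (normalised); t = Xw; p = Xᵀt/(tᵀt);
    w_o = p − (wᵀp)w, normalised; t_o = Xw_o; p_o = Xᵀt_o/(t_oᵀt_o);
    X ← X − t_o·p_oᵀ.  Stops early (with a logged notice) when nothing
    orthogonal to the response remains.
    """
    Xw = _as_matrix(X).astype(float, copy=True)
    yv = np.asarray(y, dtype=float).ravel()
    if Xw.shape[0] != yv.size:
        raise ShapeMismatchError(f"{Xw.shape[0]} spectra for {yv.size} responses")
    if n_ortho < 1:
        raise ParameterError(f"n_ortho must be ≥ 1, got {n_ortho}")
    ynorm = np.linalg.norm(yv)
    if ynorm < 1e-15:
        raise DegenerateDataError("response vector is all zeros")
    w_list: list[np.ndarray] = []
    p_list: list[np.ndarray] = []
    for a in range(n_ortho):
        w = Xw.T @ yv
        wn = np.linalg.norm(w)
        if wn < 1e-15:
            logger.info("OPLS: X carries no response-correlated variation; stopping at %d", a)
            break
        w /= wn
        t = Xw @ w
        tt = float(t @ t)
        if tt < 1e-30:
            logger.info("OPLS: degenerate predictive score; stopping at %d components", a)
            break
        p = Xw.T @ t / tt
        w_o = p - float(w @ p) * w
        won = np.linalg.norm(w_o)
        if won < 1e-12 * max(1.0, float(np.linalg.norm(p))):
            logger.info(
                "OPLS: no orthogonal variation left after %d component(s)", a
            )
            break
        w_o /= won
        t_o = Xw @ w_o
        tot = float(t_o @ t_o)
        if tot < 1e-30:
            logger.info("OPLS: degenerate orthogonal score; stopping at %d", a)
            break
        p_o = Xw.T @ t_o / tot
        Xw -= np.outer(t_o, p_o)
        w_list.append(w_o)
        p_list.append(p_o)
    p_vars = Xw.shape[1]
    W = np.column_stack(w_list) if w_list else np.empty((p_vars, 0))
    P = np.column_stack(p_list) if p_list else np.empty((p_vars, 0))
    return OPLSFilter(W, P, training_filtered=Xw)


def apply_opls(filt: OPLSFilter, X_new):
    """Remove the stored orthogonal components from new (centered) spectra."""
    A = _as_matrix(X_new).astype(float, copy=True)
    if A.shape[1] != filt.weights.shape[0]:
        raise ShapeMismatchError(
            f"data has {A.shape[1]} wavelengths, filter has {filt.weights.shape[0]}"
        )
    for a in range(filt.n_ortho):
        t_o = A @ filt.weights[:, a]
        A -= np.outer(t_o, filt.loadings[:, a])
    return _like(X_new, A)
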