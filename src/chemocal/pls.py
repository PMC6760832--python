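"""NIPALS PLS1 calibration with bootstrap selection of the latent-variable count.

The model decomposes the centered spectra X = T·Pᵀ + E and the centered
response c = T·q + f, extracting one latent variable at a time: the weight
w ∝ Xᵀc maximises covariance with the response, scores t = Xw, loadings
p = Xᵀt/(tᵀt), response loading q_a = cᵀt/(tᵀt), then X and c are deflated.
Predictions use the equivalent regression vector b = W(PᵀW)⁻¹q.

The number of latent variables is chosen by repeated random 2/3–1/3 splits of
the training set: each split is re-centered, modelled at every candidate LV
count, and scored by RMSEP on the held-out third; the LV count with the
smallest mean RMSEP (smallest count within ties) wins.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import (
    ParameterError,
    RankDeficiencyError,
    ShapeMismatchError,
)
from .io import SpectraMatrix
from .preprocess import CenteringModel, _as_matrix

#: relative tolerance below which a deflated covariance is treated as exhausted
_RANK_RTOL = 1e-12

#: absolute mean-RMSEP margin treated as an exact tie
LV_TIE_TOL = 1e-6

#: relative parsimony window: the smallest LV count whose mean RMSEP lies
#: within this fraction of the minimum is selected.  Past the chemical rank
#: the RMSEP curve is flat to within a few percent (noise refitting), so a
#: strict argmin would wander among statistically indistinguishable minima;
#: a PRESS-ratio parsimony window in the Haaland–Thomas tradition picks the
#: most parsimonious model the data cannot distinguish from the best one.
LV_PARSIMONY_RTOL = 0.10


@dataclass
class PLSModel:
    """Fitted PLS1 model (centered-space factors plus optional centering)."""

    n_lv: int
    weights: np.ndarray        # W, p × k
    scores: np.ndarray         # T, n × k (training)
    loadings: np.ndarray       # P, p × k
    y_loadings: np.ndarray     # q, (k,)
    regression_vector: np.ndarray  # b, (p,): centered spectrum → centered response
    centering: CenteringModel | None = None

    def fitted_values(self) -> np.ndarray:
        """Training predictions on the centered response scale."""
        return self.scores @ self.y_loadings


def _nipals(X: np.ndarray, y: np.ndarray, max_lv: int):
    """Run NIPALS PLS1 for up to ``max_lv`` components; may stop early at rank."""
    Xd = X.astype(float, copy=True)
    yd = y.astype(float, copy=True)
    n, p = Xd.shape
    W, T, P, q = [], [], [], []
    base = np.linalg.norm(Xd.T @ yd)
    for _ in range(max_lv):
        w = Xd.T @ yd
        wn = np.linalg.norm(w)
        if wn <= max(_RANK_RTOL * base, 1e-300):
            break
        w /= wn
        t = Xd @ w
        tt = float(t @ t)
        if tt <= 1e-300:
            break
        p_vec = Xd.T @ t / tt
        q_a = float(yd @ t) / tt
        Xd -= np.outer(t, p_vec)
        yd -= q_a * t
        W.append(w)
        T.append(t)
        P.append(p_vec)
        q.append(q_a)
    k = len(W)
    return (
        np.column_stack(W) if k else np.empty((p, 0)),
        np.column_stack(T) if k else np.empty((n, 0)),
        np.column_stack(P) if k else np.empty((p, 0)),
        np.asarray(q),
    )


def _regression_vector(W: np.ndarray, P: np.ndarray, q: np.ndarray) -> np.ndarray:
    """b = W (PᵀW)⁻¹ q, mapping a centered spectrum to a centered response."""
    if W.shape[1] == 0:
        return np.zeros(W.shape[0])
    return W @ np.linalg.solve(P.T @ W, q)


def fit_pls1(X, y, n_lv: int, centering: CenteringModel | None = None) -> PLSModel:
    """Fit a PLS1 model with exactly ``n_lv`` latent variables on centered data.

    ``X`` and ``y`` must already be centered (pass the fitted
    :class:`CenteringModel` so predictions can handle raw spectra).
    Raises :class:`RankDeficiencyError` if the data cannot support ``n_lv``
    components.
    """
    A = _as_matrix(X)
    yv = np.asarray(y, dtype=float).ravel()
    n, p = A.shape
    if yv.size != n:
        raise ShapeMismatchError(f"{n} spectra for {yv.size} responses")
    if n_lv < 1:
        raise ParameterError(f"n_lv must be ≥ 1, got {n_lv}")
    if n_lv > min(n - 1, p):
        raise ParameterError(
            f"n_lv={n_lv} exceeds min(samples-1, wavelengths)={min(n - 1, p)}"
        )
    W, T, P, q = _nipals(A, yv, n_lv)
    if W.shape[1] < n_lv:
        raise RankDeficiencyError(
            f"requested {n_lv} latent variables but the data support only "
            f"{W.shape[1]} (attained rank)"
        )
    b = _regression_vector(W, P, q)
    return PLSModel(n_lv, W, T, P, q, b, centering)


def predict_pls(model: PLSModel, X_new) -> np.ndarray:
    """Predict concentrations (μg mL⁻¹) for new spectra.

    When the model stores a :class:`CenteringModel`, raw spectra are centered
    with the training means and the response mean is added back; otherwise the
    input is assumed already centered and a centered prediction is returned.
    """
    A = _as_matrix(X_new)
    if A.shape[1] != model.regression_vector.size:
        raise ShapeMismatchError(
            f"data has {A.shape[1]} wavelengths, model has "
            f"{model.regression_vector.size}"
        )
    offset = 0.0
    if model.centering is not None:
        A = A - model.centering.column_means
        offset = model.centering.response_mean or 0.0
    out = A @ model.regression_vector + offset
    if not np.all(np.isfinite(out)):
        raise ShapeMismatchError("non-finite prediction")
    return out


def _staged_predictions(
    W: np.ndarray, P: np.ndarray, q: np.ndarray, X_new: np.ndarray
) -> np.ndarray:
    """Centered predictions after 1..k components (k × n_new), via deflation."""
    Xd = X_new.astype(float, copy=True)
    k = W.shape[1]
    preds = np.zeros((k, Xd.shape[0]))
    acc = np.zeros(Xd.shape[0])
    for a in range(k):
        t = Xd @ W[:, a]
        acc = acc + q[a] * t
        Xd -= np.outer(t, P[:, a])
        preds[a] = acc
    return preds


@dataclass
class BootstrapResult:
    """Mean held-out RMSEP per LV count and the selected count."""

    mean_rmsep_by_lv: np.ndarray  # index 0 ↔ 1 LV
    chosen_lv: int
    n_iterations: int
    seed: int


def bootstrap_select_lv(
    X,
    y,
    max_lv: int = 10,
    n_iterations: int = 1000,
    seed: int = 0,
) -> BootstrapResult:
    """Select the LV count by repeated random 2/3 train – 1/3 test splits.

    Each iteration draws ⌈2n/3⌉ samples without replacement as a bootstrap
    training set (the remainder is the bootstrap test set), re-centers X and y
    on that training set, fits PLS1 at every LV count up to ``max_lv``, and
    records RMSEP on the held-out samples.  The chosen LV count is the
    smallest whose mean RMSEP lies within the :data:`LV_PARSIMONY_RTOL`
    relative window (plus the :data:`LV_TIE_TOL` absolute floor) of the
    minimum.
    LV counts beyond the attained rank of a split reuse the highest attainable
    model (their RMSEP curve is flat there).
    """
    A = _as_matrix(X)
    yv = np.asarray(y, dtype=float).ravel()
    n = A.shape[0]
    if yv.size != n:
        raise ShapeMismatchError(f"{n} spectra for {yv.size} responses")
    if n < 3:
        raise ParameterError("bootstrap LV selection needs ≥3 samples")
    if n_iterations < 1:
        raise ParameterError("n_iterations must be ≥ 1")
    n_train = math.ceil(2 * n / 3)
    if max_lv < 1 or max_lv > n_train - 1:
        raise ParameterError(
            f"max_lv={max_lv} infeasible for bootstrap training size {n_train}"
        )
    rng = np.random.default_rng(seed)
    rmsep_sums = np.zeros(max_lv)
    for _ in range(n_iterations):
        perm = rng.permutation(n)
        tr, te = perm[:n_train], perm[n_train:]
        xm = A[tr].mean(axis=0)
        ym = yv[tr].mean()
        Xtr = A[tr] - xm
        ytr = yv[tr] - ym
        W, _, P, q = _nipals(Xtr, ytr, max_lv)
        k = W.shape[1]
        if k == 0:
            preds = np.zeros((1, te.size))
            k = 1
        else:
            preds = _staged_predictions(W, P, q, A[te] - xm)
        errs = (yv[te] - ym) - preds  # k × n_test centered residuals
        rmsep = np.sqrt(np.mean(errs**2, axis=1))
        idx = np.minimum(np.arange(max_lv), k - 1)
        rmsep_sums += rmsep[idx]
    mean_rmsep = rmsep_sums / n_iterations
    threshold = mean_rmsep.min() * (1.0 + LV_PARSIMONY_RTOL) + LV_TIE_TOL
    chosen = int(np.flatnonzero(mean_rmsep <= threshold)[0]) + 1
    return BootstrapResult(mean_rmsep, chosen, n_iterations, seed)
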