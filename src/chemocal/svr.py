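"""Linear ε-insensitive support vector regression trained on the dual problem.

The dual is expressed in the signed coefficients βᵢ = αᵢ − αᵢ* (valid because
αᵢ·αᵢ* = 0 at any optimum):

    minimise  F(β) = ½ βᵀKβ − yᵀβ + ε‖β‖₁
    subject to Σβᵢ = 0,  −C ≤ βᵢ ≤ C,

with K = XXᵀ the linear-kernel Gram matrix.  An SMO-style solver picks the
maximally KKT-violating pair (i, j), moves along eᵢ − eⱼ (which preserves the
equality constraint), and solves the resulting one-dimensional piecewise
quadratic exactly.  The bias b comes from the KKT conditions, averaged over
free support vectors, and every fit is verified against the primal objective
(duality-gap check).

Hyperparameters (ε, C) are tuned by a k-fold cross-validated grid search: for
each candidate pair, each fold is held out in turn, centering is re-estimated
on the retained samples, and RMSECV pools the squared hold-out errors over all
samples.  ε is interpreted on the centered response scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ParameterError, ShapeMismatchError, SolverError
from .io import SpectraMatrix
from .preprocess import CenteringModel, _as_matrix

#: RMSECV margin within which a simpler candidate (smaller C, then ε) wins
GRID_TIE_TOL = 1e-9


@dataclass
class SVRModel:
    """Fitted linear ε-SVR: signed dual coefficients, bias and tube parameters."""

    dual_coefficients: np.ndarray  # βᵢ = αᵢ − αᵢ*, one per training sample
    bias: float
    epsilon: float
    cost: float
    support_indices: np.ndarray
    training_inputs: np.ndarray    # retained centered spectra (n × p)
    centering: CenteringModel | None = None

    @property
    def weight_vector(self) -> np.ndarray:
        """Explicit primal weights w = Σᵢ βᵢ xᵢ."""
        return self.training_inputs.T @ self.dual_coefficients


def _solve_pair(beta_i, beta_j, g_i, g_j, eta, epsilon, hi):
    """Exact minimiser of the 1-D piecewise quadratic along eᵢ − eⱼ on [0, hi].

    Walks the sign-change breakpoints of the two absolute-value terms in
    increasing order and stops where the (convex) directional derivative
    turns non-negative; derivative-based so arbitrarily small optimal steps
    are returned exactly.
    """
    if hi <= 0.0:
        return 0.0
    knots = sorted(
        {0.0, hi} | {bp for bp in (-beta_i, beta_j) if 0.0 < bp < hi}
    )
    for a, b in zip(knots[:-1], knots[1:]):
        m = 0.5 * (a + b)
        s_i = 1.0 if beta_i + m >= 0 else -1.0
        s_j = 1.0 if beta_j - m >= 0 else -1.0
        c0 = (g_i - g_j) + epsilon * (s_i - s_j)
        if eta * a + c0 >= 0:  # derivative already non-negative at interval start
            return a
        if eta > 0:
            d_star = -c0 / eta
            if d_star <= b:
                return d_star
    return hi


def _dual_objective(K, yv, beta, epsilon) -> float:
    return (
        0.5 * float(beta @ (K @ beta))
        - float(yv @ beta)
        + epsilon * float(np.abs(beta).sum())
    )


def _free_set_refine(K, yv, beta, epsilon, cost):
    """Newton step on the free support set (active-set accelerator).

    With bound/zero coefficients frozen and the signs of the free ones fixed,
    the dual reduces to an equality-constrained quadratic whose KKT system is
    solved directly; the step is damped so no coefficient crosses zero (where
    the ε‖β‖₁ slope flips) or leaves the box.  Returns an improved copy of
    ``beta`` or None.
    """
    F = np.flatnonzero((np.abs(beta) > 1e-10 * cost) & (np.abs(beta) < cost))
    if F.size == 0:
        return None
    s = epsilon * np.sign(beta)
    trial = _solve_orthant_qp(K, yv, beta, F, s, cost)
    if trial is not None and _dual_objective(K, yv, trial, epsilon) < _dual_objective(
        K, yv, beta, epsilon
    ):
        return trial
    return None


def _solve_orthant_qp(K, yv, beta, F, s, cost):
    """Solve the dual restricted to free set F with fixed signs s[F].

    Returns the damped feasible step (new beta copy) or None.  Minimises
    ½βᵀKβ − yᵀβ + ε sᵀβ over β_F subject to Σβ = 0 with β outside F frozen,
    then damps so every free coefficient stays in its sign region and box.
    """
    n = beta.size
    B = np.setdiff1d(np.arange(n), F, assume_unique=True)
    m = F.size
    KFF = K[np.ix_(F, F)]
    # proximal ridge keeps the system nonsingular (K may be low-rank) while
    # guaranteeing the exact step decreases the unregularised objective
    lam = 1e-9 * (float(np.trace(KFF)) / m + 1.0)
    M = np.zeros((m + 1, m + 1))
    M[:m, :m] = KFF + lam * np.eye(m)
    M[:m, m] = 1.0
    M[m, :m] = 1.0
    rhs_top = yv[F] - s[F] + lam * beta[F]  # s already carries the ε factor
    if B.size:
        rhs_top = rhs_top - K[np.ix_(F, B)] @ beta[B]
    rhs = np.concatenate([rhs_top, [-float(beta[B].sum()) if B.size else 0.0]])
    sol, *_ = np.linalg.lstsq(M, rhs, rcond=None)
    step = sol[:m] - beta[F]
    if not np.all(np.isfinite(step)) or float(np.abs(step).max()) == 0.0:
        return None
    sgn = np.sign(s[F])
    alpha = 1.0
    for k in range(m):
        if step[k] == 0.0:
            continue
        lo = 0.0 if sgn[k] > 0 else -cost
        hi = cost if sgn[k] > 0 else 0.0
        if step[k] > 0:
            alpha = min(alpha, (hi - beta[F[k]]) / step[k])
        else:
            alpha = min(alpha, (lo - beta[F[k]]) / step[k])
    if alpha <= 0.0:
        return None
    out = beta.copy()
    out_F = beta[F] + alpha * step
    # snap coordinates that reached a breakpoint exactly
    out_F[np.abs(out_F) < 1e-14 * cost] = 0.0
    near = cost - np.abs(out_F) < 1e-14 * cost
    out_F[near] = np.sign(out_F[near]) * cost
    out[F] = out_F
    return out


def _active_set_polish(K, yv, beta0, epsilon, cost, tol, max_cycles=500):
    """Active-set finisher: promote the worst KKT violators into the free set
    and re-solve the restricted KKT system until the pair violation is below
    ``tol``.  Handles the end-game where pairwise updates zigzag."""
    n = beta0.size
    beta = beta0.copy()
    diag = np.diag(K)
    obj = _dual_objective(K, yv, beta, epsilon)
    for _ in range(max_cycles):
        g = K @ beta - yv
        r = g + np.where(beta >= 0, epsilon, -epsilon)
        l = g + np.where(beta > 0, epsilon, -epsilon)
        r_up = np.where(beta < cost, r, np.inf)
        l_low = np.where(beta > -cost, l, -np.inf)
        i_up = int(np.argmin(r_up))
        i_low = int(np.argmax(l_low))
        if float(l_low[i_low] - r_up[i_up]) <= tol:
            break
        s = epsilon * np.sign(beta)  # ε-subgradient term per sign region
        members = set(np.flatnonzero((np.abs(beta) > 0) & (np.abs(beta) < cost)))
        for idx, sgn_new in ((i_up, 1.0), (i_low, -1.0)):
            members.add(idx)
            if beta[idx] == 0.0:
                s[idx] = epsilon * sgn_new
            elif abs(beta[idx]) == cost:
                s[idx] = epsilon * np.sign(beta[idx])
        F = np.fromiter(sorted(members), dtype=int)
        trial = _solve_orthant_qp(K, yv, beta, F, s, cost)
        accepted = False
        if trial is not None:
            t_obj = _dual_objective(K, yv, trial, epsilon)
            if t_obj < obj - 1e-15 * (1.0 + abs(obj)):
                beta, obj, accepted = trial, t_obj, True
        if not accepted:
            # fall back to one exact pairwise step to change the active set
            hi = min(cost - beta[i_up], beta[i_low] + cost)
            eta = diag[i_up] + diag[i_low] - 2.0 * K[i_up, i_low]
            d = _solve_pair(
                beta[i_up], beta[i_low], g[i_up], g[i_low], eta, epsilon, hi
            )
            if d <= 0.0:
                break
            beta[i_up] += d
            beta[i_low] -= d
            obj = _dual_objective(K, yv, beta, epsilon)
    return beta


def train_linear_svr(
    X,
    y,
    epsilon: float,
    cost: float,
    centering: CenteringModel | None = None,
    tol: float = 1e-9,
    max_iter: int = 200_000,
) -> SVRModel:
    """Solve the linear ε-SVR dual on centered data to a small duality gap.

    Raises :class:`SolverError` (reporting the gap) if the pairwise updates do
    not reach optimality within ``max_iter`` or the final duality gap exceeds
    ``1e-6·(1 + |objective|)``.
    """
    A = _as_matrix(X).astype(float)
    yv = np.asarray(y, dtype=float).ravel()
    n = A.shape[0]
    if yv.size != n:
        raise ShapeMismatchError(f"{n} spectra for {yv.size} responses")
    if epsilon < 0:
        raise ParameterError(f"epsilon must be ≥ 0, got {epsilon}")
    if cost <= 0:
        raise ParameterError(f"cost must be > 0, got {cost}")
    if n < 1:
        raise ParameterError("need at least one training sample")

    K = A @ A.T
    diag = np.diag(K)
    beta = np.zeros(n)
    g = -yv.copy()  # gradient of the smooth part: Kβ − y
    scale = 1.0 + float(np.abs(yv).max(initial=0.0))
    tol_eff = tol * scale

    violation = np.inf
    it = 0

    def smo_until(target: float, cap: int) -> None:
        """Pairwise updates until the KKT pair violation drops below target."""
        nonlocal it, violation, beta, g
        stall_retries = 0
        while it < cap:
            if it % 64 == 0:
                if it % 512 == 256:
                    # periodic Newton polish accelerates ill-conditioned cases
                    refined = _free_set_refine(K, yv, beta, epsilon, cost)
                    if refined is not None:
                        beta = refined
                g = K @ beta - yv  # exact refresh kills incremental drift
            it += 1
            r = g + np.where(beta >= 0, epsilon, -epsilon)  # right derivative
            l = g + np.where(beta > 0, epsilon, -epsilon)   # left derivative
            r_up = np.where(beta < cost, r, np.inf)
            l_low = np.where(beta > -cost, l, -np.inf)
            i = int(np.argmin(r_up))
            violation = float(l_low.max() - r_up[i])
            if violation <= target:
                return
            # second-order pair selection: among violating partners, maximise
            # the estimated objective decrease (violation²/2η)
            diff = l_low - r_up[i]
            eta_vec = np.maximum(diag + diag[i] - 2.0 * K[:, i], 1e-12)
            gain = np.where(diff > 0, diff * diff / eta_vec, -np.inf)
            j = int(np.argmax(gain))
            hi = min(cost - beta[i], beta[j] + cost)
            eta = diag[i] + diag[j] - 2.0 * K[i, j]
            d = _solve_pair(beta[i], beta[j], g[i], g[j], eta, epsilon, hi)
            if d <= 0.0:
                # fall back to the maximal-violating partner
                j = int(np.argmax(l_low))
                hi = min(cost - beta[i], beta[j] + cost)
                eta = diag[i] + diag[j] - 2.0 * K[i, j]
                d = _solve_pair(beta[i], beta[j], g[i], g[j], eta, epsilon, hi)
            if d <= 0.0:
                # numerically stalled; attempt a Newton polish before giving up
                refined = _free_set_refine(K, yv, beta, epsilon, cost)
                if refined is not None and stall_retries < 8:
                    stall_retries += 1
                    beta = refined
                    g = K @ beta - yv
                    continue
                return  # stalled; the gap certificate decides pass/fail
            beta[i] += d
            beta[j] -= d
            # snap to the box within rounding so bound classification is exact
            for idx in (i, j):
                if cost - abs(beta[idx]) < 1e-12 * cost:
                    beta[idx] = math.copysign(cost, beta[idx])
            g += d * (K[:, i] - K[:, j])

    def kkt_bias_and_gap():
        """Bias from the KKT conditions plus the primal/dual certificate."""
        g_exact = K @ beta - yv
        r = g_exact + np.where(beta >= 0, epsilon, -epsilon)
        l = g_exact + np.where(beta > 0, epsilon, -epsilon)
        w = A.T @ beta
        resid0 = yv - A @ w

        def primal_at(b: float) -> float:
            return 0.5 * float(w @ w) + cost * float(
                np.sum(np.maximum(0.0, np.abs(resid0 - b) - epsilon))
            )

        # free support vectors sit exactly on the tube boundary
        free = (np.abs(beta) > 1e-8 * cost) & (np.abs(beta) < cost * (1 - 1e-8))
        if free.any():
            b = float(np.mean(-g_exact[free] - epsilon * np.sign(beta[free])))
        else:
            lo_b = -float(np.min(np.where(beta < cost, r, np.inf)))
            hi_b = -float(np.max(np.where(beta > -cost, l, -np.inf)))
            b = 0.5 * (lo_b + hi_b)
        primal = primal_at(b)
        # primal is piecewise linear in b (breakpoints at residual ± ε); keep
        # the candidate certifying the smallest primal
        for cand in np.concatenate([resid0 - epsilon, resid0 + epsilon]):
            p = primal_at(float(cand))
            if p < primal - 1e-12 * (1.0 + abs(primal)):
                primal, b = p, float(cand)
        dual = -(
            0.5 * float(beta @ (g_exact + yv))  # βᵀKβ via the exact gradient
            - float(yv @ beta)
            + epsilon * float(np.abs(beta).sum())
        )
        return b, primal - dual, dual

    # bulk phase: pairwise updates; end game: active-set polish, validated by
    # the duality-gap certificate (the solver's actual contract)
    smo_until(tol_eff, min(max_iter, 256 * max(n, 16)))
    polish_tol = tol_eff
    while True:
        bias, gap, dual = kkt_bias_and_gap()
        if gap <= 1e-6 * (1.0 + abs(dual)):
            break
        if polish_tol < 1e-16 * scale:
            state = "iteration cap reached" if it >= max_iter else "stalled"
            raise SolverError(
                f"SVR dual {state}: duality gap {gap:.3e} exceeds "
                f"{1e-6 * (1.0 + abs(dual)):.3e} (pair violation {violation:.3e})"
            )
        beta = _active_set_polish(K, yv, beta, epsilon, cost, polish_tol)
        polish_tol *= 1e-3

    support = np.flatnonzero(np.abs(beta) > 1e-8 * cost)
    return SVRModel(beta, bias, epsilon, cost, support, A, centering)


def predict_svr(model: SVRModel, X_new) -> np.ndarray:
    """Predict concentrations: c = Σᵢ βᵢ xᵢᵀx + b (+ response mean)."""
    A = _as_matrix(X_new)
    if A.shape[1] != model.training_inputs.shape[1]:
        raise ShapeMismatchError(
            f"data has {A.shape[1]} wavelengths, model has "
            f"{model.training_inputs.shape[1]}"
        )
    offset = 0.0
    if model.centering is not None:
        A = A - model.centering.column_means
        offset = model.centering.response_mean or 0.0
    return A @ model.weight_vector + model.bias + offset


def default_epsilon_grid() -> np.ndarray:
    """ε candidates 0.01–1.00 in steps of 0.01 (centered response scale)."""
    return np.round(np.arange(1, 101) * 0.01, 10)


def default_cost_grid() -> np.ndarray:
    """C candidates 30–1000 in steps of 10."""
    return np.arange(30.0, 1001.0, 10.0)


@dataclass
class GridSearchResult:
    """RMSECV over the (ε, C) grid and the selected pair."""

    grid: pd.DataFrame  # columns: epsilon, cost, rmsecv
    best_epsilon: float
    best_cost: float
    best_rmsecv: float
    k_folds: int
    seed: int


def grid_search_svr(
    X,
    y,
    epsilon_grid=None,
    cost_grid=None,
    k: int = 4,
    seed: int = 0,
) -> GridSearchResult:
    """k-fold cross-validated grid search over (ε, C) minimising RMSECV.

    Samples are randomly partitioned into ``k`` folds of near-equal size
    (seeded).  Per candidate, each fold is predicted by a model trained — with
    centering re-estimated — on the remaining samples; RMSECV pools squared
    errors over all samples.  RMSECV ties within :data:`GRID_TIE_TOL` go to
    the smaller C, then the smaller ε.
    """
    A = _as_matrix(X)
    yv = np.asarray(y, dtype=float).ravel()
    n = A.shape[0]
    eps_grid = default_epsilon_grid() if epsilon_grid is None else np.asarray(
        epsilon_grid, dtype=float
    )
    c_grid = default_cost_grid() if cost_grid is None else np.asarray(
        cost_grid, dtype=float
    )
    if eps_grid.size == 0 or c_grid.size == 0:
        raise ParameterError("epsilon and cost grids must be nonempty")
    if k < 2 or k > n:
        raise ParameterError(f"k={k} infeasible for {n} samples")
    rng = np.random.default_rng(seed)
    folds = np.array_split(rng.permutation(n), k)
    if min(f.size for f in folds) < 1:
        raise ParameterError("every fold needs at least one sample")

    rows = []
    best = None  # (rmsecv, cost, eps)
    for cost in c_grid:
        for eps in eps_grid:
            sq = 0.0
            for fold in folds:
                mask = np.ones(n, dtype=bool)
                mask[fold] = False
                xm = A[mask].mean(axis=0)
                ym = yv[mask].mean()
                model = train_linear_svr(A[mask] - xm, yv[mask] - ym, eps, cost)
                pred = (A[fold] - xm) @ model.weight_vector + model.bias + ym
                sq += float(np.sum((yv[fold] - pred) ** 2))
            rmsecv = float(np.sqrt(sq / n))
            rows.append((float(eps), float(cost), rmsecv))
            if (
                best is None
                or rmsecv < best[0] - GRID_TIE_TOL
                or (
                    rmsecv <= best[0] + GRID_TIE_TOL
                    and (cost, eps) < (best[1], best[2])
                )
            ):
                best = (rmsecv, float(cost), float(eps))
    grid = pd.DataFrame(rows, columns=["epsilon", "cost", "rmsecv"])
    return GridSearchResult(grid, best[2], best[1], best[0], k, seed)
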