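"""Multi-response partial least squares (PLS2), PRESS, and CV model selection.

This is a self-contained NIPALS-style PLS2: factors are extracted one at a
time, each maximizing covariance between X- and Y-scores, with regression
deflation of both blocks.  The inner NIPALS iteration converges to the
dominant left singular vector of the cross-covariance E'F; with only three
responses that fixed point is computed directly from the SVD of the p x 3
matrix, which is exact, deterministic and free of iteration-count
artifacts.  Predictors are centered only (they are already z-scored
upstream, so rescaling would be redundant); responses are centered, not
scaled, because position units are meaningful.

Model complexity (the latent-variable count) is chosen by 10-fold
cross-validation on *contiguous temporal blocks* — shuffled folds would
leak heavily autocorrelated neighbors between train and validation —
scoring each candidate count by PRESS, the predictive error sum of squares
over held-out samples and the three axes, and taking the smallest count
whose PRESS sits within a relative tolerance of the curve minimum (capped,
default 20).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import ConvergenceError, InsufficientDataError, InvalidArgumentError

__all__ = [
    "PlsModel",
    "CvCurve",
    "fit_pls",
    "fit_pls_upto",
    "predict",
    "press",
    "r_squared",
    "cross_validate",
    "select_n_latent",
]

_EXHAUSTION_TOL = 1e-12  # relative residual-covariance threshold


@dataclass
class _Factors:
    """Raw factor sequences shared by fit_pls and cross_validate."""

    W: np.ndarray  # (p, k) X-weights, unit norm
    P: np.ndarray  # (p, k) X-loadings
    C: np.ndarray  # (m, k) Y-loadings
    x_mean: np.ndarray
    y_mean: np.ndarray
    x_scores: np.ndarray  # (n, k)

    @property
    def n_extracted(self) -> int:
        return self.W.shape[1]

    def coefficients(self, n_latent: int) -> tuple[np.ndarray, np.ndarray]:
        """(B, a) using the first ``n_latent`` factors.

        B = W (P'W)^-1 C'; P'W is unit upper triangular, so the solve is
        well-posed whenever factors were extractable.
        """
        k = min(n_latent, self.n_extracted)
        W, P, C = self.W[:, :k], self.P[:, :k], self.C[:, :k]
        R = np.linalg.solve(P.T @ W, np.eye(k))
        B = W @ R @ C.T
        a = self.y_mean - self.x_mean @ B
        return B, a


def _extract_factors(X: np.ndarray, Y: np.ndarray, max_latent: int) -> _Factors:
    """Sequential factor extraction with implicit X-deflation.

    Algebraically identical to classic NIPALS PLS2 with regression
    deflation of both blocks, but the deflated predictor block
    ``E_k = E_0 - T P'`` is never materialized: scores and loadings are
    reconstructed from the centered originals plus the accumulated
    score/loading matrices, and the cross-covariance is updated by the
    rank-one identity ``M_{k+1} = M_k - (t't) p c'``.  This costs two
    passes over the (large) predictor block per factor instead of five.
    """
    x_mean = X.mean(axis=0)
    y_mean = Y.mean(axis=0)
    E0 = X - x_mean
    F = Y - y_mean
    M = E0.T @ F  # cross-covariance of the current residuals, (p, m)
    scale0 = np.linalg.norm(M)
    if scale0 == 0:
        raise ConvergenceError("X and Y are uncorrelated or degenerate (zero cross-covariance)")

    Ws, Ps, Cs, Ts = [], [], [], []
    for k in range(max_latent):
        if np.linalg.norm(M) <= _EXHAUSTION_TOL * scale0:
            break
        # NIPALS fixed point: w is the dominant left singular vector of M
        u, _, _ = np.linalg.svd(M, full_matrices=False)
        w = u[:, 0]
        w = w * np.sign(w[np.argmax(np.abs(w))] or 1.0)  # deterministic sign
        t = E0 @ w
        if k:
            T_mat = np.column_stack(Ts)
            P_mat = np.column_stack(Ps)
            t -= T_mat @ (P_mat.T @ w)
        tt = float(t @ t)
        if tt <= 0 or not np.isfinite(tt):
            break
        c = F.T @ t / tt
        p_load = E0.T @ t
        if k:
            p_load -= P_mat @ (T_mat.T @ t)
        p_load /= tt
        F -= np.outer(t, c)
        M -= tt * np.outer(p_load, c)
        Ws.append(w)
        Ps.append(p_load)
        Cs.append(c)
        Ts.append(t)

    if not Ws:
        raise ConvergenceError("no PLS factor could be extracted")
    return _Factors(
        W=np.column_stack(Ws),
        P=np.column_stack(Ps),
        C=np.column_stack(Cs),
        x_mean=x_mean,
        y_mean=y_mean,
        x_scores=np.column_stack(Ts),
    )


@dataclass
class PlsModel:
    """Fitted decoder: ``predict(X) = X @ B + a`` (centering folded into a)."""

    n_latent: int
    B: np.ndarray  # (p, m)
    a: np.ndarray  # (m,)
    x_mean: np.ndarray
    y_mean: np.ndarray
    W: np.ndarray = field(repr=False)
    P: np.ndarray = field(repr=False)
    C: np.ndarray = field(repr=False)
    x_scores: np.ndarray | None = field(default=None, repr=False)

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.B.shape[0]:
            raise InvalidArgumentError(
                f"X has {X.shape[1] if X.ndim == 2 else '?'} columns, model expects {self.B.shape[0]}"
            )
        return X @ self.B + self.a


def fit_pls(X: np.ndarray, Y: np.ndarray, n_latent: int) -> PlsModel:
    """Fit PLS2 with exactly ``n_latent`` factors.

    Raises :class:`ConvergenceError` if fewer factors are extractable
    (rank-deficient residuals), and :class:`InvalidArgumentError` for
    shape problems or an all-zero predictor block.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    if X.ndim != 2 or Y.ndim != 2 or X.shape[0] != Y.shape[0]:
        raise InvalidArgumentError("X and Y must be 2-D with matching row counts")
    if n_latent < 1:
        raise InvalidArgumentError("n_latent must be >= 1")
    if n_latent > min(X.shape[0] - 1, X.shape[1]):
        raise InvalidArgumentError(
            f"n_latent={n_latent} exceeds feasible bound "
            f"min(n_rows - 1, n_features) = {min(X.shape[0] - 1, X.shape[1])}"
        )
    if not np.any(X):
        raise InvalidArgumentError("predictor block is identically zero")

    fac = _extract_factors(X, Y, n_latent)
    if fac.n_extracted < n_latent:
        raise ConvergenceError(
            f"only {fac.n_extracted} factors extractable, {n_latent} requested"
        )
    B, a = fac.coefficients(n_latent)
    return PlsModel(
        n_latent=n_latent,
        B=B,
        a=a,
        x_mean=fac.x_mean,
        y_mean=fac.y_mean,
        W=fac.W,
        P=fac.P,
        C=fac.C,
        x_scores=fac.x_scores,
    )


def fit_pls_upto(X: np.ndarray, Y: np.ndarray, n_latent: int) -> PlsModel:
    """Like :func:`fit_pls` but tolerates factor exhaustion.

    Extracts as many factors as the data supports, up to ``n_latent``
    (also silently capped at the feasible shape bound); the returned
    model's ``n_latent`` reports the count actually used.  Convenient for
    restricted designs (single channels / bands) whose rank may fall
    below the globally selected latent count.  ``n_latent = 0`` yields
    the intercept-only model (predicts the training mean).
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    if n_latent <= 0:
        p, m = X.shape[1], Y.shape[1]
        return PlsModel(
            n_latent=0,
            B=np.zeros((p, m)),
            a=Y.mean(axis=0),
            x_mean=X.mean(axis=0),
            y_mean=Y.mean(axis=0),
            W=np.zeros((p, 0)),
            P=np.zeros((p, 0)),
            C=np.zeros((m, 0)),
        )
    n_latent = min(n_latent, X.shape[0] - 1, X.shape[1])
    fac = _extract_factors(X, Y, n_latent)
    k = fac.n_extracted
    B, a = fac.coefficients(k)
    return PlsModel(
        n_latent=k, B=B, a=a, x_mean=fac.x_mean, y_mean=fac.y_mean,
        W=fac.W, P=fac.P, C=fac.C, x_scores=fac.x_scores,
    )


def predict(model: PlsModel, X: np.ndarray) -> np.ndarray:
    return model.predict(X)


def press(Y: np.ndarray, Yhat: np.ndarray) -> float:
    """Predictive error sum of squares over all samples and axes."""
    Y = np.asarray(Y, dtype=float)
    Yhat = np.asarray(Yhat, dtype=float)
    if Y.shape != Yhat.shape:
        raise InvalidArgumentError(f"shape mismatch {Y.shape} vs {Yhat.shape}")
    return float(np.sum((Y - Yhat) ** 2))


def r_squared(Y: np.ndarray, Yhat: np.ndarray) -> tuple[np.ndarray, float]:
    """Coefficient of determination per axis plus their mean.

    R^2 = 1 - SS_res / SS_tot about the observed mean of the evaluation
    segment; out-of-sample values can be negative and are reported as-is.
    """
    Y = np.asarray(Y, dtype=float)
    Yhat = np.asarray(Yhat, dtype=float)
    if Y.ndim == 1:
        Y, Yhat = Y[:, None], Yhat[:, None]
    if Y.shape != Yhat.shape:
        raise InvalidArgumentError(f"shape mismatch {Y.shape} vs {Yhat.shape}")
    ss_tot = np.sum((Y - Y.mean(axis=0)) ** 2, axis=0)
    if np.any(ss_tot <= 0):
        raise InvalidArgumentError("zero-variance axis: R^2 undefined")
    ss_res = np.sum((Y - Yhat) ** 2, axis=0)
    per_axis = 1.0 - ss_res / ss_tot
    return per_axis, float(per_axis.mean())


@dataclass
class CvCurve:
    """PRESS and mean R^2 per candidate latent count, with fold record.

    ``baseline_press`` is the PRESS of the zero-latent model (per-fold
    training-mean predictor): the reference against which the first latent
    variable must pay for itself.
    """

    n_components: np.ndarray  # 1..max_latent
    press: np.ndarray
    r2: np.ndarray
    fold_bounds: list[tuple[int, int]]  # [start, stop) row ranges per fold
    baseline_press: float = np.inf
    embargo_rows: int = 0

    def __post_init__(self) -> None:
        if np.any(self.press < 0):
            raise InvalidArgumentError("PRESS must be nonnegative")


def cross_validate(
    X: np.ndarray,
    Y: np.ndarray,
    max_latent: int = 20,
    k_folds: int = 10,
    embargo_rows: int = 0,
) -> CvCurve:
    """Blocked k-fold CV: PRESS and mean R^2 for 1..max_latent factors.

    Rows are partitioned into ``k_folds`` contiguous temporal blocks; for
    each fold the factor sequence is extracted once up to ``max_latent``
    (or until exhaustion, after which the curve is flat) and every
    candidate count is scored on the held-out block.  Fully deterministic.

    ``embargo_rows`` additionally drops that many training rows on each
    side of the held-out block.  Lag-embedded rows within the feature
    window's horizon of the fold boundary share raw data with held-out
    rows, and on strongly autocorrelated series that leakage lets purely
    spurious factors "validate"; an embargo of one feature horizon
    restores honest held-out scoring.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    if k_folds < 2:
        raise InvalidArgumentError("need at least 2 folds")
    n = X.shape[0]
    if n < 2 * k_folds:
        raise InsufficientDataError(f"{n} rows is too few for {k_folds} folds")

    edges = np.linspace(0, n, k_folds + 1).round().astype(int)
    bounds = [(int(a), int(b)) for a, b in zip(edges[:-1], edges[1:])]

    press_acc = np.zeros(max_latent)
    r2_acc = np.zeros(max_latent)
    baseline = 0.0
    for start, stop in bounds:
        hold = np.zeros(n, dtype=bool)
        hold[start:stop] = True
        train = ~hold
        if embargo_rows > 0:
            train[max(0, start - embargo_rows) : start] = False
            train[stop : stop + embargo_rows] = False
        if train.sum() < max_latent + 1:
            raise InsufficientDataError("embargo leaves too few training rows")
        fac = _extract_factors(X[train], Y[train], max_latent)
        Xh, Yh = X[hold], Y[hold]
        baseline += press(Yh, np.broadcast_to(Y[train].mean(axis=0), Yh.shape))
        for ni in range(1, max_latent + 1):
            B, a = fac.coefficients(ni)
            Yhat = Xh @ B + a
            press_acc[ni - 1] += press(Yh, Yhat)
            _, mean_r2 = r_squared(Yh, Yhat)
            r2_acc[ni - 1] += mean_r2

    return CvCurve(
        n_components=np.arange(1, max_latent + 1),
        press=press_acc,
        r2=r2_acc / k_folds,
        fold_bounds=bounds,
        baseline_press=baseline,
        embargo_rows=embargo_rows,
    )


def select_n_latent(curve: CvCurve, plateau_tol: float = 0.01, cap: int = 20) -> int:
    """Smallest count whose PRESS is within ``plateau_tol`` of the minimum.

    Capped at ``cap`` (default 20, the fixed choice used for the original
    recordings, where PRESS kept creeping down but plateaued past ~20).
    If even the first latent variable fails to beat the zero-latent
    (training-mean) baseline — PRESS increases as soon as anything is
    added — the selection is 0: the data carry no predictive structure and
    the honest model is the intercept alone.
    """
    if curve.press.size == 0:
        raise InvalidArgumentError("empty CV curve")
    pmin = float(curve.press.min())
    if curve.baseline_press <= pmin * (1.0 + plateau_tol):
        return 0
    within = np.nonzero(curve.press <= pmin * (1.0 + plateau_tol))[0]
    n = int(curve.n_components[within[0]])
    return min(n, cap)
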