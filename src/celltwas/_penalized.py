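"""Elastic-net fitting with an unpenalized column block.

The prediction models in this package are penalized linear regressions in
which a small set of columns (the intercept and, for the cell-type mixture
design, the centered proportion) must carry no penalty.  scikit-learn's
coordinate-descent solvers penalize every coefficient, so we exploit the
Frisch-Waugh-Lovell decomposition: for the objective

    min_{a,b}  ||y - U a - X b||^2 / (2n) + lambda * P(b)

the partial minimizer over the unpenalized block ``a`` is the least-squares
fit of the residual, and substituting it back leaves an elastic-net problem
in ``b`` on the U-residualized responses and columns.  This identity is
exact for any penalty that does not involve ``a``.

Penalized columns are standardized to unit variance before the solver and
coefficients are mapped back, mirroring glmnet's default behaviour.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.linear_model import ElasticNet, ElasticNetCV
from sklearn.model_selection import KFold

__all__ = ["PenalizedFit", "fit_partially_penalized"]


@dataclass
class PenalizedFit:
    """Solution of an elastic-net problem with an unpenalized block.

    Attributes
    ----------
    coef_pen : per-column weights of the penalized block, original scale.
    coef_unpen : weights of the unpenalized block (first entry: intercept).
    lambda_ : selected regularization strength (scikit-learn ``alpha``).
    cv_r : cross-validated correlation-scale performance,
        ``sqrt(max(0, 1 - min CV MSE / var(y)))``; ``nan`` when the penalty
        was supplied rather than cross-validated.
    """

    coef_pen: np.ndarray
    coef_unpen: np.ndarray
    lambda_: float
    cv_r: float


def _residualize(U: np.ndarray, M: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Return residuals of columns of M on U and the projection coefficients."""
    gamma, *_ = np.linalg.lstsq(U, M, rcond=None)
    return M - U @ gamma, gamma


def fit_partially_penalized(
    y: np.ndarray,
    X_pen: np.ndarray,
    X_unpen: np.ndarray | None = None,
    *,
    l1_ratio: float = 0.5,
    n_folds: int = 10,
    seed: int = 0,
    lambda_: float | None = None,
    lambda_rule: str = "1se",
    n_lambdas: int = 100,
    tol: float = 1e-6,
    max_iter: int = 10_000,
) -> PenalizedFit:
    """Fit ``y ~ [1, X_unpen] (unpenalized) + X_pen (elastic net)``.

    ``lambda_`` overrides cross-validation when given (``lambda_=0`` recovers
    ordinary least squares for full-rank designs); otherwise the penalty is
    chosen on a cross-validated path by ``lambda_rule``: ``"1se"`` (default)
    takes the largest penalty within one standard error of the minimum CV
    error, which prunes noise predictors aggressively, while ``"min"`` takes
    the CV-error minimizer.  The intercept is always part of the unpenalized
    block and need not be supplied.
    """
    y = np.asarray(y, dtype=float)
    X_pen = np.asarray(X_pen, dtype=float)
    n = y.shape[0]
    if X_pen.shape[0] != n:
        raise ValueError("X_pen and y have inconsistent sample counts")
    U = np.ones((n, 1))
    if X_unpen is not None:
        X_unpen = np.atleast_2d(np.asarray(X_unpen, dtype=float))
        if X_unpen.shape[0] != n:
            X_unpen = X_unpen.T
        U = np.hstack([U, X_unpen])

    y_res, _ = _residualize(U, y[:, None])
    y_res = y_res[:, 0]
    X_res, _ = _residualize(U, X_pen)

    scale = X_res.std(axis=0)
    live = scale > 1e-12
    scale_safe = np.where(live, scale, 1.0)
    Xs = X_res / scale_safe

    coef_std = np.zeros(X_pen.shape[1])
    cv_r = float("nan")
    if not live.any():
        lam = 0.0 if lambda_ is None else float(lambda_)
    elif lambda_ is not None:
        lam = float(lambda_)
        if lam <= 0.0:
            beta, *_ = np.linalg.lstsq(Xs[:, live], y_res, rcond=None)
            coef_std[live] = beta
        else:
            en = ElasticNet(
                alpha=lam, l1_ratio=l1_ratio, fit_intercept=False,
                tol=tol, max_iter=max_iter,
            )
            en.fit(Xs[:, live], y_res)
            coef_std[live] = en.coef_
    else:
        folds = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
        cv = ElasticNetCV(
            l1_ratio=l1_ratio, alphas=n_lambdas, eps=1e-3,
            fit_intercept=False, cv=folds, tol=tol, max_iter=max_iter,
            n_jobs=None,
        )
        cv.fit(Xs[:, live], y_res)
        mean_mse = cv.mse_path_.mean(axis=1)
        se_mse = cv.mse_path_.std(axis=1, ddof=1) / np.sqrt(cv.mse_path_.shape[1])
        i_min = int(np.argmin(mean_mse))
        if lambda_rule == "1se":
            # largest penalty whose CV error is within one SE of the minimum;
            # alphas_ are sorted descending, so take the first qualifying index
            i_sel = int(np.flatnonzero(
                mean_mse <= mean_mse[i_min] + se_mse[i_min])[0])
        elif lambda_rule == "min":
            i_sel = i_min
        else:
            raise ValueError(f"unknown lambda_rule {lambda_rule!r}")
        lam = float(cv.alphas_[i_sel])
        if i_sel == i_min:
            coef_std[live] = cv.coef_
        else:
            en = ElasticNet(alpha=lam, l1_ratio=l1_ratio, fit_intercept=False,
                            tol=tol, max_iter=max_iter)
            en.fit(Xs[:, live], y_res)
            coef_std[live] = en.coef_
        var_y = float(y_res.var())
        mse = float(mean_mse[i_sel])
        cv_r = float(np.sqrt(max(0.0, 1.0 - mse / var_y))) if var_y > 0 else 0.0

    coef_pen = coef_std / scale_safe
    coef_pen[~live] = 0.0
    # unpenalized block refit given the penalized weights (exact FWL back-solve)
    resid = y - X_pen @ coef_pen
    coef_unpen, *_ = np.linalg.lstsq(U, resid, rcond=None)
    return PenalizedFit(coef_pen=coef_pen, coef_unpen=coef_unpen,
                        lambda_=lam, cv_r=cv_r)
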