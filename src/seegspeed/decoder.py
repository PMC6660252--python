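"""LASSO feature selection with cross-validated λ search and a final Gaussian
linear decoding model.

The LASSO is solved in Lagrangian form, minimising
``(1/2N)·Σ(y − β₀ − Xβ)² + λ·Σ|β_j|`` with the intercept unpenalised,
predictors standardised to unit sample standard deviation and the response
centred; coefficients are reported on the original feature scale.  Solves go
through scikit-learn's cyclic coordinate descent (the same objective
convention); Karush–Kuhn–Tucker optimality of returned solutions is checked
independently with :func:`kkt_violation`.

λ is searched on 100 geometrically spaced values from λ_max (the smallest λ
with an all-zero solution) down to 10⁻⁴·λ_max by 10-fold cross-validation on
the training set; λ̂ minimises the mean validation MSE, ties resolved toward
the largest (sparsest) λ.  The final reported model is an unpenalised
least-squares refit on the selected support; the shrunken LASSO coefficients
are persisted alongside for audit.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
from scipy.linalg import qr
from sklearn.linear_model import Lasso, lasso_path

from .behavior import SpeedNormalization

logger = logging.getLogger(__name__)

#: solver tolerance for certified single fits (KKT residuals ≲ 1e-12)
TIGHT_TOL = 1e-12
#: solver tolerance for the many cross-validation path fits
PATH_TOL = 1e-4

N_LAMBDA = 100
LAMBDA_EPS = 1e-4


class DecoderError(ValueError):
    pass


def split_train_test(n_trials: int, fraction: float = 0.8,
                     rng: np.random.Generator | None = None
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Disjoint, exhaustive random split; train size = ceil(fraction·n)."""
    if n_trials < 10:
        raise DecoderError(f"need at least 10 trials to split, got {n_trials}")
    rng = rng or np.random.default_rng()
    perm = rng.permutation(n_trials)
    n_train = int(np.ceil(fraction * n_trials))
    return np.sort(perm[:n_train]), np.sort(perm[n_train:])


def _standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    dead = sd == 0
    if dead.any():
        logger.warning("dropping %d zero-variance column(s) from LASSO fit",
                       int(dead.sum()))
        sd = np.where(dead, 1.0, sd)
    Xs = (X - mu) / sd
    Xs[:, dead] = 0.0
    return Xs, mu, sd


def lambda_max(X: np.ndarray, y: np.ndarray) -> float:
    """Smallest λ at which all LASSO coefficients are zero (standardised X)."""
    Xs, _, _ = _standardize(np.asarray(X, float))
    yc = y - np.mean(y)
    return float(np.max(np.abs(Xs.T @ yc)) / len(y))


def make_lambda_grid(X: np.ndarray, y: np.ndarray, n: int = N_LAMBDA,
                     eps: float = LAMBDA_EPS) -> np.ndarray:
    lmax = lambda_max(X, y)
    if lmax == 0:
        raise DecoderError("lambda_max is zero; response is orthogonal to all features")
    return np.geomspace(lmax, eps * lmax, n)


def lasso_fit(X: np.ndarray, y: np.ndarray, lam: float,
              tol: float = TIGHT_TOL) -> tuple[float, np.ndarray]:
    """Single Lagrangian LASSO solve; returns (intercept, coefficients) on the
    original feature scale.  λ = 0 falls back to ordinary least squares."""
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise DecoderError("non-finite values in X or y")
    if lam < 0:
        raise DecoderError("lambda must be nonnegative")
    Xs, mu, sd = _standardize(X)
    ybar = float(y.mean())
    yc = y - ybar
    if lam == 0:
        b, *_ = np.linalg.lstsq(Xs, yc, rcond=None)
    else:
        model = Lasso(alpha=lam, fit_intercept=False, tol=tol, max_iter=500_000)
        model.fit(Xs, yc)
        b = model.coef_
    coef = b / sd
    intercept = ybar - float(coef @ mu)
    return intercept, coef


def kkt_violation(X: np.ndarray, y: np.ndarray, intercept: float,
                  coef: np.ndarray, lam: float) -> float:
    """Maximum violation of the LASSO stationarity conditions on the
    standardised problem: for the subgradient g = Xsᵀ(y − ŷ)/N,
    |g_j| ≤ λ for zero coefficients and g_j = λ·sign(β_j) otherwise.
    Independent of the solver."""
    X = np.asarray(X, float)
    Xs, mu, sd = _standardize(X)
    resid = y - intercept - X @ coef
    g = Xs.T @ resid / len(y)
    b = coef * sd  # coefficients on the standardised scale
    nz = b != 0
    viol = 0.0
    if (~nz).any():
        viol = max(viol, float(np.max(np.abs(g[~nz])) - lam))
    if nz.any():
        viol = max(viol, float(np.max(np.abs(g[nz] - lam * np.sign(b[nz])))))
    return viol


@dataclass
class CVResult:
    lambda_grid: np.ndarray  # decreasing
    mean_mse: np.ndarray  # per λ, averaged over folds
    lambda_hat: float
    fold_assignments: np.ndarray  # fold index per training trial
    fold_nonzero: np.ndarray  # folds × λ × features bool, support per fold fit


def cross_validate_lambda(X: np.ndarray, y: np.ndarray, k: int = 10,
                          grid: np.ndarray | None = None,
                          rng: np.random.Generator | None = None,
                          path_tol: float = PATH_TOL) -> CVResult:
    """10-fold CV over the λ grid; λ̂ minimises mean MSE (ties → largest λ)."""
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    n = len(y)
    if k > n:
        raise DecoderError(f"cannot make {k} folds from {n} trials")
    rng = rng or np.random.default_rng()
    if grid is None:
        grid = make_lambda_grid(X, y)
    grid = np.asarray(grid, float)
    folds = rng.permutation(n) % k  # fold sizes differ by at most 1
    mse = np.zeros((k, grid.size))
    nonzero = np.zeros((k, grid.size, X.shape[1]), dtype=bool)
    for f in range(k):
        val = folds == f
        Xs, mu, sd = _standardize(X[~val])
        ybar = y[~val].mean()
        _, coefs, _ = lasso_path(Xs, y[~val] - ybar, alphas=grid,
                                 tol=path_tol, max_iter=100_000)
        # lasso_path returns coefficients for decreasing alphas in grid order
        Xv = (X[val] - mu) / sd
        pred = Xv @ coefs + ybar  # n_val × n_lambda
        mse[f] = np.mean((y[val][:, None] - pred) ** 2, axis=0)
        nonzero[f] = (coefs != 0).T
    mean_mse = mse.mean(axis=0)
    lam_hat = float(grid[int(np.argmin(mean_mse))])  # first min = largest λ
    return CVResult(lambda_grid=grid, mean_mse=mean_mse, lambda_hat=lam_hat,
                    fold_assignments=folds, fold_nonzero=nonzero)


def select_features(X: np.ndarray, y: np.ndarray, lam_hat: float,
                    tol: float = 1e-8) -> np.ndarray:
    """Indices of nonzero-coefficient features from a full-training-set LASSO
    refit at λ̂."""
    _, coef = lasso_fit(X, y, lam_hat, tol=tol)
    return np.flatnonzero(coef != 0)


def fit_final_glm(X_sel: np.ndarray, y: np.ndarray
                  ) -> tuple[float, np.ndarray, np.ndarray]:
    """Unpenalised Gaussian least-squares fit on the selected support.

    Rank-deficient supports drop dependent columns (pivoted QR) with a
    warning.  Returns (beta0, betas, kept column indices); dropped columns
    get coefficient 0.
    """
    X_sel = np.atleast_2d(np.asarray(X_sel, float))
    n, p = X_sel.shape
    if p == 0:
        return float(np.mean(y)), np.zeros(0), np.zeros(0, dtype=int)
    A = np.column_stack([np.ones(n), X_sel])
    _, R, piv = qr(A, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    rank = int(np.sum(diag > max(n, p + 1) * np.finfo(float).eps * diag[0]))
    keep_aug = np.sort(piv[:rank])
    if rank < p + 1:
        logger.warning("dropping %d linearly dependent column(s) in final fit",
                       p + 1 - rank)
    sol, *_ = np.linalg.lstsq(A[:, keep_aug], y, rcond=None)
    full = np.zeros(p + 1)
    full[keep_aug] = sol
    kept = keep_aug[keep_aug > 0] - 1
    return float(full[0]), full[1:], kept


@dataclass
class DecodingModel:
    """Final decoding model: ŷ = β₀ + Σ β_j·x_j over the selected features."""

    variant: str
    selected_indices: np.ndarray
    selected_ids: list[str]
    beta0: float
    betas: np.ndarray  # unpenalised refit, one per selected feature
    lasso_beta0: float
    lasso_betas: np.ndarray  # shrunken coefficients at λ̂ (audit)
    lambda_hat: float
    speed_norm: SpeedNormalization
    use_refit: bool = True

    def predict(self, X_full: np.ndarray) -> np.ndarray:
        """Predict from a full feature matrix (columns = all candidates)."""
        return predict_speed(self, np.asarray(X_full)[:, self.selected_indices])


def fit_decoding_model(X_train: np.ndarray, y_train: np.ndarray,
                       lam_hat: float, feature_ids: list[str],
                       speed_norm: SpeedNormalization, variant: str = "combined",
                       use_refit: bool = True) -> DecodingModel:
    sel = select_features(X_train, y_train, lam_hat)
    l0, lcoef = lasso_fit(X_train, y_train, lam_hat, tol=1e-8)
    if sel.size:
        beta0, betas, _ = fit_final_glm(X_train[:, sel], y_train)
    else:
        beta0, betas = float(np.mean(y_train)), np.zeros(0)
    return DecodingModel(
        variant=variant,
        selected_indices=sel,
        selected_ids=[feature_ids[j] for j in sel],
        beta0=beta0,
        betas=betas,
        lasso_beta0=l0,
        lasso_betas=lcoef[sel],
        lambda_hat=lam_hat,
        speed_norm=speed_norm,
        use_refit=use_refit,
    )


def predict_speed(model: DecodingModel, X: np.ndarray) -> np.ndarray:
    """ŷ = β₀ + Xβ on a matrix whose columns align with the selected features."""
    X = np.atleast_2d(np.asarray(X, float))
    if X.shape[1] != len(model.selected_indices):
        raise DecoderError(
            f"feature matrix has {X.shape[1]} columns, model expects "
            f"{len(model.selected_indices)} selected features")
    if model.use_refit:
        return model.beta0 + X @ model.betas
    return model.lasso_beta0 + X @ model.lasso_betas


def save_model(model: DecodingModel, path) -> None:
    payload = {
        "variant": model.variant,
        "lambda_hat": model.lambda_hat,
        "selected_indices": model.selected_indices.tolist(),
        "selected_features": model.selected_ids,
        "beta0": model.beta0,
        "betas": model.betas.tolist(),
        "lasso_beta0": model.lasso_beta0,
        "lasso_betas": model.lasso_betas.tolist(),
        "speed_norm": {"log_mean": model.speed_norm.log_mean,
                       "log_sd": model.speed_norm.log_sd},
        "use_refit": model.use_refit,
    }
    with open(path, "w") as f:
        json.dump(payload, f, indent=1)


def load_model(path) -> DecodingModel:
    with open(path) as f:
        d = json.load(f)
    return DecodingModel(
        variant=d["variant"],
        selected_indices=np.array(d["selected_indices"], dtype=int),
        selected_ids=d["selected_features"],
        beta0=d["beta0"],
        betas=np.array(d["betas"]),
        lasso_beta0=d["lasso_beta0"],
        lasso_betas=np.array(d["lasso_betas"]),
        lambda_hat=d["lambda_hat"],
        speed_norm=SpeedNormalization(**d["speed_norm"]),
        use_refit=d["use_refit"],
    )
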