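"""Survey-weighted L1/L2-penalized logistic regression with CV lambda selection.

The working model is Bernoulli-logistic: for respondent i with encoded
covariates X_i, sampling weight w_i and outcome y_i,

    l(theta, b) = sum_i w_i * [ y_i * eta_i - log(1 + exp(eta_i)) ],
    eta_i = b + X_i theta,

and the fit maximizes ``l - lam * ||theta||_1`` (lasso) or
``l - lam * ||theta||_2^2`` (ridge).  The ridge penalty is lam*|theta|^2
exactly (no 1/2 factor), so lam values are comparable across
implementations that print the penalty this way.  The intercept b is never
penalized.  Weights are normalized to mean 1 inside the fit so the
effective sample size matches n and lam lives on a per-sum scale: doubling
every weight changes nothing.

Columns are standardized internally to weighted mean 0 / variance 1
(penalties are scale-sensitive); coefficients are retained on both the
standardized and the original scale.  The solver is an IRLS +
coordinate-descent path algorithm with warm starts (see
:mod:`itaselect._cd`); correctness is defined by the first-order (KKT)
conditions of the objective above, which the solver checks exactly, not by
the routine's identity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import expit, log_expit, logit
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import StratifiedKFold
from sklearn.utils.validation import check_X_y, check_array

from ._cd import cd_path
from .datasets import EncodedDataset

__all__ = [
    "PenalizedFit",
    "CVCurve",
    "PenalizedLogit",
    "PenalizedLogitCV",
    "weighted_loglik",
    "fit_penalized",
    "cv_select_lambda",
    "predict_prob",
    "lambda_max",
    "default_lambda_grid",
]


def weighted_loglik(theta, intercept, ds: EncodedDataset) -> float:
    """Weighted Bernoulli log-likelihood sum_i w_i [y_i eta_i - log(1+e^eta_i)].

    Computed through ``log_expit`` so large |eta| never overflows.  This is
    the raw weighted sum (no weight normalization); the mean-1 normalization
    applied inside fits only rescales lambda, not the likelihood shape.
    """
    theta = np.asarray(theta, dtype=float)
    if theta.shape[0] != ds.p:
        raise ValueError(f"theta has {theta.shape[0]} entries for {ds.p} columns")
    eta = intercept + ds.X @ theta
    # y*eta - log(1+e^eta) = log sigmoid(eta) for y=1, log sigmoid(-eta) for y=0
    ll = np.where(ds.y == 1, log_expit(eta), log_expit(-eta))
    return float(np.sum(ds.w * ll))


@dataclass
class PenalizedFit:
    """One fitted penalized model, on both coefficient scales.

    ``theta_std`` lives on the standardized-column scale (the scale on which
    the penalty acted and on which knee selection compares magnitudes);
    ``theta`` is back-transformed to the original columns.
    """

    names: list
    theta: np.ndarray
    theta_std: np.ndarray
    intercept: float
    intercept_std: float
    penalty: str
    lam: float
    converged: bool
    objective: float
    n_nonzero: int

    def to_dict(self) -> dict:
        return {
            "penalty": self.penalty,
            "lam": self.lam,
            "converged": self.converged,
            "objective": self.objective,
            "n_nonzero": self.n_nonzero,
            "intercept": self.intercept,
            "intercept_std": self.intercept_std,
            "coefficients": {
                n: {"original": float(t), "standardized": float(ts)}
                for n, t, ts in zip(self.names, self.theta, self.theta_std)
            },
        }


@dataclass
class CVCurve:
    """Cross-validation profile of the held-out weighted log-likelihood."""

    lam_grid: np.ndarray
    mean_cv_loglik: np.ndarray
    fold_loglik: np.ndarray  # shape (k, len(grid))
    chosen_lam: float
    k: int
    seed: int

    def __post_init__(self):
        self.lam_grid = np.asarray(self.lam_grid, dtype=float)
        if np.any(np.diff(self.lam_grid) >= 0):
            raise ValueError("lam_grid must be strictly decreasing")


def _normalize_weights(w):
    w = np.asarray(w, dtype=float)
    if np.any(w <= 0):
        raise ValueError("weights must be strictly positive")
    return w / w.mean()


def _weighted_standardize(X, w):
    """Weighted mean-0/var-1 columns; zero-variance columns get scale 1."""
    wn = w / w.sum()
    mu = wn @ X
    var = wn @ (X - mu) ** 2
    scale = np.sqrt(var)
    scale[scale == 0] = 1.0
    return (X - mu) / scale, mu, scale


def lambda_max(X, y, w) -> float:
    """Smallest lam with an all-zero L1 solution.

    At the null model the intercept equals the weighted logit of prevalence
    and the KKT bound is max_j |sum_i w_i x_ij (y_i - pbar)| on standardized
    columns.
    """
    w = _normalize_weights(w)
    Xs, _, _ = _weighted_standardize(np.asarray(X, dtype=float), w)
    pbar = float(np.average(y, weights=w))
    g = Xs.T @ (w * (np.asarray(y) - pbar))
    lmax = float(np.max(np.abs(g)))
    if lmax <= 0:
        raise ValueError("degenerate design: null-model gradient is zero")
    return lmax


def default_lambda_grid(X, y, w, n_lambdas: int = 50, min_ratio: float = 1e-4):
    """Log-spaced decreasing grid from lambda_max down to min_ratio*lambda_max."""
    lmax = lambda_max(X, y, w)
    if n_lambdas == 1:
        return np.array([lmax])
    return np.geomspace(lmax, min_ratio * lmax, n_lambdas)


def _kkt_residuals(g, theta, lam, penalty):
    """Per-coordinate first-order residuals; g is the gradient of -loglik."""
    if penalty == "l1":
        active = np.abs(g + lam * np.sign(theta))
        inactive = np.maximum(0.0, np.abs(g) - lam)
        return np.where(theta != 0, active, inactive)
    return np.abs(g + 2.0 * lam * theta)


def _prepare(X, y, sample_weight):
    X, y = check_X_y(X, y, dtype=np.float64)
    classes = np.unique(y)
    if not np.all(np.isin(classes, [0, 1])) or len(classes) < 2:
        raise ValueError("y must contain both classes coded 0/1")
    w = (np.ones(len(y)) if sample_weight is None
         else np.asarray(sample_weight, dtype=float))
    w = _normalize_weights(w)
    Xs, mu, scale = _weighted_standardize(X, w)
    return np.asfortranarray(Xs), np.asarray(y, dtype=np.float64), w, mu, scale


def _solve_path(Xs, y, w, lams, penalty, tol, max_outer, max_inner,
                theta0=None, b0=None):
    p = Xs.shape[1]
    if theta0 is None:
        theta0 = np.zeros(p)
    if b0 is None:
        pbar = float(np.average(y, weights=w))
        b0 = float(logit(pbar))
    return cd_path(
        Xs, y, w, np.asarray(lams, dtype=float), penalty == "l1",
        tol, max_outer, max_inner, np.asarray(theta0, dtype=float), float(b0),
    )


class PenalizedLogit(BaseEstimator, ClassifierMixin):
    """L1- or L2-penalized weighted logistic regression at a fixed lambda.

    Parameters
    ----------
    penalty : {"l1", "l2"}
        "l1" (lasso) zeroes irrelevant coefficients; "l2" (ridge) shrinks
        without zeroing.
    lam : float
        Non-negative tuning parameter on the per-sum objective
        ``-sum_i w_i ll_i + lam * P(theta)`` with P the 1-norm or the
        squared 2-norm (no 1/2 factor).
    kkt_tol : float
        Per-observation first-order tolerance declaring convergence: the
        largest KKT residual divided by sum(w) must fall below it.
    max_outer, max_inner : int
        IRLS and coordinate-sweep iteration caps.

    Attributes
    ----------
    coef_ : ndarray of shape (p,)
        Coefficients on the original column scale.
    coef_std_ : ndarray of shape (p,)
        Coefficients on the standardized (penalized) scale.
    intercept_ : float
    converged_ : bool
    kkt_residual_ : float
        Final per-observation KKT residual.
    objective_ : float
        Final penalized objective (standardized scale).
    n_nonzero_ : int
        Count of coefficients with |theta_j| > 0.
    """

    def __init__(self, penalty="l1", lam=1.0, kkt_tol=1e-8,
                 max_outer=100, max_inner=1000):
        self.penalty = penalty
        self.lam = lam
        self.kkt_tol = kkt_tol
        self.max_outer = max_outer
        self.max_inner = max_inner

    def fit(self, X, y, sample_weight=None):
        if self.penalty not in ("l1", "l2"):
            raise ValueError(f"penalty must be 'l1' or 'l2', got {self.penalty!r}")
        if self.lam < 0:
            raise ValueError("lam must be non-negative")
        Xs, yf, w, mu, scale = _prepare(X, y, sample_weight)
        thetas, bs, kkts, _ = _solve_path(
            Xs, yf, w, [self.lam], self.penalty, self.kkt_tol,
            self.max_outer, self.max_inner,
        )
        theta, b, kkt = thetas[0], float(bs[0]), float(kkts[0])
        converged = kkt <= self.kkt_tol
        if not converged:
            warnings.warn(
                f"penalized fit stopped at KKT residual {kkt:.2e} "
                f"(> {self.kkt_tol:.0e}); returning the best iterate"
            )

        self.coef_std_ = theta
        self.coef_ = theta / scale
        self.intercept_std_ = b
        self.intercept_ = b - float(np.sum(theta * mu / scale))
        self.converged_ = bool(converged)
        self.kkt_residual_ = kkt
        pen = (np.abs(theta).sum() if self.penalty == "l1"
               else float(theta @ theta))
        eta = b + Xs @ theta
        ll = np.where(yf == 1, log_expit(eta), log_expit(-eta))
        self.objective_ = float(-(w @ ll) + self.lam * pen)
        self.n_nonzero_ = int(np.sum(theta != 0))
        self.classes_ = np.array([0, 1])
        self.n_features_in_ = Xs.shape[1]
        return self

    def decision_function(self, X):
        X = check_array(X, dtype=np.float64)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} features, fit used {self.n_features_in_}"
            )
        return self.intercept_ + X @ self.coef_

    def predict_proba(self, X):
        p1 = expit(self.decision_function(X))
        return np.column_stack([1 - p1, p1])

    def predict(self, X):
        return (self.decision_function(X) >= 0).astype(int)

    def as_fit(self, colnames=None) -> PenalizedFit:
        names = (list(colnames) if colnames is not None
                 else [f"x{j}" for j in range(self.n_features_in_)])
        return PenalizedFit(
            names=names,
            theta=self.coef_.copy(),
            theta_std=self.coef_std_.copy(),
            intercept=float(self.intercept_),
            intercept_std=float(self.intercept_std_),
            penalty={"l1": "L1", "l2": "L2"}[self.penalty],
            lam=float(self.lam),
            converged=self.converged_,
            objective=self.objective_,
            n_nonzero=self.n_nonzero_,
        )


class PenalizedLogitCV(BaseEstimator, ClassifierMixin):
    """Select lambda by stratified k-fold CV of the held-out weighted loglik.

    The grid defaults to 50 log-spaced points from lambda_max (the smallest
    lambda with an all-zero L1 solution, from the weighted null-model
    gradient) down to 1e-4 * lambda_max; the same anchor is reused for the
    ridge grid so both penalties share one grid construction.  For each
    fold the whole path is fit warm-started at a looser exploratory
    tolerance (``cv_tol``) and scored by the held-out weighted
    log-likelihood; chosen lambda maximizes the fold mean, ties going to
    the larger (more parsimonious) lambda.  The final model is refit on all
    rows at the chosen lambda at full tolerance.
    """

    def __init__(self, penalty="l1", lam_grid=None, n_lambdas=50,
                 lam_min_ratio=1e-4, k=5, seed=0, kkt_tol=1e-8, cv_tol=1e-5,
                 max_outer=100, max_inner=1000):
        self.penalty = penalty
        self.lam_grid = lam_grid
        self.n_lambdas = n_lambdas
        self.lam_min_ratio = lam_min_ratio
        self.k = k
        self.seed = seed
        self.kkt_tol = kkt_tol
        self.cv_tol = cv_tol
        self.max_outer = max_outer
        self.max_inner = max_inner

    def fit(self, X, y, sample_weight=None):
        if self.k < 2:
            raise ValueError("k must be >= 2")
        X, y = check_X_y(X, y, dtype=np.float64)
        w = (np.ones(len(y)) if sample_weight is None
             else np.asarray(sample_weight, dtype=float))
        if self.lam_grid is not None:
            grid = np.unique(np.asarray(self.lam_grid, dtype=float))[::-1]
            if grid.size == 0 or np.any(grid <= 0):
                raise ValueError("lam_grid must be non-empty and positive")
        else:
            grid = default_lambda_grid(
                X, y, w, n_lambdas=self.n_lambdas, min_ratio=self.lam_min_ratio
            )

        skf = StratifiedKFold(n_splits=self.k, shuffle=True,
                              random_state=self.seed)
        fold_ll = np.empty((self.k, grid.size))
        for f, (tr, te) in enumerate(skf.split(X, y)):
            if y[te].sum() == 0 or y[tr].sum() == 0:
                raise ValueError(
                    f"fold {f} has no positive cases; increase n or reduce k "
                    "(folds are stratified, so this signals an extremely "
                    "rare outcome)"
                )
            Xs, yf, wf, mu, scale = _prepare(X[tr], y[tr], w[tr])
            thetas, bs, _, _ = _solve_path(
                Xs, yf, wf, grid, self.penalty, self.cv_tol,
                self.max_outer, self.max_inner,
            )
            theta_orig = thetas / scale[None, :]
            b_orig = bs - thetas @ (mu / scale)
            etas = X[te] @ theta_orig.T + b_orig[None, :]
            ll = np.where(y[te, None] == 1, log_expit(etas), log_expit(-etas))
            fold_ll[f, :] = w[te] @ ll

        mean_ll = fold_ll.mean(axis=0)
        best = int(np.argmax(mean_ll))  # grid descending: first max = larger lam
        chosen = float(grid[best])
        self.cv_curve_ = CVCurve(
            lam_grid=grid, mean_cv_loglik=mean_ll, fold_loglik=fold_ll,
            chosen_lam=chosen, k=self.k, seed=self.seed,
        )
        self.best_lam_ = chosen
        self.best_estimator_ = PenalizedLogit(
            penalty=self.penalty, lam=chosen, kkt_tol=self.kkt_tol,
            max_outer=self.max_outer, max_inner=self.max_inner,
        ).fit(X, y, sample_weight=w)
        for attr in ("coef_", "coef_std_", "intercept_", "intercept_std_",
                     "converged_", "kkt_residual_", "objective_",
                     "n_nonzero_", "classes_", "n_features_in_"):
            setattr(self, attr, getattr(self.best_estimator_, attr))
        return self

    def predict_proba(self, X):
        return self.best_estimator_.predict_proba(X)

    def predict(self, X):
        return self.best_estimator_.predict(X)

    def decision_function(self, X):
        return self.best_estimator_.decision_function(X)

    def as_fit(self, colnames=None) -> PenalizedFit:
        return self.best_estimator_.as_fit(colnames)


# ---------------------------------------------------------------------------
# thin functional wrappers over the estimators

def fit_penalized(ds: EncodedDataset, penalty: str, lam: float,
                  **kwargs) -> PenalizedFit:
    """Fit one penalized model on an encoded dataset at a fixed lambda."""
    key = penalty.lower()
    if key not in ("l1", "l2"):
        raise ValueError(f"penalty must be L1 or L2, got {penalty!r}")
    est = PenalizedLogit(penalty=key, lam=lam, **kwargs)
    est.fit(ds.X, ds.y, sample_weight=ds.w)
    return est.as_fit(ds.colnames)


def cv_select_lambda(ds: EncodedDataset, penalty: str, lam_grid=None,
                     k: int = 5, seed: int = 0, **kwargs) -> CVCurve:
    """k-fold CV over a lambda grid; returns the CV curve with chosen_lam."""
    est = PenalizedLogitCV(penalty=penalty.lower(), lam_grid=lam_grid,
                           k=k, seed=seed, **kwargs)
    est.fit(ds.X, ds.y, sample_weight=ds.w)
    return est.cv_curve_


def predict_prob(fit: PenalizedFit, X) -> np.ndarray:
    """P(y=1 | X) under a fitted model, on the original column scale."""
    X = np.asarray(X, dtype=float)
    if X.shape[1] != len(fit.theta):
        raise ValueError(
            f"X has {X.shape[1]} columns, fit expects {len(fit.theta)}"
        )
    return expit(fit.intercept + X @ fit.theta)
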