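"""Shared fixtures and independent oracle implementations.

The oracles here deliberately avoid the package's own code paths: the
Newton-Raphson MLE uses dense linear algebra, the AUC oracle enumerates all
positive/negative pairs, and the knee oracle maximizes perpendicular
distance to the endpoint chord.  They exist to check the production
implementations from a different direction.
"""

import math

import numpy as np
import pytest

from itaselect import EncodedDataset


# ---------------------------------------------------------------------------
# oracles

def newton_weighted_logistic(X, y, w, ridge_lam=0.0, tol=1e-12, max_iter=200):
    """Weighted logistic MLE (optionally + lam*||theta||^2 ridge penalty,
    intercept unpenalized) by damped Newton-Raphson on the given matrix."""
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    Z = np.column_stack([np.ones(n), X])
    beta = np.zeros(p + 1)
    pen = np.diag([0.0] + [2.0 * ridge_lam] * p)
    for _ in range(max_iter):
        eta = Z @ beta
        prob = 1.0 / (1.0 + np.exp(-eta))
        grad = Z.T @ (w * (y - prob)) - pen @ beta
        H = (Z * (w * prob * (1 - prob))[:, None]).T @ Z + pen
        step = np.linalg.solve(H, grad)
        t = 1.0
        def obj(b):
            e = Z @ b
            ll = np.where(y == 1, -np.logaddexp(0, -e), -np.logaddexp(0, e))
            return float(w @ ll - ridge_lam * np.sum(b[1:] ** 2))
        base = obj(beta)
        while t > 1e-8 and obj(beta + t * step) < base:
            t /= 2
        beta = beta + t * step
        if np.max(np.abs(grad)) < tol * n:
            break
    return beta[0], beta[1:]


def auc_pair_oracle(y, p, w=None):
    """AUC by exhaustive (weighted) pair counting, ties worth 1/2."""
    y = np.asarray(y)
    p = np.asarray(p, dtype=float)
    w = np.ones(len(y)) if w is None else np.asarray(w, dtype=float)
    pos = np.flatnonzero(y == 1)
    neg = np.flatnonzero(y == 0)
    num = den = 0.0
    for i in pos:
        for j in neg:
            wij = w[i] * w[j]
            den += wij
            if p[i] > p[j]:
                num += wij
            elif p[i] == p[j]:
                num += 0.5 * wij
    return num / den


def chord_knee_oracle(values):
    """Index of maximum perpendicular distance to the endpoint chord."""
    y = np.asarray(values, dtype=float)
    n = len(y)
    x = np.linspace(0.0, 1.0, n)
    yn = (y - y.min()) / (y.max() - y.min())
    x0, y0, x1, y1 = x[0], yn[0], x[-1], yn[-1]
    dist = np.abs((y1 - y0) * x - (x1 - x0) * yn + x1 * y0 - y1 * x0)
    return int(np.argmax(dist))


def loglik_term_by_term(theta, intercept, X, y, w):
    """Direct summation of w_i * [y_i eta_i - log(1 + e^eta_i)]."""
    total = 0.0
    for i in range(len(y)):
        eta = intercept + float(np.dot(X[i], theta))
        total += w[i] * (y[i] * eta - math.log1p(math.exp(-abs(eta)))
                         - max(eta, 0.0))
    return total


# ---------------------------------------------------------------------------
# fixtures

@pytest.fixture(scope="session")
def toy_dataset():
    """200 x 6 encoded dataset: two real effects, four noise columns."""
    rng = np.random.default_rng(42)
    n = 200
    X = (rng.random((n, 6)) < 0.4).astype(float)
    eta = -1.0 + 1.5 * X[:, 0] - 1.2 * X[:, 1]
    y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
    w = rng.uniform(0.5, 2.0, n)
    w /= w.mean()
    return EncodedDataset(X=X, y=y, w=w,
                          colnames=[f"v{j}=yes" for j in range(6)])


@pytest.fixture(scope="session")
def small_benchmark():
    """Scaled-down themed benchmark: fast but structurally faithful."""
    from itaselect import default_benchmark, generate

    spec = default_benchmark(seed=7, n=2500, p_noise=80)
    ds, truth = generate(spec)
    return spec, ds, truth
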