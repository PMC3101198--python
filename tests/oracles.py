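"""Independent reference computations used to validate the fast paths.

Everything here works from first principles on dense matrices or explicit
likelihoods, deliberately sharing no code with the package implementations
it checks.
"""

import numpy as np


def gls_phylo_mean(v: np.ndarray, x: np.ndarray) -> tuple[float, float]:
    """GLS (phylogenetically weighted) mean and its variance from dense V."""
    vi = np.linalg.inv(v)
    one = np.ones(len(x))
    denom = one @ vi @ one
    return float(one @ vi @ x / denom), float(1.0 / denom)


def gls_blomberg_k(v: np.ndarray, x: np.ndarray) -> float:
    """Blomberg's K from the dense tree covariance matrix."""
    n = len(x)
    vi = np.linalg.inv(v)
    ahat, _ = gls_phylo_mean(v, x)
    dev = x - ahat
    mse0 = dev @ dev / (n - 1)
    mse = dev @ vi @ dev / (n - 1)
    one = np.ones(n)
    expected = (np.trace(v) - n / (one @ vi @ one)) / (n - 1)
    return float((mse0 / mse) / expected)


def gls_contrast_quadratic(v: np.ndarray, x: np.ndarray) -> float:
    """(x - ahat)' V^-1 (x - ahat): equals the sum of squared standardized
    contrasts under the pruning algorithm."""
    vi = np.linalg.inv(v)
    ahat, _ = gls_phylo_mean(v, x)
    dev = x - ahat
    return float(dev @ vi @ dev)


def irls_binomial(X: np.ndarray, successes: np.ndarray, trials: np.ndarray,
                  prior_weights: np.ndarray | None = None,
                  tol: float = 1e-12, max_iter: int = 200) -> np.ndarray:
    """Binomial-logit GLM coefficients by hand-rolled IRLS."""
    n, p = X.shape
    w0 = np.ones(n) if prior_weights is None else np.asarray(prior_weights, float)
    y = successes / trials
    beta = np.zeros(p)
    beta[0] = np.log((y.mean() + 1e-6) / (1 - y.mean() + 1e-6))
    for _ in range(max_iter):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        wdiag = w0 * trials * mu * (1 - mu)
        z = eta + (y - mu) / (mu * (1 - mu))
        new = np.linalg.solve(X.T @ (wdiag[:, None] * X), X.T @ (wdiag * z))
        if np.max(np.abs(new - beta)) < tol:
            return new
        beta = new
    raise RuntimeError("IRLS oracle did not converge")


def multinomial_llr_g(observed: np.ndarray, expected: np.ndarray) -> float:
    """G as 2x the multinomial log-likelihood ratio (saturated vs expected)."""
    o = np.asarray(observed, float)
    n = o.sum()
    p0 = np.asarray(expected, float) / n
    p1 = o / n
    ll = 0.0
    for oi, a, b in zip(o, p1, p0):
        if oi > 0:
            ll += oi * (np.log(a) - np.log(b))
    return float(2 * ll)
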