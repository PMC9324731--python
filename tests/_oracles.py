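"""Independent brute-force oracles used only by the tests.

These deliberately avoid the package's estimation code paths: the JMLE check
maximizes the joint Rasch likelihood by coordinate ascent on a fine parameter
grid, and the quadrature check integrates on a fixed trapezoid grid.
"""

import numpy as np


def grid_rasch_oracle(X, lo=-6.0, hi=6.0, step=0.001, max_sweeps=500):
    """Joint-likelihood maximization of the dichotomous Rasch model by
    exhaustive per-parameter grid search (coordinate ascent).

    ``X`` must contain no extreme rows/columns. Returns (theta, delta) with
    item difficulties centered to mean zero. The log-likelihood is concave,
    so coordinate ascent on the grid reaches the joint maximum to within the
    grid resolution.
    """
    X = np.asarray(X, dtype=float)
    n, L = X.shape
    grid = np.arange(lo, hi + step / 2, step)
    theta = np.zeros(n)
    delta = np.zeros(L)

    def loglik_person(i, th_grid, delta):
        z = th_grid[:, None] - delta[None, :]
        # log P = z - log(1+e^z); log(1-P) = -log(1+e^z)
        log1p = np.logaddexp(0.0, z)
        return (X[i] * z).sum(axis=1) - log1p.sum(axis=1)

    def loglik_item(j, d_grid, theta):
        z = theta[None, :] - d_grid[:, None]
        log1p = np.logaddexp(0.0, z)
        return (X[:, j] * z).sum(axis=1) - log1p.sum(axis=1)

    for _ in range(max_sweeps):
        changed = False
        for i in range(n):
            ll = loglik_person(i, grid, delta)
            new = grid[np.argmax(ll)]
            if new != theta[i]:
                theta[i] = new
                changed = True
        for j in range(L):
            ll = loglik_item(j, grid, theta)
            new = grid[np.argmax(ll)]
            if new != delta[j]:
                delta[j] = new
                changed = True
        # fix the gauge near zero so the bounded grid is never limiting
        shift = round(delta.mean() / step) * step
        if abs(shift) >= step:
            delta -= shift
            theta -= shift
        if not changed:
            break
    shift = delta.mean()
    return theta - shift, delta - shift


def trapezoid_sensitivity_oracle(delta, mean, sd, n_points=10_000, span_sd=8.0):
    """E[-P(1-P)] over a Normal(mean, sd) ability on a fixed trapezoid grid."""
    theta = np.linspace(mean - span_sd * sd, mean + span_sd * sd, n_points)
    pdf = np.exp(-0.5 * ((theta - mean) / sd) ** 2) / (sd * np.sqrt(2 * np.pi))
    p = 1.0 / (1.0 + np.exp(-(theta - delta)))
    return float(np.trapezoid(pdf * (-p * (1 - p)), theta))
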