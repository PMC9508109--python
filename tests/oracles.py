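"""Independent numerical oracles shared by the test modules."""

import numpy as np
from scipy.optimize import minimize


def qp_oracle(X, y, C, eps):
    """Generic convex solve of the epsilon-SVR primal via SLSQP.

    Decision variables (w, b, xi); the split slack constraints are folded
    into one inequality vector. Returns the optimal objective value.
    """
    X = np.atleast_2d(np.asarray(X, float))
    y = np.asarray(y, float)
    if X.shape[0] != len(y):
        X = X.T
    n, D = X.shape

    def objective(v):
        w, xi = v[:D], v[D + 1:]
        return 0.5 * w @ w + C * xi.sum()

    def constraints(v):
        w, b, xi = v[:D], v[D], v[D + 1:]
        r = y - X @ w - b
        return np.concatenate([eps + xi - r, eps + xi + r, xi])

    res = minimize(objective, np.zeros(D + 1 + n),
                   constraints=[{"type": "ineq", "fun": constraints}],
                   method="SLSQP", options={"maxiter": 1000, "ftol": 1e-14})
    return res.fun
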