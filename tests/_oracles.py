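"""Independent brute-force oracles used by the tests.

These deliberately avoid the code paths they validate.
"""

import numpy as np
from scipy.optimize import minimize


def ols_fitted(X, y):
    """Ordinary least squares fitted values with an intercept."""
    Xi = np.column_stack([np.ones(len(y)), X])
    coef, *_ = np.linalg.lstsq(Xi, y, rcond=None)
    return Xi @ coef


def oracle_tail_probability(theta, tau, gridB, r, n_restarts=25, seed=0):
    """Max P(X >= tau) over r-concave distributions on {0..gridB}/gridB
    with mean <= theta, by multi-start SLSQP over the convex sequence
    q_k = p_k^r (support swept over contiguous ranges [0, hi])."""
    rng = np.random.default_rng(seed)
    t = int(np.ceil(round(tau * gridB, 9)))
    if t <= 0:
        return 1.0
    best = 0.0
    for hi in range(t, gridB + 1):
        m = hi + 1

        def neg_tail(z):
            return -(z ** (1.0 / r))[t:].sum()

        cons = [
            {"type": "eq", "fun": lambda z: (z ** (1.0 / r)).sum() - 1.0},
            {
                "type": "ineq",
                "fun": lambda z: theta * gridB
                - (np.arange(m) * (z ** (1.0 / r))).sum(),
            },
        ]
        if m > 2:
            cons.append(
                {"type": "ineq", "fun": lambda z: z[:-2] - 2 * z[1:-1] + z[2:]}
            )
        for _ in range(n_restarts):
            # random positive convex start, rescaled so the masses sum to 1
            d2 = rng.exponential(1.0, size=max(m - 2, 0))
            z = np.empty(m)
            z[0] = rng.exponential(1.0)
            if m > 1:
                s0 = rng.exponential(1.0)
                incr = (
                    np.concatenate([[s0], s0 + np.cumsum(d2)])
                    if m > 2
                    else np.array([s0])
                )
                z[1:] = z[0] + np.cumsum(incr)
            z *= float((z ** (1.0 / r)).sum()) ** r
            res = minimize(
                neg_tail,
                z,
                method="SLSQP",
                constraints=cons,
                bounds=[(1e-12, None)] * m,
                options={"maxiter": 300, "ftol": 1e-12},
            )
            if not res.success:
                continue
            p = res.x ** (1.0 / r)
            if abs(p.sum() - 1.0) > 1e-7:
                continue
            if (np.arange(m) * p).sum() > theta * gridB + 1e-7:
                continue
            if m > 2 and np.min(res.x[:-2] - 2 * res.x[1:-1] + res.x[2:]) < -1e-9:
                continue
            best = max(best, float(p[t:].sum()))
    return best
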