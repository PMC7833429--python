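import numpy as np
import pytest
from scipy.optimize import minimize

from ecgsq.svm import fit_svm


def solve_primal_oracle(K, y, C, s0=None):
    """Independent SLSQP solve of the soft-margin primal in representer form.

    w = sum_i beta_i phi(x_i) (plus an optional fixed base score s0 inside
    the margin constraints, as in the adaptation objective).  Returns the
    optimal objective value.  SLSQP's "positive directional derivative"
    exit is accepted when the constraints hold, as it occurs at the
    optimum on flat regions.
    """
    n = y.size
    s0 = np.zeros(n) if s0 is None else s0
    margin = lambda z: y * (s0 + K @ z[:n] + z[n]) - 1 + z[n + 1:]
    cons = [{"type": "ineq", "fun": margin},
            {"type": "ineq", "fun": lambda z: z[n + 1:]}]
    obj = lambda z: 0.5 * z[:n] @ K @ z[:n] + C * z[n + 1:].sum()
    best = None
    for ftol in (1e-14, 1e-12, 1e-10):
        res = minimize(obj, np.zeros(2 * n + 1), constraints=cons,
                       method="SLSQP", options={"maxiter": 2000, "ftol": ftol})
        feasible = (margin(res.x).min() > -1e-8 and res.x[n + 1:].min() > -1e-8)
        if feasible and (res.success or res.status == 8):
            if best is None or res.fun < best:
                best = res.fun
        if best is not None and res.success:
            break
    assert best is not None, "primal oracle failed to converge"
    return best


@pytest.fixture(scope="session")
def blobs():
    """Two well-separated seeded 3-D Gaussian blobs (n=200)."""
    rng = np.random.default_rng(42)
    X = np.vstack([rng.normal(0, 1, (100, 3)), rng.normal(4, 1, (100, 3))])
    y = np.concatenate([-np.ones(100), np.ones(100)])
    return X, y


@pytest.fixture(scope="session")
def toy_model(blobs):
    X, y = blobs
    return fit_svm(X, y, C=10.0, gamma=0.5)
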