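"""Independent reference computations used only by the test suite."""

from itertools import combinations

import numpy as np


def transport_cost_bruteforce(cost: np.ndarray, a: np.ndarray, b: np.ndarray) -> float:
    """Minimum-cost transport by exhaustive vertex enumeration.

    The optimum of a transportation LP is attained at a basic feasible
    solution with at most ``n + m - 1`` nonzero entries; enumerate every
    support of that size, solve the square marginal system and keep the
    cheapest feasible candidate.  Exponential, hence only for tiny inputs.
    """
    n, m = cost.shape
    nv = n * m
    A = np.zeros((n + m - 1, nv))
    for i in range(n):
        A[i, i * m:(i + 1) * m] = 1.0
    for j in range(m - 1):
        A[n + j, j::m] = 1.0
    rhs = np.concatenate([a, b[:-1]])
    best = np.inf
    for support in combinations(range(nv), n + m - 1):
        sub = A[:, support]
        try:
            x = np.linalg.solve(sub, rhs)
        except np.linalg.LinAlgError:
            continue
        if np.all(x >= -1e-12):
            best = min(best, float(cost.ravel()[list(support)] @ x))
    return best


def real_sh_closed_form(l: int, m: int, theta: float, phi: float) -> float:
    """Textbook closed forms of the real symmetric basis for low orders.

    The basis under test is sqrt(2) Re(Y_l^|m|) for m < 0, Y_l^0 for m = 0
    and sqrt(2) Im(Y_l^m) for m > 0, with Condon-Shortley-phase complex
    harmonics; the expressions below are written out from the standard
    tables, sharing no code with the implementation.
    """
    st, ct = np.sin(theta), np.cos(theta)
    if (l, m) == (0, 0):
        return 0.5 / np.sqrt(np.pi)
    if (l, m) == (2, 0):
        return np.sqrt(5.0 / (16 * np.pi)) * (3 * ct**2 - 1)
    if (l, abs(m)) == (2, 1):
        # Y_2^1 = -sqrt(15/8pi) sin(t) cos(t) e^{i phi}
        mag = -np.sqrt(15.0 / (4 * np.pi)) * st * ct
        return mag * (np.sin(phi) if m > 0 else np.cos(phi))
    if (l, abs(m)) == (2, 2):
        # Y_2^2 = (1/4) sqrt(15/2pi) sin^2(t) e^{2 i phi}
        mag = 0.25 * np.sqrt(15.0 / np.pi) * st**2
        return mag * (np.sin(2 * phi) if m > 0 else np.cos(2 * phi))
    if (l, m) == (4, 0):
        return 3.0 / (16 * np.sqrt(np.pi)) * (35 * ct**4 - 30 * ct**2 + 3)
    raise NotImplementedError((l, m))


def quadrature_variance(values: np.ndarray, weights: np.ndarray) -> float:
    """Variance of a spherical function from quadrature samples."""
    total = weights.sum()
    mean = (values * weights).sum() / total
    return float((((values - mean) ** 2) * weights).sum() / total)
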