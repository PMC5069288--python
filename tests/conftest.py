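"""Shared fixtures and independent oracles used across the suite."""

import numpy as np
import pytest
from scipy.optimize import LinearConstraint, minimize

from wedag import build_filter_bank


# --------------------------------------------------------------------------
# independent oracles (kept free of the code paths they check)

def conv_decimate(a: np.ndarray, f: np.ndarray, axis: int) -> np.ndarray:
    """Explicit symmetric padding + full convolution + keep-odd decimation."""
    L = len(f)
    pad = [(L - 1, L - 1) if ax == axis else (0, 0) for ax in range(2)]
    ap = np.pad(a, pad, mode="symmetric")
    full = np.apply_along_axis(np.convolve, axis, ap, f, "valid")
    sl = [slice(None)] * 2
    sl[axis] = slice(1, None, 2)
    return full[tuple(sl)]


def dwt2_direct(img, fb):
    """Brute-force single-level 2D DWT: returns (LL, HL, LH, HH) grids."""
    lo, hi = fb.dec_lo, fb.dec_hi
    a = conv_decimate(img, lo, 0)
    d = conv_decimate(img, hi, 0)
    return (
        conv_decimate(a, lo, 1),
        conv_decimate(d, lo, 1),
        conv_decimate(a, hi, 1),
        conv_decimate(d, hi, 1),
    )


def entropy_direct(coeffs) -> float:
    """-sum p log2 p over the normalised energy distribution, by hand."""
    e = np.asarray(coeffs, dtype=float).ravel() ** 2
    total = e.sum()
    if total == 0:
        return 0.0
    p = e / total
    p = p[p > 0]  # after normalising: a ratio may underflow to exactly 0
    return float(-(p * np.log2(p)).sum())


def svm_dual_optimum(X, y_num, penalty) -> float:
    """Optimum of the soft-margin dual QP (equals the primal optimum by
    strong duality).  Two scipy solvers are tried and the best feasible
    solution kept, since either can stall on a degenerate instance."""
    X = np.asarray(X, dtype=float)
    y_num = np.asarray(y_num, dtype=float)
    Z = y_num[:, None] * X
    G = Z @ Z.T
    n = len(y_num)
    fun = lambda a: 0.5 * a @ G @ a - a.sum()
    jac = lambda a: G @ a - np.ones(n)
    best = None
    res = minimize(
        fun, np.full(n, min(penalty, 1e-3)), jac=jac,
        bounds=[(0.0, penalty)] * n,
        constraints=[{"type": "eq", "fun": lambda a: a @ y_num,
                      "jac": lambda a: y_num}],
        method="SLSQP", options={"maxiter": 1000, "ftol": 1e-14},
    )
    candidates = [res]
    res = minimize(
        fun, np.full(n, penalty / 2), jac=jac,
        bounds=[(0.0, penalty)] * n,
        constraints=[LinearConstraint(y_num, 0.0, 0.0)],
        method="trust-constr",
        options={"maxiter": 2000, "gtol": 1e-12, "xtol": 1e-14},
    )
    candidates.append(res)
    for res in candidates:
        if not res.success:
            continue
        a = np.clip(res.x, 0.0, penalty)
        if abs(a @ y_num) > 1e-8 * max(1.0, penalty):
            continue
        val = fun(a)
        if best is None or val < best:
            best = val
    assert best is not None, "no QP solver converged"
    return -float(best)


def gaussian_clusters(rng, centers, n_each, sd=0.15):
    """Well-separated labelled point clouds for classifier tests."""
    X, y = [], []
    for name, center in centers.items():
        X.append(rng.normal(loc=center, scale=sd, size=(n_each, len(center))))
        y += [name] * n_each
    return np.vstack(X), np.asarray(y)


# --------------------------------------------------------------------------
# fixtures

@pytest.fixture(scope="session")
def fb():
    return build_filter_bank("bior5.5")


@pytest.fixture()
def rng():
    return np.random.default_rng(20160106)
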