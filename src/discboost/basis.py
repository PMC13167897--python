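"""Reduced B-spline basis for time-varying coefficients.

A time-varying effect is written beta_j(t) = sum_{k=2..K} theta_jk B_k(t),
where B_1..B_K is the usual cubic B-spline basis on [t_1, t_S] and the first
function is dropped.  Because the full basis sums to one, dropping B_1 removes
the constant function from the span, so theta_j = 0 is exactly the
time-independent sub-model and phi_j is not aliased with the spline block.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import BSpline

from .data import TimeGrid


@dataclass(frozen=True)
class SplineBasis:
    K: int
    degree: int
    knots: np.ndarray          # full (padded) knot vector
    times: np.ndarray          # grid times the basis was built on
    Bmat: np.ndarray           # S x (K-1) reduced basis values

    @property
    def K1(self) -> int:
        """Number of reduced-basis columns, K - 1."""
        return self.K - 1

    def evaluate(self, t) -> np.ndarray:
        """Reduced basis values B_2(t)..B_K(t) at arbitrary times in [t_1, t_S]."""
        return _design(np.atleast_1d(np.asarray(t, float)), self.knots, self.degree)[:, 1:]

    def evaluate_full(self, t) -> np.ndarray:
        return _design(np.atleast_1d(np.asarray(t, float)), self.knots, self.degree)


def _design(x, knots, degree):
    x = np.clip(x, knots[0], knots[-1])
    return BSpline.design_matrix(x, knots, degree, extrapolate=False).toarray()


def build_reduced_basis(grid: TimeGrid, K: int = 7, degree: int = 3) -> SplineBasis:
    """Build the reduced (first-function-dropped) B-spline basis on a time grid.

    Interior knots are placed at equally spaced quantiles of the grid times;
    boundary knots sit at t_1 and t_S.  Requires K >= degree + 1 and S >= 2.
    """
    if K < degree + 1:
        raise ValueError(f"K={K} too small for degree-{degree} splines")
    if grid.S < 2:
        raise ValueError("need at least two distinct times to build a spline basis")
    t = grid.times
    n_interior = K - degree - 1
    qs = np.linspace(0, 1, n_interior + 2)[1:-1]
    interior = np.quantile(t, qs) if n_interior > 0 else np.empty(0)
    knots = np.concatenate([np.full(degree + 1, t[0]), interior,
                            np.full(degree + 1, t[-1])])
    full = _design(t, knots, degree)
    assert full.shape == (grid.S, K)
    return SplineBasis(K=K, degree=degree, knots=knots, times=t.copy(), Bmat=full[:, 1:])


def pspline_penalty_block(K1: int, order: int = 2) -> np.ndarray:
    """D'D with D the second-order difference operator on K-1 coefficients."""
    D = np.diff(np.eye(K1), n=order, axis=0)
    return D.T @ D


def smoothing_spline_penalty_block(basis: SplineBasis, n_quad: int = 401) -> np.ndarray:
    """Integrated squared second derivatives of the reduced basis functions.

    Omega_kl = int B_k''(t) B_l''(t) dt over [t_1, t_S], composite Simpson.
    """
    if n_quad % 2 == 0:
        n_quad += 1
    a, b = basis.times[0], basis.times[-1]
    x = np.linspace(a, b, n_quad)
    K = basis.K
    # second derivative of each full basis function, keep columns 2..K
    d2 = np.empty((n_quad, K))
    for k in range(K):
        c = np.zeros(K)
        c[k] = 1.0
        d2[:, k] = BSpline(basis.knots, c, basis.degree, extrapolate=False).derivative(2)(x)
    d2 = np.nan_to_num(d2[:, 1:])
    w = np.ones(n_quad)
    w[1:-1:2] = 4.0
    w[2:-1:2] = 2.0
    w *= (b - a) / (n_quad - 1) / 3.0
    return (d2 * w[:, None]).T @ d2
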