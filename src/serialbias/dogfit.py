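"""Deterministic least-squares fitting of the DoG bias curve.

This is the non-Bayesian reference fitter: a coarse grid over the width
parameter ``w`` (the only nonlinear parameter) with closed-form linear
least squares for ``(alpha, beta)`` at each grid node, followed by local
bounded refinement. It is deterministic given its inputs and serves as an
independent oracle for the hierarchical Bayesian back-end.
"""

from __future__ import annotations

import numpy as np
from scipy import optimize
from sklearn.base import BaseEstimator, RegressorMixin

from .circular import DOG_NORM, DoGParams, dog

__all__ = ["DoGCurveFit", "fit_dog_leastsquares"]


def _kernel(x, w):
    """Unit-amplitude DoG shape k(x; w) with peak value 1 at x = 1/(w*sqrt(2))."""
    wx = w * x
    return wx * DOG_NORM * np.exp(-(wx**2))


def _linear_ls(x, y, w):
    """Closed-form (alpha, beta, sse) minimizing sum (y - alpha*k - beta)^2."""
    k = _kernel(x, w)
    design = np.column_stack([k, np.ones_like(k)])
    coef, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    return coef[0], coef[1], float(resid @ resid)


class DoGCurveFit(RegressorMixin, BaseEstimator):
    """Least-squares DoG regression of bias values on relative colors.

    Parameters
    ----------
    w_bounds : (float, float)
        Admissible range for the width parameter, 1/degrees. The lower
        bound keeps the curve's peak inside the plotted range; the upper
        bound keeps it wider than a single condition bin.
    n_grid : int
        Number of log-spaced grid nodes over ``w_bounds`` for the coarse
        search stage.

    Attributes
    ----------
    alpha_, w_, beta_ : float
        Fitted DoG parameters (degrees, 1/degrees, degrees).
    params_ : DoGParams
    sse_ : float
        Residual sum of squares at the optimum.
    """

    def __init__(self, w_bounds=(0.002, 0.2), n_grid: int = 200):
        self.w_bounds = w_bounds
        self.n_grid = n_grid

    def fit(self, X, y):
        x = np.asarray(X, dtype=float).reshape(-1)
        y = np.asarray(y, dtype=float).reshape(-1)
        if x.shape != y.shape:
            raise ValueError("X and y must have matching lengths")
        if x.size < 4:
            raise ValueError(f"need at least 4 (x, y) pairs, got {x.size}")
        if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
            raise ValueError("inputs must be finite")
        if np.ptp(x) == 0:
            raise ValueError("degenerate design: all x values are equal")
        if np.all(x == 0):
            raise ValueError("degenerate design: all x values are zero")
        lo, hi = self.w_bounds
        if not (0 < lo < hi):
            raise ValueError(f"invalid w_bounds {self.w_bounds}")

        grid = np.geomspace(lo, hi, self.n_grid)
        sses = np.array([_linear_ls(x, y, w)[2] for w in grid])
        best = int(np.argmin(sses))

        # (alpha, beta) are profiled out exactly, so only the width needs
        # nonlinear refinement: bounded scalar minimization between the
        # grid neighbours of the best node
        def profile_sse(w):
            return _linear_ls(x, y, w)[2]

        w_lo = grid[max(best - 1, 0)]
        w_hi = grid[min(best + 1, grid.size - 1)]
        res = optimize.minimize_scalar(
            profile_sse, bounds=(w_lo, w_hi), method="bounded",
            options={"xatol": 1e-12},
        )
        w_best = float(res.x) if res.fun <= sses[best] else float(grid[best])
        a, b, sse = _linear_ls(x, y, w_best)
        self.alpha_ = float(a)
        self.w_ = w_best
        self.beta_ = float(b)
        self.sse_ = sse
        self.params_ = DoGParams(self.alpha_, self.w_, self.beta_)
        self.n_features_in_ = 1
        return self

    def predict(self, X):
        x = np.asarray(X, dtype=float).reshape(-1)
        return dog(x, self.alpha_, self.w_, self.beta_)


def fit_dog_leastsquares(xs, ys, w_bounds=(0.002, 0.2), n_grid: int = 200):
    """Fit the DoG curve by grid-plus-refine least squares.

    Returns ``(params, sse)`` where ``params`` is a :class:`DoGParams`.
    Deterministic given inputs and grid specification.
    """
    est = DoGCurveFit(w_bounds=w_bounds, n_grid=n_grid).fit(xs, ys)
    return est.params_, est.sse_
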