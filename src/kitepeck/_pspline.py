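"""Penalized B-spline (P-spline) machinery.

B-spline bases on equally spaced knots combined with difference penalties on
adjacent coefficients; tensor-product smooths are built as row-wise Kronecker
products of marginal bases with an additive Kronecker penalty.  Gaussian fits
are penalized least squares with the smoothing parameter chosen by GCV on a
log-spaced grid.  This is the standard penalized-likelihood counterpart of a
Bayesian smoothing prior: point predictions agree, and interval estimates are
delegated to the pipeline's bootstrap.
"""

from __future__ import annotations

import numpy as np
from scipy.interpolate import BSpline


class BSplineBasis:
    """Clamped B-spline basis of ``df`` functions on [lo, hi].

    Evaluation clips inputs to the fitted range, so prediction slightly
    outside the observed covariate range degrades gracefully to the boundary
    value instead of raising.
    """

    def __init__(self, lo: float, hi: float, df: int = 5, degree: int = 3):
        if df < degree + 1:
            raise ValueError(f"df must be >= degree+1 ({degree + 1}), got {df}")
        if not hi > lo:
            # degenerate covariate: widen artificially so the basis exists
            hi = lo + 1.0
        n_interior = df - degree - 1
        interior = np.linspace(lo, hi, n_interior + 2)[1:-1]
        self.knots = np.concatenate(
            [np.repeat(lo, degree + 1), interior, np.repeat(hi, degree + 1)]
        )
        self.lo, self.hi, self.df, self.degree = float(lo), float(hi), df, degree

    def design(self, x) -> np.ndarray:
        x = np.clip(np.asarray(x, dtype=float), self.lo, self.hi)
        # nudge the right endpoint inside so the last basis function is hit
        x = np.minimum(x, np.nextafter(self.hi, self.lo))
        return BSpline.design_matrix(x, self.knots, self.degree).toarray()

    def penalty(self, order: int = 2) -> np.ndarray:
        """Difference penalty D'D of the given order on the coefficients."""
        d = np.diff(np.eye(self.df), n=min(order, self.df - 1), axis=0)
        return d.T @ d


def row_kron(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Row-wise Kronecker (face-splitting) product of two design matrices."""
    return (a[:, :, None] * b[:, None, :]).reshape(a.shape[0], -1)


def tensor_penalty(p1: np.ndarray, p2: np.ndarray) -> np.ndarray:
    """Isotropic tensor-product penalty P1 (x) I + I (x) P2."""
    i1 = np.eye(p1.shape[0])
    i2 = np.eye(p2.shape[0])
    return np.kron(p1, i2) + np.kron(i1, p2)


def fit_penalized_ls(
    x: np.ndarray,
    y: np.ndarray,
    penalties: list[tuple[np.ndarray, slice]],
    lambda_grid: dict,
) -> dict:
    """Penalized least squares with GCV selection over a small grid.

    Parameters
    ----------
    x, y
        Design matrix and response.
    penalties
        ``(name, penalty_matrix, column_slice)`` blocks; each block's matrix
        is scaled by the grid value of the smoothing parameter it names.
        Several blocks may share a name (one lambda applied to each).
    lambda_grid
        ``{name: iterable of candidate lambdas}``.

    Returns
    -------
    dict with ``coef``, ``lambdas`` (chosen), ``gcv``, ``edf``.
    """
    n, p = x.shape
    xtx = x.T @ x
    xty = x.T @ y
    # tiny ridge keeps unpenalized null spaces (constant/linear) invertible
    eps = 1e-7 * (np.trace(xtx) / p + 1.0)

    names = list(lambda_grid)
    grids = [np.asarray(lambda_grid[name], dtype=float) for name in names]
    best = None
    for combo in np.stack(
        np.meshgrid(*grids, indexing="ij"), axis=-1
    ).reshape(-1, len(grids)):
        lam_of = dict(zip(names, combo))
        s = eps * np.eye(p)
        for name, pen, sl in penalties:
            s[sl, sl] += lam_of[name] * pen
        try:
            coef = np.linalg.solve(xtx + s, xty)
            hat_trace = np.trace(np.linalg.solve(xtx + s, xtx))
        except np.linalg.LinAlgError:
            continue
        resid = y - x @ coef
        rss = float(resid @ resid)
        denom = max(n - hat_trace, 1e-8)
        gcv = n * rss / denom**2
        if best is None or gcv < best["gcv"]:
            best = {
                "coef": coef,
                "lambdas": lam_of,
                "gcv": gcv,
                "edf": float(hat_trace),
            }
    if best is None:
        raise np.linalg.LinAlgError("all candidate penalized systems singular")
    return best
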