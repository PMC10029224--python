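"""Low-rank thin-plate regression spline bases and monotonic ordinal effects.

The 1-D thin-plate construction: the radial kernel eta(r) = |r|^3 is evaluated
between knot values (the unique covariate values, thinned to at most
``max_knots`` quantile knots), the kernel is restricted to the space
orthogonal to the polynomial null space {1, x}, eigen-decomposed, and the
leading ``k - 2`` eigenvectors are retained as penalized basis functions whose
wiggliness penalty is the identity after rescaling.  The null-space linear
column is kept unpenalized; the constant is absorbed by the model intercept.

Monotonic ordinal effects follow the signed-scale x cumulative-simplex
construction: an ordinal predictor at level x contributes b * sum_{i<=x} zeta_i,
with zeta a simplex over the level gaps, so the effect is monotone in the
level for every admissible (b, zeta).
"""

from __future__ import annotations

import logging

import numpy as np

logger = logging.getLogger(__name__)

MAX_KNOTS = 200


def monotonic_effect(level, b: float, zeta) -> float:
    """Effect of an ordinal predictor at ``level``: b * cumsum(zeta)[:level].

    ``zeta`` has one entry per gap between adjacent levels (L - 1 entries for
    L levels) and must lie on the simplex; the level-0 effect is 0 and the
    top-level effect is b.
    """
    zeta = np.asarray(zeta, dtype=float)
    if np.any(zeta < 0) or abs(zeta.sum() - 1.0) > 1e-8:
        raise ValueError("zeta must be non-negative and sum to 1")
    lev = np.asarray(level)
    if np.any((lev < 0) | (lev > len(zeta))):
        raise ValueError(f"level must lie in 0..{len(zeta)}")
    cum = np.concatenate([[0.0], np.cumsum(zeta)])
    out = b * cum[lev]
    return float(out) if out.ndim == 0 else out


class ThinPlateSplineBasis:
    """Low-rank 1-D thin-plate regression spline basis.

    Attributes (after construction)
    -------------------------------
    knots_ : ndarray
        Knot locations in the covariate's original units.
    linear_ : ndarray
        The unpenalized null-space column evaluated at the training points.
    penalized_ : ndarray
        The ``k - 2`` penalized columns at the training points, residualized
        against [1, x] so they are exactly orthogonal to the linear column.
    """

    def __init__(self, x, k: int = 10, max_knots: int = MAX_KNOTS):
        x = np.asarray(x, dtype=float)
        if np.any(~np.isfinite(x)):
            raise ValueError("covariate contains non-finite values")
        uniq = np.unique(x)
        if k < 3:
            raise ValueError("basis size k must be at least 3")
        if len(uniq) < k:
            raise ValueError(
                f"thin-plate basis needs at least k={k} distinct covariate values, got {len(uniq)}")
        if len(uniq) > max_knots:
            knots = np.unique(np.quantile(uniq, np.linspace(0, 1, max_knots)))
        else:
            knots = uniq
        self.k = int(k)
        self.knots_ = knots
        self.xmin_, self.xmax_ = float(x.min()), float(x.max())

        # kernel restricted to the complement of the null space span{1, x}
        E = self._kernel(knots, knots)
        T = np.column_stack([np.ones_like(knots), knots])
        q, _ = np.linalg.qr(T, mode="complete")
        Z = q[:, 2:]  # null space of T'
        M = Z.T @ E @ Z
        M = 0.5 * (M + M.T)
        evals, evecs = np.linalg.eigh(M)
        order = np.argsort(np.abs(evals))[::-1][: self.k - 2]
        lam = evals[order]
        # delta = Z V lam^{-1/2} w gives identity penalty on w
        self._delta_map = Z @ evecs[:, order] / np.sqrt(np.abs(lam))[None, :]

        raw = self._kernel(x, knots) @ self._delta_map
        # residualize against [1, x]; store the projection for reuse at prediction
        D = np.column_stack([np.ones_like(x), x])
        self._proj, *_ = np.linalg.lstsq(D, raw, rcond=None)
        self.linear_ = x.copy()
        self.penalized_ = raw - D @ self._proj

    @staticmethod
    def _kernel(a, b):
        return np.abs(a[:, None] - b[None, :]) ** 3

    @property
    def n_columns(self) -> int:
        """Total design columns contributed (linear + penalized) = k - 1."""
        return self.k - 1

    def evaluate(self, x) -> tuple[np.ndarray, np.ndarray]:
        """Basis at new points: (linear column, penalized columns).

        Points outside the training range are evaluated by linear
        extrapolation of each basis function from the nearer boundary.
        """
        x = np.asarray(x, dtype=float)
        lo, hi = x < self.xmin_, x > self.xmax_
        if lo.any() or hi.any():
            logger.warning(
                "%d covariate value(s) outside the spline's training range "
                "[%.4g, %.4g]; using linear extrapolation of the basis",
                int(lo.sum() + hi.sum()), self.xmin_, self.xmax_)
        xc = np.clip(x, self.xmin_, self.xmax_)
        pen = self._eval_inner(xc)
        if lo.any() or hi.any():
            h = 1e-6 * max(self.xmax_ - self.xmin_, 1.0)
            for mask, x0, sgn in ((lo, self.xmin_, 1.0), (hi, self.xmax_, -1.0)):
                if mask.any():
                    slope = sgn * (self._eval_inner(np.array([x0 + sgn * h]))
                                   - self._eval_inner(np.array([x0]))) / h
                    pen[mask] = self._eval_inner(np.array([x0])) + np.outer(x[mask] - x0, slope[0])
        return x.copy(), pen

    def _eval_inner(self, x):
        raw = self._kernel(x, self.knots_) @ self._delta_map
        D = np.column_stack([np.ones_like(x), x])
        return raw - D @ self._proj
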