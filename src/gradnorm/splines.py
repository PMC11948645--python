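"""Penalized B-spline (P-spline) building blocks.

Cubic B-spline design matrices on an observed covariate range with a
second-order difference penalty on the coefficients — the standard
Eilers-Marx construction used for the smooth age terms of the normative
models. Basis columns are mean-centered on the training sample so that the
smooth is identifiable next to an explicit intercept (the difference-penalty
null space contains the constant).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import BSpline


@dataclass(frozen=True)
class SplineBasis:
    """Frozen B-spline basis bound to a training covariate range."""

    lo: float
    hi: float
    n_knots: int = 10  # interior knots, equally spaced
    degree: int = 3
    penalty_order: int = 2
    column_means: np.ndarray | None = field(default=None, repr=False)

    @property
    def n_basis(self) -> int:
        return self.n_knots + self.degree + 1

    def _knots(self) -> np.ndarray:
        interior = np.linspace(self.lo, self.hi, self.n_knots + 2)[1:-1]
        return np.concatenate(
            [
                np.full(self.degree + 1, self.lo),
                interior,
                np.full(self.degree + 1, self.hi),
            ]
        )

    def design(self, x, center: bool = True) -> np.ndarray:
        """Evaluate the basis at ``x`` (clamped to the training range).

        Values outside [lo, hi] are evaluated at the nearest boundary
        (constant extrapolation); callers are expected to flag
        extrapolation to the user.
        """
        x = np.clip(np.asarray(x, dtype=float), self.lo, self.hi)
        B = BSpline.design_matrix(x, self._knots(), self.degree, extrapolate=False)
        B = np.asarray(B.todense())
        if center:
            if self.column_means is None:
                raise ValueError("basis not centered yet; call fit_centering first")
            B = B - self.column_means
        return B

    def fit_centering(self, x) -> "SplineBasis":
        """Return a copy whose columns are centered on the sample ``x``."""
        B = self.design(x, center=False)
        return SplineBasis(
            lo=self.lo,
            hi=self.hi,
            n_knots=self.n_knots,
            degree=self.degree,
            penalty_order=self.penalty_order,
            column_means=B.mean(axis=0),
        )

    def penalty(self) -> np.ndarray:
        """D'D for the configured difference order."""
        D = np.diff(np.eye(self.n_basis), n=self.penalty_order, axis=0)
        return D.T @ D


def basis_for(x, n_knots: int = 10, degree: int = 3, penalty_order: int = 2) -> SplineBasis:
    """Construct and center a basis on the observed range of ``x``."""
    x = np.asarray(x, dtype=float)
    lo, hi = float(np.min(x)), float(np.max(x))
    if hi <= lo:
        raise ValueError("covariate is constant; cannot build a spline basis")
    return SplineBasis(lo=lo, hi=hi, n_knots=n_knots, degree=degree,
                       penalty_order=penalty_order).fit_centering(x)
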