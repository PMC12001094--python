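"""Cubic B-spline bases on the dose axis.

The nonlinear candidate models expand dose through a degree-d B-spline
basis with K interior knots, giving K + d + 1 basis functions that form a
partition of unity on [min dose, max dose]. By default the interior knots
sit at the unique (transformed) dose values excluding the two boundary
doses, so knot placement follows the concentration design; knots can also
be supplied manually.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import BSpline

__all__ = ["SplineBasis", "build_spline_basis", "linear_basis", "MIN_SPLINE_DOSES"]

# Cubic splines want at least this many distinct dose levels.
MIN_SPLINE_DOSES = 4


@dataclass(frozen=True)
class SplineBasis:
    """A B-spline basis over the dose range.

    ``degree`` is the polynomial degree d (3 for cubic), ``knots`` the
    interior knots, ``boundary`` the closed dose interval. ``n_basis`` =
    K + d + 1 with K = number of interior knots. The special case
    ``degree=1, knots=()`` with ``identity=True`` is the single linear
    basis function N(D) = D used to embed the linear model in the spline
    machinery.
    """

    degree: int
    knots: tuple[float, ...]
    boundary: tuple[float, float]
    identity: bool = False

    def __post_init__(self) -> None:
        lo, hi = self.boundary
        if not lo < hi:
            raise ValueError("boundary must be an increasing interval")
        k = np.asarray(self.knots, dtype=float)
        if k.size and (np.any(k <= lo) or np.any(k >= hi)):
            raise ValueError("interior knots must lie strictly inside the boundary")
        if k.size and np.any(np.diff(k) <= 0):
            raise ValueError("interior knots must be strictly increasing")

    @property
    def n_basis(self) -> int:
        if self.identity:
            return 1
        return len(self.knots) + self.degree + 1

    @property
    def full_knots(self) -> np.ndarray:
        lo, hi = self.boundary
        return np.concatenate(
            [
                np.repeat(lo, self.degree + 1),
                np.asarray(self.knots, dtype=float),
                np.repeat(hi, self.degree + 1),
            ]
        )

    def design(self, doses: np.ndarray) -> np.ndarray:
        """Evaluate all basis functions at `doses` -> (n, n_basis) matrix.

        Doses are clipped to the boundary, so evaluation at the endpoints
        (and tiny numerical overshoots) is well defined.
        """
        x = np.clip(np.asarray(doses, dtype=float), *self.boundary)
        if self.identity:
            return x[:, None]
        dm = BSpline.design_matrix(x, self.full_knots, self.degree)
        return np.asarray(dm.todense())

    def penalty_matrix(self) -> np.ndarray:
        """Gram matrix of second derivatives, P_ij = int B_i'' B_j'' dx.

        Used to pick the minimum-curvature representative when the basis is
        richer than the dose design identifies (the fitted values at the
        observed doses are untouched; only the between-dose behavior of the
        curve is resolved).
        """
        if self.identity:
            return np.zeros((1, 1))
        nb = self.n_basis
        t = self.full_knots
        # second derivatives are piecewise linear: 2-point Gauss is exact
        # for their pairwise products on each knot span
        breaks = np.unique(t)
        gauss_x = np.array([-1.0, 1.0]) / np.sqrt(3.0)
        P = np.zeros((nb, nb))
        d2 = [
            BSpline(t, np.eye(nb)[i], self.degree, extrapolate=False).derivative(2)
            for i in range(nb)
        ]
        for a, b in zip(breaks[:-1], breaks[1:]):
            if b <= a:
                continue
            half = (b - a) / 2.0
            xs = (a + b) / 2.0 + half * gauss_x
            vals = np.array([f(xs) for f in d2])  # (nb, 2)
            P += half * vals @ vals.T
        return P

    def spline(self, coefficients: np.ndarray) -> BSpline:
        """The BSpline curve with the given basis coefficients (for analytic
        derivatives)."""
        if self.identity:
            # A straight line as a degree-1 B-spline so derivative machinery
            # applies uniformly.
            lo, hi = self.boundary
            c = np.array([coefficients[0] * lo, coefficients[0] * hi])
            t = np.array([lo, lo, hi, hi], dtype=float)
            return BSpline(t, c, 1, extrapolate=False)
        return BSpline(self.full_knots, np.asarray(coefficients, float), self.degree,
                       extrapolate=False)


def build_spline_basis(
    doses: np.ndarray,
    degree: int = 3,
    manual_knots: np.ndarray | None = None,
) -> SplineBasis:
    """Build the cubic-spline basis for a dose design.

    Default interior knots are the unique dose values with the two boundary
    doses removed; with 8 distinct doses and d=3 this yields K=6 interior
    knots and 10 basis functions. Requires >= 4 distinct dose levels.
    """
    levels = np.unique(np.asarray(doses, dtype=float))
    if levels.size < MIN_SPLINE_DOSES:
        raise ValueError(
            f"cubic splines need >= {MIN_SPLINE_DOSES} distinct dose levels, "
            f"got {levels.size}"
        )
    lo, hi = float(levels[0]), float(levels[-1])
    if manual_knots is not None:
        knots = np.sort(np.asarray(manual_knots, dtype=float))
        if knots.size and (knots[0] <= lo or knots[-1] >= hi):
            raise ValueError("manual knots must lie strictly inside the dose range")
    else:
        knots = levels[1:-1]
    return SplineBasis(degree=degree, knots=tuple(knots), boundary=(lo, hi))


def linear_basis(doses: np.ndarray) -> SplineBasis:
    """The single-function linear basis N(D) = D.

    Embedding the linear model as a one-column 'spline' lets the nonlinear
    fitting path reproduce the linear mixed model exactly, which serves as
    an internal consistency oracle.
    """
    levels = np.unique(np.asarray(doses, dtype=float))
    return SplineBasis(
        degree=1, knots=(), boundary=(float(levels[0]), float(levels[-1])),
        identity=True,
    )
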