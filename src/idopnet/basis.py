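"""B-spline bases and the quadrature used to integrate qdODE components.

Two kinds of basis are used.  A basis over the EI axis smooths each gene's
observed expression into a continuous curve M(E).  A basis over a gene's
expression range represents the rate functions g(M): because a B-spline is
linear in its coefficients, the integrated contribution
G(E) = int_{E_1}^{E} g(M(u)) du is linear in the same coefficients, which
turns the qdODE fit into (penalized) linear regression on integrated basis
columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import BSpline

from .expression import ExpressionIndex

__all__ = ["SplineBasis", "build_basis", "rk4_solve", "cumulative_integrals", "SmoothCurve"]


@dataclass
class SplineBasis:
    """B-spline basis of a given degree on [lo, hi] with interior knots.

    Basis functions are non-negative and sum to one at every point of the
    interval (partition of unity); evaluation clamps to the boundary so
    that mildly out-of-range arguments stay finite.
    """

    degree: int
    interior_knots: np.ndarray
    boundary: tuple[float, float]
    knots: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        lo, hi = self.boundary
        if not hi > lo:
            raise ValueError("degenerate basis interval")
        self.interior_knots = np.asarray(self.interior_knots, dtype=float)
        k = self.degree
        self.knots = np.concatenate(
            [[lo] * (k + 1), self.interior_knots, [hi] * (k + 1)]
        )

    @property
    def n_basis(self) -> int:
        return self.degree + 1 + len(self.interior_knots)

    @classmethod
    def from_quantiles(cls, values: np.ndarray, degree: int = 3, n_interior: int = 0):
        """Knots at quantiles of the observed values (boundary = data range)."""
        values = np.asarray(values, dtype=float)
        if len(np.unique(values)) <= degree + n_interior:
            raise ValueError(
                f"need more than {degree + n_interior} distinct points for "
                f"degree {degree} with {n_interior} interior knots"
            )
        lo, hi = float(values.min()), float(values.max())
        qs = np.linspace(0, 1, n_interior + 2)[1:-1]
        interior = np.quantile(values, qs) if n_interior else np.empty(0)
        return cls(degree=degree, interior_knots=interior, boundary=(lo, hi))

    def design(self, x: np.ndarray) -> np.ndarray:
        """Evaluation matrix (len(x), n_basis); arguments clamped to [lo, hi]."""
        lo, hi = self.boundary
        xc = np.clip(np.asarray(x, dtype=float), lo, hi)
        return BSpline.design_matrix(xc, self.knots, self.degree).toarray()

    def condition_number(self, x: np.ndarray) -> float:
        return float(np.linalg.cond(self.design(x)))


def build_basis(e: ExpressionIndex, degree: int = 3, n_interior: int = 0) -> SplineBasis:
    """Basis over the EI axis with interior knots at EI quantiles."""
    n = len(e.ei)
    if n <= degree + n_interior:
        raise ValueError(
            f"N={n} samples cannot support degree {degree} with "
            f"{n_interior} interior knots (need N > {degree + n_interior})"
        )
    return SplineBasis.from_quantiles(e.sorted_ei, degree=degree, n_interior=n_interior)


def rk4_solve(f, y0: np.ndarray, grid: np.ndarray, substeps: int = 1) -> np.ndarray:
    """Classical fourth-order Runge-Kutta solution of y' = f(E, y).

    Returns the state at every grid point, starting from ``y0`` at
    ``grid[0]``.  ``substeps`` refines each grid interval.
    """
    grid = np.asarray(grid, dtype=float)
    y = np.array(y0, dtype=float)
    out = np.empty((len(grid),) + y.shape)
    out[0] = y
    for i in range(len(grid) - 1):
        h = (grid[i + 1] - grid[i]) / substeps
        t = grid[i]
        for _ in range(substeps):
            k1 = f(t, y)
            k2 = f(t + h / 2, y + h / 2 * k1)
            k3 = f(t + h / 2, y + h / 2 * k2)
            k4 = f(t + h, y + h * k3)
            y = y + h / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
            t += h
        out[i + 1] = y
    return out


class SmoothCurve:
    """A gene's expression smoothed over EI by least-squares B-splines."""

    def __init__(self, basis: SplineBasis, e_sorted: np.ndarray, y_sorted: np.ndarray):
        X = basis.design(e_sorted)
        coef, *_ = np.linalg.lstsq(X, np.asarray(y_sorted, dtype=float), rcond=None)
        self._spline = BSpline(basis.knots, coef, basis.degree, extrapolate=False)
        self.basis = basis
        self.coef = coef

    def __call__(self, e: np.ndarray) -> np.ndarray:
        lo, hi = self.basis.boundary
        return self._spline(np.clip(e, lo, hi))


def cumulative_integrals(
    basis: SplineBasis,
    curve,
    e_from: float,
    e_points: np.ndarray,
    substeps: int = 4,
) -> np.ndarray:
    """Columns C[i, k] = int_{e_from}^{e_points[i]} B_k(curve(u)) du.

    ``e_points`` must be non-decreasing with e_points[0] >= e_from.  The
    quadrature is fourth-order (RK4 applied to the state-free rate reduces
    to composite Simpson), with ``substeps`` panels per interval.
    """
    e_points = np.asarray(e_points, dtype=float)
    edges = np.concatenate([[e_from], e_points])
    out = np.zeros((len(e_points), basis.n_basis))
    acc = np.zeros(basis.n_basis)
    for i in range(len(e_points)):
        a, b = edges[i], edges[i + 1]
        if b > a:
            fine = np.linspace(a, b, 2 * substeps + 1)
            vals = basis.design(curve(fine))  # (2s+1, nb)
            h = (b - a) / substeps
            # composite Simpson over the panels
            acc = acc + h / 6 * (
                vals[0:-1:2].sum(axis=0)
                + 4 * vals[1::2].sum(axis=0)
                + vals[2::2].sum(axis=0)
            )
        out[i] = acc
    return out
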