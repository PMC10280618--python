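"""Unit-energy normalisation and cubic-polynomial smoothing under three
error criteria.

Either the reference glucose values or the feature columns of a training
table are replaced by fitted values of a cubic polynomial whose
coefficients minimise one of

* J2 -- the residual energy (ordinary least squares, closed form),
* J1 -- the sum of absolute residuals (a linear program with one slack
  per point), or
* Jinf -- the maximum absolute residual (a linear program with a single
  scalar slack; the Chebyshev criterion).

Both linear programs are solved with :func:`scipy.optimize.linprog`
(HiGHS).  Fits are performed on an abscissa rescaled to [-1, 1] for
conditioning -- unit-energy feature values are tiny and their cubes
underflow the normal equations -- and the coefficients are mapped back to
the original coordinates exactly by polynomial composition.

Smoothing is a training-set operation: test columns are scaled by the
training gains but never smoothed, because smoothing requires the
reference glucose.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import linprog

from .errors import SolverError

__all__ = [
    "CRITERIA",
    "NormalisedColumn",
    "PolynomialFit",
    "unit_energy_normalize",
    "design_matrix",
    "fit_poly",
    "fit_poly_l2",
    "fit_poly_l1",
    "fit_poly_linf",
    "objective",
    "smooth_reference",
    "smooth_features",
]

CRITERIA = ("l1", "l2", "linf")
_ORDER = 3  # cubic


@dataclass
class NormalisedColumn:
    """A feature column scaled to unit energy, with its gain.

    ``gain`` = 1 / sqrt(sum(raw^2)); ``values`` = gain * raw, so
    sum(values^2) = 1 unless the raw column was all zero (gain 1,
    column passed through with a warning).
    """

    gain: float
    values: np.ndarray


@dataclass
class PolynomialFit:
    """A fitted cubic: coefficients a0..a3 in the original coordinates,
    the criterion used, the achieved objective and the fitted values."""

    a: np.ndarray
    criterion: str
    objective: float
    fitted: np.ndarray


def unit_energy_normalize(column) -> NormalisedColumn:
    """Scale a column to unit energy; the gain is reused on test data."""
    x = np.asarray(column, dtype=float)
    if x.size == 0:
        raise ValueError("column must be non-empty")
    if not np.all(np.isfinite(x)):
        raise ValueError("column must be finite")
    energy = float(x @ x)
    if energy == 0.0:
        warnings.warn("all-zero column: unit-energy gain set to 1", stacklevel=2)
        return NormalisedColumn(gain=1.0, values=x.copy())
    gain = 1.0 / np.sqrt(energy)
    return NormalisedColumn(gain=gain, values=gain * x)


def design_matrix(x) -> np.ndarray:
    """N x 4 cubic Vandermonde matrix with rows [1, x, x^2, x^3]."""
    x = np.asarray(x, dtype=float)
    return np.vander(x, _ORDER + 1, increasing=True)


def objective(criterion: str, residuals) -> float:
    """Evaluate J1 / J2 / Jinf on a residual vector."""
    r = np.asarray(residuals, dtype=float)
    if criterion == "l1":
        return float(np.sum(np.abs(r)))
    if criterion == "l2":
        return float(r @ r)
    if criterion == "linf":
        return float(np.max(np.abs(r))) if r.size else 0.0
    raise ValueError(f"unknown criterion {criterion!r}")


def _rescale(x: np.ndarray):
    """Map x affinely onto [-1, 1]; returns (u, compose) where compose maps
    coefficients in u back to coefficients in x."""
    lo, hi = float(np.min(x)), float(np.max(x))
    alpha = 2.0 / (hi - lo)
    beta = -(hi + lo) / (hi - lo)
    u = alpha * x + beta

    def compose(a_u: np.ndarray) -> np.ndarray:
        p = np.polynomial.Polynomial(a_u)
        q = p(np.polynomial.Polynomial([beta, alpha]))
        coef = np.zeros(_ORDER + 1)
        coef[: q.coef.size] = q.coef
        return coef

    return u, compose


def _degenerate_fit(x: np.ndarray, y: np.ndarray, criterion: str) -> PolynomialFit:
    """All abscissa values identical: the optimal cubic is the optimal
    constant (mean / median / midrange for L2 / L1 / Linf)."""
    warnings.warn("degenerate abscissa (all values identical); fitting a constant", stacklevel=3)
    if criterion == "l2":
        c = float(np.mean(y))
    elif criterion == "l1":
        c = float(np.median(y))
    else:
        c = float((np.max(y) + np.min(y)) / 2.0)
    fitted = np.full_like(y, c)
    return PolynomialFit(
        a=np.array([c, 0.0, 0.0, 0.0]),
        criterion=criterion,
        objective=objective(criterion, fitted - y),
        fitted=fitted,
    )


def _check(x: np.ndarray, y: np.ndarray) -> None:
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < _ORDER + 1:
        raise ValueError(f"need at least {_ORDER + 1} points for a cubic fit")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")


def fit_poly_l2(x, y) -> PolynomialFit:
    """Least-squares cubic: the normal-equation solution (via a rank-aware
    least-squares solve; rank-deficient designs fall back to the
    minimum-norm solution with a warning)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    _check(x, y)
    if np.min(x) == np.max(x):
        return _degenerate_fit(x, y, "l2")
    u, compose = _rescale(x)
    Xu = design_matrix(u)
    a_u, _, rank, _ = np.linalg.lstsq(Xu, y, rcond=None)
    if rank < _ORDER + 1:
        warnings.warn("rank-deficient design matrix; minimum-norm least-squares solution", stacklevel=2)
    fitted = Xu @ a_u
    return PolynomialFit(
        a=compose(a_u), criterion="l2", objective=objective("l2", fitted - y), fitted=fitted
    )


def _fit_lp(x: np.ndarray, y: np.ndarray, criterion: str) -> PolynomialFit:
    n = x.size
    u, compose = _rescale(x)
    Xu = design_matrix(u)
    if criterion == "l1":
        # variables (a0..a3, z1..zN); minimise sum z s.t. |Xa - y| <= z
        c = np.concatenate([np.zeros(_ORDER + 1), np.ones(n)])
        A = np.block([[Xu, -np.eye(n)], [-Xu, -np.eye(n)]])
        bounds = [(None, None)] * (_ORDER + 1) + [(0, None)] * n
    else:  # linf: variables (a0..a3, eps); minimise eps s.t. |Xa - y| <= eps
        c = np.concatenate([np.zeros(_ORDER + 1), [1.0]])
        ones = np.ones((n, 1))
        A = np.block([[Xu, -ones], [-Xu, -ones]])
        bounds = [(None, None)] * (_ORDER + 1) + [(0, None)]
    b = np.concatenate([y, -y])
    res = linprog(c, A_ub=A, b_ub=b, bounds=bounds, method="highs")
    if not res.success:
        raise SolverError(f"{criterion} linear program failed: {res.status} {res.message}")
    a_u = res.x[: _ORDER + 1]
    fitted = Xu @ a_u
    return PolynomialFit(
        a=compose(a_u),
        criterion=criterion,
        objective=objective(criterion, fitted - y),
        fitted=fitted,
    )


def fit_poly_l1(x, y) -> PolynomialFit:
    """Least-absolute-residual cubic via the standard slack-variable LP."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    _check(x, y)
    if np.min(x) == np.max(x):
        return _degenerate_fit(x, y, "l1")
    return _fit_lp(x, y, "l1")


def fit_poly_linf(x, y) -> PolynomialFit:
    """Minimax (Chebyshev) cubic via the scalar-slack LP."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    _check(x, y)
    if np.min(x) == np.max(x):
        return _degenerate_fit(x, y, "linf")
    return _fit_lp(x, y, "linf")


_FITTERS = {"l1": fit_poly_l1, "l2": fit_poly_l2, "linf": fit_poly_linf}


def fit_poly(x, y, criterion: str) -> PolynomialFit:
    """Dispatch to the cubic fit for ``criterion`` in {'l1','l2','linf'}."""
    try:
        fitter = _FITTERS[criterion]
    except KeyError:
        raise ValueError(f"unknown criterion {criterion!r}; expected one of {CRITERIA}") from None
    return fitter(x, y)


def _sort_by_glucose(glucose: np.ndarray) -> np.ndarray:
    return np.argsort(glucose, kind="stable")


def smooth_reference(features, glucose, criterion: str) -> np.ndarray:
    """Smooth the reference glucose through every feature column.

    Rows are sorted by ascending glucose (stable).  For each feature
    column, a cubic of glucose on that column is fitted under
    ``criterion`` and its fitted vector recorded; the element-wise mean of
    the per-feature fitted vectors, unsorted back to the original row
    order, is the smoothed reference.  Each column's fit uses the original
    glucose (parallel, not chained, so the result does not depend on
    column order).  A column whose fit fails is skipped with a warning.
    """
    F = np.asarray(features, dtype=float)
    g = np.asarray(glucose, dtype=float)
    if F.ndim != 2 or F.shape[0] != g.size:
        raise ValueError("features must be N x F with N matching glucose")
    order = _sort_by_glucose(g)
    g_sorted = g[order]
    fitted_vectors = []
    for j in range(F.shape[1]):
        x = F[order, j]
        try:
            fit = fit_poly(x, g_sorted, criterion)
        except (SolverError, ValueError) as exc:
            warnings.warn(f"reference smoothing skipped feature column {j}: {exc}", stacklevel=2)
            continue
        fitted_vectors.append(fit.fitted)
    if not fitted_vectors:
        raise SolverError("reference smoothing failed on every feature column")
    smoothed_sorted = np.mean(fitted_vectors, axis=0)
    out = np.empty_like(g)
    out[order] = smoothed_sorted
    return out


def smooth_features(features, glucose, criterion: str) -> np.ndarray:
    """Replace each feature column by its cubic-in-glucose fitted values.

    Rows sorted by ascending glucose (stable, shared across columns); each
    column fitted independently against glucose under ``criterion``; a
    failed column is left unsmoothed with a warning.  Output rows are
    returned in the original order.
    """
    F = np.asarray(features, dtype=float)
    g = np.asarray(glucose, dtype=float)
    if F.ndim != 2 or F.shape[0] != g.size:
        raise ValueError("features must be N x F with N matching glucose")
    order = _sort_by_glucose(g)
    g_sorted = g[order]
    out = F.copy()
    for j in range(F.shape[1]):
        y = F[order, j]
        try:
            fit = fit_poly(g_sorted, y, criterion)
        except (SolverError, ValueError) as exc:
            warnings.warn(f"feature smoothing left column {j} unsmoothed: {exc}", stacklevel=2)
            continue
        out[order, j] = fit.fitted
    return out
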