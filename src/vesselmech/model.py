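"""Arctangent (Langewouters) pressure-area model of the arterial lumen.

The cross-sectional lumen area of a pressurised artery follows a sigmoidal
pressure-area relation

    A(P) = Am * (1/2 + (1/pi) * arctan((P - P0) / P1))

with three parameters: ``Am`` the asymptotic maximal area (mm^2), ``P0`` the
pressure at which compliance is maximal (mmHg) and ``P1`` the half-width
pressure at which compliance has fallen to half its maximum (mmHg).

Differentiating gives the area compliance (a Lorentzian in pressure)

    C_A(P) = dA/dP = (Am / (pi * P1)) / (1 + ((P - P0) / P1)^2)

and the distensibility, the relative area change per unit pressure,

    D_A(P) = C_A(P) / A(P).

This module evaluates the model and its derived curves, fits it to measured
pressure-area series by bounded nonlinear least squares, and extracts the
summary metrics (maximal area, maximal compliance, maximal distensibility)
used to compare vessels and age groups.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .errors import DegenerateDataError, InsufficientDataError, ParameterDomainError

__all__ = [
    "ArctanParams",
    "FitResult",
    "SummaryMetrics",
    "MIN_FIT_POINTS",
    "area_at",
    "compliance_at",
    "distensibility_at",
    "fit_arctangent",
    "summary_metrics",
]

#: Minimum number of distinct pressure points accepted by the fitter:
#: three parameters plus two residual degrees of freedom.
MIN_FIT_POINTS = 5


@dataclass(frozen=True)
class ArctanParams:
    """Parameters of one vessel sample's arctangent pressure-area relation.

    Attributes
    ----------
    Am : float
        Asymptotic maximal cross-sectional area, mm^2. Must be > 0.
    P0 : float
        Pressure of maximal compliance, mmHg. May lie outside the
        measured pressure grid.
    P1 : float
        Half-width pressure, mmHg. Must be > 0.
    """

    Am: float
    P0: float
    P1: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.Am) and self.Am > 0):
            raise ParameterDomainError(f"Am must be positive and finite, got {self.Am}")
        if not (np.isfinite(self.P1) and self.P1 > 0):
            raise ParameterDomainError(f"P1 must be positive and finite, got {self.P1}")
        if not np.isfinite(self.P0):
            raise ParameterDomainError(f"P0 must be finite, got {self.P0}")


@dataclass(frozen=True)
class FitResult:
    """Outcome of fitting the arctangent model to one pressure-area series."""

    params: ArctanParams
    rss: float
    r_squared: float
    n_points: int
    converged: bool


@dataclass(frozen=True)
class SummaryMetrics:
    """Per-sample curve maxima reported in the group comparisons.

    ``max_area`` is the fitted Am; ``max_compliance`` the compliance-curve
    peak Am/(pi*P1), attained at P0 (clipped to the pressure range when P0
    lies outside it); ``max_distensibility`` the numerical maximum of D_A
    over the pressure range, with its argmax.
    """

    max_area: float
    max_compliance: float
    pressure_at_max_compliance: float
    max_distensibility: float
    pressure_at_max_distensibility: float


def area_at(params: ArctanParams, pressure):
    """Lumen area A(P) in mm^2 at ``pressure`` (mmHg; scalar or array)."""
    x = (np.asarray(pressure, dtype=float) - params.P0) / params.P1
    out = params.Am * (0.5 + np.arctan(x) / np.pi)
    return out if out.ndim else float(out)


def compliance_at(params: ArctanParams, pressure):
    """Area compliance dA/dP in mm^2/mmHg at ``pressure``.

    Peaks at P = P0 with value Am/(pi*P1) and is symmetric about P0.
    """
    x = (np.asarray(pressure, dtype=float) - params.P0) / params.P1
    out = (params.Am / (np.pi * params.P1)) / (1.0 + x * x)
    return out if out.ndim else float(out)


def distensibility_at(params: ArctanParams, pressure):
    """Distensibility D(P) = C(P)/A(P) in 1/mmHg at ``pressure``."""
    p = np.asarray(pressure, dtype=float)
    out = np.asarray(compliance_at(params, p)) / np.asarray(area_at(params, p))
    return out if out.ndim else float(out)


def _model_and_jac(theta: np.ndarray, pressures: np.ndarray):
    Am, P0, P1 = theta
    x = (pressures - P0) / P1
    denom = 1.0 + x * x
    f = Am * (0.5 + np.arctan(x) / np.pi)
    J = np.empty((pressures.size, 3))
    J[:, 0] = 0.5 + np.arctan(x) / np.pi
    J[:, 1] = -Am / (np.pi * P1 * denom)
    J[:, 2] = -Am * x / (np.pi * P1 * denom)
    return f, J


def fit_arctangent(
    pressures,
    areas,
    *,
    min_points: int = MIN_FIT_POINTS,
    ftol: float = 1e-10,
) -> FitResult:
    """Fit the arctangent model to observed (pressure, area) points.

    Bounded least squares (trust-region reflective) with a data-driven
    start: Am0 = 1.05 * max area; P0_0 = the pressure whose area is nearest
    Am0/2; P1_0 = half the interquartile range of the pressure grid.
    Bounds keep the optimiser in the identifiable regime while letting P0
    wander outside the measured grid: Am in (0, 10*max area], P1 in
    (0, 1e4], P0 in [-1e3, 1e3] mmHg.

    Parameters
    ----------
    pressures, areas : array-like
        Observed grid (mmHg) and mean lumen areas (mm^2).
    min_points : int
        Minimum number of *distinct* pressures required (default 5:
        3 parameters + 2 residual df). Truncated (ruptured) series below
        this floor raise :class:`InsufficientDataError`.
    ftol : float
        Relative cost-reduction convergence tolerance.

    Returns
    -------
    FitResult
        Fitted parameters, residual sum of squares, R^2 (about the mean
        observed area) and a truthful convergence flag.

    Raises
    ------
    InsufficientDataError
        Fewer than ``min_points`` distinct pressures.
    DegenerateDataError
        All areas (numerically) identical: the parameters are not
        identifiable and no fit is attempted.
    """
    P = np.asarray(pressures, dtype=float)
    A = np.asarray(areas, dtype=float)
    if P.shape != A.shape or P.ndim != 1:
        raise ValueError("pressures and areas must be 1-D arrays of equal length")
    n_distinct = np.unique(P).size
    if n_distinct < min_points:
        raise InsufficientDataError(
            f"need >= {min_points} distinct pressures, got {n_distinct}"
        )
    if np.any(A <= 0):
        raise ValueError("areas must be positive")

    tss = float(np.sum((A - A.mean()) ** 2))
    if tss <= 1e-12 * float(np.sum(A**2)):
        raise DegenerateDataError("all areas identical: parameters not identifiable")

    amax = float(A.max())
    am0 = 1.05 * amax
    p0_0 = float(P[np.argmin(np.abs(A - am0 / 2.0))])
    q25, q75 = np.percentile(P, [25, 75])
    p1_0 = max((q75 - q25) / 2.0, 1.0)
    theta0 = np.array([am0, p0_0, p1_0])

    lb = np.array([1e-12, -1e3, 1e-12])
    ub = np.array([10.0 * amax, 1e3, 1e4])
    theta0 = np.clip(theta0, lb, ub)

    res = least_squares(
        lambda t: _model_and_jac(t, P)[0] - A,
        theta0,
        jac=lambda t: _model_and_jac(t, P)[1],
        bounds=(lb, ub),
        method="trf",
        ftol=ftol,
        xtol=1e-12,
        gtol=1e-12,
    )
    rss = float(np.sum(res.fun**2))
    r2 = 1.0 - rss / tss
    params = ArctanParams(Am=float(res.x[0]), P0=float(res.x[1]), P1=float(res.x[2]))
    return FitResult(
        params=params,
        rss=rss,
        r_squared=r2,
        n_points=int(P.size),
        converged=bool(res.success),
    )


def summary_metrics(
    params: ArctanParams,
    pressure_range: tuple[float, float] = (15.0, 300.0),
    *,
    grid_step: float = 0.1,
) -> SummaryMetrics:
    """Curve maxima over ``pressure_range``.

    Maximal area and compliance have closed forms (Am; Am/(pi*P1) at P0);
    the distensibility maximum has none, so it is located by a dense grid
    (``grid_step`` mmHg) followed by local quadratic refinement.
    """
    lo, hi = float(pressure_range[0]), float(pressure_range[1])
    if not (np.isfinite(lo) and np.isfinite(hi)) or lo >= hi:
        raise ValueError(f"invalid pressure range ({lo}, {hi})")

    p_cmax = min(max(params.P0, lo), hi)
    c_max = compliance_at(params, p_cmax)

    grid = np.arange(lo, hi + grid_step / 2, grid_step)
    d = distensibility_at(params, grid)
    i = int(np.argmax(d))
    # quadratic refinement on interior maxima
    if 0 < i < grid.size - 1:
        y0, y1, y2 = d[i - 1], d[i], d[i + 1]
        denom = y0 - 2 * y1 + y2
        shift = 0.5 * (y0 - y2) / denom if denom != 0 else 0.0
        p_dmax = grid[i] + np.clip(shift, -1, 1) * grid_step
    else:
        p_dmax = grid[i]
    d_max = float(distensibility_at(params, p_dmax))

    return SummaryMetrics(
        max_area=params.Am,
        max_compliance=float(c_max),
        pressure_at_max_compliance=float(p_cmax),
        max_distensibility=d_max,
        pressure_at_max_distensibility=float(p_dmax),
    )
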