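"""Model evaluation and Levenberg-Marquardt fitting.

Two models are supported:

* four-parameter logistic (4PL) dose-response,
      y = bottom + (top - bottom) / (1 + (x / ec50)^hill),
  in which x = ec50 is exactly the midpoint between the asymptotes (the
  IC50/EC50).  The curve is fitted on the natural concentration scale with
  ec50 log-transformed internally, which keeps it positive without
  constraints;
* a straight line y = intercept + slope * x (initial-rate kinetics and
  other linear responses).

The fit minimises the unweighted sum of squared residuals over the
aggregated replicate means (fully-masked points are ignored) with a
classic Levenberg-Marquardt damping schedule: lambda starts at 1e-3,
is divided by 10 after an accepted step and multiplied by 10 after a
rejected one.  Convergence is declared when the relative SSR change or
the gradient norm drops below 1e-10, within a cap of 1000 iterations.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass

import numpy as np

from .preprocess import AggregatedSeries

__all__ = [
    "FitModel",
    "Logistic4Params",
    "LinearParams",
    "FitResult",
    "logistic4_eval",
    "linear_eval",
    "guess_logistic4",
    "guess_linear",
    "lm_fit",
    "refit_from",
    "gof_stats",
]

MAX_ITER = 1000
SSR_RTOL = 1e-10
GRAD_TOL = 1e-10
LAMBDA_INIT = 1e-3
LAMBDA_MAX = 1e12


class FitError(ValueError):
    """Raised for under-determined or otherwise unfittable problems."""


class FitModel(enum.Enum):
    LOGISTIC4 = "logistic4"
    LINEAR = "linear"


@dataclass(frozen=True)
class Logistic4Params:
    bottom: float
    top: float
    ec50: float  # > 0, test-value units; abscissa of the inflection point
    hill: float  # slope factor; > 0 means decreasing response

    def __post_init__(self):
        if not (np.isfinite(self.ec50) and self.ec50 > 0):
            raise FitError(f"ec50 must be positive and finite, got {self.ec50!r}")
        if not np.isfinite(self.hill) or self.hill == 0:
            raise FitError(f"hill must be finite and non-zero, got {self.hill!r}")

    def as_dict(self) -> dict[str, float]:
        return {"bottom": self.bottom, "top": self.top, "ec50": self.ec50, "hill": self.hill}


@dataclass(frozen=True)
class LinearParams:
    intercept: float
    slope: float

    def as_dict(self) -> dict[str, float]:
        return {"intercept": self.intercept, "slope": self.slope}


@dataclass(frozen=True)
class FitResult:
    model: FitModel
    params: Logistic4Params | LinearParams
    param_se: dict[str, float] | None
    ssr: float
    r2: float
    rmse: float | None
    dof: int
    converged: bool
    n_iter: int
    start_params: Logistic4Params | LinearParams


# ---------------------------------------------------------------- evaluation

def logistic4_eval(x, p: Logistic4Params):
    """Evaluate the 4PL curve; scalar or array x, x >= 0.

    x = 0 returns the limit: top for hill > 0, bottom for hill < 0.
    """
    xa = np.asarray(x, dtype=float)
    if np.any(xa < 0):
        raise FitError("concentrations must be non-negative")
    with np.errstate(divide="ignore", over="ignore"):
        ratio = np.where(xa > 0, xa / p.ec50, 0.0)
        t = np.where(
            xa > 0,
            np.power(np.where(xa > 0, ratio, 1.0), p.hill),
            0.0 if p.hill > 0 else np.inf,
        )
        y = p.bottom + (p.top - p.bottom) / (1.0 + t)
    return float(y) if np.isscalar(x) else y


def linear_eval(x, p: LinearParams):
    xa = np.asarray(x, dtype=float)
    y = p.intercept + p.slope * xa
    return float(y) if np.isscalar(x) else y


def _eval(model: FitModel, x, params):
    return logistic4_eval(x, params) if model is FitModel.LOGISTIC4 else linear_eval(x, params)


# --------------------------------------------------------------- start guess

def guess_logistic4(series: AggregatedSeries) -> Logistic4Params:
    """Heuristic start values from the data's shape.

    The asymptotes are taken from the responses at the two extreme test
    values, ec50 from the point nearest the midpoint response (clamped into
    the positive sampled range), and the hill sign from the response
    direction (+1 decreasing, -1 increasing).
    """
    x, y = series.xy()
    if len(x) < 4:
        raise FitError(f"under-determined: {len(x)} usable points < 4 parameters")
    pos = x[x > 0]
    if len(np.unique(pos)) < 2:
        raise FitError("under-determined: need >= 2 distinct positive test values")
    y_lo, y_hi = y[np.argmin(x)], y[np.argmax(x)]
    top, bottom = (y_lo, y_hi) if y_lo >= y_hi else (y_hi, y_lo)
    if top == bottom:
        warnings.warn(
            f"flat series in group {series.group_name!r}: start values poorly determined"
        )
        ec50 = float(np.exp(np.mean(np.log(pos))))  # geometric mean of positive x
        return Logistic4Params(bottom=bottom, top=top, ec50=ec50, hill=1.0)
    mid = (top + bottom) / 2.0
    ec50 = float(x[np.argmin(np.abs(y - mid))])
    ec50 = float(np.clip(ec50, pos.min(), x.max()))
    hill = 1.0 if y_lo >= y_hi else -1.0  # decreasing response -> positive hill
    return Logistic4Params(bottom=bottom, top=top, ec50=ec50, hill=hill)


def guess_linear(series: AggregatedSeries) -> LinearParams:
    """Neutral start: horizontal line at the mean response (the linear
    problem has a single optimum, so the start only sets the iteration
    count)."""
    _, y = series.xy()
    if len(y) < 2:
        raise FitError(f"under-determined: {len(y)} usable points < 2 parameters")
    return LinearParams(intercept=float(np.mean(y)), slope=0.0)


# --------------------------------------------------- internal parameterisation

def _pack(model: FitModel, params) -> np.ndarray:
    if model is FitModel.LOGISTIC4:
        return np.array([params.bottom, params.top, np.log(params.ec50), params.hill])
    return np.array([params.intercept, params.slope])


def _unpack(model: FitModel, vec: np.ndarray):
    if model is FitModel.LOGISTIC4:
        b, t, log_ec50, h = vec
        return Logistic4Params(bottom=float(b), top=float(t),
                               ec50=float(np.exp(log_ec50)), hill=float(h))
    return LinearParams(intercept=float(vec[0]), slope=float(vec[1]))


def _residuals(model: FitModel, vec: np.ndarray, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    if model is FitModel.LOGISTIC4:
        b, t, log_ec50, h = vec
        with np.errstate(over="ignore", divide="ignore", invalid="ignore"):
            u = np.where(x > 0, np.exp(h * (np.log(np.where(x > 0, x, 1.0)) - log_ec50)), 0.0)
            u = np.where(x > 0, u, 0.0 if h > 0 else np.inf)
            f = b + (t - b) / (1.0 + u)
    else:
        f = vec[0] + vec[1] * x
    return f - y


def _jacobian(model: FitModel, vec: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Analytic d(residual)/d(param); rows = points, cols = params."""
    if model is FitModel.LINEAR:
        return np.column_stack([np.ones_like(x), x])
    b, t, log_ec50, h = vec
    J = np.zeros((len(x), 4))
    pos = x > 0
    logx = np.log(np.where(pos, x, 1.0))
    with np.errstate(over="ignore"):
        u = np.where(pos, np.exp(h * (logx - log_ec50)), 0.0 if h > 0 else np.inf)
    denom = 1.0 + u
    frac = 1.0 / denom
    # d f / d bottom = 1 - 1/(1+u);  d f / d top = 1/(1+u)
    J[:, 0] = 1.0 - frac
    J[:, 1] = frac
    # d f / d log_ec50 = (t-b) * h*u / (1+u)^2 ; d f / d hill = -(t-b)*(logx-log_ec50)*u/(1+u)^2
    with np.errstate(invalid="ignore", over="ignore"):
        core = np.where(np.isfinite(u), u / denom**2, 0.0)
    J[:, 2] = (t - b) * h * core
    J[:, 3] = -(t - b) * np.where(pos, logx - log_ec50, 0.0) * core
    return np.nan_to_num(J, nan=0.0, posinf=0.0, neginf=0.0)


# --------------------------------------------------------------------- fitting

def _levenberg_marquardt(model, p0, x, y):
    """Core damped least-squares loop. Returns (vec, ssr, converged, n_iter)."""
    p = p0.copy()
    r = _residuals(model, p, x, y)
    if not np.all(np.isfinite(r)):
        return p, np.inf, False, 0
    ssr = float(r @ r)
    lam = LAMBDA_INIT
    converged = False
    it = 0
    for it in range(1, MAX_ITER + 1):
        J = _jacobian(model, p, x)
        g = J.T @ r
        if np.linalg.norm(g) < GRAD_TOL:
            converged = True
            break
        A = J.T @ J
        d = np.diag(A).copy()
        d[d <= 0] = 1.0  # guard flat directions
        accepted = False
        while lam <= LAMBDA_MAX:
            try:
                step = np.linalg.solve(A + lam * np.diag(d), -g)
            except np.linalg.LinAlgError:
                lam *= 10
                continue
            p_try = p + step
            r_try = _residuals(model, p_try, x, y)
            if np.all(np.isfinite(r_try)):
                ssr_try = float(r_try @ r_try)
                if ssr_try <= ssr:
                    rel = (ssr - ssr_try) / max(ssr, np.finfo(float).tiny)
                    p, r, ssr = p_try, r_try, ssr_try
                    lam = max(lam / 10, 1e-15)
                    accepted = True
                    if rel < SSR_RTOL:
                        converged = True
                    break
            lam *= 10
        if not accepted or converged:
            if not accepted and lam > LAMBDA_MAX:
                converged = ssr == 0.0 or converged
            break
    # final undamped Gauss-Newton polish: exact for the linear model, a
    # free refinement near the optimum otherwise (kept only if not worse)
    try:
        J = _jacobian(model, p, x)
        step = np.linalg.solve(J.T @ J, -(J.T @ r))
        r_try = _residuals(model, p + step, x, y)
        # tolerate SSR-evaluation roundoff so an exact optimum is not rejected
        if np.all(np.isfinite(r_try)) and float(r_try @ r_try) <= ssr * (1 + 1e-12):
            p = p + step
            ssr = min(ssr, float(r_try @ r_try))
    except np.linalg.LinAlgError:
        pass
    return p, ssr, converged, it


def gof_stats(series: AggregatedSeries, model: FitModel, params):
    """(ssr, r2, rmse, dof) over the non-masked aggregated means.

    Definitions do not depend on where the parameters came from, so manual
    parameter entry and fitted parameters are scored identically.
    r2 = 1 - SSR/TSS with TSS about the mean response; it may be negative.
    """
    x, y = series.xy()
    r = _residuals(model, _pack(model, params), x, y)
    ssr = float(r @ r)
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ssr / tss if tss > 0 else (1.0 if ssr == 0 else float("nan"))
    n_params = 4 if model is FitModel.LOGISTIC4 else 2
    dof = len(x) - n_params
    rmse = float(np.sqrt(ssr / dof)) if dof >= 1 else None
    return ssr, r2, rmse, dof


def _param_se(model, vec, x, ssr, dof):
    """Residual-variance-scaled covariance from the Gauss-Newton normal
    matrix; None when dof < 1 or the matrix is ill-conditioned.  The ec50
    standard error is mapped back from the log scale by the delta method."""
    if dof < 1:
        return None
    J = _jacobian(model, vec, x)
    A = J.T @ J
    if not np.all(np.isfinite(A)) or np.linalg.cond(A) > 1e12:
        return None
    cov = np.linalg.inv(A) * (ssr / dof)
    se = np.sqrt(np.clip(np.diag(cov), 0, None))
    if model is FitModel.LOGISTIC4:
        ec50 = float(np.exp(vec[2]))
        return {
            "bottom": float(se[0]),
            "top": float(se[1]),
            "ec50": float(ec50 * se[2]),
            "hill": float(se[3]),
        }
    return {"intercept": float(se[0]), "slope": float(se[1])}


def lm_fit(series: AggregatedSeries, model: FitModel, start=None) -> FitResult:
    """Fit the chosen model to the aggregated means by Levenberg-Marquardt.

    ``start`` defaults to the automatic guess.  Raises for under-determined
    problems; a fit that runs into non-finite residuals returns the best
    parameters found with ``converged=False``.
    """
    x, y = series.xy()
    n_params = 4 if model is FitModel.LOGISTIC4 else 2
    if len(x) < n_params:
        raise FitError(
            f"under-determined: {len(x)} usable points for {n_params} parameters"
        )
    if start is None:
        start = guess_logistic4(series) if model is FitModel.LOGISTIC4 else guess_linear(series)
    vec, ssr, converged, n_iter = _levenberg_marquardt(model, _pack(model, start), x, y)
    params = _unpack(model, vec)
    ssr, r2, rmse, dof = gof_stats(series, model, params)
    return FitResult(
        model=model,
        params=params,
        param_se=_param_se(model, vec, x, ssr, dof),
        ssr=ssr,
        r2=r2,
        rmse=rmse,
        dof=dof,
        converged=converged,
        n_iter=n_iter,
        start_params=start,
    )


def refit_from(series: AggregatedSeries, model: FitModel, user_params) -> FitResult:
    """Re-run the fit from user-supplied start parameters."""
    return lm_fit(series, model, start=user_params)
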