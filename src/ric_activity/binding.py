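"""Fluorescence anisotropy and four-parameter logistic (4PL) binding fits.

The binding isotherm is the standard 4PL

    y = ymin + (ymax - ymin) / (1 + (x / Kd)^(-n))

with x the protein concentration (nM), Kd the midpoint (y(Kd) is the
ymin/ymax midpoint) and n > 0 the Hill slope; for an increasing binding
curve ymax > ymin.  Fitting is unweighted nonlinear least squares with Kd
and n kept positive through a log parameterization.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares


@dataclass(frozen=True)
class FourPLFit:
    ymin: float
    ymax: float
    kd: float
    n: float
    rss: float
    se: dict[str, float]


def anisotropy(parallel, perpendicular, g_factor: float = 1.0):
    """r = (I_par - G I_perp) / (I_par + 2 G I_perp); r lies in (-0.5, 1]."""
    par = np.asarray(parallel, dtype=float)
    perp = np.asarray(perpendicular, dtype=float)
    denom = par + 2.0 * g_factor * perp
    if np.any(denom <= 0):
        raise ValueError("total intensity I_par + 2 G I_perp must be positive")
    r = (par - g_factor * perp) / denom
    return float(r) if r.ndim == 0 else r


def average_readings(frame: pd.DataFrame, by: str = "concentration_nM") -> pd.DataFrame:
    """Average technical replicate readings per concentration."""
    return frame.groupby(by, as_index=False).mean()


def four_pl(x, ymin: float, ymax: float, kd: float, n: float):
    """Evaluate the 4PL; monotone increasing in x for n > 0, ymax > ymin."""
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise ValueError("concentrations must be positive")
    y = ymin + (ymax - ymin) / (1.0 + (x / kd) ** (-n))
    return float(y) if y.ndim == 0 else y


def predict_4pl(fit: FourPLFit, x):
    return four_pl(x, fit.ymin, fit.ymax, fit.kd, fit.n)


def _validate_curve(x: np.ndarray, y: np.ndarray, flat_tol: float) -> None:
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    if len(x) < 5:
        raise ValueError("need at least 5 titration points")
    if np.any(x <= 0):
        raise ValueError("concentrations must be positive")
    if x.max() / x.min() < 10.0:
        raise ValueError("concentrations must span at least one order of magnitude")
    if np.ptp(y) < flat_tol:
        raise ValueError("flat curve: anisotropy range below tolerance")


def _init_kd(x: np.ndarray, y: np.ndarray) -> float:
    """x at the y-midpoint by log-linear interpolation."""
    order = np.argsort(x)
    xs, ys = x[order], y[order]
    target = (ys.min() + ys.max()) / 2.0
    lx = np.log(xs)
    for i in range(len(xs) - 1):
        y0, y1 = ys[i], ys[i + 1]
        if (y0 - target) * (y1 - target) <= 0 and y0 != y1:
            f = (target - y0) / (y1 - y0)
            return float(np.exp(lx[i] + f * (lx[i + 1] - lx[i])))
    return float(np.exp(lx.mean()))


def fit_4pl(
    curve: pd.DataFrame,
    flat_tol: float = 1e-6,
    max_restarts: int = 3,
) -> FourPLFit:
    """Unweighted least-squares 4PL fit of an anisotropy titration.

    ``curve`` needs columns ``concentration_nM`` and ``anisotropy``.
    Initialization: ymin = min(y), ymax = max(y), Kd at the interpolated
    y-midpoint, n = 1; Kd and n are fitted on the log scale.  On failure
    the fit is restarted up to ``max_restarts`` times from jittered
    initial values.
    """
    x = curve["concentration_nM"].to_numpy(dtype=float)
    y = curve["anisotropy"].to_numpy(dtype=float)
    _validate_curve(x, y, flat_tol)

    theta0 = np.array([y.min(), y.max(), math.log(_init_kd(x, y)), 0.0])

    def residuals(theta):
        ymin, ymax, log_kd, log_n = theta
        return four_pl(x, ymin, ymax, math.exp(log_kd), math.exp(log_n)) - y

    rng = np.random.default_rng(0)
    last_err: Exception | None = None
    for attempt in range(max_restarts + 1):
        theta = theta0.copy()
        if attempt:
            theta += rng.normal(0.0, [0.01 * np.ptp(y) + 1e-9, 0.01 * np.ptp(y) + 1e-9, 0.3, 0.3])
        try:
            sol = least_squares(residuals, theta, method="lm", xtol=1e-14, ftol=1e-14, gtol=1e-14)
        except Exception as err:  # pragma: no cover - scipy-internal failures
            last_err = err
            continue
        if sol.success:
            ymin, ymax, log_kd, log_n = sol.x
            kd, n = math.exp(log_kd), math.exp(log_n)
            rss = float(np.sum(sol.fun**2))
            se = _parameter_se(sol.jac, sol.fun, (kd, n))
            return FourPLFit(float(ymin), float(ymax), kd, n, rss, se)
        last_err = RuntimeError(sol.message)
    raise RuntimeError(
        f"4PL fit failed to converge after {max_restarts} restarts: {last_err}"
    )


def _parameter_se(jac: np.ndarray, resid: np.ndarray, kd_n: tuple[float, float]) -> dict[str, float]:
    """Asymptotic standard errors from the Jacobian at the optimum.

    The fit runs on (ymin, ymax, ln Kd, ln n); the chain rule maps the
    log-scale errors back to Kd and n.
    """
    m, k = jac.shape
    dof = max(m - k, 1)
    s2 = float(np.sum(resid**2)) / dof
    try:
        cov = s2 * np.linalg.inv(jac.T @ jac)
        diag = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:  # pragma: no cover - singular at exact fit
        diag = np.full(k, math.nan)
    kd, n = kd_n
    return {
        "ymin": float(diag[0]),
        "ymax": float(diag[1]),
        "kd": float(diag[2] * kd),
        "n": float(diag[3] * n),
    }


def fit_from_readings(curve: pd.DataFrame, g_factor_default: float = 1.0) -> FourPLFit:
    """Fit a curve TSV that carries either anisotropy or raw intensity columns."""
    if "anisotropy" not in curve.columns:
        g = curve["g_factor"] if "g_factor" in curve.columns else g_factor_default
        curve = curve.assign(
            anisotropy=anisotropy(curve["parallel"], curve["perpendicular"], g)
        )
    curve = average_readings(curve[["concentration_nM", "anisotropy"]])
    return fit_4pl(curve)
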