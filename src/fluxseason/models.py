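"""Respiration response models and temperature sensitivity.

Three fitted forms:

* linear moisture response       ``rs = m + n*W``
* exponential temperature law    ``rs = a * exp(b*T)``      with Q10 = e^(10b)
* bivariate temperature-moisture ``rs = a * exp(b*T) * W**c``

The exponential forms are fitted by nonlinear least squares on the original
rate scale (``method="nls"``, the default), initialized from the log-linear
closed form, or by the log-linear OLS itself (``method="loglinear"``).  In
both cases R^2 is reported as 1 - SSE/SST on the original rate scale, which
for a nonlinear fit can fall below the squared correlation.  Records with
rs <= 0 are excluded from log-scale steps with a logged count.
"""

from __future__ import annotations

import dataclasses
import logging
import math

import numpy as np
import pandas as pd
from scipy import optimize, stats

log = logging.getLogger(__name__)


class FitError(RuntimeError):
    """The optimizer failed to converge."""


class DegenerateDesignError(ValueError):
    """The design is unidentifiable (constant or collinear predictors)."""


@dataclasses.dataclass(frozen=True)
class LinearFit:
    """OLS fit of rs on soil moisture."""

    m: float  # intercept, umol CO2 m-2 s-1
    n: float  # slope per moisture point
    r2: float
    p_value: float
    n_obs: int


@dataclasses.dataclass(frozen=True)
class ExponentialFit:
    """Fit of rs = a * exp(b*T); q10 is always exp(10*b)."""

    a: float
    b: float  # degC^-1
    r2: float
    p_value: float
    n_obs: int
    q10: float


@dataclasses.dataclass(frozen=True)
class BivariateFit:
    """Fit of rs = a * exp(b*T) * W**c."""

    a: float
    b: float
    c: float
    r2: float
    p_value: float
    n_obs: int


def compute_q10(b: float) -> float:
    """Temperature sensitivity exp(10*b) of the exponential model."""
    if not np.isfinite(b):
        raise ValueError("b must be finite")
    return math.exp(10.0 * b)


def significance_stars(p: float) -> str:
    """'**' for p < 0.01, '*' for p < 0.05, '' otherwise."""
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def _columns(records, names):
    if isinstance(records, pd.DataFrame):
        return tuple(records[n].to_numpy(dtype=float) for n in names)
    arr = np.asarray(records, dtype=float)
    return tuple(arr[:, i] for i in range(len(names)))


def _r2_original_scale(y, yhat):
    sst = float(np.sum((y - y.mean()) ** 2))
    sse = float(np.sum((y - yhat) ** 2))
    if sst == 0:
        return 1.0 if sse == 0 else 0.0
    return 1.0 - sse / sst


def _model_f_pvalue(y, yhat, n_params):
    """F-test of the fitted model against the intercept-only model."""
    n = len(y)
    df_num = n_params - 1
    df_den = n - n_params
    sst = float(np.sum((y - y.mean()) ** 2))
    sse = float(np.sum((y - yhat) ** 2))
    if df_den <= 0 or sse <= 0:
        return 0.0 if sst > sse else 1.0
    f = ((sst - sse) / df_num) / (sse / df_den)
    return float(stats.f.sf(max(f, 0.0), df_num, df_den))


def fit_moisture_linear(records) -> LinearFit:
    """Ordinary least squares of rs on soil moisture.

    r2 is the squared Pearson correlation; the p-value is the slope's
    F-test (equivalently the two-sided t-test).
    """
    rs, w = _columns(records, ["rs", "soil_moisture"])
    if len(rs) < 3:
        raise ValueError("need at least 3 records")
    if np.ptp(w) == 0:
        raise DegenerateDesignError("soil moisture is constant")
    res = stats.linregress(w, rs)
    return LinearFit(
        m=float(res.intercept),
        n=float(res.slope),
        r2=float(res.rvalue**2),
        p_value=float(res.pvalue),
        n_obs=len(rs),
    )


def _positive_subset(arrays, what):
    rs = arrays[0]
    keep = rs > 0
    dropped = int((~keep).sum())
    if dropped:
        log.warning("%s: excluded %d record(s) with rs <= 0 from the log-linear step", what, dropped)
    return [a[keep] for a in arrays]


def fit_temperature_exponential(records, method: str = "nls") -> ExponentialFit:
    """Fit rs = a * exp(b*T).

    ``method="nls"`` (default) minimizes squared error on the rate scale,
    starting from the log-linear closed form; ``method="loglinear"`` returns
    the closed form itself (requires rs > 0).
    """
    if method not in ("nls", "loglinear"):
        raise ValueError(f"unknown method: {method!r}")
    rs, t = _columns(records, ["rs", "soil_temp_10cm"])
    if len(rs) < 3:
        raise ValueError("need at least 3 records")
    if np.ptp(t) == 0:
        raise DegenerateDesignError("soil temperature is constant")

    if method == "loglinear" and np.any(rs <= 0):
        raise ValueError("rs <= 0 is incompatible with method='loglinear'")
    rs_pos, t_pos = _positive_subset([rs, t], "exponential fit")
    if len(rs_pos) >= 3 and np.ptp(t_pos) > 0:
        init = stats.linregress(t_pos, np.log(rs_pos))
        a0, b0 = math.exp(init.intercept), float(init.slope)
    else:
        a0, b0 = max(float(np.mean(rs)), 1e-6), 0.05

    if method == "loglinear":
        a, b = a0, b0
    else:
        try:
            popt, _ = optimize.curve_fit(
                lambda x, a, b: a * np.exp(b * x), t, rs, p0=(a0, b0), maxfev=10000
            )
        except RuntimeError as exc:
            raise FitError(f"exponential fit did not converge: {exc}") from exc
        a, b = float(popt[0]), float(popt[1])
    yhat = a * np.exp(b * t)
    return ExponentialFit(
        a=a,
        b=b,
        r2=_r2_original_scale(rs, yhat),
        p_value=_model_f_pvalue(rs, yhat, 2),
        n_obs=len(rs),
        q10=compute_q10(b),
    )


def fit_temperature_moisture(records, method: str = "nls") -> BivariateFit:
    """Fit rs = a * exp(b*T) * W**c.

    Initialized from the multiple OLS of ln rs on (T, ln W); the nls path
    also restarts from the nested exponential solution (c = 0) and keeps the
    better optimum, so its R^2 never falls below the nested fit's.
    """
    if method not in ("nls", "loglinear"):
        raise ValueError(f"unknown method: {method!r}")
    rs, t, w = _columns(records, ["rs", "soil_temp_10cm", "soil_moisture"])
    if len(rs) < 4:
        raise ValueError("need at least 4 records")
    if np.any(w <= 0):
        raise ValueError("soil moisture must be > 0 for the moisture power term")
    if np.ptp(t) == 0 or np.ptp(w) == 0:
        raise DegenerateDesignError("constant predictor")
    if abs(stats.pearsonr(t, np.log(w)).statistic) > 0.9999:
        raise DegenerateDesignError("temperature and ln(moisture) are collinear")

    if method == "loglinear" and np.any(rs <= 0):
        raise ValueError("rs <= 0 is incompatible with method='loglinear'")
    rs_pos, t_pos, w_pos = _positive_subset([rs, t, w], "bivariate fit")
    if len(rs_pos) >= 4:
        design = np.column_stack([np.ones(len(t_pos)), t_pos, np.log(w_pos)])
        coef, *_ = np.linalg.lstsq(design, np.log(rs_pos), rcond=None)
        a0, b0, c0 = math.exp(coef[0]), float(coef[1]), float(coef[2])
    else:
        a0, b0, c0 = max(float(np.mean(rs)), 1e-6), 0.05, 0.0

    def f(x, a, b, c):
        return a * np.exp(b * x[0]) * np.power(x[1], c)

    if method == "loglinear":
        a, b, c = a0, b0, c0
    else:
        starts = [(a0, b0, c0)]
        try:  # nested start guards the r2 >= univariate-r2 invariant
            exp_fit = fit_temperature_exponential(records, method="nls")
            starts.append((exp_fit.a, exp_fit.b, 0.0))
        except (FitError, DegenerateDesignError):
            pass
        best, best_sse = None, np.inf
        for p0 in starts:
            try:
                popt, _ = optimize.curve_fit(f, (t, w), rs, p0=p0, maxfev=20000)
            except RuntimeError:
                continue
            sse = float(np.sum((rs - f((t, w), *popt)) ** 2))
            if sse < best_sse:
                best, best_sse = popt, sse
        if best is None:
            raise FitError("bivariate fit did not converge from any start")
        a, b, c = (float(v) for v in best)
    yhat = f((t, w), a, b, c)
    return BivariateFit(
        a=a,
        b=b,
        c=c,
        r2=_r2_original_scale(rs, yhat),
        p_value=_model_f_pvalue(rs, yhat, 3),
        n_obs=len(rs),
    )


def predict_rs(fit, T=None, W=None):
    """Evaluate a fitted model; vectorized over T and W."""
    if isinstance(fit, LinearFit):
        if W is None:
            raise ValueError("LinearFit prediction requires W")
        return fit.m + fit.n * np.asarray(W, dtype=float)
    if isinstance(fit, ExponentialFit):
        if T is None:
            raise ValueError("ExponentialFit prediction requires T")
        return fit.a * np.exp(fit.b * np.asarray(T, dtype=float))
    if isinstance(fit, BivariateFit):
        if T is None or W is None:
            raise ValueError("BivariateFit prediction requires T and W")
        w = np.asarray(W, dtype=float)
        if np.any(w <= 0):
            raise ValueError("W must be > 0 for BivariateFit")
        return fit.a * np.exp(fit.b * np.asarray(T, dtype=float)) * np.power(w, fit.c)
    raise TypeError(f"unsupported fit type: {type(fit).__name__}")
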