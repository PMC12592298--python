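"""Residual-error and inter-individual-variability initialization.

The data-driven path fits a per-subject log-linear regression to the
last three terminal concentration points, back-transforms the fitted
line and computes residuals on the original concentration scale:
sigma_add = sd(C_obs - C_pred), sigma_prop = sd(C_obs/C_pred - 1);
per-subject values are summarized by a 0.05-trimmed arithmetic mean.
When too few subjects qualify, the fallback sets
sigma_add = CV% * mean(DV) (default CV 20%) together with a pragmatic
proportional sd of 0.2.  IIV variances default to omega^2 = 0.1 for every
structural parameter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ErrorInit", "InsufficientDataError",
    "estimate_ruv_regression", "ruv_fallback", "init_iiv", "initialize_error",
]

DEFAULT_OMEGA2 = 0.1
DEFAULT_CV_FALLBACK = 0.20
#: proportional-error sd reported when the regression path is unavailable
FALLBACK_SIGMA_PROP = 0.2


class InsufficientDataError(RuntimeError):
    """Not enough terminal data for regression-based RUV estimation."""


@dataclass
class ErrorInit:
    sigma_add: float
    sigma_prop: float
    omega2: dict = field(default_factory=dict)
    source: str = "regression"  # regression | fallback
    n_subjects_used: int = 0


def estimate_ruv_regression(
    obs: pd.DataFrame, n_terminal_points: int = 3, trim: float = 0.05
) -> tuple[float, float, int]:
    """Per-subject terminal log-linear regression RUV estimates.

    For each subject with at least ``n_terminal_points`` positive
    terminal observations, fit log C ~ t on the last points, require a
    negative slope, back-transform to C_pred = exp(beta0 - Ke*t) and take
    sigma_add = sqrt(Var(C_obs - C_pred)),
    sigma_prop = sqrt(Var(C_obs/C_pred - 1)) (sample variance, n-1).
    Returns the trimmed means (trim 0.05 total, 2.5% per tail) across
    subjects plus the subject count.

    Raises
    ------
    InsufficientDataError
        When no subject qualifies.
    """
    adds, props = [], []
    for sid, sub in obs.groupby("id"):
        sub = sub[sub["dv"] > 0].sort_values("time")
        if len(sub) < n_terminal_points:
            continue
        tail = sub.tail(n_terminal_points)
        t = tail["time"].to_numpy(float)
        c = tail["dv"].to_numpy(float)
        if len(np.unique(t)) < 2:
            continue
        res = stats.linregress(t, np.log(c))
        if res.slope >= 0:
            continue
        c_pred = np.exp(res.intercept + res.slope * t)
        r_add = c - c_pred
        r_prop = c / c_pred - 1.0
        adds.append(float(np.sqrt(np.var(r_add, ddof=1))))
        props.append(float(np.sqrt(np.var(r_prop, ddof=1))))
    if not adds:
        raise InsufficientDataError("no subject with a usable terminal regression")
    cut = trim / 2.0
    return (
        float(stats.trim_mean(adds, cut)),
        float(stats.trim_mean(props, cut)),
        len(adds),
    )


def ruv_fallback(obs: pd.DataFrame, cv: float = DEFAULT_CV_FALLBACK) -> float:
    """Fixed-fraction additive error: sigma_add = CV% * mean observed DV."""
    dv = obs["dv"].dropna()
    if len(dv) == 0:
        raise ValueError("no observations")
    return float(cv * dv.mean())


def init_iiv(parameters, override: dict | None = None) -> dict:
    """omega^2 = 0.1 for every structural parameter, unless overridden."""
    out = {name: DEFAULT_OMEGA2 for name in parameters}
    if override:
        out.update({k: v for k, v in override.items() if k in out})
    return out


def initialize_error(
    obs: pd.DataFrame,
    parameters,
    n_terminal_points: int = 3,
    cv_fallback: float = DEFAULT_CV_FALLBACK,
    omega2_override: dict | None = None,
) -> ErrorInit:
    """Full Part-3 initialization: RUV (regression else fallback) + IIV."""
    omega2 = init_iiv(parameters, omega2_override)
    try:
        s_add, s_prop, n = estimate_ruv_regression(obs, n_terminal_points)
        return ErrorInit(s_add, s_prop, omega2, source="regression",
                         n_subjects_used=n)
    except InsufficientDataError:
        s_add = ruv_fallback(obs, cv_fallback)
        return ErrorInit(s_add, FALLBACK_SIGMA_PROP, omega2, source="fallback",
                         n_subjects_used=0)
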