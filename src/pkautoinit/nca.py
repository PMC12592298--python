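"""Naive pooled non-compartmental analysis.

AUC is computed with the linear-up log-down trapezoidal rule on the
pooled, dose-normalized profile.  For single-dose data CL = 1/AUC_0-inf
per unit dose; for multiple-dose data CL = 1/AUC_0-tau with tau the most
frequently used dosing interval.  Vz = CL/lambda_z.  For extravascular
data Ka comes from the Wagner-Nelson fraction-absorbed method.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .dataio import PooledProfile, ROUTE_BOLUS
from .single_point import OneCptEstimate
from .terminal_phase import TerminalFit

__all__ = [
    "AUCResult",
    "auc_linuplogdown",
    "nca_onecpt",
    "wagner_nelson_ka",
    "modal_tau",
]


@dataclass
class AUCResult:
    """Areas under the pooled curve (per unit dose when normalized)."""

    auc_0_t: float
    c_last: float
    auc_0_inf: float | None = None
    auc_0_tau: float | None = None
    extrapolated_fraction: float | None = None


def auc_linuplogdown(times, concs) -> float:
    """Linear-up log-down trapezoidal AUC over the observed range.

    Rising or flat segments use the linear trapezoid; strictly falling
    segments with both endpoints positive use the logarithmic trapezoid
    ``(C_i - C_{i+1}) / ln(C_i / C_{i+1}) * dt``; a fall to zero reverts
    to linear.
    """
    t = np.asarray(times, dtype=float)
    c = np.asarray(concs, dtype=float)
    if len(t) < 2:
        raise ValueError("AUC needs at least 2 points")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    if np.any(c < 0):
        raise ValueError("concentrations must be non-negative")
    auc = 0.0
    for i in range(len(t) - 1):
        dt = t[i + 1] - t[i]
        c0, c1 = c[i], c[i + 1]
        if c1 < c0 and c1 > 0:
            auc += (c0 - c1) / math.log(c0 / c1) * dt
        else:
            auc += 0.5 * (c0 + c1) * dt
    return float(auc)


def modal_tau(doses: pd.DataFrame) -> float | None:
    """Most commonly used dosing interval across the dataset."""
    taus = doses["tau"].dropna()
    taus = taus[taus > 0]
    if taus.empty:
        return None
    return float(taus.round(9).mode().iloc[0])


def _profile_with_origin(profile: PooledProfile, fit: TerminalFit,
                         route: str, multiple: bool, tau: float | None):
    """Prepend a TAD=0 anchor to the pooled profile for integration.

    Bolus profiles are back-extrapolated to exp(beta0); first-dose
    infusion/oral profiles start at zero; multi-dose non-bolus profiles
    start at the trough (C at tau by log-down decay), by continuity of
    the steady-state profile.
    """
    t = profile.tad
    c = profile.conc
    if t[0] <= 1e-12:
        return t, c
    if route == ROUTE_BOLUS:
        c0 = math.exp(fit.beta0)
    elif multiple and tau is not None:
        c0 = c[-1] * math.exp(-fit.lambda_z * (tau - t[-1])) if tau > t[-1] \
            else float(np.interp(tau, t, c))
    else:
        c0 = 0.0
    return np.concatenate([[0.0], t]), np.concatenate([[c0], c])


def compute_auc(
    profile: PooledProfile,
    fit: TerminalFit,
    route: str,
    multiple: bool = False,
    tau: float | None = None,
) -> AUCResult:
    """AUC_0-inf (single dose) or AUC_0-tau (multiple dose) of a profile."""
    t, c = _profile_with_origin(profile, fit, route, multiple, tau)
    lam = fit.lambda_z
    if multiple:
        if tau is None or tau <= 0:
            raise ValueError("multiple-dose AUC needs tau")
        if t[-1] < tau:
            # extend with log-down decay at lambda_z out to tau
            c_tau = c[-1] * math.exp(-lam * (tau - t[-1]))
            t = np.concatenate([t, [tau]])
            c = np.concatenate([c, [c_tau]])
        elif t[-1] > tau:
            c_tau = float(np.interp(tau, t, c))
            keep = t < tau
            t = np.concatenate([t[keep], [tau]])
            c = np.concatenate([c[keep], [c_tau]])
        auc_tau = auc_linuplogdown(t, c)
        return AUCResult(auc_0_t=auc_tau, c_last=float(c[-1]), auc_0_tau=auc_tau)
    auc_t = auc_linuplogdown(t, c)
    extra = c[-1] / lam
    auc_inf = auc_t + extra
    return AUCResult(
        auc_0_t=auc_t, c_last=float(c[-1]), auc_0_inf=auc_inf,
        extrapolated_fraction=extra / auc_inf,
    )


def nca_onecpt(
    profile: PooledProfile,
    fit: TerminalFit,
    route: str,
    multiple: bool = False,
    tau: float | None = None,
) -> OneCptEstimate:
    """CL and Vz from pooled NCA on a dose-normalized profile.

    CL = 1 / AUC per unit dose (AUC_0-inf for single-dose data,
    AUC_0-tau for multiple-dose data); Vz = CL / lambda_z.
    """
    est = OneCptEstimate(method="nca")
    if profile.is_empty or len(profile) < 2:
        est.messages.append("profile too small for AUC")
        return est
    if fit.includes_peak:
        est.messages.append(
            "lambda_z window includes the absorption peak; NCA declined"
        )
        return est
    res = compute_auc(profile, fit, route, multiple, tau)
    auc = res.auc_0_tau if multiple else res.auc_0_inf
    if auc is None or auc <= 0:
        est.messages.append("AUC undefined")
        return est
    if res.extrapolated_fraction is not None and res.extrapolated_fraction >= 0.5:
        est.messages.append(
            f"extrapolated AUC fraction {res.extrapolated_fraction:.2f} >= 0.5"
        )
    est.cl = 1.0 / auc
    est.v = est.cl / fit.lambda_z
    est.v_source = "vd"
    est.n_used = int(profile.n_points.sum())
    return est


def wagner_nelson_ka(profile: PooledProfile, ke: float) -> float | None:
    """Ka by the Wagner-Nelson fraction-absorbed method.

    F(t) = (C_t + ke*AUC_0-t) / (ke*AUC_0-inf) with plain linear-trapezoid
    cumulative AUC; the negative slope of ln(1 - F(t)) over the
    absorption phase (t <= Tmax, 1-F > 0) is Ka.  Returns None when
    fewer than two usable points remain.
    """
    if profile.is_empty or len(profile) < 3:
        return None
    t = profile.tad
    c = profile.conc
    if t[0] > 1e-12:
        t = np.concatenate([[0.0], t])
        c = np.concatenate([[0.0], c])
    cum = np.concatenate([[0.0], np.cumsum(0.5 * (c[1:] + c[:-1]) * np.diff(t))])
    auc_inf = cum[-1] + c[-1] / ke
    if auc_inf <= 0:
        return None
    frac = (c + ke * cum) / (ke * auc_inf)
    f_remaining = 1.0 - frac
    i_max = int(np.argmax(c))
    use = (np.arange(len(t)) <= i_max) & (f_remaining > 0) & (t >= 0)
    use[0] = t[0] > 0  # the synthetic origin carries no information
    if use.sum() < 2:
        return None
    res = stats.linregress(t[use], np.log(f_remaining[use]))
    if res.slope >= 0:
        return None
    return float(-res.slope)
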