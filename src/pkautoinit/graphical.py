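"""Graphical one-compartment methods on pooled first-dose data.

For intravenous data the terminal-phase regression line is extrapolated
to the y-axis: V_extrap = 1/Y_intercept (per unit dose) and
CL = lambda_z * V_extrap.  For extravascular data the method of residuals
(feathering) strips the extrapolated elimination line from the observed
curve; the log-residual slope is Ka and V_d ~ Dose/C_extrap(0) under the
Ka >> Ke assumption.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .dataio import PooledProfile
from .single_point import OneCptEstimate
from .terminal_phase import TerminalFit

__all__ = ["GraphicalEstimate", "graphical_iv", "residuals_ka", "graphical_estimate"]


@dataclass
class GraphicalEstimate:
    """Result of a graphical method (per unit dose)."""

    cl: float | None = None
    v_extrap: float | None = None
    ka: float | None = None
    residual_points: list = field(default_factory=list)


def graphical_iv(profile: PooledProfile, fit: TerminalFit) -> GraphicalEstimate:
    """Extrapolated-intercept method for IV data.

    The intercept of the terminal line at t=0 estimates C(0) per unit
    dose, so V_extrap = 1/exp(beta0) and CL = lambda_z * V_extrap.
    """
    v = 1.0 / math.exp(fit.beta0)
    return GraphicalEstimate(cl=fit.lambda_z * v, v_extrap=v)


def residuals_ka(profile: PooledProfile, fit: TerminalFit) -> GraphicalEstimate:
    """Method of residuals for extravascular data.

    C_residual(t) = C_extrap(t) - C(t) over pre-peak bins (strictly before
    the peak bin, which has zero residual by construction);
    ln C_residual = ln C_0 - Ka*t.  Non-positive residuals are dropped;
    fewer than two remaining points leaves Ka unavailable.
    """
    out = GraphicalEstimate()
    v = 1.0 / math.exp(fit.beta0)  # Dose/C_extrap(0), per unit dose
    out.v_extrap = v
    out.cl = fit.lambda_z * v
    peak_tad = profile.tmax_tad
    pre = profile.tad < peak_tad - 1e-12
    t = profile.tad[pre]
    c = profile.conc[pre]
    c_extrap = np.exp(fit.beta0 - fit.lambda_z * t)
    resid = c_extrap - c
    ok = resid > 0
    out.residual_points = list(zip(t[ok], resid[ok]))
    if ok.sum() < 2:
        return out
    res = stats.linregress(t[ok], np.log(resid[ok]))
    if res.slope >= 0:
        return out
    ka = -float(res.slope)
    if ka > fit.lambda_z:
        out.ka = ka
    return out


def graphical_estimate(
    profile: PooledProfile, fit: TerminalFit, route: str
) -> OneCptEstimate:
    """Package the graphical methods as a Part-1 candidate estimate."""
    est = OneCptEstimate(method="graphical")
    if profile.is_empty:
        est.messages.append("empty first-dose profile")
        return est
    if route == "extravascular":
        g = residuals_ka(profile, fit)
        est.ka = g.ka
        if g.ka is None:
            est.messages.append("method of residuals: < 2 positive residuals")
    else:
        g = graphical_iv(profile, fit)
    est.cl, est.v = g.cl, g.v_extrap
    est.n_used = int(profile.n_points.sum())
    return est
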